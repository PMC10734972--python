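"""Contrast-level network meta-analysis data.

Contrast-level (study-level) data carry one row per pairwise comparison per
study: the estimated log odds ratio ``TE`` of ``treat1`` relative to
``treat2`` and its standard error ``seTE``.  This is the input format of the
fixed-effect NMA fit in :mod:`nmaplan.nma` and the output format of the
arm-level converter below.

Sign convention: ``TE = log-odds(treat1) - log-odds(treat2)``.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "ContrastRecord",
    "ContrastDataset",
    "ArmRecord",
    "ContrastFormatError",
    "ContrastValidationError",
    "read_contrasts",
    "write_contrasts",
    "read_arms",
    "arm_to_contrast",
    "arms_to_contrasts",
]

CONTRAST_COLUMNS = ("studlab", "treat1", "treat2", "TE", "seTE")
ARM_COLUMNS = ("studlab", "treat", "r", "n")


class ContrastFormatError(ValueError):
    """Raised when a CSV file does not have the expected column layout."""


class ContrastValidationError(ValueError):
    """Raised when rows violate the record invariants; lists offending rows."""


@dataclass(frozen=True)
class ContrastRecord:
    """One pairwise comparison from one study.

    Attributes
    ----------
    studlab : str
        Study identifier (opaque).
    treat1, treat2 : str
        Treatment labels; must differ.
    TE : float
        Log odds ratio of ``treat1`` relative to ``treat2``.
    seTE : float
        Standard error of ``TE``; strictly positive.
    """

    studlab: str
    treat1: str
    treat2: str
    TE: float
    seTE: float

    def __post_init__(self) -> None:
        if self.treat1 == self.treat2:
            raise ContrastValidationError(
                f"study {self.studlab!r}: treat1 == treat2 == {self.treat1!r}"
            )
        if not math.isfinite(self.TE):
            raise ContrastValidationError(
                f"study {self.studlab!r}: TE must be finite, got {self.TE!r}"
            )
        if not (math.isfinite(self.seTE) and self.seTE > 0):
            raise ContrastValidationError(
                f"study {self.studlab!r}: seTE must be finite and > 0, got {self.seTE!r}"
            )

    def reversed(self) -> "ContrastRecord":
        """The same comparison with the treatment roles swapped (TE negated)."""
        return replace(self, treat1=self.treat2, treat2=self.treat1, TE=-self.TE)


@dataclass(frozen=True)
class ContrastDataset:
    """An ordered collection of :class:`ContrastRecord`."""

    records: tuple[ContrastRecord, ...]

    def __init__(self, records: Iterable[ContrastRecord]):
        object.__setattr__(self, "records", tuple(records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def treatments(self) -> tuple[str, ...]:
        """Distinct treatment labels, sorted."""
        labels = {t for rec in self.records for t in (rec.treat1, rec.treat2)}
        return tuple(sorted(labels))

    def graph(self) -> nx.MultiGraph:
        """Comparison graph: nodes are treatments, edges are contrast rows."""
        g = nx.MultiGraph()
        g.add_nodes_from(self.treatments)
        for rec in self.records:
            g.add_edge(rec.treat1, rec.treat2, studlab=rec.studlab)
        return g

    def is_connected(self) -> bool:
        return len(self.records) > 0 and nx.is_connected(nx.Graph(self.graph()))

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(nx.Graph(self.graph()))]

    def has_direct_edge(self, a: str, b: str) -> bool:
        return any(
            {rec.treat1, rec.treat2} == {a, b} for rec in self.records
        )

    def with_record(self, record: ContrastRecord) -> "ContrastDataset":
        return ContrastDataset(self.records + (record,))


@dataclass(frozen=True)
class ArmRecord:
    """Arm-level binomial summary: ``r`` events among ``n`` subjects."""

    studlab: str
    treat: str
    r: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ContrastValidationError(
                f"study {self.studlab!r} arm {self.treat!r}: n must be >= 1, got {self.n}"
            )
        if not (0 <= self.r <= self.n):
            raise ContrastValidationError(
                f"study {self.studlab!r} arm {self.treat!r}: need 0 <= r <= n, "
                f"got r={self.r}, n={self.n}"
            )


def _parse_float(value: str, column: str, row_no: int, errors: list[str]) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        errors.append(f"row {row_no}: {column}={value!r} is not a number")
        return math.nan


def read_contrasts(path: str | Path, **dialect) -> ContrastDataset:
    """Read contrast-level data from a CSV file.

    The file must have a header with at least the columns
    ``studlab, treat1, treat2, TE, seTE``; extra columns are ignored with a
    warning.  Treatment labels are whitespace-trimmed and compared as exact
    strings.  Row order is preserved.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, **dialect)
        header = reader.fieldnames or []
        missing = [c for c in CONTRAST_COLUMNS if c not in header]
        if missing:
            raise ContrastFormatError(
                f"{path}: missing required column(s) {missing}; found {header}"
            )
        extra = [c for c in header if c not in CONTRAST_COLUMNS]
        if extra:
            warnings.warn(f"{path}: ignoring extra column(s) {extra}", stacklevel=2)
        records: list[ContrastRecord] = []
        errors: list[str] = []
        for row_no, row in enumerate(reader, start=2):
            te = _parse_float(row["TE"], "TE", row_no, errors)
            se = _parse_float(row["seTE"], "seTE", row_no, errors)
            try:
                records.append(
                    ContrastRecord(
                        studlab=row["studlab"].strip(),
                        treat1=row["treat1"].strip(),
                        treat2=row["treat2"].strip(),
                        TE=te,
                        seTE=se,
                    )
                )
            except ContrastValidationError as exc:
                errors.append(f"row {row_no}: {exc}")
        if errors:
            raise ContrastValidationError(
                f"{path}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors)
            )
    return ContrastDataset(records)


def write_contrasts(dataset: ContrastDataset, path: str | Path) -> None:
    """Write a dataset back to CSV with full ``repr`` float precision.

    ``read_contrasts(write_contrasts(ds)) == ds`` holds exactly: Python float
    repr round-trips through ``float()``.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CONTRAST_COLUMNS)
        for rec in dataset:
            writer.writerow([rec.studlab, rec.treat1, rec.treat2, repr(rec.TE), repr(rec.seTE)])


def read_arms(path: str | Path, **dialect) -> list[ArmRecord]:
    """Read arm-level data (columns ``studlab, treat, r, n``) from CSV."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, **dialect)
        header = reader.fieldnames or []
        missing = [c for c in ARM_COLUMNS if c not in header]
        if missing:
            raise ContrastFormatError(
                f"{path}: missing required column(s) {missing}; found {header}"
            )
        arms: list[ArmRecord] = []
        errors: list[str] = []
        for row_no, row in enumerate(reader, start=2):
            try:
                arms.append(
                    ArmRecord(
                        studlab=row["studlab"].strip(),
                        treat=row["treat"].strip(),
                        r=int(row["r"]),
                        n=int(row["n"]),
                    )
                )
            except (ValueError, ContrastValidationError) as exc:
                errors.append(f"row {row_no}: {exc}")
        if errors:
            raise ContrastValidationError(
                f"{path}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors)
            )
    return arms


def arm_to_contrast(arm1: ArmRecord, arm2: ArmRecord) -> ContrastRecord:
    """Wald log odds ratio (and SE) of ``arm1`` relative to ``arm2``.

    ``TE = log[(r1/(n1-r1)) / (r2/(n2-r2))]`` and
    ``seTE = sqrt(1/r1 + 1/(n1-r1) + 1/r2 + 1/(n2-r2))``.

    If any of the four cells of the 2x2 table is zero, 0.5 is added to all
    four cells first (Haldane–Anscombe continuity correction).
    """
    if arm1.studlab != arm2.studlab:
        raise ValueError(
            f"arms belong to different studies: {arm1.studlab!r} vs {arm2.studlab!r}"
        )
    cells = [
        float(arm1.r),
        float(arm1.n - arm1.r),
        float(arm2.r),
        float(arm2.n - arm2.r),
    ]
    if any(c == 0 for c in cells):
        cells = [c + 0.5 for c in cells]
    a, b, c, d = cells
    te = math.log(a / b) - math.log(c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ContrastRecord(
        studlab=arm1.studlab, treat1=arm1.treat, treat2=arm2.treat, TE=te, seTE=se
    )


def arms_to_contrasts(arms: Sequence[ArmRecord]) -> ContrastDataset:
    """Convert arm-level data to contrasts, all pairwise contrasts per study.

    Arms are grouped by ``studlab`` (first-appearance order preserved); a
    study with k arms yields k*(k-1)/2 contrast rows sharing its studlab.
    """
    by_study: dict[str, list[ArmRecord]] = {}
    for arm in arms:
        by_study.setdefault(arm.studlab, []).append(arm)
    records = []
    for study_arms in by_study.values():
        if len(study_arms) < 2:
            raise ContrastValidationError(
                f"study {study_arms[0].studlab!r} has a single arm; need >= 2"
            )
        for a1, a2 in combinations(study_arms, 2):
            records.append(arm_to_contrast(a1, a2))
    return ContrastDataset(records)
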