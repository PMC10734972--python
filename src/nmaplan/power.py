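"""Closed-form variance and power formulas for the planned two-arm trial.

A new trial compares treatments 1 and 2 with event risks ``p1``/``p2`` and
group sizes ``n1``/``n2``.  The Wald variance of the trial's log odds ratio
is

    var_trial = 1/(n1 p1 q1) + 1/(n2 p2 q2),        q = 1 - p.

If the trial will be analysed jointly with an existing network
meta-analysis whose indirect A-vs-B estimate has standard error
``enma_sigma``, the precisions add:

    var_updated = (1/var_trial + 1/enma_sigma**2)**-1.

Power of the two-sided z-test of H0: lor = 0 at level alpha is

    Power = Phi(lor/sd - z_{1-alpha/2}) + Phi(-lor/sd - z_{1-alpha/2}),

with ``sd`` the "without" (trial-only) or "with" (combined) standard
deviation.  Risks and ``enma_sigma`` are treated as known plug-in values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import ndtr, ndtri

__all__ = [
    "DesignInput",
    "Allocation",
    "lor_from_risks",
    "risk_from_lor",
    "trial_variance",
    "combined_variance",
    "power",
    "design_sd",
]


def _check_risk(p: float, name: str) -> None:
    if not (0.0 < p < 1.0) or not math.isfinite(p):
        raise ValueError(f"{name} must lie strictly in (0, 1), got {p!r}")


@dataclass(frozen=True)
class Allocation:
    """Group sizes of the planned trial."""

    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError(f"group sizes must be >= 1, got ({self.n1}, {self.n2})")

    @property
    def total(self) -> int:
        return self.n1 + self.n2


@dataclass(frozen=True)
class DesignInput:
    """The design problem statement.

    Parameters
    ----------
    p1, p2 : float
        Event risks of treatments 1 and 2, strictly in (0, 1).
    enma_sigma : float, optional
        SE of the treatment-1 vs treatment-2 estimate from the existing
        network; required (and > 0) when ``method="with"``.
    sig_level : float
        Two-sided significance level, default 0.05.
    method : {"with", "without"}
        Analyse the new trial jointly with the existing network, or alone.
    allocation : {"uneven", "even"}
        Variance-minimising split vs equal group sizes.
    """

    p1: float
    p2: float
    enma_sigma: float | None = None
    sig_level: float = 0.05
    method: str = "with"
    allocation: str = "uneven"

    def __post_init__(self) -> None:
        _check_risk(self.p1, "p1")
        _check_risk(self.p2, "p2")
        if not (0.0 < self.sig_level < 1.0):
            raise ValueError(f"sig_level must lie in (0, 1), got {self.sig_level!r}")
        if self.method not in ("with", "without"):
            raise ValueError(f"method must be 'with' or 'without', got {self.method!r}")
        if self.allocation not in ("uneven", "even"):
            raise ValueError(
                f"allocation must be 'uneven' or 'even', got {self.allocation!r}"
            )
        if self.method == "with":
            if self.enma_sigma is None or not (
                math.isfinite(self.enma_sigma) and self.enma_sigma > 0
            ):
                raise ValueError(
                    "enma_sigma must be a positive number when method='with', "
                    f"got {self.enma_sigma!r}"
                )

    @property
    def lor(self) -> float:
        """Design log odds ratio of treatment 2 relative to treatment 1."""
        return lor_from_risks(self.p1, self.p2)


def lor_from_risks(p1: float, p2: float) -> float:
    """Log odds ratio of treatment 2 relative to treatment 1.

    ``log[p2/(1-p2)] - log[p1/(1-p1)]``.
    """
    _check_risk(p1, "p1")
    _check_risk(p2, "p2")
    return math.log(p2 / (1.0 - p2)) - math.log(p1 / (1.0 - p1))


def risk_from_lor(p_ref, lor: float):
    """Risk of a target treatment given a reference risk and a log odds ratio.

    ``lor`` is oriented reference-minus-target on the log-odds scale, i.e.
    ``odds(target) = odds(ref) / exp(lor)``; hence

        p = p_ref / (p_ref + exp(lor) * (1 - p_ref)).

    Accepts scalars or numpy arrays for ``p_ref``.
    """
    import numpy as np

    p_ref_arr = np.asarray(p_ref, dtype=float)
    if np.any(p_ref_arr <= 0.0) or np.any(p_ref_arr >= 1.0):
        raise ValueError(f"p_ref must lie strictly in (0, 1), got {p_ref!r}")
    out = p_ref_arr / (p_ref_arr + np.exp(lor) * (1.0 - p_ref_arr))
    return float(out) if np.isscalar(p_ref) or out.ndim == 0 else out


def trial_variance(p1: float, p2: float, alloc: Allocation) -> float:
    """Wald variance of the new trial's log odds ratio (trial alone)."""
    _check_risk(p1, "p1")
    _check_risk(p2, "p2")
    return 1.0 / (alloc.n1 * p1 * (1.0 - p1)) + 1.0 / (alloc.n2 * p2 * (1.0 - p2))


def combined_variance(var_trial: float, enma_sigma: float) -> float:
    """Variance of the updated estimate: precisions of trial and network add."""
    if not (var_trial > 0):
        raise ValueError(f"var_trial must be > 0, got {var_trial!r}")
    if not (enma_sigma > 0):
        raise ValueError(f"enma_sigma must be > 0, got {enma_sigma!r}")
    return 1.0 / (1.0 / var_trial + 1.0 / enma_sigma**2)


def power(lor: float, sd: float, sig_level: float = 0.05) -> float:
    """Two-sided rejection probability of the z-test under effect ``lor``.

    ``Phi(lor/sd - z) + Phi(-lor/sd - z)`` with ``z = z_{1 - sig_level/2}``.
    At ``lor = 0`` this equals ``sig_level`` exactly.
    """
    if not (sd > 0):
        raise ValueError(f"sd must be > 0, got {sd!r}")
    if not (0.0 < sig_level < 1.0):
        raise ValueError(f"sig_level must lie in (0, 1), got {sig_level!r}")
    z = ndtri(1.0 - sig_level / 2.0)
    shift = lor / sd
    return float(ndtr(shift - z) + ndtr(-shift - z))


def design_sd(inp: DesignInput, alloc: Allocation) -> float:
    """Standard deviation entering the power formula at a given allocation.

    ``method="without"``: sqrt of the trial-only Wald variance.
    ``method="with"``: sqrt of the precision-combined trial+network variance.
    """
    v = trial_variance(inp.p1, inp.p2, alloc)
    if inp.method == "with":
        v = combined_variance(v, inp.enma_sigma)
    return math.sqrt(v)
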