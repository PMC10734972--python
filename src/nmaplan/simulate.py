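"""Monte-Carlo validation of the power formulas and design solvers.

Two protocols, both built around a synthetic connected network of
binomial-outcome trials (stand-in for a real arm-level NMA dataset, which
is rarely published):

* Protocol I (fixed total N): per replicate, redraw every arm's event count
  from its binomial law, refit the fixed-effect NMA, simulate the planned
  A-vs-B trial at the optimal and at the even split of N, analyse it alone
  and jointly with the refitted network, and record rejection indicators,
  formula powers and SEs.  The averaged simulation power should agree with
  the averaged formula power.

* Protocol II (target power): per replicate, solve the minimum-sample-size
  problem (uneven and even variants) for the with-network analysis at the
  target power using the replicate's refitted network SE, then simulate and
  analyse as above; additionally records the average group sizes.

The planned pair must have no direct comparison in the network.  The
"logistic regression" analysis of a simulated 2x2 trial is the closed-form
Wald log odds ratio (identical coefficient and SE).  One root seed drives
per-replicate child streams, so allocation strategies within a replicate
share the same resampled network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _dc_replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .contrasts import ArmRecord, ContrastDataset, ContrastRecord, arms_to_contrasts
from .design import ssnma
from .nma import fit_nma, update_network
from .power import (
    Allocation,
    DesignInput,
    combined_variance,
    power,
    risk_from_lor,
    trial_variance,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticNetworkSpec",
    "SimulationScenario",
    "SimulationSummary",
    "example_network_spec",
    "generate_network",
    "resample_network",
    "simulate_new_trial",
    "run_simulation_I",
    "run_simulation_II",
]


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """A synthetic network: per-treatment risks plus a study layout.

    ``studies`` lists ``(treatments, n_per_arm)`` pairs; every arm of a
    study has ``n_per_arm`` subjects (>= 2).  The resulting comparison
    graph must be connected.
    """

    risks: Mapping[str, float]
    studies: Sequence[tuple[tuple[str, ...], int]]
    seed: int = 0

    def __post_init__(self) -> None:
        for t, p in self.risks.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"risk of {t!r} must lie in (0, 1), got {p}")
        seen: set[str] = set()
        for treats, n in self.studies:
            if len(treats) < 2:
                raise ValueError(f"study {treats} needs >= 2 arms")
            if n < 2:
                raise ValueError(f"study {treats}: arm size must be >= 2, got {n}")
            for t in treats:
                if t not in self.risks:
                    raise ValueError(f"study treatment {t!r} has no risk defined")
            seen.update(treats)
        missing = set(self.risks) - seen
        if missing:
            raise ValueError(f"treatment(s) {sorted(missing)} appear in no study")
        if not self._arm_template_connected():
            raise ValueError("study layout gives a disconnected comparison graph")

    def _arm_template_connected(self) -> bool:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.risks)
        for treats, _ in self.studies:
            for i in range(len(treats) - 1):
                g.add_edge(treats[i], treats[i + 1])
        return nx.is_connected(g)

    def arm_template(self) -> list[tuple[str, str, int]]:
        """``(studlab, treat, n)`` triples, one per arm."""
        return [
            (f"s{k + 1}", t, n)
            for k, (treats, n) in enumerate(self.studies)
            for t in treats
        ]

    def has_direct_edge(self, a: str, b: str) -> bool:
        return any({a, b} <= set(treats) for treats, _ in self.studies)


def example_network_spec(seed: int = 0) -> SyntheticNetworkSpec:
    """A small star network shaped like a disease-treatment NMA.

    Four treatments around a high-risk untreated control (risk 0.68, the
    kind of baseline seen in feedlot respiratory-disease networks), with
    active-treatment risks near 0.19-0.30 and 150 subjects per arm; the
    planned pair A-B is connected only indirectly through the control, and
    its indirect SE comes out near 0.22.
    """
    risks = {"NAC": 0.68, "A": 0.1869, "B": 0.2367, "C": 0.30}
    studies = (
        (("NAC", "A"), 150),
        (("NAC", "A"), 150),
        (("NAC", "A"), 150),
        (("NAC", "B"), 150),
        (("NAC", "B"), 150),
        (("NAC", "B"), 150),
        (("NAC", "C"), 150),
        (("NAC", "C"), 150),
    )
    return SyntheticNetworkSpec(risks=risks, studies=studies, seed=seed)


def _draw_arms(
    template: Iterable[tuple[str, str, int]],
    risks: Mapping[str, float],
    rng: np.random.Generator,
) -> list[ArmRecord]:
    return [
        ArmRecord(studlab=s, treat=t, r=int(rng.binomial(n, risks[t])), n=n)
        for s, t, n in template
    ]


def generate_network(
    spec: SyntheticNetworkSpec, seed: int | None = None
) -> tuple[list[ArmRecord], ContrastDataset]:
    """Draw one arm-level realisation of the spec and its contrasts."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    arms = _draw_arms(spec.arm_template(), spec.risks, rng)
    return arms, arms_to_contrasts(arms)


def resample_network(
    arms: Sequence[ArmRecord],
    risks: Mapping[str, float],
    rng: np.random.Generator | int,
) -> tuple[list[ArmRecord], ContrastDataset]:
    """Redraw every arm's event count, keeping study structure and sizes."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    missing = {a.treat for a in arms} - set(risks)
    if missing:
        raise ValueError(f"no risk defined for treatment(s) {sorted(missing)}")
    new_arms = _draw_arms(((a.studlab, a.treat, a.n) for a in arms), risks, rng)
    return new_arms, arms_to_contrasts(new_arms)


def _draw_trial(
    p1: float,
    p2: float,
    alloc: Allocation,
    rng: np.random.Generator,
    studlab: str,
    treat1: str,
    treat2: str,
) -> tuple[ContrastRecord, bool]:
    """Draw the planned trial; also report whether a cell was zero."""
    from .contrasts import arm_to_contrast

    arm1 = ArmRecord(studlab, treat1, int(rng.binomial(alloc.n1, p1)), alloc.n1)
    arm2 = ArmRecord(studlab, treat2, int(rng.binomial(alloc.n2, p2)), alloc.n2)
    corrected = 0 in (arm1.r, arm1.n - arm1.r, arm2.r, arm2.n - arm2.r)
    return arm_to_contrast(arm1, arm2), corrected


def simulate_new_trial(
    p1: float,
    p2: float,
    alloc: Allocation,
    rng: np.random.Generator | int,
    *,
    studlab: str = "new",
    treat1: str = "1",
    treat2: str = "2",
) -> ContrastRecord:
    """Simulate the planned two-arm trial and analyse it in isolation.

    Draws ``r_i ~ Binomial(n_i, p_i)`` and returns the Wald log odds ratio
    of ``treat1`` relative to ``treat2`` with its SE (zero cells continuity
    corrected).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rec, _ = _draw_trial(p1, p2, alloc, rng, studlab, treat1, treat2)
    return rec


@dataclass(frozen=True)
class SimulationScenario:
    """One protocol scenario for the planned ``treat_a`` vs ``treat_b`` trial.

    ``lor`` is the design effect of B relative to A on the log-odds scale;
    B's risk is recomputed from A's risk and ``lor``.  Exactly one of
    ``n_total`` (protocol I) / ``power_level`` (protocol II) applies.
    """

    treat_a: str
    treat_b: str
    lor: float
    n_total: int | None = None
    power_level: float | None = None
    n_reps: int = 2000
    seed: int = 0
    sig_level: float = 0.05

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if (self.n_total is None) == (self.power_level is None):
            raise ValueError("specify exactly one of n_total / power_level")
        if self.power_level is not None and self.lor == 0.0:
            raise ValueError("target-power mode requires lor != 0")


@dataclass(frozen=True)
class SimulationSummary:
    """Averages over replicates, mirroring the four reported metrics."""

    n_reps: int
    sim_power_with: float
    formula_power_with: float
    sim_se_with: float
    formula_se_with: float
    sim_power_without: float
    formula_power_without: float
    sim_se_without: float
    formula_se_without: float
    mean_n1: float
    mean_n2: float
    zero_cell_rate: float = 0.0

    @property
    def mean_total(self) -> float:
        return self.mean_n1 + self.mean_n2


class _Accumulator:
    __slots__ = (
        "rej_with", "rej_without", "se_with", "se_without",
        "fp_with", "fp_without", "fse_with", "fse_without",
        "n1", "n2", "count",
    )

    def __init__(self) -> None:
        for name in self.__slots__:
            setattr(self, name, 0.0)

    def add(
        self, *, rec: ContrastRecord, upd_te: float, upd_se: float,
        crit: float, pa: float, pb: float, sigma: float, lor: float,
        alloc: Allocation, sig_level: float,
    ) -> None:
        v_trial = trial_variance(pa, pb, alloc)
        sd_without = v_trial**0.5
        sd_with = combined_variance(v_trial, sigma) ** 0.5
        self.rej_without += abs(rec.TE / rec.seTE) > crit
        self.rej_with += abs(upd_te / upd_se) > crit
        self.se_without += rec.seTE
        self.se_with += upd_se
        self.fp_without += power(lor, sd_without, sig_level)
        self.fp_with += power(lor, sd_with, sig_level)
        self.fse_without += sd_without
        self.fse_with += sd_with
        self.n1 += alloc.n1
        self.n2 += alloc.n2
        self.count += 1

    def summary(self) -> SimulationSummary:
        k = self.count
        return SimulationSummary(
            n_reps=int(k),
            sim_power_with=self.rej_with / k,
            formula_power_with=self.fp_with / k,
            sim_se_with=self.se_with / k,
            formula_se_with=self.fse_with / k,
            sim_power_without=self.rej_without / k,
            formula_power_without=self.fp_without / k,
            sim_se_without=self.se_without / k,
            formula_se_without=self.fse_without / k,
            mean_n1=self.n1 / k,
            mean_n2=self.n2 / k,
        )


def _prepare(spec: SyntheticNetworkSpec, scenario: SimulationScenario):
    if spec.has_direct_edge(scenario.treat_a, scenario.treat_b):
        raise ValueError(
            f"{scenario.treat_a!r} and {scenario.treat_b!r} have a direct "
            "comparison in the network; the protocol requires an indirect pair"
        )
    risks = dict(spec.risks)
    pa = risks[scenario.treat_a]
    # effect of B relative to A: odds(B) = odds(A) * exp(lor)
    pb = risk_from_lor(pa, -scenario.lor)
    risks[scenario.treat_b] = pb
    return risks, pa, pb, spec.arm_template()


def _zcrit(sig_level: float) -> float:
    from scipy.special import ndtri

    return float(ndtri(1.0 - sig_level / 2.0))


def run_simulation_I(
    spec: SyntheticNetworkSpec, scenario: SimulationScenario
) -> dict[str, SimulationSummary]:
    """Protocol I: power at a fixed total N, optimal vs even split.

    Returns summaries keyed ``"optimal"`` and ``"even"``.
    """
    if scenario.n_total is None:
        raise ValueError("protocol I needs a scenario with n_total set")
    from .design import optimal_split

    risks, pa, pb, template = _prepare(spec, scenario)
    n = scenario.n_total
    allocations = {
        "optimal": optimal_split(pa, pb, n) if pa != pb else Allocation(n // 2, n - n // 2),
        "even": Allocation(n // 2, n - n // 2),
    }
    crit = _zcrit(scenario.sig_level)
    acc = {name: _Accumulator() for name in allocations}
    zero_cell = {name: 0 for name in allocations}
    for child in np.random.SeedSequence(scenario.seed).spawn(scenario.n_reps):
        rng = np.random.default_rng(child)
        _, contrasts = resample_network(
            [ArmRecord(s, t, 0, size) for s, t, size in template], risks, rng
        )
        est = fit_nma(contrasts)
        sigma = est.se(scenario.treat_a, scenario.treat_b)
        for name, alloc in allocations.items():
            rec, corrected = _draw_trial(
                pa, pb, alloc, rng, "new", scenario.treat_a, scenario.treat_b
            )
            zero_cell[name] += corrected
            upd = update_network(contrasts, rec)
            acc[name].add(
                rec=rec,
                upd_te=upd.te(scenario.treat_a, scenario.treat_b),
                upd_se=upd.se(scenario.treat_a, scenario.treat_b),
                crit=crit, pa=pa, pb=pb, sigma=sigma,
                lor=scenario.lor, alloc=alloc, sig_level=scenario.sig_level,
            )
    out = {}
    for name in allocations:
        s = acc[name].summary()
        rate = zero_cell[name] / scenario.n_reps
        if rate:
            logger.info("scenario lor=%s N=%s %s: continuity correction in %.2f%% of replicates",
                        scenario.lor, n, name, 100 * rate)
        out[name] = _dc_replace(s, zero_cell_rate=rate)
    return out


def run_simulation_II(
    spec: SyntheticNetworkSpec, scenario: SimulationScenario
) -> dict[str, SimulationSummary]:
    """Protocol II: minimum sample size at a target with-network power.

    Per replicate the solver uses the replicate's refitted network SE, so
    the group sizes vary; summaries include their means, keyed
    ``"optimal"`` (uneven) and ``"even"``.
    """
    if scenario.power_level is None:
        raise ValueError("protocol II needs a scenario with power_level set")
    risks, pa, pb, template = _prepare(spec, scenario)
    crit = _zcrit(scenario.sig_level)
    acc = {"optimal": _Accumulator(), "even": _Accumulator()}
    zero_cell = {"optimal": 0, "even": 0}
    for child in np.random.SeedSequence(scenario.seed).spawn(scenario.n_reps):
        rng = np.random.default_rng(child)
        _, contrasts = resample_network(
            [ArmRecord(s, t, 0, size) for s, t, size in template], risks, rng
        )
        est = fit_nma(contrasts)
        sigma = est.se(scenario.treat_a, scenario.treat_b)
        for name, alloc_mode in (("optimal", "uneven"), ("even", "even")):
            sol = ssnma(
                DesignInput(
                    p1=pa, p2=pb, enma_sigma=sigma,
                    sig_level=scenario.sig_level, method="with",
                    allocation=alloc_mode,
                ),
                scenario.power_level,
            )
            alloc = Allocation(sol.n1, sol.n2)
            rec, corrected = _draw_trial(
                pa, pb, alloc, rng, "new", scenario.treat_a, scenario.treat_b
            )
            zero_cell[name] += corrected
            upd = update_network(contrasts, rec)
            acc[name].add(
                rec=rec,
                upd_te=upd.te(scenario.treat_a, scenario.treat_b),
                upd_se=upd.se(scenario.treat_a, scenario.treat_b),
                crit=crit, pa=pa, pb=pb, sigma=sigma,
                lor=scenario.lor, alloc=alloc, sig_level=scenario.sig_level,
            )
    out = {}
    for name in acc:
        s = acc[name].summary()
        rate = zero_cell[name] / scenario.n_reps
        if rate:
            logger.info("scenario lor=%s target=%s %s: continuity correction in %.2f%% of replicates",
                        scenario.lor, scenario.power_level, name, 100 * rate)
        out[name] = _dc_replace(s, zero_cell_rate=rate)
    return out


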