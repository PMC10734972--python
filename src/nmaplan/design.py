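"""The two optimal-design problems.

``ssanma`` — maximise power at a fixed total sample size N: minimise the
trial variance ``a/n1 + b/n2`` (``a = 1/(p1 q1)``, ``b = 1/(p2 q2)``)
subject to ``n1 + n2 = N``.  The continuous Lagrange optimum is
``n1* = N sqrt(a) / (sqrt(a) + sqrt(b))``; the objective is strictly convex
in ``n1``, so the integer optimum is the better of floor/ceil of ``n1*``.
The optimal split does not depend on whether the trial will be analysed
with or without the network (the network term is an additive constant in
precision), so the same allocation serves both methods.

``ssnma`` — minimise total N subject to power >= a target: the target power
is converted to a required standard deviation by root-finding on the full
two-term power formula, to a required trial variance (subtracting the
network precision when analysing with the network), and then to per-group
sizes via the continuous Lagrange solution

    n1* = sqrt(a) (sqrt(a) + sqrt(b)) / var_req,
    n2* = sqrt(b) (sqrt(a) + sqrt(b)) / var_req,

taking each ceiling independently (even mode: one group size
``ceil((a + b) / var_req)``).  Independent ceilings guarantee the power
constraint but can exceed the exact integer minimum total by up to two
subjects; this rounding convention is kept deliberately because it is the
one the published worked examples follow.  ``oracle_grid`` provides the
exact exhaustive-search optimum for cross-checking.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .power import Allocation, DesignInput, design_sd, power

__all__ = [
    "DesignSolution",
    "InfeasibleDesignError",
    "required_sd",
    "optimal_split",
    "ssanma",
    "ssnma",
    "oracle_grid",
]


class InfeasibleDesignError(ValueError):
    """The design problem has no solution (e.g. zero effect size)."""


@dataclass(frozen=True)
class DesignSolution:
    """An integer allocation with its achieved power and design SD."""

    n1: int
    n2: int
    power: float
    sd: float
    method: str
    allocation: str
    degenerate: bool = False

    @property
    def total(self) -> int:
        return self.n1 + self.n2

    def to_json(self, path: str | Path | None = None, **inputs) -> str:
        payload = {
            "n1": self.n1,
            "n2": self.n2,
            "power": self.power,
            "sd": self.sd,
            "method": self.method,
            "allocation": self.allocation,
            "degenerate": self.degenerate,
        }
        if inputs:
            payload["inputs"] = inputs
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _ab(p1: float, p2: float) -> tuple[float, float]:
    return 1.0 / (p1 * (1.0 - p1)), 1.0 / (p2 * (1.0 - p2))


def required_sd(lor: float, power_level: float, sig_level: float = 0.05) -> float:
    """Standard deviation at which the two-sided test attains the target power.

    Solves ``power(lor, sd, sig_level) == power_level`` for ``sd`` by
    root-finding on the full two-term formula (power is strictly decreasing
    in ``sd`` for ``lor != 0``).
    """
    if lor == 0.0:
        raise InfeasibleDesignError("lor = 0: no sample size attains power above alpha")
    if not (sig_level < power_level < 1.0):
        raise InfeasibleDesignError(
            f"target power must lie in (sig_level, 1), got {power_level!r}"
        )
    mag = abs(lor)
    lo, hi = 1e-8 * mag, 1e8 * mag
    return brentq(
        lambda s: power(mag, s, sig_level) - power_level, lo, hi, xtol=1e-15, rtol=1e-14
    )


def optimal_split(p1: float, p2: float, n_total: int) -> Allocation:
    """Variance-minimising integer split of a fixed total sample size.

    Evaluates the floor/ceil neighbours of the continuous optimum and keeps
    the lower-variance one; on an exact tie the extra subject goes to the
    higher-variance arm (the one with the smaller ``p(1-p)``), preferring
    group 1 if both arms are equally variable.
    """
    if n_total < 2:
        raise InfeasibleDesignError(f"total sample size must be >= 2, got {n_total}")
    a, b = _ab(p1, p2)
    sa, sb = math.sqrt(a), math.sqrt(b)
    n1_star = n_total * sa / (sa + sb)
    candidates = {
        int(min(max(math.floor(n1_star), 1), n_total - 1)),
        int(min(max(math.ceil(n1_star), 1), n_total - 1)),
    }

    def objective(n1: int) -> float:
        return a / n1 + b / (n_total - n1)

    best = None
    for n1 in sorted(candidates):
        f = objective(n1)
        if best is None or f < best[0] - 1e-15 * abs(best[0]):
            best = (f, n1)
        elif abs(f - best[0]) <= 1e-15 * abs(best[0]):
            # tie: prefer the larger n1 iff arm 1 is (weakly) the
            # higher-variance arm, i.e. p1 q1 <= p2 q2  <=>  a >= b
            if a >= b:
                best = (f, max(best[1], n1))
            else:
                best = (f, min(best[1], n1))
    return Allocation(best[1], n_total - best[1])


def ssanma(inp: DesignInput, n_total: int) -> DesignSolution:
    """Best allocation of a fixed total N, with the achieved power.

    ``allocation="uneven"`` uses the variance-minimising split;
    ``allocation="even"`` splits equally (N must be even).  The allocation
    itself is method-independent; the reported power is evaluated under the
    requested analysis method.
    """
    if inp.allocation == "even":
        if n_total % 2 != 0:
            raise InfeasibleDesignError(
                f"even allocation requires an even total, got N={n_total}"
            )
        alloc = Allocation(n_total // 2, n_total // 2)
    else:
        alloc = optimal_split(inp.p1, inp.p2, n_total)
    sd = design_sd(inp, alloc)
    return DesignSolution(
        n1=alloc.n1,
        n2=alloc.n2,
        power=power(inp.lor, sd, inp.sig_level),
        sd=sd,
        method=inp.method,
        allocation=inp.allocation,
    )


def ssnma(inp: DesignInput, power_level: float) -> DesignSolution:
    """Smallest trial (by the closed-form rounding rule) reaching a target power.

    See the module docstring for the rounding convention.  If the existing
    network alone already meets the target (``method="with"`` and the
    required overall precision is below the network's), the problem is
    degenerate: the minimum allocation (1, 1) is returned with
    ``degenerate=True`` and a warning.
    """
    lor = inp.lor
    if lor == 0.0:
        raise InfeasibleDesignError(
            "p1 == p2 gives lor = 0: the target power is unattainable"
        )
    sd_req = required_sd(lor, power_level, inp.sig_level)
    prec_req = 1.0 / sd_req**2
    if inp.method == "with":
        prec_req -= 1.0 / inp.enma_sigma**2
        if prec_req <= 0.0:
            warnings.warn(
                "the existing network alone already attains the target power; "
                "returning the minimum allocation (1, 1)",
                stacklevel=2,
            )
            alloc = Allocation(1, 1)
            sd = design_sd(inp, alloc)
            return DesignSolution(
                n1=1,
                n2=1,
                power=power(lor, sd, inp.sig_level),
                sd=sd,
                method=inp.method,
                allocation=inp.allocation,
                degenerate=True,
            )
    var_req = 1.0 / prec_req
    a, b = _ab(inp.p1, inp.p2)
    if inp.allocation == "even":
        n = math.ceil((a + b) / var_req)
        alloc = Allocation(n, n)
    else:
        sa, sb = math.sqrt(a), math.sqrt(b)
        alloc = Allocation(
            math.ceil(sa * (sa + sb) / var_req), math.ceil(sb * (sa + sb) / var_req)
        )
    sd = design_sd(inp, alloc)
    return DesignSolution(
        n1=alloc.n1,
        n2=alloc.n2,
        power=power(lor, sd, inp.sig_level),
        sd=sd,
        method=inp.method,
        allocation=inp.allocation,
    )


def _power_at(inp: DesignInput, n1, n2):
    """Vectorised power over integer allocation arrays."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    a, b = _ab(inp.p1, inp.p2)
    v = a / n1 + b / n2
    if inp.method == "with":
        v = 1.0 / (1.0 / v + 1.0 / inp.enma_sigma**2)
    from scipy.special import ndtr, ndtri

    z = ndtri(1.0 - inp.sig_level / 2.0)
    shift = inp.lor / np.sqrt(v)
    return ndtr(shift - z) + ndtr(-shift - z)


def oracle_grid(
    inp: DesignInput,
    objective: str,
    *,
    power_level: float | None = None,
    n_total: int | None = None,
    n1_max: int | None = None,
) -> DesignSolution:
    """Exact optimum by exhaustive enumeration; the brute-force cross-check.

    ``objective="max_power_at_N"`` enumerates every split of ``n_total``.
    ``objective="min_total_at_power"`` enumerates ``n1`` and, per ``n1``,
    computes the minimal feasible ``n2`` directly (power is strictly
    increasing in ``n2``), keeping the smallest total.  Ties (equal totals /
    equal power) are broken toward the allocation giving more subjects to
    the higher-variance arm, as in the solvers.  Intended for testing.
    """
    a, b = _ab(inp.p1, inp.p2)
    if objective == "max_power_at_N":
        if n_total is None or n_total < 2:
            raise InfeasibleDesignError("max_power_at_N requires n_total >= 2")
        if inp.allocation == "even":
            if n_total % 2 != 0:
                raise InfeasibleDesignError("even allocation with odd total")
            n1 = np.array([n_total // 2])
        else:
            n1 = np.arange(1, n_total)
        pw = _power_at(inp, n1, n_total - n1)
        best_pw = pw.max()
        tied = n1[pw >= best_pw - 1e-15]
        # power can tie (saturation near 1, or lor = 0 where every split has
        # power alpha); maximum power at fixed N is minimum variance, so
        # break ties on the variance objective itself
        var = a / tied + b / (n_total - tied)
        tied = tied[var <= var.min() * (1 + 1e-14)]
        n1_best = int(tied.max() if a >= b else tied.min())
        alloc = Allocation(n1_best, n_total - n1_best)
    elif objective == "min_total_at_power":
        if power_level is None:
            raise InfeasibleDesignError("min_total_at_power requires power_level")
        if inp.lor == 0.0:
            raise InfeasibleDesignError("lor = 0 is infeasible")
        sd_req = required_sd(abs(inp.lor), power_level, inp.sig_level)
        prec_req = 1.0 / sd_req**2
        if inp.method == "with":
            prec_req -= 1.0 / inp.enma_sigma**2
            if prec_req <= 0.0:
                alloc = Allocation(1, 1)
                sd = design_sd(inp, alloc)
                return DesignSolution(
                    1, 1, power(inp.lor, sd, inp.sig_level), sd,
                    inp.method, inp.allocation, degenerate=True,
                )
        var_req = 1.0 / prec_req
        if inp.allocation == "even":
            n = math.ceil((a + b) / var_req)
            while n > 1 and _power_at(inp, n - 1, n - 1) >= power_level:
                n -= 1
            alloc = Allocation(n, n)
        else:
            # n1 must exceed a/var_req for any finite n2 to be feasible
            n1_lo = math.floor(a / var_req) + 1
            if n1_max is None:
                # the total n1 + n2(n1) is convex with its minimum at the
                # continuous optimum; 3x that plus slack safely brackets it
                sa, sb = math.sqrt(a), math.sqrt(b)
                n1_max = max(3 * math.ceil(sa * (sa + sb) / var_req) + 10, n1_lo + 10)
            if n1_lo > n1_max:
                raise InfeasibleDesignError(
                    f"search bound n1_max={n1_max} below the feasible region"
                )
            n1 = np.arange(n1_lo, n1_max + 1)
            slack = var_req - a / n1
            n2 = np.ceil(b / slack - 1e-12).astype(int)
            n2 = np.maximum(n2, 1)
            # guard the ceiling against float error in both directions
            infeas = _power_at(inp, n1, n2) < power_level
            n2[infeas] += 1
            down_ok = (n2 > 1) & (
                _power_at(inp, n1, np.maximum(n2 - 1, 1)) >= power_level
            )
            n2[down_ok] -= 1
            totals = n1 + n2
            best_total = totals.min()
            tied_n1 = n1[totals == best_total]
            n1_best = int(tied_n1.max() if a >= b else tied_n1.min())
            alloc = Allocation(n1_best, int(best_total - n1_best))
    else:
        raise ValueError(f"unknown objective {objective!r}")
    sd = design_sd(inp, alloc)
    return DesignSolution(
        n1=alloc.n1,
        n2=alloc.n2,
        power=power(inp.lor, sd, inp.sig_level),
        sd=sd,
        method=inp.method,
        allocation=inp.allocation,
    )
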