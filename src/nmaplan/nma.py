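"""Fixed-effect contrast-based network meta-analysis.

The model: each contrast row is an independent normal observation
``y ~ N(X mu, S)`` where ``mu`` is the vector of basic parameters (log odds
ratio of each non-baseline treatment versus the baseline), ``X`` maps basic
parameters to observed comparisons under the consistency assumption
(``mu_BC = mu_AC - mu_AB``) and ``S = diag(seTE^2)``.  The estimator is
weighted least squares,

    mu_hat = (X' S^-1 X)^-1 X' S^-1 y,     Var(mu_hat) = (X' S^-1 X)^-1,

computed here via a QR factorisation of the weighted design rather than an
explicit inverse.  Every pairwise effect and its SE follow as linear
combinations of ``mu_hat``; in particular the indirect SE of a comparison
with no direct trials — the single number the trial-design formulas borrow
from the existing network.

Within-study covariance of multi-arm trials is ignored (``S`` diagonal),
which is exactly the model stated above; no correlation adjustment is made.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .contrasts import ContrastDataset, ContrastRecord

__all__ = [
    "NetworkEstimate",
    "DisconnectedNetworkError",
    "build_design_matrix",
    "fit_nma",
    "indirect_se",
    "update_network",
]


class DisconnectedNetworkError(ValueError):
    """The comparison graph is not connected; names the components."""


@dataclass(frozen=True)
class NetworkEstimate:
    """Fitted fixed-effect NMA.

    ``te_matrix[i, j]`` is the estimated log odds ratio of ``treatments[i]``
    relative to ``treatments[j]`` (antisymmetric, zero diagonal);
    ``se_matrix[i, j]`` its standard error (symmetric, zero diagonal).
    ``basic_estimates``/``basic_cov`` are the WLS solution for the
    non-baseline treatments versus ``baseline``.
    """

    treatments: tuple[str, ...]
    baseline: str
    basic_estimates: np.ndarray
    basic_cov: np.ndarray
    te_matrix: np.ndarray
    se_matrix: np.ndarray

    def _index(self, treat: str) -> int:
        try:
            return self.treatments.index(treat)
        except ValueError:
            raise KeyError(
                f"treatment {treat!r} not in network {list(self.treatments)}"
            ) from None

    def te(self, a: str, b: str) -> float:
        """Estimated log odds ratio of ``a`` relative to ``b``."""
        return float(self.te_matrix[self._index(a), self._index(b)])

    def se(self, a: str, b: str) -> float:
        """Standard error of the ``a`` vs ``b`` estimate."""
        return float(self.se_matrix[self._index(a), self._index(b)])

    def to_frame(self) -> pd.DataFrame:
        """Long-format pairwise table (one row per unordered pair)."""
        rows = []
        for i, a in enumerate(self.treatments):
            for j, b in enumerate(self.treatments):
                if i < j:
                    rows.append(
                        {
                            "treatA": a,
                            "treatB": b,
                            "TE": self.te_matrix[i, j],
                            "seTE": self.se_matrix[i, j],
                        }
                    )
        return pd.DataFrame(rows, columns=["treatA", "treatB", "TE", "seTE"])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "baseline": self.baseline,
            "treatments": list(self.treatments),
            "basic_estimates": self.basic_estimates.tolist(),
            "basic_cov": self.basic_cov.tolist(),
            "te_matrix": self.te_matrix.tolist(),
            "se_matrix": self.se_matrix.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _check_connected(dataset: ContrastDataset) -> None:
    if len(dataset) == 0:
        raise DisconnectedNetworkError("dataset has no contrast records")
    if not dataset.is_connected():
        comps = [sorted(c) for c in dataset.components()]
        raise DisconnectedNetworkError(
            f"comparison network is disconnected; components: {comps}"
        )


def build_design_matrix(
    dataset: ContrastDataset, baseline: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    """Design matrix, response and weights for the WLS fit.

    Returns ``(X, y, w, columns)`` with one row per contrast record and one
    column per non-baseline treatment (sorted label order).  A row for
    ``(i vs baseline)`` has +1 in column i; a row for ``(i vs j)`` with
    neither being the baseline has +1 in ``treat1``'s column and -1 in
    ``treat2``'s.  Weights are ``seTE**-2``.
    """
    treatments = dataset.treatments
    if baseline not in treatments:
        raise KeyError(f"baseline {baseline!r} not among treatments {list(treatments)}")
    _check_connected(dataset)
    columns = tuple(t for t in treatments if t != baseline)
    col_index = {t: k for k, t in enumerate(columns)}
    X = np.zeros((len(dataset), len(columns)))
    y = np.empty(len(dataset))
    w = np.empty(len(dataset))
    for row, rec in enumerate(dataset):
        if rec.treat1 != baseline:
            X[row, col_index[rec.treat1]] = 1.0
        if rec.treat2 != baseline:
            X[row, col_index[rec.treat2]] = -1.0
        y[row] = rec.TE
        w[row] = rec.seTE**-2
    return X, y, w, columns


def fit_nma(dataset: ContrastDataset, baseline: str | None = None) -> NetworkEstimate:
    """Weighted least-squares fit of the fixed-effect NMA.

    ``baseline`` defaults to the lexicographically smallest treatment label;
    the pairwise matrices are invariant to this choice.
    """
    treatments = dataset.treatments
    if baseline is None:
        baseline = treatments[0]
    X, y, w, columns = build_design_matrix(dataset, baseline)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    q, r = np.linalg.qr(Xw)
    if np.min(np.abs(np.diag(r))) <= 1e-12 * max(1.0, np.max(np.abs(np.diag(r)))):
        raise np.linalg.LinAlgError(
            "X'S^-1X is numerically singular; the network may be effectively "
            "disconnected (check for zero-weight or duplicated contrasts)"
        )
    mu = scipy.linalg.solve_triangular(r, q.T @ yw)
    rinv = scipy.linalg.solve_triangular(r, np.eye(r.shape[0]))
    cov = rinv @ rinv.T

    # Embed baseline (effect 0, no uncertainty) to get full pairwise matrices:
    # te[a,b] = mu_a - mu_b, var[a,b] = cov_aa + cov_bb - 2 cov_ab.
    T = len(treatments)
    full_mu = np.zeros(T)
    full_cov = np.zeros((T, T))
    idx = [treatments.index(t) for t in columns]
    full_mu[idx] = mu
    full_cov[np.ix_(idx, idx)] = cov
    te_matrix = full_mu[:, None] - full_mu[None, :]
    var = np.diag(full_cov)
    var_matrix = var[:, None] + var[None, :] - 2.0 * full_cov
    se_matrix = np.sqrt(np.maximum(var_matrix, 0.0))
    np.fill_diagonal(se_matrix, 0.0)
    return NetworkEstimate(
        treatments=treatments,
        baseline=baseline,
        basic_estimates=mu,
        basic_cov=cov,
        te_matrix=te_matrix,
        se_matrix=se_matrix,
    )


def indirect_se(dataset: ContrastDataset, treat_a: str, treat_b: str) -> float:
    """SE of the A-vs-B comparison implied by the existing network.

    This is sigma_AB,eNMA in the design formulas; invariant to the baseline
    used in fitting.
    """
    est = fit_nma(dataset)
    return est.se(treat_a, treat_b)


def update_network(
    dataset: ContrastDataset, new_trial: ContrastRecord, baseline: str | None = None
) -> NetworkEstimate:
    """Refit the NMA with the new trial's contrast appended.

    Both of the new trial's treatments must already be in the network.  For
    the updated comparison the precision adds:
    ``se_updated**-2 == seTE_new**-2 + se_existing**-2``.
    """
    treatments = set(dataset.treatments)
    for t in (new_trial.treat1, new_trial.treat2):
        if t not in treatments:
            raise KeyError(f"new trial treatment {t!r} not in the existing network")
    return fit_nma(dataset.with_record(new_trial), baseline=baseline)
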