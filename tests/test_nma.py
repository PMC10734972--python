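"""Fixed-effect NMA: design matrix, WLS fit, indirect SEs, network updating."""

import math

import numpy as np
import pytest

from nmaplan import (
    Allocation,
    ContrastDataset,
    ContrastRecord,
    DisconnectedNetworkError,
    build_design_matrix,
    combined_variance,
    fit_nma,
    indirect_se,
    trial_variance,
    update_network,
)
from conftest import random_connected_dataset


class TestDesignMatrix:
    def test_single_record_sign_convention(self):
        ds = ContrastDataset([ContrastRecord("s1", "A", "B", 1.5, 0.4)])
        X, y, w, cols = build_design_matrix(ds, baseline="A")
        assert cols == ("B",)
        np.testing.assert_array_equal(X, [[-1.0]])
        np.testing.assert_allclose(y, [1.5])
        np.testing.assert_allclose(w, [0.4**-2])

    def test_basic_comparison_rows(self):
        ds = ContrastDataset(
            [
                ContrastRecord("s1", "A", "C", 0.1, 0.5),
                ContrastRecord("s2", "B", "C", 0.2, 0.5),
            ]
        )
        X, _, _, cols = build_design_matrix(ds, baseline="C")
        assert cols == ("A", "B")
        np.testing.assert_array_equal(X, [[1.0, 0.0], [0.0, 1.0]])

    def test_three_study_chain(self):
        ds = ContrastDataset(
            [
                ContrastRecord("s1", "A", "B", 0.1, 0.5),
                ContrastRecord("s2", "B", "C", 0.2, 0.5),
                ContrastRecord("s3", "A", "C", 0.3, 0.5),
            ]
        )
        X, _, _, cols = build_design_matrix(ds, baseline="A")
        assert cols == ("B", "C")
        np.testing.assert_array_equal(X, [[-1.0, 0.0], [1.0, -1.0], [0.0, -1.0]])

    def test_baseline_absent(self):
        ds = ContrastDataset([ContrastRecord("s1", "A", "B", 1.5, 0.4)])
        with pytest.raises(KeyError, match="baseline"):
            build_design_matrix(ds, baseline="Z")

    def test_disconnected_network_names_components(self):
        ds = ContrastDataset(
            [
                ContrastRecord("s1", "A", "B", 1.0, 0.5),
                ContrastRecord("s2", "C", "D", 1.0, 0.5),
            ]
        )
        with pytest.raises(DisconnectedNetworkError, match=r"\['A', 'B'\]"):
            fit_nma(ds)


class TestFitClosedForms:
    def test_single_study_identity(self):
        ds = ContrastDataset([ContrastRecord("s1", "A", "B", 1.5, 0.4)])
        est = fit_nma(ds)
        assert est.te("A", "B") == pytest.approx(1.5, abs=1e-12)
        assert est.se("A", "B") == pytest.approx(0.4, abs=1e-12)

    def test_inverse_variance_pooling(self):
        ds = ContrastDataset(
            [
                ContrastRecord("s1", "A", "B", 1.0, 0.2),
                ContrastRecord("s2", "A", "B", 2.0, 0.2),
            ]
        )
        est = fit_nma(ds)
        assert est.te("A", "B") == pytest.approx(1.5, abs=1e-12)
        assert est.se("A", "B") == pytest.approx(0.2 / math.sqrt(2), abs=1e-12)

    def test_chain_indirect_variance_addition(self, chain_dataset):
        est = fit_nma(chain_dataset)
        assert est.se("A", "B") == pytest.approx(0.5, abs=1e-12)
        assert est.te("A", "B") == pytest.approx(1.5, abs=1e-12)  # 1.0 + 0.5

    @pytest.mark.parametrize("k", [1, 4, 9])
    def test_star_pooling_rate(self, k):
        s = 0.3
        ds = ContrastDataset(
            [ContrastRecord(f"s{i}", "A", "B", 1.0, s) for i in range(k)]
        )
        assert indirect_se(ds, "A", "B") == pytest.approx(s / math.sqrt(k), abs=1e-12)

    def test_brute_force_dense_equivalence(self):
        # dense evaluation of the WLS normal equations with explicit inverses
        rng = np.random.default_rng(42)
        for _ in range(25):
            ds = random_connected_dataset(rng, n_treat=int(rng.integers(2, 6)))
            base = ds.treatments[0]
            X, y, w, cols = build_design_matrix(ds, base)
            S_inv = np.diag(w)
            info = X.T @ S_inv @ X
            mu = np.linalg.inv(info) @ X.T @ S_inv @ y
            cov = np.linalg.inv(info)
            est = fit_nma(ds, baseline=base)
            np.testing.assert_allclose(est.basic_estimates, mu, atol=1e-10)
            np.testing.assert_allclose(est.basic_cov, cov, atol=1e-10)

    def test_matches_statsmodels_wls(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        ds = random_connected_dataset(rng, n_treat=4, n_study=7)
        X, y, w, _ = build_design_matrix(ds, ds.treatments[0])
        fit = sm.WLS(y, X, weights=w).fit()
        est = fit_nma(ds)
        np.testing.assert_allclose(est.basic_estimates, fit.params, atol=1e-10)
        np.testing.assert_allclose(
            est.basic_cov, fit.cov_params() / fit.scale, atol=1e-10
        )


class TestMatrixInvariants:
    def test_antisymmetry_and_consistency(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            est = fit_nma(random_connected_dataset(rng))
            np.testing.assert_allclose(est.te_matrix, -est.te_matrix.T, atol=1e-12)
            np.testing.assert_allclose(est.se_matrix, est.se_matrix.T, atol=1e-12)
            assert np.all(np.diag(est.te_matrix) == 0)
            assert np.all(np.diag(est.se_matrix) == 0)
            T = len(est.treatments)
            for a in range(T):
                for b in range(T):
                    for c in range(T):
                        assert est.te_matrix[a, b] == pytest.approx(
                            est.te_matrix[a, c] + est.te_matrix[c, b], abs=1e-9
                        )

    def test_baseline_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            ds = random_connected_dataset(rng)
            fits = [fit_nma(ds, baseline=b) for b in ds.treatments]
            for other in fits[1:]:
                np.testing.assert_allclose(
                    fits[0].te_matrix, other.te_matrix, atol=1e-10
                )
                np.testing.assert_allclose(
                    fits[0].se_matrix, other.se_matrix, atol=1e-10
                )

    def test_offdiagonal_ses_positive(self, chain_dataset):
        est = fit_nma(chain_dataset)
        off = est.se_matrix[~np.eye(len(est.treatments), dtype=bool)]
        assert np.all(off > 0)


class TestUpdateNetwork:
    def test_equal_precision_update(self, chain_dataset):
        upd = update_network(chain_dataset, ContrastRecord("new", "A", "B", 1.0, 0.5))
        assert upd.se("A", "B") == pytest.approx(0.5 / math.sqrt(2), abs=1e-12)

    def test_no_information_limit(self, chain_dataset):
        upd = update_network(chain_dataset, ContrastRecord("new", "A", "B", 1.0, 1e6))
        assert upd.se("A", "B") == pytest.approx(0.5, rel=1e-6)

    def test_precision_additivity_random(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            ds = random_connected_dataset(rng)
            labels = ds.treatments
            a, b = (labels[i] for i in rng.choice(len(labels), 2, replace=False))
            sigma_old = indirect_se(ds, a, b)
            se_new = float(rng.uniform(0.1, 2.0))
            upd = update_network(ds, ContrastRecord("new", a, b, 0.0, se_new))
            expected = (se_new**-2 + sigma_old**-2) ** -0.5
            assert upd.se(a, b) == pytest.approx(expected, abs=1e-10)

    def test_cross_module_combined_variance(self, chain_dataset):
        # a new trial whose seTE is the plug-in trial SD must reproduce the
        # combined-variance formula through the network update
        v_trial = trial_variance(0.2, 0.3, Allocation(317, 277))
        sigma = indirect_se(chain_dataset, "A", "B")  # 0.5 here
        upd = update_network(
            chain_dataset, ContrastRecord("new", "A", "B", 0.5, math.sqrt(v_trial))
        )
        assert upd.se("A", "B") ** 2 == pytest.approx(
            combined_variance(v_trial, sigma), abs=1e-12
        )

    def test_unknown_treatment_rejected(self, chain_dataset):
        with pytest.raises(KeyError, match="Z"):
            update_network(chain_dataset, ContrastRecord("new", "A", "Z", 1.0, 0.5))


def test_pairwise_table_serialization(tmp_path, chain_dataset):
    est = fit_nma(chain_dataset)
    frame = est.to_frame()
    assert list(frame.columns) == ["treatA", "treatB", "TE", "seTE"]
    assert len(frame) == 3
    row = frame[(frame.treatA == "A") & (frame.treatB == "B")].iloc[0]
    assert row.seTE == pytest.approx(0.5)
    text = est.to_json(tmp_path / "est.json")
    import json

    payload = json.loads(text)
    assert payload["baseline"] == "A"
    np.testing.assert_allclose(payload["se_matrix"], est.se_matrix)
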