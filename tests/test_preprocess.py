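"""QC filters, imputation, PCA and the spatial BLUP adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dagwas.preprocess import (
    compute_pcs,
    filter_call_rate,
    filter_maf,
    impute_mean,
    marker_maf,
    run_qc,
    spatial_adjust,
)
from dagwas.simdata import SimConfig, simulate_genotypes, simulate_plot_trial


def _matrix(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols, index=[f"G{i}" for i in range(
        len(next(iter(cols.values()))))]).astype(float)


class TestCallRateFilter:
    def test_boundary_is_strict(self):
        n = 500
        cols = {}
        for name, n_missing in (("ok", 0), ("at_limit", 50), ("over", 51)):
            v = np.full(n, 2.0)
            v[:n_missing] = np.nan
            cols[name] = v
        X = _matrix(cols)
        kept, removed = filter_call_rate(X, 0.10)
        assert list(kept.columns) == ["ok", "at_limit"]
        assert removed == ["over"]

    def test_hand_counted_fractions(self):
        n = 20
        cols = {"a": np.ones(n), "b": np.ones(n), "c": np.ones(n)}
        cols["b"][:1] = np.nan    # 5%
        cols["c"][:4] = np.nan    # 20%
        kept, removed = filter_call_rate(_matrix(cols), 0.10)
        assert kept.shape[1] == 2 and removed == ["c"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            filter_call_rate(pd.DataFrame())


class TestMafFilter:
    def test_monomorphic_columns_removed(self):
        X = _matrix({"zeros": np.zeros(10), "fours": np.full(10, 4.0),
                     "poly": np.array([1, 2, 3, 2, 1, 2, 3, 2, 1, 2])})
        kept, removed = filter_maf(X, 0.05)
        assert list(kept.columns) == ["poly"]
        assert set(removed) == {"zeros", "fours"}

    def test_hand_arithmetic(self):
        X = _matrix({"m": np.array([1.0, 2.0, 3.0, 2.0])})
        maf = marker_maf(X)["m"]
        assert maf == pytest.approx(0.5)
        kept, _ = filter_maf(X, 0.05)
        assert "m" in kept.columns

    def test_all_missing_marker_removed_with_warning(self):
        X = _matrix({"gone": np.full(6, np.nan),
                     "fine": np.array([1, 2, 1, 2, 3, 2.0])})
        with pytest.warns(UserWarning):
            kept, removed = filter_maf(X, 0.05)
        assert removed == ["gone"]

    def test_maf_always_in_unit_half_interval(self):
        dos, _ = simulate_genotypes(SimConfig(n_individuals=100, n_markers=200,
                                              seed=0))
        maf = marker_maf(dos).dropna()
        assert ((maf >= 0) & (maf <= 0.5)).all()


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(
    st.lists(st.one_of(st.none(), st.integers(0, 4)), min_size=8, max_size=8),
    min_size=1, max_size=6))
def test_qc_properties_hold_for_arbitrary_matrices(columns):
    """For any dosage matrix: MAF stays in [0, 0.5], the QC bookkeeping adds
    up, and re-running QC on its own output removes nothing."""
    X = pd.DataFrame({f"m{j}": pd.array(col, dtype="Float64").to_numpy(
        dtype=float, na_value=np.nan) for j, col in enumerate(columns)},
        index=[f"G{i}" for i in range(8)])
    out, report = run_qc(X)
    assert report.n_markers_out == (report.n_markers_in
                                    - report.n_removed_call_rate
                                    - report.n_removed_maf)
    maf = report.maf.dropna()
    assert ((maf >= 0) & (maf <= 0.5)).all()
    if out.shape[1]:
        again, rep2 = run_qc(out)
        assert rep2.n_removed_call_rate == 0 and rep2.n_removed_maf == 0
        pd.testing.assert_frame_equal(out, again)


def test_qc_is_idempotent():
    dos, _ = simulate_genotypes(SimConfig(n_individuals=120, n_markers=250,
                                          missing_rate=0.08, seed=31))
    once, rep1 = run_qc(dos)
    twice, rep2 = run_qc(once)
    assert rep2.n_removed_call_rate == 0 and rep2.n_removed_maf == 0
    pd.testing.assert_frame_equal(once, twice)
    assert rep1.n_markers_out == (rep1.n_markers_in - rep1.n_removed_call_rate
                                  - rep1.n_removed_maf)


class TestImpute:
    def test_identity_without_missing(self):
        X = _matrix({"a": np.array([1, 2, 3.0])})
        pd.testing.assert_frame_equal(impute_mean(X), X)

    def test_column_mean_fill(self):
        X = _matrix({"a": np.array([0.0, 4.0, np.nan])})
        out = impute_mean(X)
        assert out["a"].iloc[2] == pytest.approx(2.0)

    def test_column_means_unchanged(self):
        dos, _ = simulate_genotypes(SimConfig(n_individuals=100, n_markers=80,
                                              missing_rate=0.1, seed=2))
        out = impute_mean(dos)
        np.testing.assert_allclose(out.mean(), dos.mean(skipna=True), atol=1e-12)

    def test_all_missing_marker_is_an_error(self):
        X = _matrix({"a": np.full(4, np.nan)})
        with pytest.raises(ValueError):
            impute_mean(X)


class TestPCA:
    def test_identical_rows_give_zero_scores(self):
        X = pd.DataFrame(np.tile([1.0, 3.0, 2.0, 4.0], (6, 1)),
                         index=[f"G{i}" for i in range(6)])
        pcs = compute_pcs(X, k=2)
        np.testing.assert_allclose(pcs.scores.to_numpy(), 0.0, atol=1e-10)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 15)))
        pcs = compute_pcs(X, k=5)
        vals = X.to_numpy()
        vals = (vals - vals.mean(0)) / vals.std(0)
        cov = vals.T @ vals / 1.0
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        scores_ref = vals @ v[:, order[:5]]
        got = pcs.scores.to_numpy()
        for j in range(5):
            # eigenvector sign is arbitrary; compare up to sign
            s = np.sign(scores_ref[:, j] @ got[:, j])
            np.testing.assert_allclose(got[:, j], s * scores_ref[:, j],
                                       atol=1e-8)

    def test_score_and_variance_invariants(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 12)))
        pcs = compute_pcs(X, k=6)
        np.testing.assert_allclose(pcs.scores.mean(), 0.0, atol=1e-10)
        evr = pcs.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-12

    def test_k_bounds_enforced(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 5)))
        with pytest.raises(ValueError):
            compute_pcs(X, k=6)
        with pytest.raises(ValueError):
            compute_pcs(X, k=10)  # k > n-1


class TestSpatialAdjust:
    def test_no_spatial_noise_recovers_genotype_means(self):
        table, _ = simulate_plot_trial(n_genotypes=50, n_reps=3, n_rows=15,
                                       n_cols=10, var_g=1.0, var_row=0.0,
                                       var_col=0.0, var_e=1e-8, seed=1)
        blups, _ = spatial_adjust(table)
        means = table.groupby("genotype_id")["value"].mean()
        np.testing.assert_allclose(blups.sort_index(), means.sort_index(),
                                   atol=1e-3)

    def test_plot_order_invariance(self):
        table, _ = simulate_plot_trial(n_genotypes=40, n_reps=3, n_rows=12,
                                       n_cols=10, seed=7)
        blups_a, _ = spatial_adjust(table)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        blups_b, _ = spatial_adjust(shuffled)
        np.testing.assert_allclose(blups_a.sort_index(), blups_b.sort_index(),
                                   atol=1e-8)

    def test_variance_component_recovery(self):
        table, truth = simulate_plot_trial(n_genotypes=500, n_reps=3,
                                           n_rows=50, n_cols=30, var_g=1.0,
                                           var_row=0.5, var_col=0.5,
                                           var_e=1.0, seed=11)
        blups, comps = spatial_adjust(table)
        realized = truth.attrs["realized_variance"]
        # 50 row / 30 column levels: the realized variances of the drawn
        # effects are the recoverable targets
        for name in ("genotype", "row", "column"):
            assert abs(comps[f"var_{name}"] - realized[name]) <= \
                0.25 * realized[name]
        assert abs(comps["var_residual"] - 1.0) <= 0.25
        # BLUPs should track the true genotype effects closely
        r = np.corrcoef(blups.sort_index(), truth.sort_index())[0, 1]
        assert r > 0.8

    def test_single_plot_is_singular(self):
        table = pd.DataFrame({"genotype_id": ["G1"], "row": [0],
                              "column": [0], "value": [1.0]})
        with pytest.raises(ValueError):
            spatial_adjust(table)
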