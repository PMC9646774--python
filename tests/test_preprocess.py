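import numpy as np
import pandas as pd
import pytest

from cytomc.core import ARCSINH, RAW, ValidationError
from cytomc.preprocess import (
    BatchNormFactors,
    SpilloverMatrix,
    apply_batch_normalization,
    arcsinh_transform,
    compensate_nnls,
    estimate_batch_factors,
    preprocess_pipeline,
    synthesize_kl,
)
from cytomc.synthetic import example_cohort_config, simulate_cohort

from oracles import nnls_grid_oracle


class TestSpilloverValidation:
    def test_diagonal_must_be_one(self):
        with pytest.raises(ValidationError, match="diagonal"):
            SpilloverMatrix(np.array([[2.0, 0.0], [0.0, 1.0]]))

    def test_off_diagonal_range(self):
        with pytest.raises(ValidationError, match="off-diagonal"):
            SpilloverMatrix(np.array([[1.0, 1.5], [0.0, 1.0]]))


class TestCompensateNNLS:
    def test_identity_noop(self, cells_factory):
        t = cells_factory([[3.0, 7.0], [1.0, 0.0]])
        out = compensate_nnls(t, SpilloverMatrix(np.eye(2)))
        np.testing.assert_allclose(out.values, t.values)

    def test_interior_solution_exact(self, cells_factory):
        # S = [[1, 0.1], [0, 1]], y = (10, 6): x solves S^T x = y -> (10, 5)
        S = SpilloverMatrix(np.array([[1.0, 0.1], [0.0, 1.0]]))
        t = cells_factory([[10.0, 6.0]])
        out = compensate_nnls(t, S)
        np.testing.assert_allclose(out.values, [[10.0, 5.0]], atol=1e-10)

    def test_unconstrained_nonnegative_kept(self, cells_factory):
        S = SpilloverMatrix(np.array([[1.0, 0.5], [0.0, 1.0]]))
        out = compensate_nnls(cells_factory([[0.0, 1.0]]), S)
        np.testing.assert_allclose(out.values, [[0.0, 1.0]], atol=1e-10)

    def test_clamped_solution_matches_grid_oracle(self, cells_factory):
        # y = (1, 0) with spill 0.9 from ch1 into ch2 forces x2 to clamp at 0
        S = np.array([[1.0, 0.0], [0.9, 1.0]])
        out = compensate_nnls(cells_factory([[1.0, 0.0]]), SpilloverMatrix(S))
        assert out.values[0, 1] == 0.0
        x_oracle, _ = nnls_grid_oracle(S.T, np.array([1.0, 0.0]), hi=2.0, steps=401)
        np.testing.assert_allclose(out.values[0], x_oracle, atol=2 * 2.0 / 400)

    def test_forward_roundtrip_when_interior(self, cells_factory):
        rng = np.random.default_rng(0)
        S = np.eye(4)
        S[0, 1] = 0.08
        S[2, 3] = 0.05
        X = rng.uniform(1, 50, size=(20, 4))
        observed = cells_factory(X @ S)
        out = compensate_nnls(observed, SpilloverMatrix(S))
        np.testing.assert_allclose(out.values, X, atol=1e-8)

    def test_requires_raw_scale(self, cells_factory):
        t = cells_factory([[1.0, 1.0]], scale=ARCSINH)
        with pytest.raises(ValidationError, match="raw"):
            compensate_nnls(t, SpilloverMatrix(np.eye(2)))

    def test_dimension_mismatch(self, cells_factory):
        with pytest.raises(ValidationError, match="does not match"):
            compensate_nnls(cells_factory([[1.0, 1.0]]), SpilloverMatrix(np.eye(3)))


class TestArcsinh:
    def test_zero_maps_to_zero(self, cells_factory):
        out = arcsinh_transform(cells_factory([[0.0]]))
        assert out.values[0, 0] == 0.0
        assert out.scale == ARCSINH

    def test_closed_form(self, cells_factory):
        out = arcsinh_transform(cells_factory([[5.0]]), scale_a=0.2)
        assert out.values[0, 0] == pytest.approx(np.log(1 + np.sqrt(2)), abs=1e-12)

    def test_large_x_limit(self, cells_factory):
        out = arcsinh_transform(cells_factory([[1000.0]]), scale_a=0.2)
        assert out.values[0, 0] == pytest.approx(np.log(400.0), rel=1e-5)

    def test_nonpositive_scale_rejected(self, cells_factory):
        with pytest.raises(ValidationError, match="positive"):
            arcsinh_transform(cells_factory([[1.0]]), scale_a=0.0)

    def test_monotone(self, cells_factory):
        x = np.sort(np.random.default_rng(1).uniform(0, 100, 50))
        out = arcsinh_transform(cells_factory(x[:, None]))
        assert np.all(np.diff(out.values[:, 0]) > 0)


class TestBatchFactors:
    def _controls(self, cells_factory, medians_by_batch):
        vals, batches = [], []
        for b, med in medians_by_batch.items():
            # 3 cells per batch whose median is exactly `med`
            for f in (0.5, 1.0, 1.5):
                vals.append([m * f for m in med])
                batches.append(b)
        return cells_factory(
            vals,
            sample_id=[f"ctrl_{b}" for b in batches],
            batch_id=batches,
            is_control=[True] * len(batches),
        )

    def test_two_batch_ratio(self, cells_factory):
        ctrl = self._controls(cells_factory, {"b0": [2.0], "b1": [4.0]})
        f = estimate_batch_factors(ctrl)
        assert f.factors.loc["b0", "M0"] == pytest.approx(1.0)
        assert f.factors.loc["b1", "M0"] == pytest.approx(2.0)

    def test_equal_medians_all_one(self, cells_factory):
        ctrl = self._controls(cells_factory, {"b0": [3.0], "b1": [3.0]})
        assert np.allclose(estimate_batch_factors(ctrl).factors.to_numpy(), 1.0)

    def test_three_batches(self, cells_factory):
        ctrl = self._controls(cells_factory, {"b0": [1.0], "b1": [2.0], "b2": [4.0]})
        f = estimate_batch_factors(ctrl)
        np.testing.assert_allclose(
            f.factors["M0"].to_numpy(), [1.0, 2.0, 4.0]
        )

    def test_zero_median_channel_rejected(self, cells_factory):
        ctrl = self._controls(cells_factory, {"b0": [0.0], "b1": [2.0]})
        with pytest.raises(ValidationError, match="zero minimum"):
            estimate_batch_factors(ctrl)

    def test_common_rescale_leaves_factors(self, cells_factory):
        a = self._controls(cells_factory, {"b0": [2.0], "b1": [6.0]})
        b = self._controls(cells_factory, {"b0": [20.0], "b1": [60.0]})
        fa = estimate_batch_factors(a).factors.to_numpy()
        fb = estimate_batch_factors(b).factors.to_numpy()
        np.testing.assert_allclose(fa, fb)

    def test_factor_invariants_enforced(self):
        with pytest.raises(ValidationError, match="minimum factor"):
            BatchNormFactors(pd.DataFrame({"M0": [2.0, 3.0]}, index=["b0", "b1"]))


class TestApplyNormalization:
    def test_identity_factors(self, cells_factory):
        t = cells_factory([[4.0]], batch_id=["b0"])
        f = BatchNormFactors(pd.DataFrame({"M0": [1.0]}, index=["b0"]))
        np.testing.assert_allclose(apply_batch_normalization(t, f).values, t.values)

    def test_division_by_factor(self, cells_factory):
        t = cells_factory([[4.0], [4.0]], sample_id=["x", "y"],
                          batch_id=["b0", "b1"])
        f = BatchNormFactors(pd.DataFrame({"M0": [1.0, 2.0]}, index=["b0", "b1"]))
        out = apply_batch_normalization(t, f)
        np.testing.assert_allclose(out.values.ravel(), [4.0, 2.0])

    def test_unknown_batch_rejected(self, cells_factory):
        t = cells_factory([[4.0]], batch_id=["mystery"])
        f = BatchNormFactors(pd.DataFrame({"M0": [1.0]}, index=["b0"]))
        with pytest.raises(ValidationError, match="unknown batch"):
            apply_batch_normalization(t, f)

    def test_planted_factor_recovery(self):
        # two-batch cohort with g = (1, 3) on one channel: estimated factors
        # within 5% and post-normalization control medians within 5%
        cfg = example_cohort_config(
            n_a=2, n_b=2, cells_per_sample=300, n_batches=2,
            spillover_off_diag=0.0, batch_effect=np.ones((2, 39)),
            control_cells=400, seed=11,
        )
        ch = 0  # CD19: expressed by every control population, so its
        # control median is stable on the raw scale
        cfg.batch_factors[1, ch] = 3.0
        cohort = simulate_cohort(cfg)
        cells = cohort.cells
        factors = estimate_batch_factors(cells)
        est = factors.factors.iloc[:, ch].to_numpy()
        np.testing.assert_allclose(est, [1.0, 3.0], rtol=0.05)
        normed = apply_batch_normalization(cells, factors)
        ctrl = normed.subset(normed.is_control)
        med = [
            np.median(ctrl.values[ctrl.batch_id == b, ch]) for b in ctrl.batches
        ]
        assert abs(med[0] - med[1]) / med[0] < 0.05


class TestSynthesizeKL:
    def test_max_rule(self, cells_factory, small_panel):
        t = cells_factory([[0, 0, 0, 0, 3.0, 1.0],
                           [0, 0, 0, 0, 0.0, 0.0],
                           [0, 0, 0, 0, 2.0, 2.0]],
                          markers=small_panel.marker_names)
        out, panel = synthesize_kl(t, small_panel)
        np.testing.assert_allclose(out.values[:, -1], [3.0, 0.0, 2.0])
        assert panel.marker_names[-1] == "KL"

    def test_missing_channel(self, cells_factory, small_panel):
        t = cells_factory([[1.0, 2.0]], markers=["M0", "M1"])
        with pytest.raises((ValidationError, KeyError)):
            synthesize_kl(t, small_panel)


class TestPipelineProperties:
    def test_reordering_commutes(self, cells_factory):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 10, size=(30, 2))
        batches = np.array(["b0", "b1"] * 15)
        samples = np.array(["s0", "s1"] * 15)
        t = cells_factory(X, sample_id=samples, batch_id=batches)
        f = BatchNormFactors(
            pd.DataFrame({"M0": [1.0, 2.0], "M1": [1.0, 1.5]}, index=["b0", "b1"])
        )
        perm = rng.permutation(30)
        a = apply_batch_normalization(t, f).values[perm]
        b = apply_batch_normalization(t.subset(perm), f).values
        np.testing.assert_allclose(a, b)

    def test_rank_order_preserved_within_batch(self, cells_factory):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 100, 40)
        t = cells_factory(x[:, None])
        out = arcsinh_transform(t)
        assert list(np.argsort(out.values[:, 0])) == list(np.argsort(x))

    def test_full_preprocess_identity_cohort(self):
        # identity spillover + all-ones batch gains -> estimated factors ~ 1
        cfg = example_cohort_config(
            n_a=1, n_b=1, cells_per_sample=150, n_batches=2,
            spillover_off_diag=0.0, batch_effect=np.ones((2, 39)),
            control_cells=300, seed=4,
        )
        cohort = simulate_cohort(cfg)
        cells, panel, factors = preprocess_pipeline(
            cohort.cells, cfg.spillover, cohort.panel
        )
        assert cells.scale == ARCSINH
        assert cells.marker_names[-1] == "KL"
        f = factors.factors
        # strongly expressed channels have stable medians -> factors ~ 1;
        # background channels (raw median ~ 1) are noisier but bounded
        for ch in ("CD19", "CD20"):
            np.testing.assert_allclose(f[ch].to_numpy(), 1.0, atol=0.05)
        assert f.to_numpy().max() < 1.6
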