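import numpy as np
import pandas as pd
import pytest

from cytomc.clonality import (
    RULE_MAJORITY_50,
    RULE_MOST_ABUNDANT,
    assign_tumor_type,
    call_clonality,
    clonal_cell_mask,
    designate_ab_metaclusters,
    flag_abnormal,
)
from cytomc.core import ValidationError


def _lc_cells(cells_factory, small_panel, kappa_vals, lambda_vals, sample="s0"):
    n = len(kappa_vals)
    vals = np.zeros((n, 6))
    vals[:, 4] = kappa_vals
    vals[:, 5] = lambda_vals
    return cells_factory(
        vals, markers=small_panel.marker_names, scale="arcsinh",
        sample_id=[sample] * n,
    )


class TestCallClonality:
    def test_balanced_polytypic(self, cells_factory, small_panel):
        # 10 kappa-positive, 10 lambda-positive -> ratio 1 -> polytypic
        kap = [2.0] * 10 + [0.1] * 10
        lam = [0.1] * 10 + [2.0] * 10
        calls = call_clonality(_lc_cells(cells_factory, small_panel, kap, lam),
                               np.zeros(20, dtype=int), small_panel)
        assert len(calls) == 1
        assert calls[0].ratio == pytest.approx(1.0)
        assert calls[0].call == "polytypic"

    def test_ratio_above_seven_monotypic_kappa(self, cells_factory, small_panel):
        kap = [2.0] * 16 + [0.1] * 2
        lam = [0.1] * 16 + [2.0] * 2
        calls = call_clonality(_lc_cells(cells_factory, small_panel, kap, lam),
                               np.zeros(18, dtype=int), small_panel)
        assert calls[0].ratio == pytest.approx(8.0)
        assert calls[0].call == "monotypic-kappa"

    def test_ratio_below_03_monotypic_lambda(self, cells_factory, small_panel):
        kap = [2.0] * 2 + [0.1] * 10
        lam = [0.1] * 2 + [2.0] * 10
        calls = call_clonality(_lc_cells(cells_factory, small_panel, kap, lam),
                               np.zeros(12, dtype=int), small_panel)
        assert calls[0].ratio == pytest.approx(0.2)
        assert calls[0].call == "monotypic-lambda"

    @pytest.mark.parametrize("k,l,expected", [
        (7, 1, "polytypic"),    # ratio exactly 7: inclusive bound
        (3, 10, "polytypic"),   # ratio exactly 0.3
        (8, 1, "monotypic-kappa"),
        (1, 5, "monotypic-lambda"),
    ])
    def test_threshold_bounds(self, cells_factory, small_panel, k, l, expected):
        kap = [2.0] * k + [0.1] * l
        lam = [0.1] * k + [2.0] * l
        calls = call_clonality(_lc_cells(cells_factory, small_panel, kap, lam),
                               np.zeros(k + l, dtype=int), small_panel)
        assert calls[0].call == expected

    def test_zero_lambda_infinite_ratio(self, cells_factory, small_panel):
        calls = call_clonality(_lc_cells(cells_factory, small_panel,
                                         [2.0] * 5, [0.1] * 5),
                               np.zeros(5, dtype=int), small_panel)
        assert np.isinf(calls[0].ratio)
        assert calls[0].call == "monotypic-kappa"

    def test_both_zero_indeterminate(self, cells_factory, small_panel):
        calls = call_clonality(_lc_cells(cells_factory, small_panel,
                                         [0.1] * 60, [0.1] * 60),
                               np.zeros(60, dtype=int), small_panel)
        assert calls[0].call == "indeterminate"

    def test_median_basis(self, cells_factory, small_panel):
        cells = _lc_cells(cells_factory, small_panel, [4.0] * 4, [2.0] * 4)
        calls = call_clonality(cells, np.zeros(4, dtype=int), small_panel,
                               basis="median")
        assert calls[0].ratio == pytest.approx(2.0)

    def test_per_sample_per_cluster(self, cells_factory, small_panel):
        from cytomc.core import concat_tables
        a = _lc_cells(cells_factory, small_panel, [2.0] * 8, [0.1] * 8, sample="s0")
        b = _lc_cells(cells_factory, small_panel, [0.1] * 8, [2.0] * 8, sample="s1")
        cells = concat_tables([a, b])
        labels = np.array([0] * 8 + [0] * 8)
        calls = call_clonality(cells, labels, small_panel)
        by_sample = {c.sample_id: c.call for c in calls}
        assert by_sample == {"s0": "monotypic-kappa", "s1": "monotypic-lambda"}


class TestFlagAbnormal:
    def _calls(self, cells_factory, small_panel):
        from cytomc.core import concat_tables
        mono = _lc_cells(cells_factory, small_panel, [2.0] * 9, [0.1] * 9)
        poly_k = [2.0] * 5 + [0.1] * 5
        poly_l = [0.1] * 5 + [2.0] * 5
        poly = _lc_cells(cells_factory, small_panel, poly_k, poly_l)
        cells = concat_tables([mono, poly])
        labels = np.array([0] * 9 + [1] * 10)
        return call_clonality(cells, labels, small_panel)

    def test_monotypic_normal_cluster_flagged(self, cells_factory, small_panel):
        calls = flag_abnormal(self._calls(cells_factory, small_panel),
                              {0: "GC", 1: "naive"})
        flags = {c.cluster_id: c.ab_flag for c in calls}
        assert flags == {0: True, 1: False}

    def test_tumor_only_cluster_not_flagged(self, cells_factory, small_panel):
        calls = flag_abnormal(self._calls(cells_factory, small_panel), {})
        assert not any(c.ab_flag for c in calls)

    def test_light_chain_mismatch_warns(self, cells_factory, small_panel):
        from cytomc.core import concat_tables
        # aberrant (unmapped) cluster is lambda; Ab-flagged cluster is kappa
        ab = _lc_cells(cells_factory, small_panel, [2.0] * 9, [0.1] * 9)
        aberrant = _lc_cells(cells_factory, small_panel, [0.1] * 9, [2.0] * 9)
        cells = concat_tables([ab, aberrant])
        labels = np.array([0] * 9 + [1] * 9)
        calls = call_clonality(cells, labels, small_panel)
        with pytest.warns(UserWarning, match="monotypic-kappa"):
            flag_abnormal(calls, {0: "GC"})


class TestClonalMask:
    def test_mask_covers_monotypic_only(self, cells_factory, small_panel):
        from cytomc.core import concat_tables
        mono = _lc_cells(cells_factory, small_panel, [2.0] * 6, [0.1] * 6)
        poly = _lc_cells(cells_factory, small_panel,
                         [2.0] * 3 + [0.1] * 3, [0.1] * 3 + [2.0] * 3)
        cells = concat_tables([mono, poly])
        labels = np.array([0] * 6 + [1] * 6)
        calls = call_clonality(cells, labels, small_panel)
        mask = clonal_cell_mask(cells, labels, calls)
        assert mask[:6].all() and not mask[6:].any()


class TestAssignTumorType:
    def test_dominant_mc_a(self):
        # clonal composition {MC-A: 0.675, other: 0.325} -> A under both rules
        counts = pd.Series({("MC-A"): 675, ("MC-L"): 325})
        for rule in (RULE_MOST_ABUNDANT, RULE_MAJORITY_50):
            t = assign_tumor_type("s", counts, 2000, "MC-A", "MC-B", rule=rule)
            assert t.type == "A"
        t = assign_tumor_type("s", counts, 2000, "MC-A", "MC-B")
        assert t.clonal_fraction == pytest.approx(0.5)

    def test_dominant_mc_b(self):
        counts = pd.Series({"MC-B": 640, "MC-I": 332, "MC-X": 28})
        for rule in (RULE_MOST_ABUNDANT, RULE_MAJORITY_50):
            t = assign_tumor_type("s", counts, 1000, "MC-A", "MC-B", rule=rule)
            assert t.type == "B"

    def test_no_clonal_cells_rln_like(self):
        t = assign_tumor_type("s", pd.Series(dtype=float), 500, "MC-A", "MC-B")
        assert t.type == "rLN-like"
        assert t.clonal_fraction == 0.0

    def test_nos_when_dominant_is_other(self):
        counts = pd.Series({"MC-C": 600, "MC-A": 400})
        t = assign_tumor_type("s", counts, 1000, "MC-A", "MC-B")
        assert t.type == "NOS"

    def test_majority_rule_stricter(self):
        counts = pd.Series({"MC-A": 450, "MC-C": 350, "MC-D": 200})
        assert assign_tumor_type("s", counts, 1000, "MC-A", "MC-B",
                                 rule=RULE_MOST_ABUNDANT).type == "A"
        assert assign_tumor_type("s", counts, 1000, "MC-A", "MC-B",
                                 rule=RULE_MAJORITY_50).type == "NOS"

    def test_majority_implies_most_abundant(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            comp = rng.dirichlet(np.ones(4))
            counts = pd.Series(comp, index=["MC-A", "MC-B", "MC-C", "MC-D"]) * 1000
            maj = assign_tumor_type("s", counts, 2000, "MC-A", "MC-B",
                                    rule=RULE_MAJORITY_50).type
            most = assign_tumor_type("s", counts, 2000, "MC-A", "MC-B",
                                     rule=RULE_MOST_ABUNDANT).type
            if maj in ("A", "B"):
                assert most == maj

    def test_tie_is_nos(self):
        counts = pd.Series({"MC-A": 500, "MC-B": 500})
        t = assign_tumor_type("s", counts, 1000, "MC-A", "MC-B")
        assert t.type == "NOS"
        assert t.dominant_mc is None

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            assign_tumor_type("s", pd.Series({"MC-A": 1}), 0, "MC-A", "MC-B")

    def test_subsampling_stability(self):
        rng = np.random.default_rng(1)
        mcs = rng.choice(["MC-A", "MC-C"], p=[0.7, 0.3], size=4000)
        full = pd.Series(mcs).value_counts()
        t_full = assign_tumor_type("s", full, 8000, "MC-A", "MC-B")
        sub = pd.Series(rng.choice(mcs, 2000, replace=False)).value_counts()
        t_sub = assign_tumor_type("s", sub, 4000, "MC-A", "MC-B")
        assert t_full.type == t_sub.type == "A"


class TestDesignateAB:
    def test_phenotype_contrast_decides(self):
        markers = ("IgG", "HLA-DR", "CD22", "IgM", "CD79B", "CD24", "CD44")
        medians = pd.DataFrame(
            [[0.2] * 7,
             [3.0, 3.0, 3.0, 0.2, 0.2, 0.2, 0.2],   # A-like profile
             [0.2, 0.2, 0.2, 3.0, 3.0, 3.0, 3.0]],  # B-like profile
            index=[0, 1, 2], columns=markers,
        )
        # B-like metacluster is MORE abundant; phenotype must still win
        counts = pd.Series({1: 100, 2: 400})
        mc_a, mc_b = designate_ab_metaclusters(medians, counts, markers)
        assert (mc_a, mc_b) == (1, 2)

    def test_fallback_to_abundance(self):
        medians = pd.DataFrame([[1.0], [2.0]], index=[0, 1], columns=["X"])
        counts = pd.Series({0: 10, 1: 90})
        assert designate_ab_metaclusters(medians, counts, ("X",)) == (1, 0)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValidationError):
            designate_ab_metaclusters(pd.DataFrame(), pd.Series(dtype=float), ())
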