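"""Relative quantification and Dunnett many-to-one statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from melapress import synth_data as sd
from melapress.assay_stats import (
    dunnett_test,
    fold_change,
    significance_stars,
)


def small_table(delta_cts: dict[str, list[float]], ref_ct=18.0) -> pd.DataFrame:
    """Build a Ct table from per-group lists of replicate dCt values."""
    rows = []
    for group, dcts in delta_cts.items():
        for i, d in enumerate(dcts):
            rows.append((group, f"{group}_{i}", "Gapdh", ref_ct))
            rows.append((group, f"{group}_{i}", "Mmp14", ref_ct + d))
    return pd.DataFrame(rows, columns=["group", "sample", "gene", "ct"])


class TestFoldChange:
    def test_identical_cts_give_unit_folds(self):
        tab = small_table({"control": [4, 4, 4], "trt": [4, 4, 4]})
        res = fold_change(tab, "Mmp14", "Gapdh", "control")
        assert np.allclose(res.per_replicate["fold"], 1.0)

    def test_one_cycle_above_calibrator_halves_expression(self):
        tab = small_table({"control": [4, 4], "trt": [5, 5]})
        res = fold_change(tab, "Mmp14", "Gapdh", "control")
        trt = res.per_replicate[res.per_replicate.group == "trt"]
        assert np.allclose(trt["delta_delta_ct"], 1.0)
        assert np.allclose(trt["fold"], 0.5)

    def test_calibrator_mean_fold_is_one_by_construction(self):
        tab = small_table({"control": [3.8, 4.0, 4.2], "trt": [2, 2, 2]})
        res = fold_change(tab, "Mmp14", "Gapdh", "control")
        ctl = res.per_group.set_index("group").loc["control"]
        # mean ddCt of the calibrator is 0; folds average near 1
        assert res.per_replicate[res.per_replicate.group == "control"][
            "delta_delta_ct"].mean() == pytest.approx(0.0, abs=1e-12)
        assert ctl["mean_fold"] == pytest.approx(1.0, rel=0.05)

    @pytest.mark.parametrize("fold", [0.5, 1.0, 4.0])
    def test_noise_free_generator_round_trip(self, fold):
        tab = sd.gen_ct_table(sd.CtTableSpec(
            group_fold_changes={"control": 1.0, "trt": fold}, ct_noise_sd=0.0, seed=1))
        res = fold_change(tab, "Mmp14", "Gapdh", "control")
        rec = res.per_group.set_index("group").loc["trt", "mean_fold"]
        assert rec == pytest.approx(fold, abs=1e-12)

    def test_technical_replicates_averaged_on_ct_scale(self):
        tab = small_table({"control": [4], "trt": [3]})
        jitter = pd.concat([tab, tab.assign(ct=tab.ct + 0.4), tab.assign(ct=tab.ct - 0.4)])
        res_a = fold_change(tab, "Mmp14", "Gapdh", "control")
        res_b = fold_change(jitter, "Mmp14", "Gapdh", "control")
        pd.testing.assert_frame_equal(res_a.per_replicate, res_b.per_replicate)

    def test_shift_both_genes_leaves_folds_unchanged(self):
        tab = small_table({"control": [4, 4.2], "trt": [2.5, 2.7]})
        shifted = tab.assign(ct=tab.ct + 3.0)
        a = fold_change(tab, "Mmp14", "Gapdh", "control").per_replicate["fold"]
        b = fold_change(shifted, "Mmp14", "Gapdh", "control").per_replicate["fold"]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_shift_target_only_halves_every_fold_vs_old_calibration(self):
        tab = small_table({"control": [4, 4], "trt": [2, 2]})
        base = fold_change(tab, "Mmp14", "Gapdh", "control")
        shifted = tab.copy()
        shifted.loc[shifted.gene == "Mmp14", "ct"] += 1.0
        # folds are calibrated within the table, so a global +1 cycle on the
        # target cancels out: raw expression halves, relative folds persist
        res = fold_change(shifted, "Mmp14", "Gapdh", "control")
        np.testing.assert_allclose(res.per_replicate["fold"],
                                   base.per_replicate["fold"], atol=1e-12)
        np.testing.assert_allclose(res.per_replicate["delta_ct"],
                                   base.per_replicate["delta_ct"] + 1.0, atol=1e-12)

    def test_missing_reference_gene_names_replicate(self):
        tab = small_table({"control": [4], "trt": [3]})
        tab = tab[~((tab["sample"] == "trt_0") & (tab.gene == "Gapdh"))]
        with pytest.raises(ValueError, match="Gapdh"):
            fold_change(tab, "Mmp14", "Gapdh", "control")

    def test_missing_calibrator_rejected(self):
        tab = small_table({"trt": [3, 3]})
        with pytest.raises(ValueError, match="calibrator"):
            fold_change(tab, "Mmp14", "Gapdh", "control")


class TestDunnett:
    def test_identical_groups_not_significant(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = dunnett_test({"control": x, "a": x.copy(), "b": x.copy()}, "control")
        assert (res.table["p_adjusted"] > 0.99).all()

    def test_single_comparison_matches_pooled_t(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        res = dunnett_test({"control": x, "g": y}, "control", n_draws=400_000)
        _, p = ss.ttest_ind(y, x, equal_var=True)
        assert res.table["p_adjusted"].iloc[0] == pytest.approx(p, abs=0.005)

    def test_two_groups_match_scipy_dunnett(self):
        """Independent oracle: scipy's Dunnett implementation on the same
        data agrees within Monte-Carlo tolerance."""
        rng = np.random.default_rng(3)
        for trial in range(5):
            x = rng.normal(0, 1, 6)
            a = rng.normal(rng.uniform(-1.5, 1.5), 1, 6)
            b = rng.normal(rng.uniform(-1.5, 1.5), 1, 6)
            res = dunnett_test({"control": x, "a": a, "b": b}, "control",
                               n_draws=400_000)
            oracle = ss.dunnett(a, b, control=x)
            mine = res.table.set_index("group")
            np.testing.assert_allclose(
                mine.loc[["a", "b"], "t"], oracle.statistic, rtol=1e-9)
            np.testing.assert_allclose(
                mine.loc[["a", "b"], "p_adjusted"], oracle.pvalue, atol=0.01)

    def test_adjusted_p_monotone_in_t(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = dunnett_test(
            {"control": x, "near": x + 0.5, "far": x + 5.0}, "control")
        tab = res.table.set_index("group")
        assert abs(tab.loc["far", "t"]) > abs(tab.loc["near", "t"])
        assert tab.loc["far", "p_adjusted"] < tab.loc["near", "p_adjusted"]

    def test_adjusted_p_grows_with_family_size(self):
        # g2 duplicates g1's spread so the pooled variance stays put
        ctrl = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        g1 = ctrl + 2.0
        g2 = ctrl + 10.0
        p1 = dunnett_test({"control": ctrl, "g1": g1}, "control") \
            .table.set_index("group").loc["g1", "p_adjusted"]
        p2 = dunnett_test({"control": ctrl, "g1": g1, "g2": g2}, "control") \
            .table.set_index("group").loc["g1", "p_adjusted"]
        assert p2 > p1

    def test_adjusted_p_at_least_unadjusted_t_p(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 6)
        a, b = rng.normal(0.8, 1, 6), rng.normal(-0.5, 1, 6)
        res = dunnett_test({"control": x, "a": a, "b": b}, "control")
        for g, sample in (("a", a), ("b", b)):
            # pooled-variance p using the full-design df, as Dunnett does
            t = res.table.set_index("group").loc[g, "t"]
            p_un = 2 * ss.t.sf(abs(t), df=res.df)
            assert res.table.set_index("group").loc[g, "p_adjusted"] >= p_un - 0.005

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            dunnett_test({"control": np.ones(3), "g": np.array([1.0])}, "control")

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        groups = {g: rng.normal(0, 1, 5) for g in ("control", "a", "b")}
        p1 = dunnett_test(groups, "control", seed=77).table["p_adjusted"]
        p2 = dunnett_test(groups, "control", seed=77).table["p_adjusted"]
        np.testing.assert_array_equal(p1, p2)


def test_significance_stars_thresholds():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.01) == "*"
    assert significance_stars(0.2) == ""
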