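"""Ratios, group comparisons, correlations, cohort profiling."""

import numpy as np
import pandas as pd
import pytest

from endoprofile import biochem, plasma


def panel_from_dict(values):
    """values: {animal_id: (group, {analyte: conc})} -> long panel."""
    rows = []
    for aid, (group, analytes) in values.items():
        for a, v in analytes.items():
            rows.append((aid, group, a, v, plasma.ANALYTE_UNITS.get(a, "a.u.")))
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "analyte", "concentration", "units"]
    )


def average_ranks(values):
    """Hand-rolled average ranks (oracle helper, independent of scipy)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def kruskal_wallis_oracle(groups):
    """Brute-force tie-corrected H from first principles."""
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = average_ranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r_mean = ranks[start : start + len(g)].mean()
        h += len(g) * (r_mean - (n_total + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return h / correction


class TestDeriveRatios:
    def test_equal_analytes_give_ratio_one(self):
        panel = panel_from_dict({"a1": ("G", {"Ang-(1-7)": 80.0, "Ang II": 80.0,
                                              "L-Arg": 50.0, "ADMA": 50.0})})
        out = biochem.derive_ratios(panel)
        ratios = out[out["analyte"] == "Ang-(1-7)/Ang II"]
        assert ratios["concentration"].iloc[0] == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        panel = panel_from_dict({"a1": ("G", {"Ang-(1-7)": 60.0, "Ang II": 120.0,
                                              "L-Arg": 100.0, "ADMA": 0.5})})
        out = biochem.derive_ratios(panel)
        by = out.set_index("analyte")["concentration"]
        assert by["Ang-(1-7)/Ang II"] == pytest.approx(0.5)
        assert by["L-Arg/ADMA"] == pytest.approx(200.0)

    def test_zero_denominator_flagged_not_infinite(self):
        panel = panel_from_dict({"a1": ("G", {"Ang-(1-7)": 60.0, "Ang II": 120.0,
                                              "L-Arg": 100.0, "ADMA": 0.0})})
        out = biochem.derive_ratios(panel)
        row = out[out["analyte"] == "L-Arg/ADMA"].iloc[0]
        assert np.isnan(row["concentration"])
        assert row["flag"] == "zero denominator"

    def test_missing_analyte_names_animal(self):
        panel = panel_from_dict({"a1": ("G", {"Ang-(1-7)": 60.0, "Ang II": 120.0,
                                              "L-Arg": 100.0, "ADMA": 0.5}),
                                 "a2": ("G", {"Ang-(1-7)": 60.0, "Ang II": 120.0,
                                              "L-Arg": 100.0})})
        with pytest.raises(ValueError, match="a2.*ADMA"):
            biochem.derive_ratios(panel)


class TestPercentChange:
    def _two_group_panel(self, ref_vals, trt_vals, analyte="Ang II"):
        rows = []
        for i, v in enumerate(ref_vals):
            rows.append((f"r{i}", "Ref", analyte, v, "fmol/ml"))
        for i, v in enumerate(trt_vals):
            rows.append((f"t{i}", "Trt", analyte, v, "fmol/ml"))
        return pd.DataFrame(
            rows, columns=["animal_id", "group", "analyte", "concentration", "units"]
        )

    def test_identical_groups_zero(self):
        panel = self._two_group_panel([1.0, 2.0], [1.0, 2.0])
        assert biochem.group_percent_change(panel, "Ang II", "Ref", "Trt") == 0.0

    def test_printed_ang2_means_give_minus_58_percent(self):
        panel = self._two_group_panel([119.8, 119.8], [50.2, 50.2])
        pc = biochem.group_percent_change(panel, "Ang II", "Ref", "Trt")
        assert pc == pytest.approx(100 * (50.2 - 119.8) / 119.8)  # -58.1

    def test_median_location_for_counts(self):
        panel = self._two_group_panel([14, 15, 16], [5, 6, 7], analyte="Npx50")
        pc = biochem.group_percent_change(panel, "Npx50", "Ref", "Trt", "median")
        assert pc == pytest.approx(-60.0)

    def test_zero_reference_rejected(self):
        panel = self._two_group_panel([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="zero"):
            biochem.group_percent_change(panel, "Ang II", "Ref", "Trt")


class TestCompareGroups:
    def test_identical_groups_no_evidence(self):
        res = biochem.compare_groups(
            {"a": [1, 1, 1], "b": [1, 1, 1], "c": [1, 1, 1]}
        )
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_kruskal_matches_brute_force_oracle(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        res = biochem.compare_groups({"a": groups[0], "b": groups[1], "c": groups[2]})
        assert res.statistic == pytest.approx(kruskal_wallis_oracle(groups), rel=1e-12)

    def test_kruskal_oracle_on_random_tied_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            sizes = rng.integers(2, 5, size=3)
            if sizes.sum() > 12:
                continue
            groups = [rng.integers(0, 5, size=s).astype(float) for s in sizes]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            res = biochem.compare_groups(
                {f"g{i}": g for i, g in enumerate(groups)}
            )
            assert res.statistic == pytest.approx(
                kruskal_wallis_oracle(groups), rel=1e-10
            )

    def test_two_groups_have_empty_posthoc(self):
        res = biochem.compare_groups({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert len(res.posthoc) == 0

    def test_dunn_posthoc_adjusted_not_smaller(self):
        res = biochem.compare_groups(
            {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        )
        assert len(res.posthoc) == 3
        assert (res.posthoc["p_adjusted"] >= res.posthoc["p_value"] - 1e-15).all()

    def test_parametric_design_runs_anova_tukey_and_ks(self):
        rng = np.random.default_rng(2)
        res = biochem.compare_groups(
            {
                "a": rng.normal(0, 1, 8),
                "b": rng.normal(2, 1, 8),
                "c": rng.normal(4, 1, 8),
            },
            design="parametric",
        )
        assert res.test_name == "one-way ANOVA"
        assert res.p_value < 0.01
        assert len(res.posthoc) == 3
        assert set(res.normality["group"]) == {"a", "b", "c"}

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="n="):
            biochem.compare_groups({"a": [1.0], "b": [1, 2]})


class TestCorrelate:
    def test_linear_relation_perfect_spearman(self):
        x = np.array([1.0, 2, 3, 4, 5])
        res = biochem.correlate(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_monotone_decreasing_perfect_negative(self):
        x = np.array([1.0, 2, 3, 4, 5])
        res = biochem.correlate(x, -(x**3))
        assert res.r == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        res = biochem.correlate(x, y)
        oracle = np.corrcoef(average_ranks(x), average_ranks(y))[0, 1]
        assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_spearman_equals_pearson_on_ranks_random_data(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        res = biochem.correlate(x, y)
        oracle = np.corrcoef(average_ranks(x), average_ranks(y))[0, 1]
        assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            biochem.correlate([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            biochem.correlate([1, 2], [3, 4])


class TestProfileCohort:
    def test_sign_pattern_matches_published_table(self):
        imaging, panel = plasma.simulate_endothelial_cohort(seed=1)
        profile = biochem.profile_cohort(imaging, panel)
        c = profile.correlation
        assert c("bca_volume_change_pct", "npx50").r < 0
        assert c("bca_volume_change_pct", "L-Arg/ADMA").r > 0
        assert c("bca_volume_change_pct", "Ang-(1-7)/Ang II").r > 0
        assert c("npx50", "L-Arg/ADMA").r < 0
        assert c("npx50", "Ang-(1-7)/Ang II").r < 0

    def test_row_order_invariance(self):
        imaging, panel = plasma.simulate_endothelial_cohort(seed=2)
        base = biochem.profile_cohort(imaging, panel)
        shuffled = biochem.profile_cohort(
            imaging.sample(frac=1, random_state=0),
            panel.sample(frac=1, random_state=1),
        )
        pd.testing.assert_frame_equal(base.per_animal, shuffled.per_animal)
        for a, b in zip(base.correlations, shuffled.correlations):
            assert a.r == pytest.approx(b.r, abs=1e-12)

    def test_orphan_animals_rejected(self):
        imaging, panel = plasma.simulate_endothelial_cohort(seed=3)
        with pytest.raises(ValueError, match="mismatch"):
            biochem.profile_cohort(imaging.iloc[:-2], panel)

    def test_tiny_cohort_rejected(self):
        imaging, panel = plasma.simulate_endothelial_cohort(seed=3)
        keep = imaging["animal_id"].iloc[:1]
        with pytest.raises(ValueError):
            biochem.profile_cohort(
                imaging[imaging["animal_id"].isin(keep)],
                panel[panel["animal_id"].isin(keep)],
            )

    def test_percent_change_table_against_untreated(self):
        imaging, panel = plasma.simulate_endothelial_cohort(seed=5)
        profile = biochem.profile_cohort(imaging, panel)
        pc = profile.percent_change
        assert set(pc["reference_group"]) == {"Untreated_6m"}
        npx = pc[(pc["group"] == "MNA_6m") & (pc["endpoint"] == "npx50")]
        assert npx["percent_change"].iloc[0] < 0
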