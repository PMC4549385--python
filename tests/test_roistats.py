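"""Atlas/ROI statistics, subgroup tests, mixed ANOVA, demographics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmvrec.grids import VolumeGrid
from gmvrec.roistats import (
    central_tendency,
    cluster_area_overlap,
    demographics_summary,
    extract_roi_values,
    interaction_anova,
    mann_whitney_both,
    mpm_from_atlas,
    shift_sqrt,
    subgroup_stats,
)
from gmvrec.synthcohort import load_reference_demographics


def _halfspace_atlas(shape=(8, 8, 8)):
    a = np.zeros(shape)
    b = np.zeros(shape)
    a[: shape[0] // 2] = 0.9
    b[shape[0] // 2 :] = 0.9
    return [VolumeGrid(a), VolumeGrid(b)]


class TestMPM:
    def test_halfspace_areas_partition_exactly(self):
        mpm = mpm_from_atlas(_halfspace_atlas())
        assert (mpm[:4] == 1).all() and (mpm[4:] == 2).all()

    def test_tie_resolved_to_first_area(self):
        a = VolumeGrid(np.full((4, 4, 4), 0.5))
        b = VolumeGrid(np.full((4, 4, 4), 0.5))
        assert (mpm_from_atlas([a, b]) == 1).all()

    def test_negligible_probability_left_unassigned(self):
        a = VolumeGrid(np.full((4, 4, 4), 0.001))
        b = VolumeGrid(np.zeros((4, 4, 4)))
        assert (mpm_from_atlas([a, b]) == 0).all()


class TestOverlap:
    def test_cluster_inside_single_area_is_total(self):
        atlas = _halfspace_atlas()
        cluster = np.zeros((8, 8, 8), bool)
        cluster[1:3, 2:4, 2:4] = True
        df = cluster_area_overlap(cluster, atlas)
        assert df.loc[df.area == "area1", "overlap_pct"].item() == 100.0

    def test_percentages_match_brute_force_counts(self):
        atlas = _halfspace_atlas()
        cluster = np.zeros((8, 8, 8), bool)
        cluster.ravel()[np.random.default_rng(0).choice(512, 20, replace=False)] = True
        df = cluster_area_overlap(cluster, atlas)
        n1 = int(cluster[:4].sum())
        assert df.loc[df.area == "area1", "overlap_pct"].item() == pytest.approx(
            100.0 * n1 / 20
        )
        assert df["overlap_pct"].sum() == pytest.approx(100.0)

    def test_reporting_threshold_marks_small_overlaps(self):
        atlas = _halfspace_atlas()
        cluster = np.zeros((8, 8, 8), bool)
        cluster[3, :, :2] = True  # 16 voxels in area1
        cluster[4:, 0, 0] = True  # 4 voxels in area2: 20%
        cluster[3, 0, 2] = False  # 15 in area1, 4 in area2 -> 78.9 / 21.1
        df = cluster_area_overlap(cluster, atlas)
        reported = set(df[df.reported].area)
        assert "area1" in reported and "area2" in reported

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cluster_area_overlap(np.zeros((8, 8, 8), bool), _halfspace_atlas())


class TestCentralTendency:
    def test_uniform_probability_gives_unity(self):
        prob = np.full((6, 6, 6), 0.4)
        cluster = np.zeros((6, 6, 6), bool)
        cluster[2:4, 2:4, 2:4] = True
        assert central_tendency(cluster, prob) == pytest.approx(1.0)

    def test_cluster_on_peak_exceeds_unity(self):
        idx = np.indices((9, 9, 9), dtype=float)
        d2 = ((idx - 4.0) ** 2).sum(0)
        prob = 0.9 * np.exp(-d2 / 8.0)
        cluster = d2 <= 1.0
        assert central_tendency(cluster, prob) > 1.0

    def test_four_voxel_arithmetic_oracle(self):
        prob = np.zeros((4, 1, 1))
        prob[:, 0, 0] = [0.8, 0.6, 0.2, 0.2]
        cluster = np.zeros((4, 1, 1), bool)
        cluster[:2] = True
        assert central_tendency(cluster, prob) == pytest.approx(0.7 / 0.45)

    def test_invariant_to_probability_rescaling(self):
        rng = np.random.default_rng(1)
        prob = rng.uniform(0, 1, size=(6, 6, 6))
        cluster = rng.uniform(size=(6, 6, 6)) > 0.7
        a = central_tendency(cluster, prob)
        b = central_tendency(cluster, 0.37 * prob)
        assert a == pytest.approx(b)

    def test_disjoint_cluster_returns_zero(self):
        prob = np.zeros((6, 6, 6))
        prob[:2] = 0.5
        cluster = np.zeros((6, 6, 6), bool)
        cluster[4:] = True
        assert central_tendency(cluster, prob) == 0.0


class TestROIExtraction:
    def test_without_nuisance_equals_raw_mean(self):
        rng = np.random.default_rng(2)
        maps = rng.normal(size=(6, 5, 5, 5))
        roi = np.zeros((5, 5, 5), bool)
        roi[1:3, 1:3, 1:3] = True
        df = extract_roi_values(maps, {"r": roi})
        np.testing.assert_allclose(
            df["value"].to_numpy(), maps[:, roi].mean(axis=1)
        )

    def test_planted_covariate_effect_removed(self):
        rng = np.random.default_rng(3)
        n = 30
        cov = rng.normal(size=n)
        maps = cov[:, None, None, None] * np.ones((1, 5, 5, 5)) + rng.normal(
            0, 0.1, size=(n, 5, 5, 5)
        )
        roi = np.ones((5, 5, 5), bool)
        df = extract_roi_values(maps, {"r": roi}, nuisance=cov[:, None])
        r = np.corrcoef(df["value"], cov)[0, 1]
        assert abs(r) < 0.05

    def test_single_voxel_roi_returns_that_voxel(self):
        maps = np.random.default_rng(4).normal(size=(3, 4, 4, 4))
        roi = np.zeros((4, 4, 4), bool)
        roi[2, 1, 3] = True
        df = extract_roi_values(maps, {"v": roi})
        np.testing.assert_allclose(df["value"].to_numpy(), maps[:, 2, 1, 3])

    def test_empty_roi_rejected(self):
        maps = np.zeros((3, 4, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            extract_roi_values(maps, {"e": np.zeros((4, 4, 4), bool)})


class TestSubgroupStats:
    def test_identical_groups_have_central_u_and_zero_h(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = subgroup_stats(np.concatenate([g, g]), ["a"] * 4 + ["b"] * 4)
        u = res["pairwise"][("a", "b")]
        assert u.value == 4 * 4 / 2
        assert res["kruskal"].value == pytest.approx(0.0, abs=1e-12)

    def test_u_statistics_sum_to_pair_count(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=9), rng.normal(size=13)
        r = mann_whitney_both(x, y)
        assert r.extra["U_x"] + r.extra["U_y"] == 9 * 13

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_u_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 8, size=rng.integers(2, 9)).astype(float)
        y = rng.integers(0, 8, size=rng.integers(2, 9)).astype(float)
        brute = sum(
            1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y
        )
        assert mann_whitney_both(x, y).extra["U_x"] == pytest.approx(brute)

    def test_two_group_h_equals_normal_approx_z_squared(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=10)
        y = rng.normal(1.0, 1.0, size=12)  # continuous: tie-free
        res = subgroup_stats(np.concatenate([x, y]), ["a"] * 10 + ["b"] * 12)
        u = res["pairwise"][("a", "b")].extra["U_x"]
        n1, n2 = 10, 12
        z = (u - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert res["kruskal"].value == pytest.approx(z**2, rel=1e-10)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            subgroup_stats(np.array([1.0, 2.0, 3.0]), ["a", "a", "b"])


class TestInteractionAnova:
    @staticmethod
    def _crossed(n_per_group=10, interaction=0.1, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for gi, g in enumerate(("fast", "slow", "poor")):
            for i in range(n_per_group):
                sid = f"{g}{i}"
                # cortical effect high in fast, subcortical high in poor
                cort = 0.02 + interaction * (2 - gi) / 2 + rng.normal(0, 0.02)
                sub = 0.02 + interaction * gi / 2 + rng.normal(0, 0.02)
                rows.append((sid, g, "cortical", cort))
                rows.append((sid, g, "subcortical", sub))
        return pd.DataFrame(rows, columns=["subject", "group", "site", "value"])

    def test_shift_makes_minimum_zero(self):
        x = np.array([-0.006, 0.0, 0.01])
        t, shift = shift_sqrt(x)
        assert shift == pytest.approx(0.006)
        assert t[0] == 0.0

    def test_nonnegative_data_left_unshifted(self):
        t, shift = shift_sqrt(np.array([0.0, 1.0, 4.0]))
        assert shift == 0.0
        np.testing.assert_allclose(t, [0.0, 1.0, 2.0])

    def test_planted_interaction_detected(self):
        res = interaction_anova(self._crossed(interaction=0.1, seed=1))
        assert res.p < 0.05
        assert res.df == (2, 27)

    def test_null_interaction_effect_size_small(self):
        etas = [
            interaction_anova(self._crossed(interaction=0.0, seed=s)).eta2
            for s in range(20)
        ]
        assert np.mean(etas) < 0.05

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        df = self._crossed(interaction=0.05, seed=3)
        ours = interaction_anova(df, transform=False)
        aov = pg.mixed_anova(
            data=df, dv="value", within="site", subject="subject", between="group"
        )
        inter = aov[aov.Source == "Interaction"].iloc[0]
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        assert ours.F == pytest.approx(inter.F, rel=1e-6)
        assert ours.p == pytest.approx(inter[p_col], rel=1e-6)
        assert ours.partial_eta2 == pytest.approx(inter.np2, rel=1e-6)

    def test_empty_cell_rejected(self):
        df = self._crossed(n_per_group=3)
        df = df[~((df.group == "slow") & (df.site == "cortical"))]
        with pytest.raises(ValueError, match="cell"):
            interaction_anova(df)


@pytest.fixture(scope="module")
def table():
    return load_reference_demographics()


class TestDemographics:

    def test_cohort_age_summary(self, table):
        demo = demographics_summary(table)
        assert demo["n"] == 28
        assert round(demo["age_mean"], 1) == 64.7
        assert demo["age_range"] == (41.0, 82.0)

    def test_age_comparison_between_hemispheres(self, table):
        demo = demographics_summary(table)
        t = demo["age_by_side_t"]
        assert round(t.value, 2) == 0.93
        assert t.df == 26
        assert t.p > 0.05

    def test_lesion_volume_summary_and_test(self, table):
        demo = demographics_summary(table)
        assert round(demo["lesion_volume_mean_cc"], 1) == 24.4
        assert demo["lesion_volume_by_side_u"].value == 133.5

    def test_ordinal_score_comparisons(self, table):
        demo = demographics_summary(table)
        assert demo["nihss_by_side_u"].extra["U_y"] == 89.0
        assert demo["mrs_by_side_u"].extra["U_y"] == 94.0
        assert demo["nihss_median"] == 4.0 and demo["mrs_median"] == 2.0

    def test_equal_groups_give_zero_t(self):
        df = pd.DataFrame(
            {
                "age": [60, 70, 60, 70],
                "sex": list("mmff"),
                "side": list("LLRR"),
                "lesion_volume_cc": [1.0, 2.0, 3.0, 4.0],
            }
        )
        assert demographics_summary(df)["age_by_side_t"].value == pytest.approx(0.0)

    def test_missing_column_rejected(self, table):
        with pytest.raises(ValueError, match="side"):
            demographics_summary(table.drop(columns=["side"]))
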