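"""Zone classification, TSI scoring and cohort safety summaries."""

import numpy as np
import pandas as pd
import pytest

from trajsafe.safety import (
    SafetyComponents,
    ZoneThresholds,
    classify_zone,
    compare_component_incidence,
    compute_tsi,
    evaluate_trajectory,
    summarize_safety,
)
from trajsafe.scene_model import (
    AnatomicalScene,
    MidlinePlane,
    Point3,
    SceneError,
    StreamlineBundle,
    TrajectoryPlan,
    VolumetricMask,
)


class TestZones:
    @pytest.mark.parametrize(
        "d,structure,zone",
        [
            (2.9, "vessel", 1),
            (16.8, "midline", 1),
            (3.0, "vessel", 2),  # boundary belongs to zone 2
            (3.0, "cst", 2),
            (2.9, "cst", 1),
            (20.0, "midline", 2),
            (25.0, "midline", 2),
        ],
    )
    def test_zone_assignment(self, d, structure, zone):
        assert classify_zone(d, structure) == zone

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            classify_zone(-0.1, "vessel")


def components(sulcus=False, eloquent=False, ventricle=False,
               vessel_zone=2, midline_zone=2, cst_zone=None):
    return SafetyComponents(
        sulcus_transgressed=sulcus, eloquent_transgressed=eloquent,
        ventricle_transgressed=ventricle, vessel_zone=vessel_zone,
        midline_zone=midline_zone, d_vessel=10.0, d_midline=30.0,
        cst_zone=cst_zone, d_cst=None,
    )


class TestTSI:
    def test_no_flags_scores_zero(self):
        assert compute_tsi(components()) == 0

    def test_all_four_flags_score_four(self):
        assert compute_tsi(components(True, True, False, 1, 1)) == 4

    def test_ventricle_and_cst_are_reported_not_scored(self):
        assert compute_tsi(components(ventricle=True, cst_zone=1)) == 0

    def test_monotone_in_each_flag(self):
        base = compute_tsi(components())
        assert compute_tsi(components(sulcus=True)) == base + 1
        assert compute_tsi(components(vessel_zone=1)) == base + 1


def _box_mask(affine_origin, shape, fill_slices, label):
    grid = np.zeros(shape, bool)
    grid[fill_slices] = True
    affine = np.eye(4)
    affine[:3, 3] = affine_origin
    return VolumetricMask(grid=grid, affine=affine, label=label)


@pytest.fixture
def constructed_scene():
    """Hand-built scene with structures at known positions (1 mm voxels).

    The trajectory (30, 0, 60) -> (30, 0, 5) runs vertically at x = 30.
    The sulcus and M1 slabs sit across its path, a vessel line passes
    2 mm from it, and the midline plane is at x = 0 (so d = 30).
    """
    shape = (60, 40, 70)
    origin = (0, -20, 0)
    tumour = _box_mask(origin, shape, (slice(27, 34), slice(17, 24), slice(2, 9)), "tumour")
    sulci = _box_mask(origin, shape, (slice(25, 36), slice(15, 26), slice(50, 53)), "sulcus")
    m1 = _box_mask(origin, shape, (slice(25, 36), slice(15, 26), slice(40, 43)),
                   "eloquent_cortex")
    vent = _box_mask(origin, shape, (slice(2, 6), slice(15, 26), slice(10, 20)), "ventricle")
    vessels = StreamlineBundle(
        [np.array([[32, -10, 30], [32, 10, 30]], dtype=np.float32)], "vessel"
    )
    cst = StreamlineBundle(
        [np.array([[45, 0, 60], [45, 0, 5]], dtype=np.float32)], "CST"
    )
    return AnatomicalScene(
        tumour_id="constructed",
        tumour_mask=tumour,
        target=Point3(30, 0, 5),
        sulci=sulci,
        eloquent_cortex=m1,
        ventricles=vent,
        midline=MidlinePlane.from_landmarks(Point3(0, 10, 0), Point3(0, -10, 0)),
        cortical_surface=np.array([[30, 0, 60]], dtype=np.float32),
        cst=cst,
        vessels=vessels,
    )


def _plan(entry, target):
    return TrajectoryPlan(
        trainee_id="TR01", tumour_id="constructed", group="T-nBx",
        entry=Point3(*entry), target=Point3(*target), planning_time_s=100.0,
        n_trajectory_changes=0, n_lobe_changes=0, exercise_order=1,
        experience_years=3.0,
    )


class TestEvaluateTrajectory:
    def test_risky_trajectory_scores_four(self, constructed_scene):
        # pierces sulcus and M1, 2 mm from the vessel, inside midline zone 1
        # (after shifting the scene so the path sits 10 mm from midline)
        rep = evaluate_trajectory(_plan((30, 0, 60), (30, 0, 5)), constructed_scene,
                                  ZoneThresholds(midline_mm=35.0))
        c = rep.components
        assert c.sulcus_transgressed and c.eloquent_transgressed
        assert c.d_vessel == pytest.approx(2.0)
        assert c.vessel_zone == 1
        assert c.d_midline == pytest.approx(30.0)
        assert c.midline_zone == 1
        assert rep.tsi == 4
        assert rep.length_mm == pytest.approx(55.0)

    def test_clear_trajectory_scores_zero(self, constructed_scene):
        # enter laterally at a depth between the slabs and the vessel plane
        rep = evaluate_trajectory(_plan((55, 0, 7), (30, 0, 5)), constructed_scene)
        assert rep.tsi == 0
        assert rep.components.cst_zone in (1, 2)

    def test_m1_only_scores_one(self, constructed_scene):
        # below the sulcus slab, medial of the vessel line
        rep = evaluate_trajectory(_plan((26, 0, 44), (26, 0, 5)), constructed_scene)
        c = rep.components
        assert c.eloquent_transgressed and not c.sulcus_transgressed
        assert rep.tsi == 1

    def test_ventricle_hit_not_scored(self, constructed_scene):
        rep = evaluate_trajectory(_plan((3, 0, 18), (30, 0, 5)), constructed_scene)
        assert rep.components.ventricle_transgressed
        assert rep.tsi <= 2  # may clip vessel/midline zones, never ventricle

    def test_missing_vessel_structure_is_named(self, constructed_scene):
        constructed_scene.vessels = None
        constructed_scene.vessel_mask = None
        with pytest.raises(SceneError, match="vessel"):
            evaluate_trajectory(_plan((30, 0, 60), (30, 0, 5)), constructed_scene)


def synthetic_report_frame(counts_t, counts_a, n_t=95, n_a=95,
                           cst_t=14, lengths=(54.54, 62.37)):
    """Build a report table whose component counts match given tallies.

    Flags are assigned to the first k rows of each arm, which is
    sufficient because summaries depend only on counts.
    """
    rows = []
    for g, counts, n, cst_n in (("T-nBx", counts_t, n_t, cst_t),
                                ("A-nBx", counts_a, n_a, 0)):
        for i in range(n):
            rows.append({
                "group": g,
                "vessel_zone": 1 if i < counts["vessel"] else 2,
                "sulcus_transgressed": i < counts["sulcus"],
                "eloquent_transgressed": i < counts["eloquent"],
                "ventricle_transgressed": i < counts.get("ventricle", 0),
                "midline_zone": 1 if i < counts["midline"] else 2,
                "cst_zone": 1 if i < cst_n else 2,
                "d_vessel": 1.0, "d_cst": 5.0, "d_midline": 25.0,
                "length_mm": lengths[0] if g == "T-nBx" else lengths[1],
            })
    df = pd.DataFrame(rows)
    df["tsi"] = (
        (df.vessel_zone == 1).astype(int)
        + df.sulcus_transgressed.astype(int)
        + df.eloquent_transgressed.astype(int)
        + (df.midline_zone == 1).astype(int)
    )
    return df


STUDY_T = {"vessel": 51, "sulcus": 42, "eloquent": 23, "midline": 14, "ventricle": 0}
STUDY_A = {"vessel": 55, "sulcus": 51, "eloquent": 41, "midline": 12, "ventricle": 1}


class TestSummaries:
    def test_overall_counts_and_percentages(self):
        df = synthetic_report_frame(STUDY_T, STUDY_A)
        s = summarize_safety(df)
        assert s.components.loc["vessel", "count"] == 106
        assert round(s.components.loc["vessel", "pct"], 2) == 55.79
        assert s.components.loc["cst", "count"] == 14
        assert round(s.components.loc["cst", "pct"], 2) == 14.74
        assert s.components.loc["vessel", "count_T"] == 51
        assert s.components.loc["vessel", "count_A"] == 55

    def test_empty_cohort_summary(self):
        s = summarize_safety(pd.DataFrame())
        assert s.n_total == 0
        assert (s.components["count"] == 0).all()
        assert s.components["pct"].isna().all()

    def test_row_permutation_leaves_summary_unchanged(self):
        df = synthetic_report_frame(STUDY_T, STUDY_A)
        perm = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a, b = summarize_safety(df), summarize_safety(perm)
        pd.testing.assert_frame_equal(a.components, b.components)
        pd.testing.assert_frame_equal(a.group_stats, b.group_stats)

    def test_group_mean_tsi_equals_component_count_sum(self):
        df = synthetic_report_frame(STUDY_T, STUDY_A)
        s = summarize_safety(df)
        t = df[df.group == "T-nBx"]
        expected = (51 + 42 + 23 + 14) / 95
        assert s.group_stats.loc["T-nBx", "mean_tsi"] == pytest.approx(expected)
        assert t.tsi.mean() == pytest.approx(expected)


class TestComponentIncidenceTest:
    def test_identical_counts_give_p_one(self):
        df = synthetic_report_frame(STUDY_T, dict(STUDY_T))
        res = compare_component_incidence(df, "vessel")
        assert res.p_value == pytest.approx(1.0)

    def test_eloquent_difference_is_significant(self):
        df = synthetic_report_frame(STUDY_T, STUDY_A)
        res = compare_component_incidence(df, "eloquent_cortex")
        assert 0.004 < res.p_value < 0.01
        assert res.odds_ratio < 1  # fewer transgressions with tractography

    def test_vessel_difference_is_not_significant(self):
        df = synthetic_report_frame(STUDY_T, STUDY_A)
        res = compare_component_incidence(df, "vessel")
        assert res.p_value > 0.05

    def test_zero_margin_falls_back_to_fisher(self):
        counts = dict(STUDY_T, ventricle=0)
        df = synthetic_report_frame(counts, dict(STUDY_A, ventricle=0))
        res = compare_component_incidence(df, "ventricle")
        assert res.method == "fisher"
        assert res.p_value == pytest.approx(1.0)


class TestThresholdMonotonicity:
    def test_shrinking_threshold_never_increases_zone1(self, reports):
        d = reports["d_vessel"].to_numpy()
        counts = [(d < thr).sum() for thr in (3.0, 2.0, 1.0, 0.5, 0.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
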