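"""Shared fixtures: synthetic study scenes, a simulated cohort, scored
reports, and the 20-replicate calibration summary used by several suites."""

import numpy as np
import pandas as pd
import pytest

import trajsafe as ts
from trajsafe.analysis import learning_curve_trend, normalize_planning_times
from trajsafe.synthetic import CohortParams, build_planner_scenes

STUDY_SCENE_SEED = 42


@pytest.fixture(scope="session")
def scenes10():
    return ts.generate_scenes(STUDY_SCENE_SEED, 10)


@pytest.fixture(scope="session")
def planner_scenes(scenes10):
    return build_planner_scenes(scenes10)


@pytest.fixture(scope="session")
def cohort(scenes10, planner_scenes):
    return ts.generate_cohort(scenes10, CohortParams(seed=1),
                              planner_scenes=planner_scenes)


def score_cohort(coh: pd.DataFrame, scenes) -> pd.DataFrame:
    by_id = {s.tumour_id: s for s in scenes}
    recs = []
    for _, r in coh.iterrows():
        plan = ts.TrajectoryPlan(
            trainee_id=r.trainee_id,
            tumour_id=r.tumour_id,
            group=r.group,
            entry=ts.Point3(r.entry_x, r.entry_y, r.entry_z),
            target=ts.Point3(r.target_x, r.target_y, r.target_z),
            planning_time_s=r.planning_time_s,
            n_trajectory_changes=int(r.n_trajectory_changes),
            n_lobe_changes=int(r.n_lobe_changes),
            exercise_order=int(r.exercise_order),
            experience_years=r.experience_years,
        )
        rep = ts.evaluate_trajectory(plan, by_id[r.tumour_id])
        d = rep.to_dict()
        d["group"] = r.group
        recs.append(d)
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def reports(cohort, scenes10):
    return score_cohort(cohort, scenes10)


@pytest.fixture(scope="session")
def calibration20(scenes10, planner_scenes):
    """Group-level means and learning-curve p-values over 20 replicate
    cohorts (seeds 1-20) on the fixed study scenes."""
    out = {
        "traj_T": [], "traj_A": [], "lobe_T": [], "lobe_A": [],
        "time_T": [], "time_A": [], "norm_T": [], "norm_A": [],
        "exp_mean": [], "lc_p_A": [], "lc_p_T": [],
    }
    for seed in range(1, 21):
        coh = ts.generate_cohort(scenes10, CohortParams(seed=seed),
                                 planner_scenes=planner_scenes)
        coh = normalize_planning_times(coh)
        for gkey, gname in (("T", "T-nBx"), ("A", "A-nBx")):
            sub = coh[coh.group == gname]
            out[f"traj_{gkey}"].append(sub.n_trajectory_changes.mean())
            out[f"lobe_{gkey}"].append(sub.n_lobe_changes.mean())
            out[f"time_{gkey}"].append(sub.planning_time_s.mean())
            out[f"norm_{gkey}"].append(sub.normalized_time.mean())
        out["exp_mean"].append(
            coh.groupby("trainee_id").experience_years.first().mean()
        )
        out["lc_p_A"].append(learning_curve_trend(coh, "A-nBx").p_value)
        out["lc_p_T"].append(learning_curve_trend(coh, "T-nBx").p_value)
    return {k: np.asarray(v) for k, v in out.items()}
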