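"""Zone classification, the Trajectory Safety Index, and cohort summaries.

The Trajectory Safety Index (TSI) is a 0-4 risk score for a planned
stereotactic biopsy trajectory: one point each for (1) transgressing a
sulcus, (2) transgressing eloquent (M1) cortex, (3) passing within the
high-risk vessel zone (< 3 mm of a vessel, "zone 1"), and (4) passing
within the high-risk midline zone (< 20 mm of the midsagittal plane).
Ventricle transgression and CST proximity zone are computed and reported
alongside, but are not part of the score.

A distance exactly equal to a zone threshold is classified as zone 2
(low risk); the zones are defined by strict inequalities on either side
and the boundary is a measure-zero case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    Segment,
    distance_to_midline,
    min_distance_to_mask,
    min_distance_to_streamlines,
    segment_length,
    transgresses_mask,
)
from .scene_model import AnatomicalScene, SceneError, TrajectoryPlan

__all__ = [
    "ZoneThresholds",
    "SafetyComponents",
    "SafetyReport",
    "classify_zone",
    "compute_tsi",
    "evaluate_trajectory",
    "summarize_safety",
    "SafetySummary",
    "compare_component_incidence",
    "ComponentTest",
    "REPORT_COLUMNS",
]

#: SafetyReport fields as cohort-table columns, in canonical order.
REPORT_COLUMNS = (
    "sulcus_transgressed",
    "eloquent_transgressed",
    "ventricle_transgressed",
    "vessel_zone",
    "midline_zone",
    "cst_zone",
    "d_vessel",
    "d_cst",
    "d_midline",
    "tsi",
    "length_mm",
)

_STRUCTURES = ("vessel", "cst", "midline")


@dataclass(frozen=True)
class ZoneThresholds:
    """Zone-1 distance thresholds in mm (vessel/CST 3, midline 20)."""

    vessel_mm: float = 3.0
    cst_mm: float = 3.0
    midline_mm: float = 20.0

    def __post_init__(self):
        if min(self.vessel_mm, self.cst_mm, self.midline_mm) < 0:
            raise ValueError("zone thresholds must be >= 0")

    def for_structure(self, structure: str) -> float:
        if structure not in _STRUCTURES:
            raise ValueError(f"unknown structure {structure!r}")
        return {"vessel": self.vessel_mm, "cst": self.cst_mm,
                "midline": self.midline_mm}[structure]


def classify_zone(d: float, structure: str, thr: ZoneThresholds = ZoneThresholds()) -> int:
    """Zone 1 (high risk) iff distance < threshold, else zone 2."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    return 1 if d < thr.for_structure(structure) else 2


@dataclass(frozen=True)
class SafetyComponents:
    """Per-trajectory geometric flags, zones and distances."""

    sulcus_transgressed: bool
    eloquent_transgressed: bool
    ventricle_transgressed: bool
    vessel_zone: int
    midline_zone: int
    d_vessel: float
    d_midline: float
    cst_zone: Optional[int] = None  # None = no CST bundle in the scene
    d_cst: Optional[float] = None

    def __post_init__(self):
        if self.vessel_zone not in (1, 2) or self.midline_zone not in (1, 2):
            raise ValueError("zones must be 1 or 2")
        if self.cst_zone is not None and self.cst_zone not in (1, 2):
            raise ValueError("cst_zone must be 1, 2 or None")


def compute_tsi(c: SafetyComponents) -> int:
    """Sum of the four scored indicators (sulcus, eloquent, vessel z1, midline z1).

    Ventricle transgression and CST zone are reported but never scored.
    """
    return int(
        bool(c.sulcus_transgressed)
        + bool(c.eloquent_transgressed)
        + (c.vessel_zone == 1)
        + (c.midline_zone == 1)
    )


@dataclass(frozen=True)
class SafetyReport:
    components: SafetyComponents
    tsi: int
    length_mm: float

    def __post_init__(self):
        if not 0 <= self.tsi <= 4:
            raise ValueError("tsi outside [0, 4]")

    def to_dict(self) -> dict:
        c = self.components
        return {
            "sulcus_transgressed": bool(c.sulcus_transgressed),
            "eloquent_transgressed": bool(c.eloquent_transgressed),
            "ventricle_transgressed": bool(c.ventricle_transgressed),
            "vessel_zone": int(c.vessel_zone),
            "midline_zone": int(c.midline_zone),
            "cst_zone": None if c.cst_zone is None else int(c.cst_zone),
            "d_vessel": float(c.d_vessel),
            "d_cst": None if c.d_cst is None else float(c.d_cst),
            "d_midline": float(c.d_midline),
            "tsi": int(self.tsi),
            "length_mm": float(self.length_mm),
        }


def evaluate_trajectory(
    plan: TrajectoryPlan,
    scene: AnatomicalScene,
    thr: ZoneThresholds = ZoneThresholds(),
) -> SafetyReport:
    """Score one planned trajectory against the full scene.

    All distances and flags come from the exact geometry primitives;
    scoring always uses the complete scene regardless of what was visible
    to the planner.  Vessels may be represented as centerline polylines, a
    mask, or both; with both, the smaller distance is used.
    """
    seg = Segment(plan.entry.to_array(), plan.target.to_array())
    for attr, label in (
        ("sulci", "sulcus"),
        ("eloquent_cortex", "eloquent_cortex"),
        ("ventricles", "ventricle"),
    ):
        if getattr(scene, attr) is None:
            raise SceneError(f"scene {scene.tumour_id!r} lacks scored structure {label!r}")
    if scene.vessels is None and scene.vessel_mask is None:
        raise SceneError(f"scene {scene.tumour_id!r} lacks scored structure 'vessel'")
    if scene.midline is None:
        raise SceneError(f"scene {scene.tumour_id!r} lacks scored structure 'midline'")

    d_vessel = np.inf
    if scene.vessels is not None:
        d_vessel = min_distance_to_streamlines(seg, scene.vessels)
    if scene.vessel_mask is not None:
        d_vessel = min(d_vessel, min_distance_to_mask(seg, scene.vessel_mask))
    d_midline = distance_to_midline(seg, scene.midline)
    d_cst = cst_zone = None
    if scene.cst is not None:
        d_cst = min_distance_to_streamlines(seg, scene.cst)
        cst_zone = classify_zone(d_cst, "cst", thr)

    components = SafetyComponents(
        sulcus_transgressed=transgresses_mask(seg, scene.sulci),
        eloquent_transgressed=transgresses_mask(seg, scene.eloquent_cortex),
        ventricle_transgressed=transgresses_mask(seg, scene.ventricles),
        vessel_zone=classify_zone(float(d_vessel), "vessel", thr),
        midline_zone=classify_zone(d_midline, "midline", thr),
        d_vessel=float(d_vessel),
        d_midline=d_midline,
        cst_zone=cst_zone,
        d_cst=d_cst,
    )
    return SafetyReport(
        components=components,
        tsi=compute_tsi(components),
        length_mm=segment_length(seg),
    )


# ---------------------------------------------------------------------------
# Cohort-level summaries
# ---------------------------------------------------------------------------

_T, _A = "T-nBx", "A-nBx"


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


@dataclass
class SafetySummary:
    """Component incidence table plus per-group TSI/length statistics."""

    components: pd.DataFrame
    group_stats: pd.DataFrame
    n_total: int


def _component_flags(df: pd.DataFrame) -> pd.DataFrame:
    """Boolean incidence columns for the six reported safety components."""
    out = pd.DataFrame(index=df.index)
    out["vessel"] = df["vessel_zone"] == 1
    out["sulcus"] = df["sulcus_transgressed"].astype(bool)
    out["eloquent_cortex"] = df["eloquent_transgressed"].astype(bool)
    out["ventricle"] = df["ventricle_transgressed"].astype(bool)
    out["midline"] = df["midline_zone"] == 1
    out["cst"] = df["cst_zone"] == 1
    return out


def summarize_safety(df: pd.DataFrame) -> SafetySummary:
    """Tabulate component incidences and group TSI/length means.

    ``df`` holds one row per scored trajectory with the
    :data:`REPORT_COLUMNS` plus a ``group`` column.  The CST row follows the
    study reporting convention: its incidence is tabulated over the
    tractography-enhanced group only.  An empty cohort yields zero counts
    with undefined percentages.
    """
    if len(df) == 0:
        comp = pd.DataFrame(
            {"n": 0, "count": 0, "pct": np.nan, "count_T": 0, "count_A": 0},
            index=pd.Index(
                ["vessel", "sulcus", "eloquent_cortex", "ventricle", "midline", "cst"],
                name="component",
            ),
        )
        gs = pd.DataFrame(
            columns=["n", "mean_tsi", "sem_tsi", "mean_length_mm", "sem_length_mm"]
        )
        return SafetySummary(components=comp, group_stats=gs, n_total=0)

    flags = _component_flags(df)
    grp = df["group"].to_numpy()
    rows = []
    for comp in ("vessel", "sulcus", "eloquent_cortex", "ventricle", "midline"):
        f = flags[comp].to_numpy()
        n = len(df)
        rows.append(
            {
                "component": comp,
                "n": n,
                "count": int(f.sum()),
                "pct": 100.0 * f.sum() / n,
                "count_T": int(f[grp == _T].sum()),
                "count_A": int(f[grp == _A].sum()),
            }
        )
    # CST incidence is reported over the tractography-enhanced arm only
    t_rows = grp == _T
    f_cst = flags["cst"].to_numpy() & t_rows
    n_t = int(t_rows.sum())
    rows.append(
        {
            "component": "cst",
            "n": n_t,
            "count": int(f_cst.sum()),
            "pct": (100.0 * f_cst.sum() / n_t) if n_t else np.nan,
            "count_T": int(f_cst.sum()),
            "count_A": 0,
        }
    )
    comp = pd.DataFrame(rows).set_index("component")

    stats_rows = {}
    for name, sub in (
        (_T, df[grp == _T]),
        (_A, df[grp == _A]),
        ("overall", df),
    ):
        stats_rows[name] = {
            "n": len(sub),
            "mean_tsi": float(np.mean(sub["tsi"])) if len(sub) else np.nan,
            "sem_tsi": _sem(sub["tsi"]) if len(sub) else np.nan,
            "mean_length_mm": float(np.mean(sub["length_mm"])) if len(sub) else np.nan,
            "sem_length_mm": _sem(sub["length_mm"]) if len(sub) else np.nan,
        }
    gs = pd.DataFrame(stats_rows).T
    gs.index.name = "group"
    return SafetySummary(components=comp, group_stats=gs, n_total=len(df))


@dataclass(frozen=True)
class ComponentTest:
    component: str
    statistic: float
    p_value: float
    odds_ratio: float
    method: str  # "chi2" or "fisher" (zero-margin fallback)


def compare_component_incidence(df: pd.DataFrame, component: str) -> ComponentTest:
    """Test the group x component-flag 2x2 table.

    Pearson chi-square without continuity correction by default; a table
    with a zero margin falls back to Fisher's exact test and the result is
    flagged via ``method``.
    """
    flags = _component_flags(df)
    if component not in flags.columns:
        raise ValueError(f"unknown component {component!r}")
    f = flags[component].to_numpy()
    grp = df["group"].to_numpy()
    table = np.array(
        [
            [int((f & (grp == g)).sum()), int((~f & (grp == g)).sum())]
            for g in (_T, _A)
        ],
        dtype=float,
    )
    a, b = table[0]
    c, d = table[1]
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        res = stats.fisher_exact(table.astype(int))
        return ComponentTest(component, np.nan, float(res.pvalue), odds, "fisher")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ComponentTest(component, float(chi2), float(p), odds, "chi2")
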