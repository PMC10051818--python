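"""Cohort statistics: normalized times, group comparisons, experience
adjustment, the learning-curve trend, and planning-profile clustering.

Continuous outcomes are compared with Welch two-sample t-tests and, for the
experience-adjusted analysis, linear regression of the outcome on group and
years of neurosurgical experience; binary flags use logistic regression.
The learning curve is the within-group trend of log planning time across
the ten sequential exercises.  Planning profiles are clustered on four
standardized features — trajectory changes, lobe changes, tractography
availability and normalized planning time — via a k-nearest-neighbour
graph and Leiden community detection, with a 2-D UMAP embedding for
display.  Raw p-values are reported without multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GroupComparison",
    "ClusterResult",
    "LearningTrend",
    "normalize_planning_times",
    "compare_group_means",
    "adjusted_comparison",
    "learning_curve_trend",
    "cluster_planning_profiles",
    "CLUSTER_FEATURES",
]

_T, _A = "T-nBx", "A-nBx"

CLUSTER_FEATURES = (
    "n_trajectory_changes",
    "n_lobe_changes",
    "tractography_available",
    "normalized_time",
)


def _sem(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


@dataclass(frozen=True)
class GroupComparison:
    """A univariate group comparison in the style of the study's Table 1."""

    variable: str
    mean_t: float
    sem_t: float
    mean_a: float
    sem_a: float
    difference: float  # A - T
    p_value: float
    p_adjusted: Optional[float] = None
    adjustment_flag: Optional[str] = None

    def __post_init__(self):
        for s in (self.sem_t, self.sem_a):
            if np.isfinite(s) and s < 0:
                raise ValueError("SEM must be >= 0")
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class LearningTrend:
    group: str
    slope: float  # change in log planning time per exercise position
    stderr: float
    p_value: float
    ci_low: float
    ci_high: float


@dataclass
class ClusterResult:
    labels: np.ndarray
    embedding: Optional[np.ndarray]
    n_clusters: int
    features: pd.DataFrame


def normalize_planning_times(df: pd.DataFrame) -> pd.DataFrame:
    """Per-trainee min-max normalization of planning time.

    Each trainee's times are mapped to [0, 1] over their own exercises:
    (t - min) / (max - min); a degenerate (constant) range maps to 0.5.
    Requires at least two plans per trainee.
    """
    counts = df.groupby("trainee_id")["planning_time_s"].count()
    bad = counts[counts < 2]
    if len(bad):
        raise ValueError(
            f"trainees with fewer than 2 plans cannot be normalized: "
            f"{', '.join(map(str, bad.index))}"
        )
    out = df.copy()

    def _minmax(s):
        lo, hi = s.min(), s.max()
        if hi - lo <= 0:
            return pd.Series(0.5, index=s.index)
        return (s - lo) / (hi - lo)

    out["normalized_time"] = (
        df.groupby("trainee_id")["planning_time_s"].transform(_minmax)
    )
    return out


def _split(df, variable):
    t = df.loc[df["group"] == _T, variable].astype(float).to_numpy()
    a = df.loc[df["group"] == _A, variable].astype(float).to_numpy()
    if len(t) == 0 or len(a) == 0:
        raise ValueError("both groups must be non-empty")
    return t, a


def compare_group_means(df: pd.DataFrame, variable: str) -> GroupComparison:
    """Welch two-sample comparison of a continuous variable between arms."""
    t, a = _split(df, variable)
    res = stats.ttest_ind(a, t, equal_var=False)
    return GroupComparison(
        variable=variable,
        mean_t=float(np.mean(t)),
        sem_t=_sem(t),
        mean_a=float(np.mean(a)),
        sem_a=_sem(a),
        difference=float(np.mean(a) - np.mean(t)),
        p_value=float(res.pvalue),
    )


def adjusted_comparison(
    df: pd.DataFrame, variable: str, binary: Optional[bool] = None
) -> GroupComparison:
    """Group comparison adjusted for years of neurosurgical experience.

    Fits outcome ~ group + experience_years (OLS for continuous outcomes,
    logistic for binary flags); the adjusted p-value is that of the group
    coefficient.  If experience is constant the adjustment is impossible:
    the unadjusted p is returned with ``adjustment_flag`` set.
    """
    base = compare_group_means(df, variable)
    y = df[variable].astype(float).to_numpy()
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}
    g = (df["group"] == _A).astype(float).to_numpy()
    exp_years = df["experience_years"].astype(float).to_numpy()
    flag = None
    if np.ptp(exp_years) <= 0:
        return GroupComparison(
            **{**base.__dict__, "p_adjusted": base.p_value,
               "adjustment_flag": "experience constant; adjusted = unadjusted"},
        )
    X = sm.add_constant(np.column_stack([g, exp_years]))
    if binary:
        fit = sm.Logit(y, X).fit(disp=False)
    else:
        fit = sm.OLS(y, X).fit()
    p_adj = float(fit.pvalues[1])
    return GroupComparison(
        **{**base.__dict__, "p_adjusted": p_adj, "adjustment_flag": flag}
    )


def learning_curve_trend(df: pd.DataFrame, group: str) -> LearningTrend:
    """Trend of log planning time across exercise order within one arm."""
    sub = df[df["group"] == group]
    orders = sub["exercise_order"].astype(float).to_numpy()
    if len(np.unique(orders)) < 2:
        raise ValueError("learning curve needs at least two exercise positions")
    y = np.log(sub["planning_time_s"].astype(float).to_numpy())
    X = sm.add_constant(orders)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()[1]
    return LearningTrend(
        group=group,
        slope=float(fit.params[1]),
        stderr=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
    )


def _feature_matrix(df: pd.DataFrame) -> pd.DataFrame:
    if "normalized_time" not in df.columns:
        df = normalize_planning_times(df)
    feats = pd.DataFrame(
        {
            "n_trajectory_changes": df["n_trajectory_changes"].astype(float),
            "n_lobe_changes": df["n_lobe_changes"].astype(float),
            "tractography_available": (df["group"] == _T).astype(float),
            "normalized_time": df["normalized_time"].astype(float),
        },
        index=df.index,
    )
    return feats


def cluster_planning_profiles(
    df: pd.DataFrame,
    seed: int = 0,
    knn: int = 15,
    resolution: float = 1.0,
    compute_embedding: bool = True,
) -> ClusterResult:
    """Graph-based clustering of planning profiles.

    Standardizes the four profile features, builds a symmetrized
    k-nearest-neighbour graph over the unique profiles, and partitions it
    with Leiden modularity community detection; optionally adds a 2-D UMAP
    embedding for display.  Identical profiles always share a cluster, and
    working on the lexicographically ordered unique rows makes the
    partition deterministic under a fixed seed and invariant to row order
    and feature column permutations.
    """
    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    feats = _feature_matrix(df)
    n = len(feats)
    if n <= knn:
        raise ValueError(f"need more than knn={knn} records, got {n}")
    X = feats.to_numpy()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    # cluster the unique feature rows (lexicographically ordered by
    # np.unique): identical profiles share a label and the partition is
    # independent of the input row order
    Zc, inverse = np.unique(Z, axis=0, return_inverse=True)
    n_u = len(Zc)
    k_eff = min(knn, n_u - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Zc)
    _, nbrs = nn.kneighbors(Zc)
    edges = set()
    for i in range(n_u):
        for j in nbrs[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    graph = igraph.Graph(n=n_u, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=4,
    )
    labels_c = np.asarray(part.membership, dtype=int)

    embedding = None
    if compute_embedding:
        import warnings

        from umap import UMAP

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb_c = UMAP(
                n_neighbors=k_eff, min_dist=0.1, random_state=int(seed), n_jobs=1
            ).fit_transform(Zc)
        embedding = np.asarray(emb_c)[inverse]

    labels = labels_c[inverse]
    return ClusterResult(
        labels=labels,
        embedding=embedding,
        n_clusters=int(labels.max()) + 1,
        features=feats,
    )
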