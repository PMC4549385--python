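"""Atlas-based post-hoc statistics on GMV-change clusters.

Given a probabilistic atlas (one probability volume per area), the
maximum-probability map (MPM) assigns each voxel to its most probable
area; significant clusters are characterized by their percentage overlap
with each MPM area and by their *central tendency* — the mean probability
of the area inside the cluster divided by the mean probability over the
area's support (>1: the cluster sits centrally on the area; <1:
peripherally).  Confound-adjusted GMV change is averaged within complete
MPM-derived ROI masks per subject and compared across recovery subgroups
with rank statistics (Kruskal-Wallis, Mann-Whitney) and a 3x2 mixed
ANOVA (between factor: recovery subgroup; within factor: effect site)
after a shift-then-square-root variance-stabilizing transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import VolumeGrid

__all__ = [
    "GroupStatResult",
    "AnovaTable",
    "mpm_from_atlas",
    "cluster_area_overlap",
    "central_tendency",
    "extract_roi_values",
    "subgroup_stats",
    "mann_whitney_both",
    "interaction_anova",
    "shift_sqrt",
    "demographics_summary",
]

log = logging.getLogger(__name__)

#: atlas probabilities below this never receive an MPM label
MPM_MIN_PROB = 0.01


@dataclass
class GroupStatResult:
    kind: str  # H | U | t | F | rho | D | W
    value: float
    df: float | tuple
    p: float
    extra: dict | None = None


@dataclass
class AnovaTable:
    """Mixed two-way ANOVA summary for the group x site interaction."""

    F: float
    df: tuple[int, int]
    p: float
    eta2: float  # SS_interaction / SS_total
    partial_eta2: float  # SS_interaction / (SS_interaction + SS_error)
    shift: float  # applied before sqrt (0 when data already non-negative)
    levene_before: GroupStatResult
    levene_after: GroupStatResult
    ks_after: GroupStatResult
    ss: dict


def mpm_from_atlas(atlas: list[VolumeGrid]) -> np.ndarray:
    """Maximum-probability map: per-voxel argmax label (1-based; 0 =
    unassigned where every probability < 0.01).  Ties go to the lowest
    area index and are logged."""
    if not atlas:
        raise ValueError("atlas must contain at least one area")
    probs = np.stack([a.data for a in atlas])
    best = probs.argmax(axis=0)
    pmax = probs.max(axis=0)
    labels = np.where(pmax >= MPM_MIN_PROB, best + 1, 0)
    ties = ((probs == pmax[None]).sum(axis=0) > 1) & (labels > 0)
    if ties.any():
        log.info("MPM ties at %d voxels resolved to the lowest area index",
                 int(ties.sum()))
    return labels


def cluster_area_overlap(
    cluster_mask: np.ndarray,
    atlas: list[VolumeGrid],
    names: list[str] | None = None,
    report_threshold: float = 10.0,
) -> pd.DataFrame:
    """Percentage of cluster voxels falling in each MPM area.

    Returns every area plus the unassigned remainder (overlaps sum to
    100); the ``reported`` column marks areas above the reporting
    threshold (default >10%).
    """
    cluster = np.asarray(cluster_mask).astype(bool)
    n_clu = int(cluster.sum())
    if n_clu == 0:
        raise ValueError("empty cluster")
    mpm = mpm_from_atlas(atlas)
    if mpm.shape != cluster.shape:
        raise ValueError("cluster and atlas grids differ")
    names = names or [f"area{i+1}" for i in range(len(atlas))]
    rows = []
    inside = mpm[cluster]
    for i, name in enumerate(names):
        pct = 100.0 * float((inside == i + 1).sum()) / n_clu
        rows.append((name, pct, pct > report_threshold))
    pct0 = 100.0 * float((inside == 0).sum()) / n_clu
    rows.append(("unassigned", pct0, False))
    return pd.DataFrame(rows, columns=["area", "overlap_pct", "reported"])


def central_tendency(
    cluster_mask: np.ndarray,
    probability: VolumeGrid | np.ndarray,
    whole_grid_denominator: bool = False,
) -> float:
    """Ratio of mean area probability inside the cluster to the mean over
    the area's support (voxels with probability > 0).

    >1 means the cluster sits centrally on the area, <1 peripherally.
    With ``whole_grid_denominator`` the denominator averages over every
    voxel instead (makes the ratio scale with brain size; off by
    default).  An empty cluster-support intersection returns 0 with a
    warning.
    """
    prob = probability.data if isinstance(probability, VolumeGrid) else np.asarray(probability, dtype=float)
    cluster = np.asarray(cluster_mask).astype(bool)
    support = prob > 0
    if not support.any():
        raise ValueError("probability volume has empty support")
    inter = cluster & support
    if not inter.any():
        log.warning("cluster does not intersect the area support; ratio = 0")
        return 0.0
    denom = prob.mean() if whole_grid_denominator else prob[support].mean()
    return float(prob[inter].mean() / denom)


def extract_roi_values(
    gmv_maps: np.ndarray,
    roi_masks: dict[str, np.ndarray],
    nuisance: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean confound-adjusted GMV change per subject and ROI.

    The subject x voxel matrix is residualized on the mean-centred
    nuisance covariates with the intercept added back, then averaged
    within each ROI.  Rows: one per subject x ROI (columns subject,
    roi, value).
    """
    maps = np.asarray(gmv_maps, dtype=float)
    n = maps.shape[0]
    Y = maps.reshape(n, -1)
    if nuisance is not None and np.size(nuisance):
        Z = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
        Zc = Z - Z.mean(axis=0, keepdims=True)
        X = np.column_stack([np.ones(n), Zc])
        beta = np.linalg.pinv(X) @ Y
        adj = Y - Zc @ beta[1:]  # remove nuisance, keep intercept
    else:
        adj = Y
    rows = []
    for name, mask in roi_masks.items():
        m = np.asarray(mask).astype(bool).ravel()
        if not m.any():
            raise ValueError(f"ROI {name!r} is empty")
        vals = adj[:, m].mean(axis=1)
        rows.extend((i, name, float(v)) for i, v in enumerate(vals))
    return pd.DataFrame(rows, columns=["subject", "roi", "value"])


def mann_whitney_both(x, y) -> GroupStatResult:
    """Mann-Whitney test reporting both group-specific U statistics.

    U_x counts pairs where an x value exceeds a y value (ties 0.5);
    U_x + U_y = n_x * n_y always.  Both are reported because reporting
    conventions differ; ``value`` is U_x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    u_x = float(res.statistic)
    u_y = float(len(x) * len(y) - u_x)
    return GroupStatResult(
        "U", u_x, (len(x), len(y)), float(res.pvalue),
        extra={"U_x": u_x, "U_y": u_y, "U_min": min(u_x, u_y)},
    )


def subgroup_stats(values: pd.DataFrame | np.ndarray, labels=None) -> dict:
    """Kruskal-Wallis across subgroups plus pairwise Mann-Whitney tests.

    Accepts either a DataFrame with columns value/label or parallel
    arrays.  Returns {'kruskal': ..., 'pairwise': {(a, b): ...},
    'medians': ...}; every group needs n >= 2.
    """
    if isinstance(values, pd.DataFrame):
        vals = values["value"].to_numpy(dtype=float)
        labels = values["label"].to_numpy()
    else:
        vals = np.asarray(values, dtype=float)
        labels = np.asarray(labels)
    groups = sorted(pd.unique(labels), key=str)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    by = {g: vals[labels == g] for g in groups}
    for g, v in by.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    H, p = stats.kruskal(*by.values())
    out = {
        "kruskal": GroupStatResult("H", float(H), len(groups) - 1, float(p)),
        "pairwise": {},
        "medians": {
            g: {"median": float(np.median(v)), "min": float(v.min()), "max": float(v.max())}
            for g, v in by.items()
        },
    }
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            out["pairwise"][(a, b)] = mann_whitney_both(by[a], by[b])
    return out


def shift_sqrt(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Shift-then-square-root transform for heteroscedastic, partly
    negative data: add the magnitude of the lowest negative value, then
    take the square root.  The shift is 0 when the data are already
    non-negative."""
    x = np.asarray(x, dtype=float)
    shift = float(-x.min()) if x.min() < 0 else 0.0
    shifted = x + shift
    if shifted.min() < -1e-12:
        raise ValueError("negative radicand after shift")
    return np.sqrt(np.clip(shifted, 0.0, None)), shift


def interaction_anova(
    roi_values: pd.DataFrame,
    group_col: str = "group",
    site_col: str = "site",
    subject_col: str = "subject",
    value_col: str = "value",
    transform: bool = True,
) -> AnovaTable:
    """Mixed 3x2 ANOVA: between-subject recovery group x within-subject
    effect site, on shift-sqrt-transformed ROI values.

    Classical partition with subject as the within-factor replicate:
    the interaction is tested against the site-by-subject-within-group
    error term, F(df_int, df_err) with df_int = (g-1)(s-1) and
    df_err = (N-g)(s-1).  eta^2 = SS_int/SS_total; partial eta^2 =
    SS_int/(SS_int+SS_err).  Levene (homoscedasticity, on the g*s cells)
    and Kolmogorov-Smirnov (normality of standardized residuals) checks
    are run before/after the transform and reported.
    """
    df = roi_values[[subject_col, group_col, site_col, value_col]].copy()
    df.columns = ["subject", "group", "site", "value"]
    groups = sorted(df["group"].unique(), key=str)
    sites = sorted(df["site"].unique(), key=str)
    cells = [df[(df.group == g) & (df.site == s)]["value"].to_numpy()
             for g in groups for s in sites]
    if any(c.size == 0 for c in cells):
        raise ValueError("every group x site cell must be non-empty")
    lev_before = GroupStatResult("W", *_levene(cells))

    raw = df["value"].to_numpy(dtype=float)
    if transform:
        tv, shift = shift_sqrt(raw)
        df["tvalue"] = tv
    else:
        df["tvalue"], shift = raw, 0.0

    wide = df.pivot_table(index=["subject", "group"], columns="site", values="tvalue")
    if wide.isna().any().any():
        raise ValueError("each subject needs a value at every site")
    data = wide.to_numpy()  # subjects x sites
    grp = np.asarray([g for (_, g) in wide.index])
    N, s = data.shape
    g_n = len(groups)

    grand = data.mean()
    ss_total = float(((data - grand) ** 2).sum())
    subj_means = data.mean(axis=1)
    ss_between_subj = float(s * ((subj_means - grand) ** 2).sum())
    ss_group = float(
        sum(s * (grp == g).sum() * (subj_means[grp == g].mean() - grand) ** 2
            for g in groups)
    )
    ss_subj_within = ss_between_subj - ss_group
    site_means = data.mean(axis=0)
    ss_site = float(N * ((site_means - grand) ** 2).sum())
    ss_int = 0.0
    for gi, g in enumerate(groups):
        rows = grp == g
        ng = rows.sum()
        gmean = data[rows].mean()
        for j in range(s):
            cell = data[rows, j].mean()
            ss_int += ng * (cell - gmean - site_means[j] + grand) ** 2
    ss_int = float(ss_int)
    ss_err = ss_total - ss_between_subj - ss_site - ss_int
    df_int = (g_n - 1) * (s - 1)
    df_err = (N - g_n) * (s - 1)
    ms_int = ss_int / df_int
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    F = ms_int / ms_err
    p = float(stats.f.sf(F, df_int, df_err))

    tcells = [df[(df.group == g) & (df.site == st)]["tvalue"].to_numpy()
              for g in groups for st in sites]
    lev_after = GroupStatResult("W", *_levene(tcells))
    resid = (df["tvalue"] - df.groupby(["group", "site"])["tvalue"].transform("mean")).to_numpy()
    sd = resid.std(ddof=1)
    if sd > 0:
        D, ks_p = stats.kstest(resid / sd, "norm")
    else:
        D, ks_p = 0.0, 1.0
    return AnovaTable(
        F=float(F),
        df=(df_int, df_err),
        p=p,
        eta2=ss_int / ss_total,
        partial_eta2=ss_int / (ss_int + ss_err),
        shift=shift,
        levene_before=lev_before,
        levene_after=lev_after,
        ks_after=GroupStatResult("D", float(D), len(resid), float(ks_p)),
        ss={
            "total": ss_total,
            "group": ss_group,
            "subj_within_group": ss_subj_within,
            "site": ss_site,
            "interaction": ss_int,
            "error": ss_err,
        },
    )


def _levene(cells) -> tuple[float, tuple, float]:
    k = len(cells)
    n_tot = sum(len(c) for c in cells)
    W, p = stats.levene(*cells, center="mean")
    return float(W), (k - 1, n_tot - k), float(p)


def demographics_summary(table: pd.DataFrame) -> dict:
    """Cohort description plus left-vs-right-lesion comparisons.

    Needs columns age, sex, side and a lesion-volume column; NIHSS / mRS
    columns are compared with Mann-Whitney when present.  The age
    comparison is a pooled-variance two-sample t test (left vs right).
    """
    cols = {c.lower(): c for c in table.columns}
    for needed in ("age", "sex", "side"):
        if needed not in cols:
            raise ValueError(f"missing column {needed!r}")
    vol_col = next((cols[c] for c in cols if "volume" in c or c.startswith("vol")), None)
    if vol_col is None:
        raise ValueError("missing lesion volume column")
    age = table[cols["age"]].to_numpy(dtype=float)
    side = table[cols["side"]].astype(str).str.upper().to_numpy()
    vol = table[vol_col].to_numpy(dtype=float)
    left, right = side == "L", side == "R"
    t, p = stats.ttest_ind(age[left], age[right], equal_var=True)
    out = {
        "n": int(len(table)),
        "age_mean": float(age.mean()),
        "age_range": (float(age.min()), float(age.max())),
        "n_left": int(left.sum()),
        "n_right": int(right.sum()),
        "sex_counts": table[cols["sex"]].value_counts().to_dict(),
        "lesion_volume_mean_cc": float(vol.mean()),
        "lesion_volume_range_cc": (float(vol.min()), float(vol.max())),
        "age_by_side_t": GroupStatResult(
            "t", float(abs(t)), int(left.sum() + right.sum() - 2), float(p)
        ),
        "lesion_volume_by_side_u": mann_whitney_both(vol[right], vol[left]),
    }
    for ordinal in ("nihss", "mrs"):
        if ordinal in cols:
            v = table[cols[ordinal]].to_numpy(dtype=float)
            out[f"{ordinal}_median"] = float(np.median(v))
            out[f"{ordinal}_range"] = (float(v.min()), float(v.max()))
            out[f"{ordinal}_by_side_u"] = mann_whitney_both(v[left], v[right])
    return out


def spearman(x, y) -> GroupStatResult:
    """Spearman rank correlation for paired measures."""
    rho, p = stats.spearmanr(x, y)
    return GroupStatResult("rho", float(rho), len(np.asarray(x)) - 2, float(p))
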