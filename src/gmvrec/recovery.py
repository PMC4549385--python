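"""Response-feature analysis (RFA) of longitudinal dexterity scores.

The behavioural input is a timed test score (seconds to complete) per
subject, task and visit.  Scores are z-transformed against healthy-control
norms with the sign flipped, so that negative z means impairment and the
normal band is z in [-2.5, +2.5].  Each subject's trajectory over ~10
visits is then summarized by:

1. the best-fitting recovery model out of three candidates

   * linear:      m(t) = I + beta * t
   * exponential: m(t) = I * exp(-beta * t)           (converges to 0)
   * exp+offset:  m(t) = I * exp(-beta * t) + c       (converges to c)

   selected by small-sample AIC (AICc), giving a categorical label
   fast / slow / poor, and

2. the projection of the trajectory onto the first principal component of
   the cohort's z-score matrix, giving a continuous recovery score
   (higher = more chronic impairment).

Time t is measured in days since stroke; I and c are in z-units and beta
in 1/day.  The fits are deterministic: beta is profiled on a bounded
interval with a multi-start grid and the remaining parameters solved in
closed form by least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "TrajectorySeries",
    "NormTable",
    "ModelFit",
    "RecoveryClassification",
    "PCFeature",
    "RankingCriteria",
    "DEFAULT_VISIT_DAYS",
    "IMPAIRMENT_CUTOFF",
    "zscore_series",
    "fit_recovery_models",
    "select_model",
    "classify_recovery",
    "classify_series",
    "pc_recovery_scores",
    "rank_subtests",
    "interpolate_missing",
    "aicc",
]

#: Default visit schedule: baseline within the first week after stroke
#: plus nine monthly examinations (days since stroke).
DEFAULT_VISIT_DAYS: tuple[int, ...] = (7, 30, 60, 90, 120, 150, 180, 210, 240, 270)

#: Boundary of the normal band; an asymptote at or below this z labels a
#: trajectory as poor recovery.
IMPAIRMENT_CUTOFF: float = -2.5

#: Upper bound for the recovery-rate parameter (1/day).
BETA_MAX: float = 1.0

MODEL_KINDS = ("linear", "exp", "exp_offset")
_MODEL_K = {"linear": 3, "exp": 3, "exp_offset": 4}  # mean params + 1 (residual var)


@dataclass
class TrajectorySeries:
    """One subject x task time series of raw scores and z-scores."""

    subject_id: str
    task_id: str
    visit_days: np.ndarray
    scores: np.ndarray | None = None  # seconds (time to complete)
    z: np.ndarray | None = None  # z-units, negative = impaired

    def __post_init__(self) -> None:
        self.visit_days = np.asarray(self.visit_days, dtype=float)
        if np.any(np.diff(self.visit_days) <= 0):
            raise ValueError("visit_days must be strictly increasing")
        for name in ("scores", "z"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.visit_days.shape:
                    raise ValueError(f"{name} length must match visit_days")
                setattr(self, name, v)


class NormTable:
    """Healthy-control mean and SD (seconds) per task."""

    def __init__(self, norms: Mapping[str, tuple[float, float]]):
        for task, (mu, sigma) in norms.items():
            if sigma <= 0:
                raise ValueError(f"sigma must be > 0 for task {task!r}")
        self._norms = {k: (float(m), float(s)) for k, (m, s) in norms.items()}

    def __contains__(self, task: str) -> bool:
        return task in self._norms

    def __getitem__(self, task: str) -> tuple[float, float]:
        if task not in self._norms:
            raise KeyError(f"task {task!r} not in norm table")
        return self._norms[task]

    @property
    def tasks(self) -> list[str]:
        return list(self._norms)

    @classmethod
    def from_csv(cls, path) -> "NormTable":
        df = pd.read_csv(path)
        return cls({r.task: (r.mu, r.sigma) for r in df.itertuples()})

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [(t, m, s) for t, (m, s) in self._norms.items()],
            columns=["task", "mu", "sigma"],
        ).to_csv(path, index=False)


@dataclass
class ModelFit:
    """A fitted recovery model with its AICc."""

    kind: str
    I: float
    beta: float
    c: float | None
    rss: float
    n_obs: int
    k_params: int
    aicc: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "linear":
            return self.I + self.beta * t
        base = self.I * np.exp(-self.beta * t)
        return base + (self.c or 0.0) if self.kind == "exp_offset" else base

    @property
    def asymptote(self) -> float:
        """Large-time limit of the model (z-units).

        A linear model has no finite asymptote; the late-window value is
        irrelevant for classification (linear => fast), so +inf*sign(beta)
        is returned for completeness.
        """
        if self.kind == "linear":
            return float(np.inf if self.beta >= 0 else -np.inf)
        return float(self.c) if self.kind == "exp_offset" else 0.0


@dataclass
class RecoveryClassification:
    label: str  # fast | slow | poor
    asymptote: float
    best_fit: ModelFit


@dataclass
class PCFeature:
    """First-principal-component recovery feature."""

    loadings: np.ndarray  # one weight per visit, unit norm
    explained_variance_fraction: float
    scores: np.ndarray  # one per subject, higher = worse recovery


@dataclass
class RankingCriteria:
    task_id: str
    longitudinal_effect_p: float
    within_subject_variance: float
    prop_impaired_final: float
    composite_rank: float = np.nan


def zscore_series(raw: TrajectorySeries, norms: NormTable) -> TrajectorySeries:
    """Fill in z-scores: z = -(score - mu) / sigma.

    The sign is flipped because a larger completion time means worse
    performance; negative z then corresponds to greater impairment.
    """
    if raw.scores is None:
        raise ValueError("series has no raw scores")
    mu, sigma = norms[raw.task_id]
    z = -(raw.scores - mu) / sigma
    return TrajectorySeries(raw.subject_id, raw.task_id, raw.visit_days, raw.scores, z)


def raw_from_z(z: np.ndarray, task_id: str, norms: NormTable) -> np.ndarray:
    """Invert the z-transform: score = mu - z * sigma."""
    mu, sigma = norms[task_id]
    return mu - np.asarray(z, dtype=float) * sigma


def aicc(rss: float, n_obs: int, k_params: int) -> float:
    """Small-sample corrected AIC for a Gaussian least-squares fit.

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1), with k counting mean
    parameters plus one for the residual variance.  RSS is floored at a
    tiny positive value so that exact (noise-free) fits compare by k.
    """
    if n_obs <= k_params + 1:
        return float(np.inf)
    rss = max(float(rss), 1e-30)
    return float(
        n_obs * np.log(rss / n_obs)
        + 2 * k_params
        + 2 * k_params * (k_params + 1) / (n_obs - k_params - 1)
    )


def _fit_linear(t: np.ndarray, z: np.ndarray) -> tuple[float, float, float]:
    X = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(X, z, rcond=None)
    rss = float(((z - X @ coef) ** 2).sum())
    return float(coef[0]), float(coef[1]), rss


def _exp_design(t: np.ndarray, beta: float, offset: bool) -> np.ndarray:
    e = np.exp(-beta * t)
    return np.column_stack([e, np.ones_like(t)]) if offset else e[:, None]


def _exp_profile_rss(t: np.ndarray, z: np.ndarray, beta: float, offset: bool) -> float:
    X = _exp_design(t, beta, offset)
    coef, *_ = np.linalg.lstsq(X, z, rcond=None)
    return float(((z - X @ coef) ** 2).sum())

# log-spaced multi-start grid for the profiled recovery rate (1/day)
_BETA_GRID = np.logspace(-4, 0, 5)


def _fit_exp(t: np.ndarray, z: np.ndarray, offset: bool) -> tuple[float, float, float | None, float]:
    """Bounded least squares for the exponential models.

    beta is profiled on [0, BETA_MAX]: for fixed beta the model is linear
    in (I[, c]), solved in closed form; beta itself is minimized over a
    5-point log-spaced multi-start with a bounded scalar search around
    each start.  Deterministic.
    """
    best_beta, best_rss = None, np.inf
    for b0 in _BETA_GRID:
        lo, hi = b0 / 10.0, min(b0 * 10.0, BETA_MAX)
        res = minimize_scalar(
            lambda b: _exp_profile_rss(t, z, b, offset),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if not np.isfinite(res.fun):
            continue
        if res.fun < best_rss:
            best_beta, best_rss = float(res.x), float(res.fun)
    if best_beta is None:
        raise RuntimeError(
            f"exponential{'-offset' if offset else ''} fit failed to converge "
            "from every start"
        )
    X = _exp_design(t, best_beta, offset)
    coef, *_ = np.linalg.lstsq(X, z, rcond=None)
    rss = float(((z - X @ coef) ** 2).sum())
    c = float(coef[1]) if offset else None
    return float(coef[0]), best_beta, c, rss


def fit_recovery_models(series: TrajectorySeries) -> list[ModelFit]:
    """Least-squares fits of the three candidate recovery models."""
    if series.z is None:
        raise ValueError("series has no z-scores; call zscore_series first")
    finite = np.isfinite(series.z)
    if finite.sum() < 5:
        raise ValueError("need at least 5 visits with finite z to fit models")
    t, z = series.visit_days[finite], series.z[finite]
    n = len(t)
    fits = []
    I, b, rss = _fit_linear(t, z)
    fits.append(ModelFit("linear", I, b, None, rss, n, 3, aicc(rss, n, 3)))
    I, b, _, rss = _fit_exp(t, z, offset=False)
    fits.append(ModelFit("exp", I, b, None, rss, n, 3, aicc(rss, n, 3)))
    I, b, c, rss = _fit_exp(t, z, offset=True)
    fits.append(ModelFit("exp_offset", I, b, c, rss, n, 4, aicc(rss, n, 4)))
    return fits


def select_model(fits: Sequence[ModelFit]) -> ModelFit:
    """Pick the best fit by AICc with a parsimony rule.

    The minimum-AICc model wins, except that any model within 2 AICc units
    of the minimum that is simpler replaces it.  Simplicity is ordered by
    (k_params, model order linear < exp < exp_offset): models inside the
    2-unit band are statistically equivalent, so the simplest is kept.
    """
    finite = [f for f in fits if np.isfinite(f.aicc)]
    if len(finite) < 2:
        raise ValueError("need at least 2 finite AICc values to select a model")
    order = {k: i for i, k in enumerate(MODEL_KINDS)}
    best = min(finite, key=lambda f: f.aicc)
    for f in finite:
        if f is best:
            continue
        if f.aicc - best.aicc < 2.0 and (f.k_params, order[f.kind]) < (
            best.k_params,
            order[best.kind],
        ):
            best = f
    return best


def classify_recovery(best: ModelFit) -> RecoveryClassification:
    """Label a best fit: linear -> fast; exponential -> slow unless the
    asymptote is at or below the impairment cutoff, then poor."""
    if best.kind == "linear":
        if best.beta < 0:
            warnings.warn(
                "linear best fit has negative slope; labelled fast by model "
                "class but the subject is deteriorating",
                stacklevel=2,
            )
        return RecoveryClassification("fast", best.asymptote, best)
    asym = best.asymptote
    label = "poor" if asym <= IMPAIRMENT_CUTOFF else "slow"
    return RecoveryClassification(label, asym, best)


def classify_series(series: TrajectorySeries) -> RecoveryClassification:
    """Fit all models, select by AICc, classify.  Convenience wrapper."""
    return classify_recovery(select_model(fit_recovery_models(series)))


def pc_recovery_scores(z_matrix: np.ndarray) -> PCFeature:
    """First-PC recovery feature from a subjects x visits z matrix.

    Columns (visits) are mean-centred; the first right singular vector is
    the loading profile; scores are the projections of the centred rows.
    The sign is oriented so that higher scores mean worse recovery
    (negative correlation with final-visit z), ties broken toward a
    positive loading sum.
    """
    Z = np.asarray(z_matrix, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 subjects")
    if not np.all(np.isfinite(Z)):
        raise ValueError("z matrix contains missing values; interpolate first")
    C = Z - Z.mean(axis=0, keepdims=True)
    if np.allclose(C, 0):
        raise ValueError("constant matrix: first principal component undefined")
    _, s, vt = np.linalg.svd(C, full_matrices=False)
    loadings = vt[0]
    scores = C @ loadings
    evf = float(s[0] ** 2 / (s**2).sum())
    # orientation: score ~ chronic impairment
    final_z = Z[:, -1]
    r = np.corrcoef(scores, final_z)[0, 1] if np.std(final_z) > 0 else 0.0
    flip = r > 0 or (r == 0 and loadings.sum() < 0)
    if flip:
        loadings, scores = -loadings, -scores
    return PCFeature(loadings, evf, scores)


def interpolate_missing(
    visit_days: np.ndarray, z: np.ndarray, max_interior: int = 2
) -> np.ndarray:
    """Linear interpolation of up to ``max_interior`` missing interior visits.

    Missing first/last visits or more than ``max_interior`` interior gaps
    raise, signalling that the subject should be excluded.
    """
    t = np.asarray(visit_days, dtype=float)
    z = np.asarray(z, dtype=float)
    missing = ~np.isfinite(z)
    if not missing.any():
        return z
    if missing[0] or missing[-1]:
        raise ValueError("cannot interpolate a missing first or last visit")
    if missing.sum() > max_interior:
        raise ValueError(
            f"{missing.sum()} missing interior visits exceeds limit {max_interior}"
        )
    out = z.copy()
    out[missing] = np.interp(t[missing], t[~missing], z[~missing])
    return out


def rank_subtests(
    z_table: pd.DataFrame, interpolate: bool = False
) -> list[RankingCriteria]:
    """Rank tasks by suitability as the recovery index.

    ``z_table`` needs columns subject_id, task_id, visit_day, z.  Per task
    three criteria are computed: the p-value of a Friedman test across
    visits (longitudinal effect), the mean within-subject variance across
    visits, and the fraction of subjects impaired (z <= -2.5) at the final
    visit.  The composite rank is the rank-sum of the three criteria
    (strong effect, large variance, high impaired fraction all rank low =
    good); ties are broken by impaired fraction, then task_id.
    """
    required = {"subject_id", "task_id", "visit_day", "z"}
    if not required.issubset(z_table.columns):
        raise ValueError(f"z_table must have columns {sorted(required)}")
    tasks = sorted(z_table["task_id"].unique())
    if len(tasks) < 2:
        raise ValueError("need at least 2 tasks to rank")
    crits: list[RankingCriteria] = []
    for task in tasks:
        sub = z_table[z_table["task_id"] == task]
        wide = sub.pivot(index="subject_id", columns="visit_day", values="z")
        wide = wide.sort_index(axis=1)
        if wide.shape[1] < 3:
            raise ValueError(f"task {task!r} has fewer than 3 visits")
        if wide.isna().any().any():
            if not interpolate:
                raise ValueError(
                    f"task {task!r} has incomplete series; enable interpolation"
                )
            days = wide.columns.to_numpy(dtype=float)
            wide = wide.apply(
                lambda row: pd.Series(
                    interpolate_missing(days, row.to_numpy()), index=wide.columns
                ),
                axis=1,
            )
        M = wide.to_numpy(dtype=float)
        if np.allclose(M, M[:, :1]):  # constant over visits: no effect
            p = 1.0
        else:
            _, p = stats.friedmanchisquare(*[M[:, j] for j in range(M.shape[1])])
        wsv = float(M.var(axis=1, ddof=1).mean())
        impaired = float((M[:, -1] <= IMPAIRMENT_CUTOFF).mean())
        crits.append(RankingCriteria(task, float(p), wsv, impaired))

    def _ranks(values: list[float], descending: bool) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return stats.rankdata(-v if descending else v)

    rp = _ranks([c.longitudinal_effect_p for c in crits], descending=False)
    rv = _ranks([c.within_subject_variance for c in crits], descending=True)
    ri = _ranks([c.prop_impaired_final for c in crits], descending=True)
    for c, a, b, d in zip(crits, rp, rv, ri):
        c.composite_rank = float(a + b + d)
    crits.sort(key=lambda c: (c.composite_rank, -c.prop_impaired_final, c.task_id))
    return crits
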