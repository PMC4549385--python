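"""Synthetic cohorts, image phantoms and a toy probabilistic atlas.

Everything downstream (response-feature analysis, morphometry, voxel-wise
statistics, ROI statistics, QC) is exercised on data from this module, so
each generator has known ground truth:

* behavioural trajectories are drawn from the three subgroup recovery
  models (linear / exponential / exponential-with-offset) evaluated at the
  visit schedule plus i.i.d. Gaussian noise;
* image pairs are related by a deformation with analytically known
  Jacobian (identity, global affine scaling, or a Gaussian radial bump);
* the probabilistic atlas is a set of smooth unimodal probability volumes
  with distinct peaks.

The subgroup model parameters and sizes default to the reference stroke
cohort that motivates this package: 5 fast (I=-0.9, beta=0.005 per day),
15 slow (I=-5.9, beta=0.023), 8 poor (I=-23.4, beta=0.031, c=-5.5), ten
visits at days 7, 30, 60, ..., 270 after stroke, and trajectory noise of
0.3 z-units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import VolumeGrid
from .recovery import DEFAULT_VISIT_DAYS, NormTable, TrajectorySeries, raw_from_z

__all__ = [
    "CohortSpec",
    "PhantomSpec",
    "SyntheticCohort",
    "Phantom",
    "DEFAULT_MODEL_PARAMS",
    "DEFAULT_NORMS",
    "TASK_SEVERITY",
    "generate_cohort_trajectories",
    "generate_brain_phantom",
    "generate_prob_atlas",
    "evaluate_model",
    "load_reference_demographics",
]

#: Subgroup recovery-model point estimates (z-units; beta in 1/day).
DEFAULT_MODEL_PARAMS: dict[str, dict[str, float]] = {
    "fast": {"I": -0.9, "beta": 0.005},
    "slow": {"I": -5.9, "beta": 0.023},
    "poor": {"I": -23.4, "beta": 0.031, "c": -5.5},
}

#: Toy control norms (seconds): mean from the healthy-control summary of
#: the timed dexterity battery; the SDs are fixture parameters (the
#: controls' SDs are not published), chosen as roughly range/4.
DEFAULT_NORMS = NormTable(
    {
        "pso": (5.7, 0.7),  # picking small objects - the dexterity index task
        "stack_checkers": (4.5, 1.0),
        "turn_cards": (4.5, 1.0),
        "lift_light": (4.1, 0.55),
        "lift_heavy": (4.0, 0.95),
    }
)

#: Relative severity of impairment per task: the z trajectory of a task is
#: the subgroup model scaled by this factor.  Precision-grip tasks are hit
#: hardest; reaching/lifting tasks are mildly affected and recover fast.
TASK_SEVERITY: dict[str, float] = {
    "pso": 1.0,
    "stack_checkers": 0.7,
    "turn_cards": 0.55,
    "lift_light": 0.3,
    "lift_heavy": 0.25,
}

_LABELS = ("fast", "slow", "poor")


def evaluate_model(params: dict[str, float], t: np.ndarray, kind: str) -> np.ndarray:
    """Noise-free subgroup model value at times t (days)."""
    t = np.asarray(t, dtype=float)
    if kind == "fast":  # linear
        return params["I"] + params["beta"] * t
    base = params["I"] * np.exp(-params["beta"] * t)
    return base + params.get("c", 0.0)


@dataclass
class CohortSpec:
    """Specification of a synthetic behavioural cohort."""

    n_fast: int = 5
    n_slow: int = 15
    n_poor: int = 8
    visit_days: tuple[float, ...] = DEFAULT_VISIT_DAYS
    noise_sd: float = 0.3
    model_params: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MODEL_PARAMS.items()}
    )
    tasks: tuple[str, ...] = tuple(TASK_SEVERITY)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fast + self.n_slow + self.n_poor < 3:
            raise ValueError("n_fast + n_slow + n_poor must be >= 3")
        if min(self.n_fast, self.n_slow, self.n_poor) < 0:
            raise ValueError("subgroup sizes must be non-negative")
        days = np.asarray(self.visit_days, dtype=float)
        if days.ndim != 1 or np.any(np.diff(days) <= 0):
            raise ValueError("visit_days must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for grp, p in self.model_params.items():
            if p.get("beta", 0.0) < 0:
                raise ValueError(f"beta must be >= 0 (subgroup {grp!r})")


@dataclass
class SyntheticCohort:
    """Generated cohort: per-subject labels, demographics and trajectories."""

    subjects: pd.DataFrame  # subject_id, true_label, age, sex, side, ...
    series: dict[tuple[str, str], TrajectorySeries]  # (subject_id, task) -> series
    spec: CohortSpec

    @property
    def subject_ids(self) -> list[str]:
        return self.subjects["subject_id"].tolist()

    def z_table(self) -> pd.DataFrame:
        rows = []
        for (sid, task), s in self.series.items():
            for d, sc, z in zip(s.visit_days, s.scores, s.z):
                rows.append((sid, task, d, sc, z))
        return pd.DataFrame(
            rows, columns=["subject_id", "task_id", "visit_day", "score_s", "z"]
        )

    def z_matrix(self, task: str = "pso") -> np.ndarray:
        """Subjects x visits z matrix for one task (subject order as in
        ``subjects``)."""
        return np.stack([self.series[(sid, task)].z for sid in self.subject_ids])

    def to_csv(self, path) -> None:
        """Long-format cohort table: subject_id, visit_day, task, hand, score_s, z."""
        rows = []
        for (sid, task), s in self.series.items():
            for d, sc, z in zip(s.visit_days, s.scores, s.z):
                rows.append((sid, d, task, "affected", sc, z))
        pd.DataFrame(
            rows, columns=["subject_id", "visit_day", "task", "hand", "score_s", "z"]
        ).to_csv(path, index=False)


def _demographics(rng: np.random.Generator, labels: list[str]) -> pd.DataFrame:
    """Demographic covariates mirroring the reference cohort's marginals."""
    n = len(labels)
    median_vol = {"fast": 5.9, "slow": 3.6, "poor": 42.8}  # cc, per subgroup
    rows = []
    for i, lab in enumerate(labels):
        age = float(np.clip(np.round(rng.normal(64.7, 11.6)), 40, 85))
        sex = "m" if rng.random() < 24 / 28 else "f"
        side = "R" if rng.random() < 16 / 28 else "L"
        vol = float(np.clip(np.exp(np.log(median_vol[lab]) + rng.normal(0, 1.1)), 0.5, 150.0))
        d_nihss = {"fast": -3.0, "slow": -2.0, "poor": -1.0}[lab] + rng.normal(0, 1.0)
        d_hd = {"fast": 14.0, "slow": 10.0, "poor": 4.0}[lab] + rng.normal(0, 4.0)
        interval = float(np.round(rng.normal(183.0, 10.0)))
        rows.append(
            (f"s{i+1:02d}", lab, age, sex, side, vol, float(d_nihss), float(d_hd), interval)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "true_label",
            "age",
            "sex",
            "side",
            "lesion_volume_cc",
            "delta_nihss",
            "delta_hd_kg",
            "acq_interval_days",
        ],
    )


def generate_cohort_trajectories(
    spec: CohortSpec, norms: NormTable = DEFAULT_NORMS
) -> SyntheticCohort:
    """Draw a behavioural cohort from the subgroup recovery models.

    Each subject's z-series per task equals its subgroup model (scaled by
    the task severity factor) evaluated at the visit schedule plus
    N(0, noise_sd^2) noise; raw scores are recovered by inverting the
    z-transform against the control norms.  Reproducible given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels = (
        ["fast"] * spec.n_fast + ["slow"] * spec.n_slow + ["poor"] * spec.n_poor
    )
    subjects = _demographics(rng, labels)
    days = np.asarray(spec.visit_days, dtype=float)
    series: dict[tuple[str, str], TrajectorySeries] = {}
    for sid, lab in zip(subjects["subject_id"], labels):
        base = evaluate_model(spec.model_params[lab], days, lab)
        for task in spec.tasks:
            sev = TASK_SEVERITY.get(task, 1.0)
            z = sev * base + rng.normal(0.0, spec.noise_sd, size=days.size)
            scores = raw_from_z(z, task, norms) if task in norms else None
            series[(sid, task)] = TrajectorySeries(sid, task, days, scores, z)
    return SyntheticCohort(subjects, series, spec)


# ---------------------------------------------------------------------------
# image phantoms


@dataclass
class PhantomSpec:
    """Specification of a paired-time-point 3-D brain phantom."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 1.0  # mm, isotropic
    deformation_kind: str = "radial_bump"  # identity | affine_scale | radial_bump
    deformation_params: dict = field(default_factory=dict)
    lesion_center: tuple[float, float, float] | None = None  # voxels
    lesion_radius: float = 3.0  # voxels
    noise_sd: float = 0.01  # intensity units (WM ~ 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 16:
            raise ValueError("grid_shape must be >= 16 per axis")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.deformation_kind not in ("identity", "affine_scale", "radial_bump"):
            raise ValueError(f"unknown deformation_kind {self.deformation_kind!r}")
        if self.lesion_center is not None:
            c = np.asarray(self.lesion_center, dtype=float)
            lo = c - self.lesion_radius
            hi = c + self.lesion_radius
            if np.any(lo < 0) or np.any(hi > np.asarray(self.grid_shape) - 1):
                raise ValueError("lesion must lie entirely inside the grid")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Phantom:
    """A generated phantom pair with ground truth."""

    t3: VolumeGrid  # early time point
    t9: VolumeGrid  # late time point = warped early + noise
    gm: VolumeGrid
    wm: VolumeGrid
    csf: VolumeGrid
    lesion: VolumeGrid  # binary
    u_true: np.ndarray  # (nx, ny, nz, 3) displacement, mm
    jd_true: np.ndarray  # analytic Jacobian determinant of the truth field
    side: str = "R"


def _tissue_maps(shape, rng):
    """Smooth tissue fractions: WM core, GM shell, a deep GM nucleus
    (thalamus-like) and a CSF rim."""
    idx = np.indices(shape, dtype=float)
    c = (np.asarray(shape, dtype=float) - 1) / 2
    r = np.sqrt(((idx - c.reshape(3, 1, 1, 1)) ** 2).sum(0))
    # brain radius kept at ~34% of the grid so moderate (<=10%) global
    # scalings keep all tissue inside the field of view
    rr = r / (0.34 * min(shape))  # ~1 at brain edge
    sharp = 16.0

    def sig(x):
        return 1.0 / (1.0 + np.exp(-sharp * x))

    wm = sig(0.55 - rr)
    brain = sig(1.0 - rr)
    gm = np.clip(brain - wm, 0.0, 1.0)
    # deep grey nucleus at the centre
    nucleus = 0.9 * np.exp(-(rr**2) / (2 * 0.18**2))
    gm = np.clip(gm + nucleus, 0.0, 1.0)
    wm = np.clip(wm - nucleus, 0.0, 1.0)
    csf = np.clip(sig(1.25 - rr) - brain, 0.0, 1.0)
    # hard head boundary (skull): no tissue beyond ~1.28 brain radii, and
    # sub-1% sigmoid tails zeroed so the head support is compact
    outside = rr > 1.28
    for m in (gm, wm, csf):
        m[outside] = 0.0
        m[m < 0.01] = 0.0
    total = gm + wm + csf
    over = total > 1.0
    if over.any():  # numerical safety; keeps per-voxel sum <= 1
        gm[over] /= total[over]
        wm[over] /= total[over]
        csf[over] /= total[over]
    return gm, wm, csf


_TISSUE_INTENSITY = {"csf": 0.2, "gm": 0.6, "wm": 1.0}  # T1-like ordering


def _deformation(spec: PhantomSpec):
    """Truth displacement (voxel units, (3, nx, ny, nz)) and analytic JD."""
    shape = spec.grid_shape
    idx = np.indices(shape, dtype=float)
    c = (np.asarray(shape, dtype=float) - 1) / 2
    if spec.deformation_kind == "identity":
        return np.zeros((3,) + shape), np.ones(shape)
    if spec.deformation_kind == "affine_scale":
        factor = np.broadcast_to(
            np.asarray(spec.deformation_params.get("factor", 1.1), dtype=float), (3,)
        ).astype(float)
        d = idx - c.reshape(3, 1, 1, 1)
        u = (factor - 1.0).reshape(3, 1, 1, 1) * d
        jd = np.full(shape, float(np.prod(factor)))
        return u, jd
    # radial_bump: u(x) = sum_k a_k * exp(-||x-x0_k||^2 / 2 s_k^2) * (x - x0_k)
    p = spec.deformation_params
    bumps = p.get("bumps") or [
        {
            "amplitude": p.get("amplitude", 0.1),
            "width": p.get("width", 5.0),
            "center": p.get("center", c),
        }
    ]
    u = np.zeros((3,) + shape)
    J = np.zeros(shape + (3, 3))
    J[..., 0, 0] = J[..., 1, 1] = J[..., 2, 2] = 1.0
    for b in bumps:
        a = float(b.get("amplitude", 0.1))
        s = float(b.get("width", 5.0))
        x0 = np.asarray(b.get("center", c), dtype=float)
        if not 0 <= abs(a) < 0.5:
            raise ValueError(
                "radial bump amplitude must satisfy |a| < 0.5 (diffeomorphic)"
            )
        d = idx - x0.reshape(3, 1, 1, 1)
        r2 = (d**2).sum(0)
        g = a * np.exp(-r2 / (2.0 * s**2))
        u += g[None] * d
        # dui/dxj of one bump: g * (delta_ij - di*dj/s^2)
        for i in range(3):
            for j in range(3):
                J[..., i, j] += g * ((i == j) - d[i] * d[j] / s**2)
    jd = np.linalg.det(J)
    if np.any(jd <= 0):
        raise ValueError("radial bump parameters produce a folding (JD <= 0) field")
    return u, jd


def generate_brain_phantom(spec: PhantomSpec) -> Phantom:
    """Paired volumes related by a known deformation, with tissue maps.

    The late volume is the early volume resampled through the truth field
    (pull-back convention, trilinear) plus Gaussian noise.  An error is
    raised if the field samples brain content from outside the grid.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    gm, wm, csf = _tissue_maps(shape, rng)
    img = (
        _TISSUE_INTENSITY["gm"] * gm
        + _TISSUE_INTENSITY["wm"] * wm
        + _TISSUE_INTENSITY["csf"] * csf
    )
    # mild smooth texture so registration has gradients everywhere in brain
    from scipy import ndimage as ndi

    tex = ndi.gaussian_filter(rng.standard_normal(shape), 1.5)
    img = img * (1.0 + 0.25 * tex)

    lesion = np.zeros(shape)
    if spec.lesion_center is not None:
        idx = np.indices(shape, dtype=float)
        d2 = ((idx - np.asarray(spec.lesion_center).reshape(3, 1, 1, 1)) ** 2).sum(0)
        lesion = (d2 <= spec.lesion_radius**2).astype(float)
        img = np.where(lesion > 0, _TISSUE_INTENSITY["csf"], img)
        gm = np.where(lesion > 0, 0.0, gm)
        wm = np.where(lesion > 0, 0.0, wm)
        csf = np.where(lesion > 0, 1.0, csf)

    u_vox, jd_true = _deformation(spec)
    coords = np.indices(shape, dtype=float) + u_vox
    support = (gm + wm + csf) > 0.01
    for ax in range(3):  # half-voxel tolerance for decayed field tails
        bad = support & ((coords[ax] < -0.5) | (coords[ax] > shape[ax] - 0.5))
        if bad.any():
            raise ValueError("deformation pushes brain content outside the grid")
    t9 = ndi.map_coordinates(img, coords, order=1, mode="nearest")
    t3 = img + rng.normal(0.0, spec.noise_sd, shape)
    t9 = t9 + rng.normal(0.0, spec.noise_sd, shape)

    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    u_mm = np.moveaxis(u_vox, 0, -1) * spec.voxel_size
    grid = VolumeGrid(t3, affine)
    return Phantom(
        t3=grid,
        t9=grid.like(t9),
        gm=grid.like(gm),
        wm=grid.like(wm),
        csf=grid.like(csf),
        lesion=grid.like(lesion),
        u_true=u_mm,
        jd_true=jd_true,
    )


def generate_prob_atlas(
    grid_shape: tuple[int, int, int],
    n_areas: int,
    seed: int = 0,
    width: float | None = None,
    peaks: list | None = None,
) -> list[VolumeGrid]:
    """A toy probabilistic atlas: smooth unimodal areas with distinct peaks.

    Peaks default to a jittered lattice inside the central region; the
    first areas can be pinned to explicit ``peaks`` locations (voxels).
    Per-voxel probabilities are Gaussian profiles scaled so the sum over
    areas never exceeds 1.
    """
    if n_areas < 2:
        raise ValueError("n_areas must be >= 2")
    rng = np.random.default_rng(seed)
    shape = np.asarray(grid_shape)
    if width is None:
        width = 0.18 * float(min(shape))
    # jittered lattice of peak locations in the central 60% of the grid
    lo, hi = 0.2 * shape, 0.8 * shape
    peaks = [np.asarray(p, dtype=float) for p in (peaks or [])][:n_areas]
    while len(peaks) < n_areas:
        p = rng.uniform(lo, hi)
        if all(np.linalg.norm(p - q) > width for q in peaks):
            peaks.append(p)
    idx = np.indices(tuple(shape), dtype=float)
    vols = []
    for p in peaks:
        d2 = ((idx - p.reshape(3, 1, 1, 1)) ** 2).sum(0)
        vols.append(0.9 * np.exp(-d2 / (2.0 * width**2)))
    total = np.sum(vols, axis=0)
    scale = np.maximum(total, 1.0)
    affine = np.eye(4)
    return [VolumeGrid(v / scale, affine) for v in vols]


def load_reference_demographics() -> pd.DataFrame:
    """Baseline demographic/clinical table of the 28-patient reference
    cohort (cortical sensorimotor stroke) used for the package's worked
    examples and summary-statistics checks."""
    path = Path(__file__).parent / "data" / "cohort_demographics.csv"
    return pd.read_csv(path)
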