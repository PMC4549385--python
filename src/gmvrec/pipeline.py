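"""End-to-end orchestration: synthesis/ingest -> RFA -> morphometry ->
voxel statistics -> ROI statistics -> QC -> report.

The demo configuration generates a synthetic cohort whose planted
morphometric effect (a radial expansion at a fixed subcortical locus,
amplitude increasing with chronic impairment) mirrors the behavioural
ground truth, so every downstream stage has signal to find.  A manifest
configuration instead reads per-subject NIfTI volumes listed in a CSV.

The JSON report is fully reproducible: identical configuration and seed
give byte-identical output (no timestamps in the report body).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import morph, qc, recovery, roistats, synthcohort, voxstats
from .grids import VolumeGrid, load_volume, save_volume
from .registration import RegConfig, nonlinear_register_ssd, rigid_register_nmi

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, subject: str | None, cause: Exception):
        self.stage, self.subject = stage, subject
        where = f"stage {stage!r}" + (f", subject {subject!r}" if subject else "")
        super().__init__(f"pipeline failed at {where}: {cause}")


@dataclass
class PipelineConfig:
    outdir: str = "gmvrec_out"
    seed: int = 0
    mode: str = "synthetic"  # synthetic | manifest
    manifest: str | None = None  # CSV: subject_id,t3,t9,gm,lesion,side
    # cohort
    n_fast: int = 4
    n_slow: int = 5
    n_poor: int = 3
    noise_sd: float = 0.3
    # phantom
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    phantom_noise_sd: float = 0.01
    bump_width: float = 3.0
    bump_amplitude: float = 0.06  # base; scaled up with chronic impairment
    # registration / smoothing
    lambda_reg: float = 4.0
    n_iter: int = 8
    fwhm_mm: float = 6.0
    do_rigid: bool = False
    # statistics
    n_perm: int = 200
    alpha: float = 0.05
    tfce_steps: int = 50
    # atlas
    n_areas: int = 3

    def validate(self) -> None:
        if self.mode not in ("synthetic", "manifest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "manifest":
            if not self.manifest:
                raise ValueError("manifest mode needs a manifest CSV")
            man = pd.read_csv(self.manifest)
            needed = {"subject_id", "t3", "t9", "gm", "lesion", "side"}
            if not needed.issubset(man.columns):
                raise ValueError(f"manifest must have columns {sorted(needed)}")
            base = Path(self.manifest).parent
            for col in ("t3", "t9", "gm", "lesion"):
                for p in man[col]:
                    path = Path(p)
                    if not path.is_absolute():
                        path = base / path
                    if not path.exists():
                        raise FileNotFoundError(f"manifest file missing: {path}")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _stat_result(r) -> dict:
    d = {"kind": r.kind, "value": r.value, "df": r.df, "p": r.p}
    if r.extra:
        d["extra"] = r.extra
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to config.outdir.

    Returns the report dict.  Any stage failure raises
    :class:`PipelineError` naming the stage (and subject, if per-subject).
    """
    t_start = time.monotonic()
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _round_floats(dataclasses.asdict(config))}
    timings: dict[str, float] = {}

    # ------------------------------------------------------------- cohort
    t0 = time.monotonic()
    try:
        if config.mode == "synthetic":
            spec = synthcohort.CohortSpec(
                n_fast=config.n_fast,
                n_slow=config.n_slow,
                n_poor=config.n_poor,
                noise_sd=config.noise_sd,
                seed=config.seed,
            )
            cohort = synthcohort.generate_cohort_trajectories(spec)
            cohort.to_csv(outdir / "cohort_scores.csv")
            subjects = cohort.subjects
        else:
            subjects = pd.read_csv(config.manifest)
            cohort = None
    except Exception as e:  # noqa: BLE001
        raise PipelineError("cohort", None, e) from e
    timings["cohort"] = time.monotonic() - t0

    # ---------------------------------------------------------------- rfa
    t0 = time.monotonic()
    rfa: dict = {}
    pc_scores = None
    if cohort is not None:
        try:
            ranking = recovery.rank_subtests(cohort.z_table())
            top_task = ranking[0].task_id
            labels = []
            for sid in cohort.subject_ids:
                cls = recovery.classify_series(cohort.series[(sid, top_task)])
                labels.append(cls.label)
            pc = recovery.pc_recovery_scores(cohort.z_matrix(top_task))
            pc_scores = pc.scores
            rfa = {
                "selected_task": top_task,
                "ranking": [
                    {
                        "task": c.task_id,
                        "p": c.longitudinal_effect_p,
                        "within_subject_variance": c.within_subject_variance,
                        "prop_impaired_final": c.prop_impaired_final,
                        "composite_rank": c.composite_rank,
                    }
                    for c in ranking
                ],
                "labels": dict(zip(cohort.subject_ids, labels)),
                "label_counts": pd.Series(labels).value_counts().to_dict(),
                "pc_explained_variance": pc.explained_variance_fraction,
                "pc_scores": dict(zip(cohort.subject_ids, pc.scores.tolist())),
            }
            subjects = subjects.assign(label=labels, pc_score=pc.scores)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("rfa", None, e) from e
    timings["rfa"] = time.monotonic() - t0

    # ------------------------------------------------------- morphometry
    t0 = time.monotonic()
    gmv_maps, gm_maps, lesion_masks, phantoms = [], [], [], []
    shape = tuple(config.grid_shape)
    center = tuple((np.asarray(shape) - 1) / 2)
    affine = np.eye(4)
    reg_cfg = RegConfig(lambda_reg=config.lambda_reg, n_iter=config.n_iter)
    sid = None
    try:
        for i, row in subjects.reset_index(drop=True).iterrows():
            sid = row["subject_id"]
            if config.mode == "synthetic":
                # crossed planted effect: deep-grey (subcortical) expansion
                # grows with chronic impairment, cortical-shell expansion
                # with successful recovery
                s = pc_scores[i]
                rel = (s - pc_scores.min()) / max(np.ptp(pc_scores), 1e-9)
                side = row["side"]

                def _ipsi(x):  # ipsilesional x: mirrored for left lesions
                    return x if side == "R" else (shape[0] - 1) - x

                sub_c = center  # deep grey nucleus (midline, flip-invariant)
                cort_c = (_ipsi(center[0] + 0.28 * shape[0]), center[1], center[2])
                bumps = [
                    {"amplitude": config.bump_amplitude * (0.4 + rel),
                     "width": config.bump_width, "center": sub_c},
                    {"amplitude": config.bump_amplitude * (1.4 - rel),
                     "width": config.bump_width, "center": cort_c},
                ]
                lesion_c = (_ipsi(shape[0] * 0.7), shape[1] * 0.35, shape[2] * 0.5)
                pspec = synthcohort.PhantomSpec(
                    grid_shape=shape,
                    deformation_kind="radial_bump",
                    deformation_params={"bumps": bumps},
                    lesion_center=lesion_c,
                    lesion_radius=2.0,
                    noise_sd=config.phantom_noise_sd,
                    seed=config.seed + 1000 + i,
                )
                ph = synthcohort.generate_brain_phantom(pspec)
                t3, t9, gm, lesion = ph.t3, ph.t9, ph.gm, ph.lesion
                side = row["side"]
                phantoms.append(ph)
            else:
                base = Path(config.manifest).parent

                def _load(p):
                    path = Path(p)
                    return load_volume(path if path.is_absolute() else base / path)

                t3, t9 = _load(row["t3"]), _load(row["t9"])
                gm, lesion = _load(row["gm"]), _load(row["lesion"])
                side = row["side"]
            if config.do_rigid:
                t3 = rigid_register_nmi(t3, t9, reg_cfg).resampled
            res = nonlinear_register_ssd(t3, t9, reg_cfg)
            jd = morph.jacobian_determinant(res.u_mm, t3.voxel_size)
            change = morph.gmv_change_map(jd, gm)
            smoothed = morph.smooth_gaussian(change, config.fwhm_mm, t3.voxel_size)
            # flipped cases are re-expressed on the common analysis grid
            gmv_maps.append(morph.flip_lateralize(t3.like(smoothed), side).data)
            gm_maps.append(morph.flip_lateralize(gm, side).data)
            lesion_masks.append(
                VolumeGrid(morph.flip_lateralize(lesion, side).data, affine)
            )
        sid = None
    except Exception as e:  # noqa: BLE001
        raise PipelineError("morphometry", sid, e) from e
    gmv_maps = np.asarray(gmv_maps)
    timings["morphometry"] = time.monotonic() - t0

    # ------------------------------------------------------------- masks
    t0 = time.monotonic()
    try:
        mean_gm = VolumeGrid(np.mean(gm_maps, axis=0), affine)
        freq = morph.lesion_frequency_map(lesion_masks)
        mean_lesion = freq.like(freq.data / len(lesion_masks))
        mask_vol = morph.build_analysis_mask(mean_gm, mean_lesion)
        mask = mask_vol.data.astype(bool)
        save_volume(mask_vol, outdir / "analysis_mask.nii.gz")
        save_volume(freq, outdir / "lesion_frequency.nii.gz")
        report["lesion"] = {
            "max_overlap_n": float(freq.data.max()),
            "mask_voxels": int(mask.sum()),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("analysis_mask", None, e) from e
    timings["analysis_mask"] = time.monotonic() - t0

    # ---------------------------------------------------------- voxstats
    t0 = time.monotonic()
    try:
        nuis_cols = ["age", "lesion_volume_cc", "acq_interval_days"]
        nuis_cols = [c for c in nuis_cols if c in subjects.columns]
        nuisance = subjects[nuis_cols].to_numpy(dtype=float) if nuis_cols else None
        avg_change = gmv_maps.reshape(len(gmv_maps), -1)[:, mask.ravel()].mean(axis=1)
        nuis_full = (
            np.column_stack([nuisance, avg_change]) if nuisance is not None else avg_change[:, None]
        )
        names = nuis_cols + ["avg_gmv_change"]
        design1 = voxstats.DesignSpec(nuisance=nuis_full, nuisance_names=names)
        stat1 = voxstats.permutation_fwe(
            gmv_maps, design1, n_perm=config.n_perm, seed=config.seed,
            mask=mask, n_steps=config.tfce_steps,
        )
        clusters1 = voxstats.cluster_table(stat1, config.alpha, affine)
        stat2 = None
        clusters2 = []
        if pc_scores is not None:
            design2 = voxstats.DesignSpec(
                covariate=pc_scores, nuisance=nuis_full, nuisance_names=names
            )
            stat2 = voxstats.permutation_fwe(
                gmv_maps, design2, n_perm=config.n_perm, seed=config.seed + 1,
                mask=mask, n_steps=config.tfce_steps,
            )
            clusters2 = voxstats.cluster_table(stat2, config.alpha, affine)

        def _clu(recs):
            return [
                {
                    "tail": r.tail,
                    "peak_mm": list(r.peak_mm),
                    "extent": r.extent,
                    "peak_tfce": r.peak_tfce,
                    "fwe_p": r.fwe_p,
                }
                for r in recs
            ]

        report["voxstats"] = {
            "one_sample_clusters": _clu(clusters1),
            "regression_clusters": _clu(clusters2),
            "n_perm": stat1.n_perm,
        }
        pd.DataFrame(report["voxstats"]["one_sample_clusters"]).to_csv(
            outdir / "clusters_one_sample.csv", index=False
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("voxstats", None, e) from e
    timings["voxstats"] = time.monotonic() - t0

    # ---------------------------------------------------------- roistats
    t0 = time.monotonic()
    try:
        sub_c = center
        cort_c = (center[0] + 0.28 * shape[0], center[1], center[2])
        atlas = synthcohort.generate_prob_atlas(
            shape, config.n_areas, seed=config.seed, peaks=[sub_c, cort_c]
        )
        mpm = roistats.mpm_from_atlas(atlas)
        roi_report: dict = {}
        if clusters1:
            top = clusters1[0]
            comp_mask = (
                (stat1.fwe_p_pos < config.alpha)
                if top.tail == "pos"
                else (stat1.fwe_p_neg < config.alpha)
            ) & mask
            overlap = roistats.cluster_area_overlap(comp_mask, atlas)
            roi_report["top_cluster_overlap"] = overlap.to_dict("records")
            roi_report["central_tendency_lesion"] = roistats.central_tendency(
                comp_mask, mean_lesion.data
            )
        roi_masks = {f"area{i+1}": mpm == i + 1 for i in range(config.n_areas)}
        roi_vals = roistats.extract_roi_values(gmv_maps, roi_masks, nuisance=nuis_full)
        roi_vals.to_csv(outdir / "roi_values.csv", index=False)
        if "label" in subjects.columns and subjects["label"].nunique() >= 2:
            lab = subjects["label"].to_numpy()
            first = roi_vals[roi_vals.roi == "area1"]["value"].to_numpy()
            ok = pd.Series(lab).value_counts().min() >= 2
            if ok:
                sub = roistats.subgroup_stats(first, lab)
                roi_report["subgroup_kruskal"] = _stat_result(sub["kruskal"])
                roi_report["subgroup_medians"] = sub["medians"]
            two = roi_vals[roi_vals.roi.isin(["area1", "area2"])].copy()
            two["group"] = two["subject"].map(dict(enumerate(lab)))
            two["site"] = two["roi"].map({"area1": "subcortical", "area2": "cortical"})
            if ok and two.groupby(["group", "site"]).size().min() >= 2:
                an = roistats.interaction_anova(two)
                roi_report["interaction_anova"] = {
                    "F": an.F, "df": list(an.df), "p": an.p,
                    "eta2": an.eta2, "partial_eta2": an.partial_eta2,
                    "shift": an.shift,
                }
        report["roistats"] = roi_report
    except Exception as e:  # noqa: BLE001
        raise PipelineError("roistats", None, e) from e
    timings["roistats"] = time.monotonic() - t0

    # ---------------------------------------------------------------- qc
    t0 = time.monotonic()
    try:
        any_lesion = np.any([m.data > 0 for m in lesion_masks], axis=0)
        sd_vol, sd_summary = qc.sd_map(gmv_maps, any_lesion)
        save_volume(VolumeGrid(sd_vol, affine), outdir / "sd_map.nii.gz")
        qc_report: dict = {"sd": sd_summary}
        if config.mode == "synthetic" and clusters1:
            means = {"csf": 0.2, "gm": 0.6, "wm": 1.0}
            rows = []
            for i, ph in enumerate(phantoms):
                for tp, vol in (("t3", ph.t3), ("t9", ph.t9)):
                    r = qc.pve_qc(vol, means, ph.gm, comp_mask)
                    rows.append(
                        {
                            "subject": subjects["subject_id"].iloc[i],
                            "timepoint": tp,
                            "n_gm_pve": r.n_gm_pve,
                            "n_gm_hard": r.n_gm_hard,
                            "ratio": r.ratio,
                            "relative_error": r.relative_error,
                        }
                    )
            pve = qc.flag_outliers(pd.DataFrame(rows))
            pve.to_csv(outdir / "pve_qc.csv", index=False)
            finite = pve["relative_error"][np.isfinite(pve["relative_error"])]
            qc_report["pve"] = {
                "mean_relative_error": float(finite.mean()) if len(finite) else None,
                "n_undefined": int((~np.isfinite(pve["relative_error"])).sum()),
                "n_outliers": int(pve["outlier"].sum()),
            }
        report["qc"] = qc_report
    except Exception as e:  # noqa: BLE001
        raise PipelineError("qc", None, e) from e
    timings["qc"] = time.monotonic() - t0

    # ------------------------------------------------------ demographics
    try:
        if {"age", "sex", "side"}.issubset(subjects.columns) and any(
            "volume" in c for c in subjects.columns
        ):
            demo = roistats.demographics_summary(subjects)
            report["demographics"] = {
                "n": demo["n"],
                "age_mean": demo["age_mean"],
                "lesion_volume_mean_cc": demo["lesion_volume_mean_cc"],
                "age_by_side_t": _stat_result(demo["age_by_side_t"]),
            }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("demographics", None, e) from e

    report["rfa"] = rfa
    report["seed"] = config.seed
    with open(outdir / "report.json", "w") as fh:
        json.dump(_round_floats(report), fh, indent=2, sort_keys=True)
    if cohort is not None:
        _trajectory_figure(cohort, outdir / "trajectories.png")
    timings["total"] = time.monotonic() - t_start
    for stage, dt in timings.items():
        log.info("stage %-14s %6.2f s", stage, dt)
    return report


def _trajectory_figure(cohort, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"fast": "tab:green", "slow": "tab:blue", "poor": "tab:red"}
    fig, ax = plt.subplots(figsize=(6, 4))
    for sid, lab in zip(cohort.subjects["subject_id"], cohort.subjects["true_label"]):
        s = cohort.series[(sid, "pso")]
        ax.plot(s.visit_days, s.z, color=colors[lab], alpha=0.5, lw=1)
    ax.axhline(-2.5, color="k", ls="--", lw=0.8)
    ax.set_xlabel("days since stroke")
    ax.set_ylabel("z score (PSO)")
    ax.set_title("synthetic recovery trajectories")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
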