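# gmvrec

Longitudinal grey-matter-volume (GMV) change and motor-recovery analysis for
subacute cortical stroke, as a tested, reusable Python pipeline.

After an ischaemic stroke in the primary sensorimotor cortex, dexterous hand
function recovers along heterogeneous trajectories, and grey-matter
morphology keeps remodelling for months. `gmvrec` implements the full
analysis chain that links the two:

1. **Response-feature analysis (RFA)** of timed dexterity scores
   (modified Jebsen–Taylor subtests, "picking small objects" = PSO as the
   index task). Scores are z-transformed against healthy-control norms
   (`z = -(score - mu)/sigma`, normal band `z = 0 +/- 2.5`), each subject's
   10-visit trajectory is fitted with three candidate models

   | model | formula | label when selected |
   |---|---|---|
   | linear | `m = I + beta*t` | fast |
   | exponential | `m = I*exp(-beta*t)` | slow (converges to 0) |
   | exponential + offset | `m = I*exp(-beta*t) + c` | slow if `c > -2.5`, poor if `c <= -2.5` |

   selected by small-sample AIC (AICc, parsimony within a 2-unit band),
   and a continuous recovery score is taken as the projection onto the
   first principal component of the cohort's z matrix.

2. **Tensor-based morphometry (TBM)**: rigid NMI alignment of the paired
   (3- and 9-month) T1 volumes, nonlinear registration minimizing
   `SSD + lambda * membrane energy` (lambda = 4, 8 iterations), the
   Jacobian determinant `JD = det(I + du/dx)` of the resulting field, the
   GMV-change map `(JD - 1) * GM`, 12-mm FWHM Gaussian smoothing, and
   mid-sagittal flipping so all lesions sit in one hemisphere.

3. **Voxel-wise inference**: per-voxel GLM with nuisance covariates (age,
   gender, lesion size, average GMV change, acquisition interval, ...),
   threshold-free cluster enhancement (TFCE, E = 0.5, H = 2), and
   family-wise-error correction from the permutation distribution of the
   maximum TFCE score (sign-flipping or Freedman–Lane).

4. **ROI statistics**: maximum-probability maps from a probabilistic
   atlas, cluster-area overlap percentages (>10% reported), central
   tendency ratios, confound-adjusted ROI means, Kruskal–Wallis /
   Mann–Whitney subgroup tests, and a 3x2 mixed ANOVA
   (recovery group x effect site) after a shift-then-sqrt transform.

5. **Quality control**: cohort SD maps with a perilesional summary and a
   partial-volume-effect check (two-tissue linear unmixing vs the hard
   segmentation, ratio and |1 - ratio| reported, 3-SD outlier flagging).

Because the underlying patient MRI data are not distributable, the package
ships a first-class synthetic module (`gmvrec.synthcohort`) that generates
behavioural cohorts from the published subgroup recovery models, 3-D image
pairs related by deformations with *analytic* Jacobians, tissue maps,
lesions and a toy probabilistic atlas — so every stage is validated against
known ground truth.

## Worked example

```python
import numpy as np
from gmvrec import synthcohort, recovery

# 28-subject cohort from the subgroup models (5 fast / 15 slow / 8 poor)
cohort = synthcohort.generate_cohort_trajectories(
    synthcohort.CohortSpec(seed=1)
)
labels = [
    recovery.classify_series(cohort.series[(sid, "pso")]).label
    for sid in cohort.subject_ids
]
print({lab: labels.count(lab) for lab in ("fast", "slow", "poor")})

pc = recovery.pc_recovery_scores(cohort.z_matrix("pso"))
print(round(pc.explained_variance_fraction, 2))
```

prints

```
{'fast': 5, 'slow': 15, 'poor': 8}
0.99
```

i.e. the full model-fitting/AICc/asymptote classification recovers every
planted subgroup at trajectory noise 0.3 z-units, and the first principal
component carries 99% of the longitudinal variance of this cohort. The end-to-end demo (synthesis -> RFA -> registration -> TFCE
permutation inference -> ROI/QC) runs from a console:

```bash
gmvrec run --config pipeline.yaml     # see PipelineConfig for the keys
```

and emits `report.json`, cluster tables, NIfTI maps and a trajectory
figure; identical configuration and seed give byte-identical reports.

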