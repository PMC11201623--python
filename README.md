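# mbrisk

Radiomic risk stratification for pediatric medulloblastoma-style MRI
studies. Medulloblastoma's molecular subgroups (here: Group 4 and SHH)
have intermediate prognosis *on average* but wide outcome disparities
within each subgroup; `mbrisk` builds a quantitative imaging signature
intended to separate low- from high-risk patients *within* a subgroup,
using only the tumor's appearance on a contrast-enhanced T1 scan.

The pipeline, per subject:

1. **Preprocess** the volume: polynomial bias-field correction,
   histogram-landmark intensity standardization, isotropic resampling.
2. **Extract features** from each tumor subcompartment (enhancing tumor,
   edema, non-enhancing tumor + cystic core) and their union (the
   habitat):
   * 214 per-voxel **texture** definitions — gradient operators, 3D
     gray-level co-occurrence (Haralick) statistics, Laws energies, Gabor
     magnitudes, and co-occurrence statistics of dominant gradient
     orientations ("gradient entropy") — each aggregated with 5 first-order
     statistics → **1070 values per region**;
   * 18 **morphology** definitions — 4 local surface descriptors
     (curvedness, sharpness, shape index, total curvature) from isosurface
     principal curvatures via fundamental forms, aggregated with the same
     5 statistics, plus 14 global contour features (ITK-style) →
     **34 values per region**.
3. **Concatenate** texture + shape into the combined radiomic signature
   (1104 values per region; 232 distinct feature definitions).
4. **Risk-stratify** with penalized regression (LASSO / ridge / elastic
   net; logistic on the event indicator by default, penalized Cox as an
   option): a continuous risk score, a training-median threshold, and
   low/high risk groups evaluated by Kaplan–Meier curves, the log-rank
   test, a Cox hazard ratio with 95% CI, and Harrell's C-index — under a
   leave-one-site-out design where each institution is held out once.

Real multi-institutional pediatric MRI cannot be redistributed, so the
package includes a **synthetic phantom cohort generator**: three-site,
two-subgroup cohorts of blob tumors with three nested subcompartments,
controllable intra-tumoral texture disorder (`z_tex`) and surface
irregularity (`z_shape`), and right-censored exponential survival whose
hazard depends on those latents. Every stage is tested against analytic
or brute-force oracles, and the full pipeline is verified by recovering
the planted risk structure from held-out sites. See `docs/methods.md` for
the model details and what the phantoms do and do not emulate.

## Worked example

```python
import numpy as np
from mbrisk.synthetic_data import PhantomParams, generate_cohort, cohort_table
from mbrisk.pipeline_cli import (
    ExperimentCell, extract_cohort_features, run_experiment_grid)
from mbrisk.risk_model import RiskModelConfig

params = PhantomParams(seed=11, beta_tex=1.5)   # texture-driven hazard
subjects = generate_cohort(params)              # 70 subjects, 3 sites
g4 = [s for s in subjects if s.survival.subgroup == "G4"]
feats = extract_cohort_features(g4, regions=("nonenhancing_cyst",))
print(feats.shape)

cells = [ExperimentCell("G4", "nonenhancing_cyst", "combined", site, "ridge")
         for site in ("site1", "site2", "site3")]
res = run_experiment_grid(feats, cohort_table(subjects), cells,
                          RiskModelConfig(seed=11))
print(res[["test_site", "status", "p_logrank", "c_index"]].to_string(index=False))
```

Output:

```
(48, 1104)
test_site status  p_logrank  c_index
    site1     ok   0.109512 0.634146
    site2     ok   0.028810 0.826087
    site3     ok   0.524135 0.607143
```

Each feature row holds the 1104-value combined signature of one Group 4
subject's non-enhancing+cystic core. Each result row is one
leave-one-site-out experiment: a ridge model trained on the other two
sites, its risk scores thresholded at the training median, and the two
held-out risk groups compared. Here the site-2 fold separates the groups
(log-rank p = 0.029) with a held-out concordance of 0.83 — the model
recovered the texture-disorder hazard planted in the phantoms; the other
folds show the power limits of 14–16-subject test sites.

The same pipeline is scriptable from the shell:

```bash
mbrisk simulate --seed 1 --out cohort/
mbrisk extract --cohort-dir cohort/ --out features.csv --regions nonenhancing_cyst
mbrisk run --features features.csv --cohort cohort/cohort.csv --out results/ --model ridge
mbrisk report --results results/results.csv
```

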