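# prmivim

Voxel-wise analysis of co-registered intravoxel incoherent motion (IVIM)
diffusion MRI and FDG-PET in tumors under chemoradiation: Bayesian IVIM
parameter mapping, rigid PET→MRI registration, parametric response mapping
(PRM), and the cohort statistics that relate pre-treatment imaging to tumor
shrinkage.  Built for imaging scientists who want a tested, reproducible
re-implementation of this analysis chain; since the underlying patient
imaging is not public, the package ships a synthetic digital-phantom cohort
generator with known ground truth that exercises every stage end to end.

## The analysis

DWI signal decay is modelled as two compartments,

    S(b) = S0 [ f·exp(−b·D*) + (1 − f)·exp(−b·D) ],

with diffusion coefficient **D** (inversely related to cellularity),
perfusion fraction **f**, and pseudo-diffusion coefficient **D\***.  Maps of
(D, f, D\*) are estimated voxel-wise inside the gross tumor volume (GTV) by
a Bayesian fit — amplitude and noise scale marginalized analytically, the
(D, f, D\*) posterior integrated on a dense per-voxel grid seeded by a
segmented least-squares fit, with empirical-Bayes shrinkage priors learned
from the volume.  The PET SUV volume is rigidly registered into the IVIM
frame (mutual information, 6 DOF) and resampled.

PRM classifies each GTV voxel against population-mean thresholds μ_SUV,
μ_D, μ_f (across-patient means of the spatially averaged pre-treatment GTV
values) into joint-histogram quadrants — e.g. SUV^hi D^lo = highly metabolic
and highly cellular — and reports each class as a percentage of the tumor
volume.  Cohort statistics: ΔGTV = 100·(GTV_on − GTV_pre)/GTV_pre, Wilcoxon
signed-rank tests for pre/on-treatment change, Spearman correlations
voxel-wise (SUV vs D, SUV vs f within each GTV) and globally (ΔGTV vs each
pre-treatment metric), Shapiro–Wilk normality screening.

## Worked example

```bash
python analysis/01_simulate_cohort.py   # 20 phantoms -> scratch/cohort/
python analysis/02_run_pipeline.py      # fit + register + PRM + stats
python analysis/03_report_findings.py   # print the findings
```

The last step prints (numbers from this exact seeded run):

```
1) pre- vs on-treatment (Wilcoxon signed-rank):
   tumor volume  significantly decreased (p = 1.9e-06)
   IVIM D        significantly increased (p = 1.9e-06)
   IVIM f        significantly increased (p = 1.9e-06)
2) voxel-wise SUV vs IVIM inside the GTV (mean +/- SD over patients):
   SUV vs D: r = -0.15 +/- 0.04
   SUV vs f: r = -0.10 +/- 0.06
3) associations of delta-GTV with pre-treatment metrics (Spearman):
   D                r = +0.88 (p = 4e-07) *
   PRM_SUVhi_Dlo    r = -0.68 (p = 0.00098) *
   PRM_SUVlo_Dhi    r = +0.78 (p = 4.9e-05) *
```

Reading: on-treatment tumors shrink while D and f rise (falling cellularity,
rising perfusion); SUV and IVIM are only weakly anti-correlated voxel-wise,
so PET and IVIM carry complementary information; and tumors dominated by the
metabolically active, highly cellular SUV^hi D^lo sub-volume shrink most,
while SUV^lo D^hi (inactive, low-cellularity) tumors resist — the phantom
cohort is constructed with exactly these couplings, and the pipeline
recovers their signs and significance from raw simulated images.

The same stages are scriptable via the CLI (`prmivim simulate / fit /
register / resample / thresholds / prm / stats / run`), e.g.

```bash
prmivim simulate --out scratch/demo --seed 1 --n-patients 5
prmivim run --config my_pipeline.yaml
```

Per-patient outputs are NIfTI maps and PRM label volumes (with PNG overlays
in the conventional cyan/magenta/red/green coding); cohort outputs are TSV
tables (summary, associations, paired tests, thresholds with provenance).

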