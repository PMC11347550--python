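# Methods

This note documents the models and procedures implemented in `ctprog`, the
design choices that were genuinely open, and what the synthetic phantoms do and
do not establish about real data.

## Phantom cohort generator

Real advanced-HCC trial imaging is private, so the package ships a generator
whose output has the same *shape* as the trial data and a fully known hazard.

**Geometry.** Each patient has four volumes — {liver, lung} × {baseline,
follow-up} — on a common voxel grid (default 32×64×64 at 5 mm × 3 mm × 3 mm,
i.e. a ~190 mm field of view; desk-scale tests use 10–16 slices). The organ is
a per-patient jittered ellipsoid; tumors are spheres with radii drawn uniformly
from 5–25 mm (1–5 cm diameters, typical of measurable advanced-HCC disease).
Tumor centers are rejection-sampled until the sphere at the *larger* of the
baseline and follow-up radius lies fully inside the organ (100 attempts, then
the radius shrinks by 20%), which guarantees `tumor ⊆ organ` at both
timepoints. A per-patient growth factor g ~ U(0.8, 1.6) scales every tumor
radius at follow-up, so follow-up volume ≈ g³ × baseline volume up to
voxelization. HU values are i.i.d. Gaussian per compartment (liver 60±15,
liver tumor 110; lung −700±40, lung tumor −100); no scanner texture, motion or
contrast-phase model — windowing and the CNN only need compartment contrast.

**Outcomes.** The log relative hazard is
`lp = β_vol · x_vol + β_growth · x_growth + β_clin · (x − E[x])` with
`x_vol = log(V_base + v₀) − log V_ref` and `x_growth = log((V_fu+v₀)/(V_base+v₀))
− E[log g³]`, where v₀ is one voxel volume (keeps the log finite for
tumor-free lungs) and V_ref is the config-implied expected total burden. The
centering constants are config-derived, not data-derived; they are monotone
affine shifts that keep a typical patient at the baseline hazard and change no
rank-based property. Event times are exponential with rate
`baseline_hazard_rate · exp(lp)` and censoring is an independent
U(0, horizon) time, which makes the expected event fraction analytic
(`P(event | lp) = 1 − (1 − e^{−λH})/(λH)`) and testable. Defaults
(rate 1/300 d⁻¹, horizon 1800 d, β_vol = 1, β_growth = 1.5, β_clin = the
published clinical coefficients) give ≈ 60–65% deaths and a median OS around
300 days, in the range reported for immunotherapy-treated advanced HCC.
Clinical covariates are independent draws matching the published marginal
frequencies (the joint distribution is not published; independence is the
explicit simplification).

**Size-based comparator.** Progression = 1 iff the sum over organs of the
longest in-plane tumor diameter grew by ≥ 20% from baseline, with measurable
baseline disease. This stands in for committee-adjudicated RECIST reads:
single-timepoint diameters, no new-lesion rule, no 5-mm absolute minimum.

## Preprocessing

Per organ and timepoint: linear z-resampling to 5-mm slices (masks use
nearest-neighbour), HU windowing `clip((HU − (WL − WW/2))/WW, 0, 1)` with
abdomen WW 400/WL 0 and chest WW 1200/WL −600, representative-slice selection,
bilinear resize to 224×224, then per-image standardization to mean 0/variance 1
(a constant image standardizes to zeros). Slice selection ranks tumor-bearing
slices by tumor area, fills remaining positions by organ area, breaks ties
toward the smaller slice index (the deterministic choice is ours; no rule is
published), and repeats the last index flagged `pad` if the organ spans fewer
than three slices. Standardization is per-image, after the resize; windowing is
applied on the volume, which is equivalent per-slice since the map is
pointwise. A missing follow-up chest scan is imputed by copying the *processed*
baseline chest images (LOCF), so a physically identical follow-up and an
LOCF-imputed one produce bit-identical packs. Horizontal flips with p = 0.5 are
applied only during training.

## Risk network

The backbone is a small CNN — four blocks of 3×3 convolution → ReLU → 2×2 max
pool, then global average pooling — shared across organs, timepoints and
slices (one backbone for parameter economy; the architecture diagram leaves
per-organ backbones open, and a config switch could add them). Slices enter at
a configurable resolution (default 64×64, downsampled from the 224×224 pack);
embeddings of the three slices per scan are averaged, which makes the score
invariant to slice order. For Rad-D a per-organ LSTM (separate liver and lung
units, since organ fusion happens after the temporal stage) runs over the
two-timepoint sequence and its **last hidden state** represents the organ (a
pooling over steps would be the alternative; with two steps the difference is
minor). Rad-S skips the temporal unit and uses the baseline embeddings. The
concatenated organ representations pass through a two-layer head
(LeakyReLU 0.1 between the linear layers — with few hidden units a plain ReLU
layer can initialize entirely dead and cut all gradient flow).

Training minimizes the event-count-normalized negative log Cox partial
likelihood with Breslow tie handling, computed within each minibatch's risk
sets (batch 16; the within-batch risk-set bias is the standard trade-off, and a
full-batch mode exists for small cohorts). Batches without events are skipped.
Adam uses the original recipe's settings by default (lr 5e-5, 200 epochs);
desk-scale recovery runs use a three-block backbone, lr 5e-4, 30 epochs and
decoupled weight decay 1e-2, chosen by pilot runs on the generator because the
small cohorts overfit quickly (training concordance rises above the ground-truth ceiling). Everything
is seeded; forward passes are deterministic.

The whole network is implemented on numpy arrays with explicit
backpropagation (im2col convolutions, unrolled two-step LSTM). The networks
are small enough that manual gradients are practical, analytically checked
against finite differences in the tests, and they expose the exact gradient
path to the feature maps that Grad-CAM needs.

## Clinical model and fusion

The clinical score is the linear predictor (no intercept — cutoffs absorb
location) of a seven-covariate Cox model fitted by Newton–Raphson with
step-halving on the Breslow partial likelihood, to gradient norm < 1e-8.
Differentiation enters ordinally (0 = high … 3 = undifferentiated) as a single
numeric covariate, matching the one-coefficient published formula; the exact
coding behind the published 0.3747 is not recoverable. Constant covariates are
dropped with a warning; diverging coefficients or standard errors raise a
separation diagnostic rather than returning a number. An optional ridge term
(0.5·λ‖β‖², default off) stabilizes desk-scale fits where a rare covariate
(EBRT at 5% prevalence) or an overfit deep score separates; the end-to-end
pipeline uses λ = 0.1 for its tiny training splits, while all oracle-agreement
tests use the unpenalized estimator. Fusion is a bivariate Cox model on the
(radiological, clinical) score pair, fitted on the training split and frozen.

## Evaluation statistics

All implemented directly (lifelines serves as the independent oracle in the
tests, never as the implementation): Harrell's C over comparable
pairs with half-credit ties and a Noether-type normal CI; IPCW
cumulative/dynamic AUC(t) with Kaplan–Meier censoring weights (the unweighted
estimator is a flag; with no censoring both reduce exactly to the Mann–Whitney
statistic); the product-limit estimator with Greenwood CIs and the median as
the smallest t with S(t) ≤ 0.5; the two-group log-rank test with the HR from a
univariate Cox fit on the group indicator (Wald CI on log HR; under complete
separation the HR is reported as ∞/0 in the direction of the observed excess);
strict-inequality stratification (score exactly at the cutoff is low-risk, per
the published rule); a nomogram point scale (100 points = the largest
single-covariate contribution range over the observed data, with an exact
affine round trip between total points and the linear predictor); and
quantile-binned calibration curves (default 3 bins — validation/test splits of
30–50 patients would leave deciles empty). Throughout, higher score = higher
risk.

## Grad-CAM

Per input slice: the gradient of the scalar risk score w.r.t. the last
convolutional feature maps is global-average-pooled into channel weights; the
weighted sum of the maps is rectified (standard Grad-CAM order, even though
informal descriptions often omit the rectification), bilinearly upsampled to
the input resolution, and min–max normalized to [0, 1] *after* upsampling so
the emitted map spans exactly [0, 1] (an all-nonpositive map is returned as
zeros with no spurious normalization). Maps are computed per slice, before the
slice-mean; both organ branches are emitted.

## Orchestration

Cohorts split by synthetic recruiting center (or per patient) with
floor-rule unit counts; the stratification cutoff is always the training-split
median of the variant's scores, frozen before touching validation/test. The
pipeline trains Rad-S and Rad-D, fits CLN and both fusions on the training
split, and reports C, AUC(t), HR and log-rank p per variant per split, plus
the size-based comparison and the ground-truth concordance ceiling — the
metrics JSON is byte-identical across reruns with the same seeds.

## Problem sizes used by the test suite

Unit tests run on 8–500-patient cohorts at 10–16 slices of 32–64² voxels.
The deep recovery experiment trains on 120 patients (16×64×64 volumes,
hazard loading only on baseline tumor volume, β_vol = 1.5) for 30 epochs and
evaluates on an independent 120-patient cohort from the same generator — an
independent test cohort gives a far tighter estimate of generalization than
holding out 40 of the 120. The fused-vs-clinical comparison uses 10 smaller
replicates, and the deep-vs-size-based comparison scores 100 freshly generated
small cohorts with one trained model. These sizes are the package's chosen
desk-scale study conditions; the ground-truth concordance ceiling at these
settings is ≈ 0.70–0.76, so recovery results must be read relative to that
ceiling, not to 1.

## What passing tests do and do not show

The phantoms exercise every pipeline contract (mask geometry, windowing,
selection, LOCF, loss, fitting, metrics) and end-to-end signal recovery, but
they are deliberately simple: Gaussian HU noise, spherical lesions, ellipsoidal
organs, independent covariates, exponential hazards. Passing here demonstrates
correctness of the machinery and recoverability of a known signal at desk
scale — not clinical performance on trial CT, which depends on texture,
segmentation quality and effect sizes the phantoms do not emulate.

## Known limitations

No DICOM ingestion (volumes are NIfTI); no automatic segmentation (masks are
inputs); no competing risks or time-varying covariates; the combined
validation+test C-index weighting reported alongside the original models is
not implemented because its construction is not fully specified; minibatch
risk sets bias the partial likelihood for very small batches; the numpy
network trains on CPU only and is sized accordingly.
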