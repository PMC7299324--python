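# Methods

## Problem setting

`slidesurv` models disease-specific survival directly from histopathology
images under *weak supervision*: the only label is case-level — a follow-up
time `T_i` and an event indicator `O_i` — while a case consists of one to
ten slide images whose prognostically informative regions are unknown. If a
fraction `p` of tissue patch positions are informative, the probability that
a bag of `n` uniformly sampled patches contains none of them is `(1-p)^n`,
which vanishes quickly in `n`; this is the statistical lever that makes
bag-level training with a handful of random patches viable.

## Model

A small CNN of depthwise-separable convolution blocks (chosen for its low
parameter count) encodes each patch with shared weights; features are
average-pooled per channel across the bag, making the case representation
exactly invariant to patch order and insensitive to bag size; a final linear
("logistic regression") head produces either a K-way softmax over discrete
survival intervals or a scalar. Bags hold 16 patches during training (case
diversity) and many more at evaluation (slide coverage).

The network, backpropagation, RMSProp and the EMA weight average are written
directly in NumPy. At the package's desk scale (32–64 px patches, four
blocks, ~20k parameters) a training run takes minutes on one CPU and is
bit-for-bit reproducible from its seed. The bag mean uses a canonical
(sorted) reduction order so patch-permutation invariance holds exactly in
floating point, not merely to tolerance.

## Training objectives

Three censoring-aware losses (all minimised; printed maximisation forms are
negated):

1. **Censored cross-entropy** (default). Time is discretised into K=4
   intervals at the quartiles of *event* times among observed-event cases,
   separately per study (cancer type), in months. Events contribute
   `-log f(X)[Y]`; censored cases contribute `-log Σ_{y>Z} f(X)[y]`, where
   `Z` is the latest interval whose right endpoint falls strictly before the
   censoring time (`Z = -1` ⇒ contribution exactly 0). Finite intervals are
   right-closed; this convention was an open choice and is tested as stated.
   The scalar risk score is the negated expectation of the interval *index*
   under the predicted distribution (any increasing representative is
   rank-equivalent).
2. **Cox partial likelihood** with Breslow tie handling, evaluated per batch
   (n ≤ 128) as an approximation to the full-cohort likelihood; batches with
   no event are resampled (counted and reported).
3. **Exponential concordance lower bound** `Σ_{(i,j)∈E} 1 - e^{f_i - f_j}`
   over comparable pairs `E = {(i,j): O_i=1, T_j>T_i}`. The raw trained
   output is survival-oriented; a single predict-time adapter negates it so
   that every head yields a higher-is-worse risk score.

When a batch mixes studies, each case's censored-CE label uses its own
study's interval scheme.

## Evaluation and checkpointing

EMA weights (decay 0.999) are snapshotted on a fixed step schedule; each
checkpoint is tagged with its tuning-split concordance. The ensemble is the
top-k checkpoints by tune c-index (ties broken toward later steps); the
case-level prediction is the member *median* over one shared sampled patch
bag per case (even counts: mean of the two middle values). Sharing the bag
across members removes a variance component the member median would
otherwise have to absorb.

All analysis times are months, `floor(days/30.44)`, applied once. The
concordance index counts a pair as informative iff the earlier time is an
observed event (for tied times, event-vs-censored counts, event first);
score ties earn 0.5. Multi-study ("combined") concordance sums concordant
and informative pairs *within* studies only — cross-study pairs would mostly
measure between-cancer-type prognosis. Risk groups are the within-study (or
within study × stage) score quartiles: below the 25th percentile low,
above the 75th high; a fully tied cell is all-medium. Group curves are
compared with the Kaplan-Meier estimator and logrank test (via lifelines,
which also provides the Cox fitter). Cox models encode stage as numeric 1–4,
age/10, a male indicator, study dummies and optional study×stage / study×age
interactions; constant covariates are dropped and reported. The added value
of the image-model score over baseline covariates is measured predictively:
leave-one-out Cox fits, out-of-fold linear predictors (centred per fold; a
rank-free normalisation), within-study pooled c-index, and the delta against
the baseline feature set. Bootstrap intervals are percentile bootstrap over
case-level resamples, stratified by study for pooled statistics (an open
choice, documented here). Five-year AUC treats events within 60 months as
positives, event-free follow-up past 60 months as negatives, and excludes
cases censored earlier than 60 months, whose five-year status is unknown.

## Synthetic cohorts

The generator plants a known case-level signal in images so the entire
pipeline is testable without any real slides. Per case: latent risk
`r ~ N(0,1)`; event time exponential with rate `λ0·exp(β·r)` (a Weibull
shape knob exists; shape 1 = exponential, so the Cox loss target is
well-specified); independent exponential censoring; 1–10 slides showing an
irregular tissue blob (intensity ≈185, eosin-leaning tint) on a bright
background (242), so a 220/255 grayscale threshold recovers tissue. The
patch grid over tissue is seeded with nuclei-like dots: a fraction `p` of
cells are *informative* — their expected dot count runs linearly in `Φ(r)`
between 8 and 44 per cell — while the rest carry the fixed mid density.
Per-dot darkening scales inversely with expected count, so the expected dark
mass per cell is density-independent: the signal lives in local texture
(many faint vs few dark nuclei), not in global mean intensity, forcing a
genuinely patch-level readout. Stage (ordinal 1–4) is simulated correlated
with `r` through noisy thresholds — a realistic confounder for the Cox
harness; age is weakly correlated, sex independent.

What these cohorts do **not** emulate: H&E colour statistics or stain
physics, pyramidal multi-resolution structure, scanner artefacts, and
intra-tumour heterogeneity beyond the single latent factor. A pass on them
shows the machinery (losses, sampling, training, protocol) is correct and
can recover a planted weak signal — not that the architecture is adequate
for real whole-slide morphology.

## Study conditions and problem sizes

The end-to-end recovery experiment uses 500 cases over two study codes
(2:1:1 stratified split), informative fraction p = 0.2, risk effect β = 1,
baseline hazard 0.002/day, censoring 0.001/day (≈ 2/3 events), 128 px
slides, 1–3 slides per case, 32 px patches. The model is four blocks of
widths 16-32-64-64 (stride 2), trained 2000 steps with RMSProp (lr 2e-3,
batch 16 cases × 16 patches, EMA 0.999), checkpointed every 100 steps (20
checkpoints, as one model's schedule at full scale would yield), ensembled
over the top 10, predictions from 256-patch bags. Under these conditions the
latent risk itself achieves a test concordance near 0.75 (the ceiling
imposed by censoring and hazard noise); the trained pipeline reaches ≈ 0.67
and the permuted-label control stays at chance. Augmentation is dihedral
orientation plus brightness/contrast/saturation jitter (hue jitter
available, off by default); it stands in for stain-normalisation-based
augmentation, whose reference method is external to this package.

## Numerical choices

- Probability floor 1e-12 inside logs (configurable; hits are warned).
- Tissue threshold 220/255 on the channel-mean grayscale; patch eligibility
  ≥ 50% tissue pixels; both exposed in the API. Coordinates are 0-based,
  top-left, half-open `[x, x+patch_px)`.
- Patch sampling is with replacement (i.i.d. uniform over the union of
  eligible positions across a case's slides; also well-defined for tiny
  tissue regions).
- Network arithmetic float32 by default; float64 available where exactness
  is asserted (gradient checks, EMA identities).
- Checkpoint-selection ties: later training step, then configuration id.
- Quantile computations use linear interpolation throughout (splits,
  interval schemes, risk-group cuts).

## Known limitations

- The latent risk is one-dimensional and the texture monotone in it; real
  prognostic morphology is not a single monotone factor.
- The concordance convention for score ties (0.5 credit) and the 5-year AUC
  exclusion rule are documented choices; other conventions shift absolute
  values slightly without changing comparisons made with a fixed convention.
- Mean event time *rises* with β in this generator (E[e^{-βr}] = e^{β²/2}
  for normal r): β strengthens the association between risk and time, it
  does not shorten average survival. Monotonicity checks are therefore made
  on concordance and on the high-risk subpopulation.
- No distributed training, vendor slide formats, Efron tie correction, or
  full-cohort partial-likelihood optimisation.
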