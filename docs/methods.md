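# Methods

## The problem

Tissue segmentation of the brain from a single T1-weighted (MPRAGE) volume
systematically mislabels structures whose T1w intensity coincides with
cortical gray matter: the dura mater (a thin membrane adhering to the outer
cortical surface), medium-sized vessels rendered bright by inflow effects,
and extracerebral connective tissue. A generative intensity model that sees
only one channel cannot distinguish these voxels from cortex; with additional
channels whose contrast differs — FLAIR, on which dura, vessels and
connective tissue are dark while gray matter is not, or apparent transverse
relaxation rate (R2*) maps, on which vessels and susceptibility-affected
tissue have elevated rates — the per-class densities separate in multivariate
intensity space and the misclassification dissolves.

This package implements that multichannel segmentation model, the R2*
relaxometry needed to derive a rate channel from a multi-echo acquisition,
Bhattacharyya-distance summaries of class separability, and a synthetic
multi-contrast phantom that reproduces the confound structure so that every
claim is testable without scan data.

## Segmentation model

Each tissue class `c` (default roster: GM with 1 Gaussian, WM with 1, CSF
with 2 because the fluid compartment is heterogeneous, and OTHER with 2 for
non-brain tissue inside the mask) emits the N-channel voxel intensity vector
`x` from a mixture of multivariate Gaussians:

    p(x | c) = sum_j  w_cj  N(x; mu_cj, Sigma_cj)

combined with class priors that are either stationary proportions `pi_c`
(re-estimated each iteration) or user-supplied spatial prior volumes
`pi_c(v)` already on the data grid (held fixed). The posterior tissue
probability maps are the per-voxel class posteriors, components summed
within class.

Fitting is expectation–maximisation on the observed-data log-likelihood:
responsibilities are computed with log-sum-exp stabilisation and Cholesky
factorisations (no explicit inverses); the M-step updates are closed-form.
Convergence is declared at a relative log-likelihood change below `rel_tol`
(default 1e-6) or `max_iter` (default 200).

Numerical choices:

* **Covariance regularisation** adds a per-channel diagonal floor of
  1e-6 × that channel's data variance (absolute floor 1e-12 for constant
  images). The floor must be per-channel: a stack mixing raw signal (~1e2
  units) with rates (~1e-2 /ms) differs by ~1e8 in variance, and any shared
  scalar floor erases the small-scale channel.
* **Initialisation** is deterministic given the seed. With spatial priors,
  each class starts from prior-weighted channel moments, multi-Gaussian
  classes split along the first principal axis. Without priors, k-means++
  (fixed seed, one restart) clusters a ≤20 000-voxel subsample; clusters are
  dealt to classes in roster order after sorting centres by first-channel
  mean, which fixes class identity in the common case of
  intensity-ordered tissues.
* **Starved components** (posterior mass < 10 voxels) are re-seeded by
  splitting the heaviest sibling of the same class along its principal axis.
  A re-seed legitimately interrupts the EM ascent, so the fit trace records
  these events as `interventions`; the monotonicity guarantee (non-decreasing
  log-likelihood, relative tolerance 1e-8) holds within the segments between
  them. None of the shipped phantom configurations triggers a re-seed.
* **Bias field** (off by default, `bias_order = 0`): one multiplicative
  smooth field per channel, `exp(b(v))` with `b` a polynomial (total degree ≤
  order) in voxel coordinates normalised to [-1, 1], constant term excluded
  and basis columns centred so the intensity scale stays in the class means.
  Minimising the precision- and responsibility-weighted squared log-residual
  `sum_{n,k} (r_nk / s_k²)(log x_n − b(v_n) − log mu_k)²`, with `s_k²` the
  component's log-scale variance `diag(Sigma_k)/mu_k²`, gives a weighted
  least-squares update with a *geometric* posterior-mean prediction.
  The precision weights matter: low-intensity fluid voxels have large
  relative noise (and a Rician floor) and otherwise pollute the smooth field
  estimate with structured shell-shaped residuals.
* **Channel scaling**: an optional robust z-scale (median/MAD) per channel
  exists for numerically disparate units; it is off by default, recorded in
  the model when active, and incompatible with bias correction (which needs
  positive raw intensities).

Masking: voxels outside the stack mask (or non-finite in any channel,
dropped with a logged count) never enter the fit and receive probability 0
in every class map.

## R2* relaxometry

The magnitude signal of a multi-echo gradient-echo acquisition decays as
`S(TE) = S0 exp(−R2* · TE)`; `T2* = 1/R2*`. The estimator is ordinary least
squares on `log S` against TE (closed form per voxel), optionally weighted by
`S²`. Voxels with any echo at or below `min_signal` are invalid; negative
fitted rates (noise-driven) are retained and counted, not clipped, so the
downstream density model sees the estimator's true distribution. The
echo-combined T1w image is the arithmetic mean over echoes. Magnitude data
are assumed; the Rician noise floor is bounded by `min_signal`
(recommended ~3× background noise SD) rather than modelled. The log-linear
choice is this package's interpretation of the standard mono-exponential
estimator; multi-compartment and complex-valued fitting are out of scope.

## Bhattacharyya separation

For Gaussians the Bhattacharyya distance has the closed (Kailath) form

    DB = 1/8 (mu1−mu2)' Sbar⁻¹ (mu1−mu2) + 1/2 ln(|Sbar| / sqrt(|Sigma1||Sigma2|)),
    Sbar = (Sigma1+Sigma2)/2,

computed via Cholesky log-determinants and triangular solves. The square
root over `|Sigma1||Sigma2|` is required for `DB(a,a) = 0` — renderings of
the formula that drop it are typographical losses, and the implementation is
cross-checked against numerical integration of `−ln ∫ sqrt(p q)` in tests.
Distances between full classes use each class's largest-weight component as
representative (the convention for quoting GM–CSF separation when CSF is a
2-mixture); all component pairs are tabulated alongside. Distances are
computed on the model's fitted intensity scale and are invariant under joint
affine rescaling of the channels (asserted in tests). Matched fits (same
replicates, different channel combinations) are compared with a two-sided
paired t-test on a chosen class-pair distance.

## Synthetic phantom

The phantom is geometric, not anatomical: nested ellipsoids (WM core, GM
ribbon of configurable thickness, CSF shell) decorated with the confounds —
a dura sheet 1–2 voxels thick hugging the outer GM boundary over a polar
arc, bright vessel tubes threaded through the CSF shell adjacent to cortex,
connective patches outside the shell, and a marked GM subregion with
gradient-echo signal dropout. The claims under test concern intensity-density
separability and adjacency, which this geometry captures while staying
dependency-free and fast (well under a second at 48³).

Default per-label contrast (arbitrary units, mean ± SD; SDs ≈ 10% of mean,
realistic tissue heterogeneity):

| label       | T1w        | FLAIR      | R2* (/ms) |
|-------------|------------|------------|-----------|
| background  | 30 ± 5     | 30 ± 5     | 0.02      |
| WM          | 700 ± 35   | 250 ± 25   | 0.045     |
| GM          | 400 ± 40   | 400 ± 40   | 0.04      |
| CSF         | 120 ± 15   | 60 ± 10    | 0.001     |
| dura        | 400 ± 40   | 150 ± 20   | 0.06      |
| vessel      | 520 ± 30   | 100 ± 15   | 0.15      |
| connective  | 404 ± 40   | 120 ± 18   | 0.05      |
| suscept. GM | 240 ± 25   | 400 ± 40   | 0.12      |

These encode the confound contracts: dura and connective tissue within 2% of
GM on T1w but ≤ 50% of GM on FLAIR; vessels at 130% of GM on T1w; the
susceptibility zone attenuated ×0.6 on T1w with FLAIR untouched and R2*
elevated. The R2* values are plausible-order defaults chosen here, not
measured values. The within-class SDs are deliberately realistic: with much
tighter classes the vessel intensity becomes its own 10σ-separable cluster
and EM isolates it even unimodally, which is not how the confound behaves in
real data, where vessels sit ~3σ inside the GM density.

When the T1w channel is requested as a multi-echo series (default), echoes
follow `S0(label) exp(−R2*(label) · TE)` at TE = 1.48, 2.98, 4.48, 5.98,
7.48 ms, with `S0` chosen so the echo-average matches the contrast table;
the R2* channel used in segmentation is then *fitted* from this series, as
in the full pipeline. Noise is Rician by default (Gaussian and none
available), with per-modality noise SD = GM mean / SNR and default SNR 30 —
a representative 3 T structural value. An optional multiplicative bias field
is a random polynomial scaled to a stated log-range over the imaged object.
Everything is bit-reproducible given the spec seed.

**Spatial priors** (`make_priors`) emulate population-atlas priors without
registration: one-hot maps of GM (including the susceptibility zone), WM,
CSF and the membranous OTHER structures (dura + connective) are smoothed
with a σ = 3 voxel Gaussian, mixed with a 25% uniform floor and renormalised.
Two deliberate asymmetries reproduce the real failure mechanism: the GM
prior bleeds onto the adjacent dura sheet (atlases carry no dura class), and
vessels get *no* prior support of their own (atlases carry no vessel class)
— so a T1w-only fit assigns dura and bright vessels to gray matter, and only
added channels can rescue them. Background never enters the fit (the stack
mask excludes it), so it is also excluded from the OTHER prior, whose bulk
would otherwise sit over the outer CSF shell and absorb fluid voxels.

### What the phantom does not emulate

Partial-volume voxels (boundaries are crisp), anatomical geometry and
topology, k-space artefacts, motion, nonstationary noise, and inter-subject
variability. Passing tests therefore demonstrate the correctness of the
estimator and the direction and mechanism of the multimodal improvement —
not clinical-grade performance on real heads, where partial volume and
registration error blur every boundary the phantom renders sharply.

## Comparison methodology

Configurations are compared exactly as segmentation studies compare them:
voxel-wise averages of tissue probability maps over replicates, difference
maps (B − A) whose per-class deltas integrate to compartment volume changes
in ml (per voxel the class deltas sum to zero — probability mass only moves
between compartments), Dice of thresholded posteriors against phantom truth,
and the confound "leak": the fraction of dura/vessel/connective voxels whose
GM posterior exceeds a threshold (default 0.5) together with the mean GM
posterior over those voxels, reported side by side because overlay figures
use continuous colour scales rather than a hard cutoff. Volumes are computed
in native space and an explicit mask argument is supported (default: the
segmentation mask); values are therefore comparable within a configuration
pair, which is how such deltas are used.

## Pipeline and reproducibility

`run_experiment` drives phantom → relaxometry → per-combination segmentation
→ separation reports → pairwise comparisons from a single YAML config with
one seed. Every stage derives its own substream seed as
`sha256(seed:stage) mod 2³¹−1`, so stages are independently reproducible;
combination labels are normalised to the fixed channel order t1w, flair,
r2star joined by "+". The manifest records versions, seeds, config hash,
per-stage wall time, EM iteration counts and a hash over all output file
hashes; re-running an identical config reproduces the manifest hash
bit-for-bit.

## Problem sizes in the shipped tests

Unit and acceptance tests run phantoms at 24³–48³ with 8–20 replicates where
replication is the point (the paired separation test uses 20 replicates at
32³); `scripts/acceptance.py` uses a 40³ confound phantom, 12 replicates at
32³ for the paired test, and 48³ recovery phantoms. These sizes give
stable statistics in seconds per fit; the model itself is resolution-
agnostic and has been exercised up to 48³ throughout.

## Known limitations

No spatial regularisation (MRF) or partial-volume model; no registration or
resampling anywhere — inputs must arrive co-registered, and grid mismatches
are hard errors; priors are either stationary or supplied on-grid; the bias
model is a low-order polynomial, not a spline field; magnitude-only
relaxometry with a threshold (not a model) for the noise floor; the paired
t-test assumes approximately normal distance differences across replicates.
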