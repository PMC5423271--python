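# multiseg

Multimodal MRI tissue segmentation with per-class Gaussian-mixture density
models, R2* relaxometry, and Bhattacharyya class-separation statistics —
plus a synthetic multi-contrast phantom that makes every stage testable
without scan data.

## The problem

Gray-matter segmentation from T1-weighted images alone is confounded by
tissue that is isointense to cortex on that contrast: dura mater adhering to
the cortical surface, inflow-bright vessels running in sulci, and
extracerebral connective tissue all end up in the gray-matter compartment,
inflating its volume. Adding channels with different contrast — FLAIR, on
which these structures are dark, or apparent transverse relaxation rate
(R2*) maps derived from a multi-echo acquisition — separates the class
densities in multivariate intensity space and lets a generative classifier
resolve the confounds. This package is for researchers who want a
transparent, registration-free implementation of that multichannel model to
study *when and why* added channels help.

## The model

Each tissue class `c` emits its voxels' N-channel intensity vector from a
Gaussian mixture `p(x|c) = Σ_j w_cj N(x; μ_cj, Σ_cj)` (default roster:
GM 1 Gaussian, WM 1, CSF 2, OTHER 2), weighted by stationary or spatial
class priors; fitting is EM with log-sum-exp stabilisation, optional
polynomial bias-field correction, and deterministic seeded initialisation.
R2* comes from log-linear least squares on `S(TE) = S0·exp(−R2*·TE)`
(`T2* = 1/R2*`). Class separability is quantified by the Bhattacharyya
distance between Gaussians,

    DB = ⅛ (μ1−μ2)ᵀ Σ̄⁻¹ (μ1−μ2) + ½ ln( |Σ̄| / √(|Σ1||Σ2|) ),  Σ̄ = (Σ1+Σ2)/2,

with the largest-weight component representing a multi-Gaussian class.
See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Generate a phantom with a dura sheet and vessels, segment it with and
without the FLAIR channel, and watch the dura leave the gray-matter class:

```python
import multiseg as ms

spec = ms.PhantomSpec(shape=(40, 40, 40), seed=3)
stack, series, truth = ms.generate(spec)
priors = ms.make_priors(truth)

unimodal  = ms.MultichannelMixture(stack.subset(["t1w"]), priors=priors).fit(seed=1)
multimodal = ms.MultichannelMixture(stack, priors=priors).fit(seed=1)

dura = truth.mask("DURA")
for name, res in [("t1w", unimodal), ("t1w+flair", multimodal)]:
    leak = ms.leak_rate(res.tissue_probability_maps.get("GM"), dura)
    db = res.separation(name).distance("GM", "CSF")
    print(f"{name:10s}  dura GM posterior {leak.mean_posterior:.2f}   "
          f"GM-CSF Bhattacharyya {db:.1f}")
print(multimodal.summary())
```

Output:

```
t1w         dura GM posterior 0.61   GM-CSF Bhattacharyya 10.1
t1w+flair   dura GM posterior 0.00   GM-CSF Bhattacharyya 24.4

Multichannel Gaussian-mixture segmentation
==========================================
channels:       t1w, flair
class priors:   spatial volumes
log-likelihood: -274888.4674
iterations:     36 (converged: True)
class  component  weight  mean[t1w]  sd[t1w]  mean[flair]  sd[flair]
   GM          1  1.0000   399.4582  40.7136     400.2750    42.3198
   WM          1  1.0000   699.9218  35.7240     250.3632    28.4574
  CSF          1  0.0334   236.7513  22.3210     399.8755    42.4345
  CSF          2  0.9666   121.0806  16.1303      61.4746    16.2679
OTHER          1  0.1513   519.8822  31.5122     102.1787    19.6921
OTHER          2  0.8487   402.1735  41.1436     148.7110    25.3639
```

With T1w alone, dura voxels (isointense to GM at ~400) carry a mean
gray-matter posterior of 0.61; adding FLAIR drops it to zero, because an
OTHER component captures the dark-on-FLAIR membranes (mean ≈ 400/149) and a
second one the vessels (≈ 520/102). The GM–CSF Bhattacharyya distance more
than doubles — the density-separation mechanism behind the cleanup.

The same experiment end-to-end, all four channel combinations with pairwise
difference maps and a reproducibility manifest:

```bash
multiseg run --config config.yaml      # see RunConfig for the YAML schema
multiseg phantom --seed 3 --out ph/    # individual stages as subcommands
multiseg fit-r2star --echoes ph/multiecho.nii.gz --echo-times 1.48,2.98,4.48,5.98,7.48 --out r2/
multiseg segment --channels ph/t1w.nii.gz,ph/flair.nii.gz --mask ph/labels.nii.gz --seed 1 --out seg/
```

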