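# fcmseg

Fuzzy C-means (FCM) brain-image segmentation with a spatially regularized
variant (NFCM), a Gaussian–Potts MRF baseline, phantom-based noise-robustness
benchmarking, and summary-level two-group clinical statistics.

## Who this is for

Researchers evaluating intensity-based tissue segmentation of grayscale MRI
slices or volumes: how well do fuzzy clustering methods recover tissue classes
as image noise grows, and how does adding a Markov-random-field style spatial
prior change that? The package also reproduces the kind of two-group clinical
comparisons (t-tests from printed mean ± SD summaries, χ² tests from 2×2
counts) that accompany such imaging studies.

## The model

FCM partitions the pixel intensities X = {x₁…xₙ} into b fuzzy classes by
minimizing

    G_FCM(U, V) = Σₖ Σᵢ μₖᵢᵐ ‖xᵢ − vₖ‖²,   subject to Σₖ μₖᵢ = 1,

with membership matrix U = (μₖᵢ), cluster centers V = (vₖ) and fuzzifier
m > 1. Setting the Lagrangian's derivatives to zero gives the alternating
closed-form updates

    vₖ = Σᵢ μₖᵢᵐ xᵢ / Σᵢ μₖᵢᵐ,
    μₖᵢ = 1 / Σₗ (cₖᵢ / cₗᵢ)^(2/(m−1)),   cₖᵢ = ‖xᵢ − vₖ‖.

**NFCM** replaces the squared distance with a spatially penalized one,

    d²ₖᵢ = c²ₖᵢ + β · (1/|N(i)|) Σ_{j∈N(i)} (1 − μₖⱼ)²,

so classes unsupported by a pixel's neighborhood are penalized; β = 0 reduces
exactly to FCM. The **MRF baseline** is a Gaussian-likelihood Potts model
optimized by iterated conditional modes (ICM). Accuracy is scored after
optimal label matching by the misclassification rate MCR = M/N and the Kappa
index KI = 2TP/(2TP+FP+FN) per class (the Dice coefficient), with KI = 1 at
perfect overlap.

## Worked example

Run the default noise-robustness benchmark (4-class 128×128 concentric
phantom, Gaussian noise SD 0–0.25 on the unit intensity range, 10 noise
realizations per level, all three algorithms segmenting the identical noisy
images):

```python
from fcmseg import SweepSpec, run_noise_sweep
result = run_noise_sweep(SweepSpec(master_seed=0))
print(result.summary.round(4).to_string(index=False))
```

```
algorithm  level  mcr_mean  mcr_sd  ki_mean  ki_sd  n
      fcm   0.00    0.0000  0.0000   1.0000 0.0000 10
      fcm   0.10    0.1000  0.0014   0.8998 0.0014 10
      fcm   0.25    0.4102  0.0037   0.5881 0.0037 10
      mrf   0.00    0.0000  0.0000   1.0000 0.0000 10
      mrf   0.10    0.0043  0.0008   0.9957 0.0008 10
      mrf   0.25    0.0409  0.0055   0.9591 0.0056 10
     nfcm   0.00    0.0000  0.0000   1.0000 0.0000 10
     nfcm   0.10    0.0042  0.0005   0.9958 0.0005 10
     nfcm   0.25    0.2706  0.0060   0.7145 0.0067 10
```

(abridged; the full table has six levels). Reading it: every algorithm is
exact on the clean phantom (MCR 0, KI 1); MCR rises and KI falls as noise
grows; the spatial prior makes NFCM far more noise-robust than plain FCM
(at noise SD 0.10, MCR 0.004 vs 0.100), while the ICM-optimized MRF baseline
is the most robust at the highest noise levels.

The same comparisons are available from the shell:

```
fcmseg phantom out/ph --shape 128,128 --seed 7
fcmseg segment out/ph/image.png out/seg --algo nfcm --clusters 4
fcmseg eval out/seg/labels.png out/ph/truth.png
fcmseg sweep out/sweep --plot
fcmseg clinstats rows.csv results.csv
```

`clinstats` on the two post-treatment clinical summaries and the gender
counts prints

```
 label     method  statistic   df      p_value  significant_0.05  significant_0.01
 nihss  student_t -10.086358 88.0 2.390620e-16              True              True
    no  student_t  12.260458 88.0 9.728049e-21              True              True
gender chi_square   0.189076  1.0 6.636871e-01             False             False
```

i.e. the stroke-scale and nitric-oxide group differences are highly
significant while the gender split is not.

## Documentation

`docs/methods.md` describes the model assumptions, parameter defaults (and
why the spatial coupling defaults to β = 0.2), what the phantom generator
does and does not emulate, and known limitations.
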