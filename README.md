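# mcbr — multiclass sparse Bayesian regression

`mcbr` fits linear regression models in severely under-determined settings
(n ≪ p), the regime of *inverse inference* / decoding in functional
neuroimaging: predict a continuous behavioral variable y from activation
images whose voxels are the features.  Instead of one global ridge penalty
(which under-regularizes noise voxels and over-regularizes informative
ones) or one penalty per feature (ARD, which underfits when p is large),
the model softly groups the p features into K latent classes and learns
one shrinkage strength per class, jointly with the weights.  A by-product
of the fit is an interpretable clustering of features by relevance.

## Model

    y = X w + b + ε,     ε ~ N(0, α⁻¹ Iₙ),      α ~ Γ(α₁, α₂)
    wⱼ | zⱼ, λ ~ N(0, λ_{zⱼ}⁻¹)                 (feature j in class zⱼ)
    λₖ ~ Γ(λ₁ₖ, λ₂ₖ),   k = 1..K                (shape/rate convention)
    zⱼ | π ~ Categorical(π),      π ~ Dirichlet(η)

K = 1 recovers Bayesian ridge regression (BRR); K = p with frozen
singleton classes recovers automatic relevance determination (ARD).  The
default "universal" preset uses K = 9 classes whose Gamma shapes ladder
through 10⁻³…10⁵ (common rate 10⁻²), spanning essentially unregularized
to hard-shrunk weight scales; classes empty out when unsupported by the
data, so K acts as an upper bound rather than a tuning parameter.

Two inference engines are provided:

* **Gibbs sampling** (`fit(method="gibbs")`) — full conditional sweeps
  over (z, λ, π, α, w), posterior means over post-burn-in samples
  (default 5000 sweeps, burn-in 4000);
* **mean-field variational Bayes** (`fit(method="vb")`) — closed-form
  coordinate ascent on the free energy with the factorization
  q(w)q(α)q(λ)q(z)q(π) (default up to 500 cycles).  On very sparse
  problems VB reliably converges to a heavily regularized one-class
  optimum — a documented pathology that the Gibbs engine avoids.

Accuracy is scored by the explained-variance ratio
ζ = (var(y) − var(y − ŷ)) / var(y).

## Worked example

```python
from mcbr import MCBR, make_sparse_regression, class_purity

# ill-posed sparse benchmark: p=200 features, 8 informative, n=50 train
train, test, truth = make_sparse_regression(seed=1)
res = MCBR.from_dataset(train).fit(method="gibbs", seed=1)
print(res.summary())
print(f"test-set explained variance: {res.score(test.X, test.y):.3f}")
rep = class_purity(res, truth)
print(f"informative class {rep.informative_class}: "
      f"size {rep.informative_size}, purity {rep.informative_purity:.0f}%")
```

prints

```
Multiclass Sparse Bayesian Regression Results
=============================================
Engine:            Gibbs sampling
No. features (p):  200
Classes (K):       9
Iterations:        5000 (burn-in 4000)
Noise precision:   1.892
Intercept:         -0.0182

Occupied classes:
 class precision    pi  size mean_abs_w
     2       6.2 0.037     5      1.497
     3       147 0.113     6     0.1507
     4  1.03e+03 0.174    73    0.01618
     5     1e+04 0.164    13   0.007746
     6  9.99e+04 0.121    32   0.006353
     7     1e+06 0.220    58    0.01069
     8     1e+07 0.116    13    0.00848

test-set explained variance: 0.924
informative class 2: size 5, purity 80%
```

The five features in the weakly regularized class 2 (mean |w| ≈ 1.5) are
almost exactly the truly informative ones, while the noise features sit
in classes with precisions 10³–10⁷ and are shrunk to ≈ 0.  The held-out
ζ of 0.92 sits just under the design's noise ceiling of 17/18 ≈ 0.94.

## Command line

```bash
mcbr simulate --kind sparse --seed 7 --out-dir data/
mcbr fit --data data/train.csv --engine gibbs --seed 0 --out model.json
mcbr predict --model model.json --data data/test.csv --out pred.txt
mcbr evaluate --model model.json --data data/test.csv --truth data/truth.json
mcbr benchmark --trials 15 --seed 1 --out-dir bench/
```

Volumetric workflows read/write NIfTI (4-D image stack + binary mask;
in-mask voxels are flattened x-fastest) so fitted weight and class maps
can be written back as images: `mcbr simulate --kind volumetric --format
nifti` and `mcbr fit --image images.nii.gz --mask mask.nii.gz ...`.

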