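# dkisub

Diffusional kurtosis imaging (DKI) needs long multi-shell diffusion MRI
acquisitions, which makes it vulnerable to scan interruptions and deliberate
shortening. `dkisub` is a simulation and scheme-design toolkit for studying
how *truncating* a multi-shell acquisition biases the seven DKI scalar
parameters — FA, MD, AD, RD (diffusion tensor) and MK, AK, RK (kurtosis
tensor) — under three gradient-ordering/subsampling strategies:

* **Opt_EEM** — the scheme is built by bipolar electrostatic-repulsion
  optimization and ordered incrementally so that every prefix keeps the
  per-shell proportions and a uniform angular spread; truncation simply
  drops the tail.
* **Opt_SC** — spherical-codes subsampling: nested subsets chosen to
  maximize the covering radius (the smallest pairwise line-angle).
* **Random_TRUNC** — the reference strategy: the whole scheme is randomly
  shuffled and then cut.

It is aimed at diffusion-MRI methods researchers who want reproducible,
seeded versions of this experiment: scheme generation and gradient-table
I/O (FSL `bvals`/`bvecs`, MRtrix `.b`), a crossing-fiber signal simulator
with Rician noise, unconstrained and positivity-constrained DKI fitting,
scalar-metric derivation, histogram summary characteristics, and a
factorial evaluation pipeline that exports tidy CSV tables.

## Model

The voxel model is a mixture of two fiber populations crossing at 60°,
each with an intra-cellular (AD/RD = 1.4/0.1 ×10⁻³ mm²/s) and an
extra-cellular (2.0/0.5 ×10⁻³ mm²/s) axially symmetric Gaussian
compartment, all with volume fraction ¼. The mixture defines the mean
tensor D̄ = Σ fₖ Dₖ and the directional kurtosis

K(n) = 3 · [Σ fₖ (nᵀDₖn)² − (nᵀD̄n)²] / (nᵀD̄n)²,

and signals follow the DKI representation
ln S(b, n) = ln S₀ − b·D(n) + (b²/6)·D(n)²·K(n)
on a 100-volume scheme (b = 1000 s/mm² × 32 directions, b = 2000 s/mm² ×
60 directions, 8 × b = 0), with Rician noise at SNR = S₀/σ defined on the
b = 0 volumes. Fitting estimates the 22 DKI coefficients by two-pass
weighted least squares, optionally constrained to non-negative apparent
kurtosis (a convex QP solved exactly in dual form). The headline statistic
is the relative error of each subset's parameter median against the fully
sampled median over the same noise realizations.

## Worked example

```python
import dkisub as dk

scheme = dk.build_reference_scheme(master_seed=0, n_restarts=20)
print("scheme volumes:", scheme.n_volumes)

gt = dk.ground_truth_metrics(dk.build_default_substrate())
print({k: float(f"{v:.4g}") for k, v in gt.items()})

config = dk.ExperimentConfig(
    methods=("opt_eem", "random_trunc"), fractions=(1.0, 0.5),
    snr_levels=(20,), n_orientations=20, n_noise=20, master_seed=0)
table = dk.run_experiment(config, scheme=scheme)
rel = table[(table.statistic == "rel_error_pct") & (table.fraction == 0.5)]
print(rel.pivot_table(index="method", columns="parameter", values="value").round(2))
```

prints

```
scheme volumes: 100
{'fa': 0.606, 'md': 0.0007667, 'ad': 0.00135, 'rd': 0.000475, 'mk': 0.807, 'ak': 0.1245, 'rk': 0.7163}
parameter       ad     ak    fa    md     mk    rd     rk
method
opt_eem       1.06  29.85  0.23  1.96   7.75  1.51  14.47
random_trunc  2.15  33.96  0.03  3.19  10.24  2.55  14.17
```

The first dictionary is the analytic ground truth of the substrate (MD in
mm²/s). The table gives, per method, the relative error (%) of each
parameter's median after discarding half the volumes at SNR 20: FA is
essentially unaffected, MD moves by 1–3%, the kurtosis parameters are the
most sensitive, and random truncation is worse than the optimized ordering
for most parameters.

A thin CLI wraps the same functions, e.g.

```
dkisub generate --dirs 32,60 --bvals 1000,2000 --b0 8 --seed 1 --out scheme.b
dkisub subsample --scheme scheme.b --method sc --retain 0.5 --out subset50.b
dkisub evaluate --orientations 20 --noise 20 --seed 1 --out results/
```

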