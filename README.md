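# epmix

Cell-mixture deconvolution from single-molecule enhancer–promoter
methylation profiles.

## The problem

Optical genome mapping of fluorescently labeled unmethylated cytosines
(at TCGA recognition sites) produces megabase-scale single-molecule
methylation maps. Because one molecule can carry both a gene promoter
and a distal enhancer tens of kilobases away, each molecule reports the
*joint* binary methylation state of an enhancer–promoter (E–P) pair —
single-cell-like information for that locus. Counting molecules that
fully span a pair gives, per pair, a distribution over the four
combinations

(P:M, E:M), (P:M, E:U), (P:U, E:M), (P:U, E:U)

with M = methylated and U = unmethylated (any label overlap ⇒ U).
Given pure reference profiles of two cell populations A and B, the
composition of an unknown mixture can be estimated from its per-pair
combination distributions. `epmix` implements that whole workflow for
people developing or benchmarking methylation-based deconvolution:
element construction, molecule profiling, in-silico mixture assembly, a
fully synthetic data generator, four estimators of the mixing ratio,
and supervised selection of the most discriminative pairs.

## The estimators

With per-pair probabilities $A_{c,p}$, $B_{c,p}$ (pure training sets)
and $T_{c,p}$ (mixed test set), the mixing ratio $\alpha$ of sample A
is estimated by:

* **projection** — per pair,
  $\alpha_p = 1 - \frac{\vec{AT}_p \cdot \vec{AB}_p}{\lVert \vec{AB}_p \rVert^2}$
  where $\vec{AT}_p = \vec T_p - \vec A_p$ and
  $\vec{AB}_p = \vec B_p - \vec A_p$; the estimate is the mean over pairs.
* **sse** / **kld** — grid search over $\alpha \in \{0, 0.01, \dots, 1\}$ of
  the linear combination $LCT_{\alpha,c,p} = \alpha A_{c,p} + (1-\alpha) B_{c,p}$,
  minimizing the summed squared error or the symmetrized
  Kullback–Leibler divergence between $T$ and $LCT$.
* **mle** — gradient ascent on the concave log-likelihood
  $\log L(\alpha) = \sum_p \sum_c N_{p,c} \log\left(\alpha P_{A,p,c} + (1-\alpha) P_{B,p,c}\right)$
  with $N_{p,c}$ the test counts.

All counts entering divergences and likelihoods are made strictly
positive by adding 0.01 to each normalized ratio and renormalizing.
Pairs are ranked for subset selection by Euclidean distance, symmetric
KLD, or coverage-weighted KLD (wKLD) between the two training
distributions.

## Worked example

```python
from epmix import SyntheticSpec, simulate_two_samples, prepare_experiment, run_sweep
from epmix.mixtures import mean_errors

spec = SyntheticSpec(n_pairs=200, seed=42)        # two synthetic samples
data = simulate_two_samples(spec)
exp = prepare_experiment(data.molecules_A, data.molecules_B, data.regions, seed=42)
sweep = run_sweep(exp, ["projection", "sse", "kld", "mle"])
print(sweep.head(4).to_string(index=False))
print(mean_errors(sweep).round(4).to_string())
```

prints

```
 ratio     method  estimate  abs_error  n_pairs_used
   0.0 projection  0.017284   0.017284           200
   0.0        sse  0.020000   0.020000           200
   0.0        kld  0.010000   0.010000           200
   0.0        mle  0.000000   0.000000           200

method
kld           0.0064
mle           0.0068
projection    0.0121
sse           0.0073
```

Each row is one (known ratio, method) cell of the standard sweep:
mixtures of the two test sets are assembled at ratios 0–100% in 10%
steps and deconvolved against the pure training profiles. The final
table is the mean absolute deviation of the estimated from the known
ratio per method — here all four methods resolve the 200-pair mixtures
to within ~1%.

The same pipeline is available as a console script
(`epmix simulate | profile | split-mix | deconvolve | rank | sweep |
build-elements`); see `epmix --help`.

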