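# Methods

This note documents the model implemented by `epmix`, the choices made
where the design was genuinely open, and what the synthetic benchmark
does and does not demonstrate.

## Data model

The read-level observation is a *labeled molecule*: one long DNA
molecule aligned to the reference, with the genomic coordinates of its
fluorescent labels. A label marks an unmethylated cytosine in a TCGA
recognition site; a fully methylated molecule has no labels. Optical
detection localizes a label only to about 1 kb, so every label
coordinate is interpreted as a symmetric 1 kb window (±500 bp, clipped
at the chromosome origin). The ±500 bp symmetric reading was chosen
over a one-sided 1 kb window because the localization error has no
preferred direction; state calling accepts `extension=0` for data whose
labels are exact.

Elements are built in BED convention (0-based, half-open):

* **Promoters**: 2000 bp upstream to 500 bp downstream of the TSS,
  strand-aware, clipped at the contig start rather than dropped.
* **Enhancers**: ambiguous genomic regions are subtracted; if the
  subtraction splits an enhancer, the longest fragment is kept (ties:
  leftmost) so each id remains one contiguous interval; anything
  shorter than 200 bp is replaced by a 200 bp window on its midpoint.
  Subtraction is applied to enhancers only (promoters are fixed-width
  TSS windows); the element builder exposes the exclusion list so
  callers can subtract from promoters too if wanted.
* **Links**: a pair is kept when both elements contain ≥1 potential
  label site (TCGA motif; the motif is its own reverse complement, so a
  forward-strand scan suffices), lie on one chromosome, and are ≥5000 bp
  apart edge to edge ("gap" = nearest-edge distance). For promoter-level
  benchmarking a single enhancer is assigned per promoter: highest
  site count, then larger enhancer, then smaller gap (the closer
  enhancer), then lexicographic id — the last step exists purely to
  make the choice deterministic.

## Profiling

A molecule contributes to a pair only if its aligned span contains the
envelope of both elements; it contributes to every pair it spans. Each
contributing molecule falls into exactly one of the four combinations
MM, MU, UM, UU (promoter letter first; the serialization fixes this
order). Pairs spanned by fewer than 30 molecules in a sample are
discarded. Promoter-only profiles are the exact row sums (M = MM+MU,
U = UM+UU) over the *same* spanning molecules, which makes pairwise and
promoter-only analyses directly comparable.

Probabilities are formed from counts by normalizing, adding a
pseudo-count of 0.01 to each ratio and renormalizing (divide by
1 + 0.01·k for k states). The pseudo-count is applied wherever
logarithms appear — the KLD grid criterion, KLD/wKLD ranking and the
MLE training probabilities — because all of them require strict
positivity; the projection estimator uses raw normalized ratios, which
need none.

## Estimators

* **Projection**: per-pair values are deliberately *not* clamped before
  averaging (a noisy pair can legitimately project outside [0, 1] and
  clamping would bias the mean); only the final mean is clipped.
  Pairs whose two training vectors coincide define no direction and
  are skipped.
* **Grid (SSE, KLD)**: 101 candidate ratios at 1% steps; ties go to the
  smaller ratio. KLD is the mean of the two directed divergences,
  natural logarithm (the base only rescales the objective and cannot
  change the argmin).
* **MLE**: the log-likelihood is concave in the mixing ratio, so
  gradient ascent with the analytic gradient
  ∂logL/∂α = Σ N·(P_A−P_B)/(αP_A+(1−α)P_B) converges to the global
  optimum. Constants: base step η = 0.005, start 0.5, stop when the
  log-likelihood gain drops below 0.001 or after 20 000 iterations,
  iterates clamped to [0, 1], and the ratio with the highest likelihood
  seen on the trace is reported. A *fixed* step of η·gradient is
  unstable whenever total test counts are more than a few hundred (the
  local curvature scales with the molecule count, so η·∇ overshoots and
  the iterate bounces between the clamps); the implementation therefore
  backtracks — the proposed step is halved, keeping the best candidate,
  until the likelihood stops improving. This preserves the update rule
  and all constants, guarantees a non-decreasing likelihood trace, and
  agrees with an exhaustive 0.001-grid likelihood scan to ~6×10⁻⁴ on
  randomized instances.

All estimators operate on whichever pairs are present in both training
sets and the test set (intersection semantics) and accept the 2-state
promoter-only alphabet unchanged.

## Pair ranking

Euclidean distance uses raw proportions; KLD and wKLD use
pseudo-counted probabilities. wKLD multiplies each directed summand by
the molecule count of the sample contributing the leading probability,
so it is linear under uniform count scaling and favors highly covered
(more reliable) pairs. Ranking uses the pure training sets only — the
mixed test set never enters, so subset selection cannot leak the
quantity being estimated.

## Mixture assembly

Both samples are split at random; each test set receives
floor(0.33 × size of the smaller sample) molecules so the two test sets
are equal-sized, and the rest trains. A mixture at ratio α draws
round(α·n) molecules (round half up) from test A and the rest from
test B; a fresh mixture is sampled per ratio (rather than partitioning
one test set across ratios) so sweep cells are independent. Replicates
of one biological sample are merged by concatenation. All randomness
flows from one user seed, fanned out to named substreams (simulate /
split / mix) so stages are independently reproducible.

## Synthetic generator

The generator emulates the *scale and structure* of a processed
optical-methylation experiment, not its genomics: pairs are laid out on
one synthetic chromosome (2500 bp promoter, 200 bp enhancer, 10 kb gap,
20 kb between pairs) so that every molecule spans exactly one pair.
Per-pair combination distributions are drawn from a symmetric
Dirichlet(0.5), which yields the realistic skew of many
near-deterministic pairs. Sample B equals sample A on non-differential
pairs; on differential pairs it is interpolated (by the `divergence`
parameter) toward an independent Dirichlet redraw. The redraw is
rejection-sampled until its symmetric KLD from sample A reaches
`min_differential_kld` (default 1 nat): a planted "differential" pair
must carry signal clearly above the sampling-noise floor of roughly
(k−1)/n ≈ 0.1 nat at the emulated coverage, otherwise it is
differential in name only. Per-pair coverage is `coverage_min` plus a
negative-binomial excess; the defaults (100 + NB(shape 10, mean 50))
produce a per-pair *test* coverage ≥ ~30 with median ≈ 50 after the 33%
split — the scale the estimators are designed for. The planted-marker
benchmark instead uses raw per-sample coverage ≈ 50 (min 30 + NB mean
20) with 1% differential pairs. Each molecule realizes its drawn
combination directly: an unmethylated element gets one label jittered
around the element midpoint (±200 bp promoter, ±80 bp enhancer, small
enough that the 1 kb window always hits its own element and never the
other), a methylated element gets none.

What the generator does *not* emulate: multiple pairs per molecule,
background labels outside elements, alignment errors, chimeric
molecules, coverage correlated with GC or mappability, and linked
pairs sharing a promoter. Benchmarks on this generator therefore
demonstrate the correctness and statistical behavior of the estimators
under the stated sampling model — not performance on real optical maps.
One consequence worth noting: with strongly divergent, well-covered
training profiles the projection estimator is nearly unbiased and can
match or beat MLE on synthetic sweeps, whereas on noisier real profiles
likelihood-based estimation has the advantage.

## Benchmark problem sizes

The packaged checks use 1000 pairs (≈300 k molecules) for parameter
recovery and 10 000 pairs (≈1 M molecules) for the planted-selection
scenario, chosen as the smallest sizes at which per-pair noise averages
out and the subset-selection effect is unambiguous; both complete in
well under a minute each on one CPU.

## Known limitations

* Two-component mixtures only; the likelihood generalizes to k
  components but the estimators here do not.
* Binary element states; partial methylation within an element is
  deliberately collapsed (any label ⇒ unmethylated).
* Molecules are assumed single-chromosome and correctly aligned.
* The element builder expects E–P links as input (e.g. from an
  enhancer–target predictor); it does not predict them.
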