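"""Dataset assembly: train/test splits, known-ratio mixtures, and a fully
synthetic two-sample generator.

The generator emulates the scale of a processed optical-methylation
experiment: two samples, a few hundred to tens of thousands of E-P
pairs, and per-pair molecule coverage such that after the 33% test
split each pair is covered by roughly 30 or more test molecules with a
median around 50.  Each pair's 4-combination distribution is drawn from
a symmetric Dirichlet(0.5), which produces the realistic skew of many
near-deterministic pairs; sample B either shares sample A's
distribution (non-differential pairs) or is pulled toward an
independent redraw by the divergence parameter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .deconvolution import (
    GradientAscentConfig,
    DeconvolutionResult,
    deconvolve,
)
from .elements import GenomicInterval
from .molecules import LABEL_HALF_WIDTH, LabeledMolecule
from .profiling import (
    MIN_COVERAGE,
    PSEUDOCOUNT,
    AssignmentIndex,
    CombinationProfile,
    PairRegion,
    SampleProfileSet,
    profile_molecules,
)

logger = logging.getLogger(__name__)

#: Fraction of the less-covered sample's molecules put into each test set.
TEST_FRACTION = 0.33
#: The standard sweep: mixing ratios 0-100% in 10% increments.
DEFAULT_RATIOS = tuple(round(0.1 * i, 1) for i in range(11))


# ---------------------------------------------------------------------------
# synthetic two-sample generator


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic two-sample experiment.

    Per-pair raw coverage (molecules per sample spanning the pair) is
    ``coverage_min`` plus a negative-binomial excess with mean
    ``coverage_extra_mean`` and shape ``coverage_nb_shape``.  The
    defaults (100 + NB(mean 50)) give a raw median near 150 so that the
    33% test split leaves a per-pair test coverage of >=30 with a median
    around 50.  ``divergence`` in [0, 1] interpolates sample B's
    distribution from sample A's (0) to an independent Dirichlet redraw
    (1) on the ``differential_fraction`` of pairs that differ.

    A planted differential pair must actually differ: the redraw is
    rejection-sampled until its symmetric KLD from sample A's
    distribution reaches ``min_differential_kld`` (nat).  The default of
    1 nat sits an order of magnitude above the sampling-noise floor at
    the emulated coverage (approximately (k-1)/n ~ 0.1 nat for k = 4
    states and n ~ 30-50 molecules), so planted pairs carry a real
    signal rather than a lucky redraw.
    """

    n_pairs: int
    coverage_min: int = 100
    coverage_extra_mean: float = 50.0
    coverage_nb_shape: float = 10.0
    divergence: float = 1.0
    differential_fraction: float = 1.0
    dirichlet_alpha: float = 0.5
    min_differential_kld: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.coverage_min < 1 or self.coverage_extra_mean < 0:
            raise ValueError("invalid coverage parameters")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")
        if not 0.0 <= self.differential_fraction <= 1.0:
            raise ValueError("differential_fraction must lie in [0, 1]")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if self.min_differential_kld < 0:
            raise ValueError("min_differential_kld must be non-negative")


@dataclass
class SimulatedDataset:
    """Synthetic molecules plus the ground truth behind them."""

    spec: SyntheticSpec
    regions: list[PairRegion]
    molecules_A: list[LabeledMolecule]
    molecules_B: list[LabeledMolecule]
    probs_A: np.ndarray  # (n_pairs, 4) true combination distributions
    probs_B: np.ndarray
    differential: np.ndarray  # bool mask over pairs

    @property
    def pair_ids(self) -> list[str]:
        return [r.pair_id for r in self.regions]


# synthetic genome layout (bp); elements far enough apart that a 1 kb
# label window can never bridge two elements or two pairs
_PROM_LEN = 2500
_ENH_LEN = 200
_PAIR_GAP = 10_000
_SPAN_MARGIN = 500
_PAIR_SPACING = 20_000
_CHROM = "chrS"


def _sym_kld(p: np.ndarray, q: np.ndarray) -> float:
    p = np.clip(p, 1e-12, None)
    q = np.clip(q, 1e-12, None)
    lr = np.log(p) - np.log(q)
    return float(0.5 * ((p * lr).sum() - (q * lr).sum()))


def _divergent_redraw(
    rng: np.random.Generator, p: np.ndarray, alpha: float, min_kld: float
) -> np.ndarray:
    """Independent Dirichlet redraw at least ``min_kld`` away from ``p``."""
    best, best_kld = None, -1.0
    for _ in range(100):
        cand = rng.dirichlet([alpha] * len(p))
        kld = _sym_kld(p, cand)
        if kld > best_kld:
            best, best_kld = cand, kld
        if best_kld >= min_kld:
            break
    return best


def _pair_layout(i: int) -> PairRegion:
    base = _SPAN_MARGIN + i * _PAIR_SPACING
    prom = GenomicInterval(_CHROM, base, base + _PROM_LEN)
    enh_start = base + _PROM_LEN + _PAIR_GAP
    enh = GenomicInterval(_CHROM, enh_start, enh_start + _ENH_LEN)
    return PairRegion(f"pair{i:06d}", _CHROM, prom, enh)


def simulate_two_samples(spec: SyntheticSpec) -> SimulatedDataset:
    """Generate molecules for two samples with known pair distributions.

    Every synthetic molecule spans exactly one pair.  Its methylation
    combination is drawn from the pair's distribution and realized as
    label coordinates: an unmethylated element receives one label
    jittered around the element midpoint, a methylated element none.
    The jitter stays small enough that the 1 kb label window always
    overlaps its own element and never the other one.
    """
    rng = substream(spec.seed, "simulate")
    n = spec.n_pairs
    regions = [_pair_layout(i) for i in range(n)]

    probs_A = rng.dirichlet([spec.dirichlet_alpha] * 4, size=n)
    n_diff = int(round(spec.differential_fraction * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    differential = np.zeros(n, dtype=bool)
    differential[diff_idx] = True
    probs_B = probs_A.copy()
    if spec.divergence > 0:
        for i in diff_idx:
            redraw = _divergent_redraw(
                rng, probs_A[i], spec.dirichlet_alpha, spec.min_differential_kld
            )
            probs_B[i] = (
                1.0 - spec.divergence
            ) * probs_A[i] + spec.divergence * redraw

    nb_p = spec.coverage_nb_shape / (spec.coverage_nb_shape + spec.coverage_extra_mean)

    def _coverages() -> np.ndarray:
        extra = (
            rng.negative_binomial(spec.coverage_nb_shape, nb_p, size=n)
            if spec.coverage_extra_mean > 0
            else np.zeros(n, dtype=int)
        )
        return spec.coverage_min + extra

    def _make_sample(sample_id: str, probs: np.ndarray) -> list[LabeledMolecule]:
        molecules: list[LabeledMolecule] = []
        coverages = _coverages()
        for i, region in enumerate(regions):
            cov = int(coverages[i])
            combo_counts = rng.multinomial(cov, probs[i])
            prom_mid = (region.promoter.start + region.promoter.end) // 2
            enh_mid = (region.enhancer.start + region.enhancer.end) // 2
            span_s = region.envelope[0] - _SPAN_MARGIN
            span_e = region.envelope[1] + _SPAN_MARGIN
            prom_jit = rng.integers(-200, 201, size=cov)
            enh_jit = rng.integers(-80, 81, size=cov)
            j = 0
            for combo, count in enumerate(combo_counts):
                prom_u = combo >= 2
                enh_u = combo % 2 == 1
                for _ in range(count):
                    labels: tuple[int, ...]
                    if prom_u and enh_u:
                        labels = (prom_mid + int(prom_jit[j]), enh_mid + int(enh_jit[j]))
                    elif prom_u:
                        labels = (prom_mid + int(prom_jit[j]),)
                    elif enh_u:
                        labels = (enh_mid + int(enh_jit[j]),)
                    else:
                        labels = ()
                    molecules.append(
                        LabeledMolecule(
                            f"{sample_id}-{region.pair_id}-{j}",
                            sample_id,
                            _CHROM,
                            span_s,
                            span_e,
                            labels,
                        )
                    )
                    j += 1
        return molecules

    molecules_A = _make_sample("A", probs_A)
    molecules_B = _make_sample("B", probs_B)
    logger.info(
        "simulated %d pairs: %d + %d molecules (%d differential pairs)",
        n,
        len(molecules_A),
        len(molecules_B),
        n_diff,
    )
    return SimulatedDataset(
        spec, regions, molecules_A, molecules_B, probs_A, probs_B, differential
    )


# ---------------------------------------------------------------------------
# split and mix


def split_train_test(
    molecules_A: Sequence[LabeledMolecule],
    molecules_B: Sequence[LabeledMolecule],
    seed: int,
    test_fraction: float = TEST_FRACTION,
) -> tuple[list, list, list, list]:
    """Random train/test partition of both samples' molecules.

    Both test sets get the same number of molecules:
    floor(test_fraction * size of the smaller sample), drawn uniformly
    without replacement.  Returns (train_A, test_A, train_B, test_B).
    """
    if not molecules_A or not molecules_B:
        raise ValueError("both molecule lists must be nonempty")
    n_test = math.floor(test_fraction * min(len(molecules_A), len(molecules_B)))
    if n_test == 0:
        raise ValueError("test size is zero; provide more molecules")
    rng = substream(seed, "split")

    def _split(mols: Sequence[LabeledMolecule]) -> tuple[list, list]:
        test_idx = rng.choice(len(mols), size=n_test, replace=False)
        mask = np.zeros(len(mols), dtype=bool)
        mask[test_idx] = True
        return (
            [m for m, t in zip(mols, mask) if not t],
            [m for m, t in zip(mols, mask) if t],
        )

    train_A, test_A = _split(molecules_A)
    train_B, test_B = _split(molecules_B)
    return train_A, test_A, train_B, test_B


def _mix_counts(n: int, ratio_A: float) -> tuple[int, int]:
    n_A = math.floor(ratio_A * n + 0.5)  # round half up
    return n_A, n - n_A


def mix_test_sets(
    test_A: Sequence[LabeledMolecule],
    test_B: Sequence[LabeledMolecule],
    ratio_A: float,
    seed: int,
) -> list[LabeledMolecule]:
    """Known-ratio mixture of the two equally sized test sets.

    round(ratio_A * n) molecules are drawn without replacement from
    test_A, the rest from test_B; the output always has n molecules.
    Sample provenance survives in each molecule's ``sample_id`` for
    evaluation but is never consulted by estimators.
    """
    if len(test_A) != len(test_B):
        raise ValueError("test sets must have equal sizes")
    if not 0.0 <= ratio_A <= 1.0:
        raise ValueError("ratio_A must lie in [0, 1]")
    n = len(test_A)
    n_A, n_B = _mix_counts(n, ratio_A)
    rng = substream(seed, f"mix:{ratio_A!r}")
    idx_A = rng.choice(n, size=n_A, replace=False)
    idx_B = rng.choice(n, size=n_B, replace=False)
    return [test_A[i] for i in idx_A] + [test_B[i] for i in idx_B]


def merge_replicates(*replicates: Sequence[LabeledMolecule]) -> list[LabeledMolecule]:
    """Concatenate replicate molecule lists into one sample."""
    out: list[LabeledMolecule] = []
    for rep in replicates:
        out.extend(rep)
    return out


# ---------------------------------------------------------------------------
# experiments


@dataclass
class MixtureExperiment:
    """Pure training profiles plus indexed test molecules, ready to mix."""

    regions: list[PairRegion]
    train_A: SampleProfileSet
    train_B: SampleProfileSet
    test_index_A: AssignmentIndex
    test_index_B: AssignmentIndex
    n_test: int
    seed: int

    def mixed_test_profiles(self, ratio_A: float, seed: int) -> SampleProfileSet:
        """Profile of a fresh known-ratio mixture of the two test sets."""
        n_A, n_B = _mix_counts(self.n_test, ratio_A)
        rng = substream(seed, f"mix:{ratio_A!r}")
        idx_A = rng.choice(self.n_test, size=n_A, replace=False)
        idx_B = rng.choice(self.n_test, size=n_B, replace=False)
        counts = self.test_index_A.count_matrix(idx_A) + self.test_index_B.count_matrix(
            idx_B
        )
        profiles = {
            r.pair_id: CombinationProfile(r.pair_id, counts[i])
            for i, r in enumerate(self.regions)
            if counts[i].sum() > 0
        }
        return SampleProfileSet(f"mix{ratio_A:g}", profiles, n_states=4)


def prepare_experiment(
    molecules_A: Sequence[LabeledMolecule],
    molecules_B: Sequence[LabeledMolecule],
    regions: Sequence[PairRegion],
    seed: int,
    min_coverage: int = MIN_COVERAGE,
    extension: int = LABEL_HALF_WIDTH,
    test_fraction: float = TEST_FRACTION,
    promoter_only: bool = False,
) -> MixtureExperiment:
    """Profile, coverage-filter, split and index a two-sample dataset.

    The coverage filter is applied to each full sample before the
    split; only pairs covered by at least ``min_coverage`` molecules in
    both samples are analyzed.  With ``promoter_only`` the training
    profiles are marginalized to the 2-state promoter alphabet (test
    mixtures are marginalized on the fly by the estimators' caller).
    """
    full_A = profile_molecules(molecules_A, regions, "A", extension)
    full_B = profile_molecules(molecules_B, regions, "B", extension)
    kept = sorted(
        set(full_A.filter_coverage(min_coverage).profiles)
        & set(full_B.filter_coverage(min_coverage).profiles)
    )
    kept_regions = [r for r in regions if r.pair_id in set(kept)]
    logger.info("prepare_experiment: %d/%d pairs pass coverage", len(kept), len(regions))

    train_A, test_A, train_B, test_B = split_train_test(
        molecules_A, molecules_B, seed, test_fraction
    )
    prof_A = profile_molecules(train_A, kept_regions, "A", extension)
    prof_B = profile_molecules(train_B, kept_regions, "B", extension)
    if promoter_only:
        prof_A, prof_B = prof_A.promoter_marginal(), prof_B.promoter_marginal()
    return MixtureExperiment(
        regions=kept_regions,
        train_A=prof_A,
        train_B=prof_B,
        test_index_A=AssignmentIndex(test_A, kept_regions, extension),
        test_index_B=AssignmentIndex(test_B, kept_regions, extension),
        n_test=len(test_A),
        seed=seed,
    )


Estimator = Callable[[SampleProfileSet, SampleProfileSet, SampleProfileSet], DeconvolutionResult]


def run_sweep(
    experiment: MixtureExperiment,
    methods: Sequence[str | Estimator],
    ratios: Sequence[float] = DEFAULT_RATIOS,
    pair_subset: Sequence[str] | None = None,
    pseudocount: float = PSEUDOCOUNT,
    ga_config: GradientAscentConfig | None = None,
    promoter_only: bool = False,
) -> pd.DataFrame:
    """Deconvolve fresh mixtures at every ratio with every method.

    Returns a tidy table with one row per (ratio, method):
    columns ratio, method, estimate, abs_error, n_pairs_used.
    ``methods`` entries may also be callables (custom estimators) taking
    (train_A, train_B, test) and returning a DeconvolutionResult.
    """
    rows = []
    train_A, train_B = experiment.train_A, experiment.train_B
    for ratio in ratios:
        test = experiment.mixed_test_profiles(ratio, experiment.seed)
        if promoter_only:
            test = test.promoter_marginal()
        for method in methods:
            if callable(method):
                res = method(train_A, train_B, test)
            else:
                res = deconvolve(
                    train_A,
                    train_B,
                    test,
                    method,
                    pseudocount=pseudocount,
                    config=ga_config,
                    pair_subset=pair_subset,
                )
            rows.append(
                {
                    "ratio": ratio,
                    "method": res.method,
                    "estimate": res.alpha_A,
                    "abs_error": abs(res.alpha_A - ratio),
                    "n_pairs_used": res.n_pairs_used,
                }
            )
    return pd.DataFrame(rows)


def mean_errors(sweep: pd.DataFrame) -> pd.Series:
    """Mean absolute deviation from the known ratio, per method."""
    return sweep.groupby("method")["abs_error"].mean()
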