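"""Supervised ranking of E-P pairs by training-set discriminative power.

Three symmetric scores measure how differently a pair's combination
distribution behaves in the two pure training samples: the Euclidean
distance between the raw proportion vectors, the symmetrized
Kullback-Leibler divergence of the pseudo-counted probabilities, and a
coverage-weighted variant (wKLD) in which each divergence summand is
multiplied by the molecule count supporting it, favoring highly covered
pairs.  Ranking is computed on the pure training sets only; the mixed
test set never enters, so subset selection cannot leak the mixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .deconvolution import GradientAscentConfig
from .mixtures import DEFAULT_RATIOS, MixtureExperiment, mean_errors, run_sweep
from .profiling import PSEUDOCOUNT, SampleProfileSet, normalize_with_pseudocount

logger = logging.getLogger(__name__)

RANKING_METHODS = ("euclidean", "kld", "wkld")

#: Default log-spaced ladder of subset sizes ("all" = no restriction).
DEFAULT_K_LADDER: tuple = (100, 500, 1000, 5000, 10_000, 50_000, "all")


@dataclass(frozen=True)
class PairScore:
    pair_id: str
    method: str
    score: float


# ---------------------------------------------------------------------------
# matrix-level scores (rows = pairs, columns = combinations)


def euclidean_distance(PA: np.ndarray, PB: np.ndarray) -> np.ndarray:
    """Per-pair Euclidean distance between the two proportion vectors."""
    return np.sqrt(((PA - PB) ** 2).sum(axis=-1))


def symmetric_kld(PA: np.ndarray, PB: np.ndarray) -> np.ndarray:
    """Per-pair mean of the two directed Kullback-Leibler divergences."""
    if np.any(PA <= 0) or np.any(PB <= 0):
        raise ValueError("kld requires strictly positive probabilities")
    log_ratio = np.log(PA) - np.log(PB)
    return 0.5 * ((PA * log_ratio).sum(axis=-1) - (PB * log_ratio).sum(axis=-1))


def weighted_kld(
    PA: np.ndarray, PB: np.ndarray, NA: np.ndarray, NB: np.ndarray
) -> np.ndarray:
    """Count-weighted symmetric KLD: each summand weighted by the molecule
    count of the same sample as its leading probability."""
    if np.any(PA <= 0) or np.any(PB <= 0):
        raise ValueError("wkld requires strictly positive probabilities")
    log_ratio = np.log(PA) - np.log(PB)
    forward = (NA * PA * log_ratio).sum(axis=-1)
    backward = -(NB * PB * log_ratio).sum(axis=-1)
    return 0.5 * (forward + backward)


# ---------------------------------------------------------------------------
# profile-set front end


def score_pairs(
    train_A: SampleProfileSet,
    train_B: SampleProfileSet,
    method: str,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Score every pair present in both training sets.

    Returns a table (pair_id, method, score, coverage_A, coverage_B)
    sorted by descending score, ties by pair_id.  Pairs missing from
    either training set are skipped with a logged count.
    """
    if method not in RANKING_METHODS:
        raise ValueError(f"unknown ranking method {method!r}")
    shared = sorted(set(train_A.profiles) & set(train_B.profiles))
    n_skipped = len(set(train_A.profiles) | set(train_B.profiles)) - len(shared)
    if n_skipped:
        logger.info("score_pairs: %d pairs missing from one training set", n_skipped)
    if not shared:
        raise ValueError("no pairs shared by the two training sets")
    NA = train_A.count_matrix(shared).astype(float)
    NB = train_B.count_matrix(shared).astype(float)
    if method == "euclidean":
        scores = euclidean_distance(
            NA / NA.sum(axis=1, keepdims=True), NB / NB.sum(axis=1, keepdims=True)
        )
    else:
        PA = normalize_with_pseudocount(NA, pseudocount)
        PB = normalize_with_pseudocount(NB, pseudocount)
        scores = (
            symmetric_kld(PA, PB)
            if method == "kld"
            else weighted_kld(PA, PB, NA, NB)
        )
    df = pd.DataFrame(
        {
            "pair_id": shared,
            "method": method,
            "score": scores,
            "coverage_A": NA.sum(axis=1).astype(int),
            "coverage_B": NB.sum(axis=1).astype(int),
        }
    )
    return df.sort_values(
        ["score", "pair_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def top_k(scores: pd.DataFrame, k: int) -> list[str]:
    """The ``k`` highest-scoring pair ids (deterministic under ties)."""
    if not 1 <= k <= len(scores):
        raise ValueError(f"k={k} out of range 1..{len(scores)}")
    return scores["pair_id"].head(k).tolist()


def subset_sweep(
    experiment: MixtureExperiment,
    ranking_method: str,
    k_grid: Sequence = DEFAULT_K_LADDER,
    deconv_methods: Sequence[str] = ("mle",),
    ratios: Sequence[float] = DEFAULT_RATIOS,
    pseudocount: float = PSEUDOCOUNT,
    ga_config: GradientAscentConfig | None = None,
) -> pd.DataFrame:
    """Mean deconvolution error for top-k pair subsets of growing size.

    For each k in ``k_grid`` (the string "all", or a k at least the
    number of available pairs, means no restriction) the standard
    multi-ratio sweep is run restricted to the top-k pairs of the
    training-set ranking.  Returns one row per (k, method) with the
    mean absolute error.
    """
    scores = score_pairs(
        experiment.train_A, experiment.train_B, ranking_method, pseudocount
    )
    n_avail = len(scores)
    rows = []
    for k in k_grid:
        if k == "all" or (isinstance(k, int) and k >= n_avail):
            subset, k_label = None, n_avail
        else:
            subset, k_label = top_k(scores, int(k)), int(k)
        sweep = run_sweep(
            experiment,
            deconv_methods,
            ratios,
            pair_subset=subset,
            pseudocount=pseudocount,
            ga_config=ga_config,
        )
        for method, err in mean_errors(sweep).items():
            rows.append(
                {
                    "k": k_label,
                    "ranking": ranking_method,
                    "method": method,
                    "mean_abs_error": err,
                }
            )
    return pd.DataFrame(rows)
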