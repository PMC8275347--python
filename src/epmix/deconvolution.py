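"""Two-sample mixture deconvolution from per-pair combination profiles.

Given pure training profiles of samples A and B and the profile of a
mixed test set, each estimator returns the mixing ratio alpha = fraction
of test molecules originating from sample A.  Four estimators are
provided:

``projection``
    Per pair, the test vector is projected onto the segment between the
    two training vectors; alpha is one minus the mean projection
    coefficient over pairs.  Local, closed form, no positivity needed.
``sse`` / ``kld``
    Global grid search: convex combinations alpha*A + (1-alpha)*B are
    scanned at 1% steps and the alpha minimizing the summed squared
    error, or the symmetrized Kullback-Leibler divergence, is reported.
``mle``
    Gradient ascent on the concave multinomial log-likelihood
    sum_p sum_c N_pc * log(alpha*P_A,pc + (1-alpha)*P_B,pc).

All estimators are agnostic to the combination alphabet and accept both
4-state pairwise and 2-state promoter-only profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .profiling import PSEUDOCOUNT, SampleProfileSet, normalize_with_pseudocount

logger = logging.getLogger(__name__)

METHODS = ("projection", "sse", "kld", "mle")

GRID_STEP = 0.01


@dataclass(frozen=True)
class GradientAscentConfig:
    """Constants of the gradient-ascent maximizer."""

    step: float = 0.005  # base step size eta
    init: float = 0.5  # starting mixing ratio
    tol: float = 1e-3  # stop when the log-likelihood gain drops below this
    max_iter: int = 20_000

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not 0.0 <= self.init <= 1.0:
            raise ValueError("init must lie in [0, 1]")


@dataclass
class DeconvolutionResult:
    method: str
    alpha_A: float
    n_pairs_used: int
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# matrix-level estimators (rows = pairs, columns = combinations)


def projection_alpha(
    A: np.ndarray, B: np.ndarray, T: np.ndarray
) -> tuple[float, np.ndarray, int]:
    """Mean per-pair projection estimate of alpha_A.

    For each pair p: alpha_p = 1 - (T_p - A_p) . (B_p - A_p) / |B_p - A_p|^2.
    Pairs whose training vectors coincide carry no direction and are
    skipped.  Per-pair values are left unclamped; only the final mean is
    clipped to [0, 1].
    """
    AB = B - A
    denom = np.einsum("pc,pc->p", AB, AB)
    usable = denom > 0
    if not usable.any():
        raise ValueError("projection: no pair separates the two training sets")
    AT = T - A
    per_pair = 1.0 - np.einsum("pc,pc->p", AT, AB)[usable] / denom[usable]
    alpha = float(np.clip(per_pair.mean(), 0.0, 1.0))
    return alpha, per_pair, int(usable.sum())


def _grid(step: float) -> np.ndarray:
    n = int(round(1.0 / step))
    return np.arange(n + 1) / n


def grid_objective(
    A: np.ndarray, B: np.ndarray, T: np.ndarray, criterion: str, step: float = GRID_STEP
) -> tuple[np.ndarray, np.ndarray]:
    """Objective values over the alpha grid for ``sse`` or ``kld``."""
    alphas = _grid(step)
    lct = alphas[:, None, None] * A[None] + (1.0 - alphas)[:, None, None] * B[None]
    if criterion == "sse":
        obj = ((T[None] - lct) ** 2).sum(axis=(1, 2))
    elif criterion == "kld":
        if np.any(T <= 0) or np.any(lct <= 0):
            raise ValueError("kld requires strictly positive probabilities")
        forward = (T[None] * (np.log(T)[None] - np.log(lct))).sum(axis=(1, 2))
        backward = (lct * (np.log(lct) - np.log(T)[None])).sum(axis=(1, 2))
        obj = 0.5 * (forward + backward)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return alphas, obj


def grid_alpha(
    A: np.ndarray, B: np.ndarray, T: np.ndarray, criterion: str, step: float = GRID_STEP
) -> tuple[float, np.ndarray, np.ndarray]:
    """Grid minimizer; ties resolved toward the smaller alpha."""
    alphas, obj = grid_objective(A, B, T, criterion, step)
    return float(alphas[int(np.argmin(obj))]), alphas, obj


def log_likelihood(
    alpha: float | np.ndarray, PA: np.ndarray, PB: np.ndarray, N: np.ndarray
) -> float | np.ndarray:
    """Mixture log-likelihood of the test counts at one or many alphas."""
    alpha = np.asarray(alpha, dtype=float)
    D = PA - PB
    if alpha.ndim == 0:
        return float((N * np.log(PB + alpha * D)).sum())
    return (N[None] * np.log(PB[None] + alpha[:, None, None] * D[None])).sum(
        axis=(1, 2)
    )


def mle_alpha(
    PA: np.ndarray,
    PB: np.ndarray,
    N: np.ndarray,
    config: GradientAscentConfig | None = None,
) -> tuple[float, list[tuple[float, float]]]:
    """Maximize the mixture log-likelihood by monotone gradient ascent.

    The update is alpha <- clip(alpha + eta * dlogL/dalpha, 0, 1) with
    dlogL/dalpha = sum N * (P_A - P_B) / (alpha*P_A + (1-alpha)*P_B).
    Because total molecule counts can make the raw step overshoot on
    this concave objective, the proposed step is halved (a backtracking
    line search, keeping the best candidate) until the log-likelihood
    does not decrease; the recorded trace is therefore non-decreasing.
    Iteration stops when the gain falls below ``tol`` or after
    ``max_iter`` steps, and the alpha with the highest log-likelihood
    seen anywhere on the trace is returned.
    """
    if np.any(PA <= 0) or np.any(PB <= 0):
        bad = np.where((PA <= 0) | (PB <= 0))[0]
        raise ValueError(f"mle requires positive training probabilities (pair row {bad[0]})")
    cfg = config or GradientAscentConfig()
    D = PA - PB
    alpha = float(cfg.init)
    ll = log_likelihood(alpha, PA, PB, N)
    if not np.isfinite(ll):
        raise ValueError("non-finite log-likelihood at initialization")
    trace = [(alpha, ll)]
    for _ in range(cfg.max_iter):
        q = PB + alpha * D
        grad = float((N * D / q).sum())
        step = cfg.step * grad
        if step == 0.0:
            break
        # backtracking: halve the step until the candidate stops improving,
        # keeping the best candidate (the likelihood is unimodal in alpha).
        best_alpha, best_ll = alpha, ll
        prev_ll = -np.inf
        for _halving in range(60):
            cand = min(1.0, max(0.0, alpha + step))
            cand_ll = log_likelihood(cand, PA, PB, N)
            if not np.isfinite(cand_ll):
                raise ValueError("non-finite log-likelihood during ascent")
            if cand_ll > best_ll:
                best_alpha, best_ll = cand, cand_ll
            if cand_ll < prev_ll:
                break
            prev_ll = cand_ll
            step *= 0.5
        if best_alpha == alpha:  # no ascent possible (boundary or optimum)
            break
        gain = best_ll - ll
        alpha, ll = best_alpha, best_ll
        trace.append((alpha, ll))
        if gain < cfg.tol:
            break
    best = max(trace, key=lambda t: t[1])
    return best[0], trace


# ---------------------------------------------------------------------------
# profile-set front end


def restrict_to_pairs(
    profile_sets: Sequence[SampleProfileSet], pair_ids: Sequence[str]
) -> list[SampleProfileSet]:
    """Restrict every profile set to a pair subset (intersection semantics)."""
    subset = set(pair_ids)
    if not subset:
        raise ValueError("empty pair subset")
    shared = set.intersection(*(set(ps.profiles) for ps in profile_sets)) & subset
    if not shared:
        raise ValueError("pair subset shares no pairs with the profile sets")
    dropped = len(subset) - len(shared)
    if dropped:
        logger.info("restrict_to_pairs: %d requested pairs absent from some set", dropped)
    return [
        SampleProfileSet(
            ps.sample_id,
            {pid: ps.profiles[pid] for pid in shared},
            ps.n_states,
        )
        for ps in profile_sets
    ]


def deconvolve(
    train_A: SampleProfileSet,
    train_B: SampleProfileSet,
    test: SampleProfileSet,
    method: str,
    pseudocount: float = PSEUDOCOUNT,
    grid_step: float = GRID_STEP,
    config: GradientAscentConfig | None = None,
    pair_subset: Sequence[str] | None = None,
) -> DeconvolutionResult:
    """Estimate the mixing ratio of ``test`` with one of the four methods.

    Only pairs present in all three profile sets contribute.  The
    projection method uses raw normalized ratios; the grid and MLE
    methods use pseudo-counted probabilities so logarithms stay finite.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    sets = [train_A, train_B, test]
    if pair_subset is not None:
        sets = restrict_to_pairs(sets, pair_subset)
    shared = sorted(set.intersection(*(set(ps.profiles) for ps in sets)))
    if not shared:
        raise ValueError("no pairs shared by train_A, train_B and test")
    NA, NB, NT = (ps.count_matrix(shared) for ps in sets)

    if method == "projection":
        A = NA / NA.sum(axis=1, keepdims=True)
        B = NB / NB.sum(axis=1, keepdims=True)
        T = NT / NT.sum(axis=1, keepdims=True)
        alpha, per_pair, n_used = projection_alpha(A, B, T)
        return DeconvolutionResult(
            method, alpha, n_used, {"per_pair_alpha": per_pair}
        )

    A = normalize_with_pseudocount(NA, pseudocount)
    B = normalize_with_pseudocount(NB, pseudocount)
    if method in ("sse", "kld"):
        T = normalize_with_pseudocount(NT, pseudocount)
        alpha, alphas, obj = grid_alpha(A, B, T, method, grid_step)
        return DeconvolutionResult(
            method, alpha, len(shared), {"alphas": alphas, "objective": obj}
        )

    alpha, trace = mle_alpha(A, B, NT, config)
    return DeconvolutionResult(
        method,
        alpha,
        len(shared),
        {"trace": trace, "n_iterations": len(trace) - 1},
    )
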