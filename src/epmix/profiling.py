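"""Per-pair methylation-combination profiles.

A molecule that fully spans both elements of an enhancer-promoter pair
reports one of four joint binary states: each element is called
unmethylated (U) when any label window overlaps it and methylated (M)
otherwise.  Counting spanning molecules per pair yields the pair's
4-combination distribution; marginalizing over the enhancer state on the
same molecules yields the matched 2-state promoter-only profile.

Combination order is fixed as MM, MU, UM, UU with the promoter state
first, e.g. ``MU`` = promoter methylated, enhancer unmethylated.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .elements import Element, EPLink, GenomicInterval
from .molecules import LABEL_HALF_WIDTH, LabeledMolecule

logger = logging.getLogger(__name__)

COMBINATIONS_4 = ("MM", "MU", "UM", "UU")
COMBINATIONS_2 = ("M", "U")

#: Minimum number of spanning molecules for a pair to be analyzed.
MIN_COVERAGE = 30
#: Added to each normalized ratio before renormalizing, to keep every
#: combination probability strictly positive.
PSEUDOCOUNT = 0.01


@dataclass(frozen=True)
class PairRegion:
    """Genomic layout of one E-P pair: the two element intervals."""

    pair_id: str
    chrom: str
    promoter: GenomicInterval
    enhancer: GenomicInterval

    @property
    def envelope(self) -> tuple[int, int]:
        """Span that contains both elements: [min start, max end)."""
        return (
            min(self.promoter.start, self.enhancer.start),
            max(self.promoter.end, self.enhancer.end),
        )


def pair_regions_from_links(
    links: Iterable[EPLink],
    promoters: Mapping[str, Element],
    enhancers: Mapping[str, Element],
) -> list[PairRegion]:
    regions = []
    for link in links:
        prom, enh = promoters[link.promoter_id], enhancers[link.enhancer_id]
        if prom.interval.chrom != enh.interval.chrom:
            raise ValueError(f"pair {link.pair_id}: elements on different chromosomes")
        regions.append(
            PairRegion(link.pair_id, prom.interval.chrom, prom.interval, enh.interval)
        )
    return regions


# ---------------------------------------------------------------------------
# state calling


def _has_label_overlap(
    labels: Sequence[int], start: int, end: int, extension: int
) -> bool:
    # A label window [l-ext, l+ext) overlaps [start, end) iff
    # start-ext < l < end+ext; with extension 0 the label is a point in
    # [start, end).  Labels are sorted, so two bisects suffice.
    if extension > 0:
        lo, hi = start - extension + 1, end + extension
    else:
        lo, hi = start, end
    i = bisect_left(labels, lo)
    return i < len(labels) and labels[i] < hi


def call_element_state(
    molecule: LabeledMolecule,
    element_interval: GenomicInterval,
    extension: int = LABEL_HALF_WIDTH,
) -> str:
    """Binary methylation state of one element on one molecule.

    Any label whose extended window overlaps the element makes the
    element 'U' (any degree of fluorescence means unmethylated);
    otherwise 'M'.  The molecule must fully span the element.
    """
    if molecule.chrom != element_interval.chrom or not (
        molecule.start <= element_interval.start
        and element_interval.end <= molecule.end
    ):
        raise ValueError(
            f"molecule {molecule.molecule_id} does not span "
            f"{element_interval.chrom}:{element_interval.start}-{element_interval.end}"
        )
    hit = _has_label_overlap(
        molecule.labels, element_interval.start, element_interval.end, extension
    )
    return "U" if hit else "M"


def combination_index(
    molecule: LabeledMolecule, region: PairRegion, extension: int = LABEL_HALF_WIDTH
) -> int:
    """Index into COMBINATIONS_4 for one spanning molecule."""
    prom_u = _has_label_overlap(
        molecule.labels, region.promoter.start, region.promoter.end, extension
    )
    enh_u = _has_label_overlap(
        molecule.labels, region.enhancer.start, region.enhancer.end, extension
    )
    return (2 if prom_u else 0) + (1 if enh_u else 0)


# ---------------------------------------------------------------------------
# assignment index: molecule -> (pair, combination), reusable across mixes


class AssignmentIndex:
    """Maps every molecule to the pairs it spans and its combination there.

    Molecules may span several pairs and are counted once per spanned
    pair.  The index is built once and supports fast count-matrix
    extraction for arbitrary molecule subsets, which is what repeated
    in-silico mixing needs.
    """

    def __init__(
        self,
        molecules: Sequence[LabeledMolecule],
        regions: Sequence[PairRegion],
        extension: int = LABEL_HALF_WIDTH,
    ) -> None:
        self.regions = list(regions)
        self.n_molecules = len(molecules)
        self.n_combos = len(COMBINATIONS_4)
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for ri, r in enumerate(self.regions):
            s, e = r.envelope
            by_chrom.setdefault(r.chrom, []).append((s, e, ri))
        for entries in by_chrom.values():
            entries.sort()
        starts = {c: [s for s, _, _ in v] for c, v in by_chrom.items()}

        offsets = np.zeros(len(molecules) + 1, dtype=np.int64)
        codes: list[int] = []
        nc = self.n_combos
        for mi, mol in enumerate(molecules):
            entries = by_chrom.get(mol.chrom)
            if entries is not None:
                ss = starts[mol.chrom]
                j = bisect_left(ss, mol.start)
                m_end = mol.end
                while j < len(entries) and entries[j][0] < m_end:
                    s, e, ri = entries[j]
                    if e <= m_end:
                        codes.append(
                            ri * nc
                            + combination_index(mol, self.regions[ri], extension)
                        )
                    j += 1
            offsets[mi + 1] = len(codes)
        self.offsets = offsets
        self.codes = np.asarray(codes, dtype=np.int64)

    def count_matrix(self, molecule_indices: Sequence[int] | None = None) -> np.ndarray:
        """(n_regions, 4) combination counts over a molecule subset."""
        if molecule_indices is None:
            sel = self.codes
        else:
            idx = np.asarray(molecule_indices, dtype=np.int64)
            lengths = self.offsets[idx + 1] - self.offsets[idx]
            total = int(lengths.sum())
            if total == 0:
                sel = np.empty(0, dtype=np.int64)
            else:
                # CSR-style row gather of self.codes
                starts = self.offsets[idx]
                pos = np.repeat(starts - np.concatenate(([0], np.cumsum(lengths)[:-1])), lengths)
                sel = self.codes[pos + np.arange(total)]
        counts = np.bincount(sel, minlength=len(self.regions) * self.n_combos)
        return counts.reshape(len(self.regions), self.n_combos)


# ---------------------------------------------------------------------------
# profiles


@dataclass(frozen=True)
class CombinationProfile:
    """Counts over the methylation combinations of one pair."""

    pair_id: str
    counts: np.ndarray  # int array, length 4 (pairwise) or 2 (promoter-only)

    @property
    def coverage(self) -> int:
        return int(self.counts.sum())


@dataclass
class SampleProfileSet:
    """All per-pair combination profiles of one sample."""

    sample_id: str
    profiles: dict[str, CombinationProfile] = field(default_factory=dict)
    n_states: int = 4

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def pair_ids(self) -> list[str]:
        return sorted(self.profiles)

    def coverage(self, pair_id: str) -> int:
        return self.profiles[pair_id].coverage

    def count_matrix(self, pair_ids: Sequence[str]) -> np.ndarray:
        return np.stack([self.profiles[p].counts for p in pair_ids])

    def filter_coverage(self, min_coverage: int = MIN_COVERAGE) -> "SampleProfileSet":
        """Drop pairs spanned by fewer than ``min_coverage`` molecules."""
        if min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        kept = {
            pid: prof
            for pid, prof in self.profiles.items()
            if prof.coverage >= min_coverage
        }
        logger.info(
            "%s: pairs filtered by coverage<%d: %d (kept %d)",
            self.sample_id,
            min_coverage,
            len(self.profiles) - len(kept),
            len(kept),
        )
        return SampleProfileSet(self.sample_id, kept, self.n_states)

    def promoter_marginal(self) -> "SampleProfileSet":
        """2-state promoter-only profiles from the same spanning molecules.

        The promoter counts are exact row sums of the pairwise counts:
        M = MM + MU, U = UM + UU.
        """
        if self.n_states != 4:
            raise ValueError("promoter_marginal needs 4-state profiles")
        out = {
            pid: CombinationProfile(
                pid,
                np.array(
                    [prof.counts[0] + prof.counts[1], prof.counts[2] + prof.counts[3]]
                ),
            )
            for pid, prof in self.profiles.items()
        }
        return SampleProfileSet(self.sample_id, out, n_states=2)


def count_combinations(
    molecules: Sequence[LabeledMolecule],
    region: PairRegion,
    extension: int = LABEL_HALF_WIDTH,
) -> CombinationProfile:
    """4-combination counts for one pair from molecules spanning it entirely."""
    counts = np.zeros(4, dtype=np.int64)
    env_s, env_e = region.envelope
    for mol in molecules:
        if mol.chrom == region.chrom and mol.start <= env_s and env_e <= mol.end:
            counts[combination_index(mol, region, extension)] += 1
    return CombinationProfile(region.pair_id, counts)


def profile_molecules(
    molecules: Sequence[LabeledMolecule],
    regions: Sequence[PairRegion],
    sample_id: str,
    extension: int = LABEL_HALF_WIDTH,
    index: AssignmentIndex | None = None,
) -> SampleProfileSet:
    """Tabulate every pair's combination counts over a molecule set.

    A molecule spanning several pairs contributes once to each of them.
    Pairs spanned by no molecule get an all-zero profile (filtered later
    by coverage).
    """
    if index is None:
        index = AssignmentIndex(molecules, regions, extension)
    mat = index.count_matrix()
    profiles = {
        r.pair_id: CombinationProfile(r.pair_id, mat[i]) for i, r in enumerate(regions)
    }
    return SampleProfileSet(sample_id, profiles, n_states=4)


def promoter_only_profiles(
    molecules: Sequence[LabeledMolecule],
    regions: Sequence[PairRegion],
    sample_id: str,
    extension: int = LABEL_HALF_WIDTH,
) -> SampleProfileSet:
    """Promoter-only profiles from the molecules that span whole pairs."""
    return profile_molecules(molecules, regions, sample_id, extension).promoter_marginal()


# ---------------------------------------------------------------------------
# probabilities


def normalize_with_pseudocount(
    counts: np.ndarray, epsilon: float = PSEUDOCOUNT
) -> np.ndarray:
    """Counts -> strictly positive probabilities.

    Counts are normalized to ratios, ``epsilon`` is added to every ratio
    and the result renormalized (dividing by 1 + k*epsilon for k states),
    so that divergence and likelihood computations never see a zero.
    Works on a single count vector or a (pairs, states) matrix.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=-1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("cannot normalize all-zero counts")
    ratios = counts / totals
    k = counts.shape[-1]
    return (ratios + epsilon) / (1.0 + k * epsilon)


# ---------------------------------------------------------------------------
# plain-text I/O


def write_profiles(profile_set: SampleProfileSet, path: str | Path) -> None:
    import pandas as pd

    labels = COMBINATIONS_4 if profile_set.n_states == 4 else COMBINATIONS_2
    rows = []
    for pid in profile_set.pair_ids:
        prof = profile_set.profiles[pid]
        row = {"pair_id": pid, "sample_id": profile_set.sample_id}
        row.update({f"n_{lab}": int(c) for lab, c in zip(labels, prof.counts)})
        row["coverage"] = prof.coverage
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> SampleProfileSet:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    labels = COMBINATIONS_4 if "n_MM" in df.columns else COMBINATIONS_2
    sample_id = str(df["sample_id"].iloc[0]) if len(df) else ""
    profiles = {
        str(row["pair_id"]): CombinationProfile(
            str(row["pair_id"]),
            np.array([int(row[f"n_{lab}"]) for lab in labels]),
        )
        for _, row in df.iterrows()
    }
    return SampleProfileSet(sample_id, profiles, n_states=len(labels))


def write_regions(regions: Sequence[PairRegion], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "pair_id": r.pair_id,
            "chrom": r.chrom,
            "promoter_start": r.promoter.start,
            "promoter_end": r.promoter.end,
            "enhancer_start": r.enhancer.start,
            "enhancer_end": r.enhancer.end,
        }
        for r in sorted(regions, key=lambda r: r.pair_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path) -> list[PairRegion]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pair_id": str})
    return [
        PairRegion(
            row["pair_id"],
            row["chrom"],
            GenomicInterval(row["chrom"], int(row["promoter_start"]), int(row["promoter_end"])),
            GenomicInterval(row["chrom"], int(row["enhancer_start"]), int(row["enhancer_end"])),
        )
        for _, row in df.iterrows()
    ]
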