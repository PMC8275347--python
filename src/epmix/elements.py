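"""Promoter/enhancer element construction, filtering and linking.

Builds the element sets that pair profiling operates on: strand-aware
promoter windows around transcription start sites, enhancers cleaned of
ambiguous genomic regions and padded to a minimum width, and the
enhancer-promoter (E-P) link graph filtered by label-site content and
genomic separation.  Coordinates are 0-based half-open (BED convention)
throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Promoter window: this many bp upstream of the TSS ...
PROMOTER_UPSTREAM = 2000
#: ... and this many bp downstream.
PROMOTER_DOWNSTREAM = 500
#: Minimum enhancer width after cleaning; shorter elements are re-centered.
MIN_ENHANCER_LENGTH = 200
#: Minimum edge-to-edge separation between the two elements of a pair.
MIN_PAIR_GAP = 5000
#: Recognition motif whose unmethylated cytosines are fluorescently labeled.
LABEL_MOTIF = "TCGA"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Element:
    """A promoter or enhancer with its potential label-site count."""

    id: str
    interval: GenomicInterval
    role: str  # "promoter" | "enhancer"
    site_count: int | None = None


@dataclass(frozen=True)
class EPLink:
    """One enhancer-promoter link; ``gap`` is the nearest-edge distance."""

    pair_id: str
    promoter_id: str
    enhancer_id: str
    gene_id: str
    gap: int | None = None


# ---------------------------------------------------------------------------
# promoters


def build_promoters(
    tss_records: Iterable[Mapping],
    id_prefix: str = "P",
) -> list[Element]:
    """Strand-aware promoter windows around transcription start sites.

    For a + strand TSS at position t the promoter is [t-2000, t+500);
    for a - strand TSS it is the mirror [t-500, t+2000).  Windows are
    clipped at the chromosome origin.  Records without a valid strand
    are rejected with a warning.
    """
    out: list[Element] = []
    seen: dict[str, int] = {}
    n_rejected = 0
    for rec in tss_records:
        strand = rec.get("strand")
        if strand not in ("+", "-"):
            n_rejected += 1
            logger.warning("TSS record %r lacks a valid strand; skipped", rec)
            continue
        pos = int(rec["pos"])
        if strand == "+":
            start, end = pos - PROMOTER_UPSTREAM, pos + PROMOTER_DOWNSTREAM
        else:
            start, end = pos - PROMOTER_DOWNSTREAM, pos + PROMOTER_UPSTREAM
        start = max(0, start)
        gene = str(rec["gene_id"])
        n = seen.get(gene, 0)
        seen[gene] = n + 1
        elem_id = f"{id_prefix}:{gene}" if n == 0 else f"{id_prefix}:{gene}.{n}"
        out.append(
            Element(
                id=elem_id,
                interval=GenomicInterval(str(rec["chrom"]), start, end, strand),
                role="promoter",
            )
        )
    if n_rejected:
        logger.info("build_promoters: rejected %d strand-less records", n_rejected)
    return out


# ---------------------------------------------------------------------------
# enhancers


def _merge_intervals(ivs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def subtract_intervals(
    interval: GenomicInterval, excluded: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Fragments of ``interval`` left after removing ``excluded`` regions."""
    cuts = _merge_intervals(
        [
            (max(x.start, interval.start), min(x.end, interval.end))
            for x in excluded
            if x.chrom == interval.chrom and x.overlaps(interval)
        ]
    )
    frags: list[GenomicInterval] = []
    cursor = interval.start
    for s, e in cuts:
        if s > cursor:
            frags.append(GenomicInterval(interval.chrom, cursor, s, interval.strand))
        cursor = max(cursor, e)
    if cursor < interval.end:
        frags.append(
            GenomicInterval(interval.chrom, cursor, interval.end, interval.strand)
        )
    return frags


def process_enhancers(
    enhancers: Iterable[Element],
    excluded_regions: Sequence[GenomicInterval] = (),
) -> list[Element]:
    """Subtract ambiguous regions and enforce the minimum enhancer width.

    An enhancer split into several fragments by the subtraction keeps its
    longest fragment (leftmost on ties) so that each id maps to one
    contiguous interval.  Any result shorter than 200 bp is replaced by a
    200 bp window centered on its midpoint (shifted right if that would
    cross the chromosome origin).  Enhancers fully covered by excluded
    regions are dropped.
    """
    out: list[Element] = []
    n_dropped = 0
    for enh in enhancers:
        frags = subtract_intervals(enh.interval, excluded_regions)
        if not frags:
            n_dropped += 1
            logger.warning("enhancer %s fully covered by excluded regions", enh.id)
            continue
        best = max(frags, key=lambda iv: (iv.length, -iv.start))
        if best.length < MIN_ENHANCER_LENGTH:
            mid = (best.start + best.end) // 2
            start = max(0, mid - MIN_ENHANCER_LENGTH // 2)
            best = GenomicInterval(
                best.chrom, start, start + MIN_ENHANCER_LENGTH, best.strand
            )
        out.append(replace(enh, interval=best))
    if n_dropped:
        logger.info("process_enhancers: dropped %d fully-excluded enhancers", n_dropped)
    return out


# ---------------------------------------------------------------------------
# label sites


def count_motif(sequence: str, motif: str = LABEL_MOTIF) -> int:
    """Occurrences of ``motif`` in ``sequence`` (forward strand).

    The default motif TCGA is its own reverse complement, so scanning one
    strand counts every potential label site.  Overlapping occurrences are
    counted.
    """
    seq = sequence.upper()
    motif = motif.upper()
    n = 0
    i = seq.find(motif)
    while i != -1:
        n += 1
        i = seq.find(motif, i + 1)
    return n


def count_label_sites(element: Element, fasta) -> int:
    """Number of potential label sites (TCGA motifs) inside an element.

    ``fasta`` is a ``pyfaidx.Fasta`` (or any mapping of chromosome name to
    sliceable sequence).  Raises ``KeyError`` if the chromosome is absent.
    """
    iv = element.interval
    if iv.chrom not in fasta:
        raise KeyError(f"chromosome {iv.chrom!r} not present in FASTA")
    seq = str(fasta[iv.chrom][iv.start : iv.end])
    return count_motif(seq)


def attach_site_counts(
    elements: Iterable[Element],
    fasta=None,
    counts: Mapping[str, int] | None = None,
) -> list[Element]:
    """Return elements with ``site_count`` filled from FASTA or a table."""
    if (fasta is None) == (counts is None):
        raise ValueError("provide exactly one of fasta or counts")
    out = []
    for el in elements:
        n = count_label_sites(el, fasta) if fasta is not None else int(counts[el.id])
        out.append(replace(el, site_count=n))
    return out


# ---------------------------------------------------------------------------
# links


def _edge_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Nearest-edge distance; negative when the intervals overlap."""
    return max(b.start - a.end, a.start - b.end)


def filter_links(
    links: Iterable[EPLink],
    promoters: Mapping[str, Element],
    enhancers: Mapping[str, Element],
    min_gap: int = MIN_PAIR_GAP,
) -> list[EPLink]:
    """Retain links whose elements are labelable and well separated.

    A link survives when both elements carry at least one potential label
    site, lie on the same chromosome, and are at least ``min_gap`` bp
    apart edge to edge.  Links referencing unknown element ids are
    dropped.  The computed gap is stored on the returned links, so the
    operation is idempotent.
    """
    out: list[EPLink] = []
    n_dangling = n_filtered = 0
    for link in links:
        prom = promoters.get(link.promoter_id)
        enh = enhancers.get(link.enhancer_id)
        if prom is None or enh is None:
            n_dangling += 1
            logger.warning("link %s references unknown element id", link.pair_id)
            continue
        if (prom.site_count or 0) < 1 or (enh.site_count or 0) < 1:
            n_filtered += 1
            continue
        if prom.interval.chrom != enh.interval.chrom:
            n_filtered += 1
            continue
        gap = _edge_gap(prom.interval, enh.interval)
        if gap < min_gap:
            n_filtered += 1
            continue
        out.append(replace(link, gap=gap))
    logger.info(
        "filter_links: kept %d, filtered %d, dangling %d",
        len(out),
        n_filtered,
        n_dangling,
    )
    return out


def assign_single_enhancer(
    links: Iterable[EPLink],
    enhancers: Mapping[str, Element],
) -> list[EPLink]:
    """One enhancer per promoter: the most reliably labelable one.

    Per promoter, keep the link whose enhancer has the highest potential
    label-site count; ties broken by larger enhancer length, then by
    smaller gap (closer enhancer), then lexicographically by enhancer id
    so the choice is deterministic.
    """
    by_promoter: dict[str, list[EPLink]] = {}
    for link in links:
        by_promoter.setdefault(link.promoter_id, []).append(link)

    def key(link: EPLink):
        enh = enhancers[link.enhancer_id]
        return (
            -(enh.site_count or 0),
            -enh.interval.length,
            link.gap if link.gap is not None else 0,
            link.enhancer_id,
        )

    return [
        min(candidates, key=key)
        for _, candidates in sorted(by_promoter.items())
    ]


# ---------------------------------------------------------------------------
# plain-text readers/writers


def read_bed(path: str | Path, role: str = "enhancer") -> list[Element]:
    """Read BED3+/BED6 records as elements (name column used as id)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 and f[3] != "." else f"{role}_{i}"
            strand = f[5] if len(f) > 5 else "."
            out.append(
                Element(
                    id=name,
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2]), strand),
                    role=role,
                )
            )
    return out


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    return [el.interval for el in read_bed(path, role="region")]


def read_tss_table(path: str | Path) -> list[dict]:
    """TSV with header columns chrom, pos, strand, gene_id."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    return df.to_dict("records")


def read_links_table(path: str | Path) -> list[EPLink]:
    """TSV with header columns promoter_id, enhancer_id, gene_id."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        EPLink(
            pair_id=row.get("pair_id") or f"{row['promoter_id']}|{row['enhancer_id']}",
            promoter_id=row["promoter_id"],
            enhancer_id=row["enhancer_id"],
            gene_id=row.get("gene_id", ""),
        )
        for row in df.to_dict("records")
    ]


def write_links_table(
    links: Sequence[EPLink],
    promoters: Mapping[str, Element],
    enhancers: Mapping[str, Element],
    path: str | Path,
) -> None:
    """Write retained links with their computed gaps and site counts."""
    import pandas as pd

    rows = []
    for link in sorted(links, key=lambda l: l.pair_id):
        prom, enh = promoters[link.promoter_id], enhancers[link.enhancer_id]
        rows.append(
            {
                "pair_id": link.pair_id,
                "promoter_id": link.promoter_id,
                "enhancer_id": link.enhancer_id,
                "gene_id": link.gene_id,
                "chrom": prom.interval.chrom,
                "promoter_start": prom.interval.start,
                "promoter_end": prom.interval.end,
                "enhancer_start": enh.interval.start,
                "enhancer_end": enh.interval.end,
                "gap": link.gap,
                "promoter_sites": prom.site_count,
                "enhancer_sites": enh.site_count,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
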