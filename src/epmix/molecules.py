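"""Single-molecule label tables.

A molecule record is the read-level observation of the assay: the aligned
genomic extent of one long DNA molecule plus the genomic coordinates of
its fluorescent labels, each label marking an unmethylated cytosine at a
recognition site.  The optical readout localizes a label only to about
1 kb, so downstream state calling works with label coordinates extended
symmetrically to 1 kb windows.

The on-disk format is a TSV with columns ``molecule_id``, ``sample_id``,
``chrom``, ``span_start``, ``span_end``, ``labels`` (semicolon-separated
positions, empty for a fully methylated molecule).  Files ending in
``.gz`` are read and written gzip-compressed.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

#: Half-width of the window a label coordinate is extended to (total 1 kb).
LABEL_HALF_WIDTH = 500

_COLUMNS = ("molecule_id", "sample_id", "chrom", "span_start", "span_end", "labels")


@dataclass(frozen=True, slots=True)
class LabeledMolecule:
    """One aligned molecule and its unmethylated-cytosine label positions."""

    molecule_id: str
    sample_id: str
    chrom: str
    start: int
    end: int
    labels: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if any(not (self.start <= p < self.end) for p in self.labels):
            raise ValueError("label position outside molecule span")
        if any(b <= a for a, b in zip(self.labels, self.labels[1:])):
            raise ValueError("labels must be strictly increasing")

    @property
    def length(self) -> int:
        return self.end - self.start


def extend_label(position: int, half_width: int = LABEL_HALF_WIDTH) -> tuple[int, int]:
    """1 kb window around a label coordinate, clipped at the genome start.

    The optical localization accuracy is ~1000 bp, so a label observed at
    ``position`` may originate anywhere in [position-500, position+500).
    """
    if position < 0:
        raise ValueError("label position must be non-negative")
    return max(0, position - half_width), position + half_width


def _open_text(path: str | Path, mode: str) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_molecules(source: str | Path | IO[str]) -> list[LabeledMolecule]:
    """Parse a molecule TSV; malformed rows are rejected with a logged count."""
    own = isinstance(source, (str, Path))
    fh = _open_text(source, "r") if own else source
    try:
        return list(_parse(fh))
    finally:
        if own:
            fh.close()


def _parse(fh: IO[str]) -> Iterator[LabeledMolecule]:
    header = fh.readline().rstrip("\n").split("\t")
    if tuple(header) != _COLUMNS:
        raise ValueError(f"unexpected molecule-table header: {header!r}")
    n_rejected = 0
    for line in fh:
        line = line.rstrip("\n")
        if not line:
            continue
        try:
            mol_id, sample_id, chrom, s, e, labels = line.split("\t")
            positions = tuple(
                sorted(int(x) for x in labels.split(";") if x != "")
            )
            yield LabeledMolecule(mol_id, sample_id, chrom, int(s), int(e), positions)
        except (ValueError, IndexError):
            n_rejected += 1
    if n_rejected:
        logger.warning("read_molecules: rejected %d malformed rows", n_rejected)


def write_molecules(
    molecules: Iterable[LabeledMolecule], target: str | Path | IO[str]
) -> None:
    """Deterministic writer: rows sorted by (chrom, span_start, molecule_id)."""
    rows = sorted(molecules, key=lambda m: (m.chrom, m.start, m.molecule_id))
    own = isinstance(target, (str, Path))
    fh = _open_text(target, "w") if own else target
    try:
        fh.write("\t".join(_COLUMNS) + "\n")
        for m in rows:
            fh.write(
                f"{m.molecule_id}\t{m.sample_id}\t{m.chrom}\t{m.start}\t{m.end}\t"
                + ";".join(str(p) for p in m.labels)
                + "\n"
            )
    finally:
        if own:
            fh.close()
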