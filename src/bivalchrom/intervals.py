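"""Genomic intervals, chromatin-state segmentations and interval algebra.

All coordinates are 0-based half-open (BED convention).  A
:class:`Segmentation` is a genome partition into intervals labelled with
the Roadmap 15-state mnemonics; the interval algebra here (merge with a
gap tolerance, per-base overlap counting, whole-interval subtraction)
underlies every downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ROADMAP_STATES",
    "GenomicInterval",
    "Segmentation",
    "GeneModel",
    "read_segmentation",
    "read_bed",
    "write_bed",
    "read_genes_bed",
    "read_genes_gtf",
    "normalize_state",
    "merge_intervals",
    "overlap_bases",
    "subtract",
    "intersect",
    "difference",
    "total_length",
]

#: The 15 Roadmap ChromHMM core-marks state mnemonics.
ROADMAP_STATES = frozenset(
    {
        "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh",
        "ZNF/Rpts", "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC",
        "ReprPCWk", "Quies",
    }
)


class SegmentationParseError(ValueError):
    """Raised for malformed segmentation/BED input, naming the line."""


class StateVocabularyError(ValueError):
    """Raised when a state label is not a Roadmap 15-state mnemonic."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)`` with an optional label."""

    chrom: str
    start: int
    end: int
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Segmentation:
    """One dataset's partition of the genome into labelled state intervals.

    Intervals are sorted per chromosome and must not overlap; every label
    must be one of the 15 Roadmap mnemonics (use ``validate_states=False``
    for already-categorised segmentations carrying category labels).
    """

    dataset_id: str
    intervals: list[GenomicInterval]
    validate_states: bool = True

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        prev: GenomicInterval | None = None
        for iv in self.intervals:
            if self.validate_states and iv.label not in ROADMAP_STATES:
                raise StateVocabularyError(
                    f"{self.dataset_id}: unknown chromatin state {iv.label!r}"
                )
            if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
                raise SegmentationParseError(
                    f"{self.dataset_id}: overlapping intervals "
                    f"{prev.chrom}:{prev.start}-{prev.end} and "
                    f"{iv.chrom}:{iv.start}-{iv.end}"
                )
            prev = iv

    def with_states(self, states: Iterable[str]) -> list[GenomicInterval]:
        """Return the intervals whose label is in *states* (sorted)."""
        wanted = set(states)
        return [iv for iv in self.intervals if iv.label in wanted]

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: stable id, half-open span and strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    def promoter_window(self, window: int = 1500) -> GenomicInterval:
        """Gene body extended *window* nt upstream of the TSS (clipped at 0)."""
        if self.strand == "+":
            return GenomicInterval(self.chrom, max(0, self.start - window), self.end)
        return GenomicInterval(self.chrom, self.start, self.end + window)


def normalize_state(raw: str) -> str:
    """Strip a leading ``<digits>_`` prefix from a state mnemonic.

    ``"10_TssBiv"`` becomes ``"TssBiv"``; matching downstream is
    case-sensitive after stripping.
    """
    head, sep, tail = raw.partition("_")
    if sep and head.isdigit():
        return tail
    return raw


def _parse_bed_line(line: str, lineno: int, path: str) -> tuple[str, int, int, str | None]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise SegmentationParseError(
            f"{path}:{lineno}: expected >=3 tab-separated columns, got {len(fields)}"
        )
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise SegmentationParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    if start < 0 or start >= end:
        raise SegmentationParseError(
            f"{path}:{lineno}: invalid coordinates {start}-{end}"
        )
    label = fields[3] if len(fields) > 3 else None
    return chrom, start, end, label


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a (3+)-column BED file into a sorted interval list."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, label = _parse_bed_line(line, lineno, str(path))
            out.append(GenomicInterval(chrom, start, end, label))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def read_segmentation(path: str | Path, dataset_id: str) -> Segmentation:
    """Read a Roadmap-dialect 4-column BED segmentation.

    State labels may carry a numeric prefix (``"10_TssBiv"``), which is
    stripped; an unknown state after normalisation raises
    :class:`StateVocabularyError`, a malformed line raises
    :class:`SegmentationParseError` naming the line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, label = _parse_bed_line(line, lineno, str(path))
            if label is None:
                raise SegmentationParseError(
                    f"{path}:{lineno}: segmentation requires a 4th state column"
                )
            intervals.append(GenomicInterval(chrom, start, end, normalize_state(label)))
    return Segmentation(dataset_id, intervals)


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    scores: Sequence[int | float] | None = None,
) -> None:
    """Write intervals as 4-column BED (name from label, '.' if absent).

    With *scores*, writes 5-column BED (name, score)."""
    intervals = list(intervals)
    if scores is not None and len(list(scores)) != len(intervals):
        raise ValueError("scores length must match intervals")
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.label or "."]
            if scores is not None:
                fields.append(str(scores[i]))
            fh.write("\t".join(fields) + "\n")


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Read genes from BED6 (chrom, start, end, gene_id, score, strand)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise SegmentationParseError(
                    f"{path}:{lineno}: gene BED needs 6 columns (strand in col 6)"
                )
            genes.append(
                GeneModel(fields[3], fields[0], int(fields[1]), int(fields[2]), fields[5])
            )
    return genes


def read_genes_gtf(path: str | Path, feature: str = "gene") -> list[GeneModel]:
    """Read gene records from a GTF file, keeping only the ``gene_id`` attribute.

    GTF is 1-based inclusive; coordinates are converted to 0-based half-open.
    """
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != feature:
                continue
            attrs = fields[8]
            gene_id = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gene_id = part.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                continue
            genes.append(
                GeneModel(gene_id, fields[0], int(fields[3]) - 1, int(fields[4]), fields[6])
            )
    return genes


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals per chromosome, joining neighbours with gap <= *max_gap*.

    Book-ended intervals merge at the default ``max_gap=0`` (the behaviour
    of ``bedtools merge``); at ``max_gap=0`` the per-base union of the
    inputs is preserved exactly.  Labels are dropped.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start - out[-1].end <= max_gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    d: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        d.setdefault(iv.chrom, []).append(iv)
    for lst in d.values():
        lst.sort(key=lambda iv: (iv.start, iv.end))
    return d


def overlap_bases(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> int:
    """Total number of bases covered by both collections (symmetric).

    Inputs may overlap internally; each is flattened to its per-base union
    first, so a base is counted at most once.
    """
    am = _by_chrom(merge_intervals(a))
    bm = _by_chrom(merge_intervals(b))
    total = 0
    for chrom in am.keys() & bm.keys():
        xs, ys = am[chrom], bm[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if hi > lo:
                total += hi - lo
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return total


def subtract(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Whole-interval subtraction: drop every member of *a* overlapping *b*.

    An interval of *a* is discarded on >=1 bp overlap with any member of
    *b*; no base-level clipping is performed.
    """
    bm = _by_chrom(merge_intervals(b))
    out = []
    for iv in sorted(a, key=lambda x: (x.chrom, x.start, x.end)):
        hits = bm.get(iv.chrom, [])
        # binary-search-free scan is fine at analysis scale; collections are merged/sorted
        if not any(h.start < iv.end and iv.start < h.end for h in hits):
            out.append(iv)
    return out


def intersect(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-level intersection of the per-base unions of *a* and *b*."""
    am = _by_chrom(merge_intervals(a))
    bm = _by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for chrom in sorted(am.keys() & bm.keys()):
        xs, ys = am[chrom], bm[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if hi > lo:
                out.append(GenomicInterval(chrom, lo, hi))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def difference(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-level set difference: bases of *a* not covered by *b*."""
    am = merge_intervals(a)
    bm = _by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for iv in am:
        cursor = iv.start
        for h in bm.get(iv.chrom, []):
            if h.end <= cursor:
                continue
            if h.start >= iv.end:
                break
            if h.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, h.start))
            cursor = max(cursor, h.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Sum of interval lengths (no de-duplication of overlapping bases)."""
    return sum(iv.length for iv in intervals)
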