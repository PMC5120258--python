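"""Frequently bivalent segments (FBS) and control sets.

Bivalent promoter/enhancer intervals from many chromatin state
segmentations are pooled, merged, and annotated with the set of distinct
contributing datasets (the semantics of ``bedtools merge -c
count_distinct``).  Thresholding the distinct-contributor count yields
frequently bivalent segments: regions bivalent in more than 80% of
normal cell types, which are markedly more stable across differentiated
tissues than stem-cell-derived bivalent sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .intervals import (
    GeneModel,
    GenomicInterval,
    Segmentation,
    merge_intervals,
    subtract,
)

__all__ = [
    "BIVALENT_MERGE_STATES",
    "MergedSegment",
    "SupportRule",
    "FbsSet",
    "GeneAssociation",
    "count_distinct_merge",
    "build_fbs",
    "build_conditional_set",
    "build_background_promoters",
    "associate_genes",
    "fbs_coverage_stats",
]

#: States pooled when building FBS: bivalent promoters and enhancers.
#: BivFlnk deliberately belongs to the stability "Bivalent" category but
#: not to FBS construction.
BIVALENT_MERGE_STATES = frozenset({"TssBiv", "EnhBiv"})


@dataclass(frozen=True)
class MergedSegment:
    """A merged interval with the set of datasets contributing to its cluster."""

    interval: GenomicInterval
    contributors: frozenset[str]

    @property
    def support(self) -> int:
        return len(self.contributors)


@dataclass(frozen=True)
class SupportRule:
    """Distinct-contributor threshold.

    ``kind="fraction"`` keeps segments with support strictly greater than
    ``value * n_inputs`` (the "more than 80%" rule: f=0.8 over 122 inputs
    gives "at least 98").  ``kind="absolute"`` keeps support >= value.
    """

    kind: Literal["fraction", "absolute"]
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("fraction", "absolute"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "fraction" and not 0 < self.value < 1:
            raise ValueError("fraction threshold must be in (0, 1)")

    def min_support(self, n_inputs: int) -> int:
        """Smallest integer support that passes the rule."""
        if self.kind == "fraction":
            import math

            return math.floor(self.value * n_inputs) + 1
        k = int(self.value)
        if k > n_inputs:
            raise ValueError(f"absolute threshold {k} exceeds n_inputs={n_inputs}")
        return k

    def passes(self, support: int, n_inputs: int) -> bool:
        return support >= self.min_support(n_inputs)


@dataclass
class FbsSet:
    """Thresholded collection of merged bivalent segments."""

    segments: list[MergedSegment]
    n_inputs: int
    min_support: int
    bivalent_states: frozenset[str] = field(default=BIVALENT_MERGE_STATES)

    def __post_init__(self) -> None:
        self.segments = sorted(
            self.segments, key=lambda s: (s.interval.chrom, s.interval.start)
        )
        for s in self.segments:
            if s.support < self.min_support:
                raise ValueError(
                    f"segment {s.interval.chrom}:{s.interval.start}-"
                    f"{s.interval.end} support {s.support} < {self.min_support}"
                )

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [s.interval for s in self.segments]

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class GeneAssociation:
    """Gene-to-segment overlap pairs (a gene window may hit many segments)."""

    pairs: list[tuple[str, int]]
    promoter_window: int = 1500

    def genes(self) -> set[str]:
        return {g for g, _ in self.pairs}

    def segments_of(self, gene_id: str) -> list[int]:
        return [s for g, s in self.pairs if g == gene_id]


def count_distinct_merge(
    segmentations: Sequence[Segmentation],
    states: Iterable[str] = BIVALENT_MERGE_STATES,
    max_gap: int = 0,
) -> list[MergedSegment]:
    """Pool *states* intervals across segmentations, merge, count contributors.

    A dataset contributes to a merged cluster if any of its intervals was
    merged into that cluster (cluster-level attribution, including
    book-ended members at ``max_gap=0``).
    """
    states = set(states)
    if not states:
        raise ValueError("state subset must be non-empty")
    if not segmentations:
        raise ValueError("need at least one segmentation")
    tagged: list[tuple[GenomicInterval, str]] = []
    for seg in segmentations:
        for iv in seg.with_states(states):
            tagged.append((iv, seg.dataset_id))
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))

    out: list[MergedSegment] = []
    cur: GenomicInterval | None = None
    members: set[str] = set()
    for iv, ds in tagged:
        if cur is not None and cur.chrom == iv.chrom and iv.start - cur.end <= max_gap:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end)
            members.add(ds)
        else:
            if cur is not None:
                out.append(MergedSegment(cur, frozenset(members)))
            cur = GenomicInterval(iv.chrom, iv.start, iv.end)
            members = {ds}
    if cur is not None:
        out.append(MergedSegment(cur, frozenset(members)))
    return out


def build_fbs(
    merged: Iterable[MergedSegment],
    n_inputs: int,
    rule: SupportRule = SupportRule("fraction", 0.8),
    states: frozenset[str] = BIVALENT_MERGE_STATES,
) -> FbsSet:
    """Threshold merged segments by distinct-contributor support.

    The default fractional rule is strict ("more than 80%"): over 122
    inputs it keeps support >= 98.
    """
    thr = rule.min_support(n_inputs)
    kept = [s for s in merged if s.support >= thr]
    return FbsSet(kept, n_inputs=n_inputs, min_support=thr, bivalent_states=states)


def build_conditional_set(
    merged_a: Iterable[MergedSegment],
    rule_a: SupportRule,
    n_inputs_a: int,
    merged_b: Iterable[MergedSegment],
    rule_b: SupportRule,
    n_inputs_b: int,
) -> FbsSet:
    """Segments passing *rule_a* in group A whose group-B support fails *rule_b*.

    A segment's group-B support is the maximal support among overlapping
    B segments (0 when nothing overlaps).  Used for ESC-conditioned
    control sets, e.g. "bivalent in at least three ESC but in less than
    12 normal segmentations" (rule_b there is the >=12 rule the segment
    must fail).
    """
    merged_b = list(merged_b)
    by_chrom: dict[str, list[MergedSegment]] = {}
    for s in merged_b:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    for lst in by_chrom.values():
        lst.sort(key=lambda s: s.interval.start)

    kept = []
    for s in merged_a:
        if not rule_a.passes(s.support, n_inputs_a):
            continue
        b_support = 0
        for other in by_chrom.get(s.interval.chrom, []):
            if other.interval.start >= s.interval.end:
                break
            if other.interval.end > s.interval.start:
                b_support = max(b_support, other.support)
        if not rule_b.passes(b_support, n_inputs_b):
            kept.append(s)
    return FbsSet(kept, n_inputs=n_inputs_a, min_support=rule_a.min_support(n_inputs_a))


def build_background_promoters(
    segmentations: Sequence[Segmentation],
    fbs: FbsSet,
    states: Iterable[str] = ("TssA",),
) -> list[GenomicInterval]:
    """Merged active-promoter background with FBS-overlapping segments discarded.

    TssA intervals across all segmentations are merged; any merged
    segment overlapping an FBS by >=1 bp is dropped whole.
    """
    pooled: list[GenomicInterval] = []
    wanted = set(states)
    for seg in segmentations:
        pooled.extend(seg.with_states(wanted))
    merged = merge_intervals(pooled)
    return subtract(merged, fbs.intervals)


def associate_genes(
    segments: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_window: int = 1500,
) -> GeneAssociation:
    """Associate genes to segments by >=1 bp overlap of the promoter-extended gene.

    The gene window is the gene body plus *promoter_window* nt upstream
    of the TSS (strand-aware, clipped at position 0).  Many-to-many:
    every overlapping (gene, segment) pair is recorded.
    """
    if promoter_window < 0:
        raise ValueError("promoter_window must be >= 0")
    seg_by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for idx, iv in enumerate(segments):
        seg_by_chrom.setdefault(iv.chrom, []).append((idx, iv))
    for lst in seg_by_chrom.values():
        lst.sort(key=lambda t: t[1].start)

    pairs: list[tuple[str, int]] = []
    for gene in genes:
        win = gene.promoter_window(promoter_window)
        for idx, iv in seg_by_chrom.get(gene.chrom, []):
            if iv.start >= win.end:
                break
            if iv.end > win.start:
                pairs.append((gene.gene_id, idx))
    return GeneAssociation(pairs, promoter_window=promoter_window)


def fbs_coverage_stats(
    fbs: FbsSet,
    seg: Segmentation,
    bivalent_states: Iterable[str] = ("TssBiv", "EnhBiv"),
) -> tuple[float, float | None]:
    """Segment-level reciprocal overlap fractions between an FBS set and one dataset.

    Returns ``(fraction of FBSs overlapping >=1 bivalent segment of seg,
    fraction of seg's bivalent segments overlapping >=1 FBS)``; the second
    value is ``None`` when the segmentation has no bivalent segments.
    """
    biv = seg.with_states(set(bivalent_states))
    fbs_ivs = fbs.intervals

    def _hits(query: GenomicInterval, pool: Sequence[GenomicInterval]) -> bool:
        return any(
            p.chrom == query.chrom and p.start < query.end and query.start < p.end
            for p in pool
        )

    if len(fbs_ivs) == 0:
        frac_fbs = 0.0
    else:
        frac_fbs = sum(_hits(iv, biv) for iv in fbs_ivs) / len(fbs_ivs)
    if not biv:
        return frac_fbs, None
    frac_biv = sum(_hits(iv, fbs_ivs) for iv in biv) / len(biv)
    return frac_fbs, frac_biv
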