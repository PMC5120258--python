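"""Chromatin-category stability between paired segmentations.

The 15 Roadmap states are grouped into 8 coarse categories; for a pair
of segmentations (a reference, typically the normal cell of origin, and
a query, typically the derived cancer cell line) the stability of a
category is the fraction of its reference bases that keep the category
in the query.  Comparing cancer pairs against related-normal pairs per
category highlights which chromatin type is preferentially disrupted in
cancer — bivalent chromatin in the motivating analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, Segmentation, intersect, overlap_bases

__all__ = [
    "CATEGORY_MAP",
    "CATEGORIES",
    "StabilityRecord",
    "categorize",
    "pair_stability",
    "compare_stability_groups",
]

#: Total map from the 15 states to 8 chromatin categories.
CATEGORY_MAP: Mapping[str, str] = {
    "TssBiv": "Bivalent",
    "BivFlnk": "Bivalent",
    "EnhBiv": "Bivalent",
    "TssA": "Promoter",
    "TssAFlnk": "Promoter",
    "TxFlnk": "Transcribed",
    "Tx": "Transcribed",
    "TxWk": "Transcribed",
    "Enh": "Enhancer",
    "EnhG": "Enhancer",
    "ReprPC": "PolycombRepressed",
    "ReprPCWk": "PolycombRepressed",
    "ZNF/Rpts": "ZNF",
    "Quies": "Quiescent",
    "Het": "Heterochromatin",
}

CATEGORIES: tuple[str, ...] = tuple(dict.fromkeys(CATEGORY_MAP.values()))


@dataclass(frozen=True)
class StabilityRecord:
    """Per-(pair, category) stability: fraction of reference bases unchanged."""

    pair_id: str
    category: str
    stability: float | None
    reference_bases: int


def categorize(
    seg: Segmentation, category_map: Mapping[str, str] = CATEGORY_MAP
) -> Segmentation:
    """Relabel a 15-state segmentation with categories, coalescing neighbours.

    Adjacent (book-ended) same-category intervals are merged; base
    coverage is preserved exactly.  An unmapped state raises ``KeyError``.
    """
    out: list[GenomicInterval] = []
    for iv in seg.intervals:
        if iv.label not in category_map:
            raise KeyError(f"state {iv.label!r} has no category mapping")
        cat = category_map[iv.label]
        if (
            out
            and out[-1].chrom == iv.chrom
            and out[-1].end == iv.start
            and out[-1].label == cat
        ):
            out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end, cat)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end, cat))
    return Segmentation(seg.dataset_id, out, validate_states=False)


def pair_stability(
    reference: Segmentation, query: Segmentation, pair_id: str = ""
) -> list[StabilityRecord]:
    """Per-category fraction of reference bases that keep their category.

    Directional: the reference (normal) segmentation defines the base
    set; reference bases not covered by the query at all count as
    changed.  A category absent from the reference yields a record with
    ``stability=None``.
    """
    ref_by_cat: dict[str, list[GenomicInterval]] = {c: [] for c in CATEGORIES}
    qry_by_cat: dict[str, list[GenomicInterval]] = {c: [] for c in CATEGORIES}
    for iv in reference.intervals:
        ref_by_cat.setdefault(iv.label, []).append(iv)
    for iv in query.intervals:
        qry_by_cat.setdefault(iv.label, []).append(iv)

    records = []
    for cat in CATEGORIES:
        ref_ivs = ref_by_cat.get(cat, [])
        nbases = sum(iv.length for iv in ref_ivs)
        if nbases == 0:
            records.append(StabilityRecord(pair_id, cat, None, 0))
            continue
        same = overlap_bases(ref_ivs, qry_by_cat.get(cat, []))
        records.append(StabilityRecord(pair_id, cat, same / nbases, nbases))
    return records


def compare_stability_groups(
    cancer: Iterable[StabilityRecord],
    normal: Iterable[StabilityRecord],
    focal_category: str = "Bivalent",
) -> pd.DataFrame:
    """Contrast per-category stability between cancer pairs and normal pairs.

    For each category: group means, the difference
    ``delta = mean(normal) - mean(cancer)``, and a z-score of each delta
    against the mean/SD (ddof=1) of all categories' deltas.  The
    ``rank_p`` column carries, on the focal category's row, the two-sided
    rank-sum p comparing the focal category's stability values in cancer
    pairs against the pooled other-category values in cancer pairs.

    Categories observed in only one group are excluded from the z-score
    distribution and reported with missing delta/z.
    """
    cancer = [r for r in cancer if r.stability is not None]
    normal = [r for r in normal if r.stability is not None]
    if not cancer or not normal:
        raise ValueError("both groups need stability records")

    def _by_cat(records: list[StabilityRecord]) -> dict[str, list[float]]:
        d: dict[str, list[float]] = {}
        for r in records:
            d.setdefault(r.category, []).append(r.stability)  # type: ignore[arg-type]
        return d

    cvals, nvals = _by_cat(cancer), _by_cat(normal)
    rows = []
    for cat in CATEGORIES:
        mc = float(np.mean(cvals[cat])) if cat in cvals else math.nan
        mn = float(np.mean(nvals[cat])) if cat in nvals else math.nan
        delta = mn - mc if cat in cvals and cat in nvals else math.nan
        rows.append({"category": cat, "mean_cancer": mc, "mean_normal": mn, "delta": delta})
    df = pd.DataFrame(rows).set_index("category")

    deltas = df["delta"].dropna()
    if len(deltas) >= 2 and deltas.std(ddof=1) > 0:
        df["z"] = (df["delta"] - deltas.mean()) / deltas.std(ddof=1)
    else:
        df["z"] = 0.0 * df["delta"]

    df["rank_p"] = math.nan
    focal_vals = cvals.get(focal_category, [])
    other_vals = [v for c, vs in cvals.items() if c != focal_category for v in vs]
    if len(focal_vals) >= 1 and len(other_vals) >= 1:
        _, p = stats.mannwhitneyu(focal_vals, other_vals, alternative="two-sided")
        df.loc[focal_category, "rank_p"] = p
    return df.reset_index()
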