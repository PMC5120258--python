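"""Joint DNA-methylation / expression-change analysis.

Differential-expression tables (produced upstream with edgeR or a
similar tool) are combined with per-gene methylation changes at
associated bivalent segments.  The key readout is the quadrant
decomposition of the (delta-methylation, log2 fold change) plane:
quadrant one — hypermethylation together with up-regulation — is the
positive-dependence signature that distinguishes bivalent-segment genes
in cancer from the transcription-silencing expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fbs import GeneAssociation
from .methylation import SegmentMethSummary

__all__ = [
    "QuadrantSummary",
    "RecurrenceSet",
    "read_de_table",
    "gene_meth_change",
    "quadrant_analysis",
    "fc_group_comparison",
    "recurrence_sets",
]

DE_COLUMNS = ["gene_id", "log2fc", "pvalue", "fdr", "logcpm_normal"]


@dataclass
class QuadrantSummary:
    """Counts/fractions of genes per (delta-meth, log2FC) sign quadrant.

    Q1: hyper & up, Q2: hyper & down, Q3: hypo & down, Q4: hypo & up.
    Genes with an exact zero on either axis are excluded from all
    quadrants.  ``q1_mean_log2fc`` / ``q1_mean_dmeth`` summarise Q1
    members.
    """

    counts: dict[str, int]
    n_genes: int
    label: str = ""
    q1_mean_log2fc: float = math.nan
    q1_mean_dmeth: float = math.nan
    empty: bool = False

    @property
    def fractions(self) -> dict[str, float]:
        if self.n_genes == 0:
            return {q: 0.0 for q in self.counts}
        return {q: c / self.n_genes for q, c in self.counts.items()}


@dataclass
class RecurrenceSet:
    """Genes recurrently significant in one direction across cancers."""

    direction: str
    genes: list[str]
    min_fraction: float
    min_datasets: int


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cancer differential-expression TSV.

    Expected columns: gene_id, log2fc, pvalue, fdr, logcpm_normal.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DE columns {sorted(missing)}")
    return df


def gene_meth_change(
    association: GeneAssociation,
    segment_summaries: Sequence[SegmentMethSummary] | Mapping[int, float],
) -> pd.Series:
    """Mean methylation change per gene over its associated segments.

    *segment_summaries* maps segment index -> mean difference; a list of
    :class:`SegmentMethSummary` is interpreted positionally only when
    accompanied by the same segment ordering used for the association —
    prefer passing a mapping keyed by segment index.  Genes whose
    segments were all discarded are absent from the result.
    """
    if isinstance(segment_summaries, Mapping):
        seg_mean = dict(segment_summaries)
    else:
        seg_mean = {i: s.mean_value for i, s in enumerate(segment_summaries)}
    per_gene: dict[str, list[float]] = {}
    for gene, seg_idx in association.pairs:
        if seg_idx in seg_mean:
            per_gene.setdefault(gene, []).append(seg_mean[seg_idx])
    return pd.Series(
        {g: float(np.mean(vs)) for g, vs in per_gene.items()}, dtype=float
    ).sort_index()


def quadrant_analysis(
    genes: Iterable[str],
    dmeth: pd.Series,
    de: pd.DataFrame,
    sig_fdr: float = 0.05,
    restrict_lowly: bool = False,
    label: str = "",
) -> QuadrantSummary:
    """Quadrant counts for significantly differentially expressed genes.

    Restricts to *genes* present in both inputs with fdr < *sig_fdr*
    (and ``logcpm_normal < 0`` under *restrict_lowly*), then counts sign
    quadrants of (delta-meth, log2fc); exact zeros on either axis are
    excluded.  An empty restricted set yields an all-zero summary with
    ``empty=True``.
    """
    de = de.set_index("gene_id") if "gene_id" in de.columns else de
    idx = [g for g in genes if g in de.index and g in dmeth.index]
    sub = de.loc[idx]
    sub = sub[sub["fdr"] < sig_fdr]
    if restrict_lowly:
        sub = sub[sub["logcpm_normal"] < 0]
    d = dmeth.loc[sub.index].to_numpy(dtype=float)
    fc = sub["log2fc"].to_numpy(dtype=float)
    ok = (d != 0) & (fc != 0) & ~np.isnan(d) & ~np.isnan(fc)
    d, fc = d[ok], fc[ok]
    counts = {
        "Q1": int(((d > 0) & (fc > 0)).sum()),
        "Q2": int(((d > 0) & (fc < 0)).sum()),
        "Q3": int(((d < 0) & (fc < 0)).sum()),
        "Q4": int(((d < 0) & (fc > 0)).sum()),
    }
    n = int(ok.sum())
    q1 = (d > 0) & (fc > 0)
    return QuadrantSummary(
        counts=counts,
        n_genes=n,
        label=label,
        q1_mean_log2fc=float(fc[q1].mean()) if q1.any() else math.nan,
        q1_mean_dmeth=float(d[q1].mean()) if q1.any() else math.nan,
        empty=n == 0,
    )


def fc_group_comparison(
    set_a: Iterable[str],
    set_b: Iterable[str],
    de: pd.DataFrame,
    restrict_lowly: bool = False,
) -> dict[str, object]:
    """Rank-sum comparison of log2 fold changes between two gene sets.

    Members of the focal set are removed from the background before
    testing.  Returns the two-sided p, the median-difference sign
    (median(a) - median(b)) and group sizes; the test is skipped (p None)
    when either restricted set has fewer than 2 genes.
    """
    de = de.set_index("gene_id") if "gene_id" in de.columns else de
    if restrict_lowly:
        de = de[de["logcpm_normal"] < 0]
    a_set = set(set_a)
    b_set = set(set_b) - a_set
    fa = de.loc[[g for g in a_set if g in de.index], "log2fc"].dropna()
    fb = de.loc[[g for g in b_set if g in de.index], "log2fc"].dropna()
    if len(fa) < 2 or len(fb) < 2:
        return {
            "p": None, "median_diff": math.nan,
            "n_a": len(fa), "n_b": len(fb), "skipped": True,
        }
    _, p = stats.mannwhitneyu(fa, fb, alternative="two-sided")
    return {
        "p": float(p),
        "median_diff": float(fa.median() - fb.median()),
        "n_a": len(fa),
        "n_b": len(fb),
        "skipped": False,
    }


def recurrence_sets(
    de_tables: Mapping[str, pd.DataFrame],
    gene_set: Iterable[str],
    min_fraction: float = 0.5,
    min_datasets: int = 10,
    sig_fdr: float = 0.05,
) -> tuple[RecurrenceSet, RecurrenceSet]:
    """Genes recurrently up- or down-regulated across cancer datasets.

    A gene enters the up set when it is significantly up-regulated
    (fdr < sig_fdr, log2fc > 0) in strictly more than
    ``min_fraction * n_tables`` tables AND in at least *min_datasets*
    tables; the down set is symmetric.  A gene qualifying for both
    directions is assigned to the direction with more supporting
    datasets (ties excluded).
    """
    if not de_tables:
        raise ValueError("need at least one DE table")
    genes = sorted(set(gene_set))
    n_tables = len(de_tables)
    up_counts = {g: 0 for g in genes}
    down_counts = {g: 0 for g in genes}
    for df in de_tables.values():
        d = df.set_index("gene_id") if "gene_id" in df.columns else df
        sig = d[d["fdr"] < sig_fdr]
        up = set(sig[sig["log2fc"] > 0].index)
        down = set(sig[sig["log2fc"] < 0].index)
        for g in genes:
            if g in up:
                up_counts[g] += 1
            elif g in down:
                down_counts[g] += 1

    need = max(min_datasets, math.floor(min_fraction * n_tables) + 1)

    up_genes, down_genes = [], []
    for g in genes:
        u, dn = up_counts[g], down_counts[g]
        u_ok, d_ok = u >= need, dn >= need
        if u_ok and d_ok:
            if u > dn:
                up_genes.append(g)
            elif dn > u:
                down_genes.append(g)
        elif u_ok:
            up_genes.append(g)
        elif d_ok:
            down_genes.append(g)
    return (
        RecurrenceSet("up", up_genes, min_fraction, min_datasets),
        RecurrenceSet("down", down_genes, min_fraction, min_datasets),
    )
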