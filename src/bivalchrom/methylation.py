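"""CpG methylation analysis over chromatin segments.

Implements group mean differences of 450k-style beta values, segment
aggregation under the >=3-covered-CpG rule, length-normalised border
profiles around segments, and the stable/lost/new bivalency-fate
partition with its methylation comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    GeneModel,
    GenomicInterval,
    Segmentation,
    difference,
    intersect,
    merge_intervals,
)

__all__ = [
    "BIVALENT_CATEGORY_STATES",
    "BetaMatrix",
    "MethDiffTrack",
    "SegmentMethSummary",
    "BorderProfile",
    "read_beta_matrix",
    "read_bedgraph_track",
    "group_mean_diff",
    "segment_aggregate",
    "gene_window_meth",
    "border_profile",
    "bivalency_fate",
    "fate_meth_comparison",
]

#: The full bivalent chromatin category used for fate analysis
#: (broader than the FBS construction states: includes BivFlnk).
BIVALENT_CATEGORY_STATES = frozenset({"TssBiv", "BivFlnk", "EnhBiv"})


@dataclass
class BetaMatrix:
    """CpG sites x samples beta values with tumor/control group labels.

    ``sites``: DataFrame indexed by site_id with columns chrom, pos.
    ``values``: DataFrame indexed by site_id, one column per sample,
    entries in [0, 1] or NaN.  ``groups``: Series sample -> {"tumor",
    "control"}.
    """

    sites: pd.DataFrame
    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.sites.index.equals(self.values.index):
            self.values = self.values.reindex(self.sites.index)
        unknown = set(self.groups.unique()) - {"tumor", "control"}
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        v = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                raise ValueError("beta values must lie in [0, 1]")

    def samples(self, group: str | None = None) -> list[str]:
        if group is None:
            return list(self.values.columns)
        return [s for s in self.values.columns if self.groups.get(s) == group]


@dataclass
class MethDiffTrack:
    """Per-CpG mean methylation difference (tumor - control).

    ``table``: DataFrame indexed by site_id with columns chrom, pos,
    diff, n_tumor, n_control; diff is NaN where either group mean is
    unavailable.
    """

    table: pd.DataFrame

    @property
    def diffs(self) -> pd.Series:
        return self.table["diff"]


@dataclass(frozen=True)
class SegmentMethSummary:
    segment: GenomicInterval
    n_cpgs: int
    mean_value: float


@dataclass
class BorderProfile:
    """300-bin profile: bins 0-99 left flank, 100-199 body, 200-299 right flank.

    ``bin_means`` holds NaN where no segment contributed data; ``bin_n``
    counts supporting segments per bin.
    """

    bin_means: np.ndarray
    bin_n: np.ndarray

    def __post_init__(self) -> None:
        if len(self.bin_means) != len(self.bin_n):
            raise ValueError("bin arrays must have equal length")


def read_beta_matrix(
    values_path: str | Path, groups_path: str | Path
) -> BetaMatrix:
    """Read the TSV beta-matrix dialect.

    Values file: columns site_id, chrom, pos, then one column per sample;
    missing entries are "NA".  Groups file: two columns sample_id, group.
    """
    df = pd.read_csv(values_path, sep="\t", na_values=["NA"])
    sites = df[["site_id", "chrom", "pos"]].set_index("site_id")
    values = df.drop(columns=["chrom", "pos"]).set_index("site_id")
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    return BetaMatrix(sites=sites, values=values, groups=groups)


def read_bedgraph_track(path: str | Path) -> MethDiffTrack:
    """Read a per-CpG difference track from bedGraph (chrom, start, end, value)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "diff"],
        comment="#",
    )
    table = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"],
            "diff": df["diff"],
            "n_tumor": 1,
            "n_control": 1,
        }
    )
    table.index = [f"cg{i:08d}" for i in range(len(table))]
    return MethDiffTrack(table)


def group_mean_diff(beta: BetaMatrix) -> MethDiffTrack:
    """Per-site mean(tumor) - mean(control) over non-missing beta values.

    Sites covered in only one group get a missing difference.  Raises if
    either group has zero samples.
    """
    tumor = beta.samples("tumor")
    control = beta.samples("control")
    if not tumor or not control:
        raise ValueError("both tumor and control groups must be non-empty")
    tvals = beta.values[tumor]
    cvals = beta.values[control]
    tmean = tvals.mean(axis=1)  # pandas skips NaN; all-NaN rows give NaN
    cmean = cvals.mean(axis=1)
    table = pd.DataFrame(
        {
            "chrom": beta.sites["chrom"],
            "pos": beta.sites["pos"],
            "diff": tmean - cmean,
            "n_tumor": tvals.notna().sum(axis=1),
            "n_control": cvals.notna().sum(axis=1),
        }
    )
    return MethDiffTrack(table)


def _site_arrays(track: MethDiffTrack) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: positions (sorted) and values, NaN rows dropped."""
    t = track.table.dropna(subset=["diff"])
    out = {}
    for chrom, sub in t.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        out[str(chrom)] = (
            sub["pos"].to_numpy()[order],
            sub["diff"].to_numpy(dtype=float)[order],
        )
    return out


def segment_aggregate(
    track: MethDiffTrack,
    segments: Sequence[GenomicInterval],
    min_cpgs: int = 3,
) -> list[SegmentMethSummary]:
    """Unweighted mean of per-CpG values within each segment.

    Segments covering fewer than *min_cpgs* CpGs with data are discarded
    (the 450k ">= 3 covered CpGs" rule).  Site membership is half-open:
    positions in [start, end).
    """
    by_chrom = _site_arrays(track)
    out = []
    for seg in segments:
        if seg.chrom not in by_chrom:
            continue
        pos, vals = by_chrom[seg.chrom]
        lo = np.searchsorted(pos, seg.start, side="left")
        hi = np.searchsorted(pos, seg.end, side="left")
        n = hi - lo
        if n >= min_cpgs:
            out.append(SegmentMethSummary(seg, int(n), float(vals[lo:hi].mean())))
    return out


def gene_window_meth(
    track: MethDiffTrack,
    genes: Sequence[GeneModel],
    promoter_window: int = 1500,
    min_cpgs: int = 3,
) -> pd.Series:
    """Mean methylation difference per gene over its promoter-extended span.

    Same >=min_cpgs coverage rule as :func:`segment_aggregate`; genes
    with insufficient coverage are absent from the returned Series.
    """
    by_chrom = _site_arrays(track)
    out = {}
    for gene in genes:
        win = gene.promoter_window(promoter_window)
        if win.chrom not in by_chrom:
            continue
        pos, vals = by_chrom[win.chrom]
        lo = np.searchsorted(pos, win.start, side="left")
        hi = np.searchsorted(pos, win.end, side="left")
        if hi - lo >= min_cpgs:
            out[gene.gene_id] = float(vals[lo:hi].mean())
    return pd.Series(out, dtype=float).sort_index()


def border_profile(
    segments: Sequence[GenomicInterval],
    track: MethDiffTrack,
    extension: float = 1.0,
    n_bins: int = 300,
) -> BorderProfile:
    """Length-normalised methylation profile across segments and flanks.

    Each segment of length L is extended by ``extension * L`` on both
    sides and the window split into *n_bins* equal bins (by default 300
    bins of width L/100: 100 per flank, 100 for the body).  Per segment
    and bin, the mean of covered CpG values is taken; the profile bin is
    the mean over segments with data in that bin — bins without data stay
    missing rather than zero.  Bin assignment uses integer arithmetic on
    ``(pos - window_start) * n_bins // window_span``; a site on a bin
    boundary belongs to the right-open bin containing it.  Left flanks
    extending past position 0 are clipped: only the covered portion can
    contribute sites.
    """
    if not segments:
        raise ValueError("need at least one segment")
    if n_bins % 3 != 0:
        raise ValueError("n_bins must be divisible by 3")
    by_chrom = _site_arrays(track)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for seg in segments:
        if seg.chrom not in by_chrom:
            continue
        L = seg.length
        ext = int(round(extension * L))
        wstart = seg.start - ext
        wend = seg.end + ext
        span = wend - wstart
        pos, vals = by_chrom[seg.chrom]
        lo = np.searchsorted(pos, max(wstart, 0), side="left")
        hi = np.searchsorted(pos, wend, side="left")
        if hi <= lo:
            continue
        p = pos[lo:hi]
        v = vals[lo:hi]
        bins = ((p - wstart) * n_bins) // span
        bins = np.clip(bins.astype(int), 0, n_bins - 1)
        binsum = np.bincount(bins, weights=v, minlength=n_bins)
        binn = np.bincount(bins, minlength=n_bins)
        has = binn > 0
        with np.errstate(invalid="ignore"):
            segmean = np.where(has, binsum / np.maximum(binn, 1), 0.0)
        sums[has] += segmean[has]
        counts[has] += 1
    means = np.full(n_bins, np.nan)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    return BorderProfile(bin_means=means, bin_n=counts)


def split_by_length(
    segments: Sequence[GenomicInterval], threshold: int = 10_000
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Partition segments into (shorter than threshold, at least threshold)."""
    short = [s for s in segments if s.length < threshold]
    long = [s for s in segments if s.length >= threshold]
    return short, long


def bivalency_fate(
    normal_seg: Segmentation,
    cancer_seg: Segmentation,
    bivalent_states: Iterable[str] = BIVALENT_CATEGORY_STATES,
) -> dict[str, list[GenomicInterval]]:
    """Partition bivalent bases into stable / lost / new sub-intervals.

    stable: bivalent in both segmentations; lost: bivalent only in the
    normal; new: bivalent only in cancer.  The three classes are disjoint
    and satisfy stable+lost = normal bivalent bases, stable+new = cancer
    bivalent bases.
    """
    states = set(bivalent_states)
    nb = merge_intervals(normal_seg.with_states(states))
    cb = merge_intervals(cancer_seg.with_states(states))
    return {
        "stable": intersect(nb, cb),
        "lost": difference(nb, cb),
        "new": difference(cb, nb),
    }


def fate_meth_comparison(
    fates: dict[str, list[GenomicInterval]],
    track: MethDiffTrack,
    min_cpgs: int = 3,
) -> dict[str, object]:
    """Compare methylation change of lost vs stably bivalent regions.

    Each fate's sub-intervals are aggregated with the >=min_cpgs rule;
    the lost-vs-stable contrast uses a two-sided rank-sum test.  Returns
    per-fate means/counts and ``p_lost_vs_stable`` (None when either fate
    has fewer than 2 aggregated segments, with ``test_skipped=True``).
    """
    summaries = {
        fate: segment_aggregate(track, ivs, min_cpgs=min_cpgs)
        for fate, ivs in fates.items()
    }
    result: dict[str, object] = {}
    for fate, summ in summaries.items():
        vals = [s.mean_value for s in summ]
        result[f"{fate}_n"] = len(vals)
        result[f"{fate}_mean"] = float(np.mean(vals)) if vals else math.nan
    lost = [s.mean_value for s in summaries.get("lost", [])]
    stable = [s.mean_value for s in summaries.get("stable", [])]
    if len(lost) >= 2 and len(stable) >= 2:
        _, p = stats.mannwhitneyu(lost, stable, alternative="two-sided")
        result["p_lost_vs_stable"] = float(p)
        result["test_skipped"] = False
    else:
        result["p_lost_vs_stable"] = None
        result["test_skipped"] = True
    return result
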