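"""Training-free relative-methylation cancer score and its evaluation.

The score of a sample is the mean beta value over a small set of
frequently bivalent descriptor regions divided by the mean beta value
over all CpGs covered on that sample's array — a methylation
fold-change of bivalent chromatin.  Because bivalent DNA is nearly
unmethylated in normal cells and frequently hypermethylated in cancer,
the ratio separates cancer from normal samples without any training
step.  The module also provides ROC/AUC evaluation, exhaustive
region-subset search, the purity at which the score's prediction band
crosses a detection threshold, and stage/grade correlation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve

from .intervals import GenomicInterval
from .methylation import BetaMatrix

__all__ = [
    "ClassifierRegions",
    "ClassifierScore",
    "RocResult",
    "PurityModel",
    "load_classifier_regions",
    "sample_score",
    "score_samples",
    "roc_auc",
    "subset_search",
    "purity_crossing",
    "map_ordinal",
    "ordinal_correlation",
    "BivalentMethylationClassifier",
]


@dataclass
class ClassifierRegions:
    """Descriptor regions with support counts and associated gene names."""

    regions: list[GenomicInterval]
    source: str
    support: list[int]
    genes: list[list[str]]

    def __len__(self) -> int:
        return len(self.regions)


@dataclass(frozen=True)
class ClassifierScore:
    """One sample's relative descriptor methylation (None when discarded)."""

    sample_id: str
    label: str
    score: float | None
    n_segments_used: int
    reason: str | None = None


@dataclass
class RocResult:
    """ROC points and the tie-half-credit (Mann-Whitney) AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class PurityModel:
    """Linear score-vs-purity fit with a prediction band and threshold crossing."""

    slope: float
    intercept: float
    band: float
    fn_threshold: float
    crossing_purity: float | None


def load_classifier_regions(variant: str = "fbs14") -> ClassifierRegions:
    """Load a packaged descriptor-region set.

    ``"fbs14"`` ships verbatim: the 14 segments bivalent in at least 120
    of the 122 normal segmentations.  The promoter-only ("promoter9") and
    enhancer-only ("enhancer12") variants have no published coordinates
    and can only be rebuilt from segmentation inputs, so requesting them
    raises.
    """
    if variant in ("promoter9", "enhancer12"):
        raise ValueError(
            f"{variant!r} is not packaged: its coordinates must be derived "
            "from segmentation inputs via fbs.build_fbs"
        )
    if variant != "fbs14":
        raise ValueError(f"unknown classifier region variant {variant!r}")
    meta = pd.read_csv(
        resources.files("bivalchrom.data").joinpath("fbs14_metadata.tsv"),
        sep="\t",
    )
    regions = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.region_id)
        for r in meta.itertuples()
    ]
    return ClassifierRegions(
        regions=regions,
        source="table1_fixture",
        support=[int(s) for s in meta["support"]],
        genes=[g.split(",") for g in meta["genes"]],
    )


def _region_site_index(
    sites: pd.DataFrame, regions: Sequence[GenomicInterval]
) -> list[np.ndarray]:
    """Positional indices of each region's CpG sites within *sites*."""
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    out = []
    for reg in regions:
        mask = (chrom == reg.chrom) & (pos >= reg.start) & (pos < reg.end)
        out.append(np.flatnonzero(mask))
    return out


def sample_score(
    beta_column: pd.Series,
    sites: pd.DataFrame,
    regions: Sequence[GenomicInterval],
    min_cpgs: int = 3,
    min_segments: int = 3,
    sample_id: str = "",
    label: str = "unknown",
) -> ClassifierScore:
    """Relative descriptor methylation of one sample.

    Per region: mean beta over its covered (non-missing) CpGs, the
    region discarded below *min_cpgs*.  The score is the mean of the
    surviving region means divided by the mean beta over ALL covered
    CpGs of the sample.  A sample is discarded when fewer than
    *min_segments* regions survive or the array-wide mean is zero.
    """
    vals = beta_column.to_numpy(dtype=float)
    covered = ~np.isnan(vals)
    if not covered.any():
        return ClassifierScore(sample_id, label, None, 0, "no covered CpGs")
    region_means = []
    for idx in _region_site_index(sites, regions):
        rv = vals[idx]
        rv = rv[~np.isnan(rv)]
        if len(rv) >= min_cpgs:
            region_means.append(rv.mean())
    n_used = len(region_means)
    if n_used < min_segments:
        return ClassifierScore(
            sample_id, label, None, n_used, f"only {n_used} segments with data"
        )
    denom = vals[covered].mean()
    if denom == 0:
        return ClassifierScore(sample_id, label, None, n_used, "zero array-wide mean")
    return ClassifierScore(sample_id, label, float(np.mean(region_means) / denom), n_used)


def score_samples(
    beta: BetaMatrix,
    regions: Sequence[GenomicInterval],
    min_cpgs: int = 3,
    min_segments: int = 3,
) -> pd.DataFrame:
    """Score every sample of a beta matrix.

    Returns a DataFrame (index sample_id) with columns label, score,
    n_segments_used, reason; discarded samples carry NaN scores.
    """
    rows = []
    for sample in beta.values.columns:
        label = str(beta.groups.get(sample, "unknown"))
        sc = sample_score(
            beta.values[sample], beta.sites, regions,
            min_cpgs=min_cpgs, min_segments=min_segments,
            sample_id=sample, label=label,
        )
        rows.append(
            {
                "sample_id": sample,
                "label": sc.label,
                "score": np.nan if sc.score is None else sc.score,
                "n_segments_used": sc.n_segments_used,
                "reason": sc.reason,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _auc_rank(scores: np.ndarray, is_pos: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties."""
    n_pos = int(is_pos.sum())
    n_neg = len(scores) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes to compute AUC")
    ranks = stats.rankdata(scores)
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_auc(
    scored: pd.DataFrame,
    positive_label: str = "tumor",
    negative_label: str = "control",
) -> RocResult:
    """ROC curve and AUC for scored samples (cancer = positive class).

    Discarded samples (NaN score) are excluded.  AUC is the probability
    a random cancer sample outscores a random normal one, ties counted
    half — identical to the trapezoidal area under the ROC points.
    """
    df = scored.dropna(subset=["score"])
    df = df[df["label"].isin([positive_label, negative_label])]
    y = (df["label"] == positive_label).to_numpy()
    s = df["score"].to_numpy(dtype=float)
    auc = _auc_rank(s, y)
    fpr, tpr, thr = roc_curve(y.astype(int), s)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def subset_search(
    regions: ClassifierRegions | Sequence[GenomicInterval],
    beta: BetaMatrix,
    min_cpgs: int = 3,
    min_segments: int = 3,
    max_regions: int = 20,
) -> pd.DataFrame:
    """Exhaustively score every non-empty region subset and rank by AUC.

    Samples are rescored per subset with the same coverage filters; for
    subsets of fewer than 3 regions the *min_segments* sample filter is
    waived (every subset region with data is required instead), flagged
    in the ``filter_waived`` column.  Refuses more than *max_regions*
    regions (2^n growth).  Returns one row per subset, best AUC first.
    """
    ivs = regions.regions if isinstance(regions, ClassifierRegions) else list(regions)
    n = len(ivs)
    if n > max_regions:
        raise ValueError(f"refusing exhaustive search over {n} > {max_regions} regions")
    site_idx = _region_site_index(beta.sites, ivs)
    vals = beta.values.to_numpy(dtype=float)  # sites x samples
    n_samples = vals.shape[1]
    labels = np.array(
        [str(beta.groups.get(s, "unknown")) for s in beta.values.columns]
    )
    covered = ~np.isnan(vals)
    denom = np.where(
        covered.any(axis=0),
        np.nansum(np.where(covered, vals, 0.0), axis=0) / np.maximum(covered.sum(axis=0), 1),
        np.nan,
    )

    region_mean = np.full((n, n_samples), np.nan)
    region_ok = np.zeros((n, n_samples), dtype=bool)
    for r, idx in enumerate(site_idx):
        sub = vals[idx]
        cnt = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            m = np.nanmean(sub, axis=0) if len(idx) else np.full(n_samples, np.nan)
        ok = cnt >= min_cpgs
        region_mean[r, ok] = m[ok]
        region_ok[r] = ok

    is_pos = labels == "tumor"
    rows = []
    for size in range(1, n + 1):
        waive = size < min_segments
        need = size if waive else min_segments
        for subset in combinations(range(n), size):
            sel = list(subset)
            ok = region_ok[sel]
            surviving = ok.sum(axis=0)
            keep = surviving >= need
            if not (keep & is_pos).any() or not (keep & ~is_pos).any():
                auc = math.nan
            else:
                with np.errstate(invalid="ignore"):
                    num = np.nanmean(region_mean[sel], axis=0)
                score = num / denom
                auc = _auc_rank(score[keep], is_pos[keep])
            rows.append(
                {
                    "subset": subset,
                    "size": size,
                    "auc": auc,
                    "n_samples": int(keep.sum()),
                    "filter_waived": waive,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values("auc", ascending=False, kind="stable").reset_index(drop=True)


def purity_crossing(
    scores: Sequence[float],
    purities: Sequence[float],
    control_scores: Sequence[float],
    fn_rate: float = 0.05,
    band: float = 0.90,
) -> PurityModel:
    """Tumor purity at which the score becomes reliably detectable.

    Fits score = a + b*purity by OLS, takes the lower bound of the
    *band* prediction interval as a function of purity, and reports the
    smallest purity in (0, 1] where that lower bound reaches the
    detection threshold — the (1 - fn_rate) quantile of the control
    scores (95th percentile by default).  ``crossing_purity`` is None
    when the bound never reaches the threshold on (0, 1].
    """
    s = np.asarray(scores, dtype=float)
    p = np.asarray(purities, dtype=float)
    if len(s) != len(p) or len(s) < 3:
        raise ValueError("need >= 3 paired (score, purity) observations")
    if np.ptp(p) == 0:
        raise ValueError("degenerate purity spread: all purities equal")
    fn_threshold = float(np.quantile(np.asarray(control_scores, dtype=float), 1 - fn_rate))

    X = sm.add_constant(p)
    fit = sm.OLS(s, X).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])

    grid = np.linspace(1e-6, 1.0, 2001)
    pred = fit.get_prediction(sm.add_constant(grid))
    lower = pred.summary_frame(alpha=1 - band)["obs_ci_lower"].to_numpy()

    crossing: float | None = None
    above = lower >= fn_threshold
    if above.any():
        i = int(np.argmax(above))
        if i == 0:
            crossing = float(grid[0])
        else:
            # refine between the bracketing grid points

            def f(x: float) -> float:
                pr = fit.get_prediction(sm.add_constant(np.array([x, 0.0]))[:1])
                lo = pr.summary_frame(alpha=1 - band)["obs_ci_lower"].iloc[0]
                return float(lo - fn_threshold)

            from scipy.optimize import brentq

            lo_x, hi_x = float(grid[i - 1]), float(grid[i])
            try:
                crossing = float(brentq(f, lo_x, hi_x, xtol=1e-10))
            except ValueError:
                crossing = hi_x
    return PurityModel(
        slope=slope,
        intercept=intercept,
        band=band,
        fn_threshold=fn_threshold,
        crossing_purity=crossing,
    )


_STAGE_RE = re.compile(r"^\s*Stage\s+(IV|III|II|I)[A-Ca-c]?\s*$")
_GRADE_RE = re.compile(r"^\s*G([1-4])\s*$")
_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4}


def map_ordinal(label: str) -> int | None:
    """Map a pathologic stage or histologic grade label to 1..4.

    Sub-stages collapse to their main stage ("Stage Ia" -> 1); anything
    else (e.g. "Stage X", "GX") maps to None and is discarded.
    """
    m = _STAGE_RE.match(label)
    if m:
        return _ROMAN[m.group(1)]
    m = _GRADE_RE.match(label)
    if m:
        return int(m.group(1))
    return None


def ordinal_correlation(
    values: Sequence[float],
    ordinal_labels: Sequence[str | int],
    method: str = "spearman",
) -> tuple[float, float, int]:
    """Correlate purity-normalised scores with ordinal stage/grade.

    Labels are mapped to 1..4 (strings via :func:`map_ordinal`, integers
    kept as-is); unmapped observations are discarded.  Rank correlation
    by default, Pearson via ``method="pearson"``.  Returns (coefficient,
    two-sided p, n used); raises on a constant ordinal vector or fewer
    than 3 usable pairs.
    """
    xs, ys = [], []
    for v, lab in zip(values, ordinal_labels, strict=True):
        o = lab if isinstance(lab, (int, np.integer)) else map_ordinal(str(lab))
        if o is not None and not math.isnan(float(v)):
            xs.append(float(v))
            ys.append(int(o))
    if len(xs) < 3:
        raise ValueError("need >= 3 mappable paired observations")
    if len(set(ys)) == 1:
        raise ValueError("ordinal vector is constant; correlation undefined")
    if method == "spearman":
        rho, p = stats.spearmanr(xs, ys)
    elif method == "pearson":
        rho, p = stats.pearsonr(xs, ys)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p), len(xs)


class BivalentMethylationClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn wrapper around the training-free relative-methylation score.

    The score itself needs no training; ``fit`` only records the control
    score distribution to place the decision threshold at the
    ``specificity`` quantile.  ``X`` is (n_samples, n_sites) beta values
    (NaN = not covered) matching ``sites`` row order; ``y`` is a binary
    label vector (1 = tumor).

    Parameters
    ----------
    sites : DataFrame with chrom/pos per CpG (row order of X columns).
    regions : region set; default the packaged 14-segment descriptor.
    min_cpgs, min_segments : coverage filters of the score.
    specificity : control-score quantile used as the decision threshold.
    """

    def __init__(
        self,
        sites: pd.DataFrame | None = None,
        regions: Sequence[GenomicInterval] | None = None,
        min_cpgs: int = 3,
        min_segments: int = 3,
        specificity: float = 0.95,
    ) -> None:
        self.sites = sites
        self.regions = regions
        self.min_cpgs = min_cpgs
        self.min_segments = min_segments
        self.specificity = specificity

    def _resolve_regions(self) -> list[GenomicInterval]:
        if self.regions is not None:
            return list(self.regions)
        return load_classifier_regions("fbs14").regions

    def decision_function(self, X) -> np.ndarray:
        if self.sites is None:
            raise ValueError("sites metadata is required")
        X = np.asarray(X, dtype=float)
        regions = self._resolve_regions()
        out = np.full(X.shape[0], np.nan)
        for i in range(X.shape[0]):
            sc = sample_score(
                pd.Series(X[i], index=self.sites.index),
                self.sites,
                regions,
                min_cpgs=self.min_cpgs,
                min_segments=self.min_segments,
            )
            if sc.score is not None:
                out[i] = sc.score
        return out

    def fit(self, X, y):
        y = np.asarray(y)
        scores = self.decision_function(X)
        ctrl = scores[(y == 0) & ~np.isnan(scores)]
        if len(ctrl) == 0:
            raise ValueError("fit requires scoreable control (y == 0) samples")
        self.classes_ = np.array([0, 1])
        self.threshold_ = float(np.quantile(ctrl, self.specificity))
        self.control_scores_ = ctrl
        return self

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return (scores >= self.threshold_).astype(int)

    def score(self, X, y) -> float:
        """AUC of the decision scores against binary labels."""
        s = self.decision_function(X)
        y = np.asarray(y)
        ok = ~np.isnan(s)
        return _auc_rank(s[ok], y[ok] == 1)
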