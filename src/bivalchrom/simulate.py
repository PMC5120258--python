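"""Seeded synthetic-data generator for the whole analysis pipeline.

Emulates the statistical structure the analyses assume, at desk scale:
multi-cell-type chromatin state segmentations sharing planted frequently
bivalent regions (plus lower-support decoys and cell-type-private
bivalent intervals), CpG sites with array-like bimodal background
methylation and near-unmethylated bivalent regions, tumor/normal beta
matrices with a configurable hypermethylation effect at bivalent
regions, mild global hypomethylation elsewhere and purity mixing, and
per-cancer differential-expression tables whose fold-change shift for
bivalent-segment genes can be coupled to the genes' methylation change.

Everything is driven by integer-seeded numpy generators: identical
configuration and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, GenomicInterval, Segmentation

__all__ = ["SimConfig", "SimTruth", "SimWorld", "simulate_world", "simulate_betas", "simulate_de"]

# Filler-state frequencies for the non-bivalent genome, loosely matching
# the composition of Roadmap segmentations (Quies dominates).
FILLER_STATES = (
    "Quies", "TxWk", "Tx", "Enh", "TssA", "TssAFlnk",
    "ReprPC", "ReprPCWk", "Het", "TxFlnk", "EnhG", "ZNF/Rpts",
)
FILLER_FREQS = (0.50, 0.12, 0.10, 0.08, 0.05, 0.03, 0.03, 0.03, 0.03, 0.01, 0.01, 0.01)


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions.

    The hypermethylation effect (+0.07 mean beta at bivalent regions),
    the mild global hypomethylation (-0.05) and the fold-change shift of
    bivalent-segment genes (+0.94 log2) anchor to the effect sizes the
    method is designed to detect.
    """

    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 400_000, "chr2": 400_000}
    )
    n_celltypes: int = 20
    n_fbs_regions: int = 12
    fbs_length_range: tuple[int, int] = (4_000, 12_000)
    fbs_support_fraction: float = 0.9
    n_decoy_regions: int = 8
    decoy_support_fraction: float = 0.4
    n_private_bivalent: int = 3
    private_length_range: tuple[int, int] = (600, 2_000)
    n_genes: int = 300
    promoter_window: int = 1_500
    cpg_spacing_bivalent: int = 150
    cpg_spacing_background: int = 1_000
    n_tumor: int = 100
    n_normal: int = 100
    mu_bivalent: float = 0.10
    background_high_mean: float = 0.85
    background_low_mean: float = 0.15
    background_high_weight: float = 0.6
    hyper_effect: float = 0.07
    affected_fraction: float = 1.0
    global_shift: float = -0.05
    region_effect_sd: float = 0.02
    beta_concentration: float = 50.0
    sample_biv_sd: float = 0.02
    sample_global_sd: float = 0.01
    missing_rate: float = 0.0
    purity_alpha: float = 5.0
    purity_beta: float = 2.0
    bivalency_loss_prob: float = 0.7
    bivalency_loss_prob_other: float = 0.2
    new_bivalent_prob: float = 0.02
    filler_flip_prob: float = 0.03
    fbs_log2fc_shift: float = 0.94
    background_log2fc_shift: float = 0.0
    de_sd: float = 1.0
    de_nrep: int = 30
    rho: float = 0.5
    lowly_fraction: float = 0.6
    background_lowly_fraction: float = 0.3

    def __post_init__(self) -> None:
        for name in ("fbs_support_fraction", "decoy_support_fraction", "affected_fraction",
                     "bivalency_loss_prob", "new_bivalent_prob", "missing_rate", "rho"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mu_bivalent + self.hyper_effect > 1:
            raise ValueError("mu_bivalent + hyper_effect must not exceed 1")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimTruth:
    """Ground truth of a simulated world, queryable by every test."""

    planted_regions: list[GenomicInterval]
    decoy_regions: list[GenomicInterval]
    region_contributors: list[frozenset[str]]
    decoy_contributors: list[frozenset[str]]
    affected: np.ndarray          # bool per planted region
    region_effects: np.ndarray    # added beta at each planted region in tumors
    fbs_genes: dict[str, int]     # gene_id -> planted region index
    gene_true_dmeth: pd.Series    # expected tumor-control beta change per gene


@dataclass
class SimWorld:
    """Simulated inputs plus ground truth.

    ``segmentations`` are the normal cell types; ``cancer_segmentations``
    are tumor-derived counterparts (index-matched) with preferential
    bivalency loss at hypermethylating regions; ``related_segmentations``
    are index-matched closely-related normal controls carrying the same
    background label churn but only the basal bivalency turnover, for
    stability comparisons.
    """

    segmentations: list[Segmentation]
    cancer_segmentations: list[Segmentation]
    related_segmentations: list[Segmentation]
    genes: list[GeneModel]
    sites: pd.DataFrame
    truth: SimTruth


def _place_regions(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Lay planted and decoy regions on a regular grid in the first 60% of
    each chromosome, leaving gaps so merging never joins two regions."""
    chroms = list(cfg.chrom_lengths.items())
    total = cfg.n_fbs_regions + cfg.n_decoy_regions
    slots: list[tuple[str, int, int]] = []
    per_chrom = int(np.ceil(total / len(chroms)))
    for chrom, length in chroms:
        zone_end = int(0.6 * length)
        width = zone_end // per_chrom
        if width < cfg.fbs_length_range[1] + 4000:
            raise ValueError(
                f"chromosome {chrom} too short to pack {per_chrom} regions"
            )
        for k in range(per_chrom):
            slots.append((chrom, k * width + 2000, width - 4000))
    if len(slots) < total:
        raise ValueError("not enough region slots; enlarge chromosomes")
    order = rng.permutation(len(slots))[:total]
    regions = []
    for j, slot_i in enumerate(sorted(order)):
        chrom, start, avail = slots[slot_i]
        lo, hi = cfg.fbs_length_range
        length = int(rng.integers(lo, min(hi, avail) + 1))
        regions.append(GenomicInterval(chrom, start, start + length))
    rng.shuffle(regions)
    planted = sorted(regions[: cfg.n_fbs_regions], key=lambda r: (r.chrom, r.start))
    decoys = sorted(regions[cfg.n_fbs_regions:], key=lambda r: (r.chrom, r.start))
    return planted, decoys


def _contributor_sets(
    cfg: SimConfig, rng: np.random.Generator, regions: Sequence[GenomicInterval],
    fraction: float, celltypes: Sequence[str],
) -> list[frozenset[str]]:
    # exact contributor count so the support threshold behaves deterministically
    n = int(round(fraction * len(celltypes)))
    return [
        frozenset(rng.choice(celltypes, size=n, replace=False))
        for _ in regions
    ]


def _fill_segmentation(
    cfg: SimConfig,
    rng: np.random.Generator,
    dataset_id: str,
    bivalent: list[GenomicInterval],
) -> Segmentation:
    """Complete a partition around the given bivalent intervals with filler states."""
    intervals: list[GenomicInterval] = list(bivalent)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in bivalent:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, length in cfg.chrom_lengths.items():
        anchors = sorted(by_chrom.get(chrom, []), key=lambda iv: iv.start)
        cursor = 0
        for nxt in anchors + [GenomicInterval(chrom, length, length + 1)]:
            while cursor < min(nxt.start, length):
                chunk = int(rng.integers(2_000, 20_000))
                end = min(cursor + chunk, nxt.start, length)
                label = str(rng.choice(FILLER_STATES, p=FILLER_FREQS))
                intervals.append(GenomicInterval(chrom, cursor, end, label))
                cursor = end
            cursor = max(cursor, nxt.end)
    return Segmentation(dataset_id, intervals)


def _private_bivalents(
    cfg: SimConfig, rng: np.random.Generator, existing: list[GenomicInterval]
) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    taken = list(existing)
    for _ in range(cfg.n_private_bivalent):
        for _try in range(20):
            chrom = str(rng.choice(list(cfg.chrom_lengths)))
            L = cfg.chrom_lengths[chrom]
            length = int(rng.integers(*cfg.private_length_range))
            start = int(rng.integers(int(0.62 * L), L - length - 1))
            iv = GenomicInterval(chrom, start, start + length,
                                 str(rng.choice(["TssBiv", "EnhBiv"])))
            if not any(iv.overlaps(t) for t in taken):
                out.append(iv)
                taken.append(iv)
                break
    return out


def _derive_cancer(
    cfg: SimConfig,
    rng: np.random.Generator,
    seg: Segmentation,
    hyper_regions: Sequence[GenomicInterval],
) -> Segmentation:
    # hypermethylating regions lose bivalency at the full rate; other
    # bivalent intervals at the lower rate, so loss and hypermethylation
    # co-occur as they do in tumors
    bivalent_states = {"TssBiv", "BivFlnk", "EnhBiv"}
    out = []
    for iv in seg.intervals:
        label = iv.label
        if label in bivalent_states:
            hyper = any(iv.overlaps(r) for r in hyper_regions)
            q = cfg.bivalency_loss_prob if hyper else cfg.bivalency_loss_prob_other
            if rng.random() < q:
                label = str(rng.choice(["ReprPC", "Quies"]))
        else:
            r = rng.random()
            if r < cfg.new_bivalent_prob:
                label = str(rng.choice(["TssBiv", "EnhBiv"]))
            elif r < cfg.new_bivalent_prob + cfg.filler_flip_prob:
                label = str(rng.choice(FILLER_STATES, p=FILLER_FREQS))
        out.append(GenomicInterval(iv.chrom, iv.start, iv.end, label))
    return Segmentation(f"{seg.dataset_id}_cancer", out)


def _place_genes(
    cfg: SimConfig,
    rng: np.random.Generator,
    planted: Sequence[GenomicInterval],
) -> tuple[list[GeneModel], dict[str, int]]:
    genes: list[GeneModel] = []
    fbs_genes: dict[str, int] = {}
    gid = 0
    for ridx, region in enumerate(planted):
        for _ in range(int(rng.integers(1, 3))):
            start = region.start + int(rng.integers(0, max(1, region.length // 2)))
            length = int(rng.integers(3_000, 8_000))
            end = min(start + length, cfg.chrom_lengths[region.chrom] - 1)
            g = GeneModel(f"G{gid:04d}", region.chrom, start, end,
                          str(rng.choice(["+", "-"])))
            genes.append(g)
            fbs_genes[g.gene_id] = ridx
            gid += 1
    while gid < cfg.n_genes:
        chrom = str(rng.choice(list(cfg.chrom_lengths)))
        L = cfg.chrom_lengths[chrom]
        length = int(rng.integers(4_000, 10_000))
        start = int(rng.integers(int(0.62 * L), L - length - 1))
        genes.append(
            GeneModel(f"G{gid:04d}", chrom, start, start + length,
                      str(rng.choice(["+", "-"])))
        )
        gid += 1
    return genes, fbs_genes


def _build_sites(
    cfg: SimConfig,
    rng: np.random.Generator,
    planted: Sequence[GenomicInterval],
    decoys: Sequence[GenomicInterval],
    affected: np.ndarray,
    region_effects: np.ndarray,
) -> pd.DataFrame:
    rows = []
    for ridx, region in enumerate(planted):
        effect = region_effects[ridx] if affected[ridx] else cfg.global_shift
        for pos in range(region.start, region.end, cfg.cpg_spacing_bivalent):
            rows.append((region.chrom, pos, "fbs", ridx, cfg.mu_bivalent,
                         cfg.mu_bivalent + effect))
    for region in decoys:
        for pos in range(region.start, region.end, cfg.cpg_spacing_bivalent):
            rows.append((region.chrom, pos, "decoy", -1, cfg.mu_bivalent,
                         cfg.mu_bivalent + cfg.global_shift))
    in_region = sorted(planted) + sorted(decoys)
    for chrom, length in cfg.chrom_lengths.items():
        hits = [iv for iv in in_region if iv.chrom == chrom]
        for pos in range(500, length, cfg.cpg_spacing_background):
            if any(iv.start <= pos < iv.end for iv in hits):
                continue
            high = rng.random() < cfg.background_high_weight
            mu = cfg.background_high_mean if high else cfg.background_low_mean
            rows.append((chrom, pos, "background", -1, mu, mu + cfg.global_shift))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "klass", "region_idx",
                                     "base_mean", "tumor_mean"])
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    df.index = [f"cg{i:06d}" for i in range(len(df))]
    df["base_mean"] = df["base_mean"].clip(0.02, 0.98)
    df["tumor_mean"] = df["tumor_mean"].clip(0.02, 0.98)
    return df


def simulate_world(config: SimConfig) -> SimWorld:
    """Generate segmentations, genes, CpG sites and the truth record.

    Each planted region is shown as bivalent (TssBiv or EnhBiv) by
    exactly ``round(fbs_support_fraction * n_celltypes)`` randomly chosen
    cell types, so the planted support is deterministic; decoys likewise
    at their lower fraction.  Cell types additionally carry private
    bivalent intervals away from the planted regions, and cancer
    counterparts of every segmentation lose bivalency per interval with
    probability ``bivalency_loss_prob`` and gain occasional new bivalent
    intervals.
    """
    rng = np.random.default_rng(config.seed)
    celltypes = [f"CT{i:02d}" for i in range(config.n_celltypes)]

    planted, decoys = _place_regions(config, rng)
    contributors = _contributor_sets(config, rng, planted,
                                     config.fbs_support_fraction, celltypes)
    decoy_contrib = _contributor_sets(config, rng, decoys,
                                      config.decoy_support_fraction, celltypes)

    n_aff = int(round(config.affected_fraction * config.n_fbs_regions))
    aff_idx = rng.choice(config.n_fbs_regions, size=n_aff, replace=False)
    affected = np.zeros(config.n_fbs_regions, dtype=bool)
    affected[aff_idx] = True
    # region heterogeneity modulates a planted effect; a zero effect stays
    # exactly zero so tumor and control remain exchangeable under the null
    if config.hyper_effect == 0:
        region_effects = np.zeros(config.n_fbs_regions)
    else:
        region_effects = np.where(
            affected,
            rng.normal(config.hyper_effect, config.region_effect_sd,
                       size=config.n_fbs_regions),
            0.0,
        )

    region_labels = ["TssBiv" if i % 2 == 0 else "EnhBiv" for i in range(len(planted))]
    decoy_labels = ["TssBiv" if i % 2 == 0 else "EnhBiv" for i in range(len(decoys))]

    segmentations = []
    cancer_segmentations = []
    related_segmentations = []
    for ct in celltypes:
        biv = [
            GenomicInterval(r.chrom, r.start, r.end, region_labels[i])
            for i, r in enumerate(planted)
            if ct in contributors[i]
        ]
        biv += [
            GenomicInterval(r.chrom, r.start, r.end, decoy_labels[i])
            for i, r in enumerate(decoys)
            if ct in decoy_contrib[i]
        ]
        biv += _private_bivalents(config, rng, biv)
        seg = _fill_segmentation(config, rng, ct, biv)
        segmentations.append(seg)
        hyper_regions = [r for i, r in enumerate(planted) if affected[i]]
        cancer_segmentations.append(
            _derive_cancer(config, rng, seg, hyper_regions)
        )
        # a related normal: same churn machinery, no preferential loss
        related = _derive_cancer(config, rng, seg, [])
        related_segmentations.append(
            Segmentation(f"{ct}_related", related.intervals)
        )

    genes, fbs_genes = _place_genes(config, rng, planted)
    sites = _build_sites(config, rng, planted, decoys, affected, region_effects)

    gene_dmeth = {}
    for g in genes:
        if g.gene_id in fbs_genes:
            ridx = fbs_genes[g.gene_id]
            gene_dmeth[g.gene_id] = (
                float(region_effects[ridx]) if affected[ridx] else config.global_shift
            )
        else:
            gene_dmeth[g.gene_id] = config.global_shift
    truth = SimTruth(
        planted_regions=planted,
        decoy_regions=decoys,
        region_contributors=contributors,
        decoy_contributors=decoy_contrib,
        affected=affected,
        region_effects=region_effects,
        fbs_genes=fbs_genes,
        gene_true_dmeth=pd.Series(gene_dmeth),
    )
    return SimWorld(
        segmentations, cancer_segmentations, related_segmentations,
        genes, sites, truth,
    )


def simulate_betas(
    config: SimConfig,
    sites: pd.DataFrame,
    purity: float | Sequence[float] | None = None,
    seed: int | None = None,
):
    """Simulate the tumor/normal beta matrix with purity mixing.

    Control samples draw around each site's baseline mean; pure-tumor
    means carry the regional hypermethylation and global shift; an
    observed tumor sample with purity p mixes the two signals as
    ``p * tumor + (1 - p) * control`` before noise.  Per-sample
    heterogeneity enters as a small jitter on bivalent-region means and
    on the array-wide level; values are Beta-distributed around the
    (clipped) means, so they stay in [0, 1] without truncation
    artifacts.  Returns ``(BetaMatrix, purities)``.
    """
    from .methylation import BetaMatrix

    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n_sites = len(sites)
    base = sites["base_mean"].to_numpy()
    tmean = sites["tumor_mean"].to_numpy()
    biv_mask = (sites["klass"] != "background").to_numpy()

    if purity is None:
        p = rng.beta(config.purity_alpha, config.purity_beta, size=config.n_tumor)
    elif np.isscalar(purity):
        p = np.full(config.n_tumor, float(purity))
    else:
        p = np.asarray(purity, dtype=float)
        if len(p) != config.n_tumor:
            raise ValueError("purity vector length must equal n_tumor")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("purity must lie in [0, 1]")

    tumor_ids = [f"T{i:03d}" for i in range(config.n_tumor)]
    control_ids = [f"N{i:03d}" for i in range(config.n_normal)]
    n_total = config.n_tumor + config.n_normal

    means = np.empty((n_sites, n_total))
    means[:, : config.n_tumor] = base[:, None] + p[None, :] * (tmean - base)[:, None]
    means[:, config.n_tumor:] = base[:, None]

    glob_jit = rng.normal(0.0, config.sample_global_sd, size=n_total)
    biv_jit = rng.normal(0.0, config.sample_biv_sd, size=n_total)
    means = means + glob_jit[None, :]
    means[biv_mask] += biv_jit[None, :]
    means = np.clip(means, 0.01, 0.99)

    k = config.beta_concentration
    values = rng.beta(means * k, (1 - means) * k)
    if config.missing_rate > 0:
        drop = rng.random(values.shape) < config.missing_rate
        values = np.where(drop, np.nan, values)

    cols = tumor_ids + control_ids
    vdf = pd.DataFrame(values, index=sites.index, columns=cols)
    groups = pd.Series(
        ["tumor"] * config.n_tumor + ["control"] * config.n_normal, index=cols
    )
    beta = BetaMatrix(sites=sites[["chrom", "pos"]].copy(), values=vdf, groups=groups)
    purities = pd.Series(p, index=tumor_ids)
    return beta, purities


def simulate_de(
    config: SimConfig, truth: SimTruth, seed: int | None = None
) -> pd.DataFrame:
    """Simulate one cancer's differential-expression table.

    Per gene, a true log2 fold change (bivalent-segment genes shifted by
    ``fbs_log2fc_shift``, background genes by
    ``background_log2fc_shift``) is optionally coupled to that gene's
    true methylation change via ``rho`` (standardised; rho=0 gives
    independence).  Observed log2fc and p-values come from a two-group
    t-test on ``de_nrep`` simulated per-group replicates, with
    Benjamini-Hochberg FDR, so significance behaves like a real DE
    analysis rather than being assigned.
    """
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    gene_ids = list(truth.gene_true_dmeth.index)
    is_fbs = np.array([g in truth.fbs_genes for g in gene_ids])
    dmeth = truth.gene_true_dmeth.to_numpy()

    true_fc = np.where(is_fbs, config.fbs_log2fc_shift, config.background_log2fc_shift)
    if config.rho > 0:
        # standardise within gene group so the coupling adds dependence
        # beyond the group-mean structure without moving the group means
        z = np.zeros_like(dmeth)
        for mask in (is_fbs, ~is_fbs):
            if mask.sum() > 1 and np.std(dmeth[mask]) > 0:
                z[mask] = (dmeth[mask] - dmeth[mask].mean()) / dmeth[mask].std()
        true_fc = true_fc + config.rho * z

    nrep = config.de_nrep
    normal_reps = rng.normal(0.0, config.de_sd, size=(len(gene_ids), nrep))
    tumor_reps = rng.normal(true_fc[:, None], config.de_sd, size=(len(gene_ids), nrep))
    log2fc = tumor_reps.mean(axis=1) - normal_reps.mean(axis=1)
    _, pvals = stats.ttest_ind(tumor_reps, normal_reps, axis=1)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")

    lowly_p = np.where(is_fbs, config.lowly_fraction, config.background_lowly_fraction)
    lowly = rng.random(len(gene_ids)) < lowly_p
    logcpm = np.where(
        lowly,
        rng.normal(-1.5, 0.8, size=len(gene_ids)),
        rng.normal(2.5, 1.5, size=len(gene_ids)).clip(min=0.05),
    )
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "logcpm_normal": logcpm,
        }
    )
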