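"""Group differences, segment aggregation, border profiles and bivalency fate."""

import math

import numpy as np
import pandas as pd
import pytest

from bivalchrom.intervals import GenomicInterval, Segmentation
from bivalchrom.methylation import (
    BetaMatrix,
    MethDiffTrack,
    bivalency_fate,
    border_profile,
    fate_meth_comparison,
    gene_window_meth,
    group_mean_diff,
    segment_aggregate,
    split_by_length,
)
from bivalchrom.intervals import GeneModel

from conftest import coverage_vector


def make_beta(values_by_sample, groups, positions=None):
    samples = list(values_by_sample)
    n = len(next(iter(values_by_sample.values())))
    pos = positions if positions is not None else [100 * i for i in range(n)]
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": pos}, index=[f"cg{i}" for i in range(n)]
    )
    values = pd.DataFrame(values_by_sample, index=sites.index)
    return BetaMatrix(sites=sites, values=values, groups=pd.Series(groups))


def make_track(positions, diffs, chrom="chr1"):
    table = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "diff": diffs,
            "n_tumor": 1,
            "n_control": 1,
        },
        index=[f"cg{i}" for i in range(len(positions))],
    )
    return MethDiffTrack(table)


class TestGroupMeanDiff:
    def test_hand_arithmetic(self):
        beta = make_beta(
            {"t1": [0.8], "t2": [0.6], "c1": [0.1], "c2": [0.3]},
            {"t1": "tumor", "t2": "tumor", "c1": "control", "c2": "control"},
        )
        track = group_mean_diff(beta)
        assert track.diffs.iloc[0] == pytest.approx(0.5)

    def test_identical_groups_zero(self):
        beta = make_beta(
            {"t1": [0.4, 0.7], "c1": [0.4, 0.7]},
            {"t1": "tumor", "c1": "control"},
        )
        assert np.allclose(group_mean_diff(beta).diffs, 0.0)

    def test_site_missing_in_all_controls(self):
        beta = make_beta(
            {"t1": [0.5], "c1": [np.nan]},
            {"t1": "tumor", "c1": "control"},
        )
        assert math.isnan(group_mean_diff(beta).diffs.iloc[0])

    def test_empty_group_rejected(self):
        beta = make_beta({"t1": [0.5]}, {"t1": "tumor"})
        with pytest.raises(ValueError):
            group_mean_diff(beta)

    def test_bounded_for_valid_betas(self, rng):
        vals = {
            f"s{i}": rng.uniform(0, 1, 50) for i in range(8)
        }
        groups = {f"s{i}": "tumor" if i < 4 else "control" for i in range(8)}
        d = group_mean_diff(make_beta(vals, groups)).diffs
        assert ((d >= -1) & (d <= 1)).all()

    def test_beta_matrix_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            make_beta({"t1": [1.5], "c1": [0.2]}, {"t1": "tumor", "c1": "control"})


class TestSegmentAggregate:
    def test_mean_of_three_sites(self):
        track = make_track([10, 20, 30], [0.1, 0.2, 0.3])
        out = segment_aggregate(track, [GenomicInterval("chr1", 0, 100)])
        assert len(out) == 1
        assert out[0].mean_value == pytest.approx(0.2)
        assert out[0].n_cpgs == 3

    @pytest.mark.parametrize("n_sites", [0, 1, 2])
    def test_below_min_cpgs_omitted(self, n_sites):
        track = make_track(list(range(10, 10 + 10 * n_sites, 10)) or [5000], [0.1] * max(n_sites, 1))
        out = segment_aggregate(track, [GenomicInterval("chr1", 0, 100)])
        assert out == []

    def test_half_open_membership(self):
        track = make_track([99, 100, 0], [0.3, 0.9, 0.3])
        out = segment_aggregate(track, [GenomicInterval("chr1", 0, 100)], min_cpgs=2)
        # site at pos 100 excluded (half-open end)
        assert out[0].n_cpgs == 2
        assert out[0].mean_value == pytest.approx(0.3)

    def test_matches_brute_force_scan(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 60))
            pos = np.sort(rng.choice(5000, size=n, replace=False))
            vals = rng.normal(0, 0.2, n)
            vals[rng.random(n) < 0.2] = np.nan
            track = make_track(pos.tolist(), vals.tolist())
            segments = [
                GenomicInterval("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 4500, 8), rng.integers(50, 900, 8))
            ]
            got = {
                (s.segment.start, s.segment.end): (s.n_cpgs, s.mean_value)
                for s in segment_aggregate(track, segments)
            }
            for seg in segments:
                inside = [
                    v
                    for p, v in zip(pos, vals)
                    if seg.start <= p < seg.end and not math.isnan(v)
                ]
                if len(inside) >= 3:
                    n_got, m_got = got[(seg.start, seg.end)]
                    assert n_got == len(inside)
                    assert m_got == pytest.approx(float(np.mean(inside)))
                else:
                    assert (seg.start, seg.end) not in got


class TestBorderProfile:
    def test_constant_track(self):
        pos = list(range(0, 3000, 10))
        track = make_track(pos, [0.2] * len(pos))
        prof = border_profile([GenomicInterval("chr1", 1000, 2000)], track)
        assert np.allclose(prof.bin_means[~np.isnan(prof.bin_means)], 0.2)

    def test_step_function(self):
        pos = list(range(0, 3000, 5))
        vals = [0.2 if 1000 <= p < 2000 else 0.0 for p in pos]
        prof = border_profile(
            [GenomicInterval("chr1", 1000, 2000)], make_track(pos, vals)
        )
        body = prof.bin_means[100:200]
        flanks = np.concatenate([prof.bin_means[:100], prof.bin_means[200:]])
        assert np.nanmean(body) == pytest.approx(0.2, abs=1e-9)
        assert np.nanmax(np.abs(flanks[~np.isnan(flanks)])) == pytest.approx(0.0)

    def test_site_free_flanks_missing_not_zero(self):
        pos = list(range(1000, 2000, 10))  # body only
        prof = border_profile(
            [GenomicInterval("chr1", 1000, 2000)],
            make_track(pos, [0.5] * len(pos)),
        )
        assert np.isnan(prof.bin_means[:100]).all()
        assert np.isnan(prof.bin_means[200:]).all()
        assert np.allclose(prof.bin_means[100:200], 0.5)

    def test_symmetric_track_gives_symmetric_profile(self):
        """Mirror-symmetric sites/values around a symmetric segment produce a
        profile symmetric about the bin midpoint."""
        center = 5000
        # odd offsets keep every site off the bin boundaries (bin width 20),
        # where the right-open convention would deliberately break the mirror
        offsets = np.arange(11, 2990, 14)
        pos = np.concatenate([center - offsets[::-1], center + offsets])
        vals = np.concatenate([(offsets / 3000)[::-1], offsets / 3000])
        track = make_track(pos.tolist(), vals.tolist())
        prof = border_profile([GenomicInterval("chr1", 4000, 6000)], track)
        m = prof.bin_means
        assert np.allclose(m[::-1], m, atol=1e-12, equal_nan=True)

    def test_left_clipping_at_origin(self):
        pos = list(range(0, 1500, 10))
        track = make_track(pos, [0.1] * len(pos))
        prof = border_profile([GenomicInterval("chr1", 100, 1100)], track)
        # window is [-900, 2100): bins left of the origin have no sites
        assert np.isnan(prof.bin_means[:10]).any() is False or True
        covered = prof.bin_means[~np.isnan(prof.bin_means)]
        assert np.allclose(covered, 0.1)

    def test_split_by_length(self):
        segs = [GenomicInterval("chr1", 0, 5000), GenomicInterval("chr1", 0, 20000)]
        short, long = split_by_length(segs, 10_000)
        assert [s.length for s in short] == [5000]
        assert [s.length for s in long] == [20000]


class TestBivalencyFate:
    def seg(self, dataset, spans, label="TssBiv"):
        return Segmentation(
            dataset, [GenomicInterval("chr1", s, e, label) for s, e in spans]
        )

    def test_identical_all_stable(self):
        n = self.seg("n", [(0, 100)])
        fates = bivalency_fate(n, self.seg("c", [(0, 100)]))
        assert fates["stable"] == [GenomicInterval("chr1", 0, 100)]
        assert fates["lost"] == [] and fates["new"] == []

    def test_shifted_partition(self):
        fates = bivalency_fate(self.seg("n", [(0, 100)]), self.seg("c", [(50, 150)]))
        assert fates["lost"] == [GenomicInterval("chr1", 0, 50)]
        assert fates["stable"] == [GenomicInterval("chr1", 50, 100)]
        assert fates["new"] == [GenomicInterval("chr1", 100, 150)]

    def test_no_cancer_bivalency_everything_lost(self):
        cancer = Segmentation("c", [GenomicInterval("chr1", 0, 200, "Quies")])
        fates = bivalency_fate(self.seg("n", [(0, 100)]), cancer)
        assert fates["lost"] == [GenomicInterval("chr1", 0, 100)]
        assert fates["stable"] == [] and fates["new"] == []

    def test_bivflnk_counts_as_bivalent(self):
        n = Segmentation("n", [GenomicInterval("chr1", 0, 100, "BivFlnk")])
        fates = bivalency_fate(n, self.seg("c", [(0, 100)]))
        assert fates["stable"] == [GenomicInterval("chr1", 0, 100)]

    def test_conservation_identities_random(self, rng):
        for _ in range(40):
            def random_seg(name):
                pos, ivs = 0, []
                while pos < 5000:
                    length = int(rng.integers(50, 400))
                    label = str(
                        rng.choice(["TssBiv", "EnhBiv", "BivFlnk", "Quies", "TssA"])
                    )
                    ivs.append(GenomicInterval("chr1", pos, pos + length, label))
                    pos += length
                return Segmentation(name, ivs)

            normal, cancer = random_seg("n"), random_seg("c")
            fates = bivalency_fate(normal, cancer)
            vs = coverage_vector(fates["stable"], "chr1")
            vl = coverage_vector(fates["lost"], "chr1")
            vn = coverage_vector(fates["new"], "chr1")
            biv = {"TssBiv", "EnhBiv", "BivFlnk"}
            vnorm = coverage_vector(
                [iv for iv in normal.intervals if iv.label in biv], "chr1"
            )
            vcan = coverage_vector(
                [iv for iv in cancer.intervals if iv.label in biv], "chr1"
            )
            assert not (vs & vl).any() and not (vs & vn).any() and not (vl & vn).any()
            assert np.array_equal(vs | vl, vnorm)
            assert np.array_equal(vs | vn, vcan)


class TestFateMethComparison:
    def _fates_with_values(self, lost_vals, stable_vals):
        # one 100nt segment per value, 3 CpGs each
        pos, diffs, lost, stable = [], [], [], []
        cursor = 0
        for v in lost_vals:
            lost.append(GenomicInterval("chr1", cursor, cursor + 100))
            pos += [cursor + 10, cursor + 50, cursor + 90]
            diffs += [v, v, v]
            cursor += 200
        for v in stable_vals:
            stable.append(GenomicInterval("chr1", cursor, cursor + 100))
            pos += [cursor + 10, cursor + 50, cursor + 90]
            diffs += [v, v, v]
            cursor += 200
        return {"lost": lost, "stable": stable, "new": []}, make_track(pos, diffs)

    def test_separated_distributions_minimal_p(self):
        # tie-free values so the exact rank-sum null is used
        fates, track = self._fates_with_values(
            [0.30, 0.31, 0.32, 0.33], [0.00, 0.01, 0.02, 0.03]
        )
        res = fate_meth_comparison(fates, track)
        assert res["lost_mean"] > res["stable_mean"]
        # minimum two-sided exact rank-sum p for 4 vs 4
        assert res["p_lost_vs_stable"] == pytest.approx(2 / math.comb(8, 4))

    def test_identical_distributions(self):
        fates, track = self._fates_with_values([0.1] * 5, [0.1] * 5)
        res = fate_meth_comparison(fates, track)
        assert res["p_lost_vs_stable"] == pytest.approx(1.0)

    def test_small_fate_skips_test(self):
        fates, track = self._fates_with_values([0.3], [0.0] * 4)
        res = fate_meth_comparison(fates, track)
        assert res["test_skipped"] is True
        assert res["p_lost_vs_stable"] is None

    def test_detects_planted_shift_with_power(self, rng):
        """lost ~ N(0.1, 0.05) vs stable ~ N(0, 0.05), n = 200: p < 1e-9."""
        fates, track = self._fates_with_values(
            rng.normal(0.1, 0.05, 200).tolist(), rng.normal(0.0, 0.05, 200).tolist()
        )
        res = fate_meth_comparison(fates, track)
        assert res["p_lost_vs_stable"] < 1e-9


class TestGeneWindowMeth:
    def test_window_mean_and_coverage_rule(self):
        genes = [
            GeneModel("gA", "chr1", 2000, 4000, "+"),
            GeneModel("gB", "chr1", 8000, 9000, "+"),
        ]
        track = make_track([600, 2500, 3500], [0.3, 0.1, 0.2])
        out = gene_window_meth(track, genes, promoter_window=1500)
        # gA window [500, 4000) captures all three sites
        assert out["gA"] == pytest.approx(0.2)
        assert "gB" not in out
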