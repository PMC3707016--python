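"""z-score formulas, cross-validated null distribution, clustering."""

import numpy as np
import pytest
from scipy import stats

from plasmacnv.errors import CohortError
from plasmacnv.segmentation import CbsParams, Segment, SegmentationResult
from plasmacnv.zscores import (
    bin_profile,
    cluster_samples,
    cohort_loo_z,
    cohort_s_scores,
    genome_wide_z,
    manhattan_distance_matrix,
    region_z,
    s_score,
    sample_window_z,
    segmental_z,
    significant_fraction,
    smallest_subtree_containing,
    to_newick,
    window_z,
)

from conftest import make_profile


def _segment(lo, hi, chrom="chr1"):
    return Segment(chrom, lo, hi, lo * 100, hi * 100, 0.0, 0.0, hi - lo)


def _one_segment_result(lo, hi):
    return SegmentationResult([_segment(lo, hi)], CbsParams())


class TestWindowZ:
    def test_sample_equal_to_control_means_gives_zero(self):
        controls = np.array([[0.9, 1.1], [1.0, 1.0], [1.1, 0.9]])
        z = sample_window_z(controls.mean(axis=0), controls)
        np.testing.assert_allclose(z, 0.0)

    def test_hand_computed_z_of_three(self):
        controls = np.array([[0.9], [1.0], [1.1]])
        z = sample_window_z(np.array([1.3]), controls)
        assert z[0] == pytest.approx(3.0, abs=1e-9)

    def test_leave_one_out_excludes_self(self):
        controls = np.array([[1.0], [2.0], [3.0], [10.0]])
        zp = window_z(controls[3], controls, cross_validate_index=3)
        rest = controls[:3, 0]
        expect = (10.0 - rest.mean()) / rest.std(ddof=1)
        assert zp.z[0] == pytest.approx(expect, abs=1e-12)
        assert zp.cross_validated

    def test_zero_sd_window_flagged_missing(self):
        controls = np.array([[1.0, 1.0], [1.0, 1.2], [1.0, 0.8]])
        z = sample_window_z(np.array([2.0, 1.0]), controls)
        assert np.isnan(z[0]) and np.isfinite(z[1])

    def test_loo_null_z_matches_scaled_t(self):
        """Cross-validated z of a null control follows sqrt(n/(n-1)) * t(n-2)."""
        rng = np.random.default_rng(3)
        n = 10
        controls = rng.normal(1.0, 0.05, size=(n, 10_000))
        z = cohort_loo_z(controls)[0]  # one control: independent draws across windows
        ref = stats.t(df=n - 2, scale=np.sqrt(n / (n - 1)))
        assert stats.kstest(z, ref.cdf).pvalue > 0.01


class TestSignificantFraction:
    def test_all_zero(self):
        frac, count = significant_fraction(np.zeros(10))
        assert frac == 1.0 and count == 0

    def test_mixed_vector(self):
        frac, count = significant_fraction(np.array([-4.0, 0.0, 4.0, 1.0]))
        assert frac == 0.5 and count == 2

    def test_null_outlier_count_matches_scaled_t_tail(self):
        """Expected |z|>3 count under the LOO null equals the scaled-t tail."""
        rng = np.random.default_rng(4)
        n, m = 10, 2909
        controls = rng.normal(1.0, 0.03, size=(n, m))
        counts = [significant_fraction(z)[1] for z in cohort_loo_z(controls)]
        scale = np.sqrt(n / (n - 1))
        expect = m * 2 * stats.t(df=n - 2).sf(3.0 / scale)
        assert np.mean(counts) == pytest.approx(expect, rel=0.35)


class TestSegmentalZ:
    def test_sample_equal_to_a_control(self):
        rng = np.random.default_rng(5)
        controls = [make_profile(np.zeros(30), ratio=rng.normal(1, 0.05, 30)) for _ in range(5)]
        res = _one_segment_result(5, 25)
        out = segmental_z(controls[0], res, controls[1:] + [controls[0]])
        assert abs(out[0].z) < 1.5  # its own sum sits inside the cohort spread

    def test_constructed_shift_formula(self):
        """20-window segment, controls flat at 1, sample at 1.1 -> z = 2/s."""
        rng = np.random.default_rng(6)
        n_ctrl, m = 10, 40
        noise = rng.normal(0, 0.02, size=(n_ctrl, m))
        controls = noise + 1.0
        res = _one_segment_result(10, 30)
        sample = make_profile(np.zeros(m), ratio=np.full(m, 1.1))
        out = segmental_z(sample, res, controls)
        sums = controls[:, 10:30].sum(axis=1)
        s = sums.std(ddof=1)
        expect = (20 * 1.1 - sums.mean()) / s
        assert out[0].z == pytest.approx(expect, abs=1e-9)
        assert out[0].z == pytest.approx(2.0 / s, rel=0.15)

    def test_monotone_in_gain(self):
        rng = np.random.default_rng(7)
        controls = rng.normal(1, 0.05, size=(6, 50))
        res = _one_segment_result(10, 30)
        base = make_profile(np.zeros(50), ratio=np.ones(50))
        z0 = segmental_z(base, res, controls)[0].z
        gained = np.ones(50)
        gained[10:30] += 0.05
        z1 = segmental_z(make_profile(np.zeros(50), ratio=gained), res, controls)[0].z
        assert z1 > z0

    def test_trisomy_like_chromosome_stands_out(self):
        """A 10% fetal/tumor fraction trisomy lifts only that chromosome's segment."""
        rng = np.random.default_rng(8)
        m = 300
        sd = 0.01  # ~3M reads over ~300 windows scale of counting noise
        controls = rng.normal(1, sd, size=(10, m))
        sample_ratio = rng.normal(1, sd, m)
        sample_ratio[200:250] = rng.normal(1.05, sd, 50)  # trisomic chromosome at +5%
        sample = make_profile(np.zeros(m), ratio=sample_ratio)
        segs = SegmentationResult(
            [_segment(0, 200), _segment(200, 250), _segment(250, 300)], CbsParams()
        )
        out = segmental_z(sample, segs, controls)
        assert out[1].z > 3
        assert abs(out[0].z) < 3 and abs(out[2].z) < 3


class TestRegionZ:
    def test_reads_expected_proportionality(self):
        out = region_z(
            ("chr1", 0, 1_000_000, "AR"),
            reads_region=10_500,
            reads_total=1_000_000,
            control_reads_region=np.array([9_900, 10_000, 10_100]),
            control_reads_total=np.array([1_000_000] * 3),
            length_genome=100_000_000,
        )
        assert out.reads_expected == pytest.approx(10_000.0, abs=1e-9)

    def test_hand_computed_region_z(self):
        out = region_z(
            ("chr1", 0, 1_000_000, "AR"),
            reads_region=13_000,
            reads_total=1_000_000,
            control_reads_region=np.array([9_000, 10_000, 11_000]),
            control_reads_total=np.array([1_000_000] * 3),
            length_genome=100_000_000,
        )
        # control ratios 0.9/1.0/1.1, sample 1.3 -> z = 3
        assert out.ratio == pytest.approx(1.3)
        assert out.z == pytest.approx(3.0, abs=1e-9)

    def test_null_calibration(self):
        """Diploid draws at expectation keep |z| < 3 in >= 99% of replicates."""
        rng = np.random.default_rng(9)
        n_rep, expected = 1000, 5_000
        hits = 0
        for _ in range(n_rep):
            ctrl = rng.poisson(expected, size=50)
            reads = rng.poisson(expected)
            out = region_z(
                ("chr1", 0, 500_000, "R"),
                reads_region=int(reads),
                reads_total=1_000_000,
                control_reads_region=ctrl,
                control_reads_total=np.full(50, 1_000_000),
                length_genome=100_000_000,
            )
            hits += abs(out.z) < 3
        assert hits / n_rep >= 0.99

    def test_agrees_with_segmental_z_on_identical_region(self):
        """When a region coincides with a segment and ratios are count-derived
        identically, the region and segmental z-scores are equal."""
        rng = np.random.default_rng(10)
        m, n_ctrl = 40, 8
        span = 1000
        counts = rng.poisson(500, size=(n_ctrl + 1, m))
        # window ratios = count / mean count (no GC term)
        ratios = counts / counts.mean(axis=1, keepdims=True)
        sample_ratio, ctrl_ratio = ratios[0], ratios[1:]
        res = _one_segment_result(10, 30)
        seg_z = segmental_z(
            make_profile(np.zeros(m), ratio=sample_ratio), res, ctrl_ratio
        )[0].z
        reg = region_z(
            ("chr1", 10 * span, 30 * span, "seg"),
            reads_region=int(counts[0, 10:30].sum()),
            reads_total=int(counts[0].sum()),
            control_reads_region=counts[1:, 10:30].sum(axis=1),
            control_reads_total=counts[1:].sum(axis=1),
            length_genome=m * span,
        )
        assert reg.z == pytest.approx(seg_z, abs=1e-9)


class TestGenomeWide:
    def test_s_of_zero_vector(self):
        assert s_score(np.zeros(5)) == 0.0

    def test_s_is_sum_of_squares(self):
        assert s_score(np.array([3.0, 4.0])) == pytest.approx(25.0, abs=1e-12)

    def test_hand_computed_genome_wide_z(self):
        out = genome_wide_z(24.0, np.array([10.0, 12.0, 14.0]))
        assert out.genome_wide_z == pytest.approx(6.0, abs=1e-9)

    def test_zero_spread_control_s_rejected(self):
        with pytest.raises(CohortError):
            genome_wide_z(5.0, np.array([2.0, 2.0, 2.0]))

    def test_cohort_s_scores_match_direct_loo(self):
        rng = np.random.default_rng(11)
        controls = rng.normal(1, 0.05, size=(6, 100))
        s = cohort_s_scores(controls)
        rest = np.delete(controls, 2, axis=0)
        direct = s_score(sample_window_z(controls[2], rest))
        assert s[2] == pytest.approx(direct, rel=1e-12)


class TestClustering:
    def test_two_window_toy_distance(self):
        d = manhattan_distance_matrix(np.array([[0.0, 0.0], [1.0, 2.0]]))
        assert d[0, 1] == pytest.approx(3.0)

    def test_duplicates_merge_first_at_zero_height(self):
        z = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        link = cluster_samples(z)
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}
        assert link[0, 2] == 0.0

    def test_metric_axioms_on_random_profiles(self):
        rng = np.random.default_rng(12)
        z = rng.normal(size=(6, 30))
        d = manhattan_distance_matrix(z)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        for a in range(6):
            for b in range(6):
                for c in range(6):
                    assert d[a, c] <= d[a, b] + d[b, c] + 1e-9

    def test_planted_signature_separates_groups(self):
        """Flat nulls and samples sharing an 8q-like gain form disjoint subtrees."""
        rng = np.random.default_rng(13)
        m = 200
        nulls = rng.normal(0, 1, size=(5, m))
        gained = rng.normal(0, 1, size=(5, m))
        gained[:, 150:180] += 8.0  # shared arm-gain z signature
        zmat = np.vstack([nulls, gained])
        link = cluster_samples(zmat)
        assert smallest_subtree_containing(link, 10, set(range(5))) == set(range(5))
        assert smallest_subtree_containing(link, 10, set(range(5, 10))) == set(range(5, 10))

    def test_newick_round_trip_parses(self):
        rng = np.random.default_rng(14)
        link = cluster_samples(rng.normal(size=(4, 10)))
        text = to_newick(link, ["a", "b", "c", "d"])
        assert text.endswith(";") and text.count(",") == 3
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(text), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["a", "b", "c", "d"]


class TestBinProfile:
    def test_bins_aggregate_by_midpoint(self):
        prof = make_profile(np.zeros(10), ratio=np.arange(10, dtype=float))
        bins, values = bin_profile(prof, bin_size=500)
        assert len(bins) == 2
        np.testing.assert_allclose(values, [2.0, 7.0])
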