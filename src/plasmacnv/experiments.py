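"""Desk-scale validation experiments.

Each function runs one self-contained study on synthetic data - the
detection-limit ROC, the null calibration of the genome-wide z-score, the
serial-dilution analysis, window-construction properties, CBS calibration
and the split-read recovery study - and returns its headline numbers as a
dict.  The experiments are seeded and sized so the full battery completes in
minutes on one CPU; the methods note documents the chosen problem sizes.

Shared study conditions: per-window baseline noise is calibrated to 3 million
reads (the throughput of roughly a quarter of a benchtop sequencing run)
spread over the 1-Mbp-scale z-score windows.
"""

from __future__ import annotations

import numpy as np

from . import simulate, zscores
from .coverage import RatioProfile
from .reference import ReferenceGenome, build_windows, mappability_track, revcomp
from .segmentation import CbsParams, cbs_segment
from .fixtures import FusionSpec, fusion_junction_truth, fusion_reads, random_genome
from .fusion import KmerIndex, detect_fusions, split_read

N_READS = 3_000_000  # depth to which baseline noise is calibrated
M_WINDOWS = 400  # z-score windows at desk scale


def _baseline(m: int = M_WINDOWS) -> tuple[np.ndarray, np.ndarray]:
    sd = simulate.counting_noise_sd(N_READS, m)
    return np.ones(m), np.full(m, sd)


def detection_limit_experiment(
    seed: int, lam: float = 0.10, n_tumors: int = 20, n_controls: int = 100
) -> dict:
    """ROC of the genome-wide z at one tumor-DNA fraction (default 10%)."""
    mean, sd = _baseline()
    rng = np.random.default_rng(seed)
    tumors = [simulate.prostate_like_profile(M_WINDOWS, rng) for _ in range(n_tumors)]
    table = simulate.detection_limit(tumors, [lam], n_controls, mean, sd, seed=seed)
    row = table.iloc[0]
    return {
        "lambda": lam,
        "sensitivity": float(row["sensitivity"]),
        "specificity": float(row["specificity"]),
        "auc": float(row["auc"]),
        "n": n_tumors + n_controls,
    }


def null_calibration_experiment(
    seed: int, n_samples: int = 500, n_cohort: int = 100
) -> dict:
    """Genome-wide z of held-out null samples: mean ~ 0, ~all within +-3."""
    mean, sd = _baseline()
    rng = np.random.default_rng(seed)
    cohort = simulate.simulate_cohort(mean, sd, n_cohort, rng)
    nulls = simulate.simulate_cohort(mean, sd, n_samples, rng)
    scores = zscores.genome_wide_scores(nulls, cohort)
    loo = zscores.cohort_loo_z(cohort)
    fraction_normal = float(
        np.mean([zscores.significant_fraction(z)[0] for z in loo])
    )
    return {
        "mean_z": float(scores.mean()),
        "fraction_within_3": float(np.mean(np.abs(scores) < 3)),
        "max_z": float(scores.max()),
        "min_z": float(scores.min()),
        "fraction_normal_windows": fraction_normal,
        "n": n_samples,
    }


def dilution_experiment(
    seed: int,
    lams: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2, 0.5),
    n_controls: int = 100,
    n_cases_at_1pct: int = 20,
) -> dict:
    """Serial in-silico dilution of a heavily aberrant cell-line-like profile.

    Reports the mean genome-wide z of 1% dilutions against the maximum of
    the simulated controls, and whether the whole dilution series falls
    outside the control subtree under Manhattan-distance clustering.
    """
    mean, sd = _baseline()
    rng = np.random.default_rng(seed)
    tumor = simulate.aggressive_profile(M_WINDOWS)
    cohort = simulate.simulate_cohort(mean, sd, n_controls, rng)
    control_s = zscores.cohort_s_scores(cohort)
    control_scores = (control_s - control_s.mean()) / control_s.std(ddof=1)

    cases_1pct = np.vstack(
        [
            simulate.simulate_case(tumor, 0.01, mean, sd, rng)
            for _ in range(n_cases_at_1pct)
        ]
    )
    case_scores = zscores.genome_wide_scores(cases_1pct, cohort)

    # dendrogram: 20 held-out controls + the dilution series
    heldout = simulate.simulate_cohort(mean, sd, 20, rng)
    series = np.vstack(
        [simulate.simulate_case(tumor, lam, mean, sd, rng) for lam in lams]
    )
    zmat = np.vstack(
        [
            np.vstack([zscores.sample_window_z(x, cohort) for x in heldout]),
            np.vstack([zscores.sample_window_z(x, cohort) for x in series]),
        ]
    )
    link = zscores.cluster_samples(zmat)
    control_leaves = set(range(20))
    subtree = zscores.smallest_subtree_containing(link, zmat.shape[0], control_leaves)
    return {
        "mean_case_z_at_1pct": float(case_scores.mean()),
        "control_max_z": float(control_scores.max()),
        "dilution_series_outside_control_subtree": subtree == control_leaves,
        "n": n_controls + n_cases_at_1pct + len(lams) + 20,
    }


def _brute_force_unique(genome: ReferenceGenome, k: int) -> dict[str, np.ndarray]:
    """All-k-mers dictionary oracle, independent of the rolling-hash path."""
    from collections import Counter

    counts: Counter = Counter()
    for seq in genome.sequences.values():
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if "N" not in kmer:
                    counts[kmer] += 1
    out = {}
    for name, seq in genome.sequences.items():
        track = np.zeros(len(seq), bool)
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            track[i] = "N" not in kmer and counts[kmer] == 1
        out[name] = track
    return out


def window_experiment(seed: int) -> dict:
    """Window-grid properties on a synthetic genome + oracle agreement (<=50 kb)."""
    rng = np.random.default_rng(seed)
    genome = random_genome({"chr1": 200_000}, rng)
    track = mappability_track(genome, 150)
    ws = build_windows(track, 50)
    counts = ws.frame["n_mappable"].to_numpy()
    coverage_ok = int(counts.sum()) == track.total_mappable

    small = random_genome({"c1": 30_000, "c2": 20_000}, rng)
    # plant a duplication so the oracle has non-trivial repeats to agree on
    seq = small.sequences["c1"]
    small = ReferenceGenome(
        {"c1": seq[:25_000] + seq[1_000:1_500] + seq[25_500:], "c2": small.sequences["c2"]}
    )
    fast = mappability_track(small, 150)
    brute = _brute_force_unique(small, 150)
    agree = all(
        bool(np.array_equal(fast.tracks[name], brute[name])) for name in small.names
    )
    return {
        "max_count_deviation": int(counts.max() - counts.min()),
        "coverage_complete": coverage_ok,
        "oracle_agreement": float(agree),
        "n": len(ws),
    }


def cbs_experiment(
    seed: int, n_noise_runs: int = 12, n_recovery_runs: int = 20
) -> dict:
    """CBS validity: oracle steps, false-split rate, diluted-deletion recovery."""
    from .reference import WindowSet
    import pandas as pd

    def make_profile(log2):
        n = len(log2)
        frame = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n) * 56_000,
                "end": (np.arange(n) + 1) * 56_000,
                "n_mappable": 1,
                "gc": 0.5,
            }
        )
        return RatioProfile(WindowSet(frame), np.exp2(log2), np.asarray(log2, float))

    # noiseless steps vs the exact boundary
    rng = np.random.default_rng(seed)
    exact = 0
    n_exact = 6
    for k in range(n_exact):
        n = int(rng.integers(40, 200))
        cut = int(rng.integers(5, n - 5))
        log2 = np.zeros(n)
        log2[cut:] = 1.0
        res = cbs_segment(make_profile(log2), CbsParams(n_permutations=200, seed=seed + k))
        exact += [(s.start_index, s.end_index) for s in res.segments] == [
            (0, cut),
            (cut, n),
        ]

    false_splits = 0
    for k in range(n_noise_runs):
        rngk = np.random.default_rng(seed + 1000 + k)
        prof = make_profile(rngk.normal(0, 0.1, 300))
        res = cbs_segment(prof, CbsParams(alpha=0.01, n_permutations=1000, seed=seed + k))
        false_splits += len(res.segments) > 1

    # 3-Mbp-scale deletion (ratio 0.5) at lambda = 0.5 over ~50 windows of 56 kb
    mean, sdv = _baseline(300)
    recovered = 0
    for k in range(n_recovery_runs):
        rngk = np.random.default_rng(seed + 2000 + k)
        controls = simulate.simulate_cohort(mean, sdv, 10, rngk)
        tumor = np.ones(300)
        tumor[140:193] = 0.5  # ~3 Mbp at 56 kb windows
        case_ratio = simulate.simulate_case(
            simulate.TumorProfile(tumor), 0.5, mean, sdv, rngk
        )
        base_mean = controls.mean(axis=0)
        with np.errstate(divide="ignore"):
            log2 = np.log2(case_ratio / base_mean)
        prof = make_profile(log2)
        prof = RatioProfile(prof.windows, case_ratio, prof.log2)
        res = cbs_segment(prof, CbsParams(n_permutations=500, seed=seed + k))
        scores = zscores.segmental_z(prof, res, controls)
        hit = [
            r
            for r in scores
            if r.segment.start_index <= 145
            and r.segment.end_index >= 188
            and r.segment.n_windows <= 120
            and r.z < -3
        ]
        recovered += bool(hit)
    return {
        "step_oracle_agreement": exact / n_exact,
        "false_split_rate": false_splits / n_noise_runs,
        "deletion_recovery_rate": recovered / n_recovery_runs,
        "n": n_recovery_runs,
    }


def zscore_oracle_experiment() -> dict:
    """Exact hand-computed checks of every z-score formula."""
    z3 = zscores.sample_window_z(np.array([1.3]), np.array([[0.9], [1.0], [1.1]]))[0]
    expected = zscores.region_z(
        ("chr1", 0, 1_000_000, "R"),
        reads_region=10_000,
        reads_total=1_000_000,
        control_reads_region=np.array([9_900, 10_000, 10_100]),
        control_reads_total=np.array([1_000_000] * 3),
        length_genome=100_000_000,
    ).reads_expected
    s = zscores.s_score(np.array([3.0, 4.0]))
    gw = zscores.genome_wide_z(24.0, np.array([10.0, 12.0, 14.0])).genome_wide_z
    return {
        "z_constructed": float(z3),
        "reads_expected_toy": float(expected),
        "s_of_3_4": float(s),
        "genome_wide_z_toy": float(gw),
        "n": 4,
    }


def fusion_experiment(
    seed: int, n_junctions: int = 20, n_concordant: int = 10_000
) -> dict:
    """Recovery of planted junctions and specificity on concordant reads."""
    rng = np.random.default_rng(seed)
    genome = random_genome({"chr1": 120_000, "chr2": 100_000}, rng)
    index = KmerIndex(genome)

    exact = 0
    for k in range(n_junctions):
        chrom = "chr1" if k % 2 == 0 else "chr2"
        length = len(genome.sequences[chrom])
        left = int(rng.integers(2_000, length - 40_000))
        right = int(rng.integers(left + 5_000, length - 2_000))
        spec = FusionSpec(chrom, left, right)
        pos_a, pos_b, _ = fusion_junction_truth(genome, spec)
        reads = fusion_reads(genome, spec, 3, 150, rng)
        calls, _ = detect_fusions(reads, genome, index=index)
        exact += any(
            c.chrom_a == chrom and c.pos_a == pos_a and c.pos_b == pos_b and c.support >= 3
            for c in calls
        )

    seq1, seq2 = genome.sequences["chr1"], genome.sequences["chr2"]
    reads = []
    for i in range(n_concordant):
        chrom, seq = ("chr1", seq1) if i % 2 == 0 else ("chr2", seq2)
        p = int(rng.integers(0, len(seq) - 150))
        reads.append((f"c{i}", seq[p : p + 150]))
    calls, _ = detect_fusions(reads, genome, index=index)

    pair = split_read("A" * 150)
    geometry_exact = pair.head == "A" * 60 and pair.gap == 30
    return {
        "junction_exact_recovery_rate": exact / n_junctions,
        "false_calls_on_concordant": len(calls),
        "split_geometry_exact": bool(geometry_exact),
        "n": n_junctions + n_concordant,
    }
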