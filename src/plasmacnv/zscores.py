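"""The z-score battery: window, segmental, region and genome-wide scores.

All scores share one idea: a sample's read representation of a genomic unit
(a 1-Mbp window, a CBS segment, a gene region) is standardized against the
mean and sample SD of the same quantity in a healthy-control cohort.  When a
control is itself being scored it is left out of its own baseline
(cross-validation), otherwise controls would partly serve as their own
reference and z-scores would shrink toward zero.  The scalar aneuploidy
measure is the genome-wide z-score: the sum of squared per-window z-scores
(S) standardized against the cross-validated S values of the controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .coverage import RatioProfile
from .errors import CohortError
from .reference import WindowSet
from .segmentation import Segment, SegmentationResult


@dataclass
class ZProfile:
    z: np.ndarray
    windows: pd.DataFrame  # chrom, start, end of the z bins
    sample_id: str = "sample"
    cross_validated: bool = False


@dataclass
class SegmentZ:
    segment: Segment
    z: float
    control_mean: float
    control_sd: float


@dataclass
class RegionZ:
    chrom: str
    start: int
    end: int
    name: str
    reads_region: int
    reads_expected: float
    ratio: float
    z: float


@dataclass
class GenomeWideScore:
    s: float
    genome_wide_z: float
    n_windows: int


# ---------------------------------------------------------------------------
# Binning equal-mappability windows into fixed-size z windows
# ---------------------------------------------------------------------------


def bin_profile(
    profile: RatioProfile, bin_size: int = 1_000_000
) -> tuple[pd.DataFrame, np.ndarray]:
    """Aggregate window ratios into fixed-size bins by window midpoint.

    Returns the bin table (chrom, start, end) and the mean GC-corrected ratio
    of the member windows per bin; bins without members are omitted.
    """
    frame = profile.windows.frame
    mid = (frame["start"].to_numpy() + frame["end"].to_numpy()) // 2
    chrom = frame["chrom"].to_numpy()
    rows = []
    values = []
    for name in profile.windows.chroms:
        mask = chrom == name
        bins = mid[mask] // bin_size
        vals = profile.ratio[mask]
        for b in np.unique(bins):
            member = vals[bins == b]
            if np.isfinite(member).any():
                rows.append((name, int(b) * bin_size, (int(b) + 1) * bin_size))
                values.append(float(np.nanmean(member)))
    return (
        pd.DataFrame(rows, columns=["chrom", "start", "end"]),
        np.asarray(values),
    )


# ---------------------------------------------------------------------------
# Window z-scores
# ---------------------------------------------------------------------------


def _check_cohort(controls: np.ndarray, minimum: int = 3) -> np.ndarray:
    controls = np.asarray(controls, float)
    if controls.ndim != 2 or controls.shape[0] < minimum:
        raise CohortError(f"need a 2-D cohort with >= {minimum} controls")
    return controls


def sample_window_z(sample: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """z_i = (sample_i - mean of controls_i) / SD of controls_i (held-out sample)."""
    controls = _check_cohort(controls)
    sample = np.asarray(sample, float)
    mean = np.nanmean(controls, axis=0)
    sd = np.nanstd(controls, axis=0, ddof=1)
    z = np.full(sample.shape, np.nan)
    ok = np.isfinite(sample) & np.isfinite(mean) & (sd > 0)
    z[ok] = (sample[ok] - mean[ok]) / sd[ok]
    return z


def cohort_loo_z(controls: np.ndarray) -> np.ndarray:
    """Leave-one-out z matrix: each control scored against the others only."""
    controls = _check_cohort(controls)
    n = controls.shape[0]
    tot = controls.sum(axis=0)
    totsq = (controls**2).sum(axis=0)
    mean_rest = (tot[None, :] - controls) / (n - 1)
    ss_rest = totsq[None, :] - controls**2 - (n - 1) * mean_rest**2
    var_rest = np.maximum(ss_rest, 0.0) / (n - 2)
    sd_rest = np.sqrt(var_rest)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (controls - mean_rest) / sd_rest
    z[~np.isfinite(z)] = np.nan
    return z


def window_z(
    sample: np.ndarray,
    controls: np.ndarray,
    cross_validate_index: int | None = None,
    windows: pd.DataFrame | None = None,
    sample_id: str = "sample",
) -> ZProfile:
    """Per-window z-scores of one sample against a control cohort.

    If the sample is row ``cross_validate_index`` of ``controls``, it is
    excluded from its own mean/SD (leave-one-out).
    """
    if cross_validate_index is not None:
        rest = np.delete(np.asarray(controls, float), cross_validate_index, axis=0)
        z = sample_window_z(sample, rest)
        cross = True
    else:
        z = sample_window_z(sample, controls)
        cross = False
    if windows is None:
        windows = pd.DataFrame(
            {"chrom": "genome", "start": np.arange(len(z)), "end": np.arange(len(z)) + 1}
        )
    return ZProfile(z, windows, sample_id=sample_id, cross_validated=cross)


def significant_fraction(z: ZProfile | np.ndarray, threshold: float = 3.0) -> tuple[float, int]:
    """(fraction of windows with |z| <= threshold, count with |z| > threshold)."""
    values = z.z if isinstance(z, ZProfile) else np.asarray(z, float)
    ok = np.isfinite(values)
    if not ok.any():
        return float("nan"), 0
    outliers = int(np.sum(np.abs(values[ok]) >= threshold))
    return 1.0 - outliers / ok.sum(), outliers


# ---------------------------------------------------------------------------
# Segmental and region z-scores
# ---------------------------------------------------------------------------


def segmental_z(
    sample: RatioProfile,
    segments: SegmentationResult,
    controls: list[RatioProfile] | np.ndarray,
) -> list[SegmentZ]:
    """Standardize each segment's summed GC-corrected ratio against controls."""
    if isinstance(controls, list):
        mat = np.vstack([c.ratio for c in controls])
    else:
        mat = np.asarray(controls, float)
    mat = _check_cohort(mat)
    out = []
    for seg in segments.segments:
        lo, hi = seg.start_index, seg.end_index
        sums = np.nansum(mat[:, lo:hi], axis=1)
        mean = float(np.mean(sums))
        sd = float(np.std(sums, ddof=1))
        sample_sum = float(np.nansum(sample.ratio[lo:hi]))
        z = (sample_sum - mean) / sd if sd > 0 else float("nan")
        out.append(SegmentZ(segment=seg, z=z, control_mean=mean, control_sd=sd))
    return out


def region_z(
    region: tuple[str, int, int, str],
    reads_region: int,
    reads_total: int,
    control_reads_region: np.ndarray,
    control_reads_total: np.ndarray,
    length_genome: int,
) -> RegionZ:
    """Gene/region z-score from raw counts.

    ratio = reads_region / reads_expected with
    reads_expected = (length_region / length_genome) * reads_total;
    the ratio is standardized against the controls' ratios.
    """
    chrom, start, end, name = region
    length_region = end - start
    if length_region <= 0 or length_genome <= 0:
        raise ValueError("region and genome lengths must be positive")
    expected = length_region / length_genome * reads_total
    if expected <= 0:
        raise ValueError("zero expected reads in region")
    ctrl_regions = np.asarray(control_reads_region, float)
    ctrl_totals = np.asarray(control_reads_total, float)
    if ctrl_regions.size < 3:
        raise CohortError("region z needs >= 3 controls")
    ctrl_expected = length_region / length_genome * ctrl_totals
    ctrl_ratio = ctrl_regions / ctrl_expected
    ratio = reads_region / expected
    sd = float(np.std(ctrl_ratio, ddof=1))
    z = (ratio - float(np.mean(ctrl_ratio))) / sd if sd > 0 else float("nan")
    return RegionZ(chrom, start, end, name, reads_region, expected, ratio, z)


def count_region_reads(
    alignments, regions: list[tuple[str, int, int, str]]
) -> tuple[dict[str, int], int]:
    """Count retained read starts per named region; returns (counts, total reads)."""
    counts = {r[3]: 0 for r in regions}
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, name in regions:
        by_chrom.setdefault(chrom, []).append((start, end, name))
    total = 0
    for rec in alignments:
        if rec.is_unmapped or rec.is_duplicate or rec.is_secondary:
            continue
        total += 1
        for start, end, name in by_chrom.get(rec.chromosome, ()):
            if start <= rec.position < end:
                counts[name] += 1
    return counts, total


# ---------------------------------------------------------------------------
# Genome-wide z-score
# ---------------------------------------------------------------------------


def s_score(z: np.ndarray | ZProfile) -> float:
    """S = sum of squared z-scores over defined windows."""
    values = z.z if isinstance(z, ZProfile) else np.asarray(z, float)
    return float(np.nansum(values**2))


def genome_wide_z(
    z: ZProfile | np.ndarray | float, control_s: np.ndarray
) -> GenomeWideScore:
    """Standardize the sample's S against cross-validated control S values."""
    control_s = np.asarray(control_s, float)
    if control_s.size < 3:
        raise CohortError("genome-wide z needs >= 3 control S values")
    if isinstance(z, (ZProfile, np.ndarray)):
        values = z.z if isinstance(z, ZProfile) else z
        s = s_score(values)
        n = int(np.isfinite(np.asarray(values, float)).sum())
    else:
        s = float(z)
        n = 0
    sd = float(np.std(control_s, ddof=1))
    if sd == 0:
        raise CohortError("control S values have zero spread")
    return GenomeWideScore(s, (s - float(np.mean(control_s))) / sd, n)


def cohort_s_scores(controls: np.ndarray) -> np.ndarray:
    """Cross-validated S per control (the genome-wide z reference)."""
    z = cohort_loo_z(controls)
    return np.nansum(z**2, axis=1)


def genome_wide_scores(samples: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """Genome-wide z for each held-out sample row against a control cohort."""
    controls = _check_cohort(controls)
    samples = np.atleast_2d(np.asarray(samples, float))
    control_s = cohort_s_scores(controls)
    mean_s = float(np.mean(control_s))
    sd_s = float(np.std(control_s, ddof=1))
    if sd_s == 0:
        raise CohortError("control S values have zero spread")
    mean = np.nanmean(controls, axis=0)
    sd = np.nanstd(controls, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (samples - mean[None, :]) / sd[None, :]
    z[:, ~(sd > 0)] = np.nan
    s = np.nansum(z**2, axis=1)
    return (s - mean_s) / sd_s


# ---------------------------------------------------------------------------
# Hierarchical clustering of z profiles
# ---------------------------------------------------------------------------


def manhattan_distance_matrix(z_matrix: np.ndarray) -> np.ndarray:
    """Pairwise Manhattan distance summing |z_a - z_b| over windows.

    Windows missing in either sample are dropped pairwise (with a warning).
    """
    z = np.asarray(z_matrix, float)
    n = z.shape[0]
    if np.isnan(z).any():
        warnings.warn("missing windows: Manhattan distances use pairwise-complete windows")
    dist = np.zeros((n, n))
    for a in range(n):
        diff = np.abs(z[a][None, :] - z[a:])
        dist[a, a:] = np.nansum(diff, axis=1)
    dist = dist + dist.T - np.diag(np.diag(dist))
    return dist


def cluster_samples(
    z_matrix: np.ndarray, labels: list[str] | None = None, linkage: str = "complete"
) -> np.ndarray:
    """Agglomerative clustering on Manhattan distances; returns a scipy linkage."""
    z = np.asarray(z_matrix, float)
    if z.shape[0] < 2:
        raise CohortError("clustering needs >= 2 samples")
    dist = manhattan_distance_matrix(z)
    return hierarchy.linkage(squareform(dist, checks=False), method=linkage)


def subtree_leaves(link: np.ndarray, n_leaves: int) -> list[set[int]]:
    """Leaf sets of every internal node of a linkage, in merge order."""
    sets: dict[int, set[int]] = {i: {i} for i in range(n_leaves)}
    out = []
    for k, (a, b, _, _) in enumerate(link):
        merged = sets[int(a)] | sets[int(b)]
        sets[n_leaves + k] = merged
        out.append(merged)
    return out


def smallest_subtree_containing(link: np.ndarray, n_leaves: int, members: set[int]) -> set[int]:
    """Leaves of the smallest clade containing all of ``members``."""
    for leaves in subtree_leaves(link, n_leaves):
        if members <= leaves:
            return leaves
    return set(range(n_leaves))


def to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage as a Newick tree with height-difference branches."""
    tree = hierarchy.to_tree(link)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
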