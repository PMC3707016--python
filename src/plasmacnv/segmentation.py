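"""Circular binary segmentation of log2 ratio profiles.

CBS finds the arc [i, j) of a (circularized) chromosome that maximizes the
two-sample t statistic between the arc and its complement, tests the maximal
statistic against a permutation reference distribution, and recurses into the
resulting pieces while splits remain significant.  Scanning all i < j covers
the circular arcs as well, since a wrap-around arc is the complement of a
linear one and yields the same |T|.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .coverage import RatioProfile

# T sentinel for a perfect step (zero within-group variance)
T_CAP = 1e6


@dataclass
class CbsParams:
    alpha: float = 0.01
    n_permutations: int = 10_000
    min_width: int = 2
    seed: int | None = None
    early_stop: bool = True

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


@dataclass
class Segment:
    chrom: str
    start_index: int  # window indices into the profile, half-open
    end_index: int
    start: int  # bp
    end: int
    mean_log2: float
    sum_ratio: float
    n_windows: int


@dataclass
class SegmentationResult:
    segments: list[Segment]
    params: CbsParams

    def for_chrom(self, chrom: str) -> list[Segment]:
        return [s for s in self.segments if s.chrom == chrom]


def _max_abs_t(
    values: np.ndarray, min_width: int, want_argmax: bool, chunk: int = 512
) -> tuple[int | None, int | None, float]:
    """Maximal |t| over arcs [i, j) with arc and complement >= min_width.

    Ties broken by smallest i then smallest j (row-major argmax order).
    Memory is bounded by chunking over i.
    """
    n = values.size
    s = np.concatenate([[0.0], np.cumsum(values)])
    sstot = float(np.sum(values**2))
    total = s[-1]
    best_t = 0.0
    best_ij: tuple[int, int] | None = None
    j = np.arange(n + 1)
    for i0 in range(0, n, chunk):
        i = np.arange(i0, min(i0 + chunk, n))
        k = j[None, :] - i[:, None]  # arc length
        ok = (k >= min_width) & ((n - k) >= min_width)
        if not ok.any():
            continue
        k = np.where(ok, k, 1)
        sum_in = s[None, :] - s[i, None]
        mean_in = sum_in / k
        mean_out = (total - sum_in) / (n - k)
        within = sstot - k * mean_in**2 - (n - k) * mean_out**2
        within = np.maximum(within, 0.0)
        denom = np.sqrt(within / (n - 2) * (1.0 / k + 1.0 / (n - k)))
        diff = np.abs(mean_in - mean_out)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, diff / denom, np.where(diff > 0, T_CAP, 0.0))
        t = np.minimum(np.where(ok, t, -1.0), T_CAP)
        flat = int(np.argmax(t))
        val = float(t.flat[flat])
        if val > best_t:
            best_t = val
            best_ij = (int(i[flat // (n + 1)]), int(flat % (n + 1)))
    if best_ij is None or best_t <= 0.0:
        return None, None, 0.0
    if not want_argmax:
        return None, None, best_t
    return best_ij[0], best_ij[1], best_t


def circular_max_stat(
    values: np.ndarray, min_width: int = 2
) -> tuple[int | None, int | None, float]:
    """Best arc (i, j, T).  Degenerate (constant) input returns (None, None, 0)."""
    values = np.asarray(values, float)
    if values.size < 2 * min_width:
        raise ValueError(f"need at least {2 * min_width} values")
    return _max_abs_t(values, min_width, want_argmax=True)


def permutation_p(
    values: np.ndarray,
    t_obs: float,
    params: CbsParams,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value (1 + #exceedances) / (n_permutations + 1).

    With ``params.early_stop`` the scan stops as soon as the p-value provably
    exceeds ``params.alpha``; the returned estimate is then based on the
    permutations seen, which is sufficient for the accept/reject decision.
    """
    values = np.asarray(values, float)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if t_obs >= T_CAP:
        return 1.0 / (params.n_permutations + 1)
    stop_at = int(np.ceil(params.alpha * (params.n_permutations + 1)))
    exceed = 0
    done = 0
    for _ in range(params.n_permutations):
        perm = rng.permutation(values)
        _, _, t = _max_abs_t(perm, params.min_width, want_argmax=False)
        done += 1
        if t >= t_obs:
            exceed += 1
            if params.early_stop and exceed >= stop_at:
                return (1 + exceed) / (done + 1)
    return (1 + exceed) / (params.n_permutations + 1)


def _segment_values(
    values: np.ndarray, params: CbsParams, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Recursive CBS on a dense value vector; returns half-open index pieces."""
    n = values.size
    if n < 2 * params.min_width:
        return [(0, n)]
    i, j, t = _max_abs_t(values, params.min_width, want_argmax=True)
    if i is None:
        return [(0, n)]
    p = permutation_p(values, t, params, rng)
    if p >= params.alpha:
        return [(0, n)]
    pieces = []
    for a, b in ((0, i), (i, j), (j, n)):
        if b > a:
            pieces.extend(
                (a + x, a + y) for x, y in _segment_values(values[a:b], params, rng)
            )
    return pieces


def cbs_segment(profile: RatioProfile, params: CbsParams | None = None) -> SegmentationResult:
    """Segment each chromosome of a log2 ratio profile.

    Missing (NaN) windows are skipped in the statistics but stay inside the
    enclosing segment's coordinates.  Each segment carries its mean log2
    ratio and the sum of GC-corrected ratios, the input to segmental
    z-scores.  Per-chromosome RNG streams are derived from the seed and a
    chromosome-name hash, so results do not depend on iteration order.
    """
    if params is None:
        params = CbsParams()
    if profile.log2 is None:
        raise ValueError("profile has no log2 ratios; run to_log2_ratio first")
    frame = profile.windows.frame
    chrom_arr = frame["chrom"].to_numpy()
    segments: list[Segment] = []
    for chrom in profile.windows.chroms:
        idx = np.flatnonzero(chrom_arr == chrom)
        log2 = profile.log2[idx]
        ok = np.isfinite(log2)
        dense = log2[ok]
        dense_pos = idx[ok]
        base_seed = params.seed if params.seed is not None else 0
        rng = np.random.default_rng(
            np.random.SeedSequence([base_seed, zlib.crc32(chrom.encode())])
        )
        if dense.size < 2 * params.min_width:
            warnings.warn(f"chromosome {chrom}: fewer than {2 * params.min_width} usable windows")
            pieces = [(0, dense.size)] if dense.size else []
        else:
            pieces = _segment_values(dense, params, rng)
        if dense.size == 0:
            continue
        # boundaries in window space: a missing run between two pieces is
        # inherited by the segment on its left, so segments tile the chromosome
        cuts = [int(idx[0])]
        for a, _ in pieces[1:]:
            cuts.append(int(dense_pos[a]))
        cuts.append(int(idx[-1]) + 1)
        for pi, (a, b) in enumerate(pieces):
            lo, hi = cuts[pi], cuts[pi + 1]
            segments.append(
                Segment(
                    chrom=chrom,
                    start_index=lo,
                    end_index=hi,
                    start=int(frame["start"].iloc[lo]),
                    end=int(frame["end"].iloc[hi - 1]),
                    mean_log2=float(np.mean(dense[a:b])),
                    sum_ratio=float(np.nansum(profile.ratio[lo:hi])),
                    n_windows=hi - lo,
                )
            )
    return SegmentationResult(segments, params)


def write_segments(path: str, result: SegmentationResult, meta: dict | None = None):
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write("chrom\tstart\tend\tn_windows\tmean_log2\tsum_ratio\n")
        for s in result.segments:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.n_windows}\t"
                f"{s.mean_log2:.6f}\t{s.sum_ratio:.6f}\n"
            )
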