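"""Per-window read counting and normalization into log2 ratio profiles.

The depth signal from shallow sequencing is turned into copy-number evidence
in three steps: (1) count read starts per equal-mappability window and divide
by the mean count, (2) remove the smooth dependence of that normalized count
on window GC content with a LOWESS fit (division, i.e. a multiplicative bias
model), (3) express the GC-corrected ratio relative to a sex-matched control
baseline as a log2 ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import CohortError, CoordinateError, NormalizationError
from .reference import WindowSet


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal view of one aligned read (0-based leftmost position)."""

    read_id: str
    chromosome: str | None
    position: int
    mapq: int = 60
    is_unmapped: bool = False
    is_duplicate: bool = False
    is_secondary: bool = False


def read_sam(path: str) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM (or BAM) file via pysam."""
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        for rec in fh:
            yield AlignmentRecord(
                read_id=rec.query_name or "",
                chromosome=rec.reference_name,
                position=rec.reference_start if not rec.is_unmapped else -1,
                mapq=rec.mapping_quality,
                is_unmapped=rec.is_unmapped,
                is_duplicate=rec.is_duplicate,
                is_secondary=rec.is_secondary or rec.is_supplementary,
            )


@dataclass
class WindowCounts:
    windows: WindowSet
    counts: np.ndarray
    total_reads: int
    sample_id: str = "sample"
    sex: str | None = None


@dataclass
class RatioProfile:
    """GC-corrected read-count ratios (mean ~= 1) and optional log2 vs baseline."""

    windows: WindowSet
    ratio: np.ndarray
    log2: np.ndarray | None = None
    sample_id: str = "sample"
    sex: str | None = None

    def values_by_chrom(self) -> dict[str, np.ndarray]:
        out = {}
        chrom = self.windows.frame["chrom"].to_numpy()
        for name in self.windows.chroms:
            out[name] = self.ratio[chrom == name]
        return out


@dataclass
class ControlBaseline:
    windows: WindowSet
    mean: np.ndarray
    sd: np.ndarray
    n_controls: int
    sex: str | None = None


def count_reads(
    alignments: Iterable[AlignmentRecord],
    windows: WindowSet,
    min_mapq: int = 0,
    strict: bool = False,
    sample_id: str = "sample",
    sex: str | None = None,
) -> WindowCounts:
    """Count retained read starts per window.

    Unmapped, duplicate and secondary records are dropped; records below
    ``min_mapq`` are dropped.  Retained reads whose start lies outside every
    window still contribute to ``total_reads``.
    """
    frame = windows.frame
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    offsets: dict[str, int] = {}
    for name in windows.chroms:
        mask = frame["chrom"] == name
        starts[name] = frame.loc[mask, "start"].to_numpy()
        ends[name] = frame.loc[mask, "end"].to_numpy()
        offsets[name] = int(np.flatnonzero(mask.to_numpy())[0])

    counts = np.zeros(len(windows), dtype=np.int64)
    total = 0
    unknown: set[str] = set()
    for rec in alignments:
        if rec.is_unmapped or rec.is_duplicate or rec.is_secondary:
            continue
        if rec.mapq < min_mapq:
            continue
        total += 1
        chrom = rec.chromosome
        if chrom not in starts:
            if strict:
                raise CoordinateError(f"alignment on unknown chromosome {chrom!r}")
            unknown.add(str(chrom))
            continue
        s = starts[chrom]
        idx = int(np.searchsorted(s, rec.position, side="right")) - 1
        if idx >= 0 and rec.position < ends[chrom][idx]:
            counts[offsets[chrom] + idx] += 1
    if unknown:
        warnings.warn(f"skipped alignments on unknown chromosomes: {sorted(unknown)}")
    return WindowCounts(windows, counts, total, sample_id=sample_id, sex=sex)


def gc_correct(
    counts: WindowCounts, span: float = 0.3, iterations: int = 1
) -> RatioProfile:
    """Divide mean-normalized counts by a LOWESS fit of count on GC fraction.

    The output is rescaled so the mean of defined ratios is exactly 1.
    Windows with missing GC, or where the fitted bias is non-positive, are
    flagged missing (NaN).
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    gc = counts.windows.frame["gc"].to_numpy(float)
    raw = counts.counts.astype(float)
    valid = np.isfinite(gc)
    if raw[valid].sum() == 0:
        raise NormalizationError("all window counts are zero")
    if np.unique(gc[valid]).size < 20:
        raise NormalizationError("need >= 20 windows with distinct GC fractions")

    norm = raw / raw[valid].mean()
    fit = np.full_like(norm, np.nan)
    fit[valid] = lowess(
        norm[valid], gc[valid], frac=span, it=iterations, return_sorted=False
    )
    ratio = np.full_like(norm, np.nan)
    ok = valid & np.isfinite(fit) & (fit > 0)
    ratio[ok] = norm[ok] / fit[ok]
    ratio[ok] /= ratio[ok].mean()
    return RatioProfile(counts.windows, ratio, sample_id=counts.sample_id, sex=counts.sex)


def build_baseline(
    profiles: list[RatioProfile], sex: str | None = None
) -> ControlBaseline:
    """Per-window mean and sample SD of control GC-corrected ratios."""
    if len(profiles) < 2:
        raise CohortError("a control baseline needs at least 2 controls")
    first = profiles[0]
    sexes = {p.sex for p in profiles if p.sex is not None}
    if len(sexes) > 1:
        raise CohortError(f"mixed-sex control cohort: {sorted(sexes)}")
    if sex is None and sexes:
        sex = sexes.pop()
    for p in profiles[1:]:
        if not p.windows.same_grid(first.windows):
            raise CohortError("control profiles are on different window sets")
    mat = np.vstack([p.ratio for p in profiles])
    return ControlBaseline(
        windows=first.windows,
        mean=np.nanmean(mat, axis=0),
        sd=np.nanstd(mat, axis=0, ddof=1),
        n_controls=len(profiles),
        sex=sex,
    )


def to_log2_ratio(sample: RatioProfile, baseline: ControlBaseline) -> RatioProfile:
    """log2(sample ratio / baseline mean); undefined where the baseline is <= 0."""
    if not sample.windows.same_grid(baseline.windows):
        raise CohortError("sample and baseline are on different window sets")
    log2 = np.full(len(sample.ratio), np.nan)
    ok = (
        np.isfinite(sample.ratio)
        & np.isfinite(baseline.mean)
        & (baseline.mean > 0)
        & (sample.ratio > 0)
    )
    log2[ok] = np.log2(sample.ratio[ok] / baseline.mean[ok])
    # ratio 0 over a positive baseline is a real (deep) loss, not missing
    zero = np.isfinite(sample.ratio) & (sample.ratio == 0) & (baseline.mean > 0)
    log2[zero] = -np.inf
    return RatioProfile(sample.windows, sample.ratio, log2, sample.sample_id, sample.sex)


# ---------------------------------------------------------------------------
# TSV round-trips (window-keyed tables with a comment header)
# ---------------------------------------------------------------------------


def _write_table(path, windows: WindowSet, columns: dict[str, np.ndarray], meta: dict):
    frame = windows.frame[["chrom", "start", "end"]].copy()
    for name, values in columns.items():
        frame[name] = values
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.8g")


def _read_table(path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t", na_values="NA")
    return frame, meta


def _grid_from_table(frame: pd.DataFrame) -> WindowSet:
    grid = frame[["chrom", "start", "end"]].copy()
    grid["n_mappable"] = 0
    grid["gc"] = np.nan
    return WindowSet(grid)


def write_counts(path: str, counts: WindowCounts, extra_meta: dict | None = None):
    meta = {
        "sample": counts.sample_id,
        "total_reads": counts.total_reads,
        "sex": counts.sex or "NA",
    }
    meta.update(extra_meta or {})
    _write_table(path, counts.windows, {"count": counts.counts}, meta)


def read_counts(path: str, windows: WindowSet | None = None) -> WindowCounts:
    frame, meta = _read_table(path)
    grid = windows if windows is not None else _grid_from_table(frame)
    sex = meta.get("sex")
    return WindowCounts(
        windows=grid,
        counts=frame["count"].to_numpy(np.int64),
        total_reads=int(meta.get("total_reads", frame["count"].sum())),
        sample_id=meta.get("sample", "sample"),
        sex=None if sex in (None, "NA") else sex,
    )


def write_ratios(path: str, profile: RatioProfile, extra_meta: dict | None = None):
    cols = {"ratio": profile.ratio}
    if profile.log2 is not None:
        cols["log2"] = profile.log2
    meta = {"sample": profile.sample_id}
    meta.update(extra_meta or {})
    _write_table(path, profile.windows, cols, meta)


def read_ratios(path: str, windows: WindowSet | None = None) -> RatioProfile:
    frame, meta = _read_table(path)
    grid = windows if windows is not None else _grid_from_table(frame)
    log2 = frame["log2"].to_numpy(float) if "log2" in frame.columns else None
    return RatioProfile(
        grid, frame["ratio"].to_numpy(float), log2, meta.get("sample", "sample")
    )


def write_baseline(path: str, baseline: ControlBaseline, extra_meta: dict | None = None):
    meta = {"n_controls": baseline.n_controls, "sex": baseline.sex or "NA"}
    meta.update(extra_meta or {})
    _write_table(path, baseline.windows, {"mean": baseline.mean, "sd": baseline.sd}, meta)


def read_baseline(path: str, windows: WindowSet | None = None) -> ControlBaseline:
    frame, meta = _read_table(path)
    grid = windows if windows is not None else _grid_from_table(frame)
    sex = meta.get("sex")
    return ControlBaseline(
        windows=grid,
        mean=frame["mean"].to_numpy(float),
        sd=frame["sd"].to_numpy(float),
        n_controls=int(meta.get("n_controls", 0)),
        sex=None if sex in (None, "NA") else sex,
    )
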