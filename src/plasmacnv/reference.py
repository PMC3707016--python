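"""Reference preparation: PAR masking, read-length mappability, equal-mappability windows.

Copy-number inference from shallow sequencing counts reads in genomic windows.
Because alignability varies along the genome, windows are not of fixed span but
hold an (almost) equal number of *mappable* start positions: a position is
mappable when a read of the configured length starting there occurs exactly
once in the genome (counting both strands).  The pseudo-autosomal region on
the Y chromosome is masked with N beforehand so X/Y-shared sequence is not
double-counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoordinateError, SizingError

_VALID = frozenset("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")

# base -> 2-bit code; anything that is not A/C/G/T (incl. N) -> 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMP)[::-1]


class ReferenceGenome:
    """In-memory reference: chromosome name -> upper-case A/C/G/T/N string."""

    def __init__(self, sequences: dict[str, str]):
        cleaned: dict[str, str] = {}
        for name, seq in sequences.items():
            s = seq.upper()
            extra = set(s) - _VALID
            if extra:
                raise ValueError(
                    f"chromosome {name!r} contains invalid bases: {sorted(extra)}"
                )
            cleaned[name] = s
        self.sequences = cleaned

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    @classmethod
    def from_fasta(cls, path: str) -> "ReferenceGenome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class ParInterval:
    """A region to mask, 0-based half-open (typically the Y-chromosome PAR)."""

    chromosome: str
    start: int
    end: int


def read_par_bed(path: str) -> list[ParInterval]:
    """Read mask intervals from a 3+ column BED file."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append(ParInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def mask_par(genome: ReferenceGenome, intervals: list[ParInterval]) -> ReferenceGenome:
    """Replace bases inside ``intervals`` with N; everything else unchanged."""
    arrays: dict[str, np.ndarray] = {}
    for iv in intervals:
        if iv.chromosome not in genome.sequences:
            raise CoordinateError(f"interval on unknown chromosome: {iv}")
        length = len(genome.sequences[iv.chromosome])
        if not (0 <= iv.start < iv.end <= length):
            raise CoordinateError(
                f"interval {iv.chromosome}:{iv.start}-{iv.end} outside chromosome "
                f"of length {length}"
            )
        if iv.chromosome not in arrays:
            arrays[iv.chromosome] = np.frombuffer(
                genome.sequences[iv.chromosome].encode(), dtype=np.uint8
            ).copy()
        arrays[iv.chromosome][iv.start : iv.end] = ord("N")
    sequences = dict(genome.sequences)
    for name, arr in arrays.items():
        sequences[name] = arr.tobytes().decode()
    return ReferenceGenome(sequences)


# ---------------------------------------------------------------------------
# Mappability
# ---------------------------------------------------------------------------

# two independent polynomial rolling hashes, combined into one uint64 key;
# collision probability over a few million k-mers is ~1e-6 or lower
_M1, _B1 = 2147483647, 1000003
_M2, _B2 = 2147483629, 998244353


def _kmer_keys(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Hash keys and N-free validity for every k-mer start position."""
    n = codes.size
    if n < k:
        return np.empty(0, np.uint64), np.empty(0, bool)
    npos = n - k + 1
    c = codes.astype(np.uint64)
    h1 = np.zeros(npos, np.uint64)
    h2 = np.zeros(npos, np.uint64)
    b1, m1 = np.uint64(_B1), np.uint64(_M1)
    b2, m2 = np.uint64(_B2), np.uint64(_M2)
    for t in range(k):
        seg = c[t : t + npos]
        h1 = (h1 * b1 + seg) % m1
        h2 = (h2 * b2 + seg) % m2
    nrun = np.concatenate([[0], np.cumsum(codes == 4)])
    valid = (nrun[k:] - nrun[:-k]) == 0
    return h1 * np.uint64(_M2) + h2, valid


@dataclass
class MappabilityTrack:
    """Per-chromosome boolean vectors over read start positions."""

    read_length: int
    tracks: dict[str, np.ndarray]

    @property
    def total_mappable(self) -> int:
        return int(sum(t.sum() for t in self.tracks.values()))

    def positions(self, chromosome: str) -> np.ndarray:
        return np.flatnonzero(self.tracks[chromosome])


def mappability_track(
    genome: ReferenceGenome, read_length: int = 150, both_strands: bool = True
) -> MappabilityTrack:
    """Mark positions whose ``read_length``-mer occurs exactly once in the genome.

    Occurrences on the reverse strand count as hits when ``both_strands`` is
    set, mirroring how an aligner would place reads.  Any k-mer containing N
    is unmappable.  Implemented with a streaming double rolling hash so
    multi-megabase genomes stay in a few tens of MB.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if genome.lengths and read_length > max(genome.lengths.values()):
        warnings.warn(
            "read_length exceeds the longest chromosome; all positions unmappable"
        )
        return MappabilityTrack(
            read_length,
            {n: np.zeros(l, bool) for n, l in genome.lengths.items()},
        )

    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    pool: list[np.ndarray] = []
    for name, seq in genome.sequences.items():
        codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        keys, valid = _kmer_keys(codes, read_length)
        per_chrom[name] = (keys, valid)
        pool.append(keys[valid])
        if both_strands:
            comp = np.where(codes == 4, np.uint8(4), 3 - codes)[::-1]
            rkeys, rvalid = _kmer_keys(comp, read_length)
            pool.append(rkeys[rvalid])

    uniq, counts = np.unique(np.concatenate(pool), return_counts=True)
    tracks: dict[str, np.ndarray] = {}
    for name, seq in genome.sequences.items():
        track = np.zeros(len(seq), bool)
        keys, valid = per_chrom[name]
        if keys.size:
            idx = np.searchsorted(uniq, keys[valid])
            track[: keys.size][valid] = counts[idx] == 1
        tracks[name] = track
    return MappabilityTrack(read_length, tracks)


# ---------------------------------------------------------------------------
# Window grid
# ---------------------------------------------------------------------------


class WindowSet:
    """Ordered, non-overlapping half-open windows with mappable counts and GC."""

    COLUMNS = ["chrom", "start", "end", "n_mappable", "gc"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"window frame missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    @property
    def spans(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()

    @property
    def total_span(self) -> int:
        return int(self.spans.sum())

    def same_grid(self, other: "WindowSet") -> bool:
        a, b = self.frame, other.frame
        return len(a) == len(b) and (
            (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["start"].to_numpy() == b["start"].to_numpy()).all()
            and (a["end"].to_numpy() == b["end"].to_numpy()).all()
        )

    def to_bed(self, path: str, header: bool = False) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write("#" + "\t".join(self.COLUMNS) + "\n")
            for row in self.frame.itertuples(index=False):
                gc = "" if pd.isna(row.gc) else f"{row.gc:.6f}"
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.n_mappable}\t{gc}\n"
                )

    @classmethod
    def from_bed(cls, path: str) -> "WindowSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                gc = float(f[4]) if len(f) > 4 and f[4] != "" else np.nan
                rows.append((f[0], int(f[1]), int(f[2]), int(f[3]), gc))
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))


def build_windows(track: MappabilityTrack, n_windows: int) -> WindowSet:
    """Partition mappable positions into ``n_windows`` equal-count windows.

    Each window holds floor(total/n) or floor(total/n)+1 mappable positions.
    Windows never cross chromosome boundaries: each chromosome is assigned a
    window count for which its mappable total decomposes exactly into
    base/base+1 sized windows, with the +1 windows placed last.  A chromosome
    whose mappable total is below the base size gets a single undersized
    window with a warning.
    """
    counts = {name: int(t.sum()) for name, t in track.tracks.items()}
    total = sum(counts.values())
    if n_windows < 1 or total < n_windows:
        raise SizingError(
            f"cannot build {n_windows} windows from {total} mappable positions"
        )
    base = total // n_windows

    names = [n for n in track.tracks if counts[n] > 0]
    lo: dict[str, int] = {}
    hi: dict[str, int] = {}
    undersized = []
    for name in names:
        mc = counts[name]
        h = mc // base
        l = -(-mc // (base + 1))  # ceil
        if h == 0:  # chromosome smaller than one full window
            l = h = 1
            undersized.append(name)
        elif l > h:  # cannot decompose into base/base+1 exactly: nearest quota
            l = h = max(1, round(mc * n_windows / total))
            undersized.append(name)
        lo[name], hi[name] = l, h
    if undersized:
        warnings.warn(
            f"chromosomes {undersized} cannot hold equal-count windows; "
            "their windows deviate from the genome-wide size"
        )

    n_c = dict(lo)
    deficit = n_windows - sum(n_c.values())
    if deficit < 0:
        # too many minimum windows (degenerate tiny-chromosome case): trim
        for name in reversed(names):
            take = min(-deficit, n_c[name] - 1)
            n_c[name] -= take
            deficit += take
            if deficit == 0:
                break
    else:
        for name in names:
            take = min(deficit, hi[name] - n_c[name])
            n_c[name] += take
            deficit -= take
            if deficit == 0:
                break
    if deficit != 0:
        warnings.warn(
            "window count not exactly representable without crossing "
            "chromosome boundaries; adjusting last chromosome"
        )
        n_c[names[-1]] += deficit

    rows = []
    for name in names:
        mc, k = counts[name], n_c[name]
        extra = mc - k * base
        if 0 <= extra <= k:
            sizes = [base] * (k - extra) + [base + 1] * extra
        else:  # undersized / irregular chromosome: spread as evenly as possible
            q, r = divmod(mc, k)
            sizes = [q] * (k - r) + [q + 1] * r
        pos = track.positions(name)
        offset = 0
        for size in sizes:
            chunk = pos[offset : offset + size]
            rows.append((name, int(chunk[0]), int(chunk[-1]) + 1, size, np.nan))
            offset += size
    return WindowSet(pd.DataFrame(rows, columns=WindowSet.COLUMNS))


def window_gc(genome: ReferenceGenome, windows: WindowSet) -> WindowSet:
    """Annotate windows with GC fraction (G+C over non-N bases of the span)."""
    frame = windows.frame.copy()
    gc_vals = np.full(len(frame), np.nan)
    cum: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in windows.chroms:
        if name not in genome.sequences:
            raise CoordinateError(f"window chromosome {name!r} not in genome")
        codes = _CODE[np.frombuffer(genome.sequences[name].encode(), dtype=np.uint8)]
        is_gc = np.concatenate([[0], np.cumsum((codes == 1) | (codes == 2))])
        is_acgt = np.concatenate([[0], np.cumsum(codes < 4)])
        cum[name] = (is_gc, is_acgt)
    for i, row in enumerate(frame.itertuples(index=False)):
        is_gc, is_acgt = cum[row.chrom]
        if row.end > len(is_acgt) - 1 or row.start < 0:
            raise CoordinateError(
                f"window {row.chrom}:{row.start}-{row.end} outside genome"
            )
        denom = is_acgt[row.end] - is_acgt[row.start]
        if denom > 0:
            gc_vals[i] = (is_gc[row.end] - is_gc[row.start]) / denom
    frame["gc"] = gc_vals
    return WindowSet(frame)
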