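"""Synthetic end-to-end dataset generator.

Emulates the study substrate at desk scale: a random (hence essentially
uniquely mappable) multi-chromosome genome, a PAR-like masked interval, a
cohort of control plasma samples and tumor-bearing cases as SAM files, cfDNA
reads across a planted fusion junction as FASTQ, and a truth JSON recording
every planted event.

Reads are sampled from mappable start positions with probabilities scaled by
the diluted copy-number ratio and a smooth injected GC bias, so the full
pipeline (counting, GC correction, control normalization, segmentation,
z-scores, fusion mapping) can be exercised and checked against truth.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .reference import (
    MappabilityTrack,
    ParInterval,
    ReferenceGenome,
    WindowSet,
    build_windows,
    mappability_track,
    mask_par,
    revcomp,
    window_gc,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CnaSpec:
    chrom: str
    start: int
    end: int
    ratio: float


@dataclass
class FusionSpec:
    """An interstitial deletion joining ``left_end`` to ``right_start`` (half-open)."""

    chrom: str
    left_end: int
    right_start: int


@dataclass
class FixtureConfig:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 120_000, "chr2": 100_000, "chr3": 80_000}
    )
    n_windows: int = 150
    read_length: int = 150
    n_reads: int = 60_000
    n_controls: int = 5
    cnas: list[CnaSpec] = field(default_factory=list)
    fusion: FusionSpec | None = None
    lam: float = 1.0
    gc_bias_strength: float = 0.6
    par: ParInterval | None = None
    n_fusion_reads: int = 8
    n_background_fusion_reads: int = 200


def random_genome(
    chrom_lengths: dict[str, int], rng: np.random.Generator
) -> ReferenceGenome:
    """Random A/C/G/T genome; at these sizes 150-mers are unique w.h.p."""
    seqs = {}
    for name, length in chrom_lengths.items():
        seqs[name] = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
    return ReferenceGenome(seqs)


def _copy_ratio_at(
    chrom: str, positions: np.ndarray, cnas: list[CnaSpec], lam: float
) -> np.ndarray:
    ratio = np.ones(positions.size)
    for cna in cnas:
        if cna.chrom != chrom:
            continue
        inside = (positions >= cna.start) & (positions < cna.end)
        ratio[inside] = cna.ratio
    return 1.0 - lam + lam * ratio


def _gc_weights(
    genome: ReferenceGenome, windows: WindowSet, strength: float
) -> dict[str, np.ndarray]:
    """Per-window sampling multiplier, a smooth linear function of GC.

    ``strength`` is the fractional efficiency change per 5 percentage points
    of GC, roughly the magnitude seen in Illumina libraries.
    """
    gc = windows.frame["gc"].to_numpy(float)
    center = np.nanmean(gc)
    w = 1.0 + strength * (gc - center) / 0.05
    return np.clip(np.nan_to_num(w, nan=1.0), 0.2, 5.0)


def _write_sam(
    path: str,
    genome: ReferenceGenome,
    reads: list[tuple[str, str, int, int, int, str]],
) -> None:
    """reads: (read_id, chrom, pos0, flag, mapq, seq)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in genome.lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rid, chrom, pos, flag, mapq, seq in reads:
            fh.write(
                f"{rid}\t{flag}\t{chrom}\t{pos + 1}\t{mapq}\t{len(seq)}M\t*\t0\t0\t"
                f"{seq}\t*\n"
            )


def _sample_reads(
    genome: ReferenceGenome,
    track: MappabilityTrack,
    windows: WindowSet,
    gc_weight: np.ndarray,
    cnas: list[CnaSpec],
    lam: float,
    n_reads: int,
    read_length: int,
    rng: np.random.Generator,
    sample_id: str,
) -> list[tuple[str, str, int, int, int, str]]:
    frame = windows.frame
    mid = (frame["start"].to_numpy() + frame["end"].to_numpy()) // 2
    chroms = frame["chrom"].to_numpy()
    copy = np.concatenate(
        [
            _copy_ratio_at(name, mid[chroms == name], cnas, lam)
            for name in windows.chroms
        ]
    )
    weight = copy * gc_weight
    prob = weight / weight.sum()
    per_window = rng.multinomial(n_reads, prob)
    reads = []
    k = 0
    for wi, count in enumerate(per_window):
        if count == 0:
            continue
        chrom = chroms[wi]
        pos = track.positions(chrom)
        lo, hi = frame["start"].iloc[wi], frame["end"].iloc[wi]
        inside = pos[(pos >= lo) & (pos < hi)]
        if inside.size == 0:
            continue
        picks = inside[rng.integers(0, inside.size, size=count)]
        seq = genome.sequences[chrom]
        for p in np.sort(picks):
            reads.append(
                (f"{sample_id}:{k}", chrom, int(p), 0, 60, seq[p : p + read_length])
            )
            k += 1
    return reads


def fusion_junction_truth(genome: ReferenceGenome, fusion: FusionSpec) -> tuple[int, int, int]:
    """Leftmost-normalized junction (posA, posB, microhomology length).

    posA is the last reference base before the junction, posB the first base
    after it.  If the bases flanking the junction are identical the junction
    is ambiguous (microhomology) and is shifted to its leftmost equivalent.
    """
    seq = genome.sequences[fusion.chrom]
    a, b = fusion.left_end, fusion.right_start
    mh = 0
    while a > 0 and seq[a - 1] == seq[b - 1]:
        a -= 1
        b -= 1
        mh += 1
    # count homology to the right as well for the total ambiguity length
    a2, b2 = fusion.left_end, fusion.right_start
    while b2 < len(seq) and seq[a2] == seq[b2]:
        a2 += 1
        b2 += 1
        mh += 1
    return a - 1, b, mh


def fusion_reads(
    genome: ReferenceGenome,
    fusion: FusionSpec,
    n_reads: int,
    read_length: int,
    rng: np.random.Generator,
    min_flank: int = 60,
) -> list[tuple[str, str]]:
    """Reads spanning the fused junction with >= ``min_flank`` bases per side."""
    seq = genome.sequences[fusion.chrom]
    fused = seq[: fusion.left_end] + seq[fusion.right_start :]
    junction = fusion.left_end  # position of the first B-side base in fused coords
    out = []
    for i in range(n_reads):
        left = int(rng.integers(min_flank, read_length - min_flank + 1))
        start = junction - left
        read = fused[start : start + read_length]
        if rng.random() < 0.5:
            read = revcomp(read)
        out.append((f"fusion:{i}", read))
    return out


def generate_fixture(
    config: FixtureConfig, seed: int, out_dir: str
) -> dict:
    """Write the synthetic dataset to ``out_dir`` and return the truth record."""
    for cna in config.cnas:
        length = config.chrom_lengths.get(cna.chrom)
        if length is None or not 0 <= cna.start < cna.end <= length:
            raise ConfigError(f"CNA outside genome: {cna}")
    if config.fusion is not None:
        length = config.chrom_lengths.get(config.fusion.chrom)
        if length is None or not (
            0 < config.fusion.left_end < config.fusion.right_start < length
        ):
            raise ConfigError(f"fusion outside genome: {config.fusion}")

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    genome = random_genome(config.chrom_lengths, rng)
    genome.to_fasta(os.path.join(out_dir, "ref.fa"))

    par_path = os.path.join(out_dir, "par.bed")
    intervals = [config.par] if config.par else []
    with open(par_path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\n")
    masked = mask_par(genome, intervals) if intervals else genome

    track = mappability_track(masked, config.read_length)
    windows = window_gc(masked, build_windows(track, config.n_windows))
    windows.to_bed(os.path.join(out_dir, "windows.bed"), header=True)
    gc_weight = _gc_weights(masked, windows, config.gc_bias_strength)

    control_paths = []
    for ci in range(config.n_controls):
        reads = _sample_reads(
            masked, track, windows, gc_weight, [], 0.0, config.n_reads,
            config.read_length, rng, f"ctrl{ci}",
        )
        path = os.path.join(out_dir, f"control_{ci}.sam")
        _write_sam(path, masked, reads)
        control_paths.append(path)

    case_reads = _sample_reads(
        masked, track, windows, gc_weight, config.cnas, config.lam,
        config.n_reads, config.read_length, rng, "case",
    )
    case_path = os.path.join(out_dir, "case.sam")
    _write_sam(case_path, masked, case_reads)

    truth: dict = {
        "seed": seed,
        "lambda": config.lam,
        "n_reads": config.n_reads,
        "n_windows": len(windows),
        "cnas": [
            {"chrom": c.chrom, "start": c.start, "end": c.end, "ratio": c.ratio}
            for c in config.cnas
        ],
        "controls": control_paths,
        "case": case_path,
    }

    if config.fusion is not None:
        pos_a, pos_b, mh = fusion_junction_truth(masked, config.fusion)
        span_reads = fusion_reads(
            masked, config.fusion, config.n_fusion_reads, config.read_length, rng
        )
        background = []
        for name in masked.names:
            pos = track.positions(name)
            take = pos[
                rng.integers(0, pos.size, size=config.n_background_fusion_reads // len(masked))
            ]
            seq = masked.sequences[name]
            background.extend(
                (f"bg:{name}:{i}", seq[p : p + config.read_length])
                for i, p in enumerate(take)
            )
        fastq_path = os.path.join(out_dir, "fusion_reads.fastq")
        with open(fastq_path, "w") as fh:
            for rid, read in span_reads + background:
                fh.write(f"@{rid}\n{read}\n+\n{'I' * len(read)}\n")
        truth["fusion"] = {
            "chrom": config.fusion.chrom,
            "pos_a": pos_a,
            "pos_b": pos_b,
            "microhomology": mh,
            "n_spanning_reads": config.n_fusion_reads,
            "fastq": fastq_path,
        }

    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
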