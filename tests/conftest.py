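"""Shared fixtures: toy window grids, random genomes, brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from plasmacnv.coverage import RatioProfile
from plasmacnv.reference import ReferenceGenome, WindowSet, revcomp


def toy_windows(n: int, chrom: str = "chr1", span: int = 100, gc=0.5) -> WindowSet:
    """A uniform single-chromosome window grid for unit tests."""
    frame = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * span,
            "end": (np.arange(n) + 1) * span,
            "n_mappable": span,
            "gc": gc,
        }
    )
    return WindowSet(frame)


def make_profile(log2: np.ndarray, ratio: np.ndarray | None = None, chrom="chr1") -> RatioProfile:
    log2 = np.asarray(log2, float)
    if ratio is None:
        ratio = np.exp2(log2)
    return RatioProfile(toy_windows(len(log2), chrom=chrom), np.asarray(ratio, float), log2)


def random_genome(chrom_lengths: dict, seed: int) -> ReferenceGenome:
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return ReferenceGenome(
        {
            name: bases[rng.integers(0, 4, size=length)].tobytes().decode()
            for name, length in chrom_lengths.items()
        }
    )


def brute_force_mappability(genome: ReferenceGenome, k: int, both_strands=True):
    """All-k-mers dictionary oracle for the mappability track."""
    from collections import Counter

    counts: Counter = Counter()
    for seq in genome.sequences.values():
        strands = (seq, revcomp(seq)) if both_strands else (seq,)
        for s in strands:
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if "N" not in kmer:
                    counts[kmer] += 1
    tracks = {}
    for name, seq in genome.sequences.items():
        track = np.zeros(len(seq), bool)
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            track[i] = "N" not in kmer and counts[kmer] == 1
        tracks[name] = track
    return tracks


@pytest.fixture(scope="session")
def small_genome():
    return random_genome({"chrA": 6000, "chrB": 4000}, seed=20_240_101)
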