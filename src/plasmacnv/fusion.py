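"""Split-read mapping of rearrangement breakpoints in cfDNA reads.

Plasma DNA is too fragmented for read-pair (insert-size) methods, so
junctions are found from single reads: the first and last 60 bp of each
>=120 bp read are aligned independently (a 150 bp read leaves a 30 bp gap
between the halves).  Pairs whose halves map discordantly - after dropping
halves with mapping quality below 25 or inside repeat regions - are
candidate rearrangements; the exact junction is then refined by scanning
every split of the full read between the two loci and is reported with
leftmost-coordinate convention and the microhomology length.

A built-in exact-seed, ungapped aligner serves self-contained runs on
synthetic references; pre-aligned SAM input of the halves is accepted for
real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .reference import ReferenceGenome, revcomp

HEAD_LEN = 60
TAIL_LEN = 60
MIN_SPLIT_READ_LEN = HEAD_LEN + TAIL_LEN


@dataclass
class SplitFragmentPair:
    read_id: str
    head: str
    tail: str
    sequence: str

    @property
    def gap(self) -> int:
        return len(self.sequence) - HEAD_LEN - TAIL_LEN


@dataclass(frozen=True)
class FragmentAlignment:
    chromosome: str
    position: int  # 0-based leftmost on the forward reference
    strand: str  # '+' or '-'
    mapq: int
    unique: bool


@dataclass
class DiscordantCandidate:
    read_id: str
    head: FragmentAlignment
    tail: FragmentAlignment
    event_class: str  # deletion | inversion | interchromosomal | insertion-like
    implied_span: int
    sequence: str  # full read, oriented so the head maps forward


@dataclass
class BreakpointCall:
    chrom_a: str
    pos_a: int  # last reference base before the junction
    chrom_b: str
    pos_b: int  # first reference base after the junction
    orientation: str
    support: int
    microhomology: int
    refined: bool


def split_read(sequence: str, read_id: str = "read") -> SplitFragmentPair | None:
    """First/last 60 bp of a read; reads shorter than 120 bp are skipped."""
    if len(sequence) < MIN_SPLIT_READ_LEN:
        return None
    return SplitFragmentPair(
        read_id=read_id,
        head=sequence[:HEAD_LEN],
        tail=sequence[-TAIL_LEN:],
        sequence=sequence,
    )


class KmerIndex:
    """Exact-seed index: k-mer -> occurrence list, for ungapped alignment."""

    def __init__(self, genome: ReferenceGenome, k: int = 20, max_hits: int = 16):
        self.genome = genome
        self.k = k
        self.max_hits = max_hits
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in genome.sequences.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                hits = self.index.setdefault(kmer, [])
                if len(hits) <= max_hits:  # cap: beyond this it is repetitive anyway
                    hits.append((name, pos))


def _matches(frag: str, ref: str, pos: int) -> int:
    """Number of matching bases of frag laid on ref at pos (no gaps)."""
    if pos < 0 or pos + len(frag) > len(ref):
        return -1
    window = ref[pos : pos + len(frag)]
    return sum(a == b for a, b in zip(frag, window))


def align_fragment(
    fragment: str, index: KmerIndex, min_identity: float = 0.9
) -> list[FragmentAlignment]:
    """Seed-and-extend both strands; unique best hit gets mapq 60, ties mapq 0."""
    k = index.k
    if len(fragment) < k:
        return []
    best_score = int(np.ceil(min_identity * len(fragment))) - 1
    best: list[tuple[str, int, str]] = []
    for strand, seq in (("+", fragment), ("-", revcomp(fragment))):
        candidates: set[tuple[str, int]] = set()
        for offset in range(0, len(seq) - k + 1, k):
            for chrom, pos in index.index.get(seq[offset : offset + k], ()):
                candidates.add((chrom, pos - offset))
        for chrom, pos in candidates:
            score = _matches(seq, index.genome.sequences[chrom], pos)
            if score > best_score:
                best_score = score
                best = [(chrom, pos, strand)]
            elif score == best_score and score >= 0:
                best.append((chrom, pos, strand))
    if not best:
        return []
    unique = len(best) == 1
    return [
        FragmentAlignment(chrom, pos, strand, 60 if unique else 0, unique)
        for chrom, pos, strand in sorted(best)
    ]


def _in_repeats(aln: FragmentAlignment, repeats) -> bool:
    if not repeats:
        return False
    for chrom, start, end in repeats:
        if aln.chromosome == chrom and start <= aln.position < end:
            return True
    return False


def find_discordant(
    pairs: Iterable[tuple[SplitFragmentPair, list[FragmentAlignment], list[FragmentAlignment]]],
    min_mapq: int = 25,
    repeats: list[tuple[str, int, int]] | None = None,
    max_concordant_gap: int = 1000,
) -> list[DiscordantCandidate]:
    """Filter and classify aligned split pairs.

    A pair survives only if both halves have a single alignment with mapping
    quality >= ``min_mapq`` outside the repeat regions.  Same
    chromosome/strand pairs with an implied gap inside [0, max_concordant_gap]
    are concordant and dropped; a larger gap is a deletion candidate, strand
    mismatch an inversion, different chromosomes interchromosomal, and a
    negative gap insertion-like.  Minus/minus pairs are canonicalized to the
    forward orientation by reverse-complementing the read.
    """
    out = []
    for pair, head_alns, tail_alns in pairs:
        if len(head_alns) != 1 or len(tail_alns) != 1:
            continue
        head, tail = head_alns[0], tail_alns[0]
        if head.mapq < min_mapq or tail.mapq < min_mapq:
            continue
        if _in_repeats(head, repeats) or _in_repeats(tail, repeats):
            continue
        sequence = pair.sequence
        if head.strand == "-" and tail.strand == "-":
            # the reverse-complemented read has the tail's locus as its head
            head, tail = (
                FragmentAlignment(tail.chromosome, tail.position, "+", tail.mapq, tail.unique),
                FragmentAlignment(head.chromosome, head.position, "+", head.mapq, head.unique),
            )
            sequence = revcomp(sequence)
        if head.chromosome != tail.chromosome:
            cls, span = "interchromosomal", 0
        elif head.strand != tail.strand:
            cls, span = "inversion", abs(tail.position - head.position)
        else:
            gap = tail.position - (head.position + HEAD_LEN)
            if 0 <= gap <= max_concordant_gap:
                continue  # concordant
            if gap < 0:
                cls, span = "insertion-like", -gap
            else:
                cls, span = "deletion", gap
        out.append(
            DiscordantCandidate(
                read_id=pair.read_id,
                head=head,
                tail=tail,
                event_class=cls,
                implied_span=span,
                sequence=sequence,
            )
        )
    return out


def refine_breakpoint(
    candidate: DiscordantCandidate,
    genome: ReferenceGenome,
    min_identity: float = 0.9,
    min_side: int = 20,
) -> BreakpointCall:
    """Scan all splits of the full read between the two loci.

    The split maximizing total matched bases defines the junction; ties
    (microhomology) resolve to the leftmost coordinate on the head
    chromosome and the number of tying splits minus one is reported as the
    microhomology length.  If no split reaches ``min_identity`` on both
    sides the candidate is returned unrefined at the implied coordinates.
    """
    read = candidate.sequence
    n = len(read)
    ref_a = genome.sequences[candidate.head.chromosome]
    ref_b = genome.sequences[candidate.tail.chromosome]
    pa = candidate.head.position
    end_b = candidate.tail.position + TAIL_LEN  # read end anchored by the tail

    # prefix matches against the head locus
    pref = np.zeros(n + 1, dtype=int)
    for s in range(1, n + 1):
        if pa + s <= len(ref_a):
            pref[s] = pref[s - 1] + (read[s - 1] == ref_a[pa + s - 1])
        else:
            pref[s] = pref[s - 1]
    # suffix matches against the tail locus (read position i maps to end_b-(n-i))
    suff = np.zeros(n + 1, dtype=int)
    for s in range(n - 1, -1, -1):
        rpos = end_b - (n - s)
        hit = 0 <= rpos < len(ref_b) and read[s] == ref_b[rpos]
        suff[s] = suff[s + 1] + int(hit)

    best_total = -1
    best_splits: list[int] = []
    for s in range(min_side, n - min_side + 1):
        if pref[s] < min_identity * s or suff[s] < min_identity * (n - s):
            continue
        total = int(pref[s] + suff[s])
        if total > best_total:
            best_total = total
            best_splits = [s]
        elif total == best_total:
            best_splits.append(s)

    orientation = "+/+" if candidate.head.strand == candidate.tail.strand else "+/-"
    if not best_splits:
        return BreakpointCall(
            chrom_a=candidate.head.chromosome,
            pos_a=pa + HEAD_LEN - 1,
            chrom_b=candidate.tail.chromosome,
            pos_b=candidate.tail.position,
            orientation=orientation,
            support=1,
            microhomology=0,
            refined=False,
        )
    s = min(best_splits)  # leftmost convention
    pos_a = pa + s - 1
    pos_b = end_b - (n - s)
    # a "junction" between adjacent reference bases is a contiguous alignment,
    # not a rearrangement: reject
    contiguous = candidate.head.chromosome == candidate.tail.chromosome and pos_b == pos_a + 1
    return BreakpointCall(
        chrom_a=candidate.head.chromosome,
        pos_a=pos_a,
        chrom_b=candidate.tail.chromosome,
        pos_b=pos_b,
        orientation=orientation,
        support=1,
        microhomology=len(best_splits) - 1,
        refined=not contiguous,
    )


def call_fusions(calls: list[BreakpointCall], tolerance: int = 10) -> list[BreakpointCall]:
    """Cluster per-read breakpoints agreeing within ``tolerance`` bp.

    Support is the cluster size; the reported coordinates are the cluster's
    modal exact breakpoint (ties to the smallest).  Output sorted by support
    (descending) then coordinate, deterministically.
    """
    groups: dict[tuple, list[BreakpointCall]] = {}
    for call in calls:
        groups.setdefault(
            (call.chrom_a, call.chrom_b, call.orientation), []
        ).append(call)
    merged: list[BreakpointCall] = []
    for (ca, cb, ori), members in groups.items():
        members = sorted(members, key=lambda c: (c.pos_a, c.pos_b))
        clusters: list[list[BreakpointCall]] = []
        for call in members:
            placed = False
            for cluster in clusters:
                rep = cluster[0]
                if abs(call.pos_a - rep.pos_a) <= tolerance and abs(call.pos_b - rep.pos_b) <= tolerance:
                    cluster.append(call)
                    placed = True
                    break
            if not placed:
                clusters.append([call])
        for cluster in clusters:
            coords: dict[tuple[int, int], int] = {}
            for call in cluster:
                coords[(call.pos_a, call.pos_b)] = coords.get((call.pos_a, call.pos_b), 0) + 1
            (pos_a, pos_b), _ = min(coords.items(), key=lambda kv: (-kv[1], kv[0]))
            merged.append(
                BreakpointCall(
                    chrom_a=ca,
                    pos_a=pos_a,
                    chrom_b=cb,
                    pos_b=pos_b,
                    orientation=ori,
                    support=len(cluster),
                    microhomology=max(c.microhomology for c in cluster),
                    refined=any(c.refined for c in cluster),
                )
            )
    return sorted(merged, key=lambda c: (-c.support, c.chrom_a, c.pos_a, c.chrom_b, c.pos_b))


def read_fastq(path: str) -> Iterator[tuple[str, str]]:
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence.upper()


def detect_fusions(
    reads: Iterable[tuple[str, str]],
    genome: ReferenceGenome,
    repeats: list[tuple[str, int, int]] | None = None,
    min_mapq: int = 25,
    max_concordant_gap: int = 1000,
    index: KmerIndex | None = None,
) -> tuple[list[BreakpointCall], dict]:
    """Full split-read pipeline on raw reads; returns calls and run statistics."""
    if index is None:
        index = KmerIndex(genome)
    pairs = []
    n_short = 0
    n_total = 0
    for read_id, seq in reads:
        n_total += 1
        pair = split_read(seq, read_id)
        if pair is None:
            n_short += 1
            continue
        pairs.append(
            (pair, align_fragment(pair.head, index), align_fragment(pair.tail, index))
        )
    candidates = find_discordant(
        pairs, min_mapq=min_mapq, repeats=repeats, max_concordant_gap=max_concordant_gap
    )
    refined = [refine_breakpoint(c, genome) for c in candidates]
    calls = call_fusions([c for c in refined if c.refined])
    stats = {
        "n_reads": n_total,
        "n_too_short": n_short,
        "n_discordant": len(candidates),
        "n_refined": sum(c.refined for c in refined),
        "n_calls": len(calls),
    }
    return calls, stats


def write_calls(path: str, calls: list[BreakpointCall], meta: dict | None = None):
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write("chromA\tposA\tchromB\tposB\torientation\tsupport\tmicrohomology\n")
        for c in calls:
            fh.write(
                f"{c.chrom_a}\t{c.pos_a}\t{c.chrom_b}\t{c.pos_b}\t{c.orientation}\t"
                f"{c.support}\t{c.microhomology}\n"
            )


def write_bnd_vcf(path: str, calls: list[BreakpointCall], genome: ReferenceGenome):
    """Minimal VCF with breakend (BND) records for the calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in genome.lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting split reads">\n')
        fh.write('##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Microhomology length">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls):
            ref_base = genome.sequences[c.chrom_a][c.pos_a]
            alt = f"{ref_base}[{c.chrom_b}:{c.pos_b + 1}["
            fh.write(
                f"{c.chrom_a}\t{c.pos_a + 1}\tbnd_{i}\t{ref_base}\t{alt}\t.\tPASS\t"
                f"SVTYPE=BND;SUPPORT={c.support};HOMLEN={c.microhomology}\n"
            )
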