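"""Split-read breakpoint detection: geometry, alignment, refinement, calling."""

import numpy as np
import pytest

from plasmacnv.fixtures import FusionSpec, fusion_junction_truth, fusion_reads, random_genome
from plasmacnv.fusion import (
    KmerIndex,
    align_fragment,
    call_fusions,
    detect_fusions,
    find_discordant,
    refine_breakpoint,
    split_read,
)
from plasmacnv.reference import ReferenceGenome, revcomp


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(77)
    return random_genome({"chr1": 60_000, "chr2": 40_000}, rng)


@pytest.fixture(scope="module")
def index(genome):
    return KmerIndex(genome)


class TestSplitGeometry:
    def test_150bp_read_leaves_30bp_gap(self):
        read = "A" * 150
        pair = split_read(read)
        assert pair.head == read[0:60]
        assert pair.tail == read[90:150]
        assert pair.gap == 30

    def test_120bp_read_zero_gap(self):
        read = "C" * 120
        pair = split_read(read)
        assert pair.head == read[:60] and pair.tail == read[60:]
        assert pair.gap == 0

    def test_119bp_read_skipped(self):
        assert split_read("G" * 119) is None


class TestAlignFragment:
    def test_unique_fragment_maps_with_q60(self, genome, index):
        frag = genome.sequences["chr1"][5000:5060]
        alns = align_fragment(frag, index)
        assert len(alns) == 1
        aln = alns[0]
        assert (aln.chromosome, aln.position, aln.strand, aln.mapq) == ("chr1", 5000, "+", 60)
        assert aln.unique

    def test_duplicated_block_gets_q0(self, genome):
        seq = genome.sequences["chr1"]
        dup_genome = ReferenceGenome({"chr1": seq + seq[2000:2100]})
        dup_index = KmerIndex(dup_genome)
        alns = align_fragment(seq[2010:2070], dup_index)
        assert len(alns) == 2
        assert all(not a.unique and a.mapq == 0 for a in alns)

    def test_reverse_complement_maps_minus_strand(self, genome, index):
        frag = revcomp(genome.sequences["chr2"][1234:1294])
        alns = align_fragment(frag, index)
        assert len(alns) == 1
        assert (alns[0].chromosome, alns[0].position, alns[0].strand) == ("chr2", 1234, "-")

    def test_mismatches_tolerated_within_identity(self, genome, index):
        frag = list(genome.sequences["chr1"][8000:8060])
        frag[30] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[30]]
        alns = align_fragment("".join(frag), index)
        assert len(alns) == 1 and alns[0].position == 8000


def _aligned_pair(genome, index, read):
    pair = split_read(read)
    return pair, align_fragment(pair.head, index), align_fragment(pair.tail, index)


class TestDiscordant:
    def test_concordant_read_dropped(self, genome, index):
        read = genome.sequences["chr1"][3000:3150]
        cands = find_discordant([_aligned_pair(genome, index, read)])
        assert cands == []

    def test_deletion_candidate_with_span(self, genome, index):
        seq = genome.sequences["chr1"]
        fused = seq[10_000 - 75 : 10_000] + seq[40_000 : 40_000 + 75]
        cands = find_discordant([_aligned_pair(genome, index, fused)])
        assert len(cands) == 1
        c = cands[0]
        assert c.event_class == "deletion"
        assert abs(c.implied_span - 30_000) < 200

    def test_interchromosomal_candidate(self, genome, index):
        fused = genome.sequences["chr1"][500:575] + genome.sequences["chr2"][9000:9075]
        cands = find_discordant([_aligned_pair(genome, index, fused)])
        assert len(cands) == 1 and cands[0].event_class == "interchromosomal"

    def test_low_mapq_half_filtered(self, genome):
        seq = genome.sequences["chr1"]
        dup_genome = ReferenceGenome({"chr1": seq + seq[20_000:20_200]})
        dup_index = KmerIndex(dup_genome)
        # head falls inside the duplicated block -> two best hits -> mapq 0
        fused = seq[20_050:20_110] + "N" * 0 + seq[45_000:45_090]
        cands = find_discordant([_aligned_pair(dup_genome, dup_index, fused)])
        assert cands == []

    def test_repeat_bed_filter(self, genome, index):
        seq = genome.sequences["chr1"]
        fused = seq[10_000 - 75 : 10_000] + seq[40_000 : 40_000 + 75]
        cands = find_discordant(
            [_aligned_pair(genome, index, fused)],
            repeats=[("chr1", 9_000, 11_000)],
        )
        assert cands == []


class TestRefine:
    def test_exact_junction_zero_microhomology(self, genome, index):
        fusion = FusionSpec("chr1", 15_000, 35_000)
        truth_a, truth_b, mh = fusion_junction_truth(genome, fusion)
        rng = np.random.default_rng(1)
        reads = fusion_reads(genome, fusion, 6, 150, rng)
        pairs = [_aligned_pair(genome, index, seq) for _, seq in reads]
        cands = find_discordant(pairs)
        assert len(cands) == 6
        for cand in cands:
            call = refine_breakpoint(cand, genome)
            assert call.refined
            assert (call.pos_a, call.pos_b) == (truth_a, truth_b)
            assert call.microhomology == mh

    def test_constructed_microhomology_leftmost(self):
        rng = np.random.default_rng(2)
        g = random_genome({"c": 4000}, rng)
        seq = list(g.sequences["c"])
        # force a 4-base homology across the junction 1000 / 3000
        seq[2996:3000] = seq[996:1000]
        # break accidental extension of the homology on either side
        comp = {"A": "C", "C": "A", "G": "T", "T": "G"}
        seq[995] = comp[seq[2995]]
        seq[1000] = comp[seq[3000]]
        g = ReferenceGenome({"c": "".join(seq)})
        fusion = FusionSpec("c", 1000, 3000)
        truth_a, truth_b, mh = fusion_junction_truth(g, fusion)
        assert mh == 4
        assert truth_a == 995  # leftmost representation
        idx = KmerIndex(g)
        reads = fusion_reads(g, fusion, 4, 150, rng)
        cands = find_discordant([_aligned_pair(g, idx, seq_) for _, seq_ in reads])
        for cand in cands:
            call = refine_breakpoint(cand, g)
            assert (call.pos_a, call.pos_b, call.microhomology) == (truth_a, truth_b, 4)

    def test_concordant_read_rejected_by_refinement(self, genome, index):
        from plasmacnv.fusion import DiscordantCandidate, FragmentAlignment

        seq = genome.sequences["chr1"][7000:7150]
        cand = DiscordantCandidate(
            read_id="r",
            head=FragmentAlignment("chr1", 7000, "+", 60, True),
            tail=FragmentAlignment("chr1", 7090, "+", 60, True),
            event_class="deletion",
            implied_span=30,
            sequence=seq,
        )
        assert not refine_breakpoint(cand, genome).refined


class TestCalling:
    def test_single_junction_support_five(self, genome, index):
        fusion = FusionSpec("chr1", 12_000, 42_000)
        truth_a, truth_b, _ = fusion_junction_truth(genome, fusion)
        rng = np.random.default_rng(3)
        reads = fusion_reads(genome, fusion, 5, 150, rng)
        calls, stats = detect_fusions(reads, genome, index=index)
        assert len(calls) == 1
        assert calls[0].support == 5
        assert (calls[0].pos_a, calls[0].pos_b) == (truth_a, truth_b)

    def test_two_distinct_junctions(self, genome, index):
        rng = np.random.default_rng(4)
        f1 = FusionSpec("chr1", 12_000, 42_000)
        f2 = FusionSpec("chr2", 5_000, 30_000)
        reads = fusion_reads(genome, f1, 4, 150, rng) + [
            (f"b{i}", s) for i, (_, s) in enumerate(fusion_reads(genome, f2, 3, 150, rng))
        ]
        calls, _ = detect_fusions(reads, genome, index=index)
        assert len(calls) == 2
        assert calls[0].support == 4 and calls[1].support == 3

    def test_no_calls_on_concordant_reads(self, genome, index):
        rng = np.random.default_rng(5)
        seq = genome.sequences["chr1"]
        reads = [
            (f"r{i}", seq[p : p + 150])
            for i, p in enumerate(rng.integers(0, len(seq) - 150, 500))
        ]
        calls, stats = detect_fusions(reads, genome, index=index)
        assert calls == [] and stats["n_discordant"] == 0

    def test_empty_input(self, genome, index):
        calls, stats = detect_fusions([], genome, index=index)
        assert calls == [] and stats["n_reads"] == 0

    def test_deterministic_ordering(self, genome, index):
        rng = np.random.default_rng(6)
        f1 = FusionSpec("chr1", 12_000, 42_000)
        reads = fusion_reads(genome, f1, 4, 150, rng)
        a, _ = detect_fusions(reads, genome, index=index)
        b, _ = detect_fusions(reads, genome, index=index)
        assert a == b
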