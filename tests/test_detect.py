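"""Split-read discovery: prefilter, split aligner (vs brute force), refinement."""

import numpy as np
import pytest

from circkit import simulate as sim
from circkit._seq import revcomp
from circkit.detect import (
    BackspliceJunction,
    call_candidates,
    collapse_duplicates,
    detect_junctions,
    dinucleotide_enrichment,
    find_split_alignments,
    linear_prefilter,
    refine_splice_signal,
)
from circkit.formats import GenomeRef, ReadRecord


from oracles import brute_force_split


class TestLinearPrefilter:
    def test_exonic_read_is_mapped(self, sim_world):
        genome, models = sim_world["genome"], sim_world["models"]
        m = models[0]
        seq = genome.fetch(m.chrom, m.exons[0][0], m.exons[0][0] + 60)
        mapped, unmapped = linear_prefilter([ReadRecord("r1", seq)], genome)
        assert len(mapped) == 1 and not unmapped
        assert mapped[0].start == m.exons[0][0]

    def test_mismatches_tolerated_up_to_two(self, sim_world):
        genome, models = sim_world["genome"], sim_world["models"]
        m = models[0]
        seq = list(genome.fetch(m.chrom, m.exons[0][0], m.exons[0][0] + 60))
        for i in (5, 25):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        mapped, unmapped = linear_prefilter([ReadRecord("r1", "".join(seq))], genome)
        assert len(mapped) == 1 and mapped[0].n_mismatches == 2
        seq[45] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[45]]
        mapped, unmapped = linear_prefilter([ReadRecord("r1", "".join(seq))], genome)
        assert not mapped and len(unmapped) == 1

    def test_backspliced_read_stays_unmapped(self, sim_world):
        genome, models = sim_world["genome"], sim_world["models"]
        m = models[0]
        a, b = m.exons[1], m.exons[2]  # back-spliced order: end of later exon + start of earlier
        read = genome.fetch(m.chrom, b[1] - 20, b[1]) + genome.fetch(m.chrom, a[0], a[0] + 20)
        mapped, unmapped = linear_prefilter([ReadRecord("r1", read)], genome)
        assert not mapped and len(unmapped) == 1

    def test_duplicate_collapse(self):
        reads = [ReadRecord(f"r{i}", "ACGT" * 15) for i in range(1000)]
        assert len(collapse_duplicates(reads)) == 1

    def test_reverse_complement_maps(self, sim_world):
        genome, models = sim_world["genome"], sim_world["models"]
        m = models[0]
        seq = revcomp(genome.fetch(m.chrom, m.exons[0][0], m.exons[0][0] + 60))
        mapped, _ = linear_prefilter([ReadRecord("r1", seq)], genome)
        assert len(mapped) == 1 and mapped[0].strand == "-"


class TestFindSplitAlignments:
    def test_planted_junction_single_placement(self, sim_world):
        genome, truth = sim_world["genome"], sim_world["truth"]
        circ = truth.circles[0]
        cseq = genome.chroms[circ.chrom]
        read = cseq[circ.donor_end - 30 : circ.donor_end] + cseq[
            circ.acceptor_start : circ.acceptor_start + 30
        ]
        (aln,) = find_split_alignments([ReadRecord("r1", read)], genome)
        assert aln.reversed_order
        junction = refine_splice_signal(aln, genome)
        assert (junction.acceptor_start, junction.donor_end) == (
            circ.acceptor_start,
            circ.donor_end,
        )

    def test_tandem_duplication_read_discarded(self):
        rng = np.random.default_rng(0)
        core = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        # duplicate a 200-nt block: every junction read has two placements
        genome = GenomeRef({"chr1": core + core[:200] + core[:200] + core[-50:]})
        read = core[100:130] + core[20:50]  # reversed-order within the repeat
        assert find_split_alignments([ReadRecord("r1", read)], genome) == []

    def test_different_chromosome_segments_not_emitted(self):
        rng = np.random.default_rng(1)
        a = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        b = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        genome = GenomeRef({"chrA": a, "chrB": b})
        read = a[50:80] + b[50:80]
        assert find_split_alignments([ReadRecord("r1", read)], genome) == []

    def test_short_reads_skipped(self, sim_world):
        genome = sim_world["genome"]
        assert find_split_alignments([ReadRecord("r1", "ACGT" * 8)], genome) == []

    def test_matches_brute_force_on_simulated_reads(self, sim_world):
        """Oracle equivalence on junction, linear and random reads."""
        genome, truth = sim_world["genome"], sim_world["truth"]
        rng = np.random.default_rng(7)
        reads = []
        cseq = genome.chroms["chrS"]
        for circ in truth.circles:
            reads.append(
                cseq[circ.donor_end - 35 : circ.donor_end]
                + cseq[circ.acceptor_start : circ.acceptor_start + 25]
            )
        reads.append(cseq[100:160])  # contiguous: placements exist? no split pair
        for _ in range(5):
            reads.append("".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)]))
        for i, seq in enumerate(reads):
            got = find_split_alignments([ReadRecord(f"r{i}", seq)], genome)
            expected = brute_force_split(seq, genome)
            if len(expected) == 1:
                (aln,) = got
                junction = refine_splice_signal(aln, genome)
                canon = brute_force_split(aln.sequence, genome)
                assert {(junction.chrom,)} == {(c,) for c, _, _ in canon}
                ((chrom, acc, de),) = expected
                assert abs(junction.acceptor_start - acc) <= 5
            else:
                assert got == []


class TestRefineSpliceSignal:
    @staticmethod
    def _genome_with_junction(donor_flank, acceptor_flank, shift_repeat=""):
        """Build a genome with a planted back-splice: acceptor exon at 100,
        donor exon ending at 400, given intronic flanks."""
        rng = np.random.default_rng(3)
        s = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 600)]))
        acc, de = 100, 400
        s[de : de + len(donor_flank)] = donor_flank
        s[acc - len(acceptor_flank) : acc] = acceptor_flank
        if shift_repeat:
            k = len(shift_repeat)
            s[de - k : de] = shift_repeat
            s[acc - len(acceptor_flank) - k : acc - len(acceptor_flank)] = shift_repeat
        genome = GenomeRef({"chr1": "".join(s)})
        read = genome.fetch("chr1", de - 30, de) + genome.fetch("chr1", acc, acc + 30)
        return genome, read, acc, de

    def test_direct_gt_ag(self):
        genome, read, acc, de = self._genome_with_junction("GTAAGT", "TTTCAG"[:4] + "AG")
        (aln,) = find_split_alignments([ReadRecord("r", read)], genome)
        j = refine_splice_signal(aln, genome)
        assert (j.signal_class, j.strand, j.acceptor_start, j.donor_end) == ("GT-AG", "+", acc, de)

    def test_at_ac_minor_spliceosome(self):
        genome, read, acc, de = self._genome_with_junction("ATATCC", "TTTTAC"[:4] + "AC")
        (aln,) = find_split_alignments([ReadRecord("r", read)], genome)
        j = refine_splice_signal(aln, genome)
        assert (j.signal_class, j.acceptor_start, j.donor_end) == ("AT-AC", acc, de)

    def test_no_signal_is_other(self):
        genome, read, acc, de = self._genome_with_junction("CCCCCC", "TTTTTT")
        (aln,) = find_split_alignments([ReadRecord("r", read)], genome)
        j = refine_splice_signal(aln, genome)
        assert j.signal_class == "other"
        assert (j.acceptor_start, j.donor_end) == (acc, de)

    def test_shift_onto_signal_with_junction_repeat(self):
        """A repeated "AG" straddling the break means the alignment is two
        placements apart from the true splice sites; GT-AG appears only at
        shift +2, found by enumerating valid shifts."""
        rng = np.random.default_rng(11)
        s = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 600)]))
        # repeated word "AG" at [100,102) and [400,402): the aligner cannot
        # distinguish breakpoints (100,400) and (102,402); the true splice
        # sites are acc=102, de=402 (AG ends the upstream intron at 102,
        # GT starts the downstream intron at 402)
        s[100:102] = "AG"
        s[400:402] = "AG"
        s[402:404] = "GT"
        genome = GenomeRef({"chr1": "".join(s)})
        read = genome.fetch("chr1", 370, 400) + genome.fetch("chr1", 100, 130)
        (aln,) = find_split_alignments([ReadRecord("r", read)], genome)
        j = refine_splice_signal(aln, genome)
        assert j.signal_class == "GT-AG"
        assert (j.acceptor_start, j.donor_end) == (102, 402)

    def test_idempotent_on_refined_coordinates(self, sim_world):
        genome, truth = sim_world["genome"], sim_world["truth"]
        circ = truth.circles[0]
        cseq = genome.chroms[circ.chrom]
        read = cseq[circ.donor_end - 30 : circ.donor_end] + cseq[
            circ.acceptor_start : circ.acceptor_start + 30
        ]
        (aln,) = find_split_alignments([ReadRecord("r1", read)], genome)
        j1 = refine_splice_signal(aln, genome)
        j2 = refine_splice_signal(aln, genome)
        assert j1.key == j2.key

    def test_n_in_flank_gives_other(self):
        genome, read, acc, de = self._genome_with_junction("GTAAGT", "TTTCAG"[:4] + "AG")
        chrom = list(genome.chroms["chr1"])
        chrom[de + 5] = "N"
        genome2 = GenomeRef({"chr1": "".join(chrom)})
        (aln,) = find_split_alignments([ReadRecord("r", read)], genome2)
        assert refine_splice_signal(aln, genome2).signal_class == "other"


class TestCallCandidates:
    @staticmethod
    def _junction(acc=100, de=400):
        return BackspliceJunction("chr1", "+", acc, de, "GT-AG")

    def test_single_read_excluded(self):
        assert call_candidates([(self._junction(), "s1")], min_reads=2) == []

    def test_three_reads_retained(self):
        refined = [(self._junction(), "s1")] * 3
        (j,) = call_candidates(refined)
        assert j.support == {"s1": 3}

    def test_support_in_any_one_sample_suffices(self):
        refined = [(self._junction(), "s1"), (self._junction(), "s2"), (self._junction(), "s2")]
        (j,) = call_candidates(refined)
        assert j.support == {"s1": 1, "s2": 2}

    def test_simulated_recall_and_precision(self, sim_pipeline):
        """All planted circles called exactly; no spurious GT-AG calls."""
        truth = sim_pipeline["truth"]
        gt_ag = {j.key for j in sim_pipeline["candidates"] if j.signal_class == "GT-AG"}
        expected = {c.junction().key for c in truth.circles}
        assert gt_ag == expected


class TestDinucleotideEnrichment:
    def test_simulated_circles_show_gt_ag(self, sim_pipeline):
        genome = sim_pipeline["genome"]
        table = dinucleotide_enrichment(sim_pipeline["candidates"], genome)
        donor0 = table[(table.side == "donor") & (table.offset == 0)].iloc[0]
        acceptor_last = table[(table.side == "acceptor") & (table.offset == 8)].iloc[0]
        assert donor0["GT"] == 1.0
        assert acceptor_last["AG"] == 1.0

    def test_rows_sum_to_one(self, sim_pipeline):
        table = dinucleotide_enrichment(sim_pipeline["candidates"], sim_pipeline["genome"])
        dinucs = [a + b for a in "ACGT" for b in "ACGT"]
        assert np.allclose(table[dinucs].sum(axis=1), 1.0)

    def test_empty_candidates_empty_table(self, sim_world):
        assert dinucleotide_enrichment([], sim_world["genome"]).empty

    def test_background_positions_near_genome_frequency(self, sim_world):
        """Junctions planted at random positions: no dinucleotide dominates."""
        genome = sim_world["genome"]
        rng = np.random.default_rng(23)
        fake = []
        for _ in range(300):
            acc = int(rng.integers(50, 2000))
            de = int(rng.integers(acc + 100, acc + 2000))
            fake.append(
                BackspliceJunction("chrS", "+", acc, de, "other", support={"s1": 5})
            )
        table = dinucleotide_enrichment(fake, genome)
        dinucs = [a + b for a in "ACGT" for b in "ACGT"]
        # uniform random genome: every dinucleotide near 1/16
        assert (table[dinucs].to_numpy() < 0.17).all()
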