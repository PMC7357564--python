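import numpy as np
import pytest

from ilpminer.detect import match_framework, scan_sequences
from ilpminer.records import SequenceRecord
from ilpminer.simulate import (
    GeneModelSpec,
    gene_model_spec,
    make_genome,
    make_ilp_gene,
    simulate_reads,
    tile_reads,
)


class TestGeneModelSpec:
    def test_aigf_archetype_has_four_coding_exons(self):
        spec = gene_model_spec("aIGF")
        assert len(spec.exon_lengths) == 4
        assert 0 < spec.alt_splice_offset < spec.exon_lengths[2]

    def test_frame_inconsistent_exons_rejected(self):
        with pytest.raises(ValueError, match="reading frame"):
            GeneModelSpec("insulin", (100, 87), (180,))

    def test_alt_site_only_for_aigf(self):
        with pytest.raises(ValueError):
            GeneModelSpec("relaxin", (90, 87), (180,), alt_splice_offset=30)


class TestMakeIlpGene:
    def test_precursor_carries_framework(self, family_genes):
        for gene in family_genes.values():
            for prot in gene.proteins.values():
                assert match_framework(prot) is not None

    def test_aigf_isoforms_differ_only_by_alt_segment(self):
        spec = gene_model_spec("aIGF")
        g = make_ilp_gene(spec, seed=3, gene_id="g")
        long, short = g.transcripts[0].residues, g.transcripts[1].residues
        off = spec.alt_splice_offset
        e12 = spec.exon_lengths[0] + spec.exon_lengths[1]
        prefix = e12 + off
        alt_len = spec.exon_lengths[2] - off
        assert long[:prefix] == short[:prefix]
        assert long[prefix + alt_len :] == short[prefix:]
        # the included segment encodes an arginine-rich stretch with 2 cysteines
        from Bio.Seq import Seq

        alt_aa = str(Seq(long[prefix : prefix + alt_len]).translate())
        assert alt_aa.count("C") == 2
        assert sum(alt_aa.count(a) for a in "RK") / len(alt_aa) >= 0.5

    def test_gtv_motif_in_last_exon(self):
        from ilpminer.detect import detect_gtv_motif

        spec = gene_model_spec("aIGF")
        g = make_ilp_gene(spec, seed=3, gene_id="g")
        for prot in g.proteins.values():
            assert detect_gtv_motif(prot) is not None

    def test_non_aigf_has_single_isoform_with_six_cysteines(self):
        g = make_ilp_gene(gene_model_spec("relaxin"), seed=3, gene_id="g")
        assert len(g.transcripts) == 1
        assert g.proteins["g.t1"].count("C") == 6

    def test_seven_cysteine_variant(self):
        g = make_ilp_gene(
            gene_model_spec("relaxin", seven_cysteines=True), seed=3, gene_id="g"
        )
        assert g.proteins["g.t1"].count("C") == 7

    def test_determinism(self):
        spec = gene_model_spec("aIGF")
        a = make_ilp_gene(spec, seed=9, gene_id="g")
        b = make_ilp_gene(spec, seed=9, gene_id="g")
        assert a.genomic == b.genomic
        assert [t.residues for t in a.transcripts] == [t.residues for t in b.transcripts]

    def test_minus_strand_gene_spliced_equivalence(self):
        from Bio.Seq import Seq

        spec = gene_model_spec("insulin", strand="-")
        g = make_ilp_gene(spec, seed=4, gene_id="g")
        plus = str(Seq(g.genomic).reverse_complement())
        cds = g.transcripts[0].residues
        # exon pieces of the minus-strand gene appear in the revcomp
        assert cds[: spec.exon_lengths[0]] in plus
        assert cds[spec.exon_lengths[0] :] in plus


class TestMakeGenome:
    def test_planted_gene_extraction_matches(self, small_genome):
        genome = small_genome.genome.residues
        for gene, (s, e) in zip(small_genome.genes, small_genome.gene_spans):
            assert genome[s - 1 : e] == gene.genomic

    def test_truth_intergenic_distances_exact(self, small_genome):
        spans = small_genome.gene_spans
        gaps = [spans[i + 1][0] - spans[i][1] - 1 for i in range(len(spans) - 1)]
        assert gaps == [5000, 8000]

    def test_pure_decoy_yields_no_precursors(self):
        gb = make_genome(n_clusters=0, decoy_length=120_000, seed=8)
        assert scan_sequences([gb.genome], min_aa=60) == []

    def test_features_consistent_with_genome(self, small_genome):
        length = len(small_genome.genome.residues)
        for f in small_genome.features:
            assert 1 <= f.start <= f.end <= length

    def test_detector_recall_on_transcripts(self, small_genome, panel):
        for gene in small_genome.genes:
            hits = scan_sequences(gene.transcripts, min_aa=60, reference_panel=panel)
            assert hits, f"gene {gene.gene_id} not detected"


@pytest.fixture(scope="module")
def transcripts():
    rng = np.random.default_rng(0)
    make = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    return [
        SequenceRecord("t1", make(600), "dna"),
        SequenceRecord("t2", make(450), "dna"),
    ]


class TestSimulateReads:

    def test_error_free_reads_are_exact_substrings(self, transcripts):
        from Bio.Seq import Seq

        spots, truth = simulate_reads(
            transcripts, [1, 1], n_spots=200, read_length=80, seed=2
        )
        seqs = {t.id: t.residues for t in transcripts}
        by_id = {s.spot_id: s for s in spots}
        for row in truth.rows:
            mate = by_id[row["read_id"].split("/")[0]].mates[row["mate"] - 1]
            origin = seqs[row["transcript_id"]]
            probe = mate if row["strand"] == "+" else str(Seq(mate).reverse_complement())
            assert origin[row["offset"] - 1 : row["offset"] - 1 + 80] == probe

    def test_paired_spots_emit_two_half_spots(self, transcripts):
        spots, truth = simulate_reads(
            transcripts, [1, 1], n_spots=500, read_length=80, paired=True, seed=2
        )
        assert len(spots) == 500
        assert sum(s.n_half_spots for s in spots) == 1000
        assert len(truth.rows) == 1000

    def test_multinomial_weights_within_binomial_noise(self, transcripts):
        # weights 10:1 over 11000 spots: expected 10000 vs 1000 reads;
        # the count for t1 is Binomial(11000, 10/11)
        n = 11000
        p = 10 / 11
        spots, truth = simulate_reads(
            transcripts, [10, 1], n_spots=n, read_length=80, seed=3
        )
        n1 = sum(1 for r in truth.rows if r["transcript_id"] == "t1")
        sd = (n * p * (1 - p)) ** 0.5
        assert abs(n1 - n * p) <= 3 * sd

    def test_weight_validation(self, transcripts):
        with pytest.raises(ValueError):
            simulate_reads(transcripts, [1, 0], n_spots=10, read_length=80)

    def test_read_longer_than_transcript_rejected(self, transcripts):
        with pytest.raises(ValueError):
            simulate_reads(transcripts, [1, 1], n_spots=10, read_length=451)

    def test_determinism(self, transcripts):
        a = simulate_reads(transcripts, [2, 1], n_spots=50, read_length=80, seed=7)
        b = simulate_reads(transcripts, [2, 1], n_spots=50, read_length=80, seed=7)
        assert [s.mates for s in a[0]] == [s.mates for s in b[0]]
        assert a[1].rows == b[1].rows

    def test_tiling_covers_both_termini(self, transcripts):
        spots, truth = tile_reads(transcripts[0], read_length=80, step=7)
        offsets = [r["offset"] for r in truth.rows]
        assert min(offsets) == 1
        assert max(offsets) == 600 - 80 + 1
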