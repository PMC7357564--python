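from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ilpminer.detect import (
    DEFAULT_PATTERN,
    FrameworkPattern,
    PrecursorAnnotation,
    alignment_identity,
    annotate_protein,
    classify_precursor,
    detect_arginine_rich,
    detect_gtv_motif,
    find_orfs,
    match_framework,
    predict_signal_peptide,
)
from ilpminer.records import SequenceRecord


def brute_force_framework(protein, pattern):
    """Independent oracle: enumerate all 6-subsets of cysteine positions."""
    cys = [i + 1 for i, a in enumerate(protein.upper()) if a == "C"]
    hits = []
    for combo in combinations(cys, 6):
        if all(
            lo <= b - a - 1 <= hi
            for (lo, hi), a, b in zip(pattern.gaps, combo, combo[1:])
        ):
            extra = [p for p in cys if combo[0] < p < combo[5] and p not in combo]
            if extra and not pattern.allow_extra_cysteines:
                continue
            hits.append(combo)
    return min(hits) if hits else None


class TestFindOrfs:
    @pytest.mark.parametrize(
        "seq,min_aa,expect",
        [
            ("ATGAAATGCTGA", 3, [("MKC", "+", 1)]),
            ("TCACATTTTCAT", 3, [("MKM", "-", 1)]),
            ("AAAAAAAAA", 1, []),
        ],
    )
    def test_known_orfs(self, seq, min_aa, expect):
        rec = SequenceRecord("s", seq, "dna")
        orfs = find_orfs(rec, min_aa=min_aa)
        assert [(o.aa_sequence, o.strand, o.frame) for o in orfs] == expect

    def test_coordinates_translate_back(self):
        rec = SequenceRecord("s", "CCATGAAATGCTGACC", "dna")
        (orf,) = find_orfs(rec, min_aa=3)
        assert (orf.start, orf.end) == (3, 14)  # ATG..TGA inclusive

    def test_protein_input_rejected(self):
        with pytest.raises(ValueError):
            find_orfs(SequenceRecord("p", "MKL", "protein"), min_aa=1)


class TestMatchFramework:
    TOY = "ACGGGGGGCGGGGGGGGGGCCGGGCGGGGGGGGCAA"

    def test_constructed_example(self):
        m = match_framework(self.TOY)
        assert m.positions == (2, 9, 20, 21, 25, 34)
        assert m.extension_length == 2
        assert m.extra_cysteines == ()

    def test_too_few_cysteines(self):
        assert match_framework("ACCA") is None

    def test_extra_cysteine_recorded_when_allowed(self):
        toy = self.TOY[:12] + "C" + self.TOY[12:]  # extra C in the C-peptide
        relaxed = FrameworkPattern(allow_extra_cysteines=True)
        m = match_framework(toy, relaxed)
        assert m is not None and len(m.extra_cysteines) == 1
        assert match_framework(toy, DEFAULT_PATTERN) is None

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(st.sampled_from("G" * 8 + "CC"), min_size=20, max_size=200)
        .map("".join)
        .filter(lambda s: s.count("C") <= 12),
        st.booleans(),
    )
    def test_agrees_with_brute_force(self, protein, allow_extra):
        pattern = FrameworkPattern(allow_extra_cysteines=allow_extra)
        got = match_framework(protein, pattern)
        want = brute_force_framework(protein, pattern)
        assert (got.positions if got else None) == want


class TestMotifs:
    @pytest.mark.parametrize(
        "seq,expect",
        [
            ("AAGTVAPSFAA", (3, 9)),
            ("GTVAPSY", (1, 7)),
            ("GTAAPSF", None),
        ],
    )
    def test_gtv_motif(self, seq, expect):
        assert detect_gtv_motif(seq) == expect

    def test_arginine_rich_core(self):
        span = detect_arginine_rich("GGRRKRRCRRRRCRRRGG")
        assert span is not None
        s, e = span
        assert s <= 3 and e >= 16  # covers the basic/cysteine core

    def test_no_basic_residues(self):
        assert detect_arginine_rich("G" * 20) is None

    def test_requires_two_cysteines(self):
        assert detect_arginine_rich("GGRRKRRCRRRRRRRRGG", required_cys=2) is None
        assert detect_arginine_rich("GGRRKRRCRRRRRRRRGG", required_cys=1) is not None


class TestSignalPeptide:
    EXAMPLE = "MKLLVLLLLLLLAGASDFGHKLMNPQRSTV"

    def test_worked_example(self):
        # hand-derived: hydrophobic 7-windows qualify at starts 1..10,
        # first position after the core with -1/-3 small residues is the
        # mature start 16, i.e. cleavage after A15
        assert predict_signal_peptide(self.EXAMPLE) == 15

    def test_acidic_n_terminus_has_no_core(self):
        assert predict_signal_peptide("MDDEEDDEEKKRRDDEEDDEEKKRRDDEE") is None

    def test_local_rule_ignores_far_c_terminus(self):
        tail1 = "A" * 30
        tail2 = "WWWWWDDDDDPPPPPGGGGGHHHHHKKKKK"
        base = self.EXAMPLE + "KLMNPQRSTV"  # pad to position 40
        assert predict_signal_peptide(base + tail1) == predict_signal_peptide(
            base + tail2
        )


class TestClassification:
    def _ann(self, positions=(20, 31, 48, 49, 53, 62), ext=2, gtv=None, arg=None):
        from ilpminer.detect import FrameworkMatch

        fw = FrameworkMatch(positions=positions, extra_cysteines=(), extension_length=ext)
        return PrecursorAnnotation("x", fw, gtv_span=gtv, arginine_rich_span=arg)

    def test_aigf_rule_wins_first(self):
        ann = self._ann(ext=80, gtv=(100, 106))
        ann.scores = {"relaxin": 0.9}
        assert classify_precursor(ann, {}, min_ext=40).family == "aIGF"

    def test_similarity_rule(self):
        ann = self._ann(ext=2)
        ann.scores = {"relaxin": 0.9, "insulin": 0.3}
        assert classify_precursor(ann, {}).family == "relaxin"

    def test_gonadulin_candidate_fallback(self):
        ann = self._ann(ext=5)
        ann.scores = {"relaxin": 0.1, "insulin": 0.1, "aIGF": 0.1}
        assert classify_precursor(ann, {}).family == "gonadulin-candidate"

    def test_tie_broken_lexicographically_and_order_invariant(self):
        for order in (("aIGF", "relaxin"), ("relaxin", "aIGF")):
            ann = self._ann(ext=2)
            ann.scores = {fam: 0.8 for fam in order}
            assert classify_precursor(ann, {}).family == "aIGF"

    def test_requires_framework(self):
        ann = PrecursorAnnotation("x", None)
        with pytest.raises(ValueError):
            classify_precursor(ann, {})

    def test_identity_bounds(self):
        assert alignment_identity("MKWVTF", "MKWVTF") == 1.0
        assert 0 <= alignment_identity("MKWVTF", "GGGGGG") < 0.5

    def test_planted_families_classified(self, family_genes, panel):
        expected = {
            "insulin": "insulin",
            "aIGF": "aIGF",
            "relaxin": "relaxin",
            "gonadulin": "gonadulin-candidate",
        }
        for fam, gene in family_genes.items():
            prot = gene.proteins[f"{fam}_g.t1"]
            ann = annotate_protein(f"{fam}_g.t1", prot, reference_panel=panel)
            assert ann is not None and ann.family == expected[fam]
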