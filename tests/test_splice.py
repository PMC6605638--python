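import numpy as np
import pytest

from oracles import sw_score

from ctt._alphabet import revcomp, translate_cds
from ctt.align import six_frame_translate
from ctt.seqio import SequenceRecord
from ctt.splice import SpliceParams, classify_model, spliced_align
from ctt.synthetic import reverse_translate

AAS = "ARNDCQEGHILKMFPSTWYV"


def _prot(rng, n):
    return "".join(AAS[i] for i in rng.integers(0, 20, n))


def _dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="module")
def orf():
    """A planted 121-codon ORF with 200-nt flanks."""
    rng = np.random.default_rng(42)
    prot = "M" + _prot(rng, 120)
    cds = reverse_translate(prot, rng)[:-3]
    left, right = _dna(rng, 200), _dna(rng, 200)
    return prot, cds, left, right, rng


def _tpl(prot):
    return SequenceRecord("tpl", prot, "protein")


class TestSplicedAlign:
    def test_intronless_planted_orf(self, orf):
        prot, cds, left, right, _ = orf
        seg = SequenceRecord("w", left + cds + right, "dna")
        m = spliced_align(_tpl(prot), seg)
        assert m is not None
        assert m.exons == [(201, 200 + len(cds))]
        assert m.protein == prot
        assert m.cds == cds
        assert m.strand == "+"
        assert not m.has_lesions

    def test_single_gt_ag_intron(self, orf):
        prot, cds, left, right, _ = orf
        rng = np.random.default_rng(1)
        intron = "GT" + _dna(rng, 76) + "AG"
        seg = SequenceRecord(
            "w", left + cds[:180] + intron + cds[180:] + right, "dna")
        m = spliced_align(_tpl(prot), seg)
        assert m is not None
        assert len(m.exons) == 2
        assert m.protein == prot
        assert m.cds == cds
        # intron boundaries exactly at the planted GT..AG
        assert m.exons[0][1] == 200 + 180
        assert m.exons[1][0] == 200 + 180 + 80 + 1

    def test_reverse_strand_exons_ascending(self, orf):
        prot, cds, left, right, _ = orf
        seg_fwd = left + cds + right
        seg = SequenceRecord("w", revcomp(seg_fwd), "dna")
        m = spliced_align(_tpl(prot), seg)
        assert m.strand == "-"
        assert all(a[1] < b[0] for a, b in zip(m.exons, m.exons[1:])) or \
            len(m.exons) == 1
        spliced = "".join(seg.residues[s - 1:e] for s, e in m.exons)
        assert revcomp(spliced) == m.cds

    def test_one_base_deletion_reports_frameshift(self, orf):
        prot, cds, left, right, _ = orf
        broken = cds[:181] + cds[182:]
        seg = SequenceRecord("w", left + broken + right, "dna")
        m = spliced_align(_tpl(prot), seg)
        assert m.lesions["frameshift"] >= 1
        assert classify_model(m, True) == "pseudogene_stop"

    def test_premature_stop_reports_internal_stop(self, orf):
        prot, cds, left, right, _ = orf
        broken = cds[:180] + "TGA" + cds[183:]
        seg = SequenceRecord("w", left + broken + right, "dna")
        m = spliced_align(_tpl(prot), seg)
        assert m.lesions["internal_stop"] >= 1
        assert "*" in m.protein

    def test_exon_concatenation_reproduces_cds(self, orf):
        prot, cds, left, right, _ = orf
        rng = np.random.default_rng(2)
        intron = "GT" + _dna(rng, 96) + "AG"
        seg_str = left + cds[:90] + intron + cds[90:] + right
        m = spliced_align(_tpl(prot), SequenceRecord("w", seg_str, "dna"))
        assert "".join(seg_str[s - 1:e] for s, e in m.exons) == m.cds
        assert translate_cds(m.cds) == m.protein

    def test_below_threshold_returns_none(self, orf):
        prot, *_ = orf
        rng = np.random.default_rng(3)
        seg = SequenceRecord("w", _dna(rng, 400), "dna")
        assert spliced_align(_tpl(prot), seg,
                             SpliceParams(score_threshold=60.0)) is None

    def test_too_short_segment(self, orf):
        prot, *_ = orf
        assert spliced_align(_tpl(prot),
                             SequenceRecord("w", "AT", "dna")) is None

    def test_mutated_templates_never_beat_self(self, orf):
        """Score degrades monotonically under template mutation: the exact
        template's score is an upper bound across 50 mutants."""
        prot, cds, left, right, _ = orf
        seg = SequenceRecord("w", left + cds + right, "dna")
        self_score = spliced_align(_tpl(prot), seg).score
        rng = np.random.default_rng(4)
        for _ in range(50):
            mut = list(prot)
            for _ in range(int(rng.integers(1, 15))):
                mut[int(rng.integers(len(mut)))] = AAS[
                    int(rng.integers(20))]
            m = spliced_align(_tpl("".join(mut)), seg,
                              SpliceParams(score_threshold=1.0))
            assert m is None or m.score <= self_score

    def test_intronless_mode_equals_six_frame_sw_oracle(self):
        """With introns and frameshifts disabled the spliced aligner is an
        exact protein-vs-translation Smith-Waterman, frame by frame."""
        rng = np.random.default_rng(5)
        params = SpliceParams(score_threshold=1.0, allow_introns=False,
                              allow_frameshifts=False,
                              stop_codon_penalty=-4)  # BLOSUM62 '*' score
        for _ in range(8):
            prot = _prot(rng, int(rng.integers(10, 30)))
            seg_str = _dna(rng, int(rng.integers(60, 200)))
            # embed a related stretch so scores are non-trivial
            seg_str += reverse_translate(prot[:12], rng)[:-3] + seg_str[:30]
            seg = SequenceRecord("w", seg_str, "dna")
            m = spliced_align(SequenceRecord("t", prot, "protein"), seg,
                              params)
            oracle = max(
                sw_score(prot, fr.protein, stop_score=-4)
                for fr in six_frame_translate(seg) if fr.protein)
            got = 0 if m is None else int(m.score)
            if oracle < 1:
                assert m is None or got == oracle
            else:
                assert got == oracle


class TestClassifyModel:
    def test_zero_lesion_model_is_coding(self, orf):
        prot, cds, left, right, _ = orf
        m = spliced_align(_tpl(prot),
                          SequenceRecord("w", left + cds + right, "dna"))
        assert classify_model(m, True) == "coding"
        assert m.model_class == "coding"

    def test_no_model_with_hit_is_pseudogene_no_transcript(self):
        assert classify_model(None, True) == "pseudogene_no_transcript"

    def test_no_model_no_hit_raises(self):
        with pytest.raises(ValueError):
            classify_model(None, False)


class TestSpliceParams:
    def test_penalties_must_be_negative(self):
        with pytest.raises(ValueError):
            SpliceParams(intron_open_penalty=1)
        with pytest.raises(ValueError):
            SpliceParams(min_intron=2)
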