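import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import greedy_cluster_ids, sw_score

from ctt.align import (
    DEFAULT_SCHEME,
    ScoringScheme,
    build_profile,
    cluster_identity,
    dna_vs_protein_search,
    evalue,
    global_identity,
    local_align,
    scan_domain,
    six_frame_translate,
    translated_genome_search,
)
from ctt.seqio import SeedSet, SequenceRecord
from ctt.synthetic import reverse_translate
from ctt._alphabet import revcomp

AAS = "ARNDCQEGHILKMFPSTWYV"


def _prot(rng, n):
    return "".join(AAS[i] for i in rng.integers(0, 20, n))


def _rec(i, s):
    return SequenceRecord(i, s, "protein")


class TestLocalAlign:
    def test_self_alignment(self):
        h = local_align(_rec("q", "MKV"), _rec("s", "MKV"))
        assert h.identity_pct == 100.0
        assert (h.q_start, h.q_end, h.s_start, h.s_end) == (1, 3, 1, 3)

    def test_disjoint_alphabets_no_hit_sentinel(self):
        h = local_align(_rec("q", "AAAA"), _rec("s", "WWWW"))
        assert h.raw_score == 0
        assert (h.q_start, h.q_end) == (0, 0)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            local_align(_rec("q", "---"), _rec("s", "MKV"))

    def test_matches_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            q = _prot(rng, int(rng.integers(5, 41)))
            s = _prot(rng, int(rng.integers(5, 41)))
            h = local_align(_rec("q", q), _rec("s", s))
            assert h.raw_score == sw_score(q, s)
            assert h.raw_score >= 0

    def test_scheme_invariants(self):
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=-1, gap_extend=-11)
        with pytest.raises(ValueError):
            ScoringScheme(ka_lambda=0.0)


class TestEvalue:
    def test_zero_score_gives_kmn(self):
        scheme = DEFAULT_SCHEME
        assert evalue(0, 10, 20) == pytest.approx(scheme.ka_k * 200)

    def test_linear_in_database_size(self):
        assert evalue(30, 100, 2000) == pytest.approx(2 * evalue(30, 100,
                                                                 1000))

    def test_closed_form(self):
        # K*m*n*exp(-lambda*S) with the default constants
        expected = 0.041 * 100 * 100 * math.exp(-0.267 * 50)
        assert evalue(50, 100, 100) == pytest.approx(expected)

    def test_strictly_decreasing_in_score(self):
        es = [evalue(s, 100, 1000) for s in range(0, 200, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))


class TestSixFrame:
    def test_standard_code_forward(self):
        frames = {f.frame: f for f in six_frame_translate(
            SequenceRecord("d", "ATGAAA", "dna"))}
        assert frames[1].protein == "MK"
        assert list(frames[1].codon_starts) == [1, 4]

    def test_reverse_complement_frame(self):
        frames = {f.frame: f for f in six_frame_translate(
            SequenceRecord("d", "TTTCAT", "dna"))}
        assert frames[-1].protein == "MK"

    def test_short_sequence_empty_frames(self):
        frames = six_frame_translate(SequenceRecord("d", "AT", "dna"))
        assert all(f.protein == "" for f in frames)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=9, max_size=60))
    def test_codon_map_round_trip(self, seq):
        """Mapping a residue back to its codon and retranslating it must
        reproduce the residue, on every frame and strand."""
        from ctt._alphabet import translate_cds
        rec = SequenceRecord("d", seq, "dna")
        for fr in six_frame_translate(rec):
            for i, aa in enumerate(fr.protein):
                start = int(fr.codon_starts[i])
                codon = seq[start - 1:start + 2]
                if fr.frame < 0:
                    codon = revcomp(codon)
                assert translate_cds(codon) == aa


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(11)
    prot = _prot(rng, 100)
    cds = reverse_translate(prot, rng)[:-3]  # drop the stop codon
    def bg(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    fwd = bg(1000) + cds + bg(1000)
    return prot, cds, fwd


class TestTranslatedGenomeSearch:
    def test_planted_orf_interval_recovered(self, planted):
        prot, cds, fwd = planted
        hits = translated_genome_search(
            [_rec("q", prot)], [SequenceRecord("c", fwd, "dna")])
        assert hits
        assert (hits[0].s_start, hits[0].s_end) == (1001, 1000 + len(cds))
        assert hits[0].strand == "+"

    def test_reverse_strand_same_interval(self, planted):
        prot, cds, fwd = planted
        hits = translated_genome_search(
            [_rec("q", prot)], [SequenceRecord("c", revcomp(fwd), "dna")])
        assert hits
        L = len(fwd)
        assert (hits[0].s_start, hits[0].s_end) == (L - (1000 + len(cds)) + 1,
                                                    L - 1000)
        assert hits[0].strand == "-"

    def test_shuffled_query_finds_nothing(self, planted):
        prot, _cds, fwd = planted
        rng = np.random.default_rng(5)
        shuffled = "".join(rng.permutation(list(prot)))
        hits = translated_genome_search(
            [_rec("q", shuffled)], [SequenceRecord("c", fwd, "dna")],
            evalue_cutoff=1e-5)
        assert hits == []

    def test_contig_reorder_invariance(self, planted):
        prot, _cds, fwd = planted
        rng = np.random.default_rng(6)
        other = "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
        a = SequenceRecord("a", fwd, "dna")
        b = SequenceRecord("b", other, "dna")
        h1 = translated_genome_search([_rec("q", prot)], [a, b])
        h2 = translated_genome_search([_rec("q", prot)], [b, a])
        key = lambda h: (h.query_id, h.subject_id, h.s_start, h.s_end,
                         h.raw_score)
        assert [key(h) for h in h1] == [key(h) for h in h2]

    def test_empty_genome(self):
        assert translated_genome_search([_rec("q", "MKVLW")], []) == []


class TestDnaVsProteinSearch:
    def test_own_translation_ranked_first(self):
        rng = np.random.default_rng(3)
        prot = _prot(rng, 60)
        cds = reverse_translate(prot, rng)
        seg = SequenceRecord("seg", cds, "dna")
        db = [_rec("other", _prot(rng, 60)), _rec("self", prot)]
        hits = dna_vs_protein_search(seg, db, top_k=2)
        assert hits[0].subject_id == "self"
        assert hits[0].identity_pct == 100.0

    def test_tie_break_by_subject_id(self):
        rng = np.random.default_rng(4)
        prot = _prot(rng, 50)
        cds = reverse_translate(prot, rng)
        seg = SequenceRecord("seg", cds, "dna")
        hits = dna_vs_protein_search(seg, [_rec("b", prot), _rec("a", prot)],
                                     top_k=2)
        assert [h.subject_id for h in hits] == ["a", "b"]

    def test_two_gene_segment_both_templates_found(self):
        rng = np.random.default_rng(9)
        p1, p2 = _prot(rng, 70), _prot(rng, 70)
        spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        seg = SequenceRecord("seg", reverse_translate(p1, rng) + spacer
                             + reverse_translate(p2, rng), "dna")
        hits = dna_vs_protein_search(seg, [_rec("p1", p1), _rec("p2", p2)],
                                     top_k=2)
        assert {h.subject_id for h in hits} == {"p1", "p2"}

    def test_empty_database(self):
        seg = SequenceRecord("seg", "ATGATGATGATG", "dna")
        assert dna_vs_protein_search(seg, [], top_k=1) == []


class TestProfile:
    def test_identical_sequences_top_residue(self):
        ss = SeedSet([_rec(f"s{i}", "MKVW") for i in range(3)], "PF")
        prof = build_profile(ss)
        order = "ARNDCQEGHILKMFPSTWYV"
        for ci, aa in enumerate("MKVW"):
            assert np.argmax(prof.matrix[ci, :20]) == order.index(aa)

    def test_log_odds_signs(self):
        ss = SeedSet([_rec(f"s{i}", "CCCC") for i in range(5)], "PF")
        prof = build_profile(ss)
        order = "ARNDCQEGHILKMFPSTWYV"
        c = order.index("C")
        assert (prof.matrix[:, c] > 0).all()
        others = [i for i in range(20) if i != c]
        assert (prof.matrix[:, others] < 0).all()

    def test_closed_form_two_column_toy(self):
        ss = SeedSet([_rec("a", "AC"), _rec("b", "AD"), _rec("c", "AC")],
                     "PF")
        prof = build_profile(ss)
        def expected(count, n=3, pseudo=1.0, bg=0.05):
            return math.log2((count + pseudo) / (n + 20 * pseudo) / bg)
        order = "ARNDCQEGHILKMFPSTWYV"
        assert prof.matrix[0, order.index("A")] == pytest.approx(
            expected(3), abs=1e-5)
        assert prof.matrix[1, order.index("C")] == pytest.approx(
            expected(2), abs=1e-5)
        assert prof.matrix[1, order.index("D")] == pytest.approx(
            expected(1), abs=1e-5)
        assert prof.matrix[1, order.index("W")] == pytest.approx(
            expected(0), abs=1e-5)

    def test_needs_two_sequences(self):
        from types import SimpleNamespace
        lone = SimpleNamespace(members=[_rec("a", "MKVW")], family_id="PF")
        with pytest.raises(ValueError):
            build_profile(lone)

    def test_unaligned_seeds_are_star_aligned(self):
        ss = SeedSet([_rec("a", "MKVWDE"), _rec("b", "MKVDE"),
                      _rec("c", "MKVWDE")], "PF")
        prof = build_profile(ss)
        assert prof.length == 6


@pytest.fixture(scope="module")
def family():
    from ctt.synthetic import make_family
    return make_family(5, domain_length=48, divergence_rate=0.08,
                       rng_seed=3)


class TestScanDomain:
    def test_planted_domain_found_and_spanned(self, family):
        seed_set, _ = family
        rng = np.random.default_rng(8)
        flank1, flank2 = _prot(rng, 30), _prot(rng, 40)
        seedseq = seed_set.members[0].residues
        prot = _rec("p", flank1 + seedseq + flank2)
        prof = build_profile(seed_set)
        hit = scan_domain(prot, prof, 1.0)
        assert hit is not None
        assert hit.d_start >= 25 and hit.d_end <= 31 + len(seedseq) + 5
        assert hit.evalue < 1e-10

    def test_reversed_protein_rejected(self, family):
        seed_set, _ = family
        rng = np.random.default_rng(8)
        prot = _rec("p", ( _prot(rng, 30) + seed_set.members[0].residues
                          + _prot(rng, 40))[::-1])
        assert scan_domain(prot, build_profile(seed_set), 1.0) is None

    def test_threshold_monotonicity(self, family):
        seed_set, _ = family
        prof = build_profile(seed_set)
        # a weak, partial domain match
        weak = _rec("w", seed_set.members[0].residues[:14])
        at_loose = scan_domain(weak, prof, 1.0)
        at_tight = scan_domain(weak, prof, 1e-5)
        if at_loose is None:
            pytest.skip("partial domain scored below the loose cutoff")
        assert at_tight is None or at_tight.evalue <= 1e-5


class TestClusterIdentity:
    def test_identical_collapse(self):
        reps = cluster_identity([_rec("a", "MKVW"), _rec("b", "MKVW")], 0.9)
        assert len(reps) == 1

    def test_threshold_one_keeps_distinct(self):
        rng = np.random.default_rng(2)
        recs = [_rec(f"s{i}", _prot(rng, 30)) for i in range(5)]
        assert len(cluster_identity(recs, 1.0)) == 5

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(12)
        base = _prot(rng, 40)
        recs = []
        for i in range(10):
            s = list(base)
            for _ in range(int(rng.integers(0, 8))):
                pos = int(rng.integers(0, 40))
                s[pos] = AAS[int(rng.integers(0, 20))]
            recs.append(_rec(f"s{i:02d}", "".join(s)))
        reps = cluster_identity(recs, 0.9)
        assert [r.id for r in reps] == greedy_cluster_ids(
            recs, 0.9, global_identity)

    def test_empty_input(self):
        assert cluster_identity([], 0.9) == []

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            cluster_identity([], 0.0)
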