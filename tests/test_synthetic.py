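import numpy as np
import pytest

from ctt._alphabet import revcomp, translate_cds
from ctt.seqio import read_fasta, read_gff3, read_manifest
from ctt.synthetic import (
    PRESETS,
    make_family,
    mutate_pseudogene,
    plant_genome,
    read_truth,
    reverse_translate,
    write_dataset,
)


class TestMakeFamily:
    def test_deterministic_per_seed(self):
        a = make_family(5, rng_seed=7)
        b = make_family(5, rng_seed=7)
        assert [m.residues for m in a[1]] == [m.residues for m in b[1]]
        assert [s.residues for s in a[0].members] == \
               [s.residues for s in b[0].members]

    def test_distinct_seeds_differ(self):
        a = make_family(5, rng_seed=1)
        b = make_family(5, rng_seed=2)
        assert [m.residues for m in a[1]] != [m.residues for m in b[1]]

    def test_zero_divergence_shares_domain_verbatim(self):
        seed_set, _ = make_family(4, divergence_rate=0.0, rng_seed=3)
        assert len({s.residues for s in seed_set.members}) == 1

    @pytest.mark.parametrize("preset", sorted(PRESETS))
    def test_domain_length_presets(self, preset):
        n = PRESETS[preset]["domain_length"]
        seed_set, _ = make_family(3, domain_length=n, rng_seed=1)
        assert all(len(s.residues) == n for s in seed_set.members)

    def test_identity_decreases_with_divergence(self):
        def mean_pairwise(rate):
            seed_set, _ = make_family(6, divergence_rate=rate, rng_seed=5)
            seqs = [s.residues for s in seed_set.members]
            idents = [np.mean([a == b for a, b in zip(x, y)])
                      for i, x in enumerate(seqs) for y in seqs[i + 1:]]
            return float(np.mean(idents))
        assert mean_pairwise(0.0) > mean_pairwise(0.1) > mean_pairwise(0.3)

    def test_too_few_members_raises(self):
        with pytest.raises(ValueError):
            make_family(2)


class TestMutatePseudogene:
    CDS = reverse_translate("M" + "AR" * 20, np.random.default_rng(0))

    def test_stop_lesion_translates_with_internal_stop(self):
        mutated = mutate_pseudogene(self.CDS, "stop", rng_seed=1)
        aa = translate_cds(mutated)
        assert "*" in aa[:-1]

    def test_frameshift_lesion_length(self):
        mutated = mutate_pseudogene(self.CDS, "frameshift", rng_seed=1)
        assert len(mutated) % 3 == 2

    def test_deterministic(self):
        assert mutate_pseudogene(self.CDS, "stop", 9) == \
               mutate_pseudogene(self.CDS, "stop", 9)

    def test_short_cds_raises(self):
        with pytest.raises(ValueError):
            mutate_pseudogene("ATG" * 10, "stop")

    def test_spliced_alignment_reports_matching_lesion(self):
        """Cross-module oracle: aligning the lesioned locus against its own
        original template reports the planted lesion type."""
        from ctt.seqio import SequenceRecord
        from ctt.splice import spliced_align
        prot = translate_cds(self.CDS)[:-1]
        tpl = SequenceRecord("t", prot, "protein")
        rng = np.random.default_rng(2)
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        stop_m = spliced_align(
            tpl, flank + mutate_pseudogene(self.CDS, "stop", 1) + flank)
        assert stop_m.lesions["internal_stop"] >= 1
        fs_m = spliced_align(
            tpl, flank + mutate_pseudogene(self.CDS, "frameshift", 1)
            + flank)
        assert fs_m.lesions["frameshift"] >= 1


class TestPlantGenome:
    def test_truth_consistency(self, small_dataset):
        truth = small_dataset.truth
        assert len(truth.of_class("annotated")) == 8
        assert len(truth.of_class("hidden_coding")) == 5
        tandem = [l for l in truth.loci if l.tandem_group]
        assert len({l.tandem_group for l in tandem}) == 2
        assert all(
            sum(1 for l in tandem if l.tandem_group == g) == 2
            for g in {l.tandem_group for l in tandem})

    def test_loci_non_overlapping(self, small_dataset):
        loci = sorted(small_dataset.truth.loci, key=lambda l: l.start)
        assert all(a.end < b.start for a, b in zip(loci, loci[1:]))

    def test_hidden_loci_absent_from_annotation(self, small_dataset):
        annotated_ids = {f.feature_id for f in small_dataset.features}
        proteome_ids = {p.id for p in small_dataset.proteome}
        for locus in small_dataset.truth.hidden:
            assert locus.locus_id not in annotated_ids
            assert locus.locus_id not in proteome_ids

    def test_gff3_cds_retranslates_to_proteome(self, small_dataset):
        """Self-consistency: splicing the emitted CDS intervals out of the
        genome and translating reproduces each proteome entry."""
        contig = small_dataset.genome[0].residues
        proteins = {p.id: p.residues for p in small_dataset.proteome}
        by_gene = {}
        for f in small_dataset.features:
            if f.kind == "CDS":
                gene = f.feature_id.split(".")[0]
                by_gene.setdefault(gene, []).append(f)
        assert set(by_gene) == set(proteins)
        for gene, rows in by_gene.items():
            rows.sort(key=lambda f: f.start)
            spliced = "".join(contig[f.start - 1:f.end] for f in rows)
            if rows[0].strand == "-":
                spliced = revcomp(spliced)
            assert translate_cds(spliced) == proteins[gene] + "*"

    def test_zero_hidden(self, small_family):
        genome, features, proteome, truth = plant_genome(
            [small_family], n_annotated=4, n_hidden=0, n_tandem_pairs=0,
            n_pseudo=0, contig_length=60_000, rng_seed=3)
        assert truth.hidden == []
        assert len(proteome) == 4

    def test_overcrowded_contig_raises(self, small_family):
        with pytest.raises(ValueError, match="overcrowded"):
            plant_genome([small_family], n_annotated=10, n_hidden=5,
                         n_tandem_pairs=2, n_pseudo=3,
                         contig_length=12_000, rng_seed=1)

    def test_deterministic(self, small_family):
        g1, _, _, t1 = plant_genome([small_family], n_annotated=4,
                                    n_hidden=2, n_tandem_pairs=1,
                                    n_pseudo=1, contig_length=60_000,
                                    rng_seed=9)
        g2, _, _, t2 = plant_genome([small_family], n_annotated=4,
                                    n_hidden=2, n_tandem_pairs=1,
                                    n_pseudo=1, contig_length=60_000,
                                    rng_seed=9)
        assert g1[0].residues == g2[0].residues
        assert [l.locus_id for l in t1.loci] == [l.locus_id for l in t2.loci]


class TestWriteDataset:
    def test_emitted_files_parse_cleanly(self, tmp_path):
        paths = write_dataset(tmp_path, preset="fbox", rng_seed=4,
                              n_annotated=4, n_hidden=2, n_tandem_pairs=1,
                              n_pseudo=1, contig_length=60_000)
        genome = read_fasta(paths["genome"], "dna")
        proteome = read_fasta(paths["proteome"], "protein")
        seeds = read_fasta(paths["seeds"], "protein", allow_gaps=True)
        feats = read_gff3(paths["gff3"])
        manifest = read_manifest(paths["manifest"])
        truth = read_truth(paths["truth"])
        assert len(genome) == 1 and len(proteome) == 4 and len(seeds) == 10
        assert len(manifest.rows) == 1
        assert {f.kind for f in feats} == {"gene", "mRNA", "CDS"}
        assert [l.locus_id for l in truth.loci] == \
               [l.locus_id for l in paths["truth_obj"].loci]
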