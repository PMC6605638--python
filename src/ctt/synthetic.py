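"""Synthetic genomes with planted superfamily loci.

The generator emulates the data situation the annotation pipeline was
built for: a genome whose prior annotation knows some family members
(emitted to GFF3 + proteome) while further members are hidden — including
tandem duplicates sitting next to annotated genes (the case that defeats
best-homology-only prediction), pseudogenized copies carrying premature
stops or 1-nt frameshifts, and optional decoy loci from an unrelated
family. Every locus is a reverse-translated protein, optionally split by
GT..AG introns inserted at codon boundaries; intergenic space is i.i.d.
uniform ACGT. All randomness flows from one integer seed.

Domain-length presets follow the three families used as published test
cases: F-box (48 aa), BTB (108 aa) and Pkinase (267 aa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from ._alphabet import revcomp, translate_cds
from .seqio import GeneFeature, SeedSet, SequenceRecord, write_fasta

AA20 = "ARNDCQEGHILKMFPSTWYV"
STOP_CODONS = ("TAA", "TAG", "TGA")

_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS_FOR.setdefault(_aa, []).append(_codon)

PRESETS = {
    "fbox": {"domain_length": 48, "family_id": "PF00646"},
    "btb": {"domain_length": 108, "family_id": "PF00651"},
    "pkinase": {"domain_length": 267, "family_id": "PF00069"},
}


@dataclass
class PlantedLocus:
    locus_id: str
    seqid: str
    start: int
    end: int
    strand: str
    cls: str  # annotated | hidden_coding | hidden_pseudo_stop |
    #           hidden_pseudo_frameshift | decoy_family
    family_id: str
    tandem_group: Optional[str]
    protein: str
    n_introns: int
    cds_exons: list[tuple[int, int]] = field(default_factory=list)
    # 1-based intervals within the locus, gene orientation

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PlantedTruth:
    loci: list[PlantedLocus]

    def of_class(self, *classes: str) -> list[PlantedLocus]:
        return [l for l in self.loci if l.cls in classes]

    @property
    def hidden(self) -> list[PlantedLocus]:
        return [l for l in self.loci if l.cls != "annotated"]


def _mutate_protein(protein: str, rate: float, rng) -> str:
    out = list(protein)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_protein(length: int, rng) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, length))


def _random_dna(length: int, rng) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def make_family(n_members: int, domain_length: int = 48,
                divergence_rate: float = 0.1, rng_seed: int = 0,
                n_seeds: int = 10, family_id: str = "PF00646"
                ) -> tuple[SeedSet, list[SequenceRecord]]:
    """A family as an ancestral full-length protein with a signature domain.

    Members are independently diverged copies of the whole ancestral
    protein (family members are homologous along their full length, as in
    real superfamilies, so any member can serve as a full-gene prediction
    template for any other); seeds are diverged copies of the domain
    region only, mimicking a curated domain seed alignment.
    """
    if n_members < 3:
        raise ValueError("need at least 3 family members")
    if not (0 <= divergence_rate <= 0.5):
        raise ValueError("divergence_rate must be in [0, 0.5]")
    rng = np.random.default_rng(rng_seed)
    domain = _random_protein(domain_length, rng)
    nflank = _random_protein(int(rng.integers(20, 61)), rng)
    cflank = _random_protein(int(rng.integers(40, 121)), rng)
    ancestor = "M" + nflank + domain + cflank
    seeds = [SequenceRecord(f"{family_id}_seed{i + 1:03d}",
                            _mutate_protein(domain, divergence_rate, rng),
                            "protein")
             for i in range(n_seeds)]
    members = []
    for i in range(n_members):
        prot = _mutate_protein(ancestor, divergence_rate, rng)
        members.append(SequenceRecord(f"{family_id}_mem{i + 1:03d}",
                                      "M" + prot[1:], "protein"))
    return SeedSet(seeds, family_id), members


def reverse_translate(protein: str, rng) -> str:
    """Protein to CDS with uniform synonymous codon choice, plus a stop."""
    codons = [_CODONS_FOR[a][rng.integers(len(_CODONS_FOR[a]))]
              for a in protein]
    codons.append(STOP_CODONS[rng.integers(3)])
    return "".join(codons)


def mutate_pseudogene(cds: str, lesion: str, rng_seed=0) -> str:
    """Introduce one pseudogene lesion into a CDS.

    ``stop`` replaces one codon in the middle third by a stop codon;
    ``frameshift`` deletes one base in the middle third. Deterministic for
    a given seed (an existing Generator is also accepted).
    """
    if len(cds) < 60 or len(cds) % 3:
        raise ValueError("cds must be >= 60 nt and a multiple of 3")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    n_codons = len(cds) // 3
    lo, hi = n_codons // 3, 2 * n_codons // 3
    if lesion == "stop":
        ci = int(rng.integers(lo, hi))
        stop = STOP_CODONS[rng.integers(3)]
        return cds[:3 * ci] + stop + cds[3 * ci + 3:]
    if lesion == "frameshift":
        pos = int(rng.integers(len(cds) // 3, 2 * len(cds) // 3))
        return cds[:pos] + cds[pos + 1:]
    raise ValueError(f"unknown lesion {lesion!r}")


def _build_gene(protein: str, rng, intron_rate: float, with_introns: bool,
                lesion: Optional[str] = None
                ) -> tuple[str, list[tuple[int, int]], int]:
    """Gene sequence (gene orientation), CDS exon intervals within it
    (1-based inclusive), and the intron count."""
    cds = reverse_translate(protein, rng)
    if lesion is not None:
        cds = mutate_pseudogene(cds, lesion, rng)
        return cds, [(1, len(cds))], 0
    n_codons = len(cds) // 3
    n_introns = 0
    if with_introns and rng.random() < intron_rate and n_codons > 40:
        n_introns = int(rng.integers(1, 3))
    junctions = sorted(rng.choice(np.arange(10, n_codons - 10),
                                  size=n_introns, replace=False)) \
        if n_introns else []
    pieces = []
    exons = []
    pos = 0  # nt written so far
    prev = 0  # codons emitted
    for j in junctions:
        exon_nt = cds[3 * prev:3 * j]
        pieces.append(exon_nt)
        exons.append((pos + 1, pos + len(exon_nt)))
        pos += len(exon_nt)
        ilen = int(rng.integers(70, 151))
        intron = "GT" + _random_dna(ilen - 4, rng) + "AG"
        pieces.append(intron)
        pos += len(intron)
        prev = j
    tail = cds[3 * prev:]
    pieces.append(tail)
    exons.append((pos + 1, pos + len(tail)))
    return "".join(pieces), exons, n_introns


def plant_genome(families: Sequence[tuple[SeedSet, list[SequenceRecord]]],
                 n_annotated: int = 30, n_hidden: int = 20,
                 n_tandem_pairs: int = 8, n_pseudo: int = 10,
                 intron_rate: float = 0.5, contig_length: int = 500_000,
                 rng_seed: int = 0, n_decoy: int = 0,
                 tandem_divergence: float = 0.04, contig_id: str = "chr1"
                 ) -> tuple[list[SequenceRecord], list[GeneFeature],
                            list[SequenceRecord], PlantedTruth]:
    """Plant family loci in a random contig.

    Tandem pairs place a hidden, lightly diverged duplicate 200-2000 nt
    from an annotated copy (on the same strand); all other loci are
    spaced at least 500 nt apart. Annotated loci are emitted to the GFF3
    and proteome; hidden ones only to the truth table. Pseudogenes carry
    one premature stop or one 1-nt deletion and are kept intronless.
    """
    if n_tandem_pairs > min(n_hidden, n_annotated):
        raise ValueError("more tandem pairs than hidden/annotated loci")
    rng = np.random.default_rng(rng_seed)
    seed_set, members = families[0]
    fam = seed_set.family_id
    need = n_annotated + (n_hidden - n_tandem_pairs) + n_pseudo
    if need > len(members):
        raise ValueError(f"need {need} member proteins, got {len(members)}")
    it = iter(members)

    # locus descriptors: (locus_id, protein, cls, family, tandem_group, lesion)
    descriptors = []
    tandem_partner: dict[str, tuple] = {}
    for i in range(n_annotated):
        m = next(it)
        desc = (f"ann{i + 1:03d}", m.residues, "annotated", fam, None, None)
        descriptors.append(desc)
        if i < n_tandem_pairs:
            dup = _mutate_protein(m.residues, tandem_divergence, rng)
            tandem_partner[desc[0]] = (f"tan{i + 1:03d}", dup,
                                       "hidden_coding", fam,
                                       f"tg{i + 1:02d}", None)
            descriptors[-1] = desc[:4] + (f"tg{i + 1:02d}", None)
    for i in range(n_hidden - n_tandem_pairs):
        m = next(it)
        descriptors.append((f"hid{i + 1:03d}", m.residues, "hidden_coding",
                            fam, None, None))
    for i in range(n_pseudo):
        m = next(it)
        lesion = "stop" if i % 2 == 0 else "frameshift"
        descriptors.append((f"psg{i + 1:03d}", m.residues,
                            f"hidden_pseudo_{lesion}", fam, None, lesion))
    if n_decoy:
        if len(families) < 2:
            raise ValueError("decoy loci need a second family")
        decoy_members = families[1][1]
        for i in range(n_decoy):
            descriptors.append((f"dcy{i + 1:03d}",
                                decoy_members[i].residues, "decoy_family",
                                families[1][0].family_id, None, None))

    # group into placement units (tandem pairs stay adjacent)
    units = []
    for desc in descriptors:
        if desc[0] in tandem_partner:
            units.append([desc, tandem_partner[desc[0]]])
        else:
            units.append([desc])
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    placements = []  # (desc, gene_seq, exons, n_introns, start, strand)
    pos = int(rng.integers(1000, 3001))
    for unit in units:
        strand = "+" if rng.random() < 0.5 else "-"
        for k, desc in enumerate(unit):
            locus_id, protein, cls, family, tgroup, lesion = desc
            with_introns = cls in ("annotated", "hidden_coding",
                                   "decoy_family")
            gene_seq, exons, n_introns = _build_gene(
                protein, rng, intron_rate, with_introns, lesion)
            placements.append((desc, gene_seq, exons, n_introns, pos,
                               strand))
            pos += len(gene_seq)
            if k < len(unit) - 1:
                pos += int(rng.integers(200, 2001))  # tandem spacing
            else:
                pos += int(rng.integers(800, 3001))
    if pos > contig_length - 1000:
        raise ValueError(
            f"overcrowded contig: need {pos + 1000} nt, have "
            f"{contig_length}")

    genome_arr = np.array(list(_random_dna(contig_length, rng)))
    features: list[GeneFeature] = []
    proteome: list[SequenceRecord] = []
    loci: list[PlantedLocus] = []
    for desc, gene_seq, exons, n_introns, start, strand in placements:
        locus_id, protein, cls, family, tgroup, lesion = desc
        end = start + len(gene_seq) - 1
        inserted = gene_seq if strand == "+" else revcomp(gene_seq)
        genome_arr[start - 1:end] = list(inserted)
        loci.append(PlantedLocus(locus_id, contig_id, start, end, strand,
                                 cls, family, tgroup, protein, n_introns,
                                 exons))
        if cls != "annotated":
            continue
        features.append(GeneFeature(contig_id, start, end, strand,
                                    locus_id, "gene"))
        features.append(GeneFeature(contig_id, start, end, strand,
                                    f"{locus_id}.1", "mRNA"))
        for xi, (a, b) in enumerate(exons, 1):
            if strand == "+":
                gs, ge = start + a - 1, start + b - 1
            else:
                gs, ge = end - b + 1, end - a + 1
            features.append(GeneFeature(contig_id, gs, ge, strand,
                                        f"{locus_id}.1.cds{xi}", "CDS"))
        proteome.append(SequenceRecord(locus_id, protein, "protein"))
    loci.sort(key=lambda l: l.start)
    genome = [SequenceRecord(contig_id, "".join(genome_arr), "dna")]
    return genome, features, proteome, PlantedTruth(loci)


# ---------------------------------------------------------------------------
# on-disk dataset


def write_dataset(out_dir, preset: str = "fbox", rng_seed: int = 0,
                  n_members: Optional[int] = None,
                  divergence_rate: float = 0.1,
                  family_seed: Optional[int] = None, **plant_kwargs) -> dict:
    """Generate a full dataset on disk: genome.fa, genes.gff3, proteome.fa,
    seeds.fa, truth.tsv and a manifest.tab referencing them.

    Returns a dict of paths plus the in-memory truth object.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = PRESETS[preset]
    n_annotated = plant_kwargs.get("n_annotated", 30)
    n_hidden = plant_kwargs.setdefault("n_hidden", 20)
    n_tandem = plant_kwargs.setdefault("n_tandem_pairs",
                                       min(8, n_hidden))
    n_pseudo = plant_kwargs.setdefault("n_pseudo", 10)
    if n_members is None:
        n_members = n_annotated + (n_hidden - n_tandem) + n_pseudo
    seed_set, members = make_family(
        max(n_members, 3), domain_length=p["domain_length"],
        divergence_rate=divergence_rate,
        rng_seed=rng_seed if family_seed is None else family_seed,
        family_id=p["family_id"])
    genome, features, proteome, truth = plant_genome(
        [(seed_set, members)], rng_seed=rng_seed + 1, **plant_kwargs)

    paths = {
        "genome": out_dir / "genome.fa",
        "gff3": out_dir / "genes.gff3",
        "proteome": out_dir / "proteome.fa",
        "seeds": out_dir / "seeds.fa",
        "truth": out_dir / "truth.tsv",
        "manifest": out_dir / "manifest.tab",
    }
    write_fasta(genome, paths["genome"])
    write_fasta(proteome, paths["proteome"])
    write_fasta(seed_set.members, paths["seeds"])
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            parent = ""
            if f.kind == "mRNA":
                parent = f";Parent={f.feature_id.rsplit('.', 1)[0]}"
            elif f.kind == "CDS":
                parent = f";Parent={f.feature_id.rsplit('.', 1)[0]}"
            fh.write(f"{f.seqid}\tsynthetic\t{f.kind}\t{f.start}\t{f.end}"
                     f"\t.\t{f.strand}\t.\tID={f.feature_id}{parent}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("locus_id\tseqid\tstart\tend\tstrand\tclass\tfamily_id\t"
                 "tandem_group\tn_introns\tprotein\n")
        for l in truth.loci:
            fh.write(f"{l.locus_id}\t{l.seqid}\t{l.start}\t{l.end}\t"
                     f"{l.strand}\t{l.cls}\t{l.family_id}\t"
                     f"{l.tandem_group or '.'}\t{l.n_introns}\t{l.protein}\n")
    with open(paths["manifest"], "w") as fh:
        fh.write("genome.fa\tgenes.gff3\tproteome.fa\n")
    paths["truth_obj"] = truth
    paths["seed_set"] = seed_set
    return paths


def read_truth(path) -> PlantedTruth:
    loci = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            loci.append(PlantedLocus(
                row["locus_id"], row["seqid"], int(row["start"]),
                int(row["end"]), row["strand"], row["class"],
                row["family_id"],
                None if row["tandem_group"] == "." else row["tandem_group"],
                row["protein"], int(row["n_introns"])))
    return PlantedTruth(loci)
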