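"""Readers and writers for the formats the pipeline touches.

Coordinate convention: 1-based inclusive everywhere (the GFF3 convention);
conversion to Python half-open slices happens only at slicing boundaries
and is never exposed. FASTA parsing is delegated to Bio.SeqIO; GFF3 rows
are read directly (only gene/mRNA/CDS rows are of interest and the
contracts on coordinates and IDs are stricter than generic parsers give).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

_DNA_RE = re.compile(r"^[ACGTN]+$")
_PROT_RE = re.compile(r"^[ARNDCQEGHILKMFPSTWYVBZXUO*]+$")
_PROT_GAP_RE = re.compile(r"^[ARNDCQEGHILKMFPSTWYVBZXUO*\-.]+$")


@dataclass(frozen=True)
class SequenceRecord:
    """A named biological sequence, DNA or protein, always uppercase."""

    id: str
    residues: str
    moltype: str  # "dna" | "protein"

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


def _validate_alphabet(rec_id: str, residues: str, moltype: str,
                       allow_gaps: bool) -> None:
    if moltype == "dna":
        pattern = _DNA_RE
    elif moltype == "protein":
        pattern = _PROT_GAP_RE if allow_gaps else _PROT_RE
    else:
        raise ValueError(f"unknown moltype {moltype!r}")
    if not pattern.match(residues):
        for pos, ch in enumerate(residues, 1):
            if not pattern.match(ch):
                raise ValueError(
                    f"record {rec_id!r}: illegal {moltype} residue {ch!r} "
                    f"at position {pos}")


def read_fasta(path, moltype: str, allow_gaps: bool = False
               ) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Residues are uppercased, order preserved. Duplicate ids, an empty
    file, or an alphabet violation raise ValueError.
    """
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        _validate_alphabet(rec.id, residues, moltype, allow_gaps)
        records.append(SequenceRecord(rec.id, residues, moltype))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70
                ) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


@dataclass(frozen=True)
class GeneFeature:
    seqid: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    feature_id: str
    kind: str  # gene | mRNA | CDS

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature {self.feature_id!r}: invalid interval "
                f"[{self.start}, {self.end}]")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos <= self.end


_ID_RE = re.compile(r"ID=([^;]+)")
_KEPT_KINDS = {"gene", "mRNA", "CDS"}


def read_gff3(path) -> list[GeneFeature]:
    """Read gene/mRNA/CDS rows of a GFF3 file (other rows are skipped).

    Coordinates are kept 1-based inclusive. start > end raises; a missing
    ID attribute gets a synthesized stable id and a warning.
    """
    path = Path(path)
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, kind, start, end, _score, strand, _phase, attrs = \
                parts[:9]
            if kind not in _KEPT_KINDS:
                continue
            start_i, end_i = int(start), int(end)
            if start_i < 1 or start_i > end_i:
                raise ValueError(
                    f"{path}:{lineno}: invalid coordinates "
                    f"{start_i}..{end_i} (GFF3 is 1-based inclusive)")
            m = _ID_RE.search(attrs)
            if m:
                fid = m.group(1)
            else:
                fid = f"{kind}:{seqid}:{start_i}-{end_i}:{lineno}"
                logger.warning("%s:%d: feature without ID, synthesized %r",
                               path, lineno, fid)
            features.append(GeneFeature(seqid, start_i, end_i, strand, fid,
                                        kind))
    return features


@dataclass
class DatasetManifest:
    """Rows of (genome, gff3, proteome) paths, one per genome, as listed in
    the tab-separated dataset manifest file."""

    rows: list[tuple[Path, Path, Path]]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("manifest must contain at least one row")
        for row in self.rows:
            for p in row:
                if not Path(p).exists():
                    raise FileNotFoundError(f"manifest path does not exist: {p}")


def read_manifest(path) -> DatasetManifest:
    """Read the 3-column tab-separated manifest; relative paths resolve
    against the manifest's own directory."""
    path = Path(path)
    base = path.parent
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns")
            rows.append(tuple((base / p).resolve() if not Path(p).is_absolute()
                              else Path(p) for p in parts))
    return DatasetManifest(rows)


@dataclass
class SeedSet:
    """Family seed sequences (possibly a gapped alignment) plus the Pfam-style
    family accession they represent."""

    members: list[SequenceRecord]
    family_id: str

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a seed set needs at least 2 members")
        for m in self.members:
            degapped = m.residues.replace("-", "").replace(".", "")
            if not degapped:
                raise ValueError(f"seed {m.id!r} is all gaps")

    def degapped(self) -> list[SequenceRecord]:
        return [SequenceRecord(m.id,
                               m.residues.replace("-", "").replace(".", ""),
                               "protein")
                for m in self.members]


def read_seed_set(path, family_id: str) -> SeedSet:
    members = read_fasta(path, "protein", allow_gaps=True)
    return SeedSet(members, family_id)


# ---------------------------------------------------------------------------
# pipeline outputs


def write_outputs(catalog, out_dir) -> None:
    """Write the per-step FASTA/TSV outputs of a finalized family catalog.

    Produces: prior member proteins, the non-redundant reference and
    combined seed sets, candidate windows before and after trimming, the
    predicted genomic/transcript/peptide sequences of new coding genes, a
    GFF3-style coordinate table, the confirmed final member list, a
    pseudogene report and a machine-readable catalog.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    write_fasta([m.record for m in catalog.prior_members],
                out_dir / "step1_family_members.faa")
    write_fasta(catalog.refpep, out_dir / "step2_refpep.faa")
    write_fasta(catalog.combined_seeds, out_dir / "step2_combined_seeds.faa")
    _write_or_touch([SequenceRecord(w.window_id, w.segment, "dna")
                     for w in catalog.windows],
                    out_dir / "step3_windows.fna")
    _write_or_touch([SequenceRecord(w.window_id, w.segment, "dna")
                     for w in catalog.trimmed_windows],
                    out_dir / "step4_trimmed_windows.fna")

    gdna, tx, pep = [], [], []
    for entry in catalog.new_coding:
        gdna.append(SequenceRecord(entry.locus_id, entry.gdna, "dna"))
        tx.append(SequenceRecord(entry.locus_id, entry.model.transcript,
                                 "dna"))
        pep.append(SequenceRecord(entry.locus_id, entry.model.protein,
                                  "protein"))
    _write_or_touch(gdna, out_dir / "step5_gdna.fna")
    _write_or_touch(tx, out_dir / "step5_transcripts.fna")
    _write_or_touch(pep, out_dir / "step5_peptides.faa")

    with open(out_dir / "step6_coordinates.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for entry in catalog.new_coding:
            fh.write(f"{entry.seqid}\tctt\tgene\t{entry.start}\t{entry.end}"
                     f"\t.\t{entry.strand}\t.\tID={entry.locus_id}\n")
            for i, (es, ee) in enumerate(entry.genomic_exons, 1):
                fh.write(f"{entry.seqid}\tctt\tCDS\t{es}\t{ee}\t.\t"
                         f"{entry.strand}\t.\tID={entry.locus_id}.cds{i};"
                         f"Parent={entry.locus_id}\n")

    _write_or_touch(pep, out_dir / "step7_final_members.faa")

    with open(out_dir / "pseudogenes.tsv", "w") as fh:
        fh.write("locus_id\tseqid\tstart\tend\tstrand\tclass\n")
        for target, model_class in catalog.new_pseudogenes:
            fh.write(f"{target.region_id}\t{target.seqid}\t{target.start}\t"
                     f"{target.end}\t{target.strand}\t{model_class}\n")

    with open(out_dir / "rejected.tsv", "w") as fh:
        fh.write("seqid\tstart\tend\treason\n")
        for target, reason in catalog.rejected:
            fh.write(f"{target.seqid}\t{target.start}\t{target.end}\t"
                     f"{reason}\n")

    with open(out_dir / "catalog.json", "w") as fh:
        json.dump(catalog.to_dict(), fh, indent=1)


def _touch(path: Path) -> None:
    path.write_text("")


def _write_or_touch(records, path) -> None:
    if records:
        write_fasta(records, path)
    else:
        _touch(Path(path))
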