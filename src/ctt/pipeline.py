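"""The seven-step superfamily annotation pipeline with closing target trimming.

Given a dataset manifest (genome + GFF3 + proteome per genome) and a family
seed set, the pipeline:

1. finds prior family members in the annotated proteomes (seed protein
   search + domain-profile confirmation);
2. builds a non-redundant reference peptide set (RefPep) and a combined
   seed set (original seeds + best domain stretch of every member);
3. anchors putative new loci by translated genome search, deduplicates
   anchors by the midpoint rule, removes anchors inside annotated genes,
   and cuts a flanking window around each survivor;
4. iteratively trims neighbouring homologous loci out of each window until
   the predicted locus encompasses the anchor (the closing-target-trimming
   loop) — the step that rescues tandem-duplicated members a best-homology
   aligner would otherwise hide;
5. re-predicts the exposed locus with the top reference templates and
   requires a class quorum (coding / pseudogene without transcript /
   pseudogene with early stops);
6. maps the winning model back to genomic coordinates;
7. confirms the family domain in the predicted peptide.

References are pooled across all manifest genomes, so adding well-annotated
relatives improves prediction of poorly annotated ones.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import yaml
from intervaltree import IntervalTree

from . import align as _align
from .align import (
    DEFAULT_SCHEME,
    DomainHit,
    Profile,
    ScoringScheme,
    build_profile,
    cluster_identity,
    dna_vs_protein_search,
    evalue as _evalue,
    local_align,
    scan_domain,
    translated_genome_search,
)
from .seqio import (
    DatasetManifest,
    GeneFeature,
    SeedSet,
    SequenceRecord,
    read_fasta,
    read_gff3,
    write_outputs,
)
from .splice import PredictedModel, SpliceParams, classify_model, spliced_align
from ._alphabet import revcomp

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with the published defaults."""

    blastp_evalue: float = 1e-5
    domain_evalue: float = 1.0
    tblastn_evalue: float = 1e-5
    flank_head: int = 5000
    flank_tail: int = 5000
    max_iterations: int = 6
    genewise_min_score: float = 50.0
    templates_for_consensus: int = 3
    min_agreeing_templates: int = 2
    cluster_threshold: float = 0.9
    exposure_rule: str = "interval"  # "interval" | "midpoint"
    require_strand_match: bool = True
    scheme: ScoringScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self):
        for name in ("blastp_evalue", "domain_evalue", "tblastn_evalue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.flank_head < 0 or self.flank_tail < 0:
            raise ValueError("flanks must be non-negative")
        if self.exposure_rule not in ("interval", "midpoint"):
            raise ValueError("exposure_rule must be 'interval' or 'midpoint'")

    def splice_params(self) -> SpliceParams:
        return SpliceParams(scheme=self.scheme,
                            score_threshold=self.genewise_min_score)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class TargetRegion:
    """A translated-search anchor: the genomic interval presumed to encode
    the family domain of a hidden locus."""

    region_id: str
    seqid: str
    start: int
    end: int
    strand: str
    seed_id: str
    bit_score: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("target start must be <= end")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class CandidateWindow:
    """A mutable genomic segment around an anchor; shrinks during trimming.

    ``offset`` is the genomic coordinate of segment position 1, so window
    position w maps to genomic coordinate offset + w - 1.
    """

    window_id: str
    seqid: str
    segment: str
    offset: int
    target: TargetRegion
    iteration: int = 0

    def __post_init__(self):
        g_start, g_end = self.offset, self.offset + len(self.segment) - 1
        if not (g_start <= self.target.start and self.target.end <= g_end):
            raise ValueError(
                f"window {self.window_id}: target not inside segment")

    def to_genomic(self, pos: int) -> int:
        return self.offset + pos - 1

    def to_window(self, genomic_pos: int) -> int:
        return genomic_pos - self.offset + 1


@dataclass
class PriorMember:
    record: SequenceRecord
    genome_id: str
    domain: DomainHit


@dataclass
class NewMember:
    """A confirmed new coding member with corrected genomic coordinates."""

    locus_id: str
    seqid: str
    strand: str
    start: int
    end: int
    genomic_exons: list[tuple[int, int]]
    model: PredictedModel
    target: TargetRegion
    gdna: str
    domain: Optional[DomainHit] = None
    low_confidence: bool = False

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class FamilyCatalog:
    """Per-genome result: prior members, new coding members, new
    pseudogenes, and the rejected anchors with reasons."""

    genome_id: str
    prior_members: list[PriorMember] = field(default_factory=list)
    refpep: list[SequenceRecord] = field(default_factory=list)
    combined_seeds: list[SequenceRecord] = field(default_factory=list)
    windows: list[CandidateWindow] = field(default_factory=list)
    trimmed_windows: list[CandidateWindow] = field(default_factory=list)
    new_coding: list[NewMember] = field(default_factory=list)
    new_pseudogenes: list[tuple[TargetRegion, str]] = field(
        default_factory=list)
    rejected: list[tuple[TargetRegion, str]] = field(default_factory=list)
    trim_log: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "prior_members": [
                {"id": m.record.id, "length": len(m.record.residues),
                 "domain": dataclasses.asdict(m.domain)}
                for m in self.prior_members],
            "new_coding": [
                {"locus_id": e.locus_id, "seqid": e.seqid,
                 "strand": e.strand, "start": e.start, "end": e.end,
                 "exons": list(map(list, e.genomic_exons)),
                 "score": e.model.score, "protein": e.model.protein,
                 "lesions": e.model.lesions,
                 "template_id": e.model.template_id,
                 "low_confidence": e.low_confidence,
                 "target": dataclasses.asdict(e.target)}
                for e in self.new_coding],
            "new_pseudogenes": [
                {"target": dataclasses.asdict(t), "class": c}
                for t, c in self.new_pseudogenes],
            "rejected": [
                {"target": dataclasses.asdict(t), "reason": r}
                for t, r in self.rejected],
        }


# ---------------------------------------------------------------------------
# steps


def step1_prior_members(proteomes: dict[str, list[SequenceRecord]],
                        seed: SeedSet, config: PipelineConfig,
                        profile: Optional[Profile] = None
                        ) -> list[PriorMember]:
    """Family members already present in the annotations: any-seed protein
    hit at the BLASTp cutoff AND a confirmed family domain."""
    if not seed.members:
        raise ValueError("empty seed set")
    if profile is None:
        profile = build_profile(seed)
    seeds = seed.degapped()
    total_len = sum(len(p.residues) for prots in proteomes.values()
                    for p in prots)
    members: list[PriorMember] = []
    for genome_id in sorted(proteomes):
        for prot in proteomes[genome_id]:
            passed = False
            for sd in seeds:
                hit = local_align(sd, prot, config.scheme)
                if hit.raw_score <= 0:
                    continue
                ev = _evalue(hit.raw_score, len(sd.residues), total_len,
                             config.scheme)
                if ev <= config.blastp_evalue:
                    passed = True
                    break
            if not passed:
                continue
            dom = scan_domain(prot, profile, config.domain_evalue,
                              config.scheme)
            if dom is None:
                continue
            members.append(PriorMember(prot, genome_id, dom))
    return members


def step2_reference_sets(members: Sequence[PriorMember], seed: SeedSet,
                         config: PipelineConfig
                         ) -> tuple[list[SequenceRecord],
                                    list[SequenceRecord]]:
    """Non-redundant full-length references (RefPep) and the combined seed
    set (original seeds plus each member's best domain stretch)."""
    full = [m.record for m in members]
    refpep = cluster_identity(full, config.cluster_threshold, config.scheme)
    domain_seqs = []
    for m in members:
        sub = m.record.residues[m.domain.d_start - 1:m.domain.d_end]
        domain_seqs.append(SequenceRecord(f"{m.record.id}_dm", sub,
                                          "protein"))
    combined = cluster_identity(list(seed.degapped()) + domain_seqs,
                                config.cluster_threshold, config.scheme)
    return refpep, combined


def _gene_trees(annotations: Sequence[GeneFeature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for feat in annotations:
        if feat.kind != "gene":
            continue
        trees.setdefault(feat.seqid, IntervalTree()).addi(
            feat.start, feat.end + 1, feat.feature_id)
    return trees


def step3_putative_loci(combined_seeds: Sequence[SequenceRecord],
                        genome: Sequence[SequenceRecord],
                        annotations: Sequence[GeneFeature],
                        config: PipelineConfig
                        ) -> list[CandidateWindow]:
    """Anchor candidate new loci and cut flanking windows around them.

    Anchors are deduplicated best-score-first by the midpoint rule (two
    hits are the same locus if either midpoint lies inside the other) and
    anchors fully contained in an annotated gene span (strand-agnostic)
    are discarded as parts of known genes.
    """
    hits = translated_genome_search(combined_seeds, genome, config.scheme,
                                    config.tblastn_evalue)
    retained: dict[str, list] = {}
    for h in hits:  # already sorted by bit score descending
        same = retained.setdefault(h.subject_id, [])
        if any(_align._same_locus(h.s_start, h.s_end, o.s_start, o.s_end)
               for o in same):
            continue
        same.append(h)
    trees = _gene_trees(annotations)
    contigs = {c.id: c for c in genome}
    windows: list[CandidateWindow] = []
    n = 0
    for seqid in sorted(retained):
        tree = trees.get(seqid)
        for h in retained[seqid]:
            if tree is not None and any(
                    iv.begin <= h.s_start and h.s_end <= iv.end - 1
                    for iv in tree.overlap(h.s_start, h.s_end + 1)):
                continue  # part of an annotated gene, not a new locus
            contig = contigs[seqid]
            ws = max(1, h.s_start - config.flank_head)
            we = min(len(contig.residues),
                     max(h.s_start + config.flank_tail, h.s_end))
            n += 1
            target = TargetRegion(f"t{n:04d}", seqid, h.s_start, h.s_end,
                                  h.strand, h.query_id, h.bit_score)
            windows.append(CandidateWindow(
                f"w{n:04d}_{seqid}_{h.s_start}", seqid,
                contig.residues[ws - 1:we], ws, target))
    return windows


@dataclass
class TrimResult:
    status: str  # "exposed" | "rejected"
    window: Optional[CandidateWindow] = None
    model: Optional[PredictedModel] = None
    reason: Optional[str] = None


def step4_ctt_trim(window: CandidateWindow, refpep: Sequence[SequenceRecord],
                   config: PipelineConfig,
                   trim_log: Optional[list] = None) -> TrimResult:
    """The closing-target-trimming loop.

    Each round predicts the best-homology locus in the current segment; if
    it encompasses the anchor the window is exposed, otherwise the locus
    footprint is trimmed away and the contiguous remainder containing the
    anchor midpoint is kept. Stops on a missing template hit, a model
    below the score threshold, or after ``max_iterations`` rounds.
    """
    refpep_by_id = {r.id: r for r in refpep}
    params = config.splice_params()
    win = replace(window)
    for it in range(config.max_iterations):
        seg = SequenceRecord(win.window_id, win.segment, "dna")
        hits = dna_vs_protein_search(seg, refpep, config.scheme, top_k=1)
        if not hits:
            return TrimResult("rejected", reason="no hit")
        template = refpep_by_id[hits[0].subject_id]
        model = spliced_align(template, seg, params, win.window_id)
        if model is None:
            return TrimResult("rejected", reason="low score")
        fs_w, fe_w = model.span
        g_start, g_end = win.to_genomic(fs_w), win.to_genomic(fe_w)
        t = win.target
        if config.exposure_rule == "interval":
            contains = g_start <= t.start and t.end <= g_end
        else:
            contains = g_start <= t.midpoint <= g_end
        strand_ok = (not config.require_strand_match
                     or model.strand == t.strand)
        if contains and strand_ok:
            win.iteration = it
            return TrimResult("exposed", window=win, model=model)
        mid_w = win.to_window(t.midpoint)
        if fs_w <= mid_w <= fe_w:
            # trimming would consume the anchor (wrong strand or partial
            # overlap); the anchor is not a recoverable new locus here
            return TrimResult("rejected", reason="target_overlap")
        if fe_w < mid_w:
            new_seg = win.segment[fe_w:]
            new_offset = win.to_genomic(fe_w + 1)
        else:
            new_seg = win.segment[:fs_w - 1]
            new_offset = win.offset
        ts_w = t.start - new_offset + 1
        te_w = t.end - new_offset + 1
        if ts_w < 1 or te_w > len(new_seg):
            return TrimResult("rejected", reason="target_overlap")
        if len(new_seg) >= len(win.segment):
            raise RuntimeError(
                f"trim iteration did not shrink window {win.window_id}")
        if trim_log is not None:
            trim_log.append({"window_id": win.window_id, "iteration": it,
                             "removed_span": [g_start, g_end],
                             "remaining_length": len(new_seg)})
        win = CandidateWindow(win.window_id, win.seqid, new_seg, new_offset,
                              t, it + 1)
    return TrimResult("rejected", reason="iterations exhausted")


@dataclass
class ConsensusResult:
    status: str  # "accepted" | "rejected"
    model: Optional[PredictedModel] = None
    model_class: Optional[str] = None
    low_confidence: bool = False
    reason: Optional[str] = None


def step5_best_model(window: CandidateWindow,
                     refpep: Sequence[SequenceRecord],
                     config: PipelineConfig) -> ConsensusResult:
    """Consensus annotation of an exposed window with the top reference
    templates; a class must be predicted by a quorum of templates, and for
    coding genes the highest-scoring agreeing model wins."""
    refpep_by_id = {r.id: r for r in refpep}
    params = config.splice_params()
    seg = SequenceRecord(window.window_id, window.segment, "dna")
    hits = dna_vs_protein_search(seg, refpep, config.scheme,
                                 top_k=config.templates_for_consensus)
    if not hits:
        return ConsensusResult("rejected", reason="no hit")
    votes: list[tuple[str, Optional[PredictedModel]]] = []
    for h in hits:
        model = spliced_align(refpep_by_id[h.subject_id], seg, params,
                              window.window_id)
        votes.append((classify_model(model, had_template_hit=True), model))
    best_cls = consensus_class([cls for cls, _ in votes],
                               config.min_agreeing_templates)
    if best_cls is None:
        return ConsensusResult("rejected", reason="no consensus")
    agreeing = [m for cls, m in votes if cls == best_cls and m is not None]
    best_model = max(agreeing, key=lambda m: m.score) if agreeing else None
    return ConsensusResult("accepted", model=best_model,
                           model_class=best_cls,
                           low_confidence=len(votes) < 2)


def consensus_class(classes: Sequence[str],
                    min_agreeing: int = 2) -> Optional[str]:
    """The model class reaching the template quorum, or None.

    With fewer available templates than the quorum, all of them must
    agree (a single template trivially agrees but is flagged
    low-confidence by the caller).
    """
    if not classes:
        return None
    quorum = min_agreeing if len(classes) >= min_agreeing else len(classes)
    counts = Counter(classes)
    winners = [cls for cls, c in counts.items() if c >= quorum]
    if not winners:
        return None
    return max(winners, key=lambda c: (counts[c], c))


def step6_correct_coords(model: PredictedModel, window: CandidateWindow,
                         genome_seq: Optional[str] = None
                         ) -> list[tuple[int, int]]:
    """Map the model's exons from window to genomic coordinates (1-based
    inclusive, ascending). When the contig sequence is provided,
    re-extracting and splicing the genomic intervals must reproduce the
    model cds exactly — a hard error otherwise."""
    genomic = [(window.to_genomic(s), window.to_genomic(e))
               for s, e in model.exons]
    for s, e in genomic:
        if s < window.offset or e > window.to_genomic(len(window.segment)):
            raise ValueError("exon outside the window span")
    if genome_seq is not None:
        spliced = "".join(genome_seq[s - 1:e] for s, e in genomic)
        if model.strand == "-":
            spliced = revcomp(spliced)
        if spliced != model.cds:
            raise RuntimeError(
                f"coordinate round-trip failed for window {window.window_id}")
    return genomic


def step7_confirm_domain(model: PredictedModel, profile: Profile,
                         config: PipelineConfig) -> Optional[DomainHit]:
    """Final family-domain check on the predicted peptide; returns the hit
    (acceptance) or None (rejection). Pseudogene candidates bypass this."""
    rec = SequenceRecord(model.window_id, model.protein, "protein")
    return scan_domain(rec, profile, config.domain_evalue, config.scheme)


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(manifest: DatasetManifest, seed: SeedSet,
                 config: Optional[PipelineConfig] = None,
                 out_dir=None) -> dict[str, FamilyCatalog]:
    """Execute steps 1-7 for every genome in the manifest.

    References (RefPep and combined seeds) are pooled across all manifest
    rows. Returns one FamilyCatalog per genome; an error in one genome is
    logged and does not abort the others. Deterministic for fixed inputs
    and config.
    """
    if config is None:
        config = PipelineConfig()
    profile = build_profile(seed)

    rows = []
    proteomes: dict[str, list[SequenceRecord]] = {}
    for genome_path, gff_path, prot_path in manifest.rows:
        genome_id = Path(genome_path).stem
        while genome_id in proteomes:
            genome_id += "_dup"
        proteomes[genome_id] = read_fasta(prot_path, "protein")
        rows.append((genome_id, Path(genome_path), Path(gff_path)))

    members = step1_prior_members(proteomes, seed, config, profile)
    logger.info("step1: %d prior members across %d genomes", len(members),
                len(rows))
    refpep, combined_seeds = step2_reference_sets(members, seed, config)
    logger.info("step2: %d RefPep, %d combined seeds", len(refpep),
                len(combined_seeds))

    catalogs: dict[str, FamilyCatalog] = {}
    for genome_id, genome_path, gff_path in rows:
        try:
            catalogs[genome_id] = _annotate_genome(
                genome_id, genome_path, gff_path, members, refpep,
                combined_seeds, profile, config)
        except Exception:
            logger.exception("genome %s aborted", genome_id)
    if out_dir is not None:
        out_dir = Path(out_dir)
        for genome_id, catalog in catalogs.items():
            write_outputs(catalog, out_dir / genome_id)
            with open(out_dir / genome_id / "trim_log.jsonl", "w") as fh:
                for event in catalog.trim_log:
                    fh.write(json.dumps(event) + "\n")
    return catalogs


def _annotate_genome(genome_id, genome_path, gff_path, members, refpep,
                     combined_seeds, profile, config) -> FamilyCatalog:
    genome = read_fasta(genome_path, "dna")
    annotations = read_gff3(gff_path)
    contigs = {c.id: c for c in genome}
    catalog = FamilyCatalog(
        genome_id,
        prior_members=[m for m in members if m.genome_id == genome_id],
        refpep=list(refpep), combined_seeds=list(combined_seeds))

    windows = step3_putative_loci(combined_seeds, genome, annotations,
                                  config)
    catalog.windows = windows
    logger.info("%s: step3 produced %d candidate windows", genome_id,
                len(windows))

    gene_trees = _gene_trees(annotations)
    coding: list[NewMember] = []
    pseudo: list[tuple[TargetRegion, str, int]] = []
    for window in windows:
        t = window.target
        tree = gene_trees.get(t.seqid)
        if tree is not None and tree.overlap(t.midpoint, t.midpoint + 1):
            catalog.rejected.append((t, "inside prior gene"))
            continue
        trimmed = step4_ctt_trim(window, refpep, config, catalog.trim_log)
        if trimmed.status == "rejected":
            catalog.rejected.append((t, trimmed.reason))
            continue
        win = trimmed.window
        catalog.trimmed_windows.append(win)
        consensus = step5_best_model(win, refpep, config)
        if consensus.status == "rejected":
            catalog.rejected.append((t, consensus.reason))
            continue
        if consensus.model_class != "coding":
            span = _entry_span(consensus.model, win, t)
            pseudo.append((t, consensus.model_class, span))
            continue
        model = consensus.model
        genome_seq = contigs[win.seqid].residues
        genomic_exons = step6_correct_coords(model, win, genome_seq)
        dom = step7_confirm_domain(model, profile, config)
        if dom is None:
            catalog.rejected.append((t, "no family domain"))
            continue
        start, end = genomic_exons[0][0], genomic_exons[-1][1]
        gdna = genome_seq[start - 1:end]
        if model.strand == "-":
            gdna = revcomp(gdna)
        coding.append(NewMember(
            locus_id=f"{genome_id}_{win.window_id}", seqid=win.seqid,
            strand=model.strand, start=start, end=end,
            genomic_exons=genomic_exons, model=model, target=t, gdna=gdna,
            domain=dom, low_confidence=consensus.low_confidence))

    _dedup_catalog(catalog, coding, pseudo)
    logger.info("%s: %d new coding, %d new pseudogenes, %d rejected",
                genome_id, len(catalog.new_coding),
                len(catalog.new_pseudogenes), len(catalog.rejected))
    return catalog


def _entry_span(model, window, target) -> tuple[int, int]:
    if model is not None:
        s, e = model.span
        return window.to_genomic(s), window.to_genomic(e)
    return target.start, target.end


def _dedup_catalog(catalog: FamilyCatalog, coding: list[NewMember],
                   pseudo: list[tuple[TargetRegion, str, tuple[int, int]]]
                   ) -> None:
    """A locus whose domain is hit by several anchors (e.g. split by an
    intron) is discovered once per anchor; collapse duplicates with the
    same midpoint-containment rule used for anchor dedup."""
    kept_spans: list[tuple[str, int, int]] = []
    for entry in sorted(coding, key=lambda e: (-e.model.score, e.start)):
        span = (entry.seqid, entry.start, entry.end)
        if any(s[0] == entry.seqid
               and _align._same_locus(entry.start, entry.end, s[1], s[2])
               for s in kept_spans):
            continue
        kept_spans.append(span)
        catalog.new_coding.append(entry)
    catalog.new_coding.sort(key=lambda e: (e.seqid, e.start))
    kept_pseudo: list[tuple[str, int, int]] = []
    for t, cls, span in sorted(pseudo, key=lambda p: (p[0].seqid,
                                                      p[0].start)):
        s, e = span
        if any(k[0] == t.seqid and _align._same_locus(s, e, k[1], k[2])
               for k in kept_spans + kept_pseudo):
            continue
        kept_pseudo.append((t.seqid, s, e))
        catalog.new_pseudogenes.append((t, cls))
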