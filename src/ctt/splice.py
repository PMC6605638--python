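"""Spliced protein-to-genome alignment and gene-model classification.

The aligner plays the role GeneWise plays in homology-based annotation:
given a protein template and a genomic segment it returns the best local
gene model, allowing

* introns between codons at GT..AG dinucleotide pairs at least
  ``min_intron`` nt apart (cost ``intron_open_penalty``),
* single-base slips inside codons (2- or 4-nt "codons", cost
  ``frameshift_penalty``, recorded as frameshift lesions),
* traversal of in-frame stop codons (cost ``stop_codon_penalty``,
  recorded as internal-stop lesions).

Like its role model it reports only the best-scoring locus in the
segment — which is exactly why the trimming loop in the pipeline module
exists. Scores are in raw substitution-matrix units; a model below
``score_threshold`` is treated as absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._alphabet import (
    AA_ALPHABET,
    codon_table,
    encode_dna,
    encode_protein,
    revcomp,
)
from ._kernels import spliced_dp
from .align import DEFAULT_SCHEME, ScoringScheme
from .seqio import SequenceRecord

MAX_SEGMENT = 200_000  # full-matrix DP guard


@dataclass(frozen=True)
class SpliceParams:
    scheme: ScoringScheme = DEFAULT_SCHEME
    intron_open_penalty: int = -25
    intron_length_penalty: int = -5  # per started 100 nt of intron
    min_intron: int = 40
    frameshift_penalty: int = -20
    stop_codon_penalty: int = -15
    score_threshold: float = 50.0
    allow_introns: bool = True
    allow_frameshifts: bool = True

    def __post_init__(self):
        if (self.intron_open_penalty >= 0 or self.frameshift_penalty >= 0
                or self.stop_codon_penalty >= 0 or
                self.intron_length_penalty > 0):
            raise ValueError("penalties must be negative")
        if self.min_intron < 4:
            raise ValueError("min_intron must be >= 4")


@dataclass
class PredictedModel:
    """A gene structure predicted from one protein template.

    ``exons`` are 1-based inclusive intervals on the forward axis of the
    window the model was predicted in, ordered by coordinate; ``cds`` (and
    the identical ``transcript``) read 5'->3' on the coding strand;
    ``protein`` is the conceptual translation produced during alignment
    ('X' at frameshift slips, '*' at traversed stops).
    """

    window_id: str
    template_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: str
    transcript: str
    protein: str
    score: float
    lesions: dict = field(default_factory=lambda: {"internal_stop": 0,
                                                   "frameshift": 0})
    model_class: Optional[str] = None

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def has_lesions(self) -> bool:
        return any(v > 0 for v in self.lesions.values())


def _traceback(pH, pEp, pEq, res, bi, bj, dna: str, m: int):
    """Reconstruct exons, introns, cds, protein and lesion counts from the
    spliced DP pointer matrices. Coordinates are 1-based on ``dna``."""
    tab = codon_table()
    enc = encode_dna(dna)
    i, j = bi, bj
    state = "H"
    exons_rev: list[tuple[int, int]] = []
    introns_rev: list[tuple[int, int]] = []
    cds_rev: list[str] = []
    prot_rev: list[str] = []
    stops = 0
    fs = 0
    cur_end: Optional[int] = None
    cur_start: Optional[int] = None

    def consume(a: int, b: int):
        nonlocal cur_end, cur_start
        if cur_end is None:
            cur_end = b
        cur_start = a

    while True:
        if state == "H":
            p = pH[i, j]
            if p == 0:
                break
            if p in (1, 2, 3):
                width = 3 if p == 1 else (2 if p == 2 else 4)
                a = j - width + 1
                cds_rev.append(dna[a - 1:j])
                if p == 1:
                    c = enc[a - 1:j]
                    if (c < 4).all():
                        aa = AA_ALPHABET[tab[25 * c[0] + 5 * c[1] + c[2]]]
                    else:
                        aa = "X"
                    if aa == "*":
                        stops += 1
                    prot_rev.append(aa)
                else:
                    fs += 1
                    prot_rev.append("X")
                consume(a, j)
                donor = int(res[i, j])
                i -= 1
                if donor:
                    t = j - width  # intron [donor .. t]
                    exons_rev.append((cur_start, cur_end))
                    introns_rev.append((donor, t))
                    j = donor - 1
                    cur_end = None
                    cur_start = None
                else:
                    j = a - 1
            elif p == 4:
                state = "Ep"
            else:
                state = "Eq"
        elif state == "Ep":
            opened = pEp[i, j] == 1
            i -= 1
            if opened:
                state = "H"
        else:  # Eq: inserted genomic codon
            opened = pEq[i, j] == 1
            a = j - 2
            cds_rev.append(dna[a - 1:j])
            c = enc[a - 1:j]
            if (c < 4).all():
                aa = AA_ALPHABET[tab[25 * c[0] + 5 * c[1] + c[2]]]
            else:
                aa = "X"
            if aa == "*":
                stops += 1
            prot_rev.append(aa)
            consume(a, j)
            j -= 3
            if opened:
                state = "H"
    if cur_start is not None:
        exons_rev.append((cur_start, cur_end))
    exons = list(reversed(exons_rev))
    introns = list(reversed(introns_rev))
    cds = "".join(reversed(cds_rev))
    protein = "".join(reversed(prot_rev))
    return exons, introns, cds, protein, stops, fs


def _align_one_strand(tpl_enc, dna: str, params: SpliceParams):
    denc = encode_dna(dna)
    scheme = params.scheme
    best, bi, bj, pH, pEp, pEq, res, _aval, _adonor = spliced_dp(
        denc, tpl_enc, scheme.matrix,
        codon_table(),
        np.int32(scheme.gap_open), np.int32(scheme.gap_extend),
        np.int32(params.frameshift_penalty),
        np.int32(params.stop_codon_penalty),
        np.int32(params.intron_open_penalty),
        np.int32(params.intron_length_penalty),
        np.int32(params.min_intron),
        params.allow_introns, params.allow_frameshifts,
        np.int8(23))  # '*' index
    if best <= 0:
        return None
    exons, introns, cds, protein, stops, fs = _traceback(
        pH, pEp, pEq, res, bi, bj, dna, len(tpl_enc))
    return dict(score=int(best), exons=exons, introns=introns, cds=cds,
                protein=protein, stops=stops, fs=fs)


def spliced_align(template: SequenceRecord, dna_segment,
                  params: SpliceParams = SpliceParams(),
                  window_id: Optional[str] = None
                  ) -> Optional[PredictedModel]:
    """Best spliced local alignment of a protein template to a DNA segment,
    or None if no model reaches ``params.score_threshold``.

    Both strands are tried; ties go to '+' and then to the leftmost start.
    Exon intervals are reported on the forward axis of the segment.
    """
    if isinstance(dna_segment, SequenceRecord):
        seg_id = dna_segment.id
        dna = dna_segment.residues
    else:
        seg_id = "segment"
        dna = str(dna_segment).upper()
    if window_id is None:
        window_id = seg_id
    if len(dna) < 3:
        return None
    if len(dna) > MAX_SEGMENT:
        raise ValueError(
            f"segment of {len(dna)} nt exceeds the {MAX_SEGMENT} nt "
            "full-matrix DP guard")
    tpl = template.residues.replace("-", "").replace(".", "")
    tpl_enc = encode_protein(tpl)
    L = len(dna)

    fwd = _align_one_strand(tpl_enc, dna, params)
    rev = _align_one_strand(tpl_enc, revcomp(dna), params)

    candidates = []
    if fwd is not None:
        candidates.append(("+", fwd, fwd["exons"]))
    if rev is not None:
        exons = sorted((L - e + 1, L - s + 1) for s, e in rev["exons"])
        candidates.append(("-", rev, exons))
    candidates = [c for c in candidates
                  if c[1]["score"] >= params.score_threshold]
    if not candidates:
        return None
    # higher score wins; ties prefer '+' then leftmost start
    candidates.sort(key=lambda c: (-c[1]["score"], c[0] != "+", c[2][0][0]))
    strand, r, exons = candidates[0]
    return PredictedModel(
        window_id=window_id, template_id=template.id, strand=strand,
        exons=exons, cds=r["cds"], transcript=r["cds"], protein=r["protein"],
        score=float(r["score"]),
        lesions={"internal_stop": r["stops"], "frameshift": r["fs"]})


def classify_model(model: Optional[PredictedModel],
                   had_template_hit: bool) -> str:
    """Assign one of the three gene-model classes.

    coding — a model exists with no lesions; pseudogene_stop — a model
    exists but contains internal stops and/or frameshifts;
    pseudogene_no_transcript — no model survived the score threshold even
    though a template hit existed for the window.
    """
    if model is None:
        if not had_template_hit:
            raise ValueError(
                "classify_model called with neither a model nor a hit")
        return "pseudogene_no_transcript"
    cls = "pseudogene_stop" if model.has_lesions else "coding"
    model.model_class = cls
    return cls
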