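"""Alignment primitives for superfamily annotation.

This module replaces the external search tools the original pipeline
shells out to with exact dynamic-programming equivalents:

* :func:`local_align` — Smith–Waterman protein alignment (BLASTp role);
* :func:`translated_genome_search` — protein queries vs the six-frame
  translation of a genome (tBLASTn role);
* :func:`dna_vs_protein_search` — six-frame translated DNA segment vs a
  protein database (BLASTx role);
* :func:`build_profile` / :func:`scan_domain` — position-specific scoring
  profile built from a family seed alignment and scanned against a
  protein (profile-HMM domain search role);
* :func:`cluster_identity` — greedy identity clustering (CD-HIT role).

E-values follow the Karlin–Altschul form E = K·m·n·exp(−λ·S) with
configurable (λ, K); the defaults are the classic ungapped BLOSUM62
constants applied to gapped scores, which is the usual approximation.
Genome-scale searches locate candidate regions by exact k-mer seeding and
then score each candidate region with the same exact Smith–Waterman fill,
so reported alignments are optimal within their window.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align as _BioAlign

from ._alphabet import (
    AA_ALPHABET,
    AA_INDEX,
    MASK_IDX,
    STOP_IDX,
    codon_table,
    encode_dna,
    encode_protein,
    revcomp,
    substitution_matrix,
)
from ._kernels import profile_scan_kernel, sw_protein, sw_traceback
from .seqio import SequenceRecord, SeedSet


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin–Altschul constants.

    ``gap_open`` is the cost of the first gapped residue, ``gap_extend``
    of each further one (so a length-g gap costs open + (g-1)*extend).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1
    ka_lambda: float = 0.267
    ka_k: float = 0.041

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")

    @property
    def matrix(self) -> np.ndarray:
        return substitution_matrix(self.matrix_name)


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class LocalHit:
    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    identity_pct: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str = "+"
    frame: Optional[int] = None

    @property
    def s_mid(self) -> int:
        return (self.s_start + self.s_end) // 2

    @property
    def aln_span(self) -> int:
        return self.q_end - self.q_start + 1


@dataclass
class DomainHit:
    protein_id: str
    d_start: int
    d_end: int
    score: float
    evalue: float


def bit_score(raw_score: float, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    return (scheme.ka_lambda * raw_score - math.log(scheme.ka_k)) / math.log(2.0)


def evalue(raw_score: float, m: int, n: int,
           scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λ·S)."""
    if m < 1 or n < 1:
        raise ValueError("search space dimensions must be >= 1")
    return scheme.ka_k * m * n * math.exp(-scheme.ka_lambda * raw_score)


def _degap(s: str) -> str:
    return s.replace("-", "").replace(".", "")


def local_align(query: SequenceRecord, subject: SequenceRecord,
                scheme: ScoringScheme = DEFAULT_SCHEME) -> LocalHit:
    """Optimal Smith–Waterman local alignment of two proteins.

    A raw score of 0 (no positively scoring pair at all) is returned as a
    sentinel hit with zeroed coordinates.
    """
    q = _degap(query.residues)
    s = _degap(subject.residues)
    if not q or not s:
        raise ValueError("cannot align empty sequence")
    qe = encode_protein(q)
    se = encode_protein(s)
    raw, bi, bj, pH, pE, pF = sw_protein(qe, se, scheme.matrix,
                                         np.int32(scheme.gap_open),
                                         np.int32(scheme.gap_extend))
    if raw <= 0:
        return LocalHit(query.id, subject.id, 0, bit_score(0, scheme),
                        evalue(0, len(q), len(s), scheme), 0.0, 0, 0, 0, 0)
    qs, qend, ss, send, pairs = sw_traceback(pH, pE, pF, bi, bj)
    matches = sum(1 for a, b in pairs
                  if a is not None and b is not None and qe[a - 1] == se[b - 1])
    ident = 100.0 * matches / len(pairs)
    return LocalHit(query.id, subject.id, int(raw), bit_score(raw, scheme),
                    evalue(raw, len(q), len(s), scheme), ident,
                    qs, qend, ss, send)


# ---------------------------------------------------------------------------
# six-frame translation


@dataclass
class FrameTranslation:
    """One reading frame of a DNA sequence with its codon coordinate map.

    ``codon_starts[i]`` is the 1-based genomic position of the smallest-
    coordinate base of the codon encoding residue i (0-based).
    """

    frame: int  # +1..+3, -1..-3
    protein: str
    codon_starts: np.ndarray

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


def six_frame_translate(dna: SequenceRecord) -> list[FrameTranslation]:
    """Translate all six frames; stops are '*', N-codons are 'X'."""
    seq = dna.residues
    L = len(seq)
    tab = codon_table()
    out = []
    fwd = encode_dna(seq)
    rev = encode_dna(revcomp(seq))
    for off in range(3):
        n_codons = (L - off) // 3
        if n_codons <= 0:
            out.append(FrameTranslation(off + 1, "", np.empty(0, np.int64)))
            out.append(FrameTranslation(-(off + 1), "", np.empty(0, np.int64)))
            continue
        # forward frame off+1
        idx = fwd[off:off + 3 * n_codons].reshape(n_codons, 3)
        aa = _codons_to_aa(idx, tab)
        starts = off + 3 * np.arange(n_codons, dtype=np.int64) + 1
        out.append(FrameTranslation(off + 1, aa, starts))
        # reverse frame -(off+1)
        idx = rev[off:off + 3 * n_codons].reshape(n_codons, 3)
        aa = _codons_to_aa(idx, tab)
        starts = L - 2 - off - 3 * np.arange(n_codons, dtype=np.int64)
        out.append(FrameTranslation(-(off + 1), aa, starts))
    return out


def _codons_to_aa(idx: np.ndarray, tab: np.ndarray) -> str:
    good = (idx < 4).all(axis=1)
    codes = 25 * idx[:, 0] + 5 * idx[:, 1] + idx[:, 2]
    codes[~good] = 124  # maps to X
    return "".join(AA_ALPHABET[a] for a in tab[codes])


# ---------------------------------------------------------------------------
# seeded translated searches


def _kmer_clusters(positions: list[int], span: int) -> list[tuple[int, int]]:
    """Group sorted k-mer hit positions into clusters; a gap larger than
    ``span`` starts a new cluster. Returns (min, max) per cluster."""
    positions = sorted(positions)
    clusters = []
    start = prev = positions[0]
    count = 1
    for p in positions[1:]:
        if p - prev > span:
            clusters.append((start, prev, count))
            start = p
            count = 0
        prev = p
        count += 1
    clusters.append((start, prev, count))
    return clusters


def _sw_window_hits(qenc: np.ndarray, senc: np.ndarray, scheme: ScoringScheme,
                    min_raw: int, max_hits: int = 4):
    """All non-overlapping local hits of query vs a subject window, found by
    iterated optimal alignment with masking of each found footprint."""
    senc = senc.copy()
    sub = scheme.matrix
    hits = []
    for _ in range(max_hits):
        raw, bi, bj, pH, pE, pF = sw_protein(qenc, senc, sub,
                                             np.int32(scheme.gap_open),
                                             np.int32(scheme.gap_extend))
        if raw < min_raw:
            break
        qs, qe_, ss, se_, pairs = sw_traceback(pH, pE, pF, bi, bj)
        matches = sum(1 for a, b in pairs
                      if a is not None and b is not None
                      and qenc[a - 1] == senc[b - 1])
        hits.append((int(raw), qs, qe_, ss, se_, matches, len(pairs)))
        senc[ss - 1:se_] = MASK_IDX
    return hits


def _same_locus(a_start, a_end, b_start, b_end) -> bool:
    """Midpoint-containment rule: two intervals describe the same locus if
    either midpoint lies inside the other interval."""
    am = (a_start + a_end) // 2
    bm = (b_start + b_end) // 2
    return (b_start <= am <= b_end) or (a_start <= bm <= a_end)


def translated_genome_search(queries: Sequence[SequenceRecord],
                             genome: Sequence[SequenceRecord],
                             scheme: ScoringScheme = DEFAULT_SCHEME,
                             evalue_cutoff: float = 1e-5,
                             k: int = 4,
                             min_cluster: int = 2,
                             min_raw: int = 30) -> list[LocalHit]:
    """Search protein queries against all six frames of every contig.

    Candidate regions are located by exact protein k-mer seeding (at least
    ``min_cluster`` shared k-mers within one frame neighbourhood) and each
    region is then aligned by optimal Smith–Waterman. Hits with E-value
    above ``evalue_cutoff`` are dropped; the rest are sorted by bit score
    (descending, ties by span then coordinate).
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue cutoff must be positive")
    db_len = sum(len(r.residues) for r in genome)
    if db_len == 0:
        return []
    qinfo = []
    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for qi, q in enumerate(queries):
        s = _degap(q.residues)
        qinfo.append((q.id, s, encode_protein(s)))
        for p in range(len(s) - k + 1):
            index[s[p:p + k]].append((qi, p))
    hits: list[LocalHit] = []
    for contig in genome:
        contig_hits: dict[int, list[LocalHit]] = defaultdict(list)
        for fr in six_frame_translate(contig):
            prot = fr.protein
            if len(prot) < k:
                continue
            matches: dict[int, list[int]] = defaultdict(list)
            get = index.get
            for p in range(len(prot) - k + 1):
                entry = get(prot[p:p + k])
                if entry:
                    for qi, _qp in entry:
                        matches[qi].append(p)
            fenc = None
            for qi, pos_list in matches.items():
                qid, qseq, qenc = qinfo[qi]
                qlen = len(qseq)
                for lo_p, hi_p, count in _kmer_clusters(pos_list,
                                                        max(qlen, 60)):
                    if count < min_cluster:
                        continue
                    lo = max(0, lo_p - qlen - 20)
                    hi = min(len(prot), hi_p + k + qlen + 20)
                    if fenc is None:
                        fenc = encode_protein(prot)
                    for (raw, qs, qe_, ss, se_, m_, cols) in _sw_window_hits(
                            qenc, fenc[lo:hi], scheme, min_raw):
                        fa = lo + ss  # 1-based frame residue coords
                        fb = lo + se_
                        g1 = int(fr.codon_starts[fa - 1])
                        g2 = int(fr.codon_starts[fb - 1])
                        s_start = min(g1, g2)
                        s_end = max(g1, g2) + 2
                        contig_hits[qi].append(LocalHit(
                            qid, contig.id, raw, bit_score(raw, scheme),
                            evalue(raw, qlen, db_len, scheme),
                            100.0 * m_ / cols, qs, qe_, s_start, s_end,
                            fr.strand, fr.frame))
        # per query: merge duplicate discoveries of the same genomic locus
        for qi, qhits in contig_hits.items():
            qhits.sort(key=lambda h: -h.raw_score)
            kept: list[LocalHit] = []
            for h in qhits:
                if not any(_same_locus(h.s_start, h.s_end, o.s_start, o.s_end)
                           for o in kept):
                    kept.append(h)
            hits.extend(kept)
    hits = [h for h in hits if h.evalue <= evalue_cutoff]
    hits.sort(key=lambda h: (-h.bit_score, -(h.s_end - h.s_start),
                             h.subject_id, h.s_start, h.query_id))
    return hits


def dna_vs_protein_search(dna_segment: SequenceRecord,
                          protein_db: Sequence[SequenceRecord],
                          scheme: ScoringScheme = DEFAULT_SCHEME,
                          top_k: int = 1,
                          k: int = 4,
                          min_cluster: int = 2,
                          min_raw: int = 30,
                          evalue_cutoff: float = 10.0) -> list[LocalHit]:
    """Rank database proteins by their best local alignment to any frame of
    the DNA segment (the template-selection primitive).

    Returns at most ``top_k`` hits ordered by bit score descending, ties
    broken by alignment span descending then subject id ascending. Hit
    coordinates: q_* are 1-based nucleotide positions on the segment,
    s_* residue positions on the matched protein. Hits above
    ``evalue_cutoff`` (the customary default reporting threshold of
    translated search tools) are not reported.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not protein_db:
        return []
    db_len = sum(len(_degap(p.residues)) for p in protein_db)
    index: dict[str, list[int]] = defaultdict(list)
    pencs = []
    for pi, p in enumerate(protein_db):
        s = _degap(p.residues)
        pencs.append((p.id, s, encode_protein(s)))
        seen = set()
        for pos in range(len(s) - k + 1):
            kmer = s[pos:pos + k]
            if (pi, kmer) not in seen:
                index[kmer].append(pi)
                seen.add((pi, kmer))
    best: dict[int, LocalHit] = {}
    for fr in six_frame_translate(dna_segment):
        prot = fr.protein
        if len(prot) < k:
            continue
        matches: dict[int, list[int]] = defaultdict(list)
        for pos in range(len(prot) - k + 1):
            for pi in index.get(prot[pos:pos + k], ()):
                matches[pi].append(pos)
        fenc = None
        for pi, pos_list in matches.items():
            pid, pseq, penc = pencs[pi]
            plen = len(pseq)
            for lo_p, hi_p, count in _kmer_clusters(pos_list, max(plen, 60)):
                if count < min_cluster:
                    continue
                lo = max(0, lo_p - plen - 20)
                hi = min(len(prot), hi_p + k + plen + 20)
                if fenc is None:
                    fenc = encode_protein(prot)
                raw, bi, bj, pH, pE, pF = sw_protein(
                    fenc[lo:hi], penc, scheme.matrix,
                    np.int32(scheme.gap_open), np.int32(scheme.gap_extend))
                if raw < min_raw:
                    continue
                qs, qe_, ss, se_, pairs = sw_traceback(pH, pE, pF, bi, bj)
                m_ = sum(1 for a, b in pairs
                         if a is not None and b is not None
                         and fenc[lo + a - 1] == penc[b - 1])
                fa = lo + qs
                fb = lo + qe_
                g1 = int(fr.codon_starts[fa - 1])
                g2 = int(fr.codon_starts[fb - 1])
                hit = LocalHit(dna_segment.id, pid, int(raw),
                               bit_score(raw, scheme),
                               evalue(raw, len(dna_segment.residues),
                                      db_len, scheme),
                               100.0 * m_ / len(pairs),
                               min(g1, g2), max(g1, g2) + 2, ss, se_,
                               fr.strand, fr.frame)
                prev = best.get(pi)
                if prev is None or hit.raw_score > prev.raw_score:
                    best[pi] = hit
    ranked = sorted((h for h in best.values() if h.evalue <= evalue_cutoff),
                    key=lambda h: (-h.bit_score,
                                   -(h.s_end - h.s_start), h.subject_id))
    return ranked[:top_k]


# ---------------------------------------------------------------------------
# family profile (position-specific scoring matrix)


@dataclass
class Profile:
    """Per-column log2-odds scores over the 20 standard amino acids.

    ``matrix`` has one extra block of columns covering the ambiguity codes
    (score 0), the stop (strongly negative) and the mask sentinel, so it
    can be indexed directly with encoded residues.
    """

    family_id: str
    matrix: np.ndarray  # (length, 25) float32
    gap_open: float = -5.0
    gap_extend: float = -1.0

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])


def _star_align_rows(members: list[str]) -> list[str]:
    """Return equal-length rows: either the input alignment, or the members
    projected onto the columns of the longest member via pairwise global
    alignment (a star alignment with insertions relative to the centre
    discarded)."""
    if len({len(m) for m in members}) == 1:
        return members
    degapped = [_degap(m) for m in members]
    centre = max(degapped, key=len)
    aligner = _pairwise_aligner()
    rows = []
    for m in degapped:
        if m == centre:
            rows.append(centre)
            continue
        aln = aligner.align(centre, m)[0]
        row = ["-"] * len(centre)
        for (ts, te), (qs, qe) in zip(*aln.aligned):
            for off in range(te - ts):
                row[ts + off] = m[qs + off]
        rows.append("".join(row))
    return rows


def build_profile(seed: SeedSet, pseudocount: float = 1.0,
                  background: float = 1.0 / 20.0,
                  max_gap_frac: float = 0.5) -> Profile:
    """Build a log-odds profile from a seed alignment.

    score(column, aa) = log2( (count + pseudocount) /
                              (N + 20·pseudocount) / background )
    where N is the number of residues observed in the column. Columns with
    more than ``max_gap_frac`` gaps are dropped (match columns only).
    """
    if len(seed.members) < 2:
        raise ValueError("profile needs at least 2 seed sequences")
    rows = _star_align_rows([m.residues.upper() for m in seed.members])
    width = len(rows[0])
    nrows = len(rows)
    cols = []
    for c in range(width):
        col = [r[c] for r in rows]
        gaps = sum(1 for x in col if x in "-.")
        if gaps / nrows <= max_gap_frac:
            cols.append([x for x in col if x not in "-."])
    mat = np.zeros((len(cols), 25), np.float32)
    for ci, col in enumerate(cols):
        counted = [AA_INDEX[x] for x in col if AA_INDEX.get(x, 99) < 20]
        n = len(counted)
        denom = (n + 20.0 * pseudocount) * background
        counts = np.zeros(20)
        for a in counted:
            counts[a] += 1
        mat[ci, :20] = np.log2((counts + pseudocount) / denom)
        mat[ci, 20:23] = 0.0  # B, Z, X: uninformative
        mat[ci, STOP_IDX] = -8.0
        mat[ci, MASK_IDX] = -1000.0
    return Profile(seed.family_id, mat)


def scan_domain(protein: SequenceRecord, profile: Profile,
                evalue_cutoff: float = 1.0,
                scheme: ScoringScheme = DEFAULT_SCHEME,
                min_profile_cov: float = 0.25) -> Optional[DomainHit]:
    """Best local profile-to-sequence alignment; None below the cutoff.

    Profile scores are in bits, so the E-value uses λ = ln 2:
    E = K·m·n·2^(−S). A reportable hit must additionally span at least
    ``min_profile_cov`` of the profile's match columns — a genuine family
    domain covers nearly the whole model, while short lucky segments of a
    few columns can reach deceptively low E-values at permissive cutoffs.
    """
    seq = _degap(protein.residues)
    if not seq:
        return None
    senc = encode_protein(seq)
    score, bi, bj, pH, pE, pF = profile_scan_kernel(
        profile.matrix, senc, np.float32(profile.gap_open),
        np.float32(profile.gap_extend))
    if score <= 0:
        return None
    qs, qe_, ss, se_, _pairs = sw_traceback(pH, pE, pF, bi, bj)
    if qe_ - qs + 1 < min_profile_cov * profile.length:
        return None
    E = scheme.ka_k * profile.length * len(seq) * math.pow(2.0, -float(score))
    if E > evalue_cutoff:
        return None
    return DomainHit(protein.id, ss, se_, float(score), E)


# ---------------------------------------------------------------------------
# greedy identity clustering


@lru_cache(maxsize=4)
def _pairwise_aligner(matrix_name: str = "BLOSUM62",
                      gap_open: int = -11, gap_extend: int = -1):
    aligner = _BioAlign.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BioAlign.substitution_matrices.load(
        matrix_name)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_identity(a: str, b: str,
                    scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Identity fraction of the optimal global alignment of two proteins
    (matches / alignment columns, end gaps included)."""
    a = _degap(a)
    b = _degap(b)
    if a == b:
        return 1.0
    aligner = _pairwise_aligner(scheme.matrix_name, scheme.gap_open,
                                scheme.gap_extend)
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    return matches / len(s1)


def cluster_identity(sequences: Sequence[SequenceRecord],
                     identity_threshold: float = 0.9,
                     scheme: ScoringScheme = DEFAULT_SCHEME
                     ) -> list[SequenceRecord]:
    """Greedy incremental clustering; returns the representatives.

    Sequences are processed longest-first (ties by id); each joins the
    first existing cluster whose representative it matches at or above the
    identity threshold, else it founds a new cluster.
    """
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity threshold must be in (0, 1]")
    ordered = sorted(sequences,
                     key=lambda r: (-len(_degap(r.residues)), r.id))
    reps: list[SequenceRecord] = []
    for rec in ordered:
        placed = False
        for rep in reps:
            if global_identity(rec.residues, rep.residues,
                               scheme) >= identity_threshold:
                placed = True
                break
        if not placed:
            reps.append(rec)
    return reps
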