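"""Evaluation of annotation runs: hold-out rediscovery, specificity of the
predicted proteins, the combined (Sn+Sp)/2 accuracy, and the new-finding
summary.

Conventions follow the published evaluation design:

* a held-out locus counts as *rediscovered* when the midpoint of a newly
  annotated locus falls inside its span, attributed to the new entry's
  class (coding vs pseudogene);
* specificity compares each rediscovered coding prediction with the
  original protein: Pident is the local-alignment identity percentage,
  Integrity the fraction of the original protein covered by that
  alignment;
* accuracy = (Sn + Sp)/2 with Sn the percentage of held-out loci
  rediscovered *as coding genes* and Sp = (mean Pident + mean Integrity)/2;
* the new-finding percentage of a catalog is 100·(new pseudogenes + new
  coding)/(prior + new pseudogenes + new coding).

All percentages are rounded half-up to one decimal, matching how such
tables are conventionally printed.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .align import DEFAULT_SCHEME, ScoringScheme, local_align
from .seqio import GeneFeature, SequenceRecord


def round1(x: float) -> float:
    """Half-up rounding to one decimal (the table-printing convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class EvalReport:
    n_heldout: int
    rediscovered_coding: int
    rediscovered_pseudo: int
    pident_mean: float
    pident_sd: float
    integrity_mean: float
    integrity_sd: float
    specificity_mean: float
    accuracy: float

    def as_tsv_row(self, label: str = "synthetic") -> str:
        return "\t".join([
            label, str(self.rediscovered_pseudo),
            str(self.rediscovered_coding),
            f"{self.pident_mean:.1f} ± {self.pident_sd:.1f}",
            f"{self.integrity_mean:.1f} ± {self.integrity_sd:.1f}",
            f"{self.specificity_mean:.1f}",
            f"{self.accuracy:.1f}"])


@dataclass
class NewEntry:
    """Class-agnostic view of one newly annotated locus (adapter over a
    FamilyCatalog or a parsed catalog.json)."""

    locus_id: str
    seqid: str
    start: int
    end: int
    is_coding: bool
    protein: Optional[str] = None

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def catalog_entries(catalog) -> list[NewEntry]:
    """Flatten a FamilyCatalog (or its to_dict/JSON form) into NewEntry
    rows covering both new coding members and new pseudogenes."""
    if isinstance(catalog, dict):
        entries = [NewEntry(e["locus_id"], e["seqid"], e["start"], e["end"],
                            True, e.get("protein"))
                   for e in catalog["new_coding"]]
        for row in catalog["new_pseudogenes"]:
            t = row["target"]
            entries.append(NewEntry(t["region_id"], t["seqid"], t["start"],
                                    t["end"], False))
        return entries
    entries = [NewEntry(e.locus_id, e.seqid, e.start, e.end, True,
                        e.model.protein)
               for e in catalog.new_coding]
    for target, _cls in catalog.new_pseudogenes:
        entries.append(NewEntry(target.region_id, target.seqid, target.start,
                                target.end, False))
    return entries


def holdout_rediscovery(catalog, heldout: Sequence[GeneFeature]
                        ) -> tuple[int, int, list[tuple[NewEntry,
                                                        GeneFeature]]]:
    """Count held-out loci rediscovered by the run.

    Returns (coding count, pseudogene count, matched pairs). Raises if the
    held-out features overlap each other (attribution would be ambiguous).
    """
    by_seq: dict[str, list[GeneFeature]] = {}
    for f in heldout:
        by_seq.setdefault(f.seqid, []).append(f)
    for feats in by_seq.values():
        feats.sort(key=lambda f: f.start)
        for a, b in zip(feats, feats[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"held-out features {a.feature_id} and {b.feature_id} "
                    "overlap")
    matched: dict[str, tuple[NewEntry, GeneFeature]] = {}
    for entry in catalog_entries(catalog):
        for f in by_seq.get(entry.seqid, ()):
            if f.contains_point(entry.midpoint):
                prev = matched.get(f.feature_id)
                # prefer a coding rediscovery if several entries land in
                # the same held-out locus
                if prev is None or (entry.is_coding
                                    and not prev[0].is_coding):
                    matched[f.feature_id] = (entry, f)
                break
    pairs = list(matched.values())
    coding = sum(1 for e, _ in pairs if e.is_coding)
    pseudo = sum(1 for e, _ in pairs if not e.is_coding)
    return coding, pseudo, pairs


def specificity_metrics(pairs: Sequence[tuple[str, str]],
                        scheme: ScoringScheme = DEFAULT_SCHEME
                        ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Pident and Integrity statistics over (predicted, original) protein
    pairs.

    Per pair: Pident is the identity percentage of the best local
    alignment; Integrity is the alignment's coverage of the original
    protein x 100. Returns ((pident_mean, sd), (integrity_mean, sd)).
    """
    if not pairs:
        raise ValueError("no protein pairs to compare")
    pidents, integrities = [], []
    for i, (pred, orig) in enumerate(pairs):
        hit = local_align(SequenceRecord(f"pred{i}", pred, "protein"),
                          SequenceRecord(f"orig{i}", orig, "protein"),
                          scheme)
        if hit.raw_score <= 0:
            pidents.append(0.0)
            integrities.append(0.0)
            continue
        pidents.append(hit.identity_pct)
        integrities.append(100.0 * (hit.s_end - hit.s_start + 1)
                           / len(orig))
    sd = (lambda xs: statistics.stdev(xs) if len(xs) > 1 else 0.0)
    return ((statistics.mean(pidents), sd(pidents)),
            (statistics.mean(integrities), sd(integrities)))


def accuracy(sensitivity_coding_count: int, n_heldout: int,
             pident_mean: float, integrity_mean: float) -> float:
    """The combined (Sn+Sp)/2 score, one decimal, half-up.

    Sn = 100 * coding rediscoveries / held-out loci;
    Sp = (mean Pident + mean Integrity) / 2.
    """
    if n_heldout <= 0:
        raise ValueError("n_heldout must be positive")
    sn = 100.0 * sensitivity_coding_count / n_heldout
    sp = (pident_mean + integrity_mean) / 2.0
    return round1((sn + sp) / 2.0)


def evaluate_holdout(catalog, heldout: Sequence[GeneFeature],
                     originals: dict[str, str],
                     scheme: ScoringScheme = DEFAULT_SCHEME) -> EvalReport:
    """Full hold-out evaluation: rediscovery counts, specificity of coding
    predictions against the original proteins, and the combined accuracy."""
    coding, pseudo, pairs = holdout_rediscovery(catalog, heldout)
    protein_pairs = [(e.protein, originals[f.feature_id])
                     for e, f in pairs
                     if e.is_coding and e.protein
                     and f.feature_id in originals]
    if protein_pairs:
        (pid_m, pid_sd), (int_m, int_sd) = specificity_metrics(
            protein_pairs, scheme)
    else:
        pid_m = pid_sd = int_m = int_sd = 0.0
    sp = (pid_m + int_m) / 2.0
    return EvalReport(
        n_heldout=len(heldout), rediscovered_coding=coding,
        rediscovered_pseudo=pseudo,
        pident_mean=pid_m, pident_sd=pid_sd,
        integrity_mean=int_m, integrity_sd=int_sd,
        specificity_mean=sp,
        accuracy=accuracy(coding, len(heldout), pid_m, int_m))


@dataclass
class NewFindingRow:
    prior: int
    pseudo: int
    coding: int
    total: int
    pct_new: float


def new_finding_summary(catalog=None, *, prior: Optional[int] = None,
                        pseudo: Optional[int] = None,
                        coding: Optional[int] = None) -> NewFindingRow:
    """The new-finding summary row: total members and the percentage that
    are newly discovered, 100·(pseudo+coding)/total at one decimal.

    Accepts either a catalog (counts are taken from it) or explicit
    counts as keyword arguments.
    """
    if catalog is not None:
        prior = len(catalog.prior_members)
        pseudo = len(catalog.new_pseudogenes)
        coding = len(catalog.new_coding)
    if prior is None or pseudo is None or coding is None:
        raise ValueError("need a catalog or explicit prior/pseudo/coding")
    total = prior + pseudo + coding
    if total == 0:
        raise ValueError("cannot summarize an empty catalog")
    pct = round1(100.0 * (pseudo + coding) / total)
    return NewFindingRow(prior, pseudo, coding, total, pct)
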