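# Methods

This note documents the models, numerical choices and limitations behind
the package, in the order the pipeline uses them.

## Alignment model and E-values

All pairwise protein alignment is exact affine-gap Smith–Waterman
(BLOSUM62; gap open −11 for the first gapped residue, −1 per further
residue). Significance uses the Karlin–Altschul form E = K·m·n·e^(−λS)
with the classic ungapped BLOSUM62 constants λ = 0.267, K = 0.041
applied to gapped scores — the standard approximation when no gapped
parameter fit is available. m is the query length, n the summed database
length. The constants are fields of `ScoringScheme` and can be replaced
wholesale; every cutoff in the pipeline is interpreted against whatever
scheme is configured.

Genome-scale searches (protein vs six-frame genome, DNA segment vs
protein database) locate candidate regions by exact k-mer seeding (k = 4,
at least 2 shared words in one frame neighbourhood) and then score each
region with the same exact Smith–Waterman fill; within a region,
additional non-overlapping hits are recovered by masking each optimal
footprint and re-aligning. Seeding is a search-space reduction only — the
reported alignments are DP-optimal within their window. Its practical
sensitivity floor is roughly 50 % amino-acid identity over a domain-sized
region (two shared 4-mers), far above the E ≤ 1e-5 anchor threshold's
own floor. The translated-segment-vs-proteins search additionally drops
hits with E > 10, the customary default reporting threshold of
translated search tools; this is what lets the trimming loop terminate
with "no hit" on windows of plain intergenic sequence.

## Family profile

The domain profile is a per-column log2-odds matrix over the 20 standard
amino acids: score = log2((count + 1)/(N + 20)/0.05) — pseudocount 1.0,
uniform background 1/20. Columns with more than 50 % gaps are dropped.
Unaligned seed input is star-aligned onto the longest member (pairwise
global alignments; insertions relative to the centre are discarded),
which is adequate for the well-conserved seed sets the pipeline expects.
Profile scanning is local DP with gap costs −5/−1 bits, and E =
K·m·n·2^(−S) (λ = ln 2 is exact for log-odds scores). A reportable
domain hit must span ≥ 25 % of the profile columns: a genuine family
domain covers nearly the whole model, whereas 5–7 lucky columns can
otherwise sneak under a permissive E < 1 cutoff (the published
confirmation threshold is deliberately permissive, so the coverage floor
carries the specificity).

## Spliced protein-to-genome alignment

The gene-structure predictor is a local DP over (template residue,
genomic position) with three state families: codon match (including
traversal of in-frame stops at −15, recorded as internal-stop lesions),
affine template/codon gaps (−11/−1), and 1-nt slips realised as 2-nt or
4-nt "codons" at −20 each (recorded as frameshift lesions). Introns are
permitted only between codons (phase 0) at GT..AG dinucleotide pairs at
least 40 nt apart, at a cost of −25 plus −5 per started 100 nt of
length. The length term is a coarse geometric intron-length model; it
matters because two homologous loci 0.5–2 kb apart would otherwise be
"spliced" into one chimeric model whenever their per-region divergences
from the template happen to complement each other. The linear form folds
into the DP's running donor maximum, so intron search stays O(m·n).
Both strands are aligned and the better model kept (ties prefer '+',
then the leftmost start). The DP holds the full matrix (no banding); a
guard rejects segments over 200 kb, far above the 10 kb windows the
pipeline cuts.

The score is reported in raw substitution-matrix units and the stop rule
("no model below 50") is interpreted in that unit. The role of the
threshold — terminating the trimming loop when homology runs out — is
preserved; its absolute calibration is specific to whatever scorer is
used and is exposed in `PipelineConfig.genewise_min_score`.

Model classes: `coding` (lesion-free model at or above threshold),
`pseudogene_stop` (model with internal stops and/or frameshifts),
`pseudogene_no_transcript` (template hit but no model survived the
threshold).

## Pipeline decisions

* "Encompasses the anchor" is implemented as full containment of the
  anchor interval in the model's genomic span with matching strand (the
  stricter reading); `exposure_rule="midpoint"` relaxes to midpoint
  containment.
* Trimming keeps only the contiguous remainder containing the anchor
  midpoint — removed footprints are never re-concatenated, which would
  manufacture chimeric sequence.
* If the best model overlaps the anchor without encompassing it (e.g. an
  opposite-strand model covering the anchor midpoint), the window is
  rejected (`target_overlap`) rather than trimmed, so the anchor can
  never be trimmed out of its own window; an anchor actually escaping
  the segment raises, as that is a bookkeeping bug by construction.
* Step 4 trims with the single best template per iteration; step 5
  re-ranks the exposed window with the top 3 templates and requires 2
  agreeing classes. With fewer than 2 usable templates all must agree
  and the catalog entry is flagged low-confidence.
* Anchor dedup processes hits best-score-first; at equal bit score the
  longer, then leftmost, then lexicographically-first seed wins.
* The prior-gene filter uses gene-type feature spans, strand-agnostic.
  Accepted catalog entries must additionally have their anchor midpoint
  outside every prior gene span (entries violating it are rejected as
  `inside prior gene`), which keeps the catalog invariant independent of
  how a hit straddles a gene boundary.
* A locus whose domain is split by an intron yields two anchors and is
  discovered twice; final catalog entries are deduplicated by the same
  midpoint-containment rule, keeping the higher-scoring model.
* References (RefPep, combined seeds) are pooled across all manifest
  genomes, so adding well-annotated relatives improves prediction in
  poorly annotated targets.

## Evaluation conventions

Rediscovery uses midpoint containment of the new locus in the held-out
span, each held-out locus counted once (a coding rediscovery outranks a
pseudogene call for the same locus). Pident is local-alignment identity;
Integrity is the local alignment's coverage of the original protein —
the coverage reading is forced by the role the quantity plays in the
combined score's arithmetic. Sensitivity in (Sn+Sp)/2 counts coding
rediscoveries only, again forced by the published arithmetic of the
worked examples. Percentages are rounded half-up to one decimal, the
table-printing convention.

## Synthetic data: what it emulates and what it does not

The generator models a family as one ancestral full-length protein with
an embedded signature domain (presets: 48, 108 and 267 residues for the
three published test families); members are independent per-site
substitution mutants of the whole ancestor (default rate 0.10), seeds
are mutants of the domain alone. Loci are uniform-synonymous reverse
translations, optionally split by 1–2 random-interior GT..AG introns of
70–150 nt inserted at codon boundaries (probability 0.5 per locus).
Tandem pairs place a hidden duplicate, diverged 4 % at the protein
level, 200–2,000 nt from its annotated partner on the same strand —
recent tandem duplication, the configuration that defeats best-homology
prediction and motivates the trimming loop. Other loci are ≥ 500 nt
apart (800–3,000 nt gaps in practice). Pseudogenes carry exactly one
lesion (premature stop or 1-nt deletion in the middle third) and are
kept intronless. Intergenic sequence is i.i.d. uniform ACGT. Everything
is deterministic per integer seed.

Deliberately not modelled: repeats and low-complexity sequence, GC/codon
bias, indel divergence between members, non-canonical or phase-1/2
splice sites, empirical intron length distributions, and fragmented
assemblies. Passing the recovery suite therefore demonstrates the
algorithmic claims (anchoring, trimming, classification, coordinate
bookkeeping) under clean sequence statistics; it does not certify
recall on repeat-rich real genomes, where anchor specificity and the
seeding floor would be stressed much harder.

The standard recovery fixture is one ~500 kb contig with 30 annotated
members, 20 hidden coding loci (8 of them tandem partners of annotated
genes) and 10 hidden pseudogenes; at this size a full pipeline run takes
on the order of a minute on one core, which keeps the end-to-end suite
cheap enough to run three pipeline variants (full, no-trimming control,
zero-hidden control) in every test session. The generator's CLI default
mirrors this fixture; larger designs (e.g. 100-locus hold-outs) are a
matter of parameters.

## Known limitations

* Phase-0 introns only; real genes splice within codons.
* The ungapped (λ, K) pair overstates significance of gapped alignments
  somewhat; cutoffs inherited from the original design (1e-5, 1, 50)
  should be read as operating points of this scorer, not as universally
  calibrated values.
* Star alignment of unaligned seeds discards insertions relative to the
  centre sequence; badly gapped seed sets deserve a real MSA upstream.
* `pseudogene_no_transcript` is reachable but rare under the generator's
  conditions (single-lesion pseudogenes still align well above the score
  threshold), so that class is exercised mainly at the unit level.
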