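# Methods

This note documents the models, conventions and numerical choices behind
`dmdkit`, in the order the pipeline applies them.

## Transcript model and coordinates

All interfaces speak 1-based coding (`c.`) coordinates counted over the CDS
only.  The model stores, per exon, only its coding span; untranslated
regions are handled by the variant parser as a distinct class (`utr`), not
by the coordinate map, because every downstream computation (codon
arithmetic, frame phases, PTC calls) is defined on the CDS.  A valid model
must have a CDS divisible by 3, starting with ATG and ending in a stop, a
contiguous 1..N exon table whose coding lengths sum to the CDS length, and
domain spans that partition the exons.  For the 79-exon reference layout
the domains are ABD (1–8), RD (9–62), CRD (63–69), CTD (70–79); synthetic
transcripts with other exon counts use the same layout scaled
proportionally.

The reading-frame arithmetic for exons 1 and 79 (which also contain UTR in
the real gene) uses coding-only lengths; because those exons are
unskippable anyway (start codon, stop codon/3' end), this convention never
affects a skip decision.

## Variant parsing and annotation

The `c.` grammar covers substitutions, deletions, duplications, insertions
and deletion-insertions, intron offsets (`+k`/`-k`), UTR anchors
(`-n`/`*n`) and range forms mixing them.  Parsing round-trips to the
canonical text.  Indels are taken at their stated position; left-most
normalization is the default for ambiguous placements and the 3'-rule can
be switched on (`normalize_indel(..., three_prime=True)`, pipeline flag
`hgvs_3prime`) — the 3' rule is the HGVS standard, but left placement keeps
hand-checked oracles simple and the choice is explicit and configurable.

Consequence dispatch: any non-zero intron offset → `splicing` (this
includes range deletions that cross an exon boundary, since intronic bases
are removed); UTR anchor → `utr`; exonic substitutions by codon comparison
(`nonsense` iff the alternate codon is a stop and the reference codon is
not); exonic indels by net length mod 3 (`frameshift` / `inframe_indel`).
A reference-allele mismatch against the CDS is a hard error, not a
warning: silent acceptance would corrupt every downstream PTC/CpG call.

CpG context is symmetric over strands: a reference C immediately followed
by G, or a reference G immediately preceded by C, covering both
deamination classes (C→T and G→A).

The first hidden PTC of a frameshift is found by applying the indel to the
CDS and re-reading codons from the first codon the indel touches; the stop
codon and its codon distance are returned, or `none` on read-through past
the end of the mutated CDS.

Splice-site classes: positive offsets are donor-side (after the upstream
exon), negative acceptor-side; |offset| 1–2 is the near-invariant core,
3–5 the conserved neighbourhood, and a range crossing the core boundary
(including into the exon) is `spanning`.  Variants are attributed to their
consensus exon (upstream exon for donor, downstream for acceptor, the
exonic endpoint's exon for boundary-spanning ranges).  The donor/acceptor
sign convention for spanning ranges is a reasoned reconstruction; no
authoritative assignment exists for such variants.

## SRE scanning and the splicing grade

The grade multiplies two binary terms.  The ORF flag is the length-based
reading-frame rule: skipping the host exon is frame-preserving iff its
coding length ≡ 0 (mod 3); terminal exons score 0.  The SRE term is 1 iff
the substitution creates a new ESS word or breaks an above-threshold ESE
matrix hit overlapping the variant, scanned in a window centred on the
variant with radius (longest motif − 1) and truncated at the host exon's
coding boundaries — SREs are exonic elements, so intronic flank is never
scanned.  Hit matching is by identical (motif, offset): a hit that merely
shifts by 1 nt counts as one lost plus one gained, the simplest
deterministic diff.

The packaged motif library (`data/sre_motifs_v1.tsv`, version
`sre-lite-1`) is a deliberately small, synthetic approximation: four
consensus-derived enhancer weight matrices with motif lengths 7/8/7/6
(mirroring the classic SR-protein profiles) and ten silencer hexamers
drawn from the purine-poor/UAG-containing motif families associated with
silencing.  Thresholds were chosen once, at design time, so that an
above-threshold enhancer hit occurs at roughly 1–3% of positions under a
uniform base background; under that density roughly a third to a half of
exonic substitutions disturb an SRE, a plausible regime for exonic
regulatory density.  The scanner is deterministic but is *not* a replica
of any external predictor's rule set; when per-variant ESS/ESE calls from
an external tool are available they are supplied as an override table
(columns `hgvs_c`, `new_ess`, `broken_ese`), which is the fidelity path
and takes precedence.

## Exon-skipping planner

Candidate strategies are contiguous blocks of 1..cap exons (default cap 3)
containing the mutated exon, clipped at the gene ends and never including
the first or last coding exon.  A block is viable iff its summed coding
length ≡ 0 (mod 3); junction-created stop codons are not part of the rule
(consistent with the length-based frame checker) but are reported as a
diagnostic flag.  Among minimal in-frame blocks the tie-break prefers the
smallest total skipped coding length, then the lowest starting exon —
preserving the most protein, deterministically.  Splicing variants are
excluded from planning (they can themselves cause exon skipping or intron
retention); UTR variants have no host exon; patients whose mutated exon is
terminal count as uncovered.  Coverage is reported cumulatively for
strategy sizes ≤ 1, ≤ 2, ≤ 3 and is monotone in the cap.

## Cohort statistics

Phenotype: loss of ambulation < 13 y → DMD, 13–15 y → IMD, ≥ 16 y → BMD;
still-ambulant patients with onset of weakness by age 5 → DMD, nearly
normal or very mild dysfunction after age 5 → BMD, intermediate severity →
IMD; otherwise `pending`.  DMD and IMD are merged into one severe group
for all contrasts; pending patients are excluded from phenotype contrasts
but included in spectrum summaries.

Test dispatch on a contingency table: Fisher's exact test when any
expected cell < 1 or the grand total < 40; the continuity-corrected χ²
when any expected cell < 5; the plain χ² otherwise.  χ² and Fisher are
delegated to scipy.  Fisher dispatch on tables larger than 2×2 raises
rather than silently substituting an approximation.

Odds ratios use the Woolf log interval, OR = ad/bc with
CI = exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)); the Haldane–Anscombe 0.5
correction is available (`zero_correction`) but off by default.  The Woolf
method was chosen because it exactly reproduces the intervals printed with
the published tables this package reconstructs.  No multiple-testing
correction is applied.

The serum-biomarker stage is a maximum-likelihood logistic regression
(statsmodels) of severe phenotype (DMD/IMD = 1 vs BMD = 0) on age at
examination, mutation type and the biomarker (SCRN in µmol/L or CK in
U/L, unstandardized), restricted to patients ≤ 16 years old — above that
age the mild phenotype dominates by definition.  Rows with a missing
predictor are dropped and counted.  Mutation type enters as four levels
(the three largest classes plus a pooled remainder): a dummy carried by a
handful of rows with a single outcome level would quasi-separate the fit.
Perfect separation and non-convergence are flagged results, never silent
estimates.

## Synthetic cohorts

The generator draws, per patient: a mutation class from the mixture
0.52/0.24/0.17/0.05/0.01/0.01 (nonsense/splicing/frameshift/missense/UTR/
synonymous); a nonsense site uniformly from the CDS's stop-capable
positions with probability 0.42 of drawing from the CpG-context pool; a
frameshift as a 1/2/4-nt deletion or 1-nt duplication; a splice-site
change at offsets ±1..5 with 75% core-site mass; and an HGVS string that
round-trips through the parser and re-annotates to the intended class.

Nonsense patients are graded through the real SRE/frame pipeline, and the
phenotype is then a logistic draw calibrated so that the population
grade→phenotype odds ratio equals its target (default 12): the grade-1
severe probability is 0.52 (the observed severe share among grade-1
patients in the reconstructed cohort) and the grade-0 probability follows
from the odds-ratio identity.  Frameshift patients use the
truncating-vs-non-truncating target (default 1/0.314) against a 0.5
baseline; other classes use 0.5.  IMD is a thin slice (10.6%) of the
severe group, matching the published 7-of-66 split; phenotype is masked to
`pending` at rate 0.15.

SCRN is an age-linear Gaussian: intercept 15 µmol/L, slope 1.3 per year,
residual sd 1.5, plus a severity shift of ln(1.9)·sd², so that the implied
per-unit odds ratio of the severe outcome given age is exactly 1.9 — with
equal within-class variances the linear-discriminant identity makes the
logistic slope δ/σ², hence the fitted per-unit OR recovers 1.9.  (The
outcome coding here is severe = 1; the comparable published coefficient is
reported per an unstated unit and outcome coding, so only the magnitude is
meaningful.)  SCRN is missing at rate 0.12; CK is log-normal and carries
no phenotype signal.  Exon lengths are drawn in 60–240 nt with ~55% of
exons frame-neutral, mirroring the roughly even split of frame-preserving
exons in the real gene; CDS bodies are sampled from sense codons so the
only stop is terminal.  All randomness flows from a single seeded
generator; a fixed seed reproduces the cohort byte-for-byte.

What the generator does *not* emulate: linkage between site position and
phenotype beyond the grade/truncating channels, recurrent hotspot
mutations, family structure, measurement noise in staining, or real
splice-site sequence context (the transcript model carries no intron
sequence, so intronic reference bases in emitted notations are plausible
but unverifiable).  Passing tests therefore demonstrate correctness of the
pipeline's logic and calibration of its statistics under these idealized
conditions, not clinical validity on real cohorts.

## Reconstructed reference cohort

`dmdkit.reference.reference_cohort()` deterministically expands the
printed summary tables of a published 115-patient small-mutation cohort
into synthetic patient rows (class × domain × severity × grade counts, CpG
and PTC marginals, splice sides, staining counts).  It carries exactly the
joint structure the printed tables determine and nothing more: variant
coordinates are absent, and the grade split of the seven unclassifiable
nonsense patients (not printed) is filled near-evenly.  It exists so the
cohort-statistics stage can recompute the published associations from
patient-level input; per-patient quantities the tables do not determine
(exon positions, serum values) cannot be reconstructed, and analyses that
need them (skip-coverage percentages, the biomarker regression) accept a
user-supplied patient-level CSV instead.

## Problem sizes and tolerances

The test suite and acceptance script use: exhaustive dispatch-rule
checking for all 2×2 tables with n ≤ 60; all ≤ 3-exon blocks of 50 random
transcripts for the frame checker; 200 replicates of n = 500 cohorts for
parameter recovery (coverage threshold 90% for a nominal 95% interval);
n = 1000 for the synthetic coverage summary.  These sizes give stable
rates while keeping the default run fast on a single CPU.  Equality
assertions on reconstructed-table statistics are exact to the printed
precision (3 decimals for odds ratios and intervals, 2 for percentages).

## Known limitations

* The SRE library is a simplified stand-in; per-variant fidelity to any
  external predictor requires the override table.
* The frame rule is length-only; a skip that creates a junction stop is
  reported but still counted in-frame, as the diagnostic flag shows.
* Fisher dispatch is implemented for 2×2 tables only.
* Genomic coordinates, multiple transcripts, deep-intronic variants and
  protein-level notation are out of scope.
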