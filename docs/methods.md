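# Methods

## The problem

Fabry disease is caused by missense mutations in lysosomal
alpha-galactosidase A (AGAL). Some mutant enzymes are misfolded but
catalytically competent; the pharmacological chaperone
1-deoxy-galactonojirimycin (DGJ), a competitive inhibitor resembling
galactose, can bind and stabilize them, raising cellular activity. Only a
fraction of genotypes respond, so predicting responsiveness from sequence
alone is clinically useful. The predictor implemented here scores a
mutation by how tolerable the *substituting* residue is at its position,
read off a position-specific substitution matrix (PSSM) built from AGAL
homologs: a replacement residue seen in homologous species earns a less
negative score.

## PSSM construction

Given a protein multiple alignment whose first (or designated) sequence is
the human AGAL query, the matrix is built by the standard profile recipe:

1. **Sequence weighting.** Position-based (Henikoff) weights: every column
   distributes one unit of mass equally over the residue types present,
   then equally over the sequences carrying each type. Raw weights are
   rescaled to sum to the effective sequence count `n_eff`, taken as the
   mean number of distinct residue types per column — the usual
   effective-observation count for profiles. `weighting="uniform"` gives
   all-ones weights and `n_eff = N`.
2. **Observed frequencies.** Weighted residue counts per query position;
   gaps and `X` contribute nothing to the denominator. Columns where the
   query is gapped do not exist in the output coordinate system (positions
   are 1-based protein coordinates, as in HGVS `p.A230T`).
3. **Pseudocounts.** The observed vector `f` is mixed with a prior push
   `g_b = Σ_a f_a · P(b|a)`, where `P(b|a)` is the conditional substitution
   probability implied by BLOSUM62 half-bit scores and its marginal
   frequencies (`P(b|a) ∝ p_b · 2^{s_ab/2}`, rows normalized):

       p_smoothed = (α·f + β·g) / (α + β),   α = n_eff − 1.

   β (`pseudocount_weight`, default 10) is the classic profile pseudocount
   constant: with one effective sequence the prior dominates entirely, and
   its influence decays as the alignment deepens.
4. **Integer log-odds.** `score(pos, r) = round(scale · log2(p/p_bg))`,
   rounded half away from zero, with `scale = 2` (half-bit units, which
   place conserved-position scores in the familiar −7…+1 integer range of
   the packaged panels) and background = BLOSUM62 marginal frequencies.
   Residues with zero smoothed probability (possible only with β = 0) are
   floored at `score_floor = −16`, a conventional integer-PSSM floor; all
   scores are clipped from below at that floor.

Construction is deterministic: identical alignment and parameters give
bit-identical matrices, and scores survive the ASCII write/read round trip
exactly (the file format stores the integer layer only).

## Scoring and classification

A mutation's score is the PSSM entry of the **mutant** residue at the
mutated position — not a mutant-minus-wildtype difference. Wild-type
conservation already shapes the column through the profile, and the direct
lookup is what reproduces the packaged panels' annotations; a delta variant
exists behind `score_mutation(..., delta=True)` for comparison. An optional
check verifies the stated wild-type residue against the matrix query.

Two classification rules:

- **binary (score ≥ −1 → responsive)** — the original benchmark threshold;
- **three-zone** — score > −2 responsive, score = −2 twilight (no
  confident call), score < −2 non-responsive — the clinician-facing
  guideline.

They coincide on all integers except −2. Both thresholds are inclusive as
stated. Mutations flagged as active-site carry a warning on their
prediction (an active-site lesion cannot bind the chaperone regardless of
conservation) but the numeric call is never overridden: one packaged
active-site mutation is a genuine false positive of the method, and
silently fixing it would misrepresent the method's measured precision.

Experimentally, a mutant counts as responsive when DGJ-treated activity
reaches **15% of wild type** (inclusive). The threshold is the highest
residual activity still associated with classic phenotype in collected
patient series (12%), rounded up for assay error; it is configurable in
`activity_call`.

## Panel evaluation

`evalstats` bins labeled mutation records by integer score and by guideline
zone, computes the responsive fraction among predicted positives, a
two-tailed Fisher exact test against explicit baseline counts, a Pearson
correlation (with t-test p) of response rate versus score, and
classification accuracy. Twilight calls enter accuracy under a configurable
policy, defaulting to non-responsive (conservative); the binary rule has no
twilight. Records without a responsiveness label are excluded with a
warning. Percentages in the validation checklist are rounded half away from
zero before comparison, matching how such figures are conventionally
printed (12/14 → 86%).

The Fisher comparison never guesses a baseline: the historical ~42%
response rate among all tested mutations is known only as a percentage, so
callers must supply explicit (responsive, non-responsive) reference counts.

The incompletely reported literature mutation at codon 166 (no target
residue printed) is stored with a missing mutant residue: it is excluded
from score lookups but retained, via its printed score and label, in every
count keyed on scores — including accuracy, which therefore runs over all
19 labeled literature records (13 correct → 68.4% under the binary rule).

## Packaged panels

Two transcribed panels ship with the package: nine mutants expressed in
COS-7 cells and assayed with/without 20 µM DGJ (with fold increase, PSSM
score, MUPRO/SDM stability, solvent accessibility, secondary structure,
domain, active-site flag, phenotype, and the ≥15% outcome), and nineteen
literature-tested mutations with the same annotations plus reported
responsiveness. A sparse per-mutation score table realizes the published
matrix over the 27 fully specified panel mutations. The original matrix was
produced by a PSI-BLAST checkpoint run on thirteen Uniprot homologs that
cannot be reconstructed from published information, so the per-mutation
integers are fixture data, not a build target of this package's profile
code; the native builder is validated against an independent naive
implementation and on synthetic alignments instead. Every load verifies a
sha256 checksum and row counts; `NA` cells map to missing, never zero.

## Synthetic data

`synthdata` samples alignments column-i.i.d. from a known per-position
residue profile (`GeneratingProfile`), with gaps injected at a fixed rate
everywhere except the query so the coordinate system is stable, and samples
labeled mutation panels whose responsive labels are Bernoulli with success
probability `sigmoid(slope·score + intercept)` — a planted version of the
empirical score-response relationship. One integer seed drives all
sampling; the default test conditions (13 sequences, 40–50 positions,
conservation spanning 0.3–0.95, 5% gaps) mirror the scale of the original
homolog set. What the generator does *not* emulate: phylogenetic
correlation between sequences, alignment error, indel structure, and any
dependence of responsiveness on stability or solvent accessibility. Tests
passing on this generator therefore demonstrate the correctness of the
profile arithmetic and classification bookkeeping, not predictive accuracy
on real mutations.

## Numerical and design choices

- Rounding is half away from zero, applied once after scaling.
- The profile-recovery check (sup-norm error ≤ 0.05 between the estimated
  frequency layer and the generating profile at 500 sequences, halving from
  50) is run with uniform weights and β = 0: pseudocount smoothing is a
  deliberately biased estimator whose prior retains fixed weight
  β/(n_eff−1+β), so convergence to the generating profile is a property of
  the unsmoothed frequency layer.
- Degenerate inputs fail loudly: empty alignments and panels, zero-variance
  correlations, zero/negative activity baselines and out-of-range positions
  raise typed exceptions rather than returning sentinels. A 2×2 table with
  a zero margin has a single attainable configuration and yields p = 1.
- All-gap columns at a query position (possible only when the query
  character is unknown) fall back to the background distribution, scoring 0
  everywhere, with a logged warning.

## Limitations

- The native profile builder does not reproduce the historical BLASTPGP
  integers; agreement with the published per-mutation scores is carried by
  the fixture table, by design.
- The 87% cross-validated accuracy of the antecedent classifier, the
  Fisher p < 0.01 against the 42% baseline, and the full response-rate
  curve with r = 0.96 all require data (training panel, baseline counts,
  mutant compendium) that is not published; the package computes these
  statistics as general operations and validates them against independent
  oracles rather than asserting those figures.
- cDNA notation is carried as annotation only; no transcript model exists,
  so no protein/cDNA consistency checking is performed.
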