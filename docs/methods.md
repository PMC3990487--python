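# Methods

## Scope and data model

`tedynamics` analyses TE subfamily abundance from *exemplar-mapped* read
counts: every read is assigned to at most one of three reference sets — a
TE exemplar database, a filtered gene set (FGS) and a knob/centromere set
(KnobC) — and all downstream quantities are per-exemplar count summaries.
No genome coordinates are used; alignment lengths are measured on the read
and strand is ignored.

## Counting rules

Genomic reads count under five rules, applied in `ingest`:

1. only alignments strictly longer than 30 bp are eligible;
2. identity ("homology") thresholds of 0.80 for the TE and knob sets and
   0.90 for the gene set are applied whenever the record carries an
   identity; records without one are assumed filtered upstream (the
   counter reports how many records each filter removed);
3. database priority is the total order KnobC > UTE > FGS, because knob
   repeats contain TE fragments and the gene set is imperfectly filtered
   of TE-derived sequence;
4. within the TE set, a read contributes at most one hit: several
   best-score positions inside one exemplar collapse to a single hit
   (the alternative reading — collapsing distinct reads — would make
   counts order-dependent and is rejected), and a best score tied across
   two or more distinct exemplars discards the read;
5. read classification never depends on record order.

siRNA reads are kept only when they align with zero mismatches, and a read
with k target exemplars contributes 1/k to each, so fractional counts still
sum to the number of retained reads.

Paired-read genomic context tallies, for pairs with exactly one mate in an
exemplar, where the other mate landed (another exemplar, gene set, knob
set, nowhere).  Pairs with both mates in the same exemplar are excluded
from numerator and denominator: the quantity measures cross-feature
context.  Exemplars with no anchored pairs report missing fractions, not
zeros.

## Abundance

RPKM_TE is `Nᵢ / (Lᵢ[kb] · R/10⁶)` with R the exemplar-set total; the
normalization identity `Σ RPKMᵢLᵢ[kb] = 10⁶` holds exactly and is tested.
The low-copy cutoff defaults to RPKM 1.2 (approximately two copies for a
maize-scale library); the boundary value is retained, since the rule
removes values *below* the cutoff, and filtering is idempotent —
filtered exemplars stay in the table flagged `passes_filter=False`.

The approximate copy number anchors on gene-set depth:
`d = H_FGS·l̄/Λ_FGS`, `Cᵢ = Nᵢ·l̄/(Lᵢ[bp]·d)`.  Λ_FGS (total gene-set
length) is a required input; for synthetic data,
`implied_fgs_length_bp` returns the value consistent with the generator's
read allocation, under which the estimator is unbiased in expectation
(verified: regression slope on truth 1 ± 0.05 and median relative error
< 10% at 10⁶ reads).

Per-copy ratios (siRNA RPKM : RPKM_TE, expression RPKM : RPKM_TE) are
missing — not zero, not infinite — where RPKM_TE is zero.  The 24:22 nt
siRNA ratio is a ratio of counts-per-million values with a pseudocount
(default 0.5) added on that normalized scale; exemplar lengths cancel, the
ratio is invariant to library depth, and a doubly-untargeted exemplar
reports exactly 1.

## Classification

DNA-class abundances are fit by a log-normal (MLE = moments of log values;
a Kolmogorov–Smirnov distance to the empirical distribution is reported
for inspection, not thresholded).  RNA-class abundances are bimodal; the
R1/R2 boundary is fit by a two-component Gaussian mixture on log RPKM with
fully deterministic EM:

- initialization: component means at the 25th/75th percentiles of the log
  values, equal weights, pooled variance;
- convergence: relative log-likelihood change < 1e-8, at most 500
  iterations; variance floor 1e-6;
- threshold: the point between the component means where the two weighted
  component densities (hence posteriors) are equal — a quadratic in x,
  solved in closed form; with no root between the means the midpoint is
  used;
- degenerate inputs: a collapsed component falls back to the midpoint of
  deterministic 1-D 2-means centers with a warning; heavily overlapping
  components (|μ₂−μ₁| < s₁+s₂) warn that the input may be unimodal but a
  threshold is still returned.

Values are sorted internally, so the split is invariant to input order,
and scaling all abundances by c shifts the threshold by exactly c.  The
upper abundance component is modelled as a second Gaussian on the log
scale rather than a Poisson: only the split point matters downstream.
Filtering precedes classification (LOW is assigned before the DNA/RNA
split), and group definitions can be frozen from a reference accession by
passing its fitted threshold.  Cross-accession agreement is computed over
RNA exemplars classified R1/R2 in every compared accession.

## Tests

No chi-square uses a continuity correction — the standard statistic is
then *exactly* the squared two-proportion Z statistic, and the corrected
statistic is exactly the normal approximation to its binomial.  Exemplars
with a zero margin are untestable: they carry no p-value and are excluded
from the Benjamini–Hochberg family size m.  Significance is strict
(q < threshold, default 0.001).

χ²_Prop models the proportionality null on the log-ratio scale.  The
default "delta" construction propagates sampling variance from both the
siRNA and the genomic counts (variance `1/s_A+1/s_B+1/n_A+1/n_B`); the
siRNA library coverages σ are estimated as each library's total hits to
the exemplar set.  A "binomial" variant conditions on the siRNA total and
ignores genomic noise; it is exposed behind a flag for sensitivity
analysis.  Requiring all four counts ≥ 1 keeps the log-ratios finite;
calibration at expected counts ≥ 50 puts the type-I error within
(0.035, 0.065) at α = 0.05, and power is monotone in the deviation factor.

The normal approximation in χ²_Corr agrees with an exact binomial test to
0.01 in the decision region (exact p ≤ 0.05, expected counts ≥ 20); for
central p-values the binomial point mass itself exceeds 0.01, so no
continuity-free approximation can match there.

Group contrasts use Kruskal–Wallis (variables routinely violate variance
homogeneity), with Dunn-type z tests on pooled ranks (tie-corrected),
BH-adjusted, and a compact letter display: letters are maximal cliques of
the non-significance graph, so groups share a letter iff not significantly
different.  Cross-accession correlations regress log hits on log hits by
OLS after excluding exemplars with zero hits in either library (natural
log; the zero-handling and base are unstated in the literature the method
follows, so both choices are made explicit here).

## Fold changes

FC_TE divides hits by gene-set coverage and multiplies by mean read
length — retained even though it cancels for equal read lengths, because
libraries may differ.  FC_22/FC_24 normalize by the upper quartile,
computed nearest-rank (`ceil(0.75·n)`-th order statistic) over *nonzero*
per-exemplar counts — deterministic across platforms and invariant to
padding with untargeted exemplars.  Exemplars with zero hits (genomic) or
zero siRNA hits (per size class) in either library are excluded and
reported as missing, with exclusion counts written to the output header.
All FC variants are antisymmetric in the accession order.  Group summaries
report both signed mean FC and mean |FC| (the literature is ambiguous
about which carries the significance claims, so both are computed), with
Welch t-tests between groups on each.  External expression fold-change
tables (the wild-type vs *mop1* contrast) are consumed as provided in log2
units — the differential-expression call is prior art — and joined by
exemplar name.

## Synthetic data

The generator emulates the study design: per-group log-normal exemplar
lengths (defaults: log-means at 3/6/9 kb for D/R1/R2, sd 0.5 — the
high-copy retroelements are the longest); log-normal copy numbers (D:
ln 20 ± 1.0; R1: ln 5 ± 0.8; R2: ln 200 ± 0.8), chosen once so that RNA
abundances are clearly bimodal and RPKM ≈ 2 per copy at the default
library composition — copy-number dispersions are not published for this
design, so these are the package's own choices; group sizes default to
841/365/198; gene/knob read fractions default to the observed values for
the three maize accessions (15.0/6.12% for the reference, etc.); 100 bp
reads; mop1 expression effects of +1.2-fold (D), −1.6-fold (R1) and
1.03-fold (R2), given as linear folds and converted internally
(−1.6 ⇒ log2(1/1.6) = −0.678).

Reads are sampled multinomially, never Poisson, so per-library totals are
exact and conservation invariants hold to the count.  An optional
Dirichlet-multinomial knob adds siRNA overdispersion; the default is plain
multinomial because the empirical dispersion of siRNA counts is not
established for this design.  Every component draws from an RNG stream
derived from the master seed and a stable text label (library, purpose),
so any single component can be re-run reproducibly.

Two emulation limits matter for interpretation.  First, compartment read
fractions are fixed per accession, so raising one group's copy numbers
reallocates reads *within* the TE compartment rather than growing the TE
share of the library; relative fold changes (a group's gain showing up as
other groups' apparent loss) are therefore expected and visible in
`examples/05_fold_changes.py`.  Second, when accessions are given
different gene/knob fractions over a shared truth, their implied gene-set
lengths differ, so the FGS coverage anchor is not exactly null across
them — mimicking real compositional differences between genomes.
Calibration claims for χ²_Corr/χ²_Prop are therefore made under shared
compartment fractions with depth imbalance only, which is the true null
those tests assume.  The generator also does not simulate nucleotide-level
reads, alignment error, cross-homology between exemplars, or insertion
ages; passing recovery tests show the estimators invert the generator's
count model, not that mapping artefacts are handled.

## Problem sizes

The test suite and the acceptance script use: 10⁴ exemplars and 10–20
million reads for test calibration; 10⁶ reads and the default 1404-exemplar
database for recovery, agreement and replicate-FC checks; 300 draws for
the bimodal-split accuracy check.  These sizes give stable rates (binomial
SE < 0.005 on the calibration estimates) while keeping a full run in
seconds.

## Known limitations

- The proportionality test's delta-method variance ignores the (small)
  sampling noise in the coverage totals F and σ.
- The EM split assumes exactly two RNA abundance modes; model selection
  between 2- and 3-component mixtures is out of scope.
- Identity thresholds can only be enforced when alignment records carry
  identities; SAM input without NM tags passes the filter silently (the
  per-filter counts in the manifest make this auditable).
- The exact constant linking RPKM 1.2 to "about two copies" depends on the
  reference library; both RPKM and the copy-number estimate are exposed and
  their correspondence is never hard-coded.
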