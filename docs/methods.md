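# Methods

## Problem setting

NGS-based HLA typing emits, per sample and locus, a genotype of two
allele names at up to 3-field resolution, or a `Not typed` sentinel when
reads are insufficient — which, for the copy-number-variable secondary
DRB loci, can also mean the gene is truly absent. With no gold-standard
truth available, typing quality is measured as *consistency*: agreement
of children with Mendelian transmission in family trios, and agreement
between two independent typings of the same DNA (different assay, or
different tool). This package implements that evaluation end to end,
together with a generative model of the data so every stage can be
exercised and calibrated without access to any cohort.

## Matching model

Allele names are parsed into zero-padded string field tokens; comparison
is token-wise, never numeric (`01` ≠ `1`). At resolution k ∈ {1,2,3} two
typed calls match iff both have ≥ k fields and the first k tokens agree.
Three deliberate choices:

* **No optimistic prefix matching.** A 2-field call does not match a
  3-field call at k = 3, even when the first two fields agree. Truncated
  calls are a coverage failure mode and are counted as third-field
  disagreement, not treated as compatible unknowns. Consequently trios
  with short calls stay in the denominator and simply fail at field 3.
* **Concordant absence.** `Not typed` vs `Not typed` is a match in
  duplicate comparisons: both assays agreeing the locus yields no allele
  is agreement (and for DRB3/4/5 plausibly a shared true deletion).
  Typed vs `Not typed` never matches.
* **Expression suffixes** (N/L/S/C/A/Q) are parsed and preserved but
  ignored in matching by default (`compare_suffix=True` opts in); no
  suffix-dependent scoring rule is defined in the evaluation this
  implements, and field tokens carry all the discriminating content.

Matching is symmetric, monotone in resolution (a match at k implies a
match at every k' < k), and an equivalence relation on the set of alleles
typed to ≥ k fields — properties the suite checks directly.

## Trio scoring

For a regular diploid locus with fully typed members, the child genotype
(c₁, c₂) is scored 1 when some ordered assignment sends one child allele
to a paternal match and the other to a maternal match; 0.5 when no such
biparental assignment exists but at least one child allele matches at
least one parental allele; 0 otherwise. Each parent transmits exactly one
haplotype, so a homozygous child scores 1 only if *both* parents carry
the allele. The implementation is validated against an independent
exhaustive enumeration over all transmissions on 10⁴ randomized trios.

### DRB3/4/5

A haplotype carries at most one of DRB3/DRB4/DRB5 (or none), determined
by its DRB1 allele group, and typing tools render a hemizygous copy as a
homozygote. A strict diploid rule would therefore mis-score genuinely
Mendelian families — e.g. a child hemizygous for DRB3 (reported
`DRB3*01:01/DRB3*01:01`) whose second haplotype carries DRB4 from the
other parent would get 0.5. These loci are instead scored on allele
multisets, per locus and pooled as a single DRB3/4/5 unit:

* duplicate child alleles are collapsed first (a reported homozygote may
  be a rendered hemizygote);
* a child with no alleles is consistent (two null haplotypes);
* one distinct allele: score 1 if it matches either parent's set (the
  other haplotype may carry no secondary DRB gene), else 0;
* two or more distinct alleles: a biparental assignment of two of them
  scores 1, any single parental match 0.5, none 0.

Pooling into the unit conserves transmitted copies: a homozygous pair at
one paralog collapses to a single copy when another paralog is also
typed (at most two secondary-DRB haplotypes per person), and contributes
both copies when it is the only typed paralog.

This rule deliberately credits cases that are ambiguous at the data
level: a true homozygote child matching one parent is indistinguishable
from a hemizygote-plus-null and is scored consistent. That is the
interpretation the evaluation design calls for; it makes noise-free
simulated cohorts score exactly 100% at these loci, which is the
calibration the test suite pins.

### Exclusion

Exclusion is per family × locus: a `Not typed` slot in any member, or a
locus absent from any member's assay, removes the family from that
locus's denominator only. For the pooled unit, "complete typing" is
required in a weaker sense: a fully `Not typed` paralog next to a typed
one is plausible absence and kept, but a partially typed paralog
genotype (one typed, one dropped slot), or a member with no typed
secondary-DRB allele at all, excludes the trio — total dropout cannot be
told apart from double gene absence, and crediting it would
manufacture consistency (a forced-dropout simulation must yield all-NA
tables, which the suite asserts).

## Duplicate scoring

Per locus, the score is the size of a maximum matching between the two
genotypes' slot lists under the resolution-k matching relation, divided
by the larger slot count (exact permutation search; lists have ≤ 4
entries). Homozygote vs heterozygote sharing one allele scores 0.5 —
two slots, one agrees. Loci absent from one dataset's assay design are
skipped, not zeroed: an 11-locus amplicon panel is only comparable on
its 11 targets. Pairs are never excluded for dropout.

## Aggregation conventions

* Per-resolution cohort means are **unweighted across loci**: a 2-family
  DRB5 row counts as much as a 25-family HLA-A row. Only this convention
  reproduces the published cohort means from their per-locus tables.
* NA rows (zero evaluable families) are excluded from means, not
  zero-filled.
* The overall mean is the arithmetic mean of the three per-resolution
  means; presentation rounds half-up to 2 decimals, with unrounded
  values kept in JSON sidecars.
* Comparisons against the published tables use ±0.01: two printed cells
  there are truncated rather than rounded, so the recomputed half-up
  values can sit one hundredth above them.
* The packaged research-exome table keeps a locus label that is printed
  twice in the original (one row is most likely a mislabelled DRB8);
  both rows enter the column means, which is what reproduces the
  printed averages. Readers of report tables therefore tolerate
  duplicate locus labels.

Success rate per locus is the share of samples with both slots typed
among samples assaying the locus.

## The generative model

Founders draw two independent haplotypes; each haplotype draws one
allele per locus from a categorical frequency spectrum (default:
geometric decay, p_i ∝ 0.6^i — few common, many rare alleles). The DRB
region is simulated as explicit haplotypes: the DRB1 allele group
determines which of DRB3/DRB4/DRB5 (or none) the haplotype carries,
using the canonical linkage (groups 03/11/13 → DRB3, 04/07 → DRB4,
15 → DRB5, 01/08 → none). Default DRB1 group frequencies (0.10, 0.06,
0.14, 0.16, 0.12, 0.16, 0.12, 0.14 in map order) keep every carriage
class at substantial frequency, as in outbred populations. Children
receive one whole haplotype per parent, so the DRB region is
co-transmitted.

Rendering truth into call tables follows tool conventions: a hemizygous
paralog becomes a homozygote, an uncarried paralog becomes `Not typed`.
Observed data then pass through three independent per-slot noise
channels applied sequentially — dropout (→ `Not typed`), truncation of
3-field calls to 2 fields, mistyping (replacement by a different pool
allele, uniform) — with every event logged; replaying the log on truth
reproduces the observed table exactly, and channel rates re-estimated
from observed-vs-truth diffs equal the log counts exactly and the
configured rates within binomial error.

Determinism: all sampling uses integer draws against integer thresholds
on a 10⁻⁶ grid (rates and frequencies are quantized to 1e-6); no
floating-point comparison sits on a sampling path, so a fixed seed gives
identical cohorts across platforms.

### What the simulator does not emulate

Synthetic allele pools are distinct already at field 1, so a mistyped
allele is detectable at every resolution and truncation is the only
channel that separates field-2 from field-3 consistency. Real data also
degrade *within* an allele group (field-2/3 miscalls inside the same
group), exhibit linkage disequilibrium beyond the DRB block, correlated
noise between loci (shared coverage), and realistic allele-frequency
spectra. Passing the calibration tests therefore demonstrates that the
scoring and aggregation are correct under the stated noise model — not
that any particular real cohort would reach a given consistency level.
The published per-locus percentages for the real cohorts depend on
genotype calls that were never released; they enter the package as
fixture tables feeding the aggregation stage, and only the cohort-level
arithmetic over them is reproduced.

## Problem sizes and tolerances

The suite's calibration runs use 2,000 simulated trios for the
noise-free 100% check and the child-mistyping expectation, 1,000
duplicate pairs for the one-sided-truncation closed form, ≥ 10⁴ observed
alleles for noise-rate recovery, and 10⁴ random toy trios for oracle
equivalence — sizes at which 3-SE binomial bands are tight enough to be
meaningful while the whole suite stays fast. Stochastic assertions all
use exact enumerated expectations with 3-SE bands; deterministic
assertions are exact.

## Known limitations

* Duo (single-parent) scoring, phasing beyond one generation, and
  imputation of missing members are out of scope.
* G-group/P-group collapsing and 4-field comparison are not implemented;
  the evaluation caps at 3 fields.
* Typed-vs-`Not typed` duplicate slots are scored through the matching
  (only the affected slot loses credit); an alternative convention that
  zeroes the whole locus would score such pairs lower.
* The unit scoring credits one-parent matches for single-distinct-allele
  children without checking that the other parent could actually have
  transmitted a null haplotype; with rendered homozygotes this is
  undecidable from calls alone, and the permissive reading is adopted
  throughout.
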