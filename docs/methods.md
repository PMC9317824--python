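# Methods

## The burden model

The unit of analysis is a gene × variant-class pair, with classes `lof`,
`missense` and `combined` (their union). For a sample *i* with stratum
*s(i)*, carrier indicator *x_i* ∈ {0, 1} (at least one alternate allele of
at least one qualifying variant of that gene/class), the model is

    logit P(case_i) = β₀ + β·x_i + Σ_s γ_s·I(s(i) = s)

fit by maximum likelihood. Reported quantities are OR = exp(β), the Wald
95% CI exp(β ± 1.959964·SE), and the two-sided Wald p. The study covariate
uses one indicator per stratum with the lexicographically first label as
reference; the Wald statistic is invariant to this choice and to stratum
relabelling (tested). With a single stratum the fitted OR equals the 2×2
cross-product ratio exactly, which the tests exploit as an oracle identity
(agreement to 1e-6 relative error).

**Aggregation.** The fit internally collapses samples into unique
(status, carrier, stratum) cells with frequency weights. The binomial
likelihood, estimates, and standard errors are identical to the per-sample
fit (verified at 1e-15); fits then cost ~1–2 ms regardless of cohort size,
which is what makes the Monte-Carlo power and calibration suites cheap.

**Separation.** When cases or controls have zero carriers, the ML estimate
diverges. The fit runs to an iteration cap (default 25) and the result is
reported in the conventional diverged form: OR coded 0 or +Inf by the sign
of the runaway coefficient, CI (0, Inf), the capped fit's (large) Wald p,
and `separation_flag = True`. No Firth or other penalised correction is
applied by default: the target analysis style reports divergent cells
as 0.00/Inf with p ≈ 0.99 rather than shrinking them. Degenerate inputs
(no carriers at all, all carriers, a single outcome class) are flagged
`degenerate` with NaN placeholders; per-gene issues never abort a suite run.

**Subtypes.** ER-restricted analyses keep cases with the requested ER label
plus *all* controls; cases with the other or unknown label are dropped.
Unknown-ER cases therefore contribute to the overall analysis only, so the
two subtype case sets are disjoint and their union is a strict subset of
all cases.

**Heterogeneity (p-diff).** Implemented as a case-only logistic regression
of ER label on carrier status with the study covariate; p-diff is the Wald
p of the carrier term. This choice is an interpretation — "p-diff" names a
statistic, not a procedure — so a case-only Fisher exact alternative is
available (`method="fisher"`). When the case-only fit itself separates
(all carriers in one subtype) the Wald p is uninformative and the
implementation falls back to the exact test, labelled
`case_only_fisher_fallback`. Under label permutation the logistic p-diff is
uniform (KS-tested at 1000 permutations).

**Fisher per-study view.** Crude cross-product OR (0/Inf-coded on zero
cells, NaN for 0/0) with the two-sided point-probability Fisher exact p
(scipy); the tests verify it against exhaustive hypergeometric enumeration
for small tables. Whether per-study tables should be crude or stratified is
not specifiable further; crude 2×2 per stratum is used.

**Single-variant screen.** Variants observed in ≥ 3 carriers with ≥ 2 in
cases (both configurable) are each tested with the same adjusted logistic
fit on their own carrier vector.

**Multiple testing.** Nominal p-values are reported; the design-level
α = 10⁻⁴ is a reporting threshold, not a row-wise adjustment.

## Variant qualification

* LoF: consequence ∈ {stop_gained, frameshift} with CDS fraction ≤ 0.95,
  or splice_site, or start_lost; and MAF < `maf_max` (default 0.01, applied
  to both classes — the reported MAF strata for LoF sit at or below 0.01,
  and the ceiling is configurable).
* Rare missense: deleteriousness score present and ≥ `delscore_min`, and
  MAF < `maf_max`. `delscore_min` **has no default**: the threshold depends
  on the score in use and must be chosen explicitly (the simulator draws
  deleterious scores in U(0.2, 0.8); examples use 0.1).
* CDS fraction: number of coding bases at or 5′ of the position, in
  transcript orientation, divided by CDS length — a value in (0, 1]; on the
  minus strand the genomic end of the last interval is the first coding
  base. The tail exclusion is strict: a truncation is dropped iff its
  fraction exceeds 1 − `cds_tail_fraction` (reading "affects only the last
  5%" as exclusive of the 95% point; the boundary is tested explicitly).
* Multi-transcript genes: the transcript giving the smallest CDS fraction
  (most severe truncation) decides — conservative inclusion.
* "Variants that inhibit transcription or translation" is operationalised
  as start-lost (initiator-codon) variants; promoter/UTR effects are out of
  scope in an exome context. This is an interpretation and is documented as
  such.
* Splice-site consequence is an input annotation; a helper flags positions
  within ± `splice_window` (default 2) bases of internal CDS-interval
  boundaries for re-derivation, since no precise window is specifiable.
* MAF defaults to the cohort-computed folded frequency over called alleles
  (missing genotypes leave the denominator); an external allele-frequency
  annotation can override it (`use_external_af`).
* Coordinates are 1-based inclusive at every interface (VCF convention),
  including the transcript interval table.

## Power model

Study-scale effect: `OR_study = exp(factor · ln OR_pop)` with factor 1.5 by
default, modelling the inflation of the observable log OR caused by
sampling cases enriched for family history, early onset and bilaterality.
Case carrier probability comes from the odds transform
`p₁ = OR·f/(1 − f + OR·f)`.

Three evaluation paths:

* `analytic_power` (default): carrier counts in cases and controls are
  independent binomials, and the single-stratum Wald decision depends only
  on those two counts, so power is computed as the exact double sum of
  binomial probability mass over the rejection region (separated tables
  never reject). Deterministic, exact for the test actually used.
* `woolf_power`: the closed-form normal approximation with expected-count
  (Woolf) variance `Var(log OR) = Σ 1/expected cell`. It ignores the
  sampling variability of the estimated SE and at rare-carrier design
  points is conservative by up to ~0.14 (e.g. 0.82 vs the exact 0.96 at
  f = 0.001, OR = 4). It was the natural first choice for the analytic
  path, but it fails 3-Monte-Carlo-SE agreement with simulation at 2000
  replicates, so the exact enumeration is the default and the closed form
  is kept as the documented approximation.
* `mc_power`: binomial cohorts pushed through the same burden logistic fit;
  agrees with the exact path within 3 MC SE (tested), deterministic under a
  fixed seed.

Sidedness defaults to two-sided; both headline design-point bounds
(power > 50% at f = 0.005/OR = 2 and f = 0.001/OR = 4 with α = 10⁻⁴,
n = 6211/6019) hold under either choice. `prior_fold(1e-4, 2.5e-6) = 40`
expresses the validation α as a prior fold over exome-wide significance.
Published per-gene powers for specific known genes depend on external
effect-size and frequency estimates and are deliberately not reproduced.

## Family scoring

Age bands are left-closed — [50, ∞) → 1, [40, 50) → 1.5, (0, 40) → 2 —
with the 39/40 and 49/50 boundaries tested explicitly. Degree weights:
index 1, first-degree 0.5, second-degree 0.25. Bilateral cases contribute
both diagnoses, and this is applied to relatives as well as the index
(the bilateral clause is not index-specific; documented interpretation).
Eligibility: index diagnosed < 50 and (≥ 1 affected first-degree relative
diagnosed < 50, or ≥ 2 affected relatives of any degree diagnosed < 60);
"any degree" is an interpretation where the rule does not restrict degree.
Score bins are left-closed: {<2, [2,2.5), [2.5,3), [3,3.5), [3.5,4), ≥4}.

## The synthetic-data generator

Defaults encode the emulated study composition: 6211 cases / 6019 controls;
five study strata with sampling proportions from the contributing studies'
sample counts (3199/2767, 979/962, 1289/1348, 600/591, 451/469 — a
convention, since only totals are authoritative); ER status typed in 57.51%
of cases with 808/3572 of typed cases ER-negative; controls always
ER-unknown.

Carrier status is drawn per gene per class at the configured control
carrier frequency, with case carrier odds = OR × control odds (per-stratum
baseline-odds multipliers default to 1; a `confounded_preset` spreads them
over [0.5, 2] to exercise the crude-vs-adjusted gap). Carriers are then
assigned one specific variant from the class's frequency spectrum —
uniform shares, or one recurrent variant holding a configured share of
carriers, emulating founder alleles that account for most carriers of a
gene. Subtype-specific ORs, when set, replace the class OR for typed cases
of that label; unknown-ER cases use the marginal OR. All genotypes are
heterozygous by default (at carrier frequencies ≤ 10⁻², homozygotes are
negligible); an option adds them. Gene transcripts are deterministic
two-exon models of 3 kb CDS with alternating strand; qualifying variants
are placed in the pre-tail CDS region, and optional decoy variants cycle
through the disqualification reasons (synonymous, unscored missense,
tail-region stop-gain). With default per-gene settings nearly all emitted
qualifying variants have MAF < 0.001, matching the rare-variant regime the
qualification rules assume.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, sequencing error and coverage variation, population
structure beyond the study strata, relatedness between cohort samples, and
genotype-aware case exclusions. Passing tests therefore demonstrate the
statistical machinery under the assumed sampling model, not robustness to
the artefacts of real sequencing data.

Pedigree simulation draws index diagnosis ages from a young-skewed normal
(mean 44, sd 7, clipped to [25, 85]), relatives from N(52, 10), Poisson
counts of affected first-/second-degree relatives (means 1.2 / 0.6) and a
12% bilateral probability — chosen so that the generated score
distribution populates all reporting bins, low to ≥ 4.

## Numerical and reporting conventions

* Random streams: `numpy.random.default_rng(seed)`; fixed seed gives
  byte-identical VCF/TSV output (the VCF header carries no timestamp).
* A fitted |β| > 15 is treated as diverged even when both carrier cells are
  non-zero (iteration-capped runaway).
* Report tables round OR/CI to 2 decimals and p to 3 significant figures
  (scientific below 10⁻³); machine outputs (`association_results.tsv`,
  `results.json`) keep full precision plus flags.
* Pipeline outputs embed the seed and a SHA-256 prefix of the
  configuration; exclusion-reason counts in the log sum exactly to
  inputs minus qualifying variants.

## Problem sizes in the test suite

Deep checks run at the emulated study scale where it matters and smaller
elsewhere: calibration uses a 198-gene null cohort at 6211/6019 (type-I
error within 3 MC SE of 0.05); CI coverage uses 100 replicates per
(f, OR) cell over {0.001, 0.005, 0.02} × {0.5, 1, 2, 4} with ≥ 90%
required coverage; Monte-Carlo power uses 2000 replicates; convergence of
the control carrier frequency is checked at n = 50,000. Shared fixtures
use 3000/3000 or 800/800 cohorts. The full suite runs in about a minute.

## Known limitations

* The deleteriousness-score threshold is study- and score-specific; no
  default is supplied, and simulated scores are synthetic draws, not
  BayesDel outputs.
* The heterogeneity procedure is an interpretation (see above); printed
  p-diff values from the motivating analysis style are not reproducible
  without individual-level data and are not targets.
* Plain ML under separation reports a capped, conventional result rather
  than a finite penalised estimate; users wanting Firth-type inference
  should fit elsewhere — the flags make the affected rows easy to find.
* Consequence annotation is consumed, never predicted; multi-allelic VCF
  records must be pre-split.
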