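# Methods

This note documents the statistical machinery in `nkaml`: the models and
estimators, the parameters that matter, the synthetic-cohort generator and
what it does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Somatic driver filtering

A candidate variant enters the filter with tumor allele depths (ref, alt),
optional matched-normal depths, and three upstream annotation booleans that
stand in for database lookups: `known_somatic_flag` (COSMIC/ClinVar-style
support), `germline_suspect_flag` (dbSNP/esp6500-style population
membership), and `control_free_somatic_flag` (a control-free somatic caller's
verdict for samples without a matched normal).  Reducing the database layer
to input flags keeps runs reproducible without version-pinned downloads;
annotation itself is upstream of this package.

Retention requires, in fixed order (the first failing rule names the reason
code):

1. **Panel** — gene on the driver panel (case-insensitive symbol match).
2. **VAF** — tumor alt/(ref+alt) ≥ `vaf_min`, default 0.03.  The floor is
   *inclusive*: a VAF of exactly 3 % passes, reading the threshold as a
   minimum.  Whether the 3 % rule should instead bind the tumor–control
   contrast is an interpretation; this package applies it to tumor VAF.
3. **Germline** — `germline_suspect_flag` must be false.
4. **Evidence** — with a control: two-sided Fisher exact *p* < `p_max`
   (default 0.001, *strict*: *p* = 0.001 fails, reading "*p* < 0.001"
   literally); without a control: `control_free_somatic_flag` must be true.

The two-sided Fisher *p* uses the probability-mass definition — the sum of
hypergeometric probabilities of all tables (same margins) no more probable
than the observed one — the convention of R's `fisher.test` and SciPy.  The
implementation enumerates the hypergeometric support with
`scipy.stats.hypergeom.pmf`; a relative guard of 1e-10 treats
floating-point-equal masses as ties.  Tests compare it against an
independent log-factorial enumeration over every table with grand total
≤ 60; agreement is ~1e-13.

Raising `vaf_min` can only shrink the retained set (the filter is a
monotone conjunction); this is property-tested.

## Profiles and the eight-way classification

Retained variants aggregate into one profile per patient: the set of
mutated panel genes, the retained-mutation count, and three derived flags —
**biallelic CEBPA** (two distinct retained *CEBPA* variants, distinguished
by protein change and variant class, or an explicit biallelic annotation;
two-variant ascertainment is a proxy for true allele phasing, which
targeted panels cannot observe), **IDH2-R172** (any *IDH2* variant whose
protein change sits at codon 172), and **FLT3-ITD** (an *FLT3* variant of
ITD class).

Class-defining lesions: NPM1; chromatin/spliceosome (any of *RUNX1, ASXL1,
BCOR, STAG2, EZH2, SRSF2, SF3B1, U2AF1, ZRSR2*); TP53; biallelic CEBPA; and
IDH2-R172, which is *subordinate* — it fires only when no other lesion
does, because its class is defined by the absence of other class-defining
lesions.  It therefore can never contribute to the multi-class bin.
Exactly one lesion → that class; two or more → `MULTI_CLASS` (no hierarchy
is imposed, e.g. TP53 takes no priority over NPM1 in a normal-karyotype
cohort, where the separate ≥2-subgroup bin replaces the original
cytogenetics-anchored precedence); none → `DRIVER_NO_CLASS` when at least
one driver is retained, else `NO_DRIVER`.  *FLT3*-ITD and the other
recurrent drivers (DNMT3A, TET2, NRAS, IDH1, IDH2-R140, monoallelic CEBPA)
are recorded but never class-defining.  Classification is total and
order-independent; adding a non-panel gene never changes a label.

## Categorical statistics

Proportions are reported on the percent scale with Wald intervals
`p ± z·√(p(1−p)/n)`, clamped to [0, 100]; small subgroups therefore print
clamped bounds such as "40.5–100".  Odds ratios use the Woolf (log-normal)
interval `exp(ln OR ± z·√(1/a+1/b+1/c+1/d))`, with the Haldane–Anscombe
+0.5 correction in every cell when a cell is zero (the estimate is tagged
`corrected`).  Association *p*-values are Pearson χ² with 1 df and no
continuity correction; expected cells below 1 trigger a warning
recommending the exact test.  z is the exact normal quantile (1.959964 at
95 %), not 1.96.  No multiplicity adjustment is applied anywhere.

## Endpoints

All clocks start at induction chemotherapy, in months.

- **OS**: time to death from any cause; otherwise censored at last
  follow-up.
- **EFS**: time to death, relapse, or CR non-achievement, whichever first.
  Non-achievement has no natural clock time; it is set to the
  induction-failure assessment when supplied, else to a configurable
  default of 1 month (`noncr_efs_time`), capped by death when death came
  first.  Setting it to 0 or to the failure date shifts the early EFS drop
  but not the subgroup ordering.
- **Relapse**: the clock restarts at the CR date; relapse is cause 1 and
  death without relapse the competing cause 2; otherwise censored at last
  follow-up.  Only CR patients enter.
- **Allogeneic SCT never censors anything**; it enters the Cox model as a
  time-dependent indicator instead.

## Survival estimation

**Kaplan–Meier** is the plain product-limit estimator; at tied times deaths
precede censorings (the risk set at *t* is everyone with time ≥ *t*).
Variance is Greenwood's.  "5-year" figures are the right-continuous step
function evaluated at exactly 60.0 months, with a plain-scale Wald interval
from the Greenwood SE, clamped to [0, 1] (printed unclamped-looking bounds
in small subgroups come from the same construction).  Evaluation beyond the
last observed time returns the last value with an extrapolation warning.

**Log-rank** is the usual k-sample score construction over pooled event
times with the hypergeometric variance (factor `d(Y−d)/(Y−1)`), compared to
χ² with k−1 df.  On tie-free data it coincides numerically with the score
test of a two-group Cox model (tested).

**Aalen–Johansen** cumulative incidence:
`CIF_k(t) = Σ_{s≤t} Ŝ(s−) d_k(s)/Y(s)` with the all-cause Kaplan–Meier
Ŝ.  The identity `Σ_k CIF_k(t) + Ŝ(t) = 1` holds at machine precision and
is asserted in tests.  The variance is the delta-method estimate from the
estimator's i.i.d. representation,

```
V(t) = Σ_{s≤t} [Ŝ(s−) − (F̂(t)−F̂(s))]² d_k(s)/Y(s)²
     + Σ_{s≤t} [F̂(t)−F̂(s)]² d_other(s)/Y(s)² ,
```

which tracks the cmprsk reference implementation to ~1–2 % and is used only
for interval display.  Delayed entry (left truncation) is supported via an
`entry` argument.

**Gray's test** (cause 1, ρ = 0) compares subdistribution hazards on the
modified risk set `R_j(t) = Y_j(t)(1 − F̂_1j(t−))/Ŝ_j(t−)`, which returns
competing-cause failures to the risk set in expectation.  The score is
`z_j = Σ_t K(t)[d_1j(t) − R_j(t) d_1(t)/R(t)]` with K ≡ 1 at ρ = 0.  The
variance estimator follows the martingale representation of the score: the
direct term `K(δ_jl − R_j/R)` against cause-1 event martingales, plus the
correction terms that arise because each group's CIF and survivor function
are estimated and feed into R_j at later times (integrands
`B_jl(s)F̂_2l(s−)/Y_l(s)` against cause-1 and `B_jl(s)(1−F̂_1l(s−))/Y_l(s)`
against cause-2 martingales, with
`B_jl(s) = −Σ_{t>s} K(t)(δ_jl − R_j/R)(Y_l/Ŝ_l(t−)) dΓ̂(t)`).  The statistic
is the quadratic form of the first k−1 scores against χ² with k−1 df.  This
estimator is consistent and agrees with the cmprsk implementation
asymptotically (within ~2 % at n = 1000 per arm) but is not bit-identical
in small samples, where the finite-sample plug-in conventions differ;
cross-checks in the test suite use frozen cmprsk reference p-values
(absolute tolerance 0.07 on n ≤ 120 fixtures), a label-permutation oracle,
and type-I simulations (observed sizes 0.04–0.05 at nominal 0.05).  Only
ρ = 0 — the default of the software family used for such analyses — is
exercised; the ρ ≠ 0 weight is applied to the score but its own estimation
variance is not corrected for.

**Cox regression** runs on start–stop (counting-process) rows, risk
interval (start, stop]; a patient transplanted at time s contributes
(0, s] with SCT = 0 and (s, T] with SCT = 1.  Ties use the Breslow
approximation — adequate at the tie density of monthly-resolution data and
simpler than Efron; with heavy ties Breslow attenuates coefficients
slightly.  Newton iterations with step-halving run to a gradient tolerance
of 1e-8 (max 100).  Monotone likelihood (perfect separation) is detected by
a runaway coefficient (|β| > 20), warned about, and the estimate bounded.
On tie-free data the fit matches lifelines to ~1e-5; on a 5-subject fixture
it matches a brute-force partial-likelihood maximisation to 1e-4.

## Synthetic cohort generator

The generator exists so that every downstream stage — filter, classifier,
statistics, survival — can be exercised end-to-end without patient-level
data, which was never deposited for this kind of cohort.  Defaults emulate
a 393-patient NK-AML cohort.

- **Subgroup mix**: multinomial with probabilities equal to the published
  subgroup counts over 393 (0.3460, 0.1069, 0.0153, 0.1349, 0.0204, 0.2952,
  0.0433, 0.0382) — exact count fractions rather than the rounded printed
  percentages, so the vector sums to 1.
- **Mutations**: each patient receives the class-defining lesion(s) of the
  drawn label (two distinct *CEBPA* variants for the biallelic class; one
  gene uniform over the nine for the chromatin/spliceosome class; two
  lesions drawn from {NPM1, chromatin, TP53, biallelic CEBPA} for the
  multi-class bin — IDH2-R172 excluded by its no-other-lesion definition),
  plus independent Bernoulli co-mutations at marginal frequencies *FLT3*
  0.349 (ITD in 70 % of hits), *DNMT3A* 0.316, *NRAS* 0.183, *TET2* 0.102.
  Co-mutated genes are never class-defining, so they cannot change the
  planted label; the driver-without-class bin is guaranteed at least one
  driver.  Real co-occurrence and mutual-exclusivity structure is *not*
  modelled (no quantitative source), nor is the full 92-gene panel content.
- **Depths**: tumor depth uniform 200–600 (deep targeted sequencing), VAF
  uniform 0.05–0.5, alt counts floored at 5 % of depth; 30 % of variants
  lack a matched normal and carry the control-free somatic flag; matched
  normals are clean (zero alt reads) at the same depth, with the alt count
  bumped in the rare draw where the Fisher rule would still not clear.  By
  construction every planted variant survives the filter, which is what
  makes the generator→classifier round-trip an exact (100 %) property.
- **Clinical covariates**: age/WBC/blast are log-normal around the
  per-subgroup published medians, with spread set from the published ranges
  (σ = ln(hi/lo)/6) and clipped to them.  These are plausibility dressing,
  not calibrated distributions.
- **Outcomes**: CR ~ Bernoulli(per-class CR rate); CR date uniform 0.9–2.0
  months.  Event times are exponential, calibrated *only* at the 5-year
  point (the source reports no shape information, so constant hazards are
  the honest minimal choice — real AML hazards fall with time, so
  off-target horizons should not be over-read).  The monthly death rate λ
  solves the class-marginal equation
  `e^{−60λ}[p_CR·E(e^{λc}) + 1−p_CR] = S₅` (CR patients are event-free
  until the CR date c; the naive −ln(S₅)/60 is the λ→0 limit and would bias
  5-year KM up by ~1.3 points in the worst subgroup).  For CR patients
  relapse competes with death-without-relapse at rates (λ₁, λ); λ₁ solves
  `λ₁/(λ₁+λ)·(1−e^{−(λ₁+λ)·60}) = R₅` (Brent's method, cached).  Because
  the death hazard is λ both before and after relapse, post-CR all-cause
  survival stays exponential at λ and both calibration targets hold
  simultaneously; relapse-to-death coupling beyond that is not modelled.
  Any R₅ < 1 is feasible in this parametrization (CIF₁+CIF₂ ≤ 1 by
  construction); configuration errors are raised for R₅ ≥ 1 or S₅ ∉ (0,1].
  SCT ~ Bernoulli(per-class SCT rate) among CR patients, timed uniformly
  within 6 months of CR and strictly before the next event.  Follow-up is
  administratively censored at 120 months.
- **Determinism**: one `numpy.random.Generator(PCG64)` seeded from
  `SimConfig.seed` drives everything; regeneration is byte-identical.

At n = 5000 per subgroup, Kaplan–Meier at 60 months and the relapse CIF at
60 months recover every configured target within ~1 point (tests assert
±3).  Passing these tests shows the estimators and the generator agree
under the generator's assumptions — exponential hazards, independent
censoring, independent co-mutations — not that the package would reproduce
any particular real cohort's curves.

The TP53 subgroup's parameters rest on six published patients; they are
carried as configured values but are statistically unstable and should not
be interpreted.

## Problem sizes used in checks

Routine tests run on cohorts of 40–393 patients; calibration checks use
5 000 patients per subgroup; test-size simulations use 2 000 replicates of
two 80-patient arms; the Fisher sweep covers all 635 375 tables with grand
total ≤ 60.  The full suite runs in a few minutes on one CPU.

## Known limitations

- Exponential hazards and the 60-month calibration point are modelling
  stand-ins; no shape inference is attempted.
- Gray's test variance is a consistent martingale plug-in, not a
  re-derivation of the original finite-sample formulas; small-sample
  statistics differ from cmprsk by a few percent.
- The Aalen–Johansen variance is likewise a delta-method plug-in.
- Breslow tie handling attenuates Cox coefficients under heavy ties.
- The default panel carries only the genes named in published NK-AML work
  (18 symbols); site-specific 90+-gene panels should be supplied as config.
- Univariate subgroup hazard ratios are deliberately not reported: with
  subgroup-versus-rest comparisons the reference group is ambiguous and
  published values of this kind cannot be reconstructed unambiguously.
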