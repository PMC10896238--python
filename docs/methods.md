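# Methods

## Scope and data model

The engine computes maternal-health surveillance indicators from three
microdata record kinds — live births (SINASC-like), deaths of women of
childbearing age (SIM-like) and public obstetric hospitalizations
(SIH-like) — plus reference tables (population by age/sex, health-plan
beneficiaries, family-health coverage, MHDI, inter-municipality distances,
facility registry with adult-ICU beds, demographic estimates of births and
deaths, death-investigation counts, congenital-syphilis cases). Raw
binary DATASUS formats are out of scope: inputs are delimited text read
through *schema maps* that carry the per-source dialect (column names,
category recodes, sentinel-to-missing conventions, 7th geo check digit).
Sentinel conventions live in the map, not in code, because "ignored" codes
vary by system and vintage.

Validation quarantines, never drops: every row that violates a type
invariant (age outside 8–60, birth weight outside 200–7,000 g, gestational
age outside 20–45 weeks, ICU days exceeding the stay, malformed ICD-10 or
geo code, inconsistent cause-class/maternal-death flag) lands in a rejection
log with `(row_number, field, reason)`, and `rows_in = records_out +
rejected_rows` always holds. Records with a missing residence municipality
are quarantined rather than reassigned to the occurrence municipality, since
imputing residence would silently move events between denominators.

## Indicator conventions

Each indicator is `numerator / denominator × scale` with the components kept
on the value. Conventions applied uniformly:

- **Missing-data rule.** Records missing a field the indicator needs are
  excluded from numerator *and* denominator; the exclusion count travels as
  a flag, and per-variable incompleteness is monitored alongside (quality
  block) instead of being absorbed into the estimate.
- **Zero denominators** yield an *undefined* flagged value, never 0.
- **Keying.** All indicators use the mother's municipality of residence;
  only place-of-occurrence and the displacement median also read the
  occurrence municipality (standard vital-statistics convention).
- **MMR** is computed for every unit, however small — a single death in a
  small municipality is informative even if unstable — with an instability
  flag when deaths < 5. "More than seven prenatal consultations" is
  implemented as ≥ 8 visits, consistent with the minimum-of-eight
  recommendation; multiparity ">3 previous births" is vaginal + cesarean
  parity ≥ 4.
- **MHDI bands**: `< 0.500` very low, `0.500–0.599` low, `0.600–0.699`
  medium, `0.700–0.799` high, `≥ 0.800` very high; values outside `[0, 1]`
  are a domain error. MHDI is consumed as an input and is not aggregable
  above the municipality.

## Robson ten-group classification

Births are classified by the canonical decision table with fixed precedence:
multiple pregnancy → 8; transverse/oblique lie → 9; breech → 6/7 by parity;
single cephalic preterm (< 37 completed weeks) → 10; prior cesarean at term
→ 5; then nulliparous 1/2 and multiparous 3/4 by labour onset (spontaneous
vs induced or pre-labour cesarean). Parity is prior vaginal + prior cesarean
births; multiparity is established by either count ≥ 1 even when the other
is missing, while nulliparity requires both present and zero. A record
missing a field *on the path actually taken* is unclassifiable and reports
the missing fields — onset is not required for group 5, so a term cephalic
birth with a prior cesarean classifies even with onset blank. Women with a
prior cesarean go to group 5 regardless of onset, per the published
ten-group table. Unclassifiable births are excluded from the three Robson
indicators' numerators and denominators and surface as a completeness flag.
No 2a/2b or 5.1/5.2 refinements are attempted.

Group-level cesarean-rate references: group 1 = 10%, group 2 = 20–35%,
group 3 = 3%, group 4 = 15%, group 5 = 50–60%, group 10 = 30%; groups 6–9
are compared with the national average. Point references are encoded as
degenerate ranges so status reads within/above/below.

## Severe maternal morbidity

A public obstetric admission is an SMM case when it matches any cause code
set (prefix match on normalized, dot-free ICD-10) or any management
criterion: transfusion flag, severe surgical procedure code, ICU days ≥ 1,
or length of stay strictly greater than 7 days ("more than 7 days").
Classification is multi-label; cause and management breakdowns use total
SMM cases as denominator and may sum past 100%. The shipped code list
(severe pre-eclampsia/eclampsia O141/O15; obstetric hemorrhage O441, O45,
O46, O67, O72; sepsis O85, O86, A41; hysterectomy/laparotomy procedure
stubs) is an **editable default**, not an official list — production use
should review it against the local coding practice. Only public admissions
enter numerators and denominators: privately financed care is invisible to
this source, which limits interpretation where health-plan coverage is
high. Admissions are counted as-is; transfers or readmissions of one woman
are not deduplicated into episodes (a known limitation of the source).

## Unsafe-abortion estimation

`UA = max(0, abortion admissions − s·LB) × m`, where `s` is the expected
hospitalized-spontaneous-abortion fraction of live births and `m` the
multiplier for induced abortions without hospital admission, in the family
of indirect-estimation methodologies. Defaults (`s = 0.034`, `m = 4.0`)
ship as explicit configuration; the estimator refuses to run without a
config, and the values used travel in the result metadata. The rate is per
1,000 women 10–49 and the ratio per 100 live births. Negative corrected
counts floor at zero with a flag; the floor makes the estimate subadditive
under aggregation in the rare case a member municipality floors while the
pool does not.

## Aggregation, benchmarks, series

Roll-up sums numerators and denominators over member municipalities and
re-takes the ratio — never averages rates. Median-type indicators are
recomputed from pooled birth-level distances at the target level (municipal
medians cannot be combined); the displacement median is taken only over
births occurring outside the municipality of residence, stratified by
adult-ICU availability of the delivery facility, with the even-count median
as the midpoint of the central pair. Missing member units are flagged, not
imputed.

Benchmark boundary conventions: goals stated as floors ("90%", "95%",
"10%", "20%") pass at the boundary; goals stated as strict ceilings
("< 30 per 100,000", "< 30 per 1,000", "< 5%") fail at it. Ranges are
inclusive at both ends. "National average" comparators are computed from
the loaded data for the same year. Undefined values benchmark as
not-applicable.

Historical series return one row per year per unit for the unit of interest
plus comparators: sibling municipalities of the same health region, or the
k municipalities nearest in MHDI (absolute difference rounded to 9 decimals
before ranking so float noise cannot reorder ties; ties break by geo code).

## Quality companions and alerts

Coverage = recorded events / demographic estimate × 100, flagged low below
90 and over-registering above 100 (reported, not clipped, and never used to
adjust indicators — no capture-recapture correction is attempted).
Incompleteness is per variable over its record kind's denominator (live
births for birth variables, deaths for death variables, admissions for
hospitalization variables), flagged at ≥ 5%. Death-investigation goals are
90% (women of childbearing age) and 100% (maternal). Alerts attach to
exactly the indicators whose declared source systems and variables are
affected; unavailable coverage produces a "not assessable" alert. Alerts
never modify values.

## Synthetic worlds

The generator emulates the study conditions end to end; its defaults are the
conditions the engine is tested under: 50 municipalities (2 macro-regions ×
2 states × 2 health regions each), 2,000 births per municipality, cesarean
56%, preterm 11%, early term 28%, low birth weight 8.5%, MMR 60 per
100,000, direct causes 65%, SMM 3% of public obstetric admissions, abortion
admissions 6% of births, adolescent fertility 50 per 1,000, multiparity 6%,
prenatal coverage 97% with 70% early start and 55% with ≥ 8 visits,
exclusive public-system dependence 75%, family-health coverage 65%, 25% of
births outside the municipality of residence, and a ten-group case mix of
(25, 17, 23, 8, 12, 4, 2, 2, 1, 6)%.

Mechanics worth knowing when interpreting tests:

- **Heterogeneity.** Each rate is jittered per municipality with a Beta
  distribution centred on the national value (concentration 5,000), giving
  real between-unit variance while keeping national estimates within the
  binomial sampling band of the target.
- **Cesarean calibration.** Births draw a Robson group from the mix;
  baseline within-group cesarean propensities are shifted on the logit
  scale (solved by bisection) so the mix-weighted overall rate equals the
  municipal target exactly in expectation. Labour onset is drawn
  consistently with the delivery (pre-labour cesarean onset only for
  cesarean deliveries), so a zero-cesarean world contains no pre-labour
  cesarean onsets.
- **Gestational age.** Group 10 is preterm by definition, groups 1–5 are
  term; the preterm share of groups 6–9 is solved so the overall preterm
  rate hits its target — hence the configured preterm rate must lie between
  the group-10 mix share and that share plus groups 6–9 (validated at
  config time).
- **Conditional parameters.** Women without prenatal care carry a missing
  start trimester, so `early_start_share` is defined *conditional on any
  prenatal care* and the indicator (which excludes missing) recovers that
  conditional value. Populations are sized from births: female 10–19 is
  derived from the adolescent-fertility target and the under-20 birth
  share, female 10–49 from a general fertility of ~60 per 1,000 — the
  synthetic world fixes population to make rate targets recoverable rather
  than simulating demography.
- **SMM injection.** Cases are created by injecting cause-specific codes
  from the shipped list into admissions; non-cases receive only benign
  codes and sub-threshold stays, so classifier recall is 1 and the
  false-positive rate 0 *by construction* — these tests validate the
  plumbing, not real-world sensitivity of the code list.
- **Missingness** is missing-completely-at-random per field (defaults
  0.2–3.5% on demographic and obstetric fields), so missing-exclusion is
  unbiased in the synthetic world; informative missingness is not modelled.

What passing tests therefore do **not** show: performance under real
Brazilian marginal distributions, informative missingness, miscoded or
duplicated records, or linkage error across systems. The generator is an
internal-consistency oracle, not a population model.

## Problem sizes and tolerances

Parameter-recovery checks run at 50 × 2,000 births (one year) and assert
national estimates within 4 binomial standard errors of the generating
value, with maternal deaths within 4·√λ of the Poisson expectation;
aggregation conservation is asserted exactly (no tolerance) at every
hierarchy level; determinism is asserted byte-for-byte on
simulate→compute→report. Unit tests use 4–8 municipalities of 60–400
births. Percentage identities (composition sums, size-weighted Robson
identity) are asserted to 1e-9.

## Known limitations

- Indicators are raw: no small-area smoothing or shrinkage; instability is
  flagged instead.
- Coverage is reported, not corrected for (no denominator adjustment).
- The SIM-like input here is the childbearing-age extract, so "mortality
  system coverage" is coverage of that extract against its estimate.
- One intermediate level ("health region") is modelled between municipality
  and state by default; additional levels would require extending the level
  ladder, though the hierarchy file format itself is generic.
- Congenital-syphilis cases are counted by residence municipality.
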