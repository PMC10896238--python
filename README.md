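# matvig — maternal-health surveillance indicator engine

Maternal death is infrequent, so most municipalities record none in a given
year — yet the conditions that lead to it (poor socioeconomic context, gaps
in reproductive planning and prenatal care, barriers to delivery care, severe
obstetric complications) are measurable everywhere from routine data.
`matvig` is the computational core of a maternal-health surveillance panel
for that problem: it turns vital-statistics and hospitalization microdata
(de-identified, SINASC/SIM/SIH-like delimited extracts) into a catalogue of
**35 indicators** spanning six determinant blocks plus information-quality
companions, for epidemiologists, health-department analysts and researchers.

What it computes:

- **Maternal mortality**: maternal-death counts and the maternal mortality
  ratio `MMR = deaths / live births × 100,000`, reported for every
  municipality however small, with an instability flag below 5 deaths;
  direct-cause and specific-cause breakdowns.
- **Robson ten-group classification** of every birth from plurality,
  presentation, gestational age, parity, prior cesarean and labour onset —
  group sizes, within-group cesarean rates, and each group's relative
  contribution to the overall cesarean rate, benchmarked against the
  group-specific reference rates.
- **Severe maternal morbidity** (potentially life-threatening conditions)
  among public obstetric hospitalizations: ICD-10 cause groups
  (hypertension, hemorrhage, infection) and severe-management markers
  (transfusion, surgery, ICU admission, stay > 7 days), multi-label.
- **Unsafe-abortion estimates** from abortion hospitalizations with a
  two-step correction: subtract expected hospitalized spontaneous abortions,
  then multiply for induced abortions that never reach hospital.
- **Access and context**: exclusive public-system dependence, family-health
  coverage, adolescent fertility, displacement to delivery care (median km
  to out-of-municipality births, stratified by adult-ICU availability),
  MHDI bands.
- **Data quality**: system coverage, death-investigation coverage and
  per-variable incompleteness, wired to every substantive indicator as
  "interpret with caution" alerts.

Every value keeps its numerator and denominator, so aggregation up the
municipality → health region → state → macro-region → country hierarchy sums
components and re-takes the ratio — rates are never averaged. A synthetic-
data module generates complete, internally consistent worlds with known true
parameters, so the whole engine is testable without any external data.

## Worked example

```python
import matvig as mv

cfg = mv.SimulationConfig(seed=1, n_municipalities=8, births_per_muni=500)
world = mv.generate_world(cfg)                  # synthetic microdata + references
data = world.to_panel_data()

vals = mv.compute_unit(data, "BR", 2015,
                       abortion_config=mv.AbortionCorrectionConfig.default())
vals = mv.benchmark_values(vals, mv.load_catalogue())
for ind in ("cesarean_pct", "preterm_pct", "mmr", "smm_pct"):
    v = next(x for x in vals if x.definition_id == ind and x.category is None)
    print(f"{ind}: {v.value:.2f} ({v.numerator:.0f}/{v.denominator:.0f})"
          f" -> {v.benchmark_status}")
```

prints

```
cesarean_pct: 55.67 (2227/4000) -> above
preterm_pct: 12.41 (490/3949) -> does_not_meet
mmr: 25.00 (1/4000) -> meets
smm_pct: 3.11 (102/3280) -> not_applicable
```

Reading: 55.67% of the 4,000 synthetic births were cesarean — *above* the
10–15% population reference band; preterm births exceed the 10% reference;
the national MMR of 25 per 100,000 (a single death — note the denominator)
*meets* the < 30 goal; the severe-morbidity share has no fixed standard
(it is benchmarked against the national average when comparators are
supplied). The generating parameters were cesarean 56%, preterm 11%,
MMR 60/100,000 and SMM 3%, so the estimates recover their targets up to
sampling noise. Missing fields are excluded from numerator and denominator
(preterm's denominator is 3,949, not 4,000) and surface as flags.

## Command line

```bash
matvig simulate --config sim.yaml --seed 7 --out world/   # synthetic world
matvig validate --data world/                             # schema + quarantine
matvig compute  --data world/ --geo BR --out panel.csv    # tidy indicator table
matvig report   --data world/ --geo 111001 --year 2015 --out report/
matvig catalogue --format json                            # indicator documentation
```

`report` writes the three presentation levels: all indicators for one place
and year, per-block historical series with comparators (same health region
or similar-MHDI municipalities), and per-indicator detail with documentation
and quality alerts.

Real DATASUS-style extracts (pre-converted to delimited text) load through
configurable schema maps (`matvig.SchemaMap`) that rename columns, recode
category tokens and map sentinel codes like `99` to missing; see
`src/matvig/data/schema_maps/sinasc_like.yaml`.

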