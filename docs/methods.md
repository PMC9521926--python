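# Methods

## The model and its assumptions

`renalcdm` implements a *built-for-purpose* common data model rather than a
general-vocabulary CDM: semantic agreement across sources is achieved by
curated code lists that map each source code directly to a clinical entity
label, not by translating codes between vocabularies. The working assumptions
are:

- every source can be exported as delimited tables (patients, diagnoses,
  procedures, prescriptions, labs, encounters) with a stable per-row record
  identifier;
- the meaning of an event is carried by its entity label plus a harmonized
  descriptor (e.g. inpatient/outpatient); interpretation that depends on
  care-system context (e.g. whether a CKD hospitalization code implies
  severity) is deliberately deferred to analysis time — the CDM stores the
  standardized event and descriptor without resolving such semantics;
- data governance may forbid pooling a source; the engine therefore builds
  per-source partitions and cohorts first and treats all combined artifacts
  as derived, rebuildable views.

The CDM registry holds seven core entity tables — diagnosis, procedure,
prescription, laboratory, encounter, observation, outcome — plus
demographics. This table set is a reconstruction: it spans every entity class
the design requires (including encounters and coded outcomes) while keeping
the registry additive, so deployments can register further tables (e.g.
cost) without touching code.

## Entity-level code standardization

Lookup is keyed on (coding_system, normalized code, entity type of the source
record stream). Normalization trims whitespace, upper-cases, and matches ICD
codes both with and without the dot (`E11.34` ≡ `E1134`), since source
dialects differ. No hierarchical prefix expansion is applied: the reference
table is a curated explicit list, and implicit descendants would silently
widen definitions. Keying by entity type also resolves codes that are valid
in more than one context (a dialysis CPT code used as both procedure and
outcome) — each record stream only sees entries of its own type. Misses
return an `UNMAPPED` sentinel and are counted, never dropped; by default they
are routed to the exclusion ledger (reason `unmapped_code`), reversibly, with
`keep_unmapped` available to load them into the observation table instead.

## Laboratory harmonization

Each analyte's specification — standard unit, inclusive plausibility bounds
in that unit, and acceptable units with conversion factor/offset and spelling
synonyms — ships as data (CSV), not code, so deployments extend the reference
tables rather than the engine. Defaults:

| analyte | standard unit | plausible range | acceptable units |
|---|---|---|---|
| creatinine | mg/dL | 0.2–20 | mg/dL, μmol/L (1/88.42), mmol/L, mol/L, mg/L, g/L |
| hemoglobin | g/dL | 3–22 | g/dL, g/L, mmol/L |
| potassium | mmol/L | 1.5–10 | mmol/L, mEq/L, mg/dL |
| bmi | kg/m² | 10–70 | kg/m² |

The observed unit string `mmol` is treated as a synonym of mmol/L; `microU/L`
is not a chemically meaningful creatinine concentration and is deliberately
not acceptable — such records are excluded as unverifiable rather than
guessed at. Plausibility bounds are inclusive on both ends so that values at
a printed bound (hemoglobin exactly 3 or 22 g/dL) survive.

**Unit inference.** Unknown units are decided per batch — one decision per
(analyte, source, raw-unit string) — because a missing unit is a property of
a source's export, not of an individual record. Each candidate acceptable
unit's plausible window is mapped to the raw scale and scored by the fraction
of batch values it covers. The winner must reach coverage ≥ 0.95 and beat the
runner-up by ≥ 0.10, with a minimum batch of 50 records; otherwise no unit is
assigned and the batch is excluded as unverifiable. The thresholds make the
canonical hemoglobin example decidable (3–22 → g/dL, 30–220 → g/L) while
forcing a refusal when a batch straddles two candidate windows (e.g.
hemoglobin values 4–13, plausible under both g/dL and mmol/L). Records
standardized via an inferred unit carry the distinct disposition
`standardized_inferred_unit`, an auditability extension, so analysts can
always stratify on it.

Every output row preserves the raw value and unit alongside the standardized
pair, and conservation is exact: standardized + excluded = input, per analyte
and per source.

## eGFR

CKD-EPI "without race" is the 2009 creatinine equation with the race
multiplier omitted (set to 1). The 2021 race-free refit (142 / −1.200 /
0.9938 / 1.012, sex-specific α −0.241/−0.302) ships in the same coefficients
file under `CKD_EPI_2021` and is selectable per run; results always carry the
equation used. Sources are routed by country — `JP` → Matsuo, otherwise the
configured default — overridable via `egfr.equation_by_country`. Age at
measurement is measurement year minus birth year, because anonymized sources
rarely carry exact birth dates; equations apply for ages 18–120 and positive
creatinine, with out-of-domain records skipped to a ledger. Both equations
are strictly decreasing in creatinine and the package provides the exact
closed-form inverse, which the generator uses to plant eGFR levels.

## Cohort criteria — operational choices

The inclusion thresholds are protocol values (eGFR < 75 mL/min/1.73 m²,
gap > 90 and ≤ 730 days, window start 2008-01-01, RRT > 30 days). Where the
protocol wording leaves operational freedom, the engine fixes and documents
one convention:

- **Window.** *Both* qualifying eGFR measures must fall on/after 2008-01-01
  (window read as a data-window start; a pair straddling the start does not
  qualify).
- **Gap.** Strictly > 90 days, inclusively ≤ 730; gaps are calendar-day
  differences.
- **Pair choice.** Among qualifying pairs, the earliest by second-measure
  date (ties by first measure); the qualifying date is the second measure's
  date. Intermediate values ≥ 75 between the pair do not disqualify it.
- **Chronic RRT.** Assessed per modality; events are grouped into episodes
  split at gaps > 90 days, and an episode qualifies if its span exceeds
  30 days (strictly). A single event carrying an explicitly-chronic entity
  label qualifies on its own. The episode logic is a reconstruction — claims
  and EHR sources record dialysis very differently — and both the break
  window and the label sets are configurable.
- **Index date** = earliest qualifying date across criteria; patients meeting
  several criteria appear once with the full criterion set.

## ETL, idempotence, federation

Mapping documents reference transforms from a closed catalog by id; columns
are never transformed by ad-hoc code. Row-level failures (unparseable date,
unmapped code, implausible lab) are quarantined to the per-source exclusion
ledger; only structural errors (missing file, schema violation, duplicate
(data_source_name, record_id)) abort a source, and never the other sources.
Storage is flat CSV partitions per source behind one store interface —
desk-scale, no database service required — with combined views always
recomputed from partitions. Loads replace a source's partition wholesale,
which also sidesteps record-id collision questions on refresh. Rows are
sorted on stable keys before writing and the audit clock is injected from
configuration, so two builds over identical inputs are byte-identical, and
refresh/removal of one source provably leaves every other partition
bit-identical. Events dated outside the configured study window are loaded
and surfaced through run-report warnings rather than excluded.

## The synthetic study

The generator emulates the heterogeneity the engine must resolve, not
disease realism. Default conditions (4 sources, 3 countries): `us_claims`
(ICD-10, creatinine mg/dL), `uk_ehr` (Read codes, μmol/L, day/month/year
dates, 30% of hemoglobin rows unit-less with hidden true unit g/L),
`jp_registry` (ICD-10, Matsuo routing, local procedure/lab codes), and
`lc_panel` (ICD-9, creatinine mg/L, non-poolable). Patient mix per source:
15% diagnosis-qualified, 20% eGFR-pair, 10% chronic RRT, 2% all three,
remainder controls; 55% female; comorbidity prevalences 30% type 2 diabetes,
50% hypertension, 15% heart failure; BMI uniform 18–40 kg/m²; invalid lab
values injected at 0.5% and junk unit strings at 0.2% of lab rows — keeping
total laboratory exclusions under 1%. Controls include deliberately *failing*
eGFR pairs (sub-threshold values with gap ≤ 90 days, or entirely pre-window)
so that a mutation of the gap or window rule flips known patients.

Creatinine is obtained by exactly inverting the equation the pipeline will
apply, at chosen target eGFR levels, then nudged at ulp scale until the full
round trip (unit conversion, CSV serialization, eGFR) lands on the intended
side of the threshold — so criterion truth is exact by construction even for
patients planted at eGFR 74.9/75.0. Ten boundary patients per source cover
every criterion edge. Unknown-unit injection targets hemoglobin, so cohort
truth never depends on unit inference succeeding; if the unit-less block
stays below the inference minimum batch, the recorded truth expects
unverifiable-unit exclusion instead. Everything derives from a single seed
via per-source spawned generators; identical seeds give byte-identical
bundles.

**What passing does and does not show.** Exact ground-truth recovery shows
the engine applies the stated rules precisely on data whose every row has a
known answer — it does not validate the rules clinically, nor does the
generator reproduce real disease trajectories, visit patterns, missingness
mechanisms, or code-usage noise. The shipped code lists are demonstration
subsets (tens of codes), not clinically complete lists.

## Numerical choices

- Floats travel through an exact path: correctly-rounded `strtod` parsing,
  shortest-round-trip CSV serialization, and `float_precision="round_trip"`
  on re-read, so raw values are preserved exactly and boundary eGFR values
  stay on their intended side of 75.
- Unit round-trips (standard → acceptable → standard) are exact to 1e-9
  relative by construction (single multiply/divide per direction).
- CKD-EPI is continuous at Scr = κ (both branches equal 1 there); tests
  check agreement to 1e-9 relative.
- Empty cohorts, single-patient strata (SD reported as absent), empty code
  lists, and zero-row tables all round-trip without error.

## Problem sizes

Tests run the full pipeline at 300–400 patients; the acceptance script and
end-to-end acceptance tests use 5,000 patients across the 4 default sources
(~16,000 laboratory rows), which completes in well under a minute on one
CPU — the generator's default study size, chosen to make the QC
parameter-recovery checks (3-standard-error bands) meaningfully tight.

## Known limitations

- No full UCUM unit grammar; units resolve by synonym lists, and affine
  conversions are limited to the factor+offset form.
- Prescription dose standardization is out of scope.
- No incremental (delta) loads within a source; refresh is whole-partition.
- The eGFR-pair scan is quadratic in the number of sub-threshold measures
  per patient — fine for clinical series, not tuned for thousands of
  measures on one patient.
- Country-contextual event semantics are stored, not resolved.
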