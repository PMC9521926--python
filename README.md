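# renalcdm

A flexible common-data-model (CDM) harmonization engine for multi-source
chronic kidney disease (CKD) real-world data.

Observational CKD research draws on claims and EHR databases that disagree on
everything operational: coding vocabularies (ICD-9-CM, ICD-10, UK Read,
source-local codes), laboratory units (creatinine alone appears as μmol/L,
mmol/L, mol/L, mg/dL, mg/L, g/L — or with no unit at all), column names, date
formats, and governance rules about which sources may be pooled. `renalcdm`
standardizes such sources into a discrete, analysis-ready data model built
from three exchangeable components, executed by a federated, idempotent ETL:

1. **Reference code lists** — every coded medical event is standardized *at
   the entity level*: a (coding_system, code) pair maps to a curated clinical
   entity label, never code-to-code between vocabularies. ICD-10 `E11.34` and
   Read `C100112` both become the entity `type 2 diabetes`.
2. **Laboratory unit harmonization** — per record: map the raw unit string to
   an *acceptable unit* (synonym/case-insensitive), convert to the analyte's
   *standard unit* (`std = raw × factor + offset`), and filter against a
   clinically plausible range. Source batches with unknown units are assigned
   the closest logical unit from the frequency distribution of their values
   (hemoglobin ranging 3–22 → g/dL; 30–220 → g/L). Both raw and standardized
   value/unit are kept on every row, and every exclusion lands in an
   auditable ledger: standardized + excluded = input, exactly.
3. **Base-cohort definition** — a patient enters the CKD base cohort by any
   of: (1) a diagnosis code for CKD stage 3A through kidney failure; (2) two
   eGFR measures < 75 mL/min/1.73 m² recorded > 90 days apart (max 730 days)
   from 2008-01-01; (3) chronic (> 30 days) renal replacement therapy. eGFR
   is computed from serum creatinine with the CKD-EPI equation without race,

       eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age · 1.018 [female],
       κ = 0.7 (F) / 0.9 (M),  α = −0.329 (F) / −0.411 (M),

   and, for Japanese sources, the Matsuo equation
   `eGFR = 194 · Scr^−1.094 · age^−0.287 · 0.739 [female]`.

The CDM holds standardized entities in seven core tables (diagnosis,
procedure, prescription, laboratory, encounter, observation, outcome) plus
demographics; every row carries trace columns (`record_id`, `encounter_id`,
`data_source_name`) that join back to exactly one raw source row, and audit
columns (`loaded_by`, `loaded_at`) injected from the run configuration so
reruns are byte-identical. Cohorts are built per source and combined
federatedly: refreshing or removing one source never touches another's files,
and non-poolable sources are reported side-by-side, never pooled.

A bundled synthetic-source generator (`renalcdm.simulate`) emits raw bundles
with exactly this heterogeneity — four sources, three countries, distinct
vocabularies/units/date formats, a unit-less hemoglobin block, injected
implausible values — plus complete ground truth, including patients planted
precisely on every criterion boundary (gaps of 90/91/730/731 days, eGFR
74.9/75.0, RRT spans of 30/31 days, dates straddling 2008-01-01).

## Worked example

```python
import renalcdm as r

print(r.egfr_ckdepi_no_race(0.9, 60, "male"))   # 92.50687759754797
print(r.egfr_matsuo(0.9, 60, "male"))           # 67.22503170871691
```

At creatinine = κ both CKD-EPI ratio terms are 1, so the male value is
exactly 141 × 0.993⁶⁰ ≈ 92.5 mL/min/1.73 m²; the same creatinine maps to a
much lower eGFR (67.2) under the Japanese equation.

End to end (`python examples/build_cohort_end_to_end.py`):

```
data_source_name        table  input  output  excluded
       us_claims demographics    300     300         0
       us_claims    diagnosis    357     357         0
       us_claims   laboratory    950     943         7
       ...
combined poolable cohort: 379 patients; non-poolable sources reported side-by-side: ['lc_panel']
ground-truth discrepancies: 0
```

Every table conserves rows (input = output + excluded); coded events load
without data loss — the only exclusions are laboratory rows with implausible
values or unverifiable units (< 1% of laboratory data) — and cohort
membership, per-criterion attribution and index dates match the generator's
ground truth exactly.

The `examples/` directory has one short script per capability
(code standardization, lab harmonization, eGFR, full build). A thin CLI
wraps the same library calls:

```bash
cdm simulate --config run.yaml --seed 42 --out raw/   # synthetic bundles
cdm build    --config run.yaml                        # full federated build
cdm refresh  --source uk_ehr --config run.yaml        # one source only
cdm remove   --source dopps  --config run.yaml
cdm validate --config run.yaml                        # code lists + mappings
cdm report   --config run.yaml                        # face-validity tables
```

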