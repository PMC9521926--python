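"""Full federated build on a synthetic multi-source study.

Generates four heterogeneous raw sources (US ICD-10 claims, UK Read-code
EHR with day/month/year dates and a unit-less hemoglobin block, a Japanese
registry routed to the Matsuo equation, and a non-poolable ICD-9 panel),
runs extract -> transform -> load per source, derives the base cohort from
the three inclusion criteria, and checks everything against ground truth.
"""

import tempfile
from pathlib import Path

import renalcdm as r

work = Path(tempfile.mkdtemp(prefix="renalcdm_demo_"))
gen = r.GeneratorConfig(seed=42, sources=r.default_sources(1000))
r.generate(gen, work / "raw")
cfg = r.make_run_config(gen, work / "raw", work / "cdm")

reports, failures = r.build_all(cfg)
assert not failures
for rep in reports:
    print(rep.to_frame().to_string(index=False), "\n")

store = r.TableStore(cfg, r.register_tables(cfg))
combined, non_poolable = r.combine_cohorts(store, cfg)
print(f"combined poolable cohort: {len(combined)} patients; "
      f"non-poolable sources reported side-by-side: {non_poolable}")

disc = r.ground_truth_check(store, cfg, work / "raw")
print(f"ground-truth discrepancies: {len(disc)}")

print((store.root / "reports" / "face_validity.txt").read_text()[:1200])

# Expected: per-table conservation (input = output + excluded) in every
# report; the only exclusions are laboratory rows (implausible values,
# unverifiable units) — coded events load without data loss; the cohort and
# per-criterion attribution match the generator's ground truth exactly
# (0 discrepancies); the face-validity report shows per-source record counts
# and baseline covariates with the non-poolable source kept out of 'overall'.
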