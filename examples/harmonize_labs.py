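"""Two-step laboratory unit harmonization with unit inference.

Step 1 maps raw unit strings to acceptable units (synonym- and
case-insensitive); step 2 converts to the analyte's standard unit and
applies the clinical plausibility filter. Batches with unknown units are
assigned the closest logical unit from the distribution of their values.
"""

import importlib.resources

import numpy as np
import pandas as pd

from renalcdm import (convert_to_standard, harmonize_lab_stream, infer_unit,
                      load_analyte_specs, map_to_acceptable_unit)

base = importlib.resources.files("renalcdm.data")
analytes = load_analyte_specs(str(base / "analytes.csv"),
                              str(base / "acceptable_units.csv"))

print("unit mapping:", map_to_acceptable_unit("UMOL/L", "creatinine", analytes))
value, unit = convert_to_standard(79.58, "umol/L", "creatinine", analytes)
print(f"creatinine 79.58 umol/L -> {value:.2f} {unit}")

rng = np.random.default_rng(0)
batch = rng.uniform(3, 22, size=200)  # hemoglobin values without a unit
print("batch 3-22 with unknown unit ->", infer_unit(batch, "hemoglobin", analytes))
print("same batch x10              ->", infer_unit(batch * 10, "hemoglobin", analytes))

stream = pd.DataFrame({
    "patient_id": ["P1", "P2", "P3"],
    "analyte": ["creatinine"] * 3,
    "raw_value": [0.9, 140.0, 25.0],
    "raw_unit": ["mg/dL", "umol/L", "mg/dL"],
    "data_source_name": ["demo"] * 3,
    "record_id": ["R1", "R2", "R3"],
})
table, ledger = harmonize_lab_stream(stream, analytes)
print(table[["record_id", "raw_value", "raw_unit", "std_value", "std_unit",
             "disposition"]].to_string(index=False))
print(f"excluded rows in ledger: {len(ledger)}")

# Expected: 79.58 umol/L converts to 0.90 mg/dL (factor 1/88.42); the
# unit-less hemoglobin batches infer g/dL and g/L respectively; in the
# stream, the 25.0 mg/dL creatinine is excluded as implausible (> 20 mg/dL
# upper bound) and lands in the ledger — standardized + excluded = input.
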