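"""Entity-level standardization of coded events.

Events are never mapped code-to-code between vocabularies; each
(coding_system, code) resolves to a curated clinical entity label, so the
same clinical concept lands on the same label no matter which vocabulary a
source uses.
"""

import importlib.resources

from renalcdm import load_code_lists, validate_code_lists

codes = load_code_lists(
    str(importlib.resources.files("renalcdm.data") / "code_lists.csv")
)
print(f"reference code lists table: {len(codes)} rows")
print(f"validation findings: {len(validate_code_lists(codes))}")

for code, system in [("E11.34", "ICD10"), ("C100112", "READ"),
                     ("E1134", "ICD10"), ("Z99.99", "ICD10")]:
    ev = codes.standardize_event(code, system, "diagnosis")
    print(f"{system:6s} {code:9s} -> {ev.entity_label}")

# Expected: the ICD-10 and Read codes (dot or no dot) all standardize to the
# entity 'type 2 diabetes'; the unknown code yields the UNMAPPED sentinel,
# which downstream ETL counts and ledgers rather than silently dropping.
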