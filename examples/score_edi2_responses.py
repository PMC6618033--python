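"""Score raw six-category questionnaire responses into subscale totals.

Builds a three-case response sheet for two tiny subscales, applies the
standard category values (always/usually/often -> 3, sometimes -> 2,
occasionally -> 1, never -> 0) and prints the per-case totals.
"""

import pandas as pd

from taxometrics import ResponseSheet, score_edi2

item_map = {
    "item1": "bulimia", "item2": "bulimia", "item3": "bulimia",
    "item4": "drive_for_thinness", "item5": "drive_for_thinness",
}
responses = pd.DataFrame({
    "item1": ["always", "never", "sometimes"],
    "item2": ["sometimes", "never", "usually"],
    "item3": ["occasionally", "never", "often"],
    "item4": ["never", "usually", "never"],
    "item5": ["never", "always", "occasionally"],
})
sheet = ResponseSheet(["case-01", "case-02", "case-03"], responses, item_map)
matrix = score_edi2(sheet)

print(matrix.to_dataframe().to_string(index=False))
print()
print("Each total is the sum of its items' category values; e.g. case-01's")
print("bulimia total 6 = always(3) + sometimes(2) + occasionally(1).")
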