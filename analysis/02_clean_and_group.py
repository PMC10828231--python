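"""Clean the raw survey and assign analysis groups.

Applies the exclusion rules (exact duplicates, bad ages, under-10-month
puppies), validates owner-reported sizes (purebreds against breed standards
with a +/-5 cm / +/-1 kg tolerance, mixed breeds against the 40-bin purebred
height-range table), and assigns the four groupings: six weight-based size
classes, lifespan tertiles (cuts 11.4 / 12.3 years), cephalic-index tertiles
(cuts 51 / 59), and purebred status.

Reads scratch/raw_survey.csv; writes scratch/clean_survey.csv,
results/cleaning_log.json, and results/group_sizes.csv.
"""

import json
from pathlib import Path

import pandas as pd

from dogaging import breeds as breed_meta
from dogaging.cleaning import clean_survey

raw = pd.read_csv("scratch/raw_survey.csv")
clean, log = clean_survey(
    raw,
    breed_meta.breed_standards(),
    breed_meta.breed_lifespans(),
    breed_meta.breed_cephalic_indices(),
)

Path("results").mkdir(exist_ok=True)
clean.to_csv("scratch/clean_survey.csv", index=False)
Path("results/cleaning_log.json").write_text(json.dumps(log.to_dict(), indent=2))

sizes = []
for col in ("size_group", "lifespan_group", "headshape_group", "purebred_status"):
    vc = clean[col].value_counts(dropna=True)
    for label, n in vc.items():
        sizes.append({"grouping": col, "group": label, "n": int(n)})
pd.DataFrame(sizes).to_csv("results/group_sizes.csv", index=False)

print(f"{log.n_input} rows in; removed {log.n_duplicates} duplicates, "
      f"{log.n_bad_age} bad ages, {log.n_underage} under-age; "
      f"{log.n_retained} retained")
print(f"purebred sizes imputed: {log.n_height_imputed} heights, "
      f"{log.n_weight_imputed} weights; mixed-size unreliable: "
      f"{log.n_mixed_size_unreliable}")
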