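"""Synthetic breed-metadata tables: standards, mean lifespans, cephalic indices.

The real analysis joins owner-reported breeds against breed standards (FCI/AKC
height and weight ranges per sex), breed mean-lifespan estimates from kennel
club mortality data, and breed-average cephalic index (skull width/length x
100).  Those tables are not redistributable, so this module carries a small
synthetic panel of 18 breeds with realistic values spanning all six size
groups, all three lifespan tertiles (cut at 11.4 and 12.3 years), and all
three head-shape tertiles (cut at cephalic index 51 and 59).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["breed_standards", "breed_lifespans", "breed_cephalic_indices", "BREED_PANEL"]

# name, weight range (kg), height range (cm), mean lifespan (y), cephalic index
# Ranges are across both sexes; per-sex subranges are derived below (females
# occupy the lower 60%, males the upper 60% of each range).
BREED_PANEL = [
    ("chihuahua",            (1.5, 3.0),   (15, 23), 13.8, 65),
    ("shih tzu",             (4.0, 7.5),   (20, 28), 12.9, 78),
    ("toy poodle",           (2.0, 4.5),   (24, 28), 14.6, 55),
    ("papillon",             (2.5, 5.0),   (20, 28), 13.9, 52),
    ("pug",                  (6.3, 8.1),   (25, 30), 10.1, 85),
    ("miniature schnauzer",  (6.5, 9.0),   (30, 36), 12.2, 58),
    ("shetland sheepdog",    (6.4, 9.5),   (33, 41), 12.8, 49),
    ("beagle",               (9.0, 14.0),  (33, 40), 11.9, 56),
    ("cocker spaniel",       (12.0, 15.0), (36, 41), 12.0, 57),
    ("whippet",              (10.0, 14.0), (44, 51), 12.5, 44),
    ("border collie",        (14.0, 20.0), (46, 56), 13.1, 48),
    ("vizsla",               (18.0, 27.0), (53, 64), 12.1, 47),
    ("australian shepherd",  (16.0, 25.0), (46, 58), 12.4, 51),
    ("labrador retriever",   (25.0, 36.0), (54, 62), 11.6, 53),
    ("boxer",                (25.0, 32.0), (53, 63),  9.5, 63),
    ("golden retriever",     (25.0, 34.0), (51, 61), 11.3, 54),
    ("german shepherd",      (22.0, 40.0), (55, 65), 10.3, 46),
    ("doberman",             (27.0, 45.0), (61, 72),  9.8, 40),
    ("rottweiler",           (35.0, 50.0), (56, 68),  9.1, 57),
    ("bernese mountain dog", (36.0, 48.0), (58, 70),  8.1, 55),
    ("great dane",           (45.0, 79.0), (71, 86),  6.8, 52),
]


def _sex_range(lo: float, hi: float, sex: str) -> tuple[float, float]:
    span = hi - lo
    if sex == "female":
        return (round(lo, 1), round(lo + 0.6 * span, 1))
    return (round(lo + 0.4 * span, 1), round(hi, 1))


def breed_standards() -> pd.DataFrame:
    """Breed-standard height/weight ranges and means per sex, one row per breed."""
    rows = []
    for name, (wlo, whi), (hlo, hhi), _, _ in BREED_PANEL:
        row: dict[str, object] = {"breed": name}
        for sex in ("female", "male"):
            w = _sex_range(wlo, whi, sex)
            h = _sex_range(hlo, hhi, sex)
            row[f"weight_min_{sex}"] = w[0]
            row[f"weight_max_{sex}"] = w[1]
            row[f"weight_mean_{sex}"] = round((w[0] + w[1]) / 2, 2)
            row[f"height_min_{sex}"] = h[0]
            row[f"height_max_{sex}"] = h[1]
            row[f"height_mean_{sex}"] = round((h[0] + h[1]) / 2, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def breed_lifespans() -> pd.DataFrame:
    """Breed mean-lifespan estimates (years)."""
    return pd.DataFrame(
        [{"breed": n, "mean_lifespan": ls} for n, _, _, ls, _ in BREED_PANEL]
    )


def breed_cephalic_indices() -> pd.DataFrame:
    """Breed-average cephalic index estimates (skull width/length x 100)."""
    return pd.DataFrame(
        [{"breed": n, "cephalic_index": ci} for n, _, _, _, ci in BREED_PANEL]
    )
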