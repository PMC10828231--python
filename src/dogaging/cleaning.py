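"""Survey cleaning: exclusion filters, size validation/imputation, group assignment.

Implements the data-preparation rules of the source analysis:

* exclusions — exact duplicates, missing/implausible ages, under-age puppies;
* purebred size validation against breed standards with a +/-5 cm / +/-1 kg
  tolerance and sex-specific mean imputation;
* mixed-breed size validation against a 40-bin weight -> height-range table
  built from the validated purebreds;
* the four group-assignment schemes: six weight-based size groups, breed
  mean-lifespan tertiles, cephalic-index tertiles, and purebred status.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import SURVEY_COLUMNS

__all__ = [
    "CleaningLog",
    "BreedStandard",
    "HeightRangeTable",
    "apply_exclusions",
    "validate_purebred_size",
    "build_height_range_table",
    "validate_mixed_size",
    "assign_size_group",
    "assign_tertile_group",
    "classify_purebred_status",
    "clean_survey",
    "MIN_AGE_YEARS",
    "MAX_AGE_YEARS",
]

#: Ten months, as owners report ages: two decimals.
MIN_AGE_YEARS = 0.83
#: Conservative upper plausibility bound (well above any verified dog age report
#: in this kind of survey).
MAX_AGE_YEARS = 25.0

HEIGHT_TOLERANCE_CM = 5.0
WEIGHT_TOLERANCE_KG = 1.0

SIZE_GROUPS = ("toy", "miniature", "medium-small", "medium-large", "large", "giant")


@dataclass
class CleaningLog:
    """Row accounting for every exclusion and imputation rule."""

    n_input: int = 0
    n_duplicates: int = 0
    n_bad_age: int = 0
    n_underage: int = 0
    n_retained: int = 0
    n_height_imputed: int = 0
    n_weight_imputed: int = 0
    n_mixed_size_missing: int = 0
    n_mixed_size_unreliable: int = 0
    warnings: list = field(default_factory=list)

    def conserved(self) -> bool:
        return self.n_input == (
            self.n_retained + self.n_duplicates + self.n_bad_age + self.n_underage
        )

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def apply_exclusions(raw: pd.DataFrame) -> tuple[pd.DataFrame, CleaningLog]:
    """Remove duplicates, bad-age rows, and under-age rows, in that order."""
    missing = [c for c in SURVEY_COLUMNS if c not in raw.columns]
    if missing:
        raise KeyError(f"raw survey table lacks required columns: {missing}")

    log = CleaningLog(n_input=len(raw))
    df = raw.copy()

    dup = df.duplicated(subset=list(SURVEY_COLUMNS), keep="first")
    log.n_duplicates = int(dup.sum())
    df = df.loc[~dup]

    age = pd.to_numeric(df["age_years"], errors="coerce")
    bad = age.isna() | (age < 0) | (age > MAX_AGE_YEARS)
    log.n_bad_age = int(bad.sum())
    df = df.loc[~bad]
    age = age.loc[~bad]

    under = age < MIN_AGE_YEARS
    log.n_underage = int(under.sum())
    df = df.loc[~under]

    log.n_retained = len(df)
    return df.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# Purebred size validation


@dataclass(frozen=True)
class BreedStandard:
    """Breed-standard size ranges (cm / kg) per sex, with per-sex means."""

    breed: str
    height_range: dict   # sex -> (min, max)
    weight_range: dict
    height_mean: dict    # sex -> mean
    weight_mean: dict

    def __post_init__(self) -> None:
        for d in (self.height_range, self.weight_range):
            for lo, hi in d.values():
                if lo > hi:
                    raise ValueError(f"{self.breed}: min > max in standard")

    @classmethod
    def from_row(cls, row: pd.Series) -> "BreedStandard":
        return cls(
            breed=row["breed"],
            height_range={s: (row[f"height_min_{s}"], row[f"height_max_{s}"])
                          for s in ("female", "male")},
            weight_range={s: (row[f"weight_min_{s}"], row[f"weight_max_{s}"])
                          for s in ("female", "male")},
            height_mean={s: row[f"height_mean_{s}"] for s in ("female", "male")},
            weight_mean={s: row[f"weight_mean_{s}"] for s in ("female", "male")},
        )

    def accepted_interval(self, dimension: str) -> tuple[float, float]:
        """[female minimum - tol, male maximum + tol] for height or weight."""
        rng, tol = (
            (self.height_range, HEIGHT_TOLERANCE_CM)
            if dimension == "height"
            else (self.weight_range, WEIGHT_TOLERANCE_KG)
        )
        lo = min(r[0] for r in rng.values()) - tol
        hi = max(r[1] for r in rng.values()) + tol
        return lo, hi


def validate_purebred_size(
    height: float, weight: float, sex: str, standard: BreedStandard
) -> tuple[float, float, dict]:
    """Keep in-range owner-reported sizes; impute sex-specific means otherwise."""
    flags = {"height": "kept", "weight": "kept"}
    hlo, hhi = standard.accepted_interval("height")
    wlo, whi = standard.accepted_interval("weight")
    sex = sex if sex in ("female", "male") else "female"

    if height is None or not np.isfinite(height) or not (hlo <= height <= hhi):
        flags["height"] = "imputed"
        height = float(standard.height_mean[sex])
    if weight is None or not np.isfinite(weight) or not (wlo <= weight <= whi):
        flags["weight"] = "imputed"
        weight = float(standard.weight_mean[sex])
    return float(height), float(weight), flags


# ---------------------------------------------------------------------------
# Mixed-breed size validation: the 40-bin weight -> height-range table

#: Bin edges: 1-kg bins on [1, 35), 5-kg bins on [35, 60), one bin >= 60.
_BIN_EDGES = [float(k) for k in range(1, 36)] + [40.0, 45.0, 50.0, 55.0, 60.0, np.inf]


@dataclass
class HeightRangeTable:
    """Per-weight-bin purebred height ranges; 40 standard bins + underflow (<1 kg)."""

    table: pd.DataFrame   # columns: lo, hi, min_height, max_height, n, underflow

    @property
    def n_standard_bins(self) -> int:
        return int((~self.table["underflow"]).sum())

    def locate(self, weight: float) -> int | None:
        if weight is None or not np.isfinite(weight) or weight <= 0:
            return None
        for i, row in self.table.iterrows():
            if row["lo"] <= weight < row["hi"]:
                return int(i)
        return None


def build_height_range_table(purebreds: pd.DataFrame) -> HeightRangeTable:
    """Min/max validated purebred height per weight bin (empty bins allowed)."""
    rows = [{"lo": 0.0, "hi": 1.0, "underflow": True}]
    for lo, hi in zip(_BIN_EDGES[:-1], _BIN_EDGES[1:]):
        rows.append({"lo": lo, "hi": hi, "underflow": False})
    tab = pd.DataFrame(rows)
    w = purebreds["weight_kg"].to_numpy(dtype=float)
    h = purebreds["height_cm"].to_numpy(dtype=float)
    mins, maxs, ns = [], [], []
    for _, row in tab.iterrows():
        m = (w >= row["lo"]) & (w < row["hi"]) & np.isfinite(h)
        ns.append(int(m.sum()))
        mins.append(float(h[m].min()) if m.any() else np.nan)
        maxs.append(float(h[m].max()) if m.any() else np.nan)
    tab["min_height"], tab["max_height"], tab["n"] = mins, maxs, ns
    return HeightRangeTable(tab)


def validate_mixed_size(
    height: float, weight: float, table: HeightRangeTable
) -> str:
    """'reliable', 'unreliable', 'missing', or 'indeterminate' (empty bin)."""
    if (height is None or not np.isfinite(height)
            or weight is None or not np.isfinite(weight)):
        return "missing"
    i = table.locate(weight)
    if i is None:
        return "unreliable"
    row = table.table.iloc[i]
    if row["n"] == 0:
        return "indeterminate"
    return "reliable" if row["min_height"] <= height <= row["max_height"] else "unreliable"


# ---------------------------------------------------------------------------
# Group assignment


def assign_size_group(weight: float) -> str:
    """Six weight classes: thresholds 6.5, 9, 15, 30, 40 kg; 40.0 is 'large'."""
    if weight is None or not np.isfinite(weight) or weight <= 0:
        raise ValueError(f"weight must be positive, got {weight!r}")
    if weight < 6.5:
        return "toy"
    if weight < 9:
        return "miniature"
    if weight < 15:
        return "medium-small"
    if weight < 30:
        return "medium-large"
    if weight <= 40:
        return "large"
    return "giant"


def assign_tertile_group(
    values: pd.Series, cutpoints: tuple[float, float] | str = "auto",
    labels: tuple[str, str, str] = ("low", "medium", "high"),
) -> tuple[pd.Series, tuple[float, float]]:
    """Three groups from a per-dog metric; lower cut inclusive to the middle group.

    ``cutpoints="auto"`` computes individual-level tertile cutpoints; explicit
    cutpoints reproduce published groupings (lifespan 11.4/12.3, cephalic
    index 51/59).  Dogs without the metric stay unlabeled (NaN).
    """
    v = pd.to_numeric(values, errors="coerce")
    if isinstance(cutpoints, str):
        if cutpoints != "auto":
            raise ValueError("cutpoints must be a pair or 'auto'")
        finite = v.dropna()
        if finite.nunique() < 3:
            raise ValueError("need at least 3 distinct values for auto tertiles")
        lo, hi = np.quantile(finite, [1 / 3, 2 / 3])
    else:
        lo, hi = cutpoints
    out = pd.Series(pd.NA, index=v.index, dtype="object")
    out[v < lo] = labels[0]
    out[(v >= lo) & (v <= hi)] = labels[1]
    out[v > hi] = labels[2]
    return out, (float(lo), float(hi))


_MIXED_PATTERNS = re.compile(
    r"(mixed|mix\b|crossbreed|cross\b|mongrel|[x×+/,]| x )", re.IGNORECASE
)


def classify_purebred_status(breed_answer: str | None, known_breeds: set[str]) -> str:
    """'purebred' (single recognized breed), 'mixed', or 'unknown'."""
    if breed_answer is None or (isinstance(breed_answer, float) and np.isnan(breed_answer)):
        return "unknown"
    text = str(breed_answer).strip().lower()
    text = re.sub(r"\s+", " ", text)
    if not text:
        return "unknown"
    if text in known_breeds:
        return "purebred"
    if _MIXED_PATTERNS.search(text):
        return "mixed"
    return "unknown"


# ---------------------------------------------------------------------------
# Full cleaning pipeline


def clean_survey(
    raw: pd.DataFrame,
    standards: pd.DataFrame,
    lifespans: pd.DataFrame,
    cephalic: pd.DataFrame,
    lifespan_cutpoints: tuple[float, float] = (11.4, 12.3),
    ci_cutpoints: tuple[float, float] = (51.0, 59.0),
) -> tuple[pd.DataFrame, CleaningLog]:
    """Exclusions + size validation + all four group assignments.

    Returns the cleaned table with added columns: purebred_status,
    size_reliability, final height/weight, size_group, lifespan_group,
    headshape_group.
    """
    df, log = apply_exclusions(raw)

    std_by_breed = {
        str(r["breed"]).strip().lower(): BreedStandard.from_row(r)
        for _, r in standards.iterrows()
    }
    known = set(std_by_breed)

    status = df["breed_answer"].map(lambda a: classify_purebred_status(a, known))
    df = df.assign(purebred_status=status)
    norm_breed = df["breed_answer"].map(
        lambda a: re.sub(r"\s+", " ", str(a).strip().lower()) if pd.notna(a) else ""
    )
    df = df.assign(breed=np.where(df["purebred_status"] == "purebred", norm_breed, ""))

    # purebred size validation / imputation
    height = pd.to_numeric(df["height_cm"], errors="coerce").to_numpy()
    weight = pd.to_numeric(df["weight_kg"], errors="coerce").to_numpy()
    reliability = np.full(len(df), "", dtype=object)
    is_pb = (df["purebred_status"] == "purebred").to_numpy()
    for i in np.flatnonzero(is_pb):
        std = std_by_breed.get(df["breed"].iat[i])
        if std is None:
            reliability[i] = "unresolvable"
            continue
        h, w, flags = validate_purebred_size(
            height[i], weight[i], df["sex"].iat[i], std
        )
        if flags["height"] == "imputed":
            log.n_height_imputed += 1
        if flags["weight"] == "imputed":
            log.n_weight_imputed += 1
        height[i], weight[i] = h, w
        reliability[i] = "reliable"

    # mixed/unknown: validate against purebred height ranges per weight bin
    pb_mask = reliability == "reliable"
    height_table = build_height_range_table(
        pd.DataFrame({"weight_kg": weight[pb_mask], "height_cm": height[pb_mask]})
    )
    for i in np.flatnonzero(~is_pb):
        verdict = validate_mixed_size(height[i], weight[i], height_table)
        reliability[i] = verdict
        if verdict == "missing":
            log.n_mixed_size_missing += 1
        elif verdict == "unreliable":
            log.n_mixed_size_unreliable += 1

    df = df.assign(height_cm=height, weight_kg=weight, size_reliability=reliability)

    size = pd.Series(pd.NA, index=df.index, dtype="object")
    ok = df["size_reliability"] == "reliable"
    size[ok] = df.loc[ok, "weight_kg"].map(assign_size_group)
    df = df.assign(size_group=size)

    ls = df["breed"].map(dict(zip(
        lifespans["breed"].str.lower(), lifespans["mean_lifespan"])))
    ls_group, _ = assign_tertile_group(ls, lifespan_cutpoints, ("short", "medium", "long"))
    ci = df["breed"].map(dict(zip(
        cephalic["breed"].str.lower(), cephalic["cephalic_index"])))
    hs_group, _ = assign_tertile_group(ci, ci_cutpoints, ("dolicho", "meso", "brachy"))
    df = df.assign(
        breed_lifespan=ls, lifespan_group=ls_group,
        cephalic_index=ci, headshape_group=hs_group,
    )
    return df, log
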