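"""CCD-risk classification and age-binned proportion (prevalence) curves.

A dog is flagged "high CCD risk" when at least three of the five symptom
ratings are at least 3 ("happens at least once per month").  Binary outcomes
(CCD risk, owner-perceived old age) are converted to per-age-bin proportions
using one-year bins with a terminal pooled 19+ bin; bins holding fewer than a
minimum number of dogs are suppressed and their dogs excluded from downstream
curve fitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CCD_ITEMS

__all__ = ["ccd_risk_flag", "bin_ages", "proportion_by_age", "PrevalenceCurve"]

RISK_MIN_SYMPTOMS = 3
RISK_MIN_RATING = 3
POOL_AGE = 19


def ccd_risk_flag(ratings: pd.DataFrame) -> pd.Series:
    """True iff >= 3 of the 5 symptom ratings are >= 3; NaN rows excluded (NA)."""
    cols = [c for c in CCD_ITEMS if c in ratings.columns]
    if len(cols) != 5:
        raise KeyError("expected all five CCD symptom columns")
    vals = ratings[cols].apply(pd.to_numeric, errors="coerce")
    if ((vals < 1) | (vals > 5)).any().any():
        raise ValueError("CCD ratings must be within 1-5")
    complete = vals.notna().all(axis=1)
    flag = (vals >= RISK_MIN_RATING).sum(axis=1) >= RISK_MIN_SYMPTOMS
    return flag.where(complete, other=pd.NA)


def bin_ages(ages) -> pd.Series:
    """One-year bins [k, k+1); every age >= 19 pools into '19+'."""
    a = pd.to_numeric(pd.Series(ages), errors="coerce")
    k = np.floor(a).astype("Int64")
    labels = k.astype(str)
    labels[k >= POOL_AGE] = f"{POOL_AGE}+"
    labels[a.isna()] = pd.NA
    return labels


class PrevalenceCurve(pd.DataFrame):
    """Per-bin proportions with suppression flags (plain DataFrame subclass)."""

    @property
    def _constructor(self):
        return PrevalenceCurve

    def fitting_points(self) -> pd.DataFrame:
        """Unsuppressed (midpoint age, proportion) pairs for curve fitting."""
        ok = ~self["suppressed"]
        return pd.DataFrame({
            "age": self.loc[ok, "midpoint"].to_numpy(dtype=float),
            "proportion": self.loc[ok, "proportion"].to_numpy(dtype=float),
        })


def proportion_by_age(flags, ages, min_n: int = 10) -> PrevalenceCurve:
    """Per-age-bin proportion of flagged dogs, suppressing bins with n < min_n.

    The pooled 19+ bin's midpoint is the mean observed age in that bin;
    others use bin centre k + 0.5.
    """
    flags = pd.Series(flags).astype("boolean")
    a = pd.to_numeric(pd.Series(ages), errors="coerce")
    ok = flags.notna() & a.notna()
    flags, a = flags[ok], a[ok]
    labels = bin_ages(a)
    rows = []
    for lab in sorted(labels.dropna().unique(), key=lambda s: float(str(s).rstrip("+"))):
        m = labels == lab
        n = int(m.sum())
        count = int(flags[m].sum())
        suppressed = n < min_n
        if str(lab).endswith("+"):
            mid = float(a[m].mean())
        else:
            mid = float(lab) + 0.5
        rows.append({
            "bin": str(lab), "midpoint": mid, "n": n, "count": count,
            "proportion": (count / n) if not suppressed else np.nan,
            "suppressed": suppressed,
        })
    return PrevalenceCurve(rows)
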