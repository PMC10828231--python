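"""Canonical study-condition runs used by the analysis drivers and acceptance checks.

Each function simulates a population under the default configuration,
pushes it through the relevant pipeline stages, and returns the quantity of
interest (a breakpoint location, a set of group contrasts, ...).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import breeds as breed_meta
from .cleaning import clean_survey
from .config import default_config
from .pipeline import GROUP_COLUMN, analyze_group_trait, trait_scores
from .prevalence import proportion_by_age
from .segmented import fit_segmented
from .simulate import make_raw_survey
from .slopes import fit_slope_model, pairwise_slope_contrasts, split_at_breakpoint

__all__ = [
    "liveliness_breakpoint",
    "old_curve_changepoints",
    "grouped_breakpoints_and_contrasts",
]


def _metadata() -> dict:
    return {
        "standards": breed_meta.breed_standards(),
        "lifespans": breed_meta.breed_lifespans(),
        "cephalic": breed_meta.breed_cephalic_indices(),
    }


def liveliness_breakpoint(seed: int, n_dogs: int = 5000) -> float:
    """Full-sample pipeline to the Liveliness-Trainability factor score and
    its one-breakpoint segmented fit; returns the estimated breakpoint age."""
    meta = _metadata()
    cfg = default_config(n_dogs=n_dogs, seed=seed)
    clean, _ = clean_survey(make_raw_survey(cfg), meta["standards"],
                            meta["lifespans"], meta["cephalic"])
    scored, _, _ = trait_scores(clean)
    sub = scored[["age_years", "liveliness"]].dropna()
    fit = fit_segmented(sub["age_years"], sub["liveliness"], 1)
    return float(fit.psi[0])


def old_curve_changepoints(seed: int, n_dogs: int = 10000) -> tuple[float, float]:
    """Age-binned proportion of owner-perceived 'old' dogs, two-breakpoint
    segmented fit; returns (first, second) change-point ages."""
    cfg = default_config(n_dogs=n_dogs, seed=seed)
    raw = make_raw_survey(cfg)
    old = raw["owner_says_old"].map({"yes": True, "no": False})
    curve = proportion_by_age(old, raw["age_years"])
    pts = curve.fitting_points()
    fit = fit_segmented(pts["age"], pts["proportion"], 2)
    return float(fit.psi[0]), float(fit.psi[1])


def grouped_breakpoints_and_contrasts(
    grouping: str, trait: str, seed: int, n_dogs: int,
) -> dict:
    """Simulate a population with ``grouping`` active, fit per-group
    breakpoints, split at them, and compute after-breakpoint slope contrasts.

    Returns {"fits": {group: (SegmentedFit, confints)},
             "contrasts_after": [PairwiseContrast, ...]}.
    """
    meta = _metadata()
    cfg = default_config(n_dogs=n_dogs, seed=seed, active_grouping=grouping)
    clean, _ = clean_survey(make_raw_survey(cfg), meta["standards"],
                            meta["lifespans"], meta["cephalic"])
    scored, _, _ = trait_scores(clean)
    col = GROUP_COLUMN[grouping]
    fits = analyze_group_trait(scored, trait, col)
    psi = {g: f.psi[0] for g, (f, _) in fits.items()}
    usable = scored[scored[col].isin(psi)]
    _, after = split_at_breakpoint(usable, psi, col)
    res = fit_slope_model(after, trait, col, phase="after")
    contrasts = pairwise_slope_contrasts(res)
    return {"fits": fits, "contrasts_after": contrasts, "model": res}
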