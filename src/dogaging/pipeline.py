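"""End-to-end orchestration: simulate -> clean -> factors -> trajectories ->
prevalence -> slopes, with report tables and a reproducibility manifest."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import breeds as breed_meta
from .cleaning import clean_survey
from .config import BEHAVIOR_ITEMS, CCD_ITEMS, GROUP_LEVELS, SimulationConfig
from .factors import retain_and_prune
from .prevalence import ccd_risk_flag, proportion_by_age
from .segmented import (
    breakpoint_confint,
    compare_breakpoints,
    fit_age_polynomials,
    fit_segmented,
    screen_trait,
    segment_slopes,
)
from .simulate import make_raw_survey
from .slopes import fit_slope_model, pairwise_slope_contrasts, split_at_breakpoint

__all__ = [
    "PipelineRunManifest",
    "run_pipeline",
    "breakpoint_table",
    "overview_table",
    "trait_scores",
]

LIVELINESS_ANCHORS = list(BEHAVIOR_ITEMS[:6])
SOCIABILITY_ANCHORS = [BEHAVIOR_ITEMS[7], BEHAVIOR_ITEMS[8]]

GROUP_COLUMN = {
    "lifespan": "lifespan_group",
    "size": "size_group",
    "headshape": "headshape_group",
    "purebred": "purebred_status",
}


@dataclass
class PipelineRunManifest:
    config: dict
    seed: int
    stage_counts: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def trait_scores(clean: pd.DataFrame) -> tuple[pd.DataFrame, object, object]:
    """EFA-derived trait columns: liveliness & severity factor scores,
    CCD-risk flag, and the owner-old indicator, aligned to ``clean``."""
    behavior = retain_and_prune(clean[list(BEHAVIOR_ITEMS)])
    ccd = retain_and_prune(clean[list(CCD_ITEMS)])
    out = clean.copy()
    out["liveliness"] = behavior.score_for(LIVELINESS_ANCHORS, clean)
    out["sociability"] = behavior.score_for(SOCIABILITY_ANCHORS, clean)
    out["severity"] = ccd.score_for(list(CCD_ITEMS), clean)
    out["ccd_risk"] = ccd_risk_flag(clean[list(CCD_ITEMS)])
    out["is_old"] = clean["owner_says_old"].map({"yes": True, "no": False})
    return out, behavior, ccd


def _fit_trait_breakpoints(age, y, n_breakpoints: int):
    fit = fit_segmented(age, y, n_breakpoints)
    return fit, breakpoint_confint(fit)


def analyze_group_trait(
    scored: pd.DataFrame, trait: str, group_col: str | None,
    n_breakpoints: int = 1, binary: bool = False, min_n: int = 10,
):
    """Per-group (or full-sample) segmented fits for one trait.

    Binary traits are converted to age-binned proportions first.  Returns
    {group: (fit, confints)}.
    """
    results = {}
    frames = (
        [("FULL", scored)] if group_col is None else
        [(g, scored[scored[group_col] == g])
         for g in scored[group_col].dropna().unique()]
    )
    for g, df in frames:
        if binary:
            curve = proportion_by_age(df[trait], df["age_years"], min_n=min_n)
            pts = curve.fitting_points()
            if len(pts) < n_breakpoints + 4:
                continue
            fit, ci = _fit_trait_breakpoints(pts["age"], pts["proportion"], n_breakpoints)
        else:
            sub = df[["age_years", trait]].dropna()
            if len(sub) < 30:
                continue
            fit, ci = _fit_trait_breakpoints(sub["age_years"], sub[trait], n_breakpoints)
        results[g] = (fit, ci)
    return results


def _fmt_cell(fit, cis) -> str:
    parts = []
    for p, (lo, hi) in zip(fit.psi, cis):
        parts.append(f"{p:.2f} ({lo:.2f}–{hi:.2f})")
    return "; ".join(parts)


def breakpoint_table(fits_by_group_trait: dict) -> pd.DataFrame:
    """One row per group, one column per trait, cells 'psi (lo-hi)';
    two-breakpoint cells joined by ';', missing fits empty."""
    rows = {}
    traits = []
    for trait, group_map in fits_by_group_trait.items():
        traits.append(trait)
        for g, payload in group_map.items():
            rows.setdefault(g, {})
            if payload is None:
                rows[g][trait] = ""
            else:
                fit, cis = payload
                rows[g][trait] = _fmt_cell(fit, cis)
    tab = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=traits)
    tab.index.name = "group"
    return tab.fillna("")


def overview_table(relations: dict) -> pd.DataFrame:
    """Rows trait x {breakpoint, slope before, slope after}; cells list the
    significant ordered relations or 'no difference'."""
    rows = []
    for (trait, aspect), rels in relations.items():
        cell = "; ".join(rels) if rels else "no difference"
        rows.append({"trait": trait, "aspect": aspect, "result": cell})
    return pd.DataFrame(rows)


def _breakpoint_relations(results: dict) -> list:
    """Ordered 'A < B' strings for every non-overlapping CI pair (first psi)."""
    rels = []
    groups = list(results)
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            fa, ca = results[a]
            fb, cb = results[b]
            try:
                differ = compare_breakpoints(ca[0], cb[0])
            except ValueError:
                continue
            if differ:
                lo, hi = (a, b) if fa.psi[0] < fb.psi[0] else (b, a)
                rels.append(f"{lo} < {hi}")
    return rels


def _slope_relations(contrasts, alpha: float = 0.05) -> list:
    rels = []
    for c in contrasts:
        if c.p_adjusted < alpha:
            if abs(c.slope_a) < abs(c.slope_b):
                rels.append(f"{c.group_a} < {c.group_b}")
            else:
                rels.append(f"{c.group_b} < {c.group_a}")
    return rels


def run_pipeline(
    config: SimulationConfig | None = None,
    raw: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
    groupings: tuple = ("lifespan", "size", "headshape", "purebred"),
    traits: tuple = ("liveliness", "severity"),
    metadata: dict | None = None,
) -> tuple[dict, PipelineRunManifest]:
    """Execute every stage in order; skip group analyses lacking metadata.

    Either ``config`` (simulate) or ``raw`` (load) must be given.  Returns
    (results, manifest); when ``outdir`` is set, all tables are written there.
    """
    if (config is None) == (raw is None):
        raise ValueError("provide exactly one of config or raw")
    if config is not None:
        raw = make_raw_survey(config)
    assert raw is not None

    meta = metadata or {
        "standards": breed_meta.breed_standards(),
        "lifespans": breed_meta.breed_lifespans(),
        "cephalic": breed_meta.breed_cephalic_indices(),
    }
    manifest = PipelineRunManifest(
        config=config.to_dict() if config is not None else {"input": "external"},
        seed=config.seed if config is not None else -1,
    )
    manifest.stage_counts["raw_rows"] = len(raw)

    clean, log = clean_survey(raw, meta["standards"], meta["lifespans"], meta["cephalic"])
    manifest.stage_counts["cleaning"] = log.to_dict()
    if not log.conserved():
        manifest.warnings.append("cleaning log row counts not conserved")

    scored, behavior_model, ccd_model = trait_scores(clean)
    manifest.stage_counts["scored_rows"] = len(scored)

    # Step 2: polynomial screening
    screening = {}
    for trait in traits:
        sub = scored[["age_years", trait]].dropna()
        rep = fit_age_polynomials(sub["age_years"], sub[trait])
        screening[trait] = {"report": rep, "verdict": screen_trait(rep)}

    # Step 3: per-group breakpoints
    fits: dict = {}
    for trait in traits:
        fits[(trait, "FULL")] = analyze_group_trait(scored, trait, None)
    fits[("old_proportion", "FULL")] = analyze_group_trait(
        scored, "is_old", None, n_breakpoints=2, binary=True
    )
    fits[("ccd_prevalence", "FULL")] = analyze_group_trait(
        scored, "ccd_risk", None, n_breakpoints=1, binary=True
    )
    available = []
    for grouping in groupings:
        col = GROUP_COLUMN[grouping]
        if scored[col].notna().sum() == 0:
            manifest.warnings.append(f"{grouping} metadata absent; analyses skipped")
            continue
        available.append(grouping)
        for trait in traits:
            fits[(trait, grouping)] = analyze_group_trait(scored, trait, col)

    # Step 4: slope comparisons
    slope_results: dict = {}
    relations: dict = {}
    for grouping in available:
        col = GROUP_COLUMN[grouping]
        sub = scored[scored[col].notna()]
        if grouping == "purebred":
            sub = sub[sub[col].isin(GROUP_LEVELS["purebred"])]
        for trait in traits:
            group_fits = fits.get((trait, grouping), {})
            psi_map = {g: f.psi[0] for g, (f, _) in group_fits.items()}
            if len(psi_map) < 2:
                continue
            usable = sub[sub[col].isin(psi_map)]
            before, after = split_at_breakpoint(usable, psi_map, col)
            rels_bp = _breakpoint_relations(group_fits)
            relations[(f"{trait}/{grouping}", "breakpoint")] = rels_bp
            for phase, dataset in (("before", before), ("after", after)):
                res = fit_slope_model(dataset, trait, col, phase=phase)
                contrasts = (
                    pairwise_slope_contrasts(res) if res.interaction_p < 0.05 else []
                )
                slope_results[(trait, grouping, phase)] = (res, contrasts)
                relations[(f"{trait}/{grouping}", f"slope {phase}")] = (
                    _slope_relations(contrasts)
                )

    results = {
        "raw": raw, "clean": scored, "cleaning_log": log,
        "behavior_model": behavior_model, "ccd_model": ccd_model,
        "screening": screening, "fits": fits,
        "slopes": slope_results, "relations": relations,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        def emit(name: str, writer) -> None:
            path = outdir / name
            writer(path)
            manifest.outputs.append(str(path))

        emit("cleaning_log.json",
             lambda p: p.write_text(json.dumps(log.to_dict(), indent=2)))
        emit("behavior_factor_model.json",
             lambda p: p.write_text(json.dumps(behavior_model.to_dict(), indent=2)))
        emit("ccd_factor_model.json",
             lambda p: p.write_text(json.dumps(ccd_model.to_dict(), indent=2)))

        bp_layout: dict = {}
        for (trait, grouping), group_map in fits.items():
            bp_layout.setdefault(trait, {})
            for g, payload in group_map.items():
                label = g if grouping == "FULL" or g != "FULL" else "FULL"
                bp_layout[trait][label] = payload
        emit("breakpoints.csv", lambda p: breakpoint_table(bp_layout).to_csv(p))
        emit("overview.csv",
             lambda p: overview_table(relations).to_csv(p, index=False))
        emit("manifest.json", lambda p: p.write_text(manifest.to_json()))

    return results, manifest
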