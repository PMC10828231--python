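"""Full-sample age trajectories: screening, breakpoint count, and location.

For each trait (the two factor scores plus the two binary prevalences turned
into age-binned proportions) this driver:
  1. fits linear/quadratic/cubic age regressions and drops traits with
     max R^2 < 0.1 (Sociability is expected to fall here);
  2. selects the number of breakpoints by sequential Davies testing with
     Bonferroni correction (the "old dog" proportion is expected to need two);
  3. fits the segmented model and reports breakpoints with 95% CIs and
     per-segment slopes.

Reads scratch/clean_survey.csv; writes results/age_regressions.csv and
results/breakpoints_full.csv.
"""

from pathlib import Path

import pandas as pd

from dogaging.pipeline import _fmt_cell, trait_scores
from dogaging.prevalence import proportion_by_age
from dogaging.segmented import (
    breakpoint_confint,
    fit_age_polynomials,
    fit_segmented,
    screen_trait,
    segment_slopes,
    select_breakpoints,
)

clean = pd.read_csv("scratch/clean_survey.csv")
scored, _, _ = trait_scores(clean)

targets = {}
for trait in ("liveliness", "sociability", "severity"):
    sub = scored[["age_years", trait]].dropna()
    targets[trait] = (sub["age_years"].to_numpy(), sub[trait].to_numpy())

for name, col in (("ccd_prevalence", "ccd_risk"), ("old_proportion", "is_old")):
    curve = proportion_by_age(scored[col], scored["age_years"])
    pts = curve.fitting_points()
    targets[name] = (pts["age"].to_numpy(), pts["proportion"].to_numpy())

Path("results").mkdir(exist_ok=True)
reg_rows, bp_rows = [], []
for name, (age, y) in targets.items():
    rep = fit_age_polynomials(age, y)
    verdict = screen_trait(rep)
    for d, label in ((1, "linear"), (2, "quadratic"), (3, "cubic")):
        reg_rows.append({
            "trait": name, "model": label, "r2": round(rep.r2[d], 3),
            "F": round(rep.fstat[d], 1), "p": rep.pvalues[d],
        })
    if verdict == "drop":
        print(f"{name}: max R^2 {rep.max_r2:.3f} < 0.1 -> not analyzed further")
        continue
    sel = select_breakpoints(age, y)
    nb = max(1, min(sel.n_breakpoints, 2))
    fit = fit_segmented(age, y, nb)
    cis = breakpoint_confint(fit)
    slopes = segment_slopes(fit)
    bp_rows.append({
        "trait": name,
        "selected_breakpoints": sel.n_breakpoints,
        "breakpoints": _fmt_cell(fit, cis),
        "slopes": "; ".join(f"{s:.3f}" for s in fit.slopes),
    })
    print(f"{name}: {sel.n_breakpoints} breakpoint(s) selected; "
          f"location(s) {_fmt_cell(fit, cis)}; "
          f"slopes {[round(s, 3) for s in fit.slopes]}")

pd.DataFrame(reg_rows).to_csv("results/age_regressions.csv", index=False)
pd.DataFrame(bp_rows).to_csv("results/breakpoints_full.csv", index=False)
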