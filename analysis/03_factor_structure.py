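"""Extract the behavioural and CCD factor structures.

Runs the two exploratory factor analyses (principal axis factoring, varimax
rotation, eigenvalue>1 retention, stepwise pruning of items loading <= 0.4):
the nine behaviour items are expected to drop the low-variance
owner-sociability item and form two factors (Liveliness-Trainability and
Sociability); the five CCD symptoms form a single Severity factor.

Reads scratch/clean_survey.csv; writes results/behavior_loadings.csv,
results/ccd_loadings.csv, and results/factor_models.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dogaging.config import BEHAVIOR_ITEMS, CCD_ITEMS
from dogaging.factors import retain_and_prune

clean = pd.read_csv("scratch/clean_survey.csv")

behavior = retain_and_prune(clean[list(BEHAVIOR_ITEMS)])
ccd = retain_and_prune(clean[list(CCD_ITEMS)])

Path("results").mkdir(exist_ok=True)


def loading_table(model):
    cols = [f"factor{j + 1}" for j in range(model.n_factors)]
    tab = pd.DataFrame(np.round(model.loadings, 3), index=model.items, columns=cols)
    tab.loc["Eigenvalue"] = np.round(model.eigenvalues[: model.n_factors], 3)
    tab.loc["Explained variance (%)"] = np.round(model.explained_pct, 3)
    tab.loc["Cronbach's alpha"] = np.round(model.alphas, 3)
    return tab


loading_table(behavior).to_csv("results/behavior_loadings.csv")
loading_table(ccd).to_csv("results/ccd_loadings.csv")
Path("results/factor_models.json").write_text(json.dumps(
    {"behavior": behavior.to_dict(), "ccd": ccd.to_dict()}, indent=2
))

print(f"behaviour battery: dropped {behavior.dropped_items}; "
      f"{behavior.n_factors} factors explain {behavior.cumulative_pct:.2f}% "
      f"(KMO {behavior.kmo_overall:.3f}, alphas "
      f"{[round(a, 3) for a in behavior.alphas]})")
print(f"CCD battery: {ccd.n_factors} factor explains {ccd.cumulative_pct:.2f}% "
      f"(KMO {ccd.kmo_overall:.3f}, alpha {ccd.alphas[0]:.3f})")
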