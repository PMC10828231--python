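"""Synthetic owner-survey generator.

Produces raw survey tables with the statistical structure the downstream
analysis assumes: a truncated-normal age distribution, a two-factor structure
over the nine behaviour items, a one-factor structure over the five CCD
symptom items, piecewise-linear latent age trajectories, a two-change-point
"is your dog old" probability curve, and configurable contamination
(duplicate rows, bad ages, under-age puppies) for exercising the cleaning
stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import breeds as breed_meta
from .config import (
    BEHAVIOR_ITEMS,
    CCD_ITEMS,
    GROUP_LEVELS,
    GROUP_WEIGHTS,
    ITEM_CENTER,
    ITEM_SCALE,
    OWNER_ITEM_SCALE,
    SEX_NEUTER_PROPS,
    OldCurveSpec,
    SimulationConfig,
    TrajectorySpec,
)
from .schema import (
    PROVENANCE_BAD_AGE,
    PROVENANCE_BASE,
    PROVENANCE_DUPLICATE,
    PROVENANCE_UNDERAGE,
    SURVEY_COLUMNS,
)

__all__ = [
    "piecewise_mean",
    "sample_demographics",
    "sample_behavior_items",
    "sample_ccd_symptoms",
    "sample_old_perception",
    "make_raw_survey",
]

_SIZE_INTERVALS = {
    "toy": (1.5, 6.49),
    "miniature": (6.5, 8.99),
    "medium-small": (9.0, 14.99),
    "medium-large": (15.0, 29.99),
    "large": (30.0, 40.0),
    "giant": (40.01, 60.0),
}

_LIFESPAN_CUTS = (11.4, 12.3)
_CI_CUTS = (51.0, 59.0)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Named substream: all randomness flows from config.seed."""
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def piecewise_mean(age, spec: TrajectorySpec):
    """Continuous broken-line mean the breakpoint stage estimates.

    mean(age) = intercept + slope_before*age + sum_k delta_k * max(0, age - psi_k)
    """
    return spec.mean(age)


def round_half_up(x):
    """Deterministic round-half-up (numpy rounds half to even)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def _lifespan_tertile(ls: float) -> str:
    if ls < _LIFESPAN_CUTS[0]:
        return "short"
    if ls <= _LIFESPAN_CUTS[1]:
        return "medium"
    return "long"


def _ci_tertile(ci: float) -> str:
    if ci < _CI_CUTS[0]:
        return "dolicho"
    if ci <= _CI_CUTS[1]:
        return "meso"
    return "brachy"


def _allometric_height(weight: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mixed-breed height from weight: h ~ 12 * w^0.45, log-normal scatter."""
    return 12.0 * weight**0.45 * np.exp(rng.normal(0.0, 0.06, size=len(weight)))


def _breed_lookup():
    panel = breed_meta.BREED_PANEL
    names = [b[0] for b in panel]
    wr = {b[0]: b[1] for b in panel}
    hr = {b[0]: b[2] for b in panel}
    ls = {b[0]: b[3] for b in panel}
    ci = {b[0]: b[4] for b in panel}
    return names, wr, hr, ls, ci


def sample_demographics(config: SimulationConfig) -> pd.DataFrame:
    """Sample ages, sex/neuter status, breed answers, sizes, and group labels.

    The ``sim_group`` column records the group driving each dog's latent
    trajectories: a level of ``config.active_grouping``, or ``"full"`` when no
    grouping is active.
    """
    if config.age_law.min >= config.age_law.max:
        raise ValueError("invalid age law")
    n = config.n_dogs
    rng = _rng(config, 1)
    names, wr, hr, ls_map, ci_map = _breed_lookup()

    cols: dict[str, object] = {}
    cols["age_years"] = config.age_law.sample(n, rng)

    sn_labels = list(SEX_NEUTER_PROPS)
    sn_probs = np.array([SEX_NEUTER_PROPS[k] for k in sn_labels])
    sn = rng.choice(sn_labels, size=n, p=sn_probs / sn_probs.sum()).astype(str)
    cols["sex"] = np.where(np.char.endswith(sn, "_male"), "male", "female")
    cols["neuter_status"] = np.where(
        np.char.startswith(sn, "neutered"), "neutered", "intact"
    )

    grouping = config.active_grouping
    breed = np.empty(n, dtype=object)
    weight = np.empty(n)
    height = np.empty(n)
    sim_group = np.empty(n, dtype=object)

    def draw_purebred(idx: np.ndarray, candidates: list[str],
                      weight_window: tuple[float, float] | None = None) -> None:
        chosen = rng.choice(candidates, size=len(idx))
        for b in set(chosen):
            sub = idx[chosen == b]
            lo, hi = wr[b]
            if weight_window is not None:
                lo, hi = max(lo, weight_window[0]), min(hi, weight_window[1])
            weight[sub] = rng.uniform(lo, hi, size=len(sub))
            hlo, hhi = hr[b]
            height[sub] = rng.uniform(hlo, hhi, size=len(sub))
            breed[sub] = b

    if n == 0:
        pass
    elif grouping is None or grouping == "purebred":
        if grouping == "purebred":
            levels = GROUP_LEVELS["purebred"]
            w = np.array([GROUP_WEIGHTS["purebred"][g] for g in levels], dtype=float)
            status = rng.choice(levels, size=n, p=w / w.sum())
        else:
            status = rng.choice(
                ["purebred", "mixed", "unknown"], size=n, p=[0.592, 0.400, 0.008]
            )
        pb = np.flatnonzero(status == "purebred")
        mx = np.flatnonzero(status != "purebred")
        draw_purebred(pb, names)
        breed[mx] = np.where(status[mx] == "mixed", "mixed-breed", "")
        weight[mx] = np.exp(rng.normal(np.log(15.0), 0.55, size=len(mx)))
        weight[mx] = np.clip(weight[mx], 1.5, 60.0)
        height[mx] = _allometric_height(weight[mx], rng)
        sim_group[:] = status if grouping == "purebred" else "full"
        if grouping == "purebred":
            sim_group[status == "unknown"] = "mixed"
    elif grouping == "size":
        levels = GROUP_LEVELS["size"]
        w = np.array([GROUP_WEIGHTS["size"][g] for g in levels], dtype=float)
        grp = rng.choice(levels, size=n, p=w / w.sum())
        sim_group[:] = grp
        purebred_flag = rng.random(n) < 0.6
        for g in levels:
            lo, hi = _SIZE_INTERVALS[g]
            gi = np.flatnonzero(grp == g)
            pb = gi[purebred_flag[gi]]
            mx = gi[~purebred_flag[gi]]
            candidates = [b for b in names if wr[b][0] < hi and wr[b][1] > lo]
            if candidates:
                draw_purebred(pb, candidates, weight_window=(lo, hi))
            else:  # no breed covers this window; fall back to mixed
                mx = gi
                pb = gi[:0]
            breed[mx] = "mixed-breed"
            weight[mx] = rng.uniform(lo, hi, size=len(mx))
            height[mx] = _allometric_height(weight[mx], rng)
    elif grouping in ("lifespan", "headshape"):
        levels = GROUP_LEVELS[grouping]
        w = np.array([GROUP_WEIGHTS[grouping][g] for g in levels], dtype=float)
        grp = rng.choice(levels, size=n, p=w / w.sum())
        sim_group[:] = grp
        for g in levels:
            gi = np.flatnonzero(grp == g)
            if grouping == "lifespan":
                candidates = [b for b in names if _lifespan_tertile(ls_map[b]) == g]
            else:
                candidates = [b for b in names if _ci_tertile(ci_map[b]) == g]
            draw_purebred(gi, candidates)
    else:  # pragma: no cover - guarded by SimulationConfig validation
        raise ValueError(f"unknown grouping {grouping!r}")

    cols["breed_answer"] = breed
    cols["height_cm"] = np.round(height, 1)
    cols["weight_kg"] = np.round(weight, 1)
    df = pd.DataFrame(cols)
    df["sim_group"] = sim_group
    df.insert(0, "dog_id", np.arange(n))
    return df


def _latent(demographics: pd.DataFrame, config: SimulationConfig, trait: str,
            rng: np.random.Generator, standardize: bool = True) -> np.ndarray:
    """Trajectory-driven latent trait: group mean function + Gaussian noise."""
    age = demographics["age_years"].to_numpy(dtype=float)
    groups = demographics["sim_group"].to_numpy()
    raw = np.empty(len(age))
    for g in pd.unique(groups):
        m = groups == g
        spec = config.trait_spec(trait, None if g == "full" else str(g))
        raw[m] = spec.mean(age[m]) + rng.normal(0.0, spec.noise_sd, size=int(m.sum()))
    if standardize and len(raw) > 1 and raw.std() > 0:
        return (raw - raw.mean()) / raw.std()
    return raw


def sample_behavior_items(
    demographics: pd.DataFrame, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Nine 1-10 behaviour items from two latent factors via the loading matrix.

    item_j = Lambda_j1*F1 + Lambda_j2*F2 + psi_j*eps, affine-mapped to the
    1-10 scale, rounded half-up, clipped.  The owner-sociability item is
    mapped with reduced dispersion so it carries too little variance to load.
    """
    rng = _rng(config, 2) if rng is None else rng
    n = len(demographics)
    L = np.asarray(config.loading_matrix, dtype=float)
    uni = np.asarray(config.unique_sd, dtype=float)
    f1 = _latent(demographics, config, "liveliness", rng)
    f2 = _latent(demographics, config, "sociability", rng)
    F = np.column_stack([f1, f2]) if n else np.empty((0, 2))
    latent_items = F @ L.T + rng.normal(0.0, 1.0, size=(n, 9)) * uni
    scales = np.full(9, ITEM_SCALE)
    scales[BEHAVIOR_ITEMS.index("soc_owner")] = OWNER_ITEM_SCALE
    values = round_half_up(ITEM_CENTER + latent_items * scales)
    values = np.clip(values, 1, 10).astype(int)
    return pd.DataFrame(values, columns=list(BEHAVIOR_ITEMS), index=demographics.index)


def ccd_ratings_from_latent(
    severity_z: np.ndarray, loadings, thresholds, unique_noise: np.ndarray,
) -> np.ndarray:
    """Map a standardized severity latent to 1-5 ordinal ratings via cutpoints."""
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("ccd thresholds must be strictly increasing")
    lam = np.asarray(loadings, dtype=float)
    latent = severity_z[:, None] * lam[None, :] + unique_noise
    return 1 + (latent[:, :, None] > thresholds[None, None, :]).sum(axis=2)


def sample_ccd_symptoms(
    demographics: pd.DataFrame, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Five ordinal CCD symptom ratings from a single latent severity."""
    rng = _rng(config, 3) if rng is None else rng
    n = len(demographics)
    lam = np.asarray(config.ccd_loadings, dtype=float)
    sev = _latent(demographics, config, "severity", rng)
    noise = rng.normal(0.0, 1.0, size=(n, len(lam))) * np.sqrt(1.0 - lam**2)
    ratings = ccd_ratings_from_latent(sev, lam, config.ccd_thresholds, noise)
    return pd.DataFrame(ratings, columns=list(CCD_ITEMS), index=demographics.index)


def sample_old_perception(
    demographics: pd.DataFrame, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Bernoulli 'is your dog old' answers from the group's two-change-point curve."""
    rng = _rng(config, 4) if rng is None else rng
    age = demographics["age_years"].to_numpy(dtype=float)
    groups = demographics["sim_group"].to_numpy()
    p = np.empty(len(age))
    for g in pd.unique(groups):
        m = groups == g
        spec: OldCurveSpec = config.trait_spec("old", None if g == "full" else str(g))
        p[m] = spec.probability(age[m])
    draws = rng.random(len(age)) < p
    return pd.Series(np.where(draws, "yes", "no"), index=demographics.index,
                     name="owner_says_old")


def _assemble(demographics: pd.DataFrame, config: SimulationConfig,
              provenance: str) -> pd.DataFrame:
    items = sample_behavior_items(demographics, config)
    ccd = sample_ccd_symptoms(demographics, config)
    old = sample_old_perception(demographics, config)
    out = pd.concat([demographics, items, ccd, old], axis=1)
    out["sim_provenance"] = provenance
    return out


def make_raw_survey(config: SimulationConfig) -> pd.DataFrame:
    """Assemble the raw survey table, injecting configured contamination.

    The clean population comes first; duplicate copies, bad-age rows, and
    under-age rows follow in a shuffled block, each labelled in
    ``sim_provenance`` so tests can recover them exactly.
    """
    cont = config.contamination
    if cont.n_duplicates > config.n_dogs:
        raise ValueError("more duplicates requested than source rows")

    base = _assemble(sample_demographics(config), config, PROVENANCE_BASE)
    rng = _rng(config, 5)

    extra_frames = []
    if cont.n_duplicates:
        src = rng.choice(config.n_dogs, size=cont.n_duplicates, replace=False)
        dup = base.iloc[np.sort(src)].copy()
        dup["sim_provenance"] = PROVENANCE_DUPLICATE
        extra_frames.append(dup)

    def fresh_rows(count: int, stream: int) -> pd.DataFrame:
        sub = SimulationConfig(
            n_dogs=count, seed=(config.seed * 1000 + stream) % (2**31),
            age_law=config.age_law, active_grouping=config.active_grouping,
            loading_matrix=config.loading_matrix, unique_sd=config.unique_sd,
            ccd_loadings=config.ccd_loadings, ccd_thresholds=config.ccd_thresholds,
        )
        return _assemble(sample_demographics(sub), sub, "fresh")

    if cont.n_bad_age:
        bad = fresh_rows(cont.n_bad_age, 7)
        kinds = rng.choice(["missing", "too_old", "negative"],
                           size=cont.n_bad_age, p=[0.5, 0.3, 0.2])
        age = bad["age_years"].to_numpy(dtype=float)
        age[kinds == "missing"] = np.nan
        age[kinds == "too_old"] = np.round(rng.uniform(25.5, 35.0, (kinds == "too_old").sum()), 2)
        age[kinds == "negative"] = np.round(-rng.uniform(0.5, 5.0, (kinds == "negative").sum()), 2)
        bad["age_years"] = age
        bad["sim_provenance"] = PROVENANCE_BAD_AGE
        extra_frames.append(bad)

    if cont.n_underage:
        und = fresh_rows(cont.n_underage, 8)
        und["age_years"] = np.minimum(
            np.round(rng.uniform(0.10, 0.824, cont.n_underage), 2), 0.82
        )
        und["sim_provenance"] = PROVENANCE_UNDERAGE
        extra_frames.append(und)

    if extra_frames:
        extra = pd.concat(extra_frames, ignore_index=True)
        extra = extra.sample(frac=1.0, random_state=int(rng.integers(2**31))
                             ).reset_index(drop=True)
        out = pd.concat([base, extra], ignore_index=True)
    else:
        out = base.copy()

    out["dog_id"] = np.arange(len(out))
    # restore shared ids for exact duplicates so the copy is field-for-field
    # identical on the survey schema (ids are bookkeeping, not survey fields)

    # guarantee the only exact duplicates are the injected ones
    dup_mask = out.duplicated(subset=list(SURVEY_COLUMNS), keep="first")
    unintended = dup_mask & (out["sim_provenance"] != PROVENANCE_DUPLICATE)
    if unintended.any():
        idx = out.index[unintended]
        out.loc[idx, "weight_kg"] = out.loc[idx, "weight_kg"] + 0.1
    return out
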