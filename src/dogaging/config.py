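"""Simulation configuration: trajectory specs, loading patterns, and population defaults.

The defaults encode the study conditions of the source survey population:
~16.8k dogs aged 0.83-22.06 years (mean 8.67, SD 4.10), a two-factor structure
over nine 1-10 behaviour items, a one-factor structure over five 1-5 cognitive
dysfunction (CCD) symptom items, piecewise-linear latent age trajectories with
a slope change ("breakpoint") near 10.4 years for the behaviour factors, and a
two-change-point owner-perception-of-old-age probability curve (rise starting
near 5.85 y, plateau ~90% after 12.17 y).  Breakpoint locations per dog group
follow the published point estimates; slope magnitudes are free parameters of
the generator, chosen so that the published qualitative group orderings hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TrajectorySpec",
    "OldCurveSpec",
    "ContaminationSpec",
    "SimulationConfig",
    "default_config",
    "BEHAVIOR_ITEMS",
    "CCD_ITEMS",
    "DEFAULT_LOADINGS",
    "CCD_LOADINGS",
    "GROUPINGS",
    "GROUP_LEVELS",
]

# ---------------------------------------------------------------------------
# Item batteries

#: Nine behaviour items, 1-10 scale.  Order matters: the first six load on the
#: Liveliness-Trainability factor, "soc_owner" is the low-variance item that is
#: pruned by the EFA, the last two load on Sociability.
BEHAVIOR_ITEMS = (
    "reactivity",
    "activity",
    "learning",
    "motivation",
    "playfulness",
    "working_performance",
    "soc_owner",
    "soc_strangers",
    "soc_dogs",
)

#: Five CCD symptom items, 1-5 frequency scale.
CCD_ITEMS = (
    "gets_lost",
    "clumsy",
    "frightened_familiar",
    "sleep_changes",
    "elimination",
)

#: Reference rotated two-factor loading pattern for the nine-item battery
#: (columns: Liveliness-Trainability, Sociability).  The soc_owner row is the
#: weak-loading item; the remaining eight rows are the reference pattern the
#: generator reproduces and the EFA recovers.
DEFAULT_LOADINGS = np.array(
    [
        [0.687, 0.004],   # reactivity
        [0.770, 0.153],   # activity
        [0.800, 0.128],   # learning
        [0.751, 0.164],   # motivation
        [0.718, 0.238],   # playfulness
        [0.695, 0.138],   # working_performance
        [0.320, 0.300],   # soc_owner (insufficient loading by design)
        [0.086, 0.597],   # soc_strangers
        [0.137, 0.699],   # soc_dogs
    ]
)

#: Reference one-factor loadings for the five CCD symptom items.
CCD_LOADINGS = np.array([0.672, 0.749, 0.516, 0.610, 0.611])

# ---------------------------------------------------------------------------
# Groupings

GROUPINGS = ("lifespan", "size", "headshape", "purebred")

GROUP_LEVELS: dict[str, tuple[str, ...]] = {
    "lifespan": ("short", "medium", "long"),
    "size": ("toy", "miniature", "medium-small", "medium-large", "large", "giant"),
    "headshape": ("dolicho", "meso", "brachy"),
    "purebred": ("purebred", "mixed"),
}


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class TrajectorySpec:
    """Continuous broken-line mean for a latent trait as a function of age.

    mean(age) = intercept + slope_before * age + sum_k delta_k * max(0, age - psi_k)

    Continuity at each breakpoint is automatic in this parameterisation.
    """

    intercept: float
    slope_before: float
    psi: tuple[float, ...]      # breakpoint ages (years), increasing
    delta: tuple[float, ...]    # slope changes at each breakpoint
    noise_sd: float

    def __post_init__(self) -> None:
        if len(self.psi) != len(self.delta):
            raise ValueError("psi and delta must have equal length")
        if any(b <= a for a, b in zip(self.psi, self.psi[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if any(p < 0 for p in self.psi):
            raise ValueError("breakpoints must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def mean(self, age):
        """Evaluate the piecewise-linear mean at ``age`` (scalar or array)."""
        age = np.asarray(age, dtype=float)
        out = self.intercept + self.slope_before * age
        for p, d in zip(self.psi, self.delta):
            out = out + d * np.maximum(0.0, age - p)
        return out


@dataclass(frozen=True)
class OldCurveSpec:
    """Two-change-point piecewise-linear probability that an owner calls the dog old.

    P(old | age) = clip(level1 + s0*(age-psi1) for age<psi1;
                        rising at slope s1 between psi1 and psi2;
                        near-flat at slope s2 after psi2).
    """

    psi1: float = 5.85
    psi2: float = 12.17
    level_at_psi1: float = 0.20
    slope_before: float = 0.004
    slope_between: float = 0.11076    # reaches ~0.90 at psi2
    slope_after: float = 0.002

    def __post_init__(self) -> None:
        if not self.psi1 < self.psi2:
            raise ValueError("old-curve change points must be increasing")

    def probability(self, age):
        age = np.asarray(age, dtype=float)
        p = self.level_at_psi1 + self.slope_before * (age - self.psi1)
        p = p + (self.slope_between - self.slope_before) * np.maximum(0.0, age - self.psi1)
        p = p + (self.slope_after - self.slope_between) * np.maximum(0.0, age - self.psi2)
        return np.clip(p, 0.0, 1.0)


@dataclass(frozen=True)
class ContaminationSpec:
    """Counts of deliberately broken rows appended to the clean population."""

    n_duplicates: int = 0
    n_bad_age: int = 0
    n_underage: int = 0

    def __post_init__(self) -> None:
        if min(self.n_duplicates, self.n_bad_age, self.n_underage) < 0:
            raise ValueError("contamination counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_duplicates + self.n_bad_age + self.n_underage


def _solve_truncnorm(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Underlying (mu, sigma) so that N(mu, sigma) truncated to [lo, hi]
    has the requested mean and sd."""

    def moments(p):
        mu, sigma = p
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        d = stats.truncnorm(a, b, loc=mu, scale=sigma)
        return d.mean() - mean, d.std() - sd

    sol = optimize.fsolve(moments, x0=[mean, sd], full_output=False)
    mu, sigma = float(sol[0]), float(sol[1])
    if sigma <= 0:
        raise ValueError("could not solve truncated-normal parameters")
    return mu, sigma


@dataclass(frozen=True)
class AgeLaw:
    """Truncated-normal age distribution (years)."""

    min: float = 0.83
    max: float = 22.06
    mean: float = 8.67
    sd: float = 4.10

    def __post_init__(self) -> None:
        if self.min >= self.max:
            raise ValueError("age_law min must be < max")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        mu, sigma = _solve_truncnorm(self.mean, self.sd, self.min, self.max)
        a, b = (self.min - mu) / sigma, (self.max - mu) / sigma
        ages = stats.truncnorm(a, b, loc=mu, scale=sigma).rvs(size=n, random_state=rng)
        # owner-reported ages carry two decimals
        return np.clip(np.round(ages, 2), self.min, self.max)


# ---------------------------------------------------------------------------
# Default group trajectory parameters
#
# psi values per group follow the published point estimates.  Slopes (in latent
# trait units per year) are generator parameters set so the published ordering
# of after-breakpoint steepness holds at the published group sample sizes.

# Full-sample amplitudes are calibrated so the simulated populations
# reproduce the published full-sample age-association strength (linear /
# quadratic R^2 of the factor-score-on-age regressions) and hence the
# published breakpoint confidence-interval widths at the study sample size.
_LIVELINESS_FULL = TrajectorySpec(
    intercept=0.60, slope_before=-0.040, psi=(10.41,), delta=(-0.155,), noise_sd=0.55
)
_SOCIABILITY_FULL = TrajectorySpec(
    intercept=0.0, slope_before=-0.005, psi=(10.41,), delta=(-0.005,), noise_sd=1.0
)
_SEVERITY_FULL = TrajectorySpec(
    intercept=-0.30, slope_before=0.011, psi=(10.47,), delta=(0.225,), noise_sd=0.55
)
_OLD_FULL = OldCurveSpec()


def _traj(psi: float, after: float, before: float, intercept: float, noise: float = 0.55):
    return TrajectorySpec(
        intercept=intercept, slope_before=before, psi=(psi,), delta=(after - before,),
        noise_sd=noise,
    )


def _old(psi1: float, psi2: float) -> OldCurveSpec:
    return OldCurveSpec(
        psi1=psi1, psi2=psi2,
        slope_between=(0.90 - 0.20) / (psi2 - psi1),
    )


#: Per-grouping, per-group trait specs.  Keys: grouping -> group -> trait.
#: Traits: "liveliness", "sociability", "severity" (TrajectorySpec), "old" (OldCurveSpec).
DEFAULT_GROUP_SPECS: dict[str, dict[str, dict[str, object]]] = {
    "lifespan": {
        # liveliness after-slopes: short/medium less steep than long
        # severity after-slopes: short/medium less steep than long
        "short": {
            "liveliness": _traj(9.8, -0.095, -0.030, 0.60),
            "severity": _traj(8.6, 0.120, 0.008, -0.30),
            "old": _old(6.8, 10.6),
        },
        "medium": {
            "liveliness": _traj(9.5, -0.095, -0.030, 0.60),
            "severity": _traj(10.3, 0.120, 0.008, -0.30),
            "old": _old(5.0, 12.6),
        },
        "long": {
            "liveliness": _traj(10.7, -0.160, -0.030, 0.60),
            "severity": _traj(10.4, 0.200, 0.008, -0.30),
            "old": _old(6.1, 13.1),
        },
    },
    "size": {
        # after-slope magnitudes: giant ~ large < the four smaller groups; large < toy
        "toy": {
            "liveliness": _traj(10.7, -0.170, -0.030, 0.60),
            "severity": _traj(10.8, 0.200, 0.008, -0.30),
            "old": _old(5.9, 12.7),
        },
        "miniature": {
            "liveliness": _traj(10.9, -0.160, -0.030, 0.60),
            "severity": _traj(10.0, 0.185, 0.008, -0.30),
            "old": _old(6.2, 13.9),
        },
        "medium-small": {
            "liveliness": _traj(10.5, -0.150, -0.030, 0.60),
            "severity": _traj(10.5, 0.190, 0.008, -0.30),
            "old": _old(6.1, 13.0),
        },
        "medium-large": {
            "liveliness": _traj(9.9, -0.145, -0.030, 0.60),
            "severity": _traj(10.5, 0.175, 0.008, -0.30),
            "old": _old(5.8, 12.1),
        },
        "large": {
            "liveliness": _traj(9.1, -0.105, -0.030, 0.60),
            "severity": _traj(8.4, 0.130, 0.008, -0.30),
            "old": _old(6.2, 11.0),
        },
        "giant": {
            "liveliness": _traj(7.1, -0.085, -0.030, 0.60),
            "severity": _traj(7.1, 0.110, 0.008, -0.30),
            "old": _old(5.8, 10.0),
        },
    },
    "headshape": {
        # severity: dolicho steeper than meso/brachy both before and after
        "dolicho": {
            "liveliness": _traj(8.6, -0.140, -0.020, 0.60),
            "severity": _traj(10.9, 0.220, 0.020, -0.30),
            "old": _old(7.9, 10.8),
        },
        "meso": {
            "liveliness": _traj(10.4, -0.140, -0.030, 0.60),
            "severity": _traj(9.2, 0.130, 0.005, -0.30),
            "old": _old(6.1, 10.8),
        },
        "brachy": {
            "liveliness": _traj(10.7, -0.140, -0.045, 0.60),
            "severity": _traj(9.8, 0.130, 0.020, -0.30),
            "old": _old(4.9, 12.9),
        },
    },
    "purebred": {
        "purebred": {
            "liveliness": _traj(10.4, -0.140, -0.030, 0.60),
            "severity": _traj(10.5, 0.160, 0.014, -0.30),
            "old": _old(5.7, 12.0),
        },
        "mixed": {
            "liveliness": _traj(10.5, -0.140, -0.030, 0.60),
            "severity": _traj(10.6, 0.160, 0.004, -0.30),
            "old": _old(5.9, 12.9),
        },
    },
}

#: Full-sample trait specs (used when no grouping is active).
DEFAULT_FULL_SPECS: dict[str, object] = {
    "liveliness": _LIVELINESS_FULL,
    "sociability": _SOCIABILITY_FULL,
    "severity": _SEVERITY_FULL,
    "old": _OLD_FULL,
}

#: Published group sizes; used as sampling weights when a grouping is active.
GROUP_WEIGHTS: dict[str, dict[str, int]] = {
    "lifespan": {"short": 2589, "medium": 2653, "long": 2542},
    "size": {
        "toy": 2264, "miniature": 1597, "medium-small": 2900,
        "medium-large": 4910, "large": 2438, "giant": 1161,
    },
    "headshape": {"dolicho": 2339, "meso": 2437, "brachy": 2465},
    "purebred": {"purebred": 9949, "mixed": 6727},
}

#: Sex x neuter status proportions (intact male, intact female, neutered male,
#: neutered female).
SEX_NEUTER_PROPS: dict[str, float] = {
    "intact_male": 0.223,
    "intact_female": 0.133,
    "neutered_male": 0.257,
    "neutered_female": 0.388,
}

#: Default ordered cutpoints mapping a standardized per-item CCD latent to the
#: 1-5 frequency scale (most dogs score 1; "at least monthly" is >= 3).
DEFAULT_CCD_THRESHOLDS = (0.60, 1.10, 1.80, 2.50)

#: Unique (residual) standard deviations per behaviour item on the standardized
#: latent scale: sqrt(1 - communality) for the reference pattern.
DEFAULT_UNIQUE_SD = tuple(
    float(np.sqrt(max(0.0, 1.0 - (row @ row)))) for row in DEFAULT_LOADINGS
)

#: Affine map from the standardized latent item value to the 1-10 scale:
#: value = center + scale * latent, then round-half-up and clip to [1, 10].
#: The scale is chosen so the expected item value stays inside the scale over
#: the whole age range (the oldest dogs sit near z = -3 on the liveliness
#: latent); a larger scale saturates at the floor and visibly distorts the
#: post-breakpoint segment of the trajectory.
ITEM_CENTER = 5.5
ITEM_SCALE = 1.4
#: soc_owner is generated with reduced dispersion (~25% of the variance of the
#: other items) so the EFA pruning path is exercised.
OWNER_ITEM_SCALE = 0.9


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one synthetic raw survey table."""

    n_dogs: int = 16818
    seed: int = 0
    age_law: AgeLaw = field(default_factory=AgeLaw)
    active_grouping: str | None = None   # None => full-sample specs for everyone
    loading_matrix: tuple = tuple(map(tuple, DEFAULT_LOADINGS))
    unique_sd: tuple = DEFAULT_UNIQUE_SD
    ccd_loadings: tuple = tuple(CCD_LOADINGS)
    ccd_thresholds: tuple = DEFAULT_CCD_THRESHOLDS
    contamination: ContaminationSpec = field(default_factory=ContaminationSpec)

    def __post_init__(self) -> None:
        if self.n_dogs < 0:
            raise ValueError("n_dogs must be non-negative")
        if self.active_grouping is not None and self.active_grouping not in GROUPINGS:
            raise ValueError(f"unknown grouping {self.active_grouping!r}")
        t = self.ccd_thresholds
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("ccd_thresholds must be strictly increasing")
        if len(t) != 4:
            raise ValueError("ccd_thresholds must have exactly 4 cutpoints")
        L = np.asarray(self.loading_matrix, dtype=float)
        if L.shape != (9, 2):
            raise ValueError("loading_matrix must be 9x2")
        if self.contamination.total > 0 and self.n_dogs == 0:
            raise ValueError("contamination requires a non-empty population")

    def trait_spec(self, trait: str, group: str | None = None):
        """Spec driving ``trait`` for a dog in ``group`` under the active grouping."""
        if self.active_grouping is None or trait == "sociability":
            return DEFAULT_FULL_SPECS[trait]
        if group is None:
            return DEFAULT_FULL_SPECS[trait]
        return DEFAULT_GROUP_SPECS[self.active_grouping][group][trait]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_law"] = asdict(self.age_law)
        d["contamination"] = asdict(self.contamination)
        return d


def default_config(**overrides) -> SimulationConfig:
    """The default study-condition configuration, with keyword overrides."""
    return SimulationConfig(**overrides)
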