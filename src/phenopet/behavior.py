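"""Synthetic behavioural battery: correlated four-test tables for mouse cohorts.

The phenotyping stage assumes a population in which the four behavioural
endpoints — open-field centre time, sucrose preference, water-maze platform
crossings and forced-swim immobility — co-vary through a latent depression
propensity. One scalar latent factor per animal drives all four traits via
signed linear loadings; independent Gaussian noise is added on top, values
are clipped to their physical ranges and crossings are rounded to integers.

Sign convention: animals with a *low* latent value are the at-risk extreme —
little centre exploration, low sucrose preference, few platform crossings and
long immobility — so the immobility loading has the opposite sign to the
other three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Column order of the behavioural table (TSV header).
TRAITS = ("of_center_s", "sucrose_pref", "platform_crossings", "fst_immobile_s")

_DEFAULT_MEANS = {
    "of_center_s": 30.0,      # s in arena centre during the 10-min open field
    "sucrose_pref": 0.65,     # sucrose/(sucrose+water) consumption ratio
    "platform_crossings": 2.0,  # probe-test crossings of the platform site
    "fst_immobile_s": 50.0,   # s immobile during the 6-min forced swim
}
# Residual (noise) SDs, i.e. trait SD conditional on the latent factor.
_DEFAULT_SDS = {
    "of_center_s": 12.0,
    "sucrose_pref": 0.20,
    "platform_crossings": 1.0,
    "fst_immobile_s": 45.0,
}
# Trait change per unit latent factor. Immobility loads negatively: higher
# immobility marks higher risk, opposite the other three endpoints.
_DEFAULT_LOADINGS = {
    "of_center_s": 9.0,
    "sucrose_pref": 0.15,
    "platform_crossings": 0.8,
    "fst_immobile_s": -30.0,
}
# Physical ranges: 10-min open field, a ratio, a count, 6-min forced swim.
_DEFAULT_BOUNDS = {
    "of_center_s": (0.0, 600.0),
    "sucrose_pref": (0.0, 1.0),
    "platform_crossings": (0.0, np.inf),
    "fst_immobile_s": (0.0, 360.0),
}


@dataclass
class BehaviorSimConfig:
    """Parameters of the latent-factor behavioural simulator.

    Defaults emulate the study design: 10 cohorts of 30 adolescent mice,
    with population means/SDs chosen so that the selected 10% extremes land
    near the published group summaries. ``null_mode`` severs the latent
    structure (all loadings act as zero) for calibration runs.
    """

    n_cohorts: int = 10
    cohort_size: int = 30
    latent_sd: float = 1.0
    loadings: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_LOADINGS))
    trait_means: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    trait_sds: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SDS))
    trait_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS))
    seed: int = 0
    null_mode: bool = False

    def validate(self) -> None:
        if self.n_cohorts <= 0 or self.cohort_size <= 0:
            raise ValueError("n_cohorts and cohort_size must be positive")
        if self.latent_sd < 0:
            raise ValueError("latent_sd must be >= 0")
        for t in TRAITS:
            if self.trait_sds[t] <= 0:
                raise ValueError(f"trait SD for {t} must be > 0")
            lo, hi = self.trait_bounds[t]
            if not lo < hi:
                raise ValueError(f"bounds for {t} must be ordered")
        if np.sign(self.loadings["fst_immobile_s"]) == np.sign(
                self.loadings["of_center_s"]) and not self.null_mode \
                and self.loadings["of_center_s"] != 0:
            raise ValueError(
                "fst_immobile_s loading must oppose the other traits "
                "(higher immobility = higher risk)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BehaviorSimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "trait_bounds" in raw:
            raw["trait_bounds"] = {k: tuple(v) for k, v in raw["trait_bounds"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "n_cohorts": self.n_cohorts, "cohort_size": self.cohort_size,
            "latent_sd": self.latent_sd, "loadings": dict(self.loadings),
            "trait_means": dict(self.trait_means), "trait_sds": dict(self.trait_sds),
            "trait_bounds": {k: [float(v[0]), float(v[1])]
                             for k, v in self.trait_bounds.items()},
            "seed": self.seed, "null_mode": self.null_mode,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def generate_cohorts(config: BehaviorSimConfig) -> pd.DataFrame:
    """Simulate the full behavioural battery for all cohorts.

    Returns one row per animal with columns
    ``animal_id, cohort_id, of_center_s, sucrose_pref, platform_crossings,
    fst_immobile_s``. Each trait is ``mean + loading * latent + noise``,
    clipped to its physical range; crossings are additionally rounded to a
    non-negative integer. Bit-reproducible for a given (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cohorts * config.cohort_size

    latent = rng.normal(0.0, config.latent_sd, size=n)
    if config.null_mode:
        latent = np.zeros(n)

    cohorts = np.repeat([f"c{i + 1:02d}" for i in range(config.n_cohorts)],
                        config.cohort_size)
    within = np.tile(np.arange(1, config.cohort_size + 1), config.n_cohorts)
    animal_ids = [f"{c}_m{j:03d}" for c, j in zip(cohorts, within)]

    cols: dict[str, np.ndarray] = {}
    for t in TRAITS:
        raw = (config.trait_means[t]
               + config.loadings[t] * latent
               + rng.normal(0.0, config.trait_sds[t], size=n))
        lo, hi = config.trait_bounds[t]
        raw = np.clip(raw, lo, hi)
        if t == "platform_crossings":
            raw = np.rint(raw)
        cols[t] = raw

    return pd.DataFrame({"animal_id": animal_ids, "cohort_id": cohorts, **cols})


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
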