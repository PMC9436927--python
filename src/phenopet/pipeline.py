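"""End-to-end study replica: simulate -> phenotype -> preprocess -> voxel
statistics -> report, plus the design-stage ANOVA power utility.

A run is fully determined by a RunConfig and a global seed: the seed is
split deterministically into per-stage streams, and the manifest written at
the end records everything needed to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .behavior import BehaviorSimConfig, generate_cohorts, write_table
from .petsim import (PetSimConfig, build_atlas, expected_uptake,
                     simulate_subject_volume, uniform_baseline)
from .phenotype import GROUPS, characterize_groups, phenotype_table
from .preproc import (SmoothingSpec, gaussian_smooth, normalize_uptake,
                      rigid_register, whole_brain_mask)
from .volume import VolumeImage
from .voxelstats import contrast_analysis

log = logging.getLogger("phenopet")

#: The three group comparisons reported for the PET arm.
CONTRASTS = (("HDR", "IDR"), ("LDR", "IDR"), ("HDR", "LDR"))

# Default planted regional effects (multipliers vs the IDR reference level),
# encoding the published direction structure after whole-brain-mean
# normalisation: HDR hypermetabolic vs IDR in prelimbic/infralimbic, motor
# and auditory cortex, ventral striatum and amygdala but hypometabolic in
# thalamus; LDR hypometabolic vs IDR in dorsal striatum and thalamus; HDR
# above LDR additionally (and more mildly vs IDR) in somatosensory cortex,
# hippocampus, PAG, superior colliculus, red nucleus and cerebellum. The
# large "Rest" region (label 14) stays at 1, so focal effects barely move
# the whole-brain mean and survive the ratio normalisation with their signs.
DEFAULT_GROUP_MULTIPLIERS = {
    "HDR": {1: 1.05, 2: 1.05, 4: 1.05, 6: 1.05, 8: 1.05, 7: 0.95,
            3: 1.02, 9: 1.02, 10: 1.02, 11: 1.02, 12: 1.02, 13: 1.02},
    "IDR": {},
    "LDR": {7: 0.91, 5: 0.95,
            3: 0.98, 9: 0.98, 10: 0.98, 11: 0.98, 12: 0.98, 13: 0.98},
}


@dataclass
class StatsConfig:
    alpha: float = 0.05
    min_extent: int = 50
    connectivity: int = 6
    fdr_q: float = 0.05


@dataclass
class RunConfig:
    behavior: BehaviorSimConfig = field(default_factory=BehaviorSimConfig)
    # noise calibrated so the planted ~5% effects land at post-smoothing
    # per-voxel d near 1, the magnitude regime the ROI tables report
    pet: PetSimConfig = field(
        default_factory=lambda: PetSimConfig(noise_sd=12.0))
    smoothing: SmoothingSpec = field(default_factory=SmoothingSpec)
    stats: StatsConfig = field(default_factory=StatsConfig)
    register: bool = False
    selection_fraction: float = 0.10
    imaging_n_per_group: int | None = None  # None: all selected animals
    save_subject_volumes: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "behavior" in raw:
            b = dict(raw["behavior"])
            if "trait_bounds" in b:
                b["trait_bounds"] = {k: tuple(v)
                                     for k, v in b["trait_bounds"].items()}
            kwargs["behavior"] = BehaviorSimConfig(**b)
        if "pet" in raw:
            p = dict(raw["pet"])
            for key in ("baseline_uptake",):
                if key in p:
                    p[key] = {int(k): float(v) for k, v in p[key].items()}
            if "group_multipliers" in p:
                p["group_multipliers"] = {
                    g: {int(k): float(v) for k, v in m.items()}
                    for g, m in p["group_multipliers"].items()}
            kwargs["pet"] = PetSimConfig(**p)
        if "smoothing" in raw:
            kwargs["smoothing"] = SmoothingSpec(
                fwhm_mm=tuple(raw["smoothing"]["fwhm_mm"]))
        if "stats" in raw:
            kwargs["stats"] = StatsConfig(**raw["stats"])
        for key in ("register", "selection_fraction", "imaging_n_per_group",
                    "save_subject_volumes", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministic per-stage integer seeds (< 2**31) from a global seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full replica and write all artifacts under ``out_dir``.

    Layout: out/{phenotype,preproc,stats,report}/ with one stats
    subdirectory per contrast. Returns the manifest dictionary.
    """
    out = Path(out_dir)
    for sub in ("phenotype", "preproc", "stats", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    # --- stage 1: behaviour + phenotyping -------------------------------
    log.info("stage phenotype: simulating %d cohorts x %d mice",
             config.behavior.n_cohorts, config.behavior.cohort_size)
    bconf = config.behavior
    bconf.seed = seeds[0]
    behavior = generate_cohorts(bconf)
    pheno = phenotype_table(behavior, fraction=config.selection_fraction)
    group_stats = characterize_groups(pheno)
    write_table(behavior, out / "phenotype" / "behavior.tsv")
    write_table(pheno, out / "phenotype" / "phenotype.tsv")
    write_table(group_stats, out / "phenotype" / "group_stats.tsv")
    timings["phenotype"] = time.perf_counter() - t0

    # --- stage 2: PET simulation ----------------------------------------
    t1 = time.perf_counter()
    atlas = build_atlas()
    pconf = config.pet
    if not pconf.baseline_uptake:
        pconf.baseline_uptake = uniform_baseline(atlas)
    if not pconf.group_multipliers:
        pconf.group_multipliers = {g: dict(m) for g, m in
                                   DEFAULT_GROUP_MULTIPLIERS.items()}
    pconf.seed = seeds[1]
    selected = pheno[pheno["group"].isin(GROUPS)]
    if config.imaging_n_per_group is not None:
        parts = []
        for g in GROUPS:
            rows = selected[selected["group"] == g]
            if len(rows) < config.imaging_n_per_group:
                raise ValueError(
                    f"imaging_n_per_group={config.imaging_n_per_group} exceeds "
                    f"the {len(rows)} selected {g} animals")
            parts.append(rows.iloc[:config.imaging_n_per_group])
        selected = pd.concat(parts)
    log.info("stage pet_synth: %d animals across %s", len(selected), GROUPS)
    volumes: dict[str, list] = {g: [] for g in GROUPS}
    for i, row in enumerate(selected.itertuples()):
        vol = simulate_subject_volume(atlas, pconf, row.group, animal_seed=i)
        volumes[row.group].append((row.animal_id, vol))
    atlas.save(out / "preproc" / "atlas.nii.gz")
    atlas.save_names(out / "preproc" / "roi_names.tsv")
    timings["pet_synth"] = time.perf_counter() - t1

    # --- stage 3: preprocessing -----------------------------------------
    t2 = time.perf_counter()
    wbm = whole_brain_mask(atlas)
    wbm.save(out / "preproc" / "whole_brain_mask.nii.gz")
    template = None
    if config.register:
        tconf = PetSimConfig(baseline_uptake=pconf.baseline_uptake,
                             group_multipliers={"template": {}})
        tdata = expected_uptake(atlas, tconf, "template")
        template = gaussian_smooth(
            VolumeImage(tdata, spacing=atlas.spacing,
                        affine=atlas.affine.copy()),
            config.smoothing)
    processed: dict[str, list] = {g: [] for g in GROUPS}
    transforms: dict[str, list[float]] = {}
    for g in GROUPS:
        for animal_id, vol in volumes[g]:
            sm = gaussian_smooth(vol, config.smoothing)
            if config.register and template is not None:
                reg = rigid_register(sm, template)
                sm = reg.resampled
                transforms[animal_id] = [float(x)
                                         for x in reg.transform.as_params()]
            norm = normalize_uptake(sm, wbm)
            processed[g].append(norm)
            if config.save_subject_volumes:
                norm.save(out / "preproc" / f"{animal_id}.nii.gz")
    if transforms:
        with open(out / "preproc" / "transforms.yaml", "w") as fh:
            yaml.safe_dump(transforms, fh, sort_keys=True)
    timings["preproc"] = time.perf_counter() - t2

    # --- stage 4: voxel statistics --------------------------------------
    t3 = time.perf_counter()
    summaries = []
    for ga, gb in CONTRASTS:
        cdir = out / "stats" / f"{ga}_vs_{gb}"
        cdir.mkdir(parents=True, exist_ok=True)
        stat, clusters, summary = contrast_analysis(
            processed[ga], processed[gb], wbm, atlas, (ga, gb),
            alpha=config.stats.alpha, min_extent=config.stats.min_extent,
            connectivity=config.stats.connectivity)
        for name in ("t", "p", "q", "z", "d"):
            bg = 1.0 if name in ("p", "q") else 0.0
            stat.volume(name, background=bg).save(cdir / f"{name}.nii.gz")
        clusters.label_volume(wbm).save(cdir / "clusters.nii.gz")
        summary.to_csv(cdir / "roi_summary.tsv", sep="\t", index=False,
                       float_format="%.6g")
        summaries.append(summary)
        log.info("contrast %s vs %s: %d clusters, %d ROI rows",
                 ga, gb, len(clusters.clusters), len(summary))
    non_empty = [s for s in summaries if not s.empty]
    combined = pd.concat(non_empty, ignore_index=True) if non_empty \
        else summaries[0]
    combined.to_csv(out / "report" / "roi_summary.tsv", sep="\t", index=False,
                    float_format="%.6g")
    timings["stats"] = time.perf_counter() - t3

    # --- manifest --------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_phenotyped": int(len(behavior)),
        "n_selected": int(len(selected)),
        "groups": {g: len(processed[g]) for g in GROUPS},
        "contrasts": [f"{a} vs {b}" for a, b in CONTRASTS],
        "selection_fraction": config.selection_fraction,
        "register": config.register,
        "stats": {"alpha": config.stats.alpha,
                  "min_extent": config.stats.min_extent,
                  "connectivity": config.stats.connectivity,
                  "fdr_q": config.stats.fdr_q},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out / "report" / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Design-stage power analysis

@dataclass
class PowerSpec:
    eta_squared: float = 0.1
    alpha: float = 0.05
    target_power: float = 0.80
    n_groups: int = 3

    def __post_init__(self) -> None:
        for name in ("eta_squared", "alpha", "target_power"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups")


def anova_power(spec: PowerSpec, n_per_group: int) -> float:
    """Analytic power of the balanced one-way fixed-effects ANOVA.

    Noncentrality lambda = N * eta^2 / (1 - eta^2) with N the total sample
    size; power is the upper tail of the noncentral F beyond the central-F
    critical value.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    N = spec.n_groups * n_per_group
    df1 = spec.n_groups - 1
    df2 = N - spec.n_groups
    lam = N * spec.eta_squared / (1.0 - spec.eta_squared)
    crit = stats.f.isf(spec.alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, lam))


def anova_power_mc(spec: PowerSpec, n_per_group: int, n_reps: int = 10_000,
                   seed: int = 0) -> float:
    """Monte-Carlo cross-check of ``anova_power``.

    Group means are equally spaced so that the between-group variance
    matches the requested eta^2 at unit error variance; each replicate's F
    is computed in closed form from group summaries, vectorised over reps.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    k = spec.n_groups
    N = k * n_per_group
    lam = N * spec.eta_squared / (1.0 - spec.eta_squared)
    # centred equally spaced means: sum mu_i^2 = lambda / n_per_group
    base = np.arange(k, dtype=float) - (k - 1) / 2.0
    mu = base * np.sqrt(lam / n_per_group / (base ** 2).sum())
    x = rng.standard_normal((n_reps, k, n_per_group)) + mu[None, :, None]
    gmean = x.mean(axis=2)
    grand = gmean.mean(axis=1, keepdims=True)
    ssb = n_per_group * ((gmean - grand) ** 2).sum(axis=1)
    ssw = ((x - gmean[:, :, None]) ** 2).sum(axis=(1, 2))
    F = (ssb / (k - 1)) / (ssw / (N - k))
    crit = stats.f.isf(spec.alpha, k - 1, N - k)
    return float((F > crit).mean())
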