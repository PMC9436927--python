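"""Synthetic FDG-PET phantom: geometric mouse-brain atlas and uptake volumes.

The atlas is a deterministic arrangement of rectangular ROI blocks on the
PET grid (voxel size 0.3875 x 0.3875 x 0.775 mm), naming a subset of the
regions a mouse-brain ROI atlas provides (prelimbic/infralimbic cortex,
motor cortex, thalamus, amygdala, ...). It is a stand-in with the same
NIfTI interface as a real digital atlas, so the real one is a drop-in.

Subject volumes are

    voxel = baseline[roi] * multiplier[group][roi] * global_scale(animal)
            + Gaussian noise,

with the per-animal global scale drawn lognormal. The multiplicative scale
is the nuisance the whole-brain-mean normalisation must cancel; the
group-by-ROI multipliers encode the planted regional effects the voxel-wise
statistics should recover. Optional rigid misalignment exercises the
registration stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import DEFAULT_SPACING, LabelAtlas, VolumeImage

# (label, abbrev, fullname, origin voxel, box size) on the default 40x40x24
# grid. Blocks are disjoint with >= 2-voxel gaps; each has 6*6*4 = 144
# voxels, comfortably above the 50-voxel cluster-extent threshold.
DEFAULT_ROI_SPEC = [
    (1, "PrL/IL", "prelimbic/infralimbic cortex", (4, 4, 3), (6, 6, 4)),
    (2, "Mot", "motor cortex", (12, 4, 3), (6, 6, 4)),
    (3, "Som", "somatosensory cortex", (20, 4, 3), (6, 6, 4)),
    (4, "Aud", "dorsal secondary auditory cortex", (28, 4, 3), (6, 6, 4)),
    (5, "DStr", "dorsal striatum", (4, 12, 3), (6, 6, 4)),
    (6, "VStr", "ventral striatum (nucleus accumbens)", (12, 12, 3), (6, 6, 4)),
    (7, "Thal", "thalamus", (20, 12, 3), (6, 6, 4)),
    (8, "Amyg", "amygdala", (28, 12, 3), (6, 6, 4)),
    (9, "Hipp", "hippocampus", (4, 20, 3), (6, 6, 4)),
    (10, "PAG", "periaqueductal gray", (12, 20, 3), (6, 6, 4)),
    (11, "SupCol", "superior colliculus", (20, 20, 3), (6, 6, 4)),
    (12, "RN", "red nucleus", (28, 20, 3), (6, 6, 4)),
    (13, "Cereb", "cerebellum", (12, 28, 3), (6, 6, 4)),
    # large unassigned-tissue region: absorbs the whole-brain-mean shift of
    # focal effects, as the many unlisted regions of a real atlas do
    (14, "Rest", "rest of brain", (2, 2, 10), (36, 36, 12)),
]

DEFAULT_SHAPE = (40, 40, 24)
MIN_ROI_VOXELS = 50


def build_atlas(shape=DEFAULT_SHAPE, spacing=DEFAULT_SPACING,
                roi_spec=None) -> LabelAtlas:
    """Deterministic box-ROI atlas. Raises on overlap or undersized ROIs."""
    if roi_spec is None:
        roi_spec = DEFAULT_ROI_SPEC
    labels = np.zeros(shape, dtype=np.int32)
    names: dict[int, str] = {}
    fullnames: dict[int, str] = {}
    for lab, abbrev, full, origin, size in roi_spec:
        sl = tuple(slice(o, o + s) for o, s in zip(origin, size))
        if any(o < 0 or o + s > dim for o, s, dim in zip(origin, size, shape)):
            raise ValueError(f"ROI {abbrev} does not fit in shape {shape}")
        if (labels[sl] != 0).any():
            raise ValueError(f"ROI {abbrev} overlaps an earlier ROI")
        n_vox = int(np.prod(size))
        if n_vox < MIN_ROI_VOXELS:
            raise ValueError(
                f"ROI {abbrev} has {n_vox} voxels < {MIN_ROI_VOXELS}")
        labels[sl] = lab
        names[lab] = abbrev
        fullnames[lab] = full
    return LabelAtlas(labels, names, fullnames=fullnames, spacing=tuple(spacing))


@dataclass
class PetSimConfig:
    """Simulation parameters for synthetic uptake volumes.

    ``baseline_uptake`` maps ROI label -> mean activity (arbitrary units);
    ``group_multipliers`` maps group -> {label: multiplicative effect}
    (ROIs not listed default to 1). ``global_scale_sd`` is the SD of the
    per-animal lognormal global scale (log-space); ``noise_sd`` is additive
    Gaussian noise in activity units. ``misalign`` optionally gives rigid
    perturbation half-ranges: {"translation_mm": t, "rotation_deg": r}.
    """

    baseline_uptake: dict[int, float] = field(default_factory=dict)
    group_multipliers: dict[str, dict[int, float]] = field(default_factory=dict)
    noise_sd: float = 5.0
    global_scale_sd: float = 0.1
    misalign: dict[str, float] | None = None
    seed: int = 0

    def validate(self, atlas: LabelAtlas) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.global_scale_sd < 0:
            raise ValueError("global_scale_sd must be >= 0")
        for lab in atlas.names:
            if self.baseline_uptake.get(lab, 1.0) <= 0:
                raise ValueError(f"baseline for label {lab} must be > 0")
        for g, mults in self.group_multipliers.items():
            for lab, m in mults.items():
                if m <= 0:
                    raise ValueError(f"multiplier {g}/{lab} must be > 0")


def uniform_baseline(atlas: LabelAtlas, level: float = 100.0) -> dict[int, float]:
    return {lab: level for lab in atlas.names}


def expected_uptake(atlas: LabelAtlas, config: PetSimConfig, group: str
                    ) -> np.ndarray:
    """Noise-free unit-scale uptake map for one group (background 0)."""
    mults = config.group_multipliers.get(group, {})
    out = np.zeros(atlas.shape, dtype=float)
    for lab in atlas.names:
        base = config.baseline_uptake.get(lab, 1.0)
        out[atlas.labels == lab] = base * mults.get(lab, 1.0)
    return out


def simulate_subject_volume(atlas: LabelAtlas, config: PetSimConfig,
                            group: str, animal_seed: int) -> VolumeImage:
    """One animal's uptake volume; reproducible per (config.seed, animal_seed).

    Misalignment, when configured, draws a rigid perturbation from the
    per-animal stream and resamples the clean-geometry volume through it,
    so the registration stage has a known ground truth to undo.
    """
    if group not in config.group_multipliers:
        raise KeyError(f"unknown group {group!r}")
    config.validate(atlas)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, animal_seed]))
    scale = float(np.exp(rng.normal(0.0, config.global_scale_sd))) \
        if config.global_scale_sd > 0 else 1.0
    data = expected_uptake(atlas, config, group) * scale
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=atlas.shape)
    vol = VolumeImage(data, spacing=atlas.spacing, affine=atlas.affine.copy())
    if config.misalign:
        from .preproc import RigidTransform, apply_rigid
        t = float(config.misalign.get("translation_mm", 0.0))
        r = float(config.misalign.get("rotation_deg", 0.0))
        tr = RigidTransform(
            translations=tuple(rng.uniform(-t, t, 3)),
            rotations=tuple(rng.uniform(-r, r, 3)))
        vol = apply_rigid(vol, tr)
        vol.true_misalignment = tr  # type: ignore[attr-defined]
    return vol


def simulate_group_volumes(atlas: LabelAtlas, config: PetSimConfig,
                           groups: dict[str, int]) -> dict[str, list[VolumeImage]]:
    """Simulate ``groups[name]`` animals per group with distinct seeds."""
    out: dict[str, list[VolumeImage]] = {}
    counter = 0
    for g, n in groups.items():
        out[g] = [simulate_subject_volume(atlas, config, g, counter + i)
                  for i in range(n)]
        counter += n
    return out
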