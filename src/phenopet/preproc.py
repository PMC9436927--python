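"""PET preprocessing: Gaussian smoothing, rigid MI registration, whole-brain
mask and whole-brain-mean intensity normalisation.

Smoothing is specified in mm FWHM and converted per axis with
sigma = FWHM / (2 sqrt(2 ln 2)) / spacing. Registration is six-parameter
rigid (three translations in mm, three rotations in degrees about the
volume centre, intrinsic x->y->z order, no warping or scaling), maximising
the mutual information of the joint intensity histogram with Powell's
derivative-free optimiser and trilinear resampling. Uptake is normalised by
dividing every voxel by the mean activity inside the whole-brain mask, so
any per-animal global scale cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .volume import LabelAtlas, MaskVolume, VolumeImage

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # approx 2.35482


@dataclass
class SmoothingSpec:
    fwhm_mm: tuple[float, float, float] = (0.6, 0.6, 0.6)

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fwhm_mm):
            raise ValueError("FWHM must be >= 0")

    def sigma_voxels(self, spacing) -> tuple[float, float, float]:
        return tuple(f / FWHM_TO_SIGMA / s for f, s in zip(self.fwhm_mm, spacing))


def gaussian_smooth(vol: VolumeImage, spec: SmoothingSpec) -> VolumeImage:
    """Separable Gaussian smoothing; nearest-neighbour edge extension."""
    sigma = spec.sigma_voxels(vol.spacing)
    if all(s == 0 for s in sigma):
        return vol.like(vol.data.copy())
    return vol.like(ndimage.gaussian_filter(vol.data, sigma=sigma, mode="nearest"))


# ---------------------------------------------------------------------------
# Rigid transforms

@dataclass
class RigidTransform:
    """Six-parameter rigid map: translations (mm), rotations (deg, about the
    volume centre, applied intrinsically x then y then z)."""

    translations: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotations: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def as_params(self) -> np.ndarray:
        return np.asarray(self.translations + self.rotations, dtype=float)

    @classmethod
    def from_params(cls, p) -> "RigidTransform":
        p = np.asarray(p, dtype=float)
        return cls(tuple(p[:3]), tuple(p[3:6]))

    def matrix(self, center_mm) -> np.ndarray:
        """Homogeneous world-space matrix: p' = R (p - c) + c + t."""
        rx, ry, rz = np.deg2rad(self.rotations)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        R = Rz @ Ry @ Rx
        c = np.asarray(center_mm, dtype=float)
        t = np.asarray(self.translations, dtype=float)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c + t - R @ c
        return M


def apply_rigid(vol: VolumeImage, transform: RigidTransform,
                reference: VolumeImage | None = None, order: int = 1
                ) -> VolumeImage:
    """Resample ``vol`` through a rigid transform into ``reference`` geometry
    (default: its own). Trilinear by default; out-of-field voxels are 0."""
    ref = reference if reference is not None else vol
    M = transform.matrix(ref.center_mm())
    # output voxel -> world -> inverse rigid -> input voxel
    full = np.linalg.inv(vol.affine) @ np.linalg.inv(M) @ ref.affine
    out = ndimage.affine_transform(vol.data, full[:3, :3], offset=full[:3, 3],
                                   output_shape=ref.shape, order=order,
                                   mode="constant", cval=0.0)
    return VolumeImage(out, spacing=ref.spacing, affine=ref.affine.copy())


# ---------------------------------------------------------------------------
# Mutual information + Powell registration

def _histogram_range(data: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(data, [1.0, 99.0])
    if hi <= lo:
        hi = lo + 1e-6
    return float(lo), float(hi)


def mutual_information(a: VolumeImage, b: VolumeImage, bins: int = 32,
                       a_range=None, b_range=None) -> float:
    """MI (nats) of the 2-D intensity histogram of two aligned volumes.

    Intensities are binned over the 1st-99th percentile range of each
    volume (robust to hot voxels), 32 bins per axis by default.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if a.shape != b.shape:
        raise ValueError("volumes must share geometry")
    ar = a_range if a_range is not None else _histogram_range(a.data)
    br = b_range if b_range is not None else _histogram_range(b.data)
    joint, _, _ = np.histogram2d(a.data.ravel(), b.data.ravel(), bins=bins,
                                 range=[ar, br])
    n = joint.sum()
    if n == 0:
        raise ValueError("empty overlap between intensity ranges")
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())


@dataclass
class RegistrationResult:
    transform: RigidTransform
    resampled: VolumeImage
    mi: float
    mi_init: float
    converged: bool
    n_evaluations: int


def rigid_register(moving: VolumeImage, fixed: VolumeImage,
                   init: RigidTransform | None = None, bins: int = 32,
                   max_iter: int = 200,
                   coarse_fwhm_mm: float | None = 1.5) -> RegistrationResult:
    """Six-DOF rigid registration of ``moving`` onto ``fixed`` by Powell
    maximisation of mutual information, coarse-to-fine.

    A first Powell pass runs on copies of both volumes smoothed by an
    extra ``coarse_fwhm_mm`` kernel — the smoother MI landscape steers the
    optimiser out of the interpolation-induced local optima that trap a
    single-resolution search — and its optimum seeds the pass on the
    native volumes. Each candidate transform resamples the moving volume
    trilinearly; histogram ranges are frozen per resolution. A
    non-converged optimiser is reported via ``converged=False``, never
    silently.
    """
    init = init or RigidTransform()
    n_eval = 0
    opts = {"maxiter": max_iter, "xtol": 1e-4, "ftol": 1e-7}

    def make_objective(mov, fix):
        mov_range = _histogram_range(mov.data)
        fix_range = _histogram_range(fix.data)

        def neg_mi(params: np.ndarray) -> float:
            nonlocal n_eval
            n_eval += 1
            resampled = apply_rigid(mov, RigidTransform.from_params(params),
                                    reference=fix)
            return -mutual_information(resampled, fix, bins=bins,
                                       a_range=mov_range, b_range=fix_range)
        return neg_mi

    start = init.as_params()
    if coarse_fwhm_mm:
        spec = SmoothingSpec(fwhm_mm=(coarse_fwhm_mm,) * 3)
        coarse = make_objective(gaussian_smooth(moving, spec),
                                gaussian_smooth(fixed, spec))
        start = optimize.minimize(coarse, start, method="Powell",
                                  options=opts).x

    neg_mi = make_objective(moving, fixed)
    mi_init = -neg_mi(init.as_params())
    res = optimize.minimize(neg_mi, start, method="Powell", options=opts)
    best = RigidTransform.from_params(res.x)
    mi_final = -float(res.fun)
    if mi_final < mi_init:  # Powell must never worsen the start point
        best, mi_final = init, mi_init
    return RegistrationResult(
        transform=best,
        resampled=apply_rigid(moving, best, reference=fixed),
        mi=mi_final, mi_init=mi_init,
        converged=bool(res.success), n_evaluations=n_eval)


# ---------------------------------------------------------------------------
# Whole-brain mask and uptake normalisation

def whole_brain_mask(atlas: LabelAtlas) -> MaskVolume:
    """Union of all non-background atlas labels."""
    mask = atlas.labels > 0
    if not mask.any():
        raise ValueError("atlas has no labelled voxels")
    return MaskVolume(mask.astype(np.uint8), spacing=atlas.spacing,
                      affine=atlas.affine.copy())


def normalize_uptake(vol: VolumeImage, wbm: MaskVolume) -> VolumeImage:
    """Divide every voxel by the mean activity inside the whole-brain mask."""
    if vol.shape != wbm.data.shape:
        raise ValueError("volume and mask geometry mismatch")
    mean = vol.data[wbm.data].mean()
    if mean <= 0:
        raise ValueError(f"non-positive whole-brain mean activity ({mean})")
    return vol.like(vol.data / mean)
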