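"""Voxel-wise group statistics: pooled t-tests, BH FDR, signed Z-maps,
cluster-extent filtering, Cohen's d, and per-ROI summary tables.

The headline significance path is the uncorrected-p threshold (default
0.05) combined with a minimum cluster extent (default 50 face-connected
voxels); BH-adjusted q-values are always computed and carried alongside.
Signed Z is the standard-normal quantile transform of the t cumulative
probability. Cohen's d for a two-sample contrast is d = t*sqrt(1/nA+1/nB),
classified moderate (<0.80), large (0.80-1.20) or very large (>1.20).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .volume import LabelAtlas, MaskVolume, VolumeImage


@dataclass
class StatMap:
    """Per-voxel statistics for one two-group contrast, flattened over a mask.

    All 1-D arrays are ordered like ``mask.data[mask.data]`` (C order).
    ``degenerate`` flags zero-pooled-variance voxels (t=0, p=1).
    """

    contrast: tuple[str, str]
    mask: MaskVolume
    t: np.ndarray
    df: int
    p: np.ndarray
    q: np.ndarray
    z: np.ndarray
    d: np.ndarray
    n_a: int
    n_b: int
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def volume(self, name: str, background: float = 0.0) -> VolumeImage:
        """Embed a flattened statistic back into the 3-D grid."""
        arr = getattr(self, name)
        out = np.full(self.mask.data.shape, background, dtype=float)
        out[self.mask.data] = arr
        return VolumeImage(out, spacing=self.mask.spacing,
                           affine=self.mask.affine.copy())


def voxelwise_ttest(group_a: list[VolumeImage], group_b: list[VolumeImage],
                    wbm: MaskVolume, contrast: tuple[str, str] = ("A", "B")
                    ) -> StatMap:
    """Pooled-variance unpaired two-tailed t-test at every in-mask voxel.

    t is (mean_A - mean_B)/SE with df = n_A + n_B - 2. Zero-pooled-variance
    voxels get t=0, p=1 and a degeneracy flag rather than being dropped, so
    map geometry is preserved.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 volumes per group")
    for v in group_a + group_b:
        if v.shape != wbm.data.shape:
            raise ValueError("volume/mask geometry mismatch")
    m = wbm.data
    A = np.stack([v.data[m] for v in group_a])  # (n_a, V)
    B = np.stack([v.data[m] for v in group_b])
    n_a, n_b = A.shape[0], B.shape[0]
    df = n_a + n_b - 2
    diff = A.mean(axis=0) - B.mean(axis=0)
    ss_a = ((A - A.mean(axis=0)) ** 2).sum(axis=0)
    ss_b = ((B - B.mean(axis=0)) ** 2).sum(axis=0)
    pooled_var = (ss_a + ss_b) / df
    degenerate = pooled_var == 0
    se = np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, diff / np.where(se == 0, 1.0, se))
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = bh_fdr(p)
    z = t_to_z(t, df)
    d = cohens_d_map(t, n_a, n_b)
    return StatMap(contrast=contrast, mask=wbm, t=t, df=df, p=p, q=q, z=z,
                   d=d, n_a=n_a, n_b=n_b, degenerate=degenerate)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Signed Z: standard-normal quantile of the t cumulative probability.

    Computed through the upper tail of |t| for numerical stability; strictly
    increasing in t and sign-preserving.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    tail = stats.t.sf(np.abs(t), df)
    z = stats.norm.isf(tail)
    return np.sign(t) * z


def cohens_d_map(t: np.ndarray, n_a: int, n_b: int) -> np.ndarray:
    """Cohen's d from the two-sample t: d = t * sqrt(1/n_A + 1/n_B)."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    return np.asarray(t, dtype=float) * np.sqrt(1.0 / n_a + 1.0 / n_b)


D_CUTOFF_LARGE = 0.80
D_CUTOFF_VERY_LARGE = 1.20


def classify_d(d: float) -> str:
    """Effect-size class: |d| < 0.80 moderate, 0.80-1.20 large, > 1.20 very
    large (both boundaries belong to 'large')."""
    a = abs(float(d))
    if a < D_CUTOFF_LARGE:
        return "moderate"
    if a <= D_CUTOFF_VERY_LARGE:
        return "large"
    return "very large"


# ---------------------------------------------------------------------------
# Cluster-extent filtering

@dataclass
class Cluster:
    cluster_id: int
    indices: np.ndarray  # (n, 3) voxel indices
    size: int
    sign: int
    peak_abs_z: float


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    min_extent: int
    connectivity: int

    def voxel_mask(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        for c in self.clusters:
            out[tuple(c.indices.T)] = True
        return out

    def label_volume(self, like: MaskVolume) -> VolumeImage:
        out = np.zeros(like.data.shape, dtype=float)
        for c in self.clusters:
            out[tuple(c.indices.T)] = c.cluster_id * c.sign
        return VolumeImage(out, spacing=like.spacing, affine=like.affine.copy())


_STRUCTURES = {6: 1, 18: 2, 26: 3}


def cluster_extent_filter(signed_sig: np.ndarray, z: np.ndarray | None = None,
                          min_extent: int = 50, connectivity: int = 6
                          ) -> ClusterSet:
    """Connected components of signed significant voxels, size-filtered.

    ``signed_sig`` holds -1/0/+1 per voxel. Positive and negative voxels are
    labelled independently (a sign flip breaks contiguity), and components
    smaller than ``min_extent`` are discarded. Connectivity 6 (faces), 18
    (+edges) or 26 (+corners).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    signed_sig = np.asarray(signed_sig)
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    clusters: list[Cluster] = []
    cid = 0
    for sign in (+1, -1):
        labelled, n = ndimage.label(signed_sig == sign, structure=structure)
        for comp in range(1, n + 1):
            idx = np.argwhere(labelled == comp)
            if idx.shape[0] < min_extent:
                continue
            cid += 1
            peak = float(np.abs(z[tuple(idx.T)]).max()) if z is not None else np.nan
            clusters.append(Cluster(cid, idx, idx.shape[0], sign, peak))
    return ClusterSet(clusters, min_extent, connectivity)


def significance_map(stat: StatMap, alpha: float = 0.05,
                     use_fdr: bool = False) -> np.ndarray:
    """Signed -1/0/+1 per-voxel significance grid at threshold ``alpha``.

    Uncorrected p by default; set ``use_fdr`` to threshold the BH q-values
    instead.
    """
    pvals = stat.q if use_fdr else stat.p
    sig = np.zeros(stat.mask.data.shape, dtype=np.int8)
    flat = np.where(pvals < alpha, np.sign(stat.t).astype(np.int8), 0)
    sig[stat.mask.data] = flat
    return sig


# ---------------------------------------------------------------------------
# ROI summaries (output schema mirrors a per-ROI Z / d / p results table)

def roi_summarize(stat: StatMap, clusters: ClusterSet, atlas: LabelAtlas
                  ) -> pd.DataFrame:
    """Per-ROI summary over significant voxels inside surviving clusters.

    For each ROI that overlaps at least one surviving cluster: mean +/- SD
    of signed Z and of d over the in-ROI surviving voxels, the median p of
    those voxels as the representative p, the voxel count, and the effect
    class of the mean |d|. ROIs without overlap are omitted.
    """
    if atlas.shape != stat.mask.data.shape:
        raise ValueError("atlas/map geometry mismatch")
    surviving = clusters.voxel_mask(atlas.shape)
    zvol = stat.volume("z").data
    dvol = stat.volume("d").data
    pvol = stat.volume("p", background=1.0).data
    rows = []
    for lab in sorted(atlas.names):
        sel = surviving & (atlas.labels == lab)
        n = int(sel.sum())
        if n == 0:
            continue
        zs, ds, ps = zvol[sel], dvol[sel], pvol[sel]
        mean_d = float(ds.mean())
        rows.append({
            "roi": atlas.names[lab],
            "contrast": f"{stat.contrast[0]} vs {stat.contrast[1]}",
            "mean_z": float(zs.mean()),
            "sd_z": float(zs.std(ddof=1)) if n > 1 else 0.0,
            "mean_d": mean_d,
            "sd_d": float(ds.std(ddof=1)) if n > 1 else 0.0,
            "p": float(np.median(ps)),
            "n_voxels": n,
            "d_class": classify_d(mean_d),
        })
    return pd.DataFrame(rows, columns=["roi", "contrast", "mean_z", "sd_z",
                                       "mean_d", "sd_d", "p", "n_voxels",
                                       "d_class"])


def contrast_analysis(group_a, group_b, wbm, atlas, contrast,
                      alpha: float = 0.05, min_extent: int = 50,
                      connectivity: int = 6) -> tuple[StatMap, ClusterSet, pd.DataFrame]:
    """Full statistical chain for one contrast: t-test -> threshold ->
    cluster filter -> ROI summary."""
    stat = voxelwise_ttest(group_a, group_b, wbm, contrast=contrast)
    sig = significance_map(stat, alpha=alpha)
    clusters = cluster_extent_filter(sig, z=stat.volume("z").data,
                                     min_extent=min_extent,
                                     connectivity=connectivity)
    summary = roi_summarize(stat, clusters, atlas)
    return stat, clusters, summary
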