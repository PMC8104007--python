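"""Monte-Carlo cluster-extent correction and cluster reporting.

The multiple-comparison strategy simulates the null: standard-normal noise
on the analysis grid, Gaussian-smoothed at the nominal applied FWHM,
rescaled to unit variance inside the mask, thresholded at the voxel height
``p``, and labeled into connected components.  The distribution of the
maximum null cluster size over iterations yields the smallest extent
``k_min`` whose exceedance fraction is at most the cluster-wise alpha;
observed clusters of at least ``k_min`` voxels are then reported with peak
coordinates in world (MNI) millimeters and a corrected p equal to the null
exceedance fraction of their size.

Noise is smoothed on the full grid and masked afterwards (smoothing across
the mask boundary is ignored), which is conservative at edges; smoothness
is taken as the nominal applied FWHM.  The voxel threshold is two-sided
(|z| for p/2) since undirected F-difference maps are the primary use case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .glm import StatMap

__all__ = [
    "ClusterConfig",
    "MonteCarloNull",
    "monte_carlo_cluster_threshold",
    "threshold_clusters",
    "gray_matter_mask_3mm",
    "CLUSTER_COLUMNS",
]

CLUSTER_COLUMNS = [
    "cluster_id",
    "size_vox",
    "peak_x",
    "peak_y",
    "peak_z",
    "peak_stat",
    "p_corrected",
]

_CONN_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class ClusterConfig:
    voxel_p: float = 0.005
    alpha_cluster: float = 0.05
    n_iter: int = 1000
    fwhm_mm: float = 8.0
    connectivity: int = 26
    two_sided: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.voxel_p < 1:
            raise ValueError("voxel_p must be in (0, 1)")
        if self.n_iter < 100:
            raise ValueError("n_iter must be >= 100")
        if self.connectivity not in _CONN_STRUCTS:
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def z_threshold(self) -> float:
        p = self.voxel_p / 2 if self.two_sided else self.voxel_p
        return float(stats.norm.isf(p))


@dataclass
class MonteCarloNull:
    """Null distribution of maximum cluster sizes and the derived k_min."""

    k_min: int
    max_sizes: np.ndarray
    config: ClusterConfig
    n_mask_voxels: int

    def corrected_p(self, size: int) -> float:
        """Fraction of null iterations whose max cluster reached ``size``."""
        return float(np.mean(self.max_sizes >= size))


def monte_carlo_cluster_threshold(
    mask: np.ndarray,
    cfg: ClusterConfig = ClusterConfig(),
    voxel_size_mm: float = 3.0,
) -> MonteCarloNull:
    """Derive the cluster-extent threshold by null simulation.

    Each iteration draws standard-normal noise on the full grid, smooths at
    ``cfg.fwhm_mm`` (converted to voxels via ``voxel_size_mm``), rescales to
    unit variance inside the mask, thresholds at the voxel height, labels
    connected components and records the maximum cluster size.  ``k_min`` is
    the smallest extent whose exceedance fraction is <= ``alpha_cluster``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    sigma = (
        cfg.fwhm_mm / (voxel_size_mm * np.sqrt(8.0 * np.log(2.0)))
        if cfg.fwhm_mm > 0
        else 0.0
    )
    zthr = cfg.z_threshold
    struct = _CONN_STRUCTS[cfg.connectivity]
    rng = np.random.default_rng(cfg.seed)
    max_sizes = np.zeros(cfg.n_iter, dtype=np.int64)
    for i in range(cfg.n_iter):
        noise = rng.standard_normal(mask.shape)
        if sigma > 0:
            noise = ndimage.gaussian_filter(noise, sigma)
        vals = noise[mask]
        noise = (noise - vals.mean()) / vals.std()
        supra = mask & (np.abs(noise) > zthr if cfg.two_sided else noise > zthr)
        labels, n = ndimage.label(supra, structure=struct)
        if n:
            max_sizes[i] = np.bincount(labels.ravel())[1:].max()

    k_min = 1
    if max_sizes.max() == 0:
        import warnings

        warnings.warn(
            "no suprathreshold voxels in any null iteration; k_min = 1",
            stacklevel=2,
        )
    else:
        for k in range(1, int(max_sizes.max()) + 2):
            if np.mean(max_sizes >= k) <= cfg.alpha_cluster:
                k_min = k
                break
    return MonteCarloNull(
        k_min=int(k_min),
        max_sizes=max_sizes,
        config=cfg,
        n_mask_voxels=int(mask.sum()),
    )


def _stat_threshold(stat: str, df, voxel_p: float, two_sided: bool) -> float:
    if df is None:
        raise ValueError("statistic map carries no degrees of freedom")
    if stat == "t":
        p = voxel_p / 2 if two_sided else voxel_p
        return float(stats.t.isf(p, df[0]))
    if stat == "F":
        return float(stats.f.isf(voxel_p, df[0], df[1]))
    if stat == "z":
        p = voxel_p / 2 if two_sided else voxel_p
        return float(stats.norm.isf(p))
    raise ValueError(f"cannot threshold a {stat!r} map")


def threshold_clusters(
    stat_map: StatMap,
    null: MonteCarloNull | int,
    cfg: ClusterConfig = ClusterConfig(),
) -> pd.DataFrame:
    """Cluster the suprathreshold voxels of a statistic map.

    The voxel height ``cfg.voxel_p`` is converted to a statistic cutoff via
    the map's degrees of freedom (|t| two-sided, F one-sided).  Clusters
    smaller than ``k_min`` are discarded; peaks are reported in world mm via
    the map's affine.  When ``null`` is a :class:`MonteCarloNull`, each
    cluster's corrected p is its size's null exceedance fraction.
    """
    if isinstance(null, MonteCarloNull):
        k_min = null.k_min
    else:
        k_min = int(null)
        null = None
    thr = _stat_threshold(stat_map.stat, stat_map.df, cfg.voxel_p, cfg.two_sided)
    vol = np.nan_to_num(stat_map.values)
    if stat_map.stat == "t" and cfg.two_sided:
        supra = stat_map.mask & (np.abs(vol) > thr)
    else:
        supra = stat_map.mask & (vol > thr)
    labels, n = ndimage.label(supra, structure=_CONN_STRUCTS[cfg.connectivity])
    rows = []
    mag = np.abs(vol) if stat_map.stat == "t" else vol
    for lab in range(1, n + 1):
        where = labels == lab
        size = int(where.sum())
        if size < k_min:
            continue
        peak_flat = np.argmax(np.where(where, mag, -np.inf))
        ijk = np.unravel_index(peak_flat, vol.shape)
        world = stat_map.affine @ np.array([*ijk, 1.0])
        rows.append(
            {
                "cluster_id": len(rows) + 1,
                "size_vox": size,
                "peak_x": world[0],
                "peak_y": world[1],
                "peak_z": world[2],
                "peak_stat": float(vol[ijk]),
                "p_corrected": (
                    null.corrected_p(size) if null is not None else np.nan
                ),
            }
        )
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    if len(table):
        table = (
            table.sort_values("peak_stat", key=np.abs, ascending=False)
            .reset_index(drop=True)
            .assign(cluster_id=lambda d: np.arange(1, len(d) + 1))
        )
    return table


def surviving_cluster_mask(
    stat_map: StatMap,
    null: MonteCarloNull | int,
    cfg: ClusterConfig = ClusterConfig(),
) -> np.ndarray:
    """Binary volume of all voxels inside clusters that pass the extent
    threshold (used to build coupling-difference restriction masks)."""
    k_min = null.k_min if isinstance(null, MonteCarloNull) else int(null)
    thr = _stat_threshold(stat_map.stat, stat_map.df, cfg.voxel_p, cfg.two_sided)
    vol = np.nan_to_num(stat_map.values)
    if stat_map.stat == "t" and cfg.two_sided:
        supra = stat_map.mask & (np.abs(vol) > thr)
    else:
        supra = stat_map.mask & (vol > thr)
    labels, n = ndimage.label(supra, structure=_CONN_STRUCTS[cfg.connectivity])
    if n == 0:
        return np.zeros(stat_map.mask.shape, dtype=bool)
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= k_min)
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def gray_matter_mask_3mm() -> tuple[np.ndarray, np.ndarray]:
    """MNI152 gray-matter mask on the 3 mm grid (mask, affine).

    Uses the template distributed with nilearn; no download is performed.
    """
    from nilearn.datasets import load_mni152_gm_mask

    img = load_mni152_gm_mask(resolution=3)
    return np.asarray(img.dataobj) > 0, img.affine
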