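"""BOLD spectral power: ALFF / mALFF maps and their group contrasts.

ALFF (amplitude of low-frequency fluctuation) summarizes each voxel's BOLD
spectral content in 0.01-0.08 Hz: after residualizing the six motion
parameters and removing the linear trend, the untapered full-length Fourier
amplitude (square-rooted power) is averaged over the in-band bins, which lie
at k/(T*TR) Hz.  mALFF subtracts the mask-wide mean (``ALFF - mean(ALFF)``);
the more common divisive normalization (``ALFF / mean``) is available as a
dialect.  Group differences are voxelwise two-sample t-tests, whole-brain or
restricted to a mask of coupling differences, with Monte-Carlo
cluster-extent correction on the tested mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .cluster import ClusterConfig, monte_carlo_cluster_threshold, threshold_clusters
from .glm import BoldRun, StatMap, group_ttest2

__all__ = [
    "AlffConfig",
    "AlffMaps",
    "residualize_motion",
    "compute_alff",
    "normalize_malff",
    "group_map_ttest",
    "AlffGroupTest",
]


@dataclass(frozen=True)
class AlffConfig:
    band: tuple[float, float] = (0.01, 0.08)  # Hz
    normalization: str = "subtractive"        # or 'divisive'
    detrend: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("ALFF band must satisfy 0 < lo < hi")
        if self.normalization not in ("subtractive", "divisive"):
            raise ValueError("normalization must be 'subtractive' or 'divisive'")


@dataclass
class AlffMaps:
    """Per-subject ALFF and normalized (mALFF) volumes."""

    alff: np.ndarray
    malff: np.ndarray | None
    mask: np.ndarray
    affine: np.ndarray
    config: AlffConfig = field(default_factory=AlffConfig)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(self.alff[self.mask] < 0):
            raise ValueError("ALFF must be non-negative inside the mask")

    def malff_map(self) -> StatMap:
        if self.malff is None:
            raise ValueError("mALFF not computed; call normalize_malff first")
        return StatMap(
            values=self.malff, stat="beta", df=None, mask=self.mask,
            affine=self.affine,
            provenance={"measure": "mALFF", "normalization": self.config.normalization},
        )


def residualize_motion(run: BoldRun) -> BoldRun:
    """Regress the six motion parameters out of every voxel series.

    Per voxel, the OLS residual of the time series on [1, motion] with the
    temporal mean added back, so baseline levels survive.
    """
    T = run.n_volumes
    X = np.column_stack([np.ones(T), run.motion])
    Y = run.masked_series()  # V x T
    beta = Y @ np.linalg.pinv(X).T
    resid = Y - beta @ X.T
    resid += Y.mean(axis=1, keepdims=True)
    data = np.zeros_like(run.data)
    data[run.mask] = resid
    return BoldRun(
        data=data, affine=run.affine, tr=run.tr, mask=run.mask,
        motion=run.motion, wm=run.wm, csf=run.csf,
    )


def amplitude_spectrum(
    run: BoldRun, detrend: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Untapered full-length Fourier amplitude of every in-mask voxel.

    Returns ``(freqs, amp)`` with ``amp`` of shape voxels x bins, scaled
    ``2 |X_k| / T`` so a unit-amplitude on-bin sinusoid reads ~1.  Bins lie
    at k/(T*TR) Hz.
    """
    T = run.n_volumes
    Y = run.masked_series()
    if detrend:
        Y = signal.detrend(Y, axis=1, type="linear")
    freqs = np.fft.rfftfreq(T, d=run.tr)
    amp = np.abs(np.fft.rfft(Y, axis=1)) * (2.0 / T)
    return freqs, amp


def compute_alff(run: BoldRun, cfg: AlffConfig = AlffConfig()) -> AlffMaps:
    """Compute the ALFF volume for one (motion-residualized) run.

    The transform length equals the series length (no padding, no taper);
    ALFF is the mean over in-band bins of the Fourier amplitude (the
    square-rooted power spectrum).
    """
    nyquist = 1.0 / (2.0 * run.tr)
    if cfg.band[1] > nyquist + 1e-12:
        raise ValueError(
            f"ALFF band upper edge {cfg.band[1]} Hz exceeds Nyquist {nyquist:.4f} Hz"
        )
    freqs, amp = amplitude_spectrum(run, cfg.detrend)
    sel = (freqs >= cfg.band[0]) & (freqs <= cfg.band[1])
    if not sel.any():
        raise ValueError("ALFF band contains no frequency bins")
    vals = amp[:, sel].mean(axis=1)
    alff = np.zeros(run.mask.shape)
    alff[run.mask] = vals
    return AlffMaps(alff=alff, malff=None, mask=run.mask, affine=run.affine,
                    config=cfg)


def normalize_malff(maps: AlffMaps) -> AlffMaps:
    """Spatial normalization of ALFF over the mask.

    Subtractive dialect: ``mALFF = ALFF - mean(ALFF)`` (mask mean of the
    result is zero); divisive dialect: ``ALFF / mean(ALFF)``.
    """
    if not maps.mask.any():
        raise ValueError("mask is empty")
    mean = maps.alff[maps.mask].mean()
    malff = np.zeros_like(maps.alff)
    if maps.config.normalization == "subtractive":
        malff[maps.mask] = maps.alff[maps.mask] - mean
    else:
        if mean == 0:
            raise ValueError("divisive normalization undefined: mask mean ALFF is 0")
        malff[maps.mask] = maps.alff[maps.mask] / mean
    return AlffMaps(
        alff=maps.alff, malff=malff, mask=maps.mask, affine=maps.affine,
        config=maps.config,
    )


def group_map_ttest(
    maps: list[AlffMaps],
    groups,
    cluster_cfg: ClusterConfig = ClusterConfig(),
    restrict_mask: np.ndarray | None = None,
    voxel_size_mm: float | None = None,
) -> tuple[StatMap, pd.DataFrame]:
    """Two-sample t-test on subject mALFF maps with cluster correction.

    With ``restrict_mask`` given, both the test and the Monte-Carlo null run
    inside the restriction (which must be a non-empty subset of the analysis
    mask); otherwise the full analysis mask is used.
    """
    base_mask = maps[0].mask
    if restrict_mask is not None:
        restrict_mask = np.asarray(restrict_mask, dtype=bool)
        if not restrict_mask.any():
            raise ValueError("restriction mask is empty")
        if np.any(restrict_mask & ~base_mask):
            raise ValueError("restriction mask extends outside the analysis mask")
        test_mask = restrict_mask
    else:
        test_mask = base_mask
    stat_inputs = [
        StatMap(
            values=np.nan_to_num(m.malff_map().values),
            stat="beta", df=None, mask=test_mask, affine=m.affine,
        )
        for m in maps
    ]
    tmap = group_ttest2(stat_inputs, groups)
    tmap.provenance["measure"] = "mALFF"
    if voxel_size_mm is None:
        voxel_size_mm = float(
            np.abs(np.linalg.det(maps[0].affine[:3, :3])) ** (1.0 / 3.0)
        )
    null = monte_carlo_cluster_threshold(test_mask, cluster_cfg, voxel_size_mm)
    table = threshold_clusters(tmap, null, cluster_cfg)
    return tmap, table


class AlffGroupTest:
    """Estimator wrapper for the mALFF group comparison.

    ``AlffGroupTest(maps, groups).fit()`` returns an object holding the t
    map and the cluster-corrected table, mirroring the coupling-side
    Model/Results convention.
    """

    def __init__(
        self,
        maps: list[AlffMaps],
        groups,
        cluster_config: ClusterConfig = ClusterConfig(),
        restrict_mask: np.ndarray | None = None,
    ):
        self.maps = maps
        self.groups = groups
        self.cluster_config = cluster_config
        self.restrict_mask = restrict_mask

    def fit(self) -> "AlffGroupResults":
        tmap, table = group_map_ttest(
            self.maps, self.groups, self.cluster_config, self.restrict_mask
        )
        return AlffGroupResults(tmap=tmap, clusters=table)


@dataclass
class AlffGroupResults:
    tmap: StatMap
    clusters: pd.DataFrame

    def summary(self) -> str:
        t = self.tmap.in_mask()
        return "\n".join(
            [
                "mALFF two-sample group comparison",
                "=================================",
                f"groups: {self.tmap.provenance.get('groups')}   "
                f"n: {self.tmap.provenance.get('n')}   df: {self.tmap.df}",
                f"t: min {t.min():+.2f}  max {t.max():+.2f}",
                f"surviving clusters: {len(self.clusters)}",
            ]
        )
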