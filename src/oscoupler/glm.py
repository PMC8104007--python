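"""Voxelwise parametric-modulation GLM linking EEG band power to BOLD.

First level
-----------
The model for each voxel time series :math:`y` is

.. math:: y = X\\beta + \\varepsilon,\\qquad \\varepsilon \\sim AR(1)

where the column of interest in :math:`X` is the canonical double-gamma HRF
convolved with the z-scored per-volume band-power series (a boxcar "eyes
closed" condition parametrically modulated by EEG power reduces to exactly
this column once mean-centered), plus six motion parameters, white-matter
and CSF signals, a DCT high-pass basis for periods above 128 s, and an
intercept.  Serial correlation is handled by a single pooled AR(1)
coefficient estimated from OLS residuals over the analysis mask, followed by
prewhitening of both sides; at ``rho = 0`` the fit equals ordinary least
squares exactly.

Second level
------------
Subject-level interest betas are carried to one-sample t (within-group) and
two-group F contrasts (the undirected "group A >< group B" difference,
:math:`F = t^2` with 1 and :math:`n-2` degrees of freedom).

The model objects follow the estimator/results convention:
``FirstLevelCoupling(run, series).fit()`` returns a
:class:`FirstLevelResults`; ``GroupDifference(maps, labels).fit()`` returns
a :class:`GroupResults` whose ``cluster_table`` applies Monte-Carlo
cluster-extent correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "BoldRun",
    "StatMap",
    "DesignMatrix",
    "GLMConfig",
    "canonical_hrf",
    "build_design",
    "fit_first_level",
    "contrast_t",
    "group_onesample",
    "group_fcontrast",
    "smooth_volume",
    "FirstLevelCoupling",
    "FirstLevelResults",
    "GroupDifference",
    "GroupResults",
]

#: sentinel for t/F statistics with zero residual variance
STAT_CAP = 1e6


# ---------------------------------------------------------------------------
# containers

@dataclass
class BoldRun:
    """A 4D BOLD run in template space plus its confounds."""

    data: np.ndarray        # X x Y x Z x T
    affine: np.ndarray      # 4x4 voxel -> world (mm)
    tr: float
    mask: np.ndarray        # X x Y x Z boolean
    motion: np.ndarray      # T x 6
    wm: np.ndarray          # (T,)
    csf: np.ndarray         # (T,)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match data grid")
        if not self.mask.any():
            raise ValueError("analysis mask is empty")
        T = self.data.shape[3]
        self.motion = np.asarray(self.motion, dtype=np.float64).reshape(T, -1)
        self.wm = np.asarray(self.wm, dtype=np.float64).reshape(T)
        self.csf = np.asarray(self.csf, dtype=np.float64).reshape(T)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> float:
        return float(np.abs(np.linalg.det(self.affine[:3, :3])) ** (1.0 / 3.0))

    def masked_series(self) -> np.ndarray:
        """V x T matrix of in-mask voxel time series."""
        return self.data[self.mask]

    # -- IO ---------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        import nibabel as nib

        nib.Nifti1Image(self.data.astype(np.float32), self.affine).to_filename(
            str(path)
        )

    def save_mask(self, path: str | Path) -> None:
        import nibabel as nib

        nib.Nifti1Image(self.mask.astype(np.uint8), self.affine).to_filename(
            str(path)
        )

    def save_confounds(self, path: str | Path) -> None:
        cols = {f"motion{i+1}": self.motion[:, i] for i in range(self.motion.shape[1])}
        cols["wm"] = self.wm
        cols["csf"] = self.csf
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_files(
        cls,
        bold: str | Path,
        mask: str | Path,
        confounds: str | Path,
        tr: float | None = None,
    ) -> "BoldRun":
        import nibabel as nib

        img = nib.load(str(bold))
        mimg = nib.load(str(mask))
        conf = pd.read_csv(confounds, sep="\t")
        motion = conf[[c for c in conf.columns if c.startswith("motion")]].to_numpy()
        if tr is None:
            tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 2.1
        return cls(
            data=np.asarray(img.dataobj, dtype=np.float64),
            affine=img.affine,
            tr=tr,
            mask=np.asarray(mimg.dataobj) > 0,
            motion=motion,
            wm=conf["wm"].to_numpy(),
            csf=conf["csf"].to_numpy(),
        )


@dataclass
class StatMap:
    """A voxelwise statistic volume: finite inside the mask, NaN outside."""

    values: np.ndarray
    stat: str                      # 't', 'F' or 'beta'
    df: tuple[float, ...] | None
    mask: np.ndarray
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)
    saturated: np.ndarray | None = None  # voxels where the statistic was capped

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        vol = np.full(self.mask.shape, np.nan)
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape == self.mask.shape:
            vol[self.mask] = vals[self.mask]
        elif vals.ndim == 1 and vals.size == int(self.mask.sum()):
            vol[self.mask] = vals
        else:
            raise ValueError("values must be a full volume or an in-mask vector")
        if not np.all(np.isfinite(vol[self.mask])):
            raise ValueError("statistic must be finite inside the mask")
        self.values = vol

    def in_mask(self) -> np.ndarray:
        return self.values[self.mask]

    def save(self, path: str | Path) -> None:
        import json

        import nibabel as nib

        path = Path(path)
        nib.Nifti1Image(
            np.nan_to_num(self.values).astype(np.float32), self.affine
        ).to_filename(str(path))
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz
        meta = {"stat": self.stat, "df": self.df, **self.provenance}
        Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=1, default=str))

    def plot(self, ax=None, **imshow_kw):
        """Quick orthogonal-slice view through the peak voxel."""
        import matplotlib.pyplot as plt

        vol = np.nan_to_num(self.values)
        peak = np.unravel_index(np.argmax(np.abs(vol)), vol.shape)
        fig, axes = plt.subplots(1, 3, figsize=(9, 3))
        for i, axis in enumerate(axes):
            sl = [slice(None)] * 3
            sl[i] = peak[i]
            axis.imshow(vol[tuple(sl)].T, origin="lower", **imshow_kw)
            axis.set_title("xyz"[i] + f"={peak[i]}")
        return fig


# ---------------------------------------------------------------------------
# design

def canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR, normalized to unit peak.

    Response gamma peaks near 5-6 s, the undershoot near 16 s with ratio 6 —
    the standard SPM parameterization.
    """
    t = np.arange(0.0, duration, tr)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    return h / h.max()


def dct_highpass_basis(T: int, tr: float, cutoff: float) -> np.ndarray:
    """DCT-II drift columns for periods longer than ``cutoff`` seconds.

    The k-th basis function has period 2*T*tr/k; columns are mutually
    orthogonal on the sample grid.
    """
    K = int(np.floor(2.0 * T * tr / cutoff))
    t = np.arange(T)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2.0 * T)) for k in range(1, K + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((T, 0))


@dataclass(frozen=True)
class GLMConfig:
    hp_cutoff: float = 128.0   # s
    zscore_modulator: bool = True
    hrf_duration: float = 32.0


@dataclass
class DesignMatrix:
    X: np.ndarray
    names: list[str]
    interest_index: int
    hp_cutoff: float
    degenerate: bool = False

    @property
    def T(self) -> int:
        return self.X.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.names)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    flagged = [n for j, n in enumerate(names) if np.allclose(X[:, j], X[:, j].mean())
               and n != "intercept"]
    Xc = X - X.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.linalg.norm(Xc, axis=0)
        C = (Xc / np.where(norm > 0, norm, 1.0)).T @ (
            Xc / np.where(norm > 0, norm, 1.0)
        )
    for j in range(len(names)):
        for k in range(j + 1, len(names)):
            if abs(C[j, k]) > 0.9999 and norm[j] > 0 and norm[k] > 0:
                flagged.extend([names[j], names[k]])
    return sorted(set(flagged))


def build_design(
    series,
    run: BoldRun,
    cfg: GLMConfig = GLMConfig(),
) -> DesignMatrix:
    """Assemble the first-level design for one band-power regressor.

    ``series`` may be a :class:`~oscoupler.spectral.BandPowerSeries` or a
    plain length-T array.  The modulator is z-scored (unless disabled) and
    convolved with the canonical HRF at TR resolution.
    """
    values = np.asarray(getattr(series, "values", series), dtype=np.float64)
    T = run.n_volumes
    if values.shape != (T,):
        raise ValueError(f"regressor length {values.shape} != n_volumes {T}")

    degenerate = False
    sd = values.std()
    if cfg.zscore_modulator:
        if sd == 0:
            warnings.warn(
                "constant modulator: interest column is all zero (degenerate)",
                stacklevel=2,
            )
            degenerate = True
            mod = np.zeros(T)
        else:
            mod = (values - values.mean()) / sd
    else:
        mod = values
    hrf = canonical_hrf(run.tr, cfg.hrf_duration)
    interest = np.convolve(mod, hrf)[:T]

    def _z(col: np.ndarray) -> np.ndarray:
        s = col.std()
        return (col - col.mean()) / s if s > 0 else col - col.mean()

    confounds = np.column_stack(
        [_z(run.motion[:, i]) for i in range(run.motion.shape[1])]
        + [_z(run.wm), _z(run.csf)]
    )
    dct = dct_highpass_basis(T, run.tr, cfg.hp_cutoff)
    X = np.column_stack([interest, confounds, dct, np.ones(T)])
    names = (
        ["interest"]
        + [f"motion{i+1}" for i in range(run.motion.shape[1])]
        + ["wm", "csf"]
        + [f"dct{k+1}" for k in range(dct.shape[1])]
        + ["intercept"]
    )
    design = DesignMatrix(
        X=X, names=names, interest_index=0, hp_cutoff=cfg.hp_cutoff,
        degenerate=degenerate,
    )
    expected = X.shape[1] - (1 if degenerate else 0)
    if design.rank < expected:
        cols = _collinear_columns(X, names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {cols}")
    return design


# ---------------------------------------------------------------------------
# first-level fit

def _whiten(rho: float, A: np.ndarray) -> np.ndarray:
    """AR(1) prewhitening along axis 0: first row scaled by sqrt(1-rho^2),
    subsequent rows first-differenced with coefficient rho."""
    W = np.empty_like(A)
    W[0] = np.sqrt(1.0 - rho * rho) * A[0]
    W[1:] = A[1:] - rho * A[:-1]
    return W


@dataclass
class FirstLevelResults:
    """Per-voxel GLS estimates of one first-level coupling model."""

    beta: np.ndarray          # P x V
    sigma2: np.ndarray        # (V,)
    xtx_inv: np.ndarray       # P x P (whitened)
    rho: float
    df_resid: int
    design: DesignMatrix
    mask: np.ndarray
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)

    def beta_map(self, name: str = "interest") -> StatMap:
        j = self.design.names.index(name)
        return StatMap(
            values=self.beta[j],
            stat="beta",
            df=None,
            mask=self.mask,
            affine=self.affine,
            provenance={**self.provenance, "column": name, "rho": self.rho},
        )

    def contrast_t(self, c) -> StatMap:
        return contrast_t(self, c)

    def contrast_f(self, c) -> StatMap:
        tmap = contrast_t(self, c)
        vals = np.nan_to_num(tmap.values) ** 2
        return StatMap(
            values=np.minimum(vals, STAT_CAP),
            stat="F",
            df=(1, self.df_resid),
            mask=self.mask,
            affine=self.affine,
            provenance=tmap.provenance,
            saturated=tmap.saturated,
        )

    def tvalues(self) -> StatMap:
        c = np.zeros(len(self.design.names))
        c[self.design.interest_index] = 1.0
        return self.contrast_t(c)

    def summary(self) -> str:
        t = self.tvalues().in_mask()
        b = self.beta[self.design.interest_index]
        lines = [
            "First-level EEG-power coupling GLM",
            "==================================",
            f"volumes: {self.design.T}   regressors: {len(self.design.names)}"
            f"   df_resid: {self.df_resid}",
            f"AR(1) rho (pooled): {self.rho:+.3f}   high-pass: {self.design.hp_cutoff:.0f} s",
            f"mask voxels: {int(self.mask.sum())}",
            f"interest beta: mean {b.mean():+.4f}  sd {b.std():.4f}",
            f"interest t: min {t.min():+.2f}  max {t.max():+.2f}",
        ]
        for k, v in self.provenance.items():
            lines.append(f"{k}: {v}")
        return "\n".join(lines)


def fit_first_level(
    run: BoldRun, design: DesignMatrix, ar1: float | None = None
) -> FirstLevelResults:
    """Fit the voxelwise GLM with pooled-AR(1) prewhitening.

    ``ar1`` forces the serial-correlation coefficient (0 reproduces OLS
    exactly); by default it is estimated from pooled OLS residuals over the
    mask.
    """
    X = design.X
    Y = run.masked_series()  # V x T
    T = X.shape[0]

    if ar1 is None:
        pinv = np.linalg.pinv(X)
        beta_ols = Y @ pinv.T
        resid = Y - beta_ols @ X.T
        denom = float(np.sum(resid**2))
        rho = (
            float(np.sum(resid[:, 1:] * resid[:, :-1])) / denom if denom > 0 else 0.0
        )
        rho = float(np.clip(rho, -0.95, 0.95))
    else:
        rho = float(ar1)
        if not abs(rho) < 1:
            raise ValueError("|ar1| must be < 1")

    Xw = _whiten(rho, X)
    Yw = _whiten(rho, Y.T).T
    rank = int(np.linalg.matrix_rank(Xw))
    if rank < X.shape[1] - (1 if design.degenerate else 0):
        raise ValueError("whitened design is near-singular")
    pinv_w = np.linalg.pinv(Xw)
    beta = (Yw @ pinv_w.T).T  # P x V
    resid_w = Yw - (beta.T @ Xw.T)
    df = T - rank
    sigma2 = np.sum(resid_w**2, axis=1) / df
    xtx_inv = np.linalg.pinv(Xw.T @ Xw)
    return FirstLevelResults(
        beta=beta,
        sigma2=sigma2,
        xtx_inv=xtx_inv,
        rho=rho,
        df_resid=df,
        design=design,
        mask=run.mask,
        affine=run.affine,
    )


def contrast_t(fit: FirstLevelResults, c) -> StatMap:
    """Voxelwise t statistic for contrast vector ``c`` on the whitened fit."""
    c = np.asarray(c, dtype=np.float64)
    if c.shape != (fit.beta.shape[0],):
        raise ValueError(f"contrast length {c.shape} != P {fit.beta.shape[0]}")
    eff = c @ fit.beta
    var_c = float(c @ fit.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(fit.sigma2 * var_c)
        t = eff / se
    saturated_vec = ~np.isfinite(t) & (eff != 0)
    t = np.where(np.isfinite(t), t, np.sign(eff) * STAT_CAP)
    t = np.where(eff == 0, np.where(np.isfinite(se) & (se > 0), t, 0.0), t)
    t = np.clip(t, -STAT_CAP, STAT_CAP)
    sat = np.zeros(fit.mask.shape, dtype=bool)
    sat[fit.mask] = saturated_vec
    if saturated_vec.any():
        warnings.warn(
            f"{int(saturated_vec.sum())} voxels have zero residual variance; "
            "t capped at sentinel",
            stacklevel=2,
        )
    return StatMap(
        values=t,
        stat="t",
        df=(fit.df_resid,),
        mask=fit.mask,
        affine=fit.affine,
        provenance={**fit.provenance, "contrast": c.tolist(), "rho": fit.rho},
        saturated=sat,
    )


# ---------------------------------------------------------------------------
# second level

def _stack_maps(maps: list[StatMap]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(maps) < 2:
        raise ValueError("need at least two subject maps")
    mask = maps[0].mask
    for m in maps[1:]:
        if m.mask.shape != mask.shape or not np.array_equal(m.mask, mask):
            raise ValueError("subject maps must share a common mask")
    data = np.stack([m.in_mask() for m in maps])  # N x V
    return data, mask, maps[0].affine


def group_onesample(maps: list[StatMap]) -> StatMap:
    """Voxelwise one-sample t of subject betas against zero (df = n-1)."""
    data, mask, affine = _stack_maps(maps)
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    sat_vec = (sd == 0) & (mean != 0)
    t = np.where(sd == 0, np.sign(mean) * STAT_CAP, t)
    t = np.clip(t, -STAT_CAP, STAT_CAP)
    sat = np.zeros(mask.shape, dtype=bool)
    sat[mask] = sat_vec
    return StatMap(
        values=t, stat="t", df=(n - 1,), mask=mask, affine=affine,
        provenance={"level": "group", "test": "one-sample", "n": n},
        saturated=sat,
    )


def group_fcontrast(maps: list[StatMap], groups) -> StatMap:
    """Undirected two-group F contrast on subject betas, F(1, n-2) = t^2."""
    data, mask, affine = _stack_maps(maps)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    a = data[groups == levels[0]]
    b = data[groups == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two subjects")
    na, nb = len(a), len(b)
    diff = a.mean(axis=0) - b.mean(axis=0)
    pooled = (
        (na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)
    ) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    t = np.where(pooled == 0, np.sign(diff) * STAT_CAP, t)
    F = np.clip(t**2, 0.0, STAT_CAP)
    sat = np.zeros(mask.shape, dtype=bool)
    sat[mask] = (pooled == 0) & (diff != 0)
    return StatMap(
        values=F, stat="F", df=(1, na + nb - 2), mask=mask, affine=affine,
        provenance={
            "level": "group",
            "test": "two-group F",
            "groups": [str(levels[0]), str(levels[1])],
            "n": [na, nb],
        },
        saturated=sat,
    )


def group_ttest2(maps: list[StatMap], groups) -> StatMap:
    """Directed two-sample t (used for the ALFF group comparison)."""
    data, mask, affine = _stack_maps(maps)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    a, b = data[groups == levels[0]], data[groups == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two subjects")
    na, nb = len(a), len(b)
    diff = a.mean(axis=0) - b.mean(axis=0)
    pooled = (
        (na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)
    ) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    t = np.where(pooled == 0, np.sign(diff) * STAT_CAP, t)
    t = np.clip(t, -STAT_CAP, STAT_CAP)
    return StatMap(
        values=t, stat="t", df=(na + nb - 2,), mask=mask, affine=affine,
        provenance={
            "level": "group",
            "test": "two-sample t",
            "groups": [str(levels[0]), str(levels[1])],
            "n": [na, nb],
        },
    )


# ---------------------------------------------------------------------------
# smoothing

def _fwhm_to_sigma_vox(fwhm_mm: float, voxel_mm: float) -> float:
    return fwhm_mm / (voxel_mm * np.sqrt(8.0 * np.log(2.0)))


def smooth_volume(obj, fwhm: float, mask: np.ndarray | None = None):
    """Gaussian smoothing with the stated FWHM in mm, mask-renormalized.

    Accepts a :class:`BoldRun` (smooths every volume), a :class:`StatMap`,
    or a bare 3D array (then ``mask`` and unit voxel size are assumed unless
    given via a (array, voxel_size) call through :class:`BoldRun`).
    ``fwhm = 0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")

    if isinstance(obj, BoldRun):
        if fwhm == 0:
            return obj
        sig = _fwhm_to_sigma_vox(fwhm, obj.voxel_size)
        m = obj.mask.astype(np.float64)
        sm_mask = ndimage.gaussian_filter(m, sig)
        out = np.zeros_like(obj.data)
        for t in range(obj.n_volumes):
            num = ndimage.gaussian_filter(obj.data[..., t] * m, sig)
            with np.errstate(invalid="ignore", divide="ignore"):
                vol = num / sm_mask
            out[..., t] = np.where(obj.mask, vol, 0.0)
        return BoldRun(
            data=out, affine=obj.affine, tr=obj.tr, mask=obj.mask,
            motion=obj.motion, wm=obj.wm, csf=obj.csf,
        )
    if isinstance(obj, StatMap):
        if fwhm == 0:
            return obj
        voxel = float(np.abs(np.linalg.det(obj.affine[:3, :3])) ** (1 / 3))
        sig = _fwhm_to_sigma_vox(fwhm, voxel)
        m = obj.mask.astype(np.float64)
        sm_mask = ndimage.gaussian_filter(m, sig)
        num = ndimage.gaussian_filter(np.nan_to_num(obj.values) * m, sig)
        with np.errstate(invalid="ignore", divide="ignore"):
            vol = num / sm_mask
        return StatMap(
            values=np.where(obj.mask, vol, np.nan),
            stat=obj.stat, df=obj.df, mask=obj.mask, affine=obj.affine,
            provenance={**obj.provenance, "smoothed_fwhm_mm": fwhm},
        )
    # bare 3D array with voxel size 1 mm
    arr = np.asarray(obj, dtype=np.float64)
    if fwhm == 0:
        return arr
    sig = _fwhm_to_sigma_vox(fwhm, 1.0)
    if mask is None:
        return ndimage.gaussian_filter(arr, sig)
    m = mask.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        vol = ndimage.gaussian_filter(arr * m, sig) / ndimage.gaussian_filter(m, sig)
    return np.where(mask, vol, 0.0)


# ---------------------------------------------------------------------------
# model objects

class FirstLevelCoupling:
    """Estimator for the first-level EEG-power -> BOLD coupling GLM.

    Parameters
    ----------
    run : BoldRun
        The (optionally pre-smoothed) BOLD run.
    series : BandPowerSeries or array
        The per-volume EEG band-power modulator.
    config : GLMConfig
        High-pass cutoff and modulator handling.
    """

    def __init__(self, run: BoldRun, series, config: GLMConfig = GLMConfig()):
        self.run = run
        self.series = series
        self.config = config
        self.design = build_design(series, run, config)

    def fit(self, ar1: float | None = None) -> FirstLevelResults:
        res = fit_first_level(self.run, self.design, ar1=ar1)
        band = getattr(self.series, "band", None)
        res.provenance = {
            "band": getattr(band, "name", None),
            "regressor": getattr(self.series, "kind", None),
        }
        return res


class GroupDifference:
    """Second-level undirected two-group contrast on subject beta maps."""

    def __init__(self, maps: list[StatMap], groups):
        self.maps = maps
        self.groups = np.asarray(groups)

    def fit(self) -> "GroupResults":
        return GroupResults(
            fmap=group_fcontrast(self.maps, self.groups),
            maps=self.maps,
            groups=self.groups,
        )


@dataclass
class GroupResults:
    fmap: StatMap
    maps: list[StatMap]
    groups: np.ndarray

    def cluster_table(self, null, cluster_config) -> pd.DataFrame:
        """Cluster-extent corrected summary (Monte-Carlo null ``null``)."""
        from .cluster import threshold_clusters

        return threshold_clusters(self.fmap, null, cluster_config)

    def summary(self) -> str:
        f = self.fmap.in_mask()
        g = self.fmap.provenance.get("groups")
        n = self.fmap.provenance.get("n")
        return "\n".join(
            [
                "Group coupling difference (undirected F contrast)",
                "=================================================",
                f"groups: {g}   n: {n}   df: {self.fmap.df}",
                f"F: max {f.max():.2f}  median {np.median(f):.2f}",
            ]
        )
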