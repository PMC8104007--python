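"""Per-volume EEG spectra and the two band-power regressor families.

Clean, volume-triggered EEG is cut into one epoch per fMRI volume, each
epoch Fourier-transformed with a 10 % cosine (Tukey) taper at exactly 0.5 Hz
bin spacing, averaged over in-band bins per channel, and reduced to the two
regressors used for coupling analysis:

* **GSP** (global spectral power): per epoch, the root mean square of band
  power across all scalp channels — total oscillatory activity over the
  scalp;
* **regional alpha**: per epoch, the arithmetic mean of alpha-band power
  over the midline parieto-occipital electrodes Oz, POz and Pz.

A 2.1 s epoch at 256 Hz has 537 samples; the spectral estimator uses the
first ``2 s * rate`` samples of each epoch (512 at 256 Hz) so that the bin
spacing is exactly 0.5 Hz with no padding.  A pad-and-average dialect
(zero-pad to 0.25 Hz bins, average adjacent pairs) is available via
``mode="pad"``.  Spectra are stored as absolute amplitude (uV); a squared
(power, uV^2) dialect is one switch — regressors are z-scored downstream,
so the GLM is invariant to this choice up to monotone scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import windows

from .bands import ALPHA, DEFAULT_BANDS, BandDefinition
from .recording import EEGRecording

__all__ = [
    "VolumeEpochSpectra",
    "BandPowerSeries",
    "epoch_by_volume",
    "epoch_spectrum",
    "volume_spectra",
    "band_power",
    "gsp",
    "regional_alpha",
    "REGIONAL_ELECTRODES",
]

REGIONAL_ELECTRODES: tuple[str, ...] = ("Oz", "POz", "Pz")

#: the analyzer's epoch length for 0.5 Hz bins: 2.0 s of samples
SPECTRUM_SECONDS = 2.0


@dataclass
class VolumeEpochSpectra:
    """Per-epoch, per-channel amplitude spectra (epochs x channels x bins)."""

    amplitude: np.ndarray
    freqs: np.ndarray
    labels: list[str]
    epoch_length: float  # s of EEG per volume epoch

    def __post_init__(self) -> None:
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.amplitude.shape[0]

    @property
    def bin_spacing(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class BandPowerSeries:
    """One scalar per volume: a GSP or regional band-power regressor."""

    values: np.ndarray
    band: BandDefinition
    kind: str  # 'GSP' or 'regional'
    electrodes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("band-power series must be one scalar per epoch")
        if np.any(self.values < 0):
            raise ValueError("band power must be non-negative")
        if self.kind not in ("GSP", "regional"):
            raise ValueError("kind must be 'GSP' or 'regional'")

    def __len__(self) -> int:
        return self.values.size

    def zscored(self) -> np.ndarray:
        sd = self.values.std()
        if sd == 0:
            return np.zeros_like(self.values)
        return (self.values - self.values.mean()) / sd


def epoch_by_volume(rec: EEGRecording, tr: float) -> np.ndarray:
    """Cut the recording into one epoch per volume trigger.

    Returns epochs x channels x samples; every epoch is ``tr`` seconds long
    and starts at its trigger.  Raises if the recording ends before the last
    epoch does.
    """
    if rec.triggers.size == 0:
        raise ValueError("recording has no volume triggers")
    length = int(round(tr * rec.rate))
    last_end = rec.triggers[-1] + length
    if last_end > rec.n_samples:
        raise ValueError(
            f"recording truncated: last epoch needs samples up to {last_end}, "
            f"recording has {rec.n_samples}"
        )
    return np.stack([rec.data[:, t : t + length] for t in rec.triggers])


def _taper(n: int, fraction: float = 0.10) -> np.ndarray:
    """Cosine taper over the outer ``fraction`` of samples (half per end)."""
    return windows.tukey(n, alpha=fraction)


def epoch_spectrum(
    epoch: np.ndarray,
    rate: float,
    resolution: float = 0.5,
    mode: str = "truncate",
) -> tuple[np.ndarray, np.ndarray]:
    """Absolute amplitude spectrum of one epoch at the stated resolution.

    ``epoch`` is channels x samples (or a single channel).  With
    ``mode="truncate"`` the first ``1/resolution`` seconds of samples are
    used so bins land exactly on multiples of ``resolution``; ``mode="pad"``
    zero-pads to double length and averages adjacent bin pairs.  Amplitudes
    are scaled so a full-scale unit sinusoid reads ~1 at its bin.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    n_need = int(round(rate / resolution))
    if epoch.shape[-1] < n_need:
        raise ValueError(
            f"epoch too short: need {n_need} samples for {resolution} Hz bins"
        )
    x = epoch[:, :n_need]
    w = _taper(n_need)
    xw = x * w
    if mode == "truncate":
        spec = np.abs(np.fft.rfft(xw, axis=-1))
        freqs = np.fft.rfftfreq(n_need, d=1.0 / rate)
    elif mode == "pad":
        # zero-pad to half-spaced bins, then average each adjacent pair
        spec_fine = np.abs(np.fft.rfft(xw, n=2 * n_need, axis=-1))
        n_bins = n_need // 2  # coarse bins below Nyquist
        paired = 0.5 * (
            spec_fine[:, 0 : 2 * n_bins : 2] + spec_fine[:, 1 : 2 * n_bins : 2]
        )
        spec = np.concatenate([paired, spec_fine[:, [2 * n_bins]]], axis=-1)
        freqs = np.arange(spec.shape[-1]) * resolution
    else:
        raise ValueError("mode must be 'truncate' or 'pad'")
    amp = spec * (2.0 / w.sum())
    return amp, freqs


def volume_spectra(
    rec: EEGRecording,
    tr: float,
    resolution: float = 0.5,
    mode: str = "truncate",
) -> VolumeEpochSpectra:
    """Per-volume amplitude spectra for every channel (scalp + others)."""
    epochs = epoch_by_volume(rec, tr)
    amps = []
    freqs = None
    for ep in epochs:
        amp, freqs = epoch_spectrum(ep, rec.rate, resolution, mode)
        amps.append(amp)
    return VolumeEpochSpectra(
        amplitude=np.stack(amps),
        freqs=freqs,
        labels=list(rec.labels),
        epoch_length=tr,
    )


def band_power(
    spectra: VolumeEpochSpectra,
    band: BandDefinition,
    squared: bool = False,
) -> np.ndarray:
    """Mean absolute spectral value over the band's bins, per epoch/channel.

    Bins with ``lo <= f <= hi`` (inclusive) are averaged.  ``squared``
    switches to power (uV^2) units.
    """
    sel = (spectra.freqs >= band.lo) & (spectra.freqs <= band.hi)
    if not sel.any():
        raise ValueError(
            f"band {band.name} ({band.lo}-{band.hi} Hz) contains no spectral bins"
        )
    vals = spectra.amplitude[..., sel]
    if squared:
        vals = vals**2
    return vals.mean(axis=-1)


def _scalp_columns(spectra: VolumeEpochSpectra) -> np.ndarray:
    keep = [
        i
        for i, lab in enumerate(spectra.labels)
        if not lab.upper().startswith(("ECG", "EKG", "EOG"))
    ]
    return np.asarray(keep, dtype=np.intp)


def gsp(
    spectra: VolumeEpochSpectra,
    band: BandDefinition,
    squared: bool = False,
) -> BandPowerSeries:
    """Global spectral power: per-epoch RMS of band power across channels."""
    bp = band_power(spectra, band, squared)  # epochs x channels
    cols = _scalp_columns(spectra)
    if cols.size < 1:
        raise ValueError("no scalp channels available for GSP")
    values = np.sqrt(np.mean(bp[:, cols] ** 2, axis=1))
    return BandPowerSeries(values=values, band=band, kind="GSP")


def regional_alpha(
    spectra: VolumeEpochSpectra,
    band: BandDefinition = ALPHA,
    electrodes: tuple[str, ...] = REGIONAL_ELECTRODES,
    squared: bool = False,
) -> BandPowerSeries:
    """Regional regressor: mean band power over named electrodes per epoch.

    Defaults to the merged alpha band (8-13 Hz) at Oz, POz and Pz.
    """
    missing = [e for e in electrodes if e not in spectra.labels]
    if missing:
        raise ValueError(f"electrodes not present in the recording: {missing}")
    cols = np.asarray([spectra.labels.index(e) for e in electrodes], dtype=np.intp)
    bp = band_power(spectra, band, squared)
    values = bp[:, cols].mean(axis=1)
    return BandPowerSeries(
        values=values, band=band, kind="regional", electrodes=tuple(electrodes)
    )


def regressor_table(series: list[BandPowerSeries]) -> pd.DataFrame:
    """Audit table: one column per regressor, one row per volume."""
    cols = {}
    for s in series:
        name = f"{s.kind}_{s.band.name}"
        cols[name] = s.values
    return pd.DataFrame(cols)
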