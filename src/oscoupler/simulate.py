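"""Seeded synthetic EEG-fMRI cohorts with known ground-truth coupling.

Every downstream stage of the package (artifact cleaning, spectral
regressors, coupling GLM, cluster inference, ALFF) is exercised against
cohorts produced here, for which the generative truth is known exactly.

The generative model
--------------------
*EEG*: each simulated frequency band is a sinusoidal oscillator whose
amplitude follows a log-normal AR(1) envelope, constant within each fMRI
volume epoch (so per-volume band power is an exact function of the
envelope).  A 1/f background is added per channel, plus -- when enabled --
two in-scanner artifact families: a fixed gradient waveform repeated at
every volume trigger, and a ballistocardiogram template placed at a fixed
delay after each simulated R-peak.  An ECG channel carrying the R-peaks is
appended.

*BOLD*: voxels inside a coupled region carry
``baseline + beta * (HRF (*) z-scored band power)`` in percent-signal units
(baseline 100, so 1 unit == 1 %), on top of a slow drift and stationary
AR(1) noise; voxels in an ALFF region additionally carry low-frequency
(0.01-0.08 Hz) sinusoids whose amplitude is scaled by a group-specific
multiplier.  Motion parameters are smooth random walks and WM/CSF series
low-pass noise; they are returned as confounds but (deliberately) not mixed
into the data -- the analysis treats them as nuisance regressors only.

Defaults reproduce the study conditions: TR 2.1 s, 185 volumes in a
6 min 30 s session, 60-channel EEG at 5 kHz, a 3 mm grid, and a planted
thalamic alpha coupling of 0.8 %/z in one diagnostic group and 0 in the
other.  All randomness derives from ``SimConfig.seed`` via per-subject
``numpy.random.SeedSequence`` spawning, so a seed fully determines a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .recording import EEGRecording, write_eeg
from .glm import BoldRun, canonical_hrf

__all__ = [
    "BandProcess",
    "ArtifactConfig",
    "BoldNoise",
    "Coupling",
    "AlffEffect",
    "GridSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_eeg",
    "simulate_bold",
    "simulate_cohort",
    "cohort_truth",
    "MONTAGE_10_10",
]

# 60-channel 10-10 montage; the midline parieto-occipital trio comes first so
# that reduced-channel simulations always retain the regional-alpha electrodes.
MONTAGE_10_10: tuple[str, ...] = (
    "Oz", "POz", "Pz", "O1", "O2", "PO3", "PO4", "PO7", "PO8",
    "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8",
    "CPz", "CP1", "CP2", "CP3", "CP4", "CP5", "CP6", "TP7", "TP8",
    "Cz", "C1", "C2", "C3", "C4", "C5", "C6", "T7", "T8",
    "FCz", "FC1", "FC2", "FC3", "FC4", "FC5", "FC6", "FT7", "FT8",
    "Fz", "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8",
    "AFz", "AF3", "AF4", "AF7", "AF8", "Fp1", "Fp2",
)

POSTERIOR_CHANNELS = frozenset(
    {"Oz", "POz", "Pz", "O1", "O2", "PO3", "PO4", "PO7", "PO8"}
)


@dataclass(frozen=True)
class BandProcess:
    """One simulated oscillator: carrier frequency + log-normal AR(1) envelope.

    ``mean_power`` is the target mean band power in uV^2 (sinusoid power
    A^2/2 averaged over epochs); ``ar1`` and ``innovation_sd`` parameterize
    the AR(1) process on the log-amplitude.
    """

    freq: float
    mean_power: float
    ar1: float = 0.85
    innovation_sd: float = 0.3


@dataclass(frozen=True)
class ArtifactConfig:
    gradient_amplitude: float = 2000.0  # uV, scale of the per-TR gradient waveform
    gradient_jitter_sd: float = 0.0     # s, per-TR timing jitter of the waveform
    bcg_amplitude: float = 40.0         # uV, ballistocardiogram template scale
    bcg_delay: float = 0.21             # s from R-peak to pulse-artifact onset
    rr_mean: float = 1.0                # s, mean R-R interval
    rr_jitter_sd: float = 0.05          # s, R-R interval jitter


@dataclass(frozen=True)
class BoldNoise:
    ar1: float = 0.3
    sd: float = 1.0              # stationary SD, % of baseline
    drift_amplitude: float = 1.0  # % of baseline


@dataclass(frozen=True)
class Coupling:
    """Planted band-power -> BOLD coupling in one ROI for one group."""

    roi: str
    band: str
    group: str
    beta: float  # % BOLD signal per unit z-scored band power


@dataclass(frozen=True)
class AlffEffect:
    """Group-specific low-frequency amplitude multiplier in one ROI."""

    roi: str
    group: str
    multiplier: float


@dataclass(frozen=True)
class GridSpec:
    """Small MNI-like template grid: cubic voxels, ellipsoidal brain mask,
    named spherical ROIs given in voxel coordinates."""

    shape: tuple[int, int, int] = (20, 20, 18)
    voxel_size: float = 3.0  # mm
    rois: dict = field(
        default_factory=lambda: {
            "thalamus": ((10, 10, 9), 2),
            "occipital": ((10, 4, 8), 2),
            "frontal": ((10, 16, 9), 2),
        }
    )

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = -np.asarray(self.shape) * self.voxel_size / 2.0
        return aff

    def mask(self) -> np.ndarray:
        """Ellipsoidal 'gray-matter' mask with semi-axes 0.45 * shape."""
        idx = np.indices(self.shape)
        center = (np.asarray(self.shape) - 1) / 2.0
        semi = np.asarray(self.shape) * 0.45
        r2 = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
        return r2 <= 1.0

    def roi_mask(self, name: str) -> np.ndarray:
        try:
            center, radius = self.rois[name]
        except KeyError:
            raise KeyError(f"unknown ROI {name!r}; known: {sorted(self.rois)}") from None
        idx = np.indices(self.shape)
        r2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
        return r2 <= radius**2


def _default_bands() -> dict[str, BandProcess]:
    return {
        "delta": BandProcess(freq=2.0, mean_power=8.0),
        "theta": BandProcess(freq=6.0, mean_power=5.0),
        "alpha": BandProcess(freq=9.5, mean_power=20.0),
        "beta": BandProcess(freq=20.0, mean_power=3.0),
    }


@dataclass
class SimConfig:
    """Full description of one synthetic two-group cohort."""

    seed: int = 0
    n_per_group: int = 10
    groups: tuple[str, str] = ("HCS", "MCI")
    tr: float = 2.1
    n_volumes: int = 185
    session_duration: float = 390.0  # s; 6 min 30 s eyes-closed session
    eeg_rate_raw: float = 5000.0
    n_channels: int = 60
    background_sd: float = 3.0  # uV RMS of the 1/f background
    band_envelopes: dict[str, BandProcess] = field(default_factory=_default_bands)
    coupling_table: list[Coupling] = field(
        default_factory=lambda: [
            Coupling("thalamus", "alpha", "HCS", 0.8),
            Coupling("thalamus", "alpha", "MCI", 0.0),
        ]
    )
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    bold_noise: BoldNoise = field(default_factory=BoldNoise)
    alff_rois: list[AlffEffect] = field(
        default_factory=lambda: [
            AlffEffect("thalamus", "MCI", 1.5),
            AlffEffect("thalamus", "HCS", 1.0),
        ]
    )
    alff_base_amplitude: float = 1.0  # % of baseline, per LF sinusoid
    baseline: float = 100.0
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_volumes * self.tr > self.session_duration + 1e-9:
            raise ValueError(
                f"session of {self.session_duration} s too short for "
                f"{self.n_volumes} volumes at TR {self.tr} s"
            )
        if self.n_channels < 1 or self.n_channels > len(MONTAGE_10_10):
            raise ValueError(
                f"n_channels must be in 1..{len(MONTAGE_10_10)}"
            )
        mask = self.grid.mask()
        for name in {c.roi for c in self.coupling_table} | {
            a.roi for a in self.alff_rois
        }:
            roi = self.grid.roi_mask(name)
            if not np.all(mask[roi]):
                raise ValueError(f"ROI {name!r} extends outside the brain mask")
        for c in self.coupling_table:
            if not np.isfinite(c.beta):
                raise ValueError(f"non-finite coupling beta for {c}")
            if c.band not in self.band_envelopes:
                raise ValueError(
                    f"coupling references unsimulated band {c.band!r}"
                )
            if c.group not in self.groups:
                raise ValueError(f"coupling references unknown group {c.group!r}")

    # -- bookkeeping ------------------------------------------------------

    @property
    def labels(self) -> list[str]:
        return list(MONTAGE_10_10[: self.n_channels])

    def subject_ids(self) -> list[str]:
        return [f"sub{i:02d}" for i in range(2 * self.n_per_group)]

    def group_of(self, index: int) -> str:
        return self.groups[0] if index < self.n_per_group else self.groups[1]

    def subject_seed(self, index: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(entropy=self.seed, spawn_key=(index,))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["band_envelopes"] = {
            k: BandProcess(**v) for k, v in raw.get("band_envelopes", {}).items()
        }
        raw["coupling_table"] = [Coupling(**c) for c in raw.get("coupling_table", [])]
        raw["alff_rois"] = [AlffEffect(**a) for a in raw.get("alff_rois", [])]
        raw["artifact"] = ArtifactConfig(**raw["artifact"])
        raw["bold_noise"] = BoldNoise(**raw["bold_noise"])
        grid = raw["grid"]
        grid["shape"] = tuple(grid["shape"])
        grid["rois"] = {
            k: (tuple(v[0]), v[1]) for k, v in grid.get("rois", {}).items()
        }
        raw["grid"] = GridSpec(**grid)
        raw["groups"] = tuple(raw["groups"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Per-subject realized band power and planted effects, keyed by seed."""

    config: SimConfig
    subjects: list[str]
    groups: dict[str, str]                      # subject -> group label
    band_power: dict[str, dict[str, np.ndarray]]  # subject -> band -> (T,)
    betas: dict[str, dict[tuple[str, str], float]]  # subject -> (roi, band) -> beta
    alff_multipliers: dict[str, dict[str, float]]   # subject -> roi -> multiplier

    def roi_mask(self, name: str) -> np.ndarray:
        return self.config.grid.roi_mask(name)


# ---------------------------------------------------------------------------
# envelopes

def _log_ar1(rng: np.random.Generator, n: int, a: float, sd: float) -> np.ndarray:
    """Stationary Gaussian AR(1) on the log scale, exponentiated."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd / np.sqrt(max(1.0 - a * a, 1e-12)))
    innov = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        x[t] = a * x[t - 1] + innov[t - 1]
    return np.exp(x)


def _subject_envelopes(
    config: SimConfig, index: int
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-band (amplitude per epoch, power per epoch), deterministic by seed.

    Amplitudes are scaled so the realized mean sinusoid power A^2/2 equals the
    configured band mean power.
    """
    ss = config.subject_seed(index)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for j, (name, bp) in enumerate(sorted(config.band_envelopes.items())):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(index, 1 + j))
        )
        env = _log_ar1(rng, config.n_volumes, bp.ar1, bp.innovation_sd)
        scale = np.sqrt(2.0 * bp.mean_power / np.mean(env**2))
        amp = env * scale
        out[name] = (amp, amp**2 / 2.0)
    return out


def _one_over_f(rng: np.random.Generator, n: int, rate: float, sd: float) -> np.ndarray:
    """1/f-power background noise with RMS ``sd``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = (np.maximum(f[nz], 0.5)) ** -0.5  # flat below 0.5 Hz
    x = np.fft.irfft(spec * shaping, n=n)
    return x * (sd / np.std(x))


def _gradient_waveform(tau: np.ndarray, tr: float) -> np.ndarray:
    """Continuous gradient-artifact template over one TR (unit scale).

    A sum of harmonics of the slice frequency (30 slices per TR), the
    dominant spectral signature of echo-planar readout in scalp EEG.
    """
    f_slice = 30.0 / tr
    w = np.zeros_like(tau)
    for k, a in enumerate((1.0, 0.6, 0.35, 0.2, 0.12), start=1):
        w += a * np.sin(2 * np.pi * k * f_slice * tau + 0.7 * k)
    return w


def _bcg_template(tau: np.ndarray) -> np.ndarray:
    """Pulse-artifact template: a damped 7 Hz oscillation ~0.4 s long."""
    return np.exp(-(((tau - 0.15) / 0.08) ** 2)) * np.sin(2 * np.pi * 7.0 * tau)


def _qrs_shape(tau: np.ndarray, width: float = 0.012) -> np.ndarray:
    """Mexican-hat QRS complex (unit peak at tau = 0)."""
    u = (tau / width) ** 2
    return (1.0 - u) * np.exp(-u / 2.0)


def _r_peak_times(
    rng: np.random.Generator, duration: float, rr_mean: float, rr_sd: float
) -> np.ndarray:
    times = []
    t = 0.4
    while t < duration - 0.5:
        times.append(t)
        t += max(0.3, rng.normal(rr_mean, rr_sd))
    return np.asarray(times)


def simulate_eeg(config: SimConfig, subject: int | str) -> EEGRecording:
    """Simulate one subject's in-scanner EEG recording.

    Returns a channels x samples uV recording with volume-onset triggers and
    an appended ECG channel.  Identical (config, subject) => identical output.
    """
    index = _subject_index(config, subject)
    rate = config.eeg_rate_raw
    n_samples = int(round(config.session_duration * rate))
    spacing = int(round(config.tr * rate))
    triggers = np.arange(config.n_volumes, dtype=np.int64) * spacing
    if triggers[-1] + spacing > n_samples:
        raise ValueError("recording shorter than n_volumes * tr")

    labels = config.labels
    n_ch = len(labels)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(index, 100))
    )
    envelopes = _subject_envelopes(config, index)

    # per-sample envelope: constant within each volume epoch
    epoch_of_sample = np.minimum(
        np.arange(n_samples) // spacing, config.n_volumes - 1
    )
    t = np.arange(n_samples) / rate
    data = np.zeros((n_ch, n_samples))
    for name, bp in sorted(config.band_envelopes.items()):
        amp_epoch, _ = envelopes[name]
        amp = amp_epoch[epoch_of_sample]
        # per-channel carrier phase: scalp topographies are not spatially
        # phase-coherent, and this keeps the average reference from
        # cancelling the oscillation
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        weights = np.ones(n_ch)
        if name == "alpha":
            for i, lab in enumerate(labels):
                weights[i] = 1.5 if lab in POSTERIOR_CHANNELS else 0.8
        carriers = np.sin(
            2 * np.pi * bp.freq * t[None, :] + phases[:, None]
        )
        data += weights[:, None] * amp[None, :] * carriers
    if config.background_sd > 0:
        for i in range(n_ch):
            data[i] += _one_over_f(rng, n_samples, rate, config.background_sd)

    art = config.artifact
    # ECG channel and R-peaks are generated whenever a BCG is requested, and
    # also with zero-amplitude artifacts so the cleaning chain stays runnable.
    r_times = _r_peak_times(rng, config.session_duration, art.rr_mean, art.rr_jitter_sd)
    ecg = np.zeros(n_samples)
    half = int(0.05 * rate)
    for rt in r_times:
        c = int(round(rt * rate))
        lo, hi = max(0, c - half), min(n_samples, c + half)
        tau = (np.arange(lo, hi) - c) / rate
        ecg[lo:hi] += 800.0 * _qrs_shape(tau)
    ecg += rng.normal(0.0, 5.0, size=n_samples)

    if art.gradient_amplitude > 0:
        gains = rng.uniform(0.5, 1.5, size=n_ch)
        base_tau = np.arange(spacing) / rate
        for k, trig in enumerate(triggers):
            jitter = (
                rng.normal(0.0, art.gradient_jitter_sd)
                if art.gradient_jitter_sd > 0
                else 0.0
            )
            wave = _gradient_waveform(base_tau + jitter, config.tr)
            data[:, trig : trig + spacing] += (
                art.gradient_amplitude * gains[:, None] * wave[None, :]
            )

    if art.bcg_amplitude > 0:
        gains = rng.uniform(0.7, 1.3, size=n_ch)
        wlen = int(0.4 * rate)
        tau_w = np.arange(wlen) / rate
        template = _bcg_template(tau_w)
        for rt in r_times:
            start = int(round((rt + art.bcg_delay) * rate))
            if start < 0 or start + wlen > n_samples:
                continue
            data[:, start : start + wlen] += (
                art.bcg_amplitude * gains[:, None] * template[None, :]
            )

    return EEGRecording(
        data=np.vstack([data, ecg[None, :]]),
        rate=rate,
        labels=[*labels, "ECG"],
        triggers=triggers,
        ecg="ECG",
        history=[{"stage": "simulate_eeg", "seed": config.seed, "subject": index}],
    )


# ---------------------------------------------------------------------------
# BOLD

def _ar1_noise(
    rng: np.random.Generator, shape: tuple[int, ...], rho: float, sd: float
) -> np.ndarray:
    """Stationary AR(1) noise along the last axis with marginal SD ``sd``."""
    if not abs(rho) < 1:
        raise ValueError("AR(1) coefficient must satisfy |rho| < 1")
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    w = rng.normal(0.0, innov_sd, size=shape)
    x = np.empty(shape)
    x[..., 0] = rng.normal(0.0, sd, size=shape[:-1])  # stationary start
    for t in range(1, shape[-1]):
        x[..., t] = rho * x[..., t - 1] + w[..., t]
    return x


def simulate_bold(
    config: SimConfig, truth: GroundTruth, subject: int | str
) -> BoldRun:
    """Simulate one subject's 4D BOLD run on the template grid."""
    index = _subject_index(config, subject)
    sid = config.subject_ids()[index]
    group = config.group_of(index)
    grid = config.grid
    mask = grid.mask()
    T = config.n_volumes
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(index, 200))
    )

    n_vox = int(mask.sum())
    noise_cfg = config.bold_noise
    series = np.full((n_vox, T), config.baseline)

    if noise_cfg.drift_amplitude > 0:
        t_norm = np.linspace(-1.0, 1.0, T)
        slow = np.cos(np.pi * t_norm)
        coeffs = rng.uniform(-1.0, 1.0, size=(n_vox, 2)) * noise_cfg.drift_amplitude
        series += coeffs[:, :1] * t_norm[None, :] + coeffs[:, 1:] * slow[None, :]
    if noise_cfg.sd > 0:
        series += _ar1_noise(rng, (n_vox, T), noise_cfg.ar1, noise_cfg.sd)

    flat_mask = mask.reshape(-1)
    voxel_index = np.full(flat_mask.size, -1, dtype=np.int64)
    voxel_index[flat_mask] = np.arange(n_vox)

    hrf = canonical_hrf(config.tr)
    for c in config.coupling_table:
        if c.group != group or c.beta == 0.0:
            continue
        power = truth.band_power[sid][c.band]
        z = (power - power.mean()) / power.std()
        reg = np.convolve(z, hrf)[:T]
        rows = voxel_index[grid.roi_mask(c.roi).reshape(-1)]
        series[rows] += c.beta * reg[None, :]

    t_s = np.arange(T) * config.tr
    for a in config.alff_rois:
        if a.group != group:
            continue
        rows = voxel_index[grid.roi_mask(a.roi).reshape(-1)]
        lf = config.alff_base_amplitude * a.multiplier * (
            np.sin(2 * np.pi * 0.04 * t_s + rng.uniform(0, 2 * np.pi))
            + 0.6 * np.sin(2 * np.pi * 0.025 * t_s + rng.uniform(0, 2 * np.pi))
        )
        series[rows] += lf[None, :]

    data = np.zeros((*grid.shape, T))
    data[mask] = series

    from scipy.ndimage import gaussian_filter1d

    motion = gaussian_filter1d(
        np.cumsum(rng.normal(0.0, 0.02, size=(T, 6)), axis=0), 3.0, axis=0
    )
    wm = 70.0 + 0.5 * gaussian_filter1d(rng.standard_normal(T), 4.0)
    csf = 30.0 + 0.5 * gaussian_filter1d(rng.standard_normal(T), 4.0)

    return BoldRun(
        data=data,
        affine=grid.affine,
        tr=config.tr,
        mask=mask,
        motion=motion,
        wm=wm,
        csf=csf,
    )


# ---------------------------------------------------------------------------
# cohort

def _subject_index(config: SimConfig, subject: int | str) -> int:
    if isinstance(subject, str):
        ids = config.subject_ids()
        try:
            return ids.index(subject)
        except ValueError:
            raise KeyError(f"unknown subject {subject!r}") from None
    index = int(subject)
    if not 0 <= index < 2 * config.n_per_group:
        raise IndexError(f"subject index {index} out of range")
    return index


def cohort_truth(config: SimConfig) -> GroundTruth:
    """Realize the cohort-level ground truth (band power, betas, ROIs)."""
    subjects = config.subject_ids()
    groups = {sid: config.group_of(i) for i, sid in enumerate(subjects)}
    band_power: dict[str, dict[str, np.ndarray]] = {}
    betas: dict[str, dict[tuple[str, str], float]] = {}
    alff_mult: dict[str, dict[str, float]] = {}
    for i, sid in enumerate(subjects):
        env = _subject_envelopes(config, i)
        band_power[sid] = {name: power for name, (_, power) in env.items()}
        betas[sid] = {
            (c.roi, c.band): c.beta
            for c in config.coupling_table
            if c.group == groups[sid]
        }
        alff_mult[sid] = {
            a.roi: a.multiplier
            for a in config.alff_rois
            if a.group == groups[sid]
        }
    return GroundTruth(
        config=config,
        subjects=subjects,
        groups=groups,
        band_power=band_power,
        betas=betas,
        alff_multipliers=alff_mult,
    )


@dataclass
class SimulatedSubject:
    subject_id: str
    group: str
    bold: BoldRun
    eeg: EEGRecording | None = None


def simulate_cohort(
    config: SimConfig,
    include_eeg: bool = False,
    out_dir: str | Path | None = None,
) -> tuple[list[SimulatedSubject], pd.DataFrame, GroundTruth]:
    """Simulate a full two-group cohort.

    Returns the subject list, the group/covariate table and the ground truth.
    With ``out_dir`` set, writes per-subject NIfTI + confound TSV (+ EEG pair
    when ``include_eeg``), the analysis mask and ``participants.tsv``.
    """
    if config.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 for group statistics")
    truth = cohort_truth(config)
    amyloid_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(999,))
    )
    rows = []
    subjects = []
    for i, sid in enumerate(truth.subjects):
        group = truth.groups[sid]
        bold = simulate_bold(config, truth, i)
        eeg = simulate_eeg(config, i) if include_eeg else None
        subjects.append(SimulatedSubject(sid, group, bold, eeg))
        # amyloid positivity: more prevalent in the patient group, as in
        # typical MCI cohorts (~30 % of controls, ~45 % of patients)
        p_pos = 0.3 if group == config.groups[0] else 0.45
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "amyloid": "PiB+" if amyloid_rng.random() < p_pos else "PiB-",
            }
        )
    table = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "participants.tsv", sep="\t", index=False)
        config.to_yaml(out / "sim_config.yaml")
        first = subjects[0].bold
        first.save_mask(out / "mask.nii.gz")
        for sub in subjects:
            sub.bold.save(out / f"{sub.subject_id}_bold.nii.gz")
            sub.bold.save_confounds(out / f"{sub.subject_id}_confounds.tsv")
            if sub.eeg is not None:
                write_eeg(sub.eeg, out / f"{sub.subject_id}_eeg")
    return subjects, table, truth
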