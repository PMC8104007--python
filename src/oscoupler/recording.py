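"""In-scanner EEG recording container and its on-disk format.

An :class:`EEGRecording` holds a channels x samples microvolt array together
with the metadata every cleaning stage needs: sampling rate, channel labels
(10-10 convention), fMRI volume-onset trigger sample indices and the name of
the ECG channel.  ``history`` is an append-only audit trail: each processing
stage records its name and parameters so a cleaned file documents how it was
produced.

On disk a recording is a two-file pair: ``<stem>.tsv`` holding the
samples x channels matrix (tab-separated, header row of labels) and
``<stem>.json`` holding rate, labels, trigger indices, ECG channel name and
history.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EEGRecording", "read_eeg", "write_eeg"]


@dataclass
class EEGRecording:
    data: np.ndarray          # channels x samples, microvolts
    rate: float               # Hz
    labels: list[str]
    triggers: np.ndarray      # volume-onset sample indices, strictly increasing
    ecg: str | None = None    # label of the ECG channel, if recorded
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.triggers = np.asarray(self.triggers, dtype=np.int64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.triggers.size and not np.all(np.diff(self.triggers) > 0):
            raise ValueError("trigger indices must be strictly increasing")
        if self.triggers.size and (
            self.triggers[0] < 0 or self.triggers[-1] >= self.data.shape[1]
        ):
            raise ValueError("trigger index outside the recording")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG samples must be finite")
        if self.ecg is not None and self.ecg not in self.labels:
            raise ValueError(f"ECG channel {self.ecg!r} not among labels")

    # -- convenience ------------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's series by label."""
        try:
            return self.data[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def scalp_channels(self, exclude: set[str] | None = None) -> list[int]:
        """Indices of scalp channels (ECG and EOG-like channels excluded)."""
        skip = set(exclude or ())
        if self.ecg is not None:
            skip.add(self.ecg)
        return [
            i
            for i, lab in enumerate(self.labels)
            if lab not in skip and not lab.upper().startswith(("EOG", "ECG", "EKG"))
        ]

    def with_history(self, stage: str, **params) -> "EEGRecording":
        """Copy with one audit entry appended (data shared, not copied)."""
        entry = {"stage": stage, **params}
        return replace(self, history=[*self.history, entry])

    def trigger_spacing(self) -> float:
        """Median trigger-to-trigger spacing in samples."""
        if self.triggers.size < 2:
            raise ValueError("need at least two triggers")
        return float(np.median(np.diff(self.triggers)))


def write_eeg(rec: EEGRecording, stem: str | Path) -> tuple[Path, Path]:
    """Write a recording as the ``<stem>.tsv`` + ``<stem>.json`` pair."""
    stem = Path(stem)
    tsv = stem.with_suffix(".tsv")
    meta = stem.with_suffix(".json")
    df = pd.DataFrame(rec.data.T, columns=rec.labels)
    df.to_csv(tsv, sep="\t", index=False, float_format="%.6g")
    meta.write_text(
        json.dumps(
            {
                "rate": rec.rate,
                "labels": rec.labels,
                "triggers": rec.triggers.tolist(),
                "ecg": rec.ecg,
                "history": rec.history,
            },
            indent=1,
        )
    )
    return tsv, meta


def read_eeg(stem: str | Path) -> EEGRecording:
    """Read a recording written by :func:`write_eeg`."""
    stem = Path(stem)
    tsv = stem.with_suffix(".tsv")
    meta = json.loads(stem.with_suffix(".json").read_text())
    df = pd.read_csv(tsv, sep="\t")
    if list(df.columns) != meta["labels"]:
        raise ValueError(f"label mismatch between {tsv} and its sidecar")
    return EEGRecording(
        data=df.to_numpy().T,
        rate=float(meta["rate"]),
        labels=list(meta["labels"]),
        triggers=np.asarray(meta["triggers"], dtype=np.int64),
        ecg=meta.get("ecg"),
        history=list(meta.get("history", [])),
    )
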