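"""Core data containers and plain-text I/O.

EEG recordings are channels x samples matrices with a sampling rate and
unique channel labels; clinical covariates live in a flat record per
patient. Signals are serialized as TSV with a small ``#``-prefixed header
so files stay diff-able and language-neutral.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: the three clinician-assigned disease states, in fixed class order
STATES = ("calm", "transitional", "morbidity")

CLINICAL_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "hypertension",
    "hyperlipidemia",
    "diabetes",
    "eye_movement",
    "label",
)


class FormatError(ValueError):
    """Raised when a signal or table file cannot be parsed."""


@dataclass
class EEGRecording:
    """A multichannel EEG epoch.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        Unique electrode names (10-20 convention, e.g. ``Fp1``).
    state : str or None
        Optional disease-state label, one of ``calm``, ``transitional``,
        ``morbidity``.
    subject_id : str or None
        Optional subject identifier, so subject-level splits are possible.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    state: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        n_ch, n_s = self.data.shape
        if n_ch < 1:
            raise ValueError("need at least one channel")
        if n_s < 2:
            raise ValueError("need at least two samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal contains non-finite values")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if len(self.channel_labels) != n_ch:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {n_ch} channels"
            )
        if len(set(self.channel_labels)) != n_ch:
            raise ValueError("channel labels must be unique")
        if self.state is not None and self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D series for a named channel."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown channel {label!r}; have {self.channel_labels}"
            ) from None
        return self.data[idx]

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        return replace(self, data=data)


@dataclass
class ClinicalRecord:
    """Per-patient clinical covariates with the disease-state label."""

    age: float
    sex: str
    hypertension: int
    hyperlipidemia: int
    diabetes: int
    eye_movement: float
    label: str
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if not 40 <= self.age <= 100:
            raise ValueError(f"age {self.age} outside [40, 100]")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        for name in ("hypertension", "hyperlipidemia", "diabetes"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {v}")
        if self.label not in STATES:
            raise ValueError(f"label must be one of {STATES}")


def write_recording(path: str | os.PathLike, recording: EEGRecording) -> None:
    """Write a recording as TSV: 2-3 ``#`` header lines, one row per channel."""
    with open(path, "w") as fh:
        fh.write(f"#fs\t{recording.fs!r}\n")
        fh.write("#channels\t" + "\t".join(recording.channel_labels) + "\n")
        if recording.state is not None:
            fh.write(f"#state\t{recording.state}\n")
        for row in recording.data:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_recording(path: str | os.PathLike) -> EEGRecording:
    """Read a recording written by :func:`write_recording`.

    Raises
    ------
    FormatError
        Naming the offending line for malformed input.
    """
    fs = None
    labels = None
    state = None
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(ln.strip() for ln in lines):
        raise FormatError(f"{path}: empty file")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line.split("\t")
            key = parts[0][1:]
            if key == "fs":
                try:
                    fs = float(parts[1])
                except (IndexError, ValueError):
                    raise FormatError(f"{path}:{lineno}: bad #fs line") from None
            elif key == "channels":
                labels = parts[1:]
            elif key == "state":
                state = parts[1] if len(parts) > 1 else None
            else:
                raise FormatError(f"{path}:{lineno}: unknown header {key!r}")
            continue
        try:
            rows.append([float(v) for v in line.split("\t")])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric data") from None
    if fs is None:
        raise FormatError(f"{path}: missing #fs header")
    if labels is None:
        raise FormatError(f"{path}: missing #channels header")
    if not rows:
        raise FormatError(f"{path}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    try:
        return EEGRecording(np.array(rows), fs, labels, state=state)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def clinical_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Tabulate clinical records with the fixed column order."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "age": r.age,
                "sex": r.sex,
                "hypertension": r.hypertension,
                "hyperlipidemia": r.hyperlipidemia,
                "diabetes": r.diabetes,
                "eye_movement": r.eye_movement,
                "label": r.label,
            }
            for r in records
        ],
        columns=list(CLINICAL_COLUMNS),
    )


def frame_to_clinical(frame: pd.DataFrame) -> list[ClinicalRecord]:
    missing = set(CLINICAL_COLUMNS) - {"subject_id"} - set(frame.columns)
    if missing:
        raise FormatError(f"clinical table missing columns {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        out.append(
            ClinicalRecord(
                age=float(row["age"]),
                sex=str(row["sex"]),
                hypertension=int(row["hypertension"]),
                hyperlipidemia=int(row["hyperlipidemia"]),
                diabetes=int(row["diabetes"]),
                eye_movement=float(row["eye_movement"]),
                label=str(row["label"]),
                subject_id=None
                if "subject_id" not in frame.columns or pd.isna(row["subject_id"])
                else str(row["subject_id"]),
            )
        )
    return out


def write_clinical(path: str | os.PathLike, records: list[ClinicalRecord]) -> None:
    clinical_to_frame(records).to_csv(path, index=False)


def read_clinical(path: str | os.PathLike) -> list[ClinicalRecord]:
    return frame_to_clinical(pd.read_csv(path))


def read_edf(path: str | os.PathLike, state: str | None = None) -> EEGRecording:
    """Import an EDF file as an :class:`EEGRecording` (requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF import requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(os.fspath(path), preload=True, verbose="error")
    return EEGRecording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        state=state,
    )
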