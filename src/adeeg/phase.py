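"""Instantaneous phase and the phase-locking value (PLV).

The PLV between two channels is the modulus of the time-averaged unit
phasor of their phase difference::

    PLV = | (1/N) * sum_j exp(i * (phi_x(j) - phi_y(j))) |

It is 1 for perfectly locked phases (any constant offset) and decays to
the finite-sample noise floor ~ sqrt(pi)/(2*sqrt(N)) for independent
phases. Phase is extracted by zero-phase band-pass filtering (4th-order
Butterworth, forward-backward) followed by the analytic-signal angle via
the Hilbert transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import EEGRecording


@dataclass
class PhaseSeries:
    """Instantaneous phase of one channel, wrapped to (-pi, pi]."""

    phase: np.ndarray
    fs: float
    source_channel: str = ""

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 1:
            raise ValueError("phase must be 1-D")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase contains non-finite values")
        if np.any(self.phase <= -np.pi) or np.any(self.phase > np.pi):
            raise ValueError("phase must be wrapped to (-pi, pi]")

    def __len__(self) -> int:
        return self.phase.size


@dataclass
class PLVMatrix:
    """Symmetric pairwise phase-locking matrix; the weighted adjacency of
    the functional-connectivity network."""

    values: np.ndarray
    n_samples_used: int
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLV matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("PLV matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("PLV diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("PLV entries must lie in [0, 1]")
        if len(self.channel_labels) != v.shape[0]:
            raise ValueError("label count disagrees with matrix size")
        self.values = v
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi] (note the closed upper end)."""
    wrapped = np.mod(phi + np.pi, 2 * np.pi) - np.pi
    wrapped[wrapped == -np.pi] = np.pi
    return wrapped


def instantaneous_phase(
    recording: EEGRecording,
    channel: str,
    band: tuple[float, float] = (8.0, 30.0),
) -> PhaseSeries:
    """Band-pass a channel and take the analytic-signal angle.

    An all-zero (or constant) channel yields an all-zero phase rather than
    NaN: the analytic signal of the zero series is zero and its angle is
    defined as 0 here.
    """
    lo, hi = band
    if not 0 < lo < hi < recording.fs / 2:
        raise ValueError(
            f"band {band} must lie strictly inside (0, {recording.fs / 2}) Hz"
        )
    x = recording.channel(channel)
    order = 4
    if x.size < 8 * order:
        raise ValueError(f"series too short: need >= {8 * order} samples")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=recording.fs,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, x - x.mean())
    analytic = sps.hilbert(filtered)
    phi = np.where(np.abs(analytic) == 0.0, 0.0, np.angle(analytic))
    return PhaseSeries(_wrap_phase(phi), recording.fs, source_channel=channel)


def plv_pair(phase_x: PhaseSeries, phase_y: PhaseSeries,
             trim_edges: bool = False) -> float:
    """PLV of two phase series: modulus of the mean difference phasor.

    With ``trim_edges`` the first and last 5% of samples are dropped
    before averaging, limiting band-pass filter transients.
    """
    if len(phase_x) != len(phase_y):
        raise ValueError(
            f"length mismatch: {len(phase_x)} vs {len(phase_y)}"
        )
    if phase_x.fs != phase_y.fs:
        raise ValueError("sampling rates differ")
    dphi = phase_x.phase - phase_y.phase
    if trim_edges:
        cut = int(0.05 * dphi.size)
        if cut:
            dphi = dphi[cut:-cut]
    return float(np.abs(np.exp(1j * dphi).mean()))


def plv_matrix(
    recording: EEGRecording,
    band: tuple[float, float] = (8.0, 30.0),
    trim_edges: bool = False,
) -> PLVMatrix:
    """All-pairs PLV of a recording within a band."""
    if recording.n_channels < 2:
        raise ValueError("need at least two channels for a PLV matrix")
    phases = []
    for label in recording.channel_labels:
        try:
            phases.append(instantaneous_phase(recording, label, band))
        except ValueError as exc:
            raise ValueError(f"channel {label!r}: {exc}") from exc
    n = recording.n_channels
    values = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            values[a, b] = values[b, a] = plv_pair(
                phases[a], phases[b], trim_edges=trim_edges
            )
    return PLVMatrix(values, n_samples_used=recording.n_samples,
                     channel_labels=recording.channel_labels)


def sliding_plv_pair(
    phase_x: PhaseSeries,
    phase_y: PhaseSeries,
    window: int,
    step: int,
) -> np.ndarray:
    """Exploratory sliding-window PLV (window/step in samples)."""
    if window < 2 or step < 1:
        raise ValueError("window must be >= 2 and step >= 1")
    if len(phase_x) != len(phase_y):
        raise ValueError("length mismatch")
    dphi = phase_x.phase - phase_y.phase
    starts = range(0, dphi.size - window + 1, step)
    return np.array(
        [np.abs(np.exp(1j * dphi[s:s + window]).mean()) for s in starts]
    )


def write_plv(path, plv: PLVMatrix) -> None:
    """Write a PLV matrix as labeled TSV."""
    with open(path, "w") as fh:
        fh.write("#n_samples\t%d\n" % plv.n_samples_used)
        fh.write("\t" + "\t".join(plv.channel_labels) + "\n")
        for label, row in zip(plv.channel_labels, plv.values):
            fh.write(label + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_plv(path) -> PLVMatrix:
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    n_samples = 0
    if lines and lines[0].startswith("#n_samples"):
        n_samples = int(lines[0].split("\t")[1])
        lines = lines[1:]
    labels = lines[0].split("\t")[1:]
    rows = [[float(v) for v in ln.split("\t")[1:]] for ln in lines[1:]]
    return PLVMatrix(np.array(rows), n_samples, tuple(labels))
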