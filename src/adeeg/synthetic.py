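"""Synthetic multichannel EEG and clinical tables with known ground truth.

The generator emulates the study conditions downstream stages are built
for: 8-30 Hz band-limited oscillations with controllable pairwise phase
coupling, three disease-state amplitude regimes of increasing amplitude
and volatility (calm < transitional < morbidity), 1,000 samples per
period, and a clinical covariate table in which age, diabetes and the
eye-movement score carry real class effects while sex, hypertension and
hyperlipidemia are label-independent.

Coupling model
--------------
Each channel's instantaneous phase is a convex mixture of an independent
phase random walk and a phase walk shared within its coupling group::

    phi_i(t) = 2*pi*f0*t + (1 - k_i) * u_i(t) + k_i * s_g(t) + theta_i

where ``k_i`` is the channel's strongest pairwise coupling and the groups
are the connected components of the coupling matrix. The signal is an
amplitude-modulated cosine of that phase plus white noise, band-passed to
the requested band. Coupling near 1 freezes the pairwise phase difference
(PLV -> 1); coupling 0 lets the phase difference diffuse across many
cycles (PLV -> the finite-sample noise floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.sparse.csgraph import connected_components

from .recording import STATES, ClinicalRecord, EEGRecording

#: per-sample std (radians) of the phase random walks; sets both how fast
#: uncoupled phases decorrelate and the intrinsic bandwidth of each channel
PHASE_WALK_STD = 0.35

#: default electrode names; the first four are the representative frontal set
DEFAULT_CHANNELS = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz", "Oz",
)


@dataclass(frozen=True)
class AmplitudeProfile:
    """Per-state envelope parameters.

    gain
        Baseline envelope amplitude (microvolts).
    volatility
        Relative depth of the slow stochastic amplitude modulation.
    """

    gain: float
    volatility: float


#: the three disease-state regimes: amplitude and its volatility both grow
#: from the calm period through the transitional period to morbidity
DEFAULT_PROFILES: dict[str, AmplitudeProfile] = {
    "calm": AmplitudeProfile(gain=1.0, volatility=0.1),
    "transitional": AmplitudeProfile(gain=2.0, volatility=0.3),
    "morbidity": AmplitudeProfile(gain=4.0, volatility=0.6),
}

#: additive sensor-noise std in microvolts, independent of the state gain
NOISE_STD = 0.3

#: per-state multiplier on the off-diagonal coupling: phase synchrony
#: degrades as the disease progresses, so the PLV network and the spatial
#: covariance structure carry class information alongside amplitude
DEFAULT_COUPLING_SCALE: dict[str, float] = {
    "calm": 1.0,
    "transitional": 0.6,
    "morbidity": 0.3,
}


@dataclass
class CouplingSpec:
    """Ground-truth pairwise phase-coupling structure.

    kappa
        Symmetric (n_channels, n_channels) matrix of coupling strengths in
        [0, 1] with unit diagonal. Off-diagonal 0 = independent phases,
        near 1 = locked phases.
    band
        (low, high) passband in Hz.
    profiles
        Mapping state -> :class:`AmplitudeProfile`.
    """

    kappa: np.ndarray
    band: tuple[float, float] = (8.0, 30.0)
    profiles: dict[str, AmplitudeProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        k = self.kappa
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError("kappa must be square")
        if not np.allclose(k, k.T):
            raise ValueError("kappa must be symmetric")
        if not np.allclose(np.diag(k), 1.0):
            raise ValueError("kappa diagonal must be 1")
        if k.min() < 0 or k.max() > 1 + 1e-12:
            raise ValueError("kappa entries must lie in [0, 1]")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < low < high")

    @property
    def n_channels(self) -> int:
        return self.kappa.shape[0]


def default_coupling(n_channels: int = 4) -> CouplingSpec:
    """Default coupling: a strongly coupled Fp2/F3/F4-style clique with the
    first channel only weakly attached (one loosely connected frontal site)."""
    k = np.zeros((n_channels, n_channels))
    np.fill_diagonal(k, 1.0)
    if n_channels >= 2:
        core = slice(1, n_channels)
        k[core, core] = 0.8
        np.fill_diagonal(k, 1.0)
        k[0, 1:] = k[1:, 0] = 0.2
    return CouplingSpec(kappa=k)


def _channel_names(n_channels: int) -> tuple[str, ...]:
    if n_channels <= len(DEFAULT_CHANNELS):
        return DEFAULT_CHANNELS[:n_channels]
    extra = tuple(
        f"ch{i:02d}" for i in range(len(DEFAULT_CHANNELS), n_channels)
    )
    return DEFAULT_CHANNELS + extra


def _smooth_envelope(rng: np.random.Generator, n: int, fs: float,
                     profile: AmplitudeProfile) -> np.ndarray:
    """Slow positive envelope: gain * (1 + volatility * smoothed noise)."""
    width = max(int(round(fs / 4)), 1)
    raw = rng.standard_normal(n + width)
    kernel = np.hanning(width + 2)[1:-1]
    kernel /= np.linalg.norm(kernel)
    slow = np.convolve(raw, kernel, mode="same")[:n]
    env = profile.gain * (1.0 + profile.volatility * slow)
    return np.clip(env, 0.1 * profile.gain, None)


def generate_coupled_recording(
    spec: CouplingSpec,
    n_samples: int = 1000,
    fs: float = 128.0,
    seed: int | np.random.SeedSequence = 0,
    state: str | None = None,
    channel_labels: tuple[str, ...] | None = None,
) -> EEGRecording:
    """Simulate one band-limited recording with the given coupling.

    Deterministic given ``seed``. ``state`` selects the amplitude regime
    (default: the calm profile).
    """
    if n_samples < 64:
        raise ValueError("n_samples must be at least 64")
    lo, hi = spec.band
    if hi >= fs / 2:
        raise ValueError(
            f"band high {hi} Hz at or above Nyquist ({fs / 2} Hz); "
            "raise fs or lower the band"
        )
    n_ch = spec.n_channels
    labels = channel_labels or _channel_names(n_ch)
    profile = spec.profiles[state or "calm"]
    rng = np.random.default_rng(seed)

    f0 = 0.5 * (lo + hi)
    t = np.arange(n_samples) / fs
    ramp = 2 * np.pi * f0 * t

    # coupling groups: connected components of the off-diagonal support
    offdiag = spec.kappa.copy()
    np.fill_diagonal(offdiag, 0.0)
    n_comp, comp = connected_components(offdiag > 0, directed=False)
    shared = {
        g: np.cumsum(rng.normal(0.0, PHASE_WALK_STD, n_samples))
        for g in range(n_comp)
    }
    # per-channel effective coupling = strongest pairwise coupling
    k_eff = offdiag.max(axis=1) if n_ch > 1 else np.zeros(1)

    data = np.empty((n_ch, n_samples))
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    for i in range(n_ch):
        own = np.cumsum(rng.normal(0.0, PHASE_WALK_STD, n_samples))
        theta0 = rng.uniform(-np.pi, np.pi)
        phase = ramp + (1.0 - k_eff[i]) * own + k_eff[i] * shared[comp[i]] + theta0
        env = _smooth_envelope(rng, n_samples, fs, profile)
        x = env * np.cos(phase) + rng.normal(0.0, NOISE_STD, n_samples)
        data[i] = sps.sosfiltfilt(sos, x)
    return EEGRecording(data, fs, labels, state=state)


def generate_state_dataset(
    n_per_state: int,
    n_channels: int = 4,
    n_samples: int = 1000,
    fs: float = 128.0,
    seed: int = 0,
    coupling: CouplingSpec | None = None,
    coupling_scale: dict[str, float] | None = None,
) -> list[EEGRecording]:
    """Balanced labeled recordings across the three disease states.

    Each state scales the base coupling's off-diagonal by
    ``coupling_scale`` (default: synchrony weakens with disease
    progression) in addition to its amplitude regime. Returns
    ``3 * n_per_state`` recordings ordered state-major (all calm, all
    transitional, all morbidity), each with a unique ``subject_id`` and
    reproducible from ``seed``.
    """
    if n_per_state < 1:
        raise ValueError("n_per_state must be >= 1")
    spec = coupling or default_coupling(n_channels)
    if spec.n_channels != n_channels:
        raise ValueError("coupling spec size disagrees with n_channels")
    scale = dict(DEFAULT_COUPLING_SCALE)
    scale.update(coupling_scale or {})
    per_state_spec = {}
    for state in STATES:
        k = spec.kappa * scale[state]
        np.fill_diagonal(k, 1.0)
        per_state_spec[state] = CouplingSpec(
            kappa=k, band=spec.band, profiles=spec.profiles
        )
    root = np.random.SeedSequence(seed)
    children = root.spawn(3 * n_per_state)
    out: list[EEGRecording] = []
    idx = 0
    for state in STATES:
        for j in range(n_per_state):
            rec = generate_coupled_recording(
                per_state_spec[state], n_samples=n_samples, fs=fs,
                seed=children[idx], state=state,
            )
            rec.subject_id = f"{state}-{j:03d}"
            out.append(rec)
            idx += 1
    return out


#: default injected class effects: Cohen's d per state step for continuous
#: features, risk difference per state step for binary ones
DEFAULT_EFFECTS: dict[str, float] = {
    "age": 1.0,
    "diabetes": 0.3,
    "eye_movement": 1.0,
}

_CONTINUOUS = {"age": (62.0, 6.0), "eye_movement": (50.0, 10.0)}
_BINARY_BASE = {"hypertension": 0.4, "hyperlipidemia": 0.35, "diabetes": 0.2}


def generate_clinical_table(
    n_patients: int,
    effects: dict[str, float] | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[ClinicalRecord]:
    """Clinical covariates with injected class effects.

    Features named in ``effects`` shift monotonically across the state
    order (continuous: ``effect`` standard deviations per step; binary:
    ``effect`` added to the event rate per step); all other features are
    drawn independently of the label. Defaults make age, diabetes and
    eye_movement real effects and sex, hypertension, hyperlipidemia null.
    """
    if n_patients < 10:
        raise ValueError("n_patients must be >= 10")
    eff = dict(DEFAULT_EFFECTS) if effects is None else dict(effects)
    known = set(_CONTINUOUS) | set(_BINARY_BASE)
    unknown = set(eff) - known
    if unknown:
        raise ValueError(f"unknown feature(s) in effects: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    base, rem = divmod(n_patients, 3)
    counts = [base + (1 if i < rem else 0) for i in range(3)]
    records: list[ClinicalRecord] = []
    pid = 0
    for step, (state, count) in enumerate(zip(STATES, counts)):
        for _ in range(count):
            vals: dict[str, float] = {}
            for name, (mu, sd) in _CONTINUOUS.items():
                shift = eff.get(name, 0.0) * sd * step
                vals[name] = float(rng.normal(mu + shift, sd))
            for name, p0 in _BINARY_BASE.items():
                p = np.clip(p0 + eff.get(name, 0.0) * step, 0.02, 0.98)
                vals[name] = int(rng.random() < p)
            records.append(
                ClinicalRecord(
                    age=float(np.clip(vals["age"], 40.0, 100.0)),
                    sex="F" if rng.random() < 0.5 else "M",
                    hypertension=int(vals["hypertension"]),
                    hyperlipidemia=int(vals["hyperlipidemia"]),
                    diabetes=int(vals["diabetes"]),
                    eye_movement=vals["eye_movement"],
                    label=state,
                    subject_id=f"p{pid:04d}",
                )
            )
            pid += 1
    return records
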