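"""Recurrence representations of 1-D series.

A scalar series is time-delay embedded into m-dimensional states
X(i) = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau}); the pairwise state
distances r_ij feed either the classic binary recurrence plot
R_ij = step(eps - r_ij) or the no-threshold variant ER_ij = |eps - r_ij|,
which keeps the continuous distance information the binary plot throws
away. With eps = 0 the no-threshold plot is exactly the distance matrix.

Defaults: embedded mode uses m = 3, tau = 4; the faithful full-resolution
mode uses m = 1, tau = 1 so a 1,000-point series yields a 1000 x 1000
matrix. Images for the CNN are block-mean downsampled and scaled to
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

_NORMS = {"euclidean": "euclidean", "manhattan": "cityblock",
          "chebyshev": "chebyshev"}


@dataclass(frozen=True)
class EmbeddingConfig:
    """Time-delay embedding parameters: dimension m, delay tau (samples),
    and the state-space distance norm."""

    m: int = 1
    tau: int = 1
    norm: str = "euclidean"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.tau < 1:
            raise ValueError("delay tau must be >= 1")
        if self.norm not in _NORMS:
            raise ValueError(f"norm must be one of {sorted(_NORMS)}")


#: embedded-mode default
EMBEDDED = EmbeddingConfig(m=3, tau=4)
#: full-resolution default: N points give an N x N matrix
FULL_RESOLUTION = EmbeddingConfig(m=1, tau=1)


@dataclass
class RecurrenceImage:
    """Distance matrix plus whichever recurrence variants were computed."""

    r: np.ndarray
    epsilon: float
    binary: np.ndarray | None = None
    unthresholded: np.ndarray | None = None

    @property
    def side(self) -> int:
        return self.r.shape[0]


def embed(series: np.ndarray, config: EmbeddingConfig = FULL_RESOLUTION
          ) -> np.ndarray:
    """Delay-embed a series; returns (N - (m-1)*tau) x m state matrix."""
    x = np.asarray(series, dtype=float).ravel()
    span = (config.m - 1) * config.tau
    n_states = x.size - span
    if n_states < 1:
        raise ValueError(
            f"series length {x.size} too short for m={config.m}, "
            f"tau={config.tau}; need at least {span + 1} samples"
        )
    cols = [x[k * config.tau: k * config.tau + n_states]
            for k in range(config.m)]
    return np.stack(cols, axis=1)


def distance_matrix(states: np.ndarray, norm: str = "euclidean") -> np.ndarray:
    """Pairwise state distances r_ij (symmetric, zero diagonal)."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if norm not in _NORMS:
        raise ValueError(f"norm must be one of {sorted(_NORMS)}")
    if states.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(states, metric=_NORMS[norm]))


def recurrence_plot(r: np.ndarray, epsilon: float) -> np.ndarray:
    """Binary recurrence matrix: R_ij = 1 iff eps - r_ij >= 0.

    A negative eps zeroes everything including the diagonal (the step
    function of a negative argument is 0).
    """
    if not np.isfinite(epsilon):
        raise ValueError("epsilon must be finite")
    return (np.asarray(r, dtype=float) <= epsilon).astype(np.uint8)


def no_threshold_rp(r: np.ndarray, epsilon: float = 0.0) -> np.ndarray:
    """No-threshold recurrence matrix ER_ij = |eps - r_ij|.

    With the default eps = 0 this is the distance matrix itself, the
    maximally information-preserving choice.
    """
    if not np.isfinite(epsilon):
        raise ValueError("epsilon must be finite")
    return np.abs(epsilon - np.asarray(r, dtype=float))


def quantile_epsilon(r: np.ndarray, q: float) -> float:
    """eps as a quantile of the off-diagonal distances."""
    r = np.asarray(r, dtype=float)
    mask = ~np.eye(r.shape[0], dtype=bool)
    return float(np.quantile(r[mask], q)) if r.shape[0] > 1 else 0.0


def recurrence_image(
    series: np.ndarray,
    config: EmbeddingConfig = FULL_RESOLUTION,
    epsilon: float = 0.0,
    binary: bool = False,
) -> RecurrenceImage:
    """Embed, measure distances and build the requested recurrence matrix."""
    states = embed(series, config)
    r = distance_matrix(states, norm=config.norm)
    img = RecurrenceImage(r=r, epsilon=float(epsilon))
    if binary:
        img.binary = recurrence_plot(r, epsilon)
    else:
        img.unthresholded = no_threshold_rp(r, epsilon)
    return img


def block_reduce(mat: np.ndarray, side_out: int) -> np.ndarray:
    """Block-mean to side_out x side_out using near-equal block boundaries."""
    n = mat.shape[0]
    edges = np.linspace(0, n, side_out + 1).round().astype(int)
    sums = np.add.reduceat(np.add.reduceat(mat, edges[:-1], axis=0),
                           edges[:-1], axis=1)
    areas = np.outer(np.diff(edges), np.diff(edges))
    return sums / areas


def rp_to_image(
    er: np.ndarray,
    side_out: int = 64,
    scaling: str = "minmax",
    scale: float | None = None,
) -> np.ndarray:
    """Downsample a recurrence matrix and scale it into [0, 1].

    scaling
        ``minmax`` (default): per-image (x - min)/(max - min); a constant
        matrix maps to all zeros.
        ``global``: x / scale clipped to [0, 1], preserving absolute
        amplitude across images; ``scale`` is required.
    """
    er = np.asarray(er, dtype=float)
    if side_out < 8:
        raise ValueError("side_out must be >= 8")
    if side_out > er.shape[0]:
        raise ValueError(
            f"side_out {side_out} exceeds matrix side {er.shape[0]}; "
            "no upsampling"
        )
    img = block_reduce(er, side_out)
    if scaling == "minmax":
        lo, hi = img.min(), img.max()
        return np.zeros_like(img) if hi <= lo else (img - lo) / (hi - lo)
    if scaling == "global":
        if scale is None or scale <= 0:
            raise ValueError("global scaling needs a positive scale")
        return np.clip(img / scale, 0.0, 1.0)
    raise ValueError("scaling must be 'minmax' or 'global'")
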