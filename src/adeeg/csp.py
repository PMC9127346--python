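"""Common Spatial Patterns: variance-maximizing spatial filters.

Two-class CSP simultaneously diagonalizes the class-average normalized
covariances. With R_i = X X^T / trace(X X^T) averaged per class, the
composite Rc = R1 + R2 is eigendecomposed, whitened with
P = Lambda_c^{-1/2} Uc^T (so that P Rc P^T = I), and the whitened class
covariance S1 = P R1 P^T is rotated by its eigenvectors B. Because
S1 + S2 = I, the same rotation diagonalizes both classes with
Lambda1 + Lambda2 = I: filters with the largest/smallest Lambda1
eigenvalues maximize the variance ratio between the classes. The filter
bank W = B^T P (rows are filters, sorted by Lambda1 descending) projects
a recording to Z = W X, from which 2m features are read off the first
and last m rows.

The three-state problem is handled one-vs-rest: one two-class filter bank
per state, features concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .recording import STATES, EEGRecording


@dataclass
class CSPModel:
    """Fitted two-class CSP filter bank and its intermediate matrices."""

    R1_bar: np.ndarray
    R2_bar: np.ndarray
    Rc: np.ndarray
    Uc: np.ndarray
    lambda_c: np.ndarray
    P: np.ndarray          # whitening transform, P Rc P^T = I
    B: np.ndarray          # shared eigenvectors of the whitened classes
    lambda1: np.ndarray    # class-1 eigenvalues, descending
    lambda2: np.ndarray    # = 1 - lambda1
    W: np.ndarray          # filter bank, rows = filters
    m: int
    channel_labels: tuple[str, ...] = ()

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]

    def selected_rows(self) -> np.ndarray:
        """Indices of the first m and last m filter rows."""
        M = self.n_channels
        return np.r_[np.arange(self.m), np.arange(M - self.m, M)]


def normalized_covariance(X: np.ndarray) -> np.ndarray:
    """Trace-normalized covariance X X^T / trace(X X^T)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be channels x samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    S = X @ X.T
    t = np.trace(S)
    if t <= 0:
        raise ValueError("zero signal: covariance trace is 0")
    return S / t


def _as_matrix(rec) -> np.ndarray:
    return rec.data if isinstance(rec, EEGRecording) else np.asarray(rec, float)


def fit_csp(
    class1: list,
    class2: list,
    m: int = 2,
    regularize: bool = True,
    ridge: float = 1e-6,
) -> CSPModel:
    """Fit a two-class CSP filter bank.

    Parameters
    ----------
    class1, class2 : lists of EEGRecording or channels x samples arrays
    m : filters kept per side (feature length 2m)
    regularize : add ridge * trace(Rc)/M * I to Rc before whitening,
        guarding rank deficiency.
    """
    if not class1 or not class2:
        raise ValueError("both classes must be non-empty")
    mats1 = [_as_matrix(r) for r in class1]
    mats2 = [_as_matrix(r) for r in class2]
    M = mats1[0].shape[0]
    for X in mats1 + mats2:
        if X.shape[0] != M:
            raise ValueError("inconsistent channel counts across recordings")
    if 2 * m > M:
        raise ValueError(f"2m = {2 * m} filters exceed {M} channels")

    R1 = np.mean([normalized_covariance(X) for X in mats1], axis=0)
    R2 = np.mean([normalized_covariance(X) for X in mats2], axis=0)
    Rc = R1 + R2
    if regularize:
        Rc = Rc + ridge * (np.trace(Rc) / M) * np.eye(M)

    lam_c, Uc = linalg.eigh(Rc)
    if lam_c.min() <= 1e-12 * lam_c.max():
        raise np.linalg.LinAlgError(
            "composite covariance is rank deficient; enable the ridge "
            "regularizer (regularize=True) or supply longer recordings"
        )
    P = np.diag(lam_c ** -0.5) @ Uc.T

    S1 = P @ R1 @ P.T
    lam1, B = linalg.eigh(S1)
    order = np.argsort(lam1)[::-1]
    lam1 = lam1[order]
    B = B[:, order]

    W = B.T @ P
    # sign convention: each filter's largest-magnitude entry positive
    signs = np.sign(W[np.arange(M), np.argmax(np.abs(W), axis=1)])
    signs[signs == 0] = 1.0
    W = W * signs[:, None]
    B = B * signs[None, :]

    labels = ()
    if isinstance(class1[0], EEGRecording):
        labels = class1[0].channel_labels
    return CSPModel(
        R1_bar=R1, R2_bar=R2, Rc=Rc, Uc=Uc, lambda_c=lam_c, P=P, B=B,
        lambda1=lam1, lambda2=1.0 - lam1, W=W, m=m, channel_labels=labels,
    )


def csp_features(
    model: CSPModel,
    X,
    selector: str = "log_variance",
) -> np.ndarray:
    """Project a recording and read off the 2m-dimensional feature vector.

    selector
        ``log_variance`` (default): log of each selected row's variance
        normalized by the summed variance of the selected rows — the
        standard CSP feature, invariant to overall signal scale.
        ``row_max``: the maximum absolute value of each selected row of
        Z = W X, a literal row-max readout.
    """
    X = _as_matrix(X)
    if X.shape[0] != model.n_channels:
        raise ValueError(
            f"recording has {X.shape[0]} channels, model expects "
            f"{model.n_channels}"
        )
    Z = model.W @ X
    rows = model.selected_rows()
    if selector == "row_max":
        return np.abs(Z[rows]).max(axis=1)
    if selector == "log_variance":
        var = Z[rows].var(axis=1)
        total = var.sum()
        if total <= 0:
            raise ValueError("zero-variance projection; degenerate input")
        return np.log(var / total)
    raise ValueError("selector must be 'log_variance' or 'row_max'")


@dataclass
class OneVsRestCSP:
    """Three one-vs-rest CSP banks for the calm/transitional/morbidity
    problem; features are the concatenation over states (length 6m)."""

    models: dict[str, CSPModel]
    m: int
    selector: str = "log_variance"

    @classmethod
    def fit(cls, recordings: list[EEGRecording], m: int = 2,
            selector: str = "log_variance", **kwargs) -> "OneVsRestCSP":
        present = {r.state for r in recordings}
        if None in present:
            raise ValueError("all recordings need a state label")
        if len(present) < 2:
            raise ValueError("need at least two states to fit CSP")
        models = {}
        for state in STATES:
            if state not in present:
                continue
            pos = [r for r in recordings if r.state == state]
            neg = [r for r in recordings if r.state != state]
            models[state] = fit_csp(pos, neg, m=m, **kwargs)
        return cls(models=models, m=m, selector=selector)

    def transform(self, recording) -> np.ndarray:
        return np.concatenate([
            csp_features(self.models[s], recording, selector=self.selector)
            for s in STATES if s in self.models
        ])


def write_csp(path, model: CSPModel) -> None:
    """Serialize a CSP model as labeled TSV blocks."""
    def block(fh, name, mat):
        mat = np.atleast_2d(mat)
        fh.write(f"#{name}\t{mat.shape[0]}\t{mat.shape[1]}\n")
        for row in mat:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")

    with open(path, "w") as fh:
        fh.write(f"#m\t{model.m}\n")
        if model.channel_labels:
            fh.write("#channels\t" + "\t".join(model.channel_labels) + "\n")
        for name in ("R1_bar", "R2_bar", "Rc", "Uc", "lambda_c", "P", "B",
                     "lambda1", "lambda2", "W"):
            block(fh, name, getattr(model, name))


def read_csp(path) -> CSPModel:
    with open(path) as fh:
        lines = fh.read().splitlines()
    m = None
    labels: tuple[str, ...] = ()
    blocks: dict[str, np.ndarray] = {}
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("#m\t"):
            m = int(line.split("\t")[1])
            i += 1
        elif line.startswith("#channels\t"):
            labels = tuple(line.split("\t")[1:])
            i += 1
        elif line.startswith("#"):
            name, rows, _cols = line[1:].split("\t")
            rows = int(rows)
            mat = np.array(
                [[float(v) for v in lines[i + 1 + r].split("\t")]
                 for r in range(rows)]
            )
            blocks[name] = mat
            i += 1 + rows
        else:
            i += 1
    vectors = {"lambda_c", "lambda1", "lambda2"}
    kwargs = {k: (v.ravel() if k in vectors else v) for k, v in blocks.items()}
    return CSPModel(m=m, channel_labels=labels, **kwargs)
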