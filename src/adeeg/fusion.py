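"""Clinical screening, the two classifier branches and decision fusion.

Screening tests each clinical covariate across the three disease states:
continuous features with the Kruskal-Wallis rank test, binary features
with an exact conditional independence test on the 2x3 contingency table
(multivariate hypergeometric enumeration, Fisher's rule), and keeps
features with p below the significance level (no multiplicity
correction by default, with an optional Bonferroni flag).

PE is a seeded L2-regularized multinomial logistic model over the
concatenated CSP and network-metric features; the clinical probability is
the same model family over screened covariates only. Fusion combines the
per-source probability vectors at decision level: arithmetic mean, fixed
convex weights, or a stacked logistic meta-classifier fitted on held-out
source probabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .recording import STATES, ClinicalRecord, clinical_to_frame

CONTINUOUS_FEATURES = ("age", "eye_movement")
BINARY_FEATURES = ("sex", "hypertension", "hyperlipidemia", "diabetes")


@dataclass
class ScreeningResult:
    """Per-feature test outcomes and the selected set at level alpha."""

    tests: pd.DataFrame          # feature, test, statistic, p_value
    alpha: float
    selected: tuple[str, ...]

    def __contains__(self, feature: str) -> bool:
        return feature in self.selected


def _exact_2x3_pvalue(table: np.ndarray) -> float:
    """Exact conditional test of independence for a 2 x k table.

    Enumerates all tables with the observed margins under the
    multivariate hypergeometric null and sums the probabilities of
    tables no more probable than the observed one (Fisher's rule).
    """
    table = np.asarray(table, dtype=int)
    col_tot = table.sum(axis=0)
    k_tot = int(table[1].sum())

    def log_table_prob(successes: tuple[int, ...]) -> float:
        lp = -math.lgamma(sum(col_tot) + 1) + math.lgamma(k_tot + 1) \
             + math.lgamma(sum(col_tot) - k_tot + 1)
        for n_j, a_j in zip(col_tot, successes):
            lp += (math.lgamma(n_j + 1) - math.lgamma(a_j + 1)
                   - math.lgamma(n_j - a_j + 1))
        return lp

    obs_lp = log_table_prob(tuple(int(v) for v in table[1]))
    total = 0.0
    # enumerate successes per column summing to k_tot
    ranges = [range(min(int(n), k_tot) + 1) for n in col_tot[:-1]]
    def rec(prefix, remaining, depth):
        nonlocal total
        if depth == len(col_tot) - 1:
            last = remaining
            if 0 <= last <= col_tot[-1]:
                lp = log_table_prob(prefix + (last,))
                if lp <= obs_lp + 1e-9:
                    total += math.exp(lp)
            return
        for a in ranges[depth]:
            if a > remaining:
                break
            rec(prefix + (a,), remaining - a, depth + 1)
    rec((), k_tot, 0)
    return min(total, 1.0)


def screen_clinical(
    records: list[ClinicalRecord],
    alpha: float = 0.05,
    exact_binary: bool = True,
    bonferroni: bool = False,
) -> ScreeningResult:
    """Screen clinical covariates for association with the disease state."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    frame = clinical_to_frame(records)
    labels = frame["label"]
    present = [s for s in STATES if (labels == s).any()]
    if len(present) < 2:
        raise ValueError("screening needs at least two states represented")

    rows = []
    n_tests = len(CONTINUOUS_FEATURES) + len(BINARY_FEATURES)
    level = alpha / n_tests if bonferroni else alpha
    for feat in CONTINUOUS_FEATURES:
        groups = [frame.loc[labels == s, feat].to_numpy() for s in present]
        if np.ptp(frame[feat].to_numpy()) == 0:
            warnings.warn(f"constant feature {feat!r}; p set to 1")
            stat, p = float("nan"), 1.0
        else:
            stat, p = stats.kruskal(*groups)
        rows.append((feat, "kruskal-wallis", float(stat), float(p)))
    for feat in BINARY_FEATURES:
        col = frame[feat]
        values = (col == "M").astype(int) if feat == "sex" else col.astype(int)
        table = np.array([
            [int(((labels == s) & (values == v)).sum()) for s in present]
            for v in (0, 1)
        ])
        if (table.sum(axis=1) == 0).any():
            warnings.warn(f"constant feature {feat!r}; p set to 1")
            rows.append((feat, "exact-2xk", float("nan"), 1.0))
            continue
        if exact_binary:
            p = _exact_2x3_pvalue(table)
            stat = float("nan")
            name = "exact-2xk"
        else:
            stat, p, _, _ = stats.chi2_contingency(table)
            name = "chi2"
        rows.append((feat, name, float(stat), float(p)))

    tests = pd.DataFrame(rows, columns=["feature", "test", "statistic",
                                        "p_value"])
    selected = tuple(tests.loc[tests["p_value"] < level, "feature"])
    return ScreeningResult(tests=tests, alpha=alpha, selected=selected)


def _simplex(v: np.ndarray) -> np.ndarray:
    v = np.clip(np.asarray(v, dtype=float), 0.0, None)
    s = v.sum(axis=-1, keepdims=True)
    uniform = np.full_like(v, 1.0 / v.shape[-1])
    return np.where(s > 0, v / np.where(s > 0, s, 1.0), uniform)


@dataclass
class ClassProbabilities:
    """Per-source and fused 3-class probabilities for one sample, in the
    fixed (calm, transitional, morbidity) class order."""

    pe: np.ndarray | None = None
    re: np.ndarray | None = None
    clinical: np.ndarray | None = None
    fused: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("pe", "re", "clinical", "fused"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if v.shape != (3,) or v.min() < -1e-9 \
                    or abs(v.sum() - 1.0) > 1e-6:
                raise ValueError(f"{name} is not a 3-class probability vector")
            setattr(self, name, v)

    def sources(self) -> list[np.ndarray]:
        return [v for v in (self.pe, self.re, self.clinical) if v is not None]


class PEClassifier:
    """Multinomial logistic regression over PE-branch features
    (CSP features concatenated with the network metric vector)."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        self._model = LogisticRegression(
            C=C, max_iter=2000, random_state=seed
        )
        self._dim: int | None = None

    def fit(self, features: np.ndarray, labels) -> "PEClassifier":
        features = np.asarray(features, dtype=float)
        y = _label_indices(labels)
        self._model.fit(features, y)
        self._dim = features.shape[1]
        return self

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self._dim:
            raise ValueError(
                f"feature dimension {features.shape[1]} does not match the "
                f"fitted model ({self._dim})"
            )
        return _expand_classes(self._model.predict_proba(features),
                               self._model.classes_)


def _label_indices(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "USO":
        return np.array([STATES.index(str(s)) for s in labels])
    return labels.astype(int)


def _expand_classes(probs: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Map sklearn's class-subset columns onto the fixed 3-class order."""
    out = np.zeros((probs.shape[0], 3))
    for j, cls in enumerate(classes):
        out[:, int(cls)] = probs[:, j]
    return _simplex(out)


class ClinicalModel:
    """Multinomial logistic model over the screened covariates only."""

    def __init__(self, screened: ScreeningResult, C: float = 1.0,
                 seed: int = 0):
        self.screened = screened
        self._model = LogisticRegression(C=C, max_iter=2000, random_state=seed)
        self._fitted = bool(screened.selected)

    @staticmethod
    def _design(records: list[ClinicalRecord],
                features: tuple[str, ...]) -> np.ndarray:
        frame = clinical_to_frame(records)
        cols = []
        for feat in features:
            if feat == "sex":
                cols.append((frame["sex"] == "M").astype(float).to_numpy())
            else:
                cols.append(frame[feat].astype(float).to_numpy())
        return np.stack(cols, axis=1)

    def fit(self, records: list[ClinicalRecord]) -> "ClinicalModel":
        if not self.screened.selected:
            warnings.warn(
                "no screened features; clinical branch falls back to the "
                "uniform probability"
            )
            return self
        X = self._design(records, self.screened.selected)
        y = _label_indices([r.label for r in records])
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self._model.fit((X - self._mu) / self._sd, y)
        return self

    def predict_proba(self, records: list[ClinicalRecord]) -> np.ndarray:
        if not self._fitted:
            return np.full((len(records), 3), 1.0 / 3)
        X = self._design(records, self.screened.selected)
        probs = self._model.predict_proba((X - self._mu) / self._sd)
        return _expand_classes(probs, self._model.classes_)


def fuse(
    probs: ClassProbabilities | list[ClassProbabilities],
    method: str = "mean",
    weights: tuple[float, ...] | None = None,
    meta_model: LogisticRegression | None = None,
) -> np.ndarray:
    """Fuse the available source probabilities into one simplex vector.

    mean
        Arithmetic mean of the available sources, renormalized.
    weighted
        Convex combination in (pe, re, clinical) order; weights are
        renormalized (with a warning) if they do not sum to 1.
    stacked
        Apply a fitted meta-classifier (see :func:`fit_stacker`) to the
        concatenated source probabilities.
    """
    if isinstance(probs, list):
        return np.stack([fuse(p, method, weights, meta_model) for p in probs])
    sources = probs.sources()
    if not sources:
        raise ValueError("no source probabilities present")
    if method == "mean":
        return _simplex(np.mean(sources, axis=0))
    if method == "weighted":
        if weights is None:
            raise ValueError("weighted fusion needs weights")
        w = np.asarray(weights, dtype=float)
        if w.size != len(sources):
            raise ValueError(
                f"{w.size} weights for {len(sources)} present sources"
            )
        if w.min() < 0:
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            warnings.warn("weights do not sum to 1; renormalizing")
            w = w / w.sum()
        return _simplex(np.tensordot(w, np.stack(sources), axes=1))
    if method == "stacked":
        if meta_model is None:
            raise ValueError("stacked fusion needs a fitted meta model")
        x = np.concatenate(sources)[None, :]
        return _expand_classes(meta_model.predict_proba(x),
                               meta_model.classes_)[0]
    raise ValueError("method must be 'mean', 'weighted' or 'stacked'")


def fit_stacker(prob_list: list[ClassProbabilities], labels,
                C: float = 10.0, seed: int = 0) -> LogisticRegression:
    """Fit the logistic meta-classifier of stacked fusion on held-out
    source probabilities."""
    X = np.stack([np.concatenate(p.sources()) for p in prob_list])
    y = _label_indices(labels)
    model = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    model.fit(X, y)
    return model


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts for a single positive class."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_counts(y_true, y_pred, positive_class) -> ConfusionCounts:
    """Tally one-vs-rest counts for a positive class (index or name)."""
    t = _label_indices(np.asarray(y_true))
    p = _label_indices(np.asarray(y_pred))
    pos = STATES.index(positive_class) if isinstance(positive_class, str) \
        else int(positive_class)
    return ConfusionCounts(
        TP=int(((t == pos) & (p == pos)).sum()),
        FP=int(((t != pos) & (p == pos)).sum()),
        TN=int(((t != pos) & (p != pos)).sum()),
        FN=int(((t == pos) & (p != pos)).sum()),
    )


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FP + TN + FN)."""
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    return (counts.TP + counts.TN) / counts.total


def multiclass_accuracy(y_true, y_pred) -> float:
    """Fraction of correct 3-way decisions."""
    t = _label_indices(np.asarray(y_true))
    p = _label_indices(np.asarray(y_pred))
    return float((t == p).mean())


def roc_curve(scores: np.ndarray, labels, positive_class):
    """One-vs-rest ROC by threshold sweep; returns (fpr, tpr, auc).

    ``scores`` may be the (n, 3) class-probability matrix (the positive
    class column is used) or a 1-D score vector.
    """
    y = _label_indices(np.asarray(labels))
    pos = STATES.index(positive_class) if isinstance(positive_class, str) \
        else int(positive_class)
    scores = np.asarray(scores, dtype=float)
    s = scores[:, pos] if scores.ndim == 2 else scores
    binary = (y == pos).astype(int)
    if binary.min() == binary.max():
        raise ValueError("ROC needs both positive and negative samples")
    fpr, tpr, _ = _sk_roc_curve(binary, s)
    return fpr, tpr, float(_sk_auc(fpr, tpr))
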