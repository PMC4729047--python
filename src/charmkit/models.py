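"""Dimension reduction and classifiers.

Two classification paths are provided:

* **PCA-LDA** — features are z-scored, projected onto the minimal set of
  principal components explaining at least 98 % of the variance
  (user-tunable), and classified with linear discriminant analysis.
* **Fisher + WND** — the weighted-neighbor-distance baseline: per-feature
  Fisher discriminant scores, retention of the top 15 % of features by
  weight, and a WND classifier with exponent p = -5.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .features import FeatureMatrix

__all__ = [
    "PCAModel",
    "LDAModel",
    "WNDModel",
    "fisher_weights",
    "select_top_fraction",
    "fit_pca",
    "transform_pca",
    "fit_lda",
    "predict_lda",
    "wnd_fit",
    "wnd_predict",
    "shuffle_labels",
    "tanimoto_similarity",
    "save_model",
    "load_model",
    "DEFAULT_VARIANCE_THRESHOLD",
    "DEFAULT_SELECT_FRACTION",
    "DEFAULT_WND_EXPONENT",
    "FISHER_SENTINEL",
]

DEFAULT_VARIANCE_THRESHOLD = 0.98
DEFAULT_SELECT_FRACTION = 0.15
DEFAULT_WND_EXPONENT = -5.0
FISHER_SENTINEL = 1e12
_RIDGE = 1e-8  # times trace/d, added to the pooled covariance diagonal


def _round_half_up(x: float) -> int:
    """round() with halves away from zero (3.5 -> 4, 142.95 -> 143)."""
    return int(math.floor(x + 0.5))


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.X.to_numpy(dtype=np.float64)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=np.float64)
    return np.asarray(X, dtype=np.float64)


def _labels_of(X, y) -> np.ndarray:
    if y is None and isinstance(X, FeatureMatrix):
        if X.labels is None:
            raise ValueError("feature matrix has no labels")
        return X.labels.to_numpy()
    return np.asarray(y)


# ---------------------------------------------------------------------------
# Fisher weighting and selection (WND-CHARM path)
# ---------------------------------------------------------------------------

def fisher_weights(X, y=None) -> np.ndarray:
    """Per-feature Fisher discriminant scores.

    w_f = Var_c(mu_{f,c}) / mean_c(sigma^2_{f,c}) with unweighted class
    means and population variances. A feature that separates classes
    perfectly (zero within-class variance, nonzero between) gets a large
    sentinel weight; a globally constant feature gets 0.
    """
    A = _as_array(X)
    labels = _labels_of(X, y)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("fisher_weights: need at least 2 classes")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"fisher_weights: class {c!r} has fewer than 2 samples")
    mu = np.stack([A[labels == c].mean(axis=0) for c in classes])
    s2 = np.stack([A[labels == c].var(axis=0) for c in classes])
    between = mu.var(axis=0)       # population variance over class means
    within = s2.mean(axis=0)
    w = np.zeros(A.shape[1])
    ok = within > 0
    w[ok] = between[ok] / within[ok]
    w[(~ok) & (between > 0)] = FISHER_SENTINEL
    return w


def select_top_fraction(
    w: np.ndarray, fraction: float = DEFAULT_SELECT_FRACTION
) -> np.ndarray:
    """Indices of the top-weighted features; ties broken by ascending index."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    w = np.asarray(w, dtype=np.float64)
    n_keep = _round_half_up(fraction * w.size)
    if n_keep < 1:
        raise ValueError(
            f"fraction {fraction} selects 0 of {w.size} features"
        )
    order = np.argsort(-w, kind="stable")  # stable: equal weights keep index order
    return np.sort(order[:n_keep])


def tanimoto_similarity(a, b) -> float:
    """Tanimoto (Jaccard) similarity of two selected-feature index sets.

    Diagnostic for feature-selection stability across resampled runs.
    """
    sa, sb = set(np.asarray(a).tolist()), set(np.asarray(b).tolist())
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Fitted standardization + PCA state."""

    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray              # std, with zero-variance divisors set to 1
    components: np.ndarray         # (n_retained, n_features)
    explained_variance_ratio: np.ndarray  # all components, sorted desc
    n_retained: int
    variance_threshold: float


def fit_pca(X, variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD) -> PCAModel:
    """Standardize features and fit PCA, retaining the minimal leading
    set of components whose cumulative explained variance reaches the
    threshold (default 0.98)."""
    A = _as_array(X)
    if A.shape[0] < 2:
        raise ValueError("fit_pca: need at least 2 samples")
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    names = (
        list(X.X.columns)
        if isinstance(X, FeatureMatrix)
        else (list(X.columns) if isinstance(X, pd.DataFrame)
              else [f"f{i}" for i in range(A.shape[1])])
    )
    mean = A.mean(axis=0)
    scale = A.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (A - mean) / scale
    pca = PCA(svd_solver="full")
    pca.fit(Z)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    # minimal prefix reaching the threshold (floating slack for threshold 1.0)
    n_retained = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    n_retained = min(n_retained, evr.size)
    return PCAModel(
        feature_names=names,
        mean=mean,
        scale=scale,
        components=pca.components_[:n_retained].copy(),
        explained_variance_ratio=evr.copy(),
        n_retained=n_retained,
        variance_threshold=variance_threshold,
    )


def transform_pca(model: PCAModel, X) -> np.ndarray:
    """Project data onto the retained components (name-aligned columns)."""
    if isinstance(X, FeatureMatrix):
        X = X.X
    if isinstance(X, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in X.columns]
        if missing:
            raise KeyError(f"feature columns missing from input: {missing[:5]}")
        A = X[model.feature_names].to_numpy(dtype=np.float64)
    else:
        A = np.asarray(X, dtype=np.float64)
        if A.shape[1] != len(model.feature_names):
            raise KeyError(
                f"expected {len(model.feature_names)} columns, got {A.shape[1]}"
            )
    Z = (A - model.mean) / model.scale
    return Z @ model.components.T


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Gaussian LDA with pooled within-class covariance.

    Discriminant: delta_c(x) = x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 + log pi_c.
    """

    classes: list[str]
    means: np.ndarray              # (n_classes, d)
    cov_inv: np.ndarray            # (d, d), ridge-regularized pooled covariance
    priors: np.ndarray             # (n_classes,), sums to 1


def fit_lda(scores: np.ndarray, y, priors: np.ndarray | None = None) -> LDAModel:
    S = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(y)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("fit_lda: need at least 2 classes")
    d = S.shape[1]
    means = np.stack([S[labels == c].mean(axis=0) for c in classes])
    pooled = np.zeros((d, d))
    for c, m in zip(classes, means):
        R = S[labels == c] - m
        pooled += R.T @ R
    dof = max(S.shape[0] - len(classes), 1)
    pooled /= dof
    ridge = _RIDGE * np.trace(pooled) / d if d else 0.0
    pooled[np.diag_indices(d)] += max(ridge, _RIDGE)
    cov_inv = np.linalg.inv(pooled)
    if priors is None:
        priors = np.array([np.mean(labels == c) for c in classes])
    priors = np.asarray(priors, dtype=np.float64)
    priors = priors / priors.sum()
    return LDAModel(
        classes=[str(c) for c in classes],
        means=means,
        cov_inv=cov_inv,
        priors=priors,
    )


def lda_discriminants(model: LDAModel, scores: np.ndarray) -> np.ndarray:
    """delta_c(x) per sample and class."""
    S = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    G = model.cov_inv @ model.means.T            # (d, n_classes)
    lin = S @ G                                  # x' S^-1 mu_c
    quad = 0.5 * np.einsum("cd,dc->c", model.means, G)
    return lin - quad + np.log(model.priors)


def predict_lda(
    model: LDAModel, scores: np.ndarray, return_posteriors: bool = False
):
    """Predicted labels (ties -> lexicographically first class) and,
    optionally, per-class posteriors (softmax of the discriminants)."""
    delta = lda_discriminants(model, scores)
    idx = np.argmax(delta, axis=1)  # argmax returns first max; classes sorted
    labels = np.array([model.classes[i] for i in idx])
    if not return_posteriors:
        return labels
    z = delta - delta.max(axis=1, keepdims=True)
    e = np.exp(z)
    post = e / e.sum(axis=1, keepdims=True)
    return labels, pd.DataFrame(post, columns=model.classes)


# ---------------------------------------------------------------------------
# WND
# ---------------------------------------------------------------------------

@dataclass
class WNDModel:
    """Weighted-neighbor-distance classifier state."""

    selected: np.ndarray           # retained feature indices into the input
    feature_names: list[str]
    train_X: np.ndarray            # (n_train, n_selected), standardized
    train_y: np.ndarray
    weights: np.ndarray            # (n_selected,)
    exponent: float = DEFAULT_WND_EXPONENT
    mean: np.ndarray | None = None     # standardization of selected features
    scale: np.ndarray | None = None


def wnd_fit(
    X,
    y=None,
    fraction: float = DEFAULT_SELECT_FRACTION,
    exponent: float = DEFAULT_WND_EXPONENT,
) -> WNDModel:
    """Standardize, weight with Fisher scores, keep the top fraction."""
    A = _as_array(X)
    labels = _labels_of(X, y)
    names = (
        list(X.X.columns)
        if isinstance(X, FeatureMatrix)
        else (list(X.columns) if isinstance(X, pd.DataFrame)
              else [f"f{i}" for i in range(A.shape[1])])
    )
    mean = A.mean(axis=0)
    scale = A.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (A - mean) / scale
    w = fisher_weights(Z, labels)
    sel = select_top_fraction(w, fraction)
    return WNDModel(
        selected=sel,
        feature_names=[names[i] for i in sel],
        train_X=Z[:, sel],
        train_y=labels.astype(str),
        weights=w[sel],
        exponent=exponent,
        mean=mean,
        scale=scale,
    )


def wnd_class_scores(model: WNDModel, x: np.ndarray) -> dict[str, float]:
    """S(c) = mean over training samples t of class c of D(x,t)^p,
    D(x,t) = sum_f w_f^2 (x_f - t_f)^2."""
    x = np.asarray(x, dtype=np.float64)
    D = ((model.weights**2) * (model.train_X - x) ** 2).sum(axis=1)
    scores: dict[str, float] = {}
    for c in sorted(set(model.train_y.tolist())):
        Dc = D[model.train_y == c]
        scores[c] = float(np.mean(Dc**model.exponent))
    return scores


def wnd_predict(model: WNDModel, X, return_scores: bool = False):
    """Predict labels; a query exactly matching a training sample takes
    that sample's class immediately."""
    if isinstance(X, FeatureMatrix):
        X = X.X
    if isinstance(X, pd.DataFrame):
        A = X.to_numpy(dtype=np.float64)
    else:
        A = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if model.mean is not None:
        A = (A - model.mean) / model.scale
        A = A[:, model.selected]
    out_labels, out_scores = [], []
    classes = sorted(set(model.train_y.tolist()))
    for x in A:
        D = ((model.weights**2) * (model.train_X - x) ** 2).sum(axis=1)
        exact = np.where(D == 0.0)[0]
        if exact.size:
            out_labels.append(model.train_y[exact[0]])
            s = {c: (np.inf if model.train_y[exact[0]] == c else 0.0)
                 for c in classes}
        else:
            s = {
                c: float(np.mean(D[model.train_y == c] ** model.exponent))
                for c in classes
            }
            # argmax with ties toward the lexicographically first class
            best = classes[0]
            for c in classes[1:]:
                if s[c] > s[best]:
                    best = c
            out_labels.append(best)
        out_scores.append(s)
    labels = np.array(out_labels)
    if return_scores:
        return labels, pd.DataFrame(out_scores)
    return labels


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------

def shuffle_labels(y, seed: int) -> np.ndarray:
    """Uniform random permutation of the label vector (seed-reproducible)."""
    y = np.asarray(y)
    if y.size < 2:
        raise ValueError("shuffle_labels: need at least 2 labels")
    rng = np.random.default_rng(seed)
    return y[rng.permutation(y.size)]


# ---------------------------------------------------------------------------
# serialization: one JSON archive for PCA+LDA or WND
# ---------------------------------------------------------------------------

def _enc(a):
    return np.asarray(a).tolist() if a is not None else None


def save_model(path, pca: PCAModel | None = None, lda: LDAModel | None = None,
               wnd: WNDModel | None = None) -> None:
    """Serialize fitted models to a self-describing JSON archive."""
    doc: dict = {"format": "charmkit-model", "version": 1}
    if pca is not None:
        doc["pca"] = {
            "feature_names": pca.feature_names,
            "mean": _enc(pca.mean),
            "scale": _enc(pca.scale),
            "components": _enc(pca.components),
            "explained_variance_ratio": _enc(pca.explained_variance_ratio),
            "n_retained": pca.n_retained,
            "variance_threshold": pca.variance_threshold,
        }
    if lda is not None:
        doc["lda"] = {
            "classes": lda.classes,
            "means": _enc(lda.means),
            "cov_inv": _enc(lda.cov_inv),
            "priors": _enc(lda.priors),
        }
    if wnd is not None:
        doc["wnd"] = {
            "selected": _enc(wnd.selected),
            "feature_names": wnd.feature_names,
            "train_X": _enc(wnd.train_X),
            "train_y": _enc(wnd.train_y),
            "weights": _enc(wnd.weights),
            "exponent": wnd.exponent,
            "mean": _enc(wnd.mean),
            "scale": _enc(wnd.scale),
        }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> dict:
    """Load a model archive; returns {'pca': ..., 'lda': ..., 'wnd': ...}."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "charmkit-model":
        raise ValueError(f"{path} is not a charmkit model archive")
    out: dict = {}
    if "pca" in doc:
        p = doc["pca"]
        out["pca"] = PCAModel(
            feature_names=p["feature_names"],
            mean=np.array(p["mean"]),
            scale=np.array(p["scale"]),
            components=np.array(p["components"]),
            explained_variance_ratio=np.array(p["explained_variance_ratio"]),
            n_retained=p["n_retained"],
            variance_threshold=p["variance_threshold"],
        )
    if "lda" in doc:
        l = doc["lda"]
        out["lda"] = LDAModel(
            classes=l["classes"],
            means=np.array(l["means"]),
            cov_inv=np.array(l["cov_inv"]),
            priors=np.array(l["priors"]),
        )
    if "wnd" in doc:
        w = doc["wnd"]
        out["wnd"] = WNDModel(
            selected=np.array(w["selected"], dtype=int),
            feature_names=w["feature_names"],
            train_X=np.array(w["train_X"]),
            train_y=np.array(w["train_y"]),
            weights=np.array(w["weights"]),
            exponent=w["exponent"],
            mean=np.array(w["mean"]) if w["mean"] is not None else None,
            scale=np.array(w["scale"]) if w["scale"] is not None else None,
        )
    return out
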