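"""Linear discriminant classification of well morphologies.

Control wells anchor three phenotype classes — negative-control and
mock wells are mesenchymal (the baseline of a spindle-shaped line),
miR-373 positive-control wells are epithelial, and siPTK6/miCon wells
are intermediate.  An LDA model with pooled within-class covariance is
trained on half the control wells, validated on the other half, and
applied to library wells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthgen import FEATURE_COLUMNS, LIBRARY, MICON, MOCK, NEG_CTRL, POS_CTRL, SIPTK6

EPITHELIAL = "epithelial"
INTERMEDIATE = "intermediate"
MESENCHYMAL = "mesenchymal"
# fixed order; also the deterministic tie-break order in prediction
CLASS_ORDER = (EPITHELIAL, INTERMEDIATE, MESENCHYMAL)

CONTROL_CLASS = {
    NEG_CTRL: MESENCHYMAL,
    MOCK: MESENCHYMAL,
    POS_CTRL: EPITHELIAL,
    SIPTK6: INTERMEDIATE,
    MICON: INTERMEDIATE,
}

RIDGE_LAMBDA = 1e-6  # ridge on pooled covariance, scaled by trace/p


def label_controls(
    well_features: pd.DataFrame, feature_columns: Sequence[str] = FEATURE_COLUMNS
) -> pd.DataFrame:
    """Assign phenotype class labels to control wells; library wells excluded.

    Raises when any of the three classes ends up empty, listing the
    missing classes.
    """
    df = well_features[well_features["content"].isin(CONTROL_CLASS)].copy()
    df["class"] = df["content"].map(CONTROL_CLASS)
    missing = [c for c in CLASS_ORDER if c not in set(df["class"])]
    if missing:
        raise ValueError(f"control classes not represented in layout: {missing}")
    X = df[list(feature_columns)]
    if not np.isfinite(X.to_numpy(dtype=float)).all():
        raise ValueError("non-finite feature values in control wells")
    return df


def split_train_test(
    labeled: pd.DataFrame, fraction: float = 0.5, rng_seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split preserving class proportions, seeded."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for _, grp in labeled.groupby("class", sort=True):
        if len(grp) < 2:
            raise ValueError(f"class {grp['class'].iloc[0]!r} has fewer than 2 wells")
        order = grp.index.to_numpy()[rng.permutation(len(grp))]
        n_train = int(round(fraction * len(order)))
        n_train = min(max(n_train, 1), len(order) - 1)
        train_idx.extend(order[:n_train])
        test_idx.extend(order[n_train:])
    return labeled.loc[sorted(train_idx)], labeled.loc[sorted(test_idx)]


@dataclass
class LDAModel:
    classes: tuple[str, ...]
    means: np.ndarray        # (n_classes, p)
    covariance: np.ndarray   # pooled within-class, ridge-regularized, (p, p)
    priors: np.ndarray       # (n_classes,), sums to 1
    feature_columns: tuple[str, ...]

    @property
    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.covariance)


def fit_lda(
    train: pd.DataFrame,
    feature_columns: Sequence[str] = FEATURE_COLUMNS,
) -> LDAModel:
    """Fit LDA with class-mean centroids and pooled within-class covariance.

    The pooled covariance sums within-class scatter over classes and
    divides by N - n_classes, then adds a ridge of
    ``RIDGE_LAMBDA * trace/p`` on the diagonal to guard against
    near-collinear shape features.  Priors are uniform: control classes
    have arbitrary replication unrelated to library prevalence.
    """
    cols = list(feature_columns)
    classes = tuple(c for c in CLASS_ORDER if c in set(train["class"]))
    p = len(cols)
    n_total = len(train)
    means = []
    scatter = np.zeros((p, p))
    for cls in classes:
        X = train.loc[train["class"] == cls, cols].to_numpy(dtype=float)
        if len(X) < p + 1:
            import warnings

            warnings.warn(
                f"class {cls!r} has {len(X)} samples for {p} features; "
                "covariance estimate may be unstable",
                stacklevel=2,
            )
        mu = X.mean(axis=0)
        means.append(mu)
        R = X - mu
        scatter += R.T @ R
    cov = scatter / (n_total - len(classes))
    cov = cov + RIDGE_LAMBDA * (np.trace(cov) / p) * np.eye(p)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 0:
        raise ValueError("pooled covariance singular after regularization")
    priors = np.full(len(classes), 1.0 / len(classes))
    return LDAModel(classes, np.asarray(means), cov, priors, tuple(cols))


def discriminants(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Linear discriminant scores d_c(x) = x'S^-1 mu_c - mu_c'S^-1 mu_c / 2 + log pi_c."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.feature_columns):
        raise ValueError(
            f"feature dimension mismatch: got {X.shape[1]}, expected {len(model.feature_columns)}"
        )
    P = model.precision
    lin = X @ P @ model.means.T
    const = -0.5 * np.einsum("cp,pq,cq->c", model.means, P, model.means) + np.log(model.priors)
    return lin + const


def posteriors(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Class posterior probabilities (softmax over discriminants)."""
    d = discriminants(model, X)
    d = d - d.max(axis=1, keepdims=True)
    e = np.exp(d)
    return e / e.sum(axis=1, keepdims=True)


def predict_and_rate(
    model: LDAModel,
    features: pd.DataFrame,
    labels: Sequence[str] | None = None,
) -> tuple[pd.Series, pd.DataFrame, float | None]:
    """Predict a class per well; with labels, also the misclassification rate.

    Ties in the discriminant are broken deterministically by the fixed
    class order (epithelial < intermediate < mesenchymal), which is the
    argmax convention on the ordered class axis.
    """
    if len(features) == 0:
        empty = pd.Series([], dtype=object, name="class")
        return empty, pd.DataFrame(columns=model.classes), None
    X = features[list(model.feature_columns)].to_numpy(dtype=float)
    post = posteriors(model, X)
    idx = np.argmax(discriminants(model, X), axis=1)
    pred = pd.Series(
        [model.classes[i] for i in idx], index=features.index, name="class"
    )
    post_df = pd.DataFrame(post, index=features.index, columns=model.classes)
    rate = None
    if labels is not None:
        labels = pd.Series(list(labels), index=features.index)
        rate = float((pred != labels).mean())
    return pred, post_df, rate


def classify_library(
    model: LDAModel, well_features: pd.DataFrame
) -> pd.DataFrame:
    """Apply a fitted model to the library wells of a feature table."""
    lib = well_features[well_features["content"] == LIBRARY]
    pred, post, _ = predict_and_rate(model, lib)
    out = lib[["plate", "well", "mir_name"]].copy()
    out["class"] = pred
    for cls in model.classes:
        out[f"p_{cls}"] = post[cls].to_numpy()
    return out
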