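"""Linear discriminant analysis of survey outcomes vs the environment.

Summarizes how light, nitrogen and prey separate the categorical outcomes of
a survey: the discriminant axes (linear combinations of the environmental
variables) and the proportion of between-class variance each axis explains
("proportion of trace").  Fitting solves the generalized eigenproblem of
between- vs within-class scatter with class-proportional priors; the heavy
lifting is delegated to scikit-learn's eigen solver, whose eigenvectors are
within-scatter-orthonormal (the same scaling convention as classical LDA
software).  Axis signs are not identifiable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = ["LdaModel", "DegeneracyError", "SchemaError", "fit_lda", "project"]


class DegeneracyError(ValueError):
    """Within-class scatter is singular for some variable."""


class SchemaError(ValueError):
    """Feature columns do not match the fitted variables."""


@dataclass
class LdaModel:
    """Fitted discriminant summary.

    Attributes
    ----------
    class_labels : list of str
        Outcome categories, in the fitted order.
    variables : list of str
        Feature column names, in the fitted order.
    scalings : ndarray, (n_variables, n_axes)
        Loadings of each variable on each discriminant axis.
    proportion_of_trace : ndarray, (n_axes,)
        Share of between-class variance per axis; sums to 1.
    class_means : ndarray, (n_classes, n_axes)
        Class centroids in discriminant space.
    grand_mean : ndarray, (n_variables,)
        Prior-weighted centroid used for centering before projection.
    """

    class_labels: list
    variables: list
    scalings: np.ndarray
    proportion_of_trace: np.ndarray
    class_means: np.ndarray
    grand_mean: np.ndarray

    def to_json(self) -> str:
        return json.dumps({
            "class_labels": list(self.class_labels),
            "variables": list(self.variables),
            "scalings": self.scalings.tolist(),
            "proportion_of_trace": self.proportion_of_trace.tolist(),
            "class_means": self.class_means.tolist(),
            "grand_mean": self.grand_mean.tolist(),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LdaModel":
        d = json.loads(text)
        return cls(
            class_labels=d["class_labels"],
            variables=d["variables"],
            scalings=np.asarray(d["scalings"], dtype=float),
            proportion_of_trace=np.asarray(d["proportion_of_trace"], dtype=float),
            class_means=np.asarray(d["class_means"], dtype=float),
            grand_mean=np.asarray(d["grand_mean"], dtype=float),
        )


def _as_matrix(features) -> tuple:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns)
    X = np.asarray(features, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def fit_lda(features, labels) -> LdaModel:
    """Fit LDA of categorical ``labels`` on the feature table.

    Variables that are exactly constant overall carry no information and are
    dropped (their loadings are reported as 0).  A variable that is constant
    *within* every class but varies between classes makes the within-class
    scatter singular and raises :class:`DegeneracyError` naming it.
    """
    X, names = _as_matrix(features)
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise DegeneracyError("need at least 2 classes")
    counts = np.bincount(y_idx)
    if np.any(counts < 1):
        raise DegeneracyError("every class needs at least one observation")

    # Overall-constant columns: droppable; within-constant but between-varying
    # columns: genuinely singular within-class scatter.
    keep = []
    for j, name in enumerate(names):
        col = X[:, j]
        if np.ptp(col) == 0:
            continue
        within_var = sum(np.var(col[y_idx == c]) * np.sum(y_idx == c)
                         for c in range(len(classes)))
        if within_var == 0:
            raise DegeneracyError(
                f"within-class scatter is singular: variable {name!r} is "
                "constant within every class"
            )
        keep.append(j)
    if not keep:
        raise DegeneracyError("no variable with nonzero variance")

    lda = LinearDiscriminantAnalysis(solver="eigen")
    lda.fit(X[:, keep], y)
    n_axes = min(len(classes) - 1, len(keep))
    scal_kept = lda.scalings_[:, :n_axes]
    ev = lda.explained_variance_ratio_[:n_axes]

    scalings = np.zeros((X.shape[1], n_axes))
    scalings[keep, :] = scal_kept
    grand_mean = np.zeros(X.shape[1])
    # class-proportional priors make the weighted grand mean the plain mean
    grand_mean[keep] = X[:, keep].mean(axis=0)
    # report loadings of dropped constants as 0 but center on their value
    dropped = [j for j in range(X.shape[1]) if j not in keep]
    for j in dropped:
        grand_mean[j] = X[0, j]

    centered_means = np.zeros((len(classes), n_axes))
    for c in range(len(classes)):
        mu = X[y_idx == c].mean(axis=0)
        centered_means[c] = (mu - grand_mean) @ scalings

    return LdaModel(
        class_labels=[str(c) for c in classes],
        variables=names,
        scalings=scalings,
        proportion_of_trace=ev / ev.sum(),
        class_means=centered_means,
        grand_mean=grand_mean,
    )


def project(model: LdaModel, features) -> np.ndarray:
    """Map feature rows to discriminant coordinates (center, then scalings)."""
    if isinstance(features, pd.DataFrame):
        if list(features.columns) != list(model.variables):
            raise SchemaError(
                f"feature columns {list(features.columns)} do not match "
                f"fitted variables {list(model.variables)}"
            )
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.shape[1] != len(model.variables):
            raise SchemaError("wrong number of feature columns")
    return (X - model.grand_mean) @ model.scalings
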