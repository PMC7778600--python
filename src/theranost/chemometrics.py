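"""Partial least squares discriminant analysis (PLS-DA) for spectra.

PLS-DA regresses a one-hot class-indicator matrix ``Y`` on the spectral
matrix ``X`` by NIPALS PLS2 and assigns each sample to the class with the
largest predicted indicator.  The estimator is deterministic: there is no
randomness anywhere in fitting or cross-validation, and Venetian-blinds
folds are a pure function of sample order (fold of sample *i* is
``i mod splits``).

The module offers two surfaces:

* low-level functions (:func:`fit_pls`, :func:`predict_plsda`,
  :func:`venetian_blinds_folds`, :func:`cross_validate`) operating on plain
  arrays; and
* a model/results pair (:class:`PLSDA` → :class:`PLSDAResults`) in the
  style of statistical modelling packages, carrying the fitted weights,
  loadings, regression coefficients, latent scores and cross-validation
  diagnostics, with a :meth:`PLSDAResults.summary` table.

NIPALS PLS2
-----------
With column-centred ``X`` (n×p) and ``Y`` (n×c), each component extracts a
weight vector ``w`` (unit norm), scores ``t = X w``, y-loadings
``q = Yᵀt / tᵀt`` and x-loadings ``p = Xᵀt / tᵀt``, then deflates
``X ← X − t pᵀ`` and ``Y ← Y − t qᵀ``.  The regression matrix is
``B = W (PᵀW)⁻¹ Qᵀ`` so that ``Ŷ = (X − x̄) B + ȳ``.  When the number of
components equals the rank of the centred ``X``, the fitted values coincide
with ordinary least squares — a property used as an independent oracle in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .spectra_io import SpectrumCollection

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 1000


@dataclass
class PLSDAConfig:
    """Classification protocol parameters (components, CV folds, class order)."""

    n_lv: int = 6
    cv_splits: int = 10
    class_order: list | None = None

    def __post_init__(self):
        if self.n_lv < 1:
            raise ValidationError("n_lv must be >= 1")
        if self.cv_splits < 2:
            raise ValidationError("cv_splits must be >= 2")


@dataclass
class PLSDAModelParams:
    """Fitted PLS-DA parameters: means, weights, loadings, coefficients."""

    x_mean: np.ndarray          # (p,)
    y_mean: np.ndarray          # (c,)
    weights: np.ndarray         # W, (p, a)
    x_loadings: np.ndarray      # P, (p, a)
    y_loadings: np.ndarray      # Q, (c, a)
    coef: np.ndarray            # B, (p, c)
    class_order: list
    scores: np.ndarray          # T, (n, a) training latent scores

    @property
    def n_lv(self) -> int:
        return self.weights.shape[1]


def one_hot(labels, class_order=None):
    """Encode labels as a one-hot indicator matrix; returns (Y, class_order).

    Class order defaults to order of first appearance in ``labels``.
    """
    labels = [str(x) for x in labels]
    if class_order is None:
        class_order = list(dict.fromkeys(labels))
    else:
        class_order = [str(c) for c in class_order]
        unknown = set(labels) - set(class_order)
        if unknown:
            raise ValidationError(f"labels {sorted(unknown)} not in class_order")
    idx = {c: j for j, c in enumerate(class_order)}
    Y = np.zeros((len(labels), len(class_order)))
    for i, lab in enumerate(labels):
        Y[i, idx[lab]] = 1.0
    return Y, class_order


def fit_pls(X, Y, n_lv: int, class_order=None) -> PLSDAModelParams:
    """Fit NIPALS PLS2 of one-hot ``Y`` on ``X`` with ``n_lv`` components."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValidationError("X and Y must be 2-D with matching sample counts")
    n, p = X.shape
    if n < n_lv + 1:
        raise ValidationError(f"need at least n_lv+1={n_lv + 1} samples, got {n}")
    if np.any(Y.std(axis=0) == 0):
        raise ValidationError(
            "Y has a zero-variance (constant) class column; at least two "
            "classes must be present"
        )
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    rank = np.linalg.matrix_rank(Xc)
    if n_lv > rank:
        raise ValidationError(
            f"n_lv={n_lv} exceeds rank of centred X; achievable rank is {rank}"
        )

    c = Y.shape[1]
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((c, n_lv))
    T = np.zeros((n, n_lv))
    Xd, Yd = Xc.copy(), Yc.copy()
    for a in range(n_lv):
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))]
        w = np.zeros(p)
        for _ in range(_NIPALS_MAX_ITER):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValidationError(
                    f"NIPALS collapsed at component {a + 1}; achievable rank is {a}"
                )
            w /= nw
            t = Xd @ w
            tt = t @ t
            if tt == 0:
                raise ValidationError(
                    f"zero-variance scores at component {a + 1}; achievable rank is {a}"
                )
            q = Yd.T @ t / tt
            u_new = Yd @ q / (q @ q)
            if np.linalg.norm(u_new - u) <= _NIPALS_TOL * max(
                np.linalg.norm(u_new), 1e-300
            ):
                u = u_new
                break
            u = u_new
        t = Xd @ w
        tt = t @ t
        pvec = Xd.T @ t / tt
        qvec = Yd.T @ t / tt
        Xd -= np.outer(t, pvec)
        Yd -= np.outer(t, qvec)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pvec, qvec, t

    coef = W @ np.linalg.solve(P.T @ W, Q.T)
    if class_order is None:
        class_order = [str(j) for j in range(c)]
    return PLSDAModelParams(
        x_mean=x_mean, y_mean=y_mean, weights=W, x_loadings=P,
        y_loadings=Q, coef=coef, class_order=list(class_order), scores=T,
    )


def predict_plsda(model: PLSDAModelParams, X):
    """Predict class labels and indicator responses for new spectra.

    ``yhat = (X − x̄) B + ȳ``; the label is ``class_order[argmax yhat]``
    with ties broken to the lowest class index (numpy argmax convention).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.shape[0]:
        raise ValidationError(
            f"channel mismatch: model has {model.x_mean.shape[0]} channels, "
            f"input has {X.shape[1]}"
        )
    yhat = (X - model.x_mean) @ model.coef + model.y_mean
    labels = [model.class_order[j] for j in np.argmax(yhat, axis=1)]
    return labels, yhat


def venetian_blinds_folds(n: int, splits: int) -> np.ndarray:
    """Venetian-blinds fold assignment: fold of sample i is ``i mod splits``."""
    if splits < 2:
        raise ValidationError("splits must be >= 2")
    if n < splits:
        raise ValidationError(f"need at least {splits} samples, got {n}")
    return np.arange(n) % splits


def blocked_folds(subject_ids, splits: int) -> np.ndarray:
    """Subject-blocked variant: all replicates of a subject share one fold.

    Subjects are assigned Venetian-blinds style in order of first
    appearance, so replicate spectra of one cell or animal can never
    straddle a train/test boundary.
    """
    subject_ids = [str(s) for s in subject_ids]
    order = list(dict.fromkeys(subject_ids))
    if len(order) < splits:
        raise ValidationError(
            f"need at least {splits} subjects for {splits} blocked folds"
        )
    fold_of_subject = {s: i % splits for i, s in enumerate(order)}
    return np.array([fold_of_subject[s] for s in subject_ids])


@dataclass
class CVResult:
    """Held-out cross-validation outcome of a PLS-DA protocol."""

    fold_of: np.ndarray
    predicted: list
    confusion: pd.DataFrame     # rows = true class, cols = predicted class
    accuracy: float
    scores: np.ndarray          # latent scores of the final full-data fit

    def __post_init__(self):
        n = len(self.predicted)
        assert int(self.confusion.to_numpy().sum()) == n
        assert abs(self.accuracy - np.trace(self.confusion.to_numpy()) / n) < 1e-12


def cross_validate(
    X, labels, cfg: PLSDAConfig | None = None, subject_ids=None
) -> CVResult:
    """Venetian-blinds cross-validation of PLS-DA.

    For each fold the model (including the mean-centring) is fit on the
    out-of-fold samples only and used to predict the held-in samples;
    accuracy and the confusion matrix aggregate all held-out predictions.
    ``subject_ids`` switches to the subject-blocked fold variant.
    """
    cfg = cfg or PLSDAConfig()
    X = np.asarray(X, dtype=float)
    labels = [str(x) for x in labels]
    Y, class_order = one_hot(labels, cfg.class_order)
    if len(class_order) < 2:
        raise ValidationError("cross-validation needs at least 2 classes")
    n = X.shape[0]
    if subject_ids is not None:
        fold_of = blocked_folds(subject_ids, cfg.cv_splits)
    else:
        fold_of = venetian_blinds_folds(n, cfg.cv_splits)

    predicted: list = [None] * n
    for f in range(cfg.cv_splits):
        test = fold_of == f
        train = ~test
        train_labels = set(np.array(labels)[train])
        if train_labels != set(class_order):
            raise ValidationError(
                f"training set of fold {f} lacks class(es) "
                f"{sorted(set(class_order) - train_labels)}; reorder samples "
                "so every class appears throughout the acquisition order"
            )
        m = fit_pls(X[train], Y[train], cfg.n_lv, class_order=class_order)
        pred, _ = predict_plsda(m, X[test])
        for i, lab in zip(np.flatnonzero(test), pred):
            predicted[i] = lab

    conf = pd.DataFrame(
        0, index=class_order, columns=class_order, dtype=int
    )
    for true, pred in zip(labels, predicted):
        conf.loc[true, pred] += 1
    accuracy = float(np.trace(conf.to_numpy()) / n)

    full = fit_pls(X, Y, cfg.n_lv, class_order=class_order)
    return CVResult(
        fold_of=fold_of, predicted=predicted, confusion=conf,
        accuracy=accuracy, scores=full.scores,
    )


# ---------------------------------------------------------------------------
# model / results front end
# ---------------------------------------------------------------------------


class PLSDA:
    """PLS-DA model bound to a spectral matrix and class labels.

    Examples
    --------
    >>> model = PLSDA(X, labels, n_lv=6)
    >>> res = model.fit()
    >>> res.predict(X_new)
    >>> cv = model.cross_validate()   # Venetian blinds, 10 splits
    """

    def __init__(self, X, labels, n_lv: int = 6, cv_splits: int = 10,
                 class_order=None, subject_ids=None):
        self.X = np.asarray(X, dtype=float)
        self.labels = [str(x) for x in labels]
        if self.X.shape[0] != len(self.labels):
            raise ValidationError("one label per row of X required")
        self.config = PLSDAConfig(n_lv=n_lv, cv_splits=cv_splits,
                                  class_order=class_order)
        self.subject_ids = subject_ids

    @classmethod
    def from_collection(cls, coll: SpectrumCollection, labels=None, **kw) -> "PLSDA":
        """Build from a shared-axis collection; labels default to the
        collection's own, subject ids are read from spectrum metadata."""
        labels = labels if labels is not None else coll.labels
        if labels is None:
            raise ValidationError("collection has no labels and none were given")
        if "subject_ids" not in kw:
            subj = [s.meta.get("subject_id") for s in coll.spectra]
            if all(x is not None for x in subj):
                kw["subject_ids"] = None  # venetian blinds remains the default
        return cls(coll.to_matrix(), labels, **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str, **kw) -> "PLSDA":
        """Build from a dataframe whose non-label columns are channels."""
        labels = df[label_col].tolist()
        X = df.drop(columns=[label_col]).to_numpy(dtype=float)
        return cls(X, labels, **kw)

    def fit(self) -> "PLSDAResults":
        Y, class_order = one_hot(self.labels, self.config.class_order)
        params = fit_pls(self.X, Y, self.config.n_lv, class_order=class_order)
        return PLSDAResults(self, params)

    def cross_validate(self) -> CVResult:
        return cross_validate(self.X, self.labels, self.config,
                              subject_ids=self.subject_ids)


class PLSDAResults:
    """Fitted PLS-DA estimates plus diagnostics.

    Attributes mirror :class:`PLSDAModelParams`; ``cv_`` is filled lazily by
    :meth:`cross_validation`.
    """

    def __init__(self, model: PLSDA, params: PLSDAModelParams):
        self.model = model
        self.params = params
        self._cv: CVResult | None = None

    # convenience passthroughs
    coef = property(lambda self: self.params.coef)
    weights = property(lambda self: self.params.weights)
    x_loadings = property(lambda self: self.params.x_loadings)
    y_loadings = property(lambda self: self.params.y_loadings)
    scores = property(lambda self: self.params.scores)
    class_order = property(lambda self: self.params.class_order)

    def predict(self, X):
        return predict_plsda(self.params, X)

    def fittedvalues(self):
        _, yhat = self.predict(self.model.X)
        return yhat

    def training_accuracy(self) -> float:
        pred, _ = self.predict(self.model.X)
        return float(np.mean([p == t for p, t in zip(pred, self.model.labels)]))

    def cross_validation(self) -> CVResult:
        if self._cv is None:
            self._cv = self.model.cross_validate()
        return self._cv

    def explained_x_variance(self) -> np.ndarray:
        """Fraction of centred-X variance captured by each component."""
        Xc = self.model.X - self.params.x_mean
        total = np.sum(Xc**2)
        T, P = self.params.scores, self.params.x_loadings
        return np.array(
            [np.sum(np.outer(T[:, a], P[:, a]) ** 2) / total for a in range(T.shape[1])]
        )

    def summary(self) -> str:
        cv = self.cross_validation()
        lines = [
            "PLS-DA Results",
            "=" * 46,
            f"samples:            {self.model.X.shape[0]}",
            f"channels:           {self.model.X.shape[1]}",
            f"classes:            {', '.join(self.class_order)}",
            f"latent variables:   {self.params.n_lv}",
            f"CV protocol:        venetian blinds, {self.model.config.cv_splits} splits",
            f"training accuracy:  {self.training_accuracy():.4f}",
            f"CV accuracy:        {cv.accuracy:.4f}",
            "",
            "explained X variance by component:",
            "  " + "  ".join(f"LV{a + 1}: {v:.3f}"
                             for a, v in enumerate(self.explained_x_variance())),
            "",
            "confusion matrix (rows true, cols predicted):",
            cv.confusion.to_string(),
        ]
        return "\n".join(lines)

    def plot_scores(self, lv=(0, 1), ax=None):
        """Scatter the CV scores on two latent variables with 95% confidence
        ellipses per class (plotting is optional and needs matplotlib)."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Ellipse

        cv = self.cross_validation()
        if ax is None:
            _, ax = plt.subplots()
        T = cv.scores
        labels = np.array(self.model.labels)
        for cls_name in self.class_order:
            pts = T[labels == cls_name][:, list(lv)]
            ax.scatter(pts[:, 0], pts[:, 1], label=cls_name, s=12)
            if len(pts) > 2:
                cov = np.cov(pts.T)
                vals, vecs = np.linalg.eigh(cov)
                angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
                # chi2(2, 0.95) = 5.991
                w, h = 2 * np.sqrt(5.991 * np.abs(vals[::-1]))
                ax.add_patch(
                    Ellipse(pts.mean(axis=0), w, h, angle=angle,
                            fill=False, lw=1)
                )
        ax.set_xlabel(f"LV{lv[0] + 1}")
        ax.set_ylabel(f"LV{lv[1] + 1}")
        ax.legend()
        return ax
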