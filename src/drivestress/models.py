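"""Binary logistic stress classifiers and their evaluation measures.

The stress model is a plain binary logistic regression of the windowed
conductance features: the probability of high stress for case *i* is
``p_i = 1 / (1 + exp(-(b0 + sum_j b_j x_ij)))``, fitted by maximum
likelihood, and a case is called high stress exactly when ``p_i > 0.5``
(ties go to low stress).

Evaluation uses the confusion counts with high stress as the positive
class:

* accuracy      A   = (TP + TN) / (TP + TN + FP + FN)
* sensitivity   Sn  = TP / (TP + FN)
* specificity   Sp  = TN / (TN + FP)
* pos. pred. v. PPV = TP / (TP + FP)

Goodness of fit is summarized by the likelihood-based pseudo-R² of Cox &
Snell, ``1 - exp(2 (ll0 - ll1) / n)``, and its Nagelkerke rescaling to a
unit maximum.  Ranking performance uses the rank (Mann-Whitney) AUC with
midranks for ties.  A comparison harness runs any set of fit/score
classifiers under stratified 10-fold cross-validation or a stratified
70/30 split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .errors import DegenerateLabelsError, SchemaError, SeparationWarning

#: Cap on the magnitude of the fitted linear predictor; beyond this the
#: likelihood is flat to machine precision and estimates are diverging.
_ETA_CAP = 30.0


@dataclass(frozen=True)
class LogisticModel:
    """A fitted binary logistic stress classifier.

    ``coefficients`` maps feature name to slope; ``constant`` is the
    intercept.  Log-likelihoods of the intercept-only (``ll_null``) and
    fitted (``ll_full``) models support the pseudo-R² measures.
    ``p_values`` holds per-coefficient Wald p-values (key ``"constant"``
    for the intercept).  ``separation`` marks fits where perfect
    separation was detected and the coefficients were capped.
    """

    coefficients: dict[str, float]
    constant: float
    ll_null: float
    ll_full: float
    n: int
    p_values: dict[str, float] = field(default_factory=dict)
    r2_cox_snell: float = np.nan
    r2_nagelkerke: float = np.nan
    converged: bool = True
    separation: bool = False

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients)

    def linear_predictor(self, X) -> np.ndarray:
        X = _as_feature_frame(X, self.feature_names)
        eta = np.full(len(X), self.constant, dtype=float)
        for name, coef in self.coefficients.items():
            eta += coef * X[name].to_numpy(dtype=float)
        return eta


def _as_feature_frame(X, feature_names: Sequence[str]) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        missing = [f for f in feature_names if f not in X.columns]
        if missing:
            raise SchemaError(f"missing model feature(s): {missing}")
        return X
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(feature_names):
        raise SchemaError(
            f"expected {len(feature_names)} feature columns, got {X.shape[1]}"
        )
    return pd.DataFrame(X, columns=list(feature_names))


def fit_logistic(X, y, feature_names: Sequence[str] | None = None) -> LogisticModel:
    """Maximum-likelihood logistic fit of binary labels on features.

    ``X`` is a DataFrame (columns are feature names) or 2-D array;
    ``y`` a binary vector with both classes present.  Newton iterations
    stop when the log-likelihood changes by less than 1e-8 or after 100
    iterations.  If the fitted linear predictor exceeds ±30 — the
    signature of perfect separation, where the likelihood surface is
    flat and estimates diverge — a :class:`SeparationWarning` is issued
    and the coefficients are scaled down so predictions stay finite;
    the reported log-likelihoods are those of the unconstrained fit.
    """
    y = np.asarray(y).astype(float)
    if feature_names is None:
        feature_names = (
            list(X.columns) if isinstance(X, pd.DataFrame)
            else [f"x{i}" for i in range(np.atleast_2d(X).shape[1])]
        )
    Xf = _as_feature_frame(X, feature_names)
    if len(Xf) != len(y):
        raise ValueError("X and y lengths differ")
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateLabelsError("labels contain a single class; cannot fit")
    if len(y) < len(feature_names) + 1:
        raise ValueError("need at least one more case than parameters")

    design = sm.add_constant(Xf[list(feature_names)].to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels' own separation chatter
        try:
            res = sm.Logit(y, design).fit(
                disp=0, maxiter=100, method="newton", tol=1e-8
            )
        except np.linalg.LinAlgError:
            # singular Hessian (collinear features or near-separation):
            # fall back to a gradient method
            res = sm.Logit(y, design).fit(
                disp=0, maxiter=200, method="bfgs", gtol=1e-8
            )
    params = np.asarray(res.params, dtype=float)
    eta = design @ params
    separation = bool(np.max(np.abs(eta)) > _ETA_CAP)
    if separation:
        warnings.warn(
            "perfect separation detected; coefficient estimates capped",
            SeparationWarning,
            stacklevel=2,
        )
        params = params * (_ETA_CAP / np.max(np.abs(eta)))

    pvals = np.asarray(res.pvalues, dtype=float)
    ll_null, ll_full = float(res.llnull), float(res.llf)
    cs, ng = pseudo_r2(ll_null, ll_full, len(y))
    names = list(feature_names)
    return LogisticModel(
        coefficients=dict(zip(names, params[1:])),
        constant=float(params[0]),
        ll_null=ll_null,
        ll_full=ll_full,
        n=len(y),
        p_values={"constant": float(pvals[0]), **dict(zip(names, pvals[1:]))},
        r2_cox_snell=cs,
        r2_nagelkerke=ng,
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation,
    )


def predict(model: LogisticModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities of high stress and the 0.5-rule labels.

    Returns ``(p, label)`` where ``label`` is True (high stress) exactly
    when ``p > 0.5`` — a probability of exactly one half is low stress.
    """
    eta = model.linear_predictor(X)
    p = 1.0 / (1.0 + np.exp(-eta))
    return p, p > 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with high stress as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion table must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally a confusion table from binary vectors (True = high stress)."""
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    return ConfusionCounts(
        tp=int(np.sum(y_true & y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
        tn=int(np.sum(~y_true & ~y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
    )


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, sensitivity, specificity and PPV as proportions.

    A metric whose denominator is zero is ``None`` (undefined), never
    silently zero.
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None

    def as_percent(self) -> dict[str, float | None]:
        return {
            k: (None if v is None else 100.0 * v)
            for k, v in (
                ("accuracy", self.accuracy),
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
            )
        }


def metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity, PPV from confusion counts."""

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return MetricSet(
        accuracy=ratio(c.tp + c.tn, c.total),
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
        ppv=ratio(c.tp, c.tp + c.fp),
    )


def pseudo_r2(ll_null: float, ll_full: float, n: int) -> tuple[float, float]:
    """Cox-Snell and Nagelkerke pseudo-R² from two log-likelihoods.

    ``CS = 1 - exp(2 (ll_null - ll_full) / n)`` and ``NG = CS / (1 -
    exp(2 ll_null / n))``; Nagelkerke divides by the largest value
    Cox-Snell can attain so a perfect fit scores 1.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if ll_full < ll_null - 1e-9:
        raise ValueError(
            f"full-model log-likelihood ({ll_full}) below null ({ll_null})"
        )
    cs = -np.expm1(2.0 * (ll_null - ll_full) / n)
    cs_max = -np.expm1(2.0 * ll_null / n)
    ng = cs / cs_max if cs_max > 0 else 0.0
    return float(max(cs, 0.0)), float(max(ng, 0.0))


def auc(scores, y_true) -> float:
    """Rank-based (Mann-Whitney) AUC with midranks for tied scores."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true).astype(bool)
    n_pos = int(y_true.sum())
    n_neg = int((~y_true).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("AUC needs both classes present")
    ranks = rankdata(scores)  # average (mid) ranks
    return float(
        (ranks[y_true].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def evaluate_model(y_true, y_pred) -> dict:
    """Percent-scale metric row (plus counts) for a prediction vector."""
    c = confusion(y_true, y_pred)
    m = metrics(c).as_percent()
    m.update(tp=c.tp, fp=c.fp, tn=c.tn, fn=c.fn)
    return m


# ---------------------------------------------------------------------------
# Classifier comparison harness
# ---------------------------------------------------------------------------

class LogisticClassifier:
    """Estimator-style wrapper over :func:`fit_logistic` / :func:`predict`."""

    def __init__(self) -> None:
        self.model_: LogisticModel | None = None

    def fit(self, X, y) -> "LogisticClassifier":
        self.model_ = fit_logistic(X, y)
        return self

    def predict(self, X) -> np.ndarray:
        _, labels = predict(self.model_, X)
        return labels

    def predict_proba(self, X) -> np.ndarray:
        p, _ = predict(self.model_, X)
        return np.column_stack([1.0 - p, p])


def _scores_of(clf, X) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return np.asarray(clf.predict_proba(X))[:, 1]
    return np.asarray(clf.decision_function(X), dtype=float)


def default_comparison_classifiers(seed: int = 0) -> dict[str, object]:
    """The five stock comparison learners, treated as black boxes.

    Random forest (RF), AdaBoost (AB), naive Bayes (NB), support vector
    machine (SVM) and multi-layer perceptron (MLP), all at library
    defaults apart from the seed.
    """
    from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    return {
        "RF": RandomForestClassifier(random_state=seed),
        "AB": AdaBoostClassifier(random_state=seed),
        "NB": GaussianNB(),
        "SVM": make_pipeline(StandardScaler(), SVC(random_state=seed)),
        "MLP": make_pipeline(
            StandardScaler(),
            MLPClassifier(random_state=seed, max_iter=500),
        ),
    }


def evaluate_classifiers(
    X,
    y,
    classifiers: Mapping[str, object],
    scheme: str = "cv10",
    seed: int = 0,
    groups=None,
) -> pd.DataFrame:
    """Sn/Sp/PPV/AUC per classifier under a resampling scheme.

    ``scheme='cv10'`` pools out-of-fold predictions from a stratified
    10-fold split; ``scheme='split70_30'`` uses one stratified 70/30
    train/test split.  When ``groups`` is given (e.g. the drive index
    of each window) the folds and the split keep whole groups together:
    overlapping sliding windows from one drive share most of their
    events, so scattering them across train and test folds would leak
    group identity into the evaluation.  Classifiers follow the usual
    fit/predict(_proba) estimator protocol and are cloned-by-refit on
    each fold.  Requires at least 20 cases per class for
    cross-validation so every fold sees both classes.
    """
    from sklearn.model_selection import (
        GroupShuffleSplit,
        StratifiedGroupKFold,
        StratifiedKFold,
        train_test_split,
    )

    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if scheme == "cv10" and min(n_pos, n_neg) < 20:
        raise ValueError(
            f"10-fold CV needs >= 20 cases per class, got {n_pos} / {n_neg}"
        )
    if scheme not in ("cv10", "split70_30"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if groups is not None:
        groups = np.asarray(groups)

    rows = []
    for name, clf in classifiers.items():
        if scheme == "cv10":
            if groups is None:
                skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
                splits = skf.split(X, y)
            else:
                skf = StratifiedGroupKFold(
                    n_splits=10, shuffle=True, random_state=seed
                )
                splits = skf.split(X, y, groups)
            pred = np.zeros(len(y), dtype=bool)
            score = np.zeros(len(y), dtype=float)
            for train, test in splits:
                fitted = _refit(clf, X.iloc[train], y[train])
                pred[test] = np.asarray(fitted.predict(X.iloc[test])).astype(bool)
                score[test] = _scores_of(fitted, X.iloc[test])
            y_eval = y
        else:
            if groups is None:
                idx_train, idx_test = train_test_split(
                    np.arange(len(y)), test_size=0.3, stratify=y, random_state=seed
                )
            else:
                gss = GroupShuffleSplit(
                    n_splits=1, test_size=0.3, random_state=seed
                )
                idx_train, idx_test = next(gss.split(X, y, groups))
            fitted = _refit(clf, X.iloc[idx_train], y[idx_train])
            pred = np.asarray(fitted.predict(X.iloc[idx_test])).astype(bool)
            score = _scores_of(fitted, X.iloc[idx_test])
            y_eval = y[idx_test]
        row = {"classifier": name, "scheme": scheme}
        row.update(evaluate_model(y_eval, pred))
        row["auc"] = 100.0 * auc(score, y_eval)
        rows.append(row)
    return pd.DataFrame(rows)


def _refit(clf, X, y):
    from sklearn.base import clone

    try:
        clf = clone(clf)
    except TypeError:
        clf = type(clf)()  # non-sklearn estimators: fresh instance
    return clf.fit(X, y)
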