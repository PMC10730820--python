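"""NIPALS latent-variable models: PCA, PLS1 and OPLS-DA.

The central object is :class:`OPLSDA`, a two-class discriminant model in
the statsmodels mould: construct it from data, call :meth:`OPLSDA.fit`,
and get back an :class:`OPLSDAResults` carrying scores, loadings, the
assembled linear coefficients, training diagnostics (R2X, R2Y, RMSEE) and
methods for cross-validated Q2Y, permutation diagnostics, VIP feature
importance, prediction and JSON serialization.

Model form
----------
Predictors are centered and scaled to unit variance; the class label is
coded 0/1 and centered. Orthogonal components — systematic predictor
variation uncorrelated with the class — are estimated by the
orthogonal-projection construction (w_ortho proportional to
p - (w'p) w) and removed from X before the predictive PLS1 component(s)
are fitted. Because every step is linear, the whole model collapses to a
single linear form y_hat = b0 + x_scaled . b, which is what gets
serialized and projected onto new cohorts.

Quality metrics follow chemometrics convention: R2X/R2Y are training
variance fractions, Q2Y = 1 - PRESS/SS from stratified K-fold
cross-validation with scaling refit inside each training split, and pQ2
is the add-one permutation p-value for Q2Y. Verdicts: Q2Y > 0.5 good,
0 < Q2Y < 0.5 some predictive character, Q2Y < 0 none.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .tables import FeatureTable

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500

SERIALIZATION_VERSION = 1


# ---------------------------------------------------------------------------
# NIPALS PCA
# ---------------------------------------------------------------------------

def nipals_pca(
    X, n_comp: int, center: bool = True, scale: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal components by NIPALS with successive deflation.

    Parameters
    ----------
    X : array-like, samples x features.
    n_comp : number of components; must be <= min(n_samples - 1, n_features).
    center, scale : column preprocessing applied before extraction.

    Returns
    -------
    scores : (n, k), loadings : (p, k) orthonormal, r2x : (k,) variance
    fraction per component (nonincreasing).

    Each component is initialized from the column of maximal variance and
    iterated until the relative score change falls below 1e-10; sign is
    fixed so the largest-magnitude loading entry is positive.
    """
    X = np.asarray(X, dtype=float).copy()
    n, p = X.shape
    if n_comp > min(n - 1 if center else n, p):
        raise ValueError(f"n_comp={n_comp} exceeds matrix rank bound")
    if center:
        X -= X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant column; cannot scale")
        X /= sd
    ss_total = float(np.sum(X**2))
    scores = np.zeros((n, n_comp))
    loadings = np.zeros((p, n_comp))
    r2x = np.zeros(n_comp)
    for a in range(n_comp):
        col_var = X.var(axis=0)
        t = X[:, int(np.argmax(col_var))].copy()
        if not np.any(t):
            break  # residual is exactly zero: remaining components are null
        for it in range(_NIPALS_MAX_ITER):
            w = X.T @ t
            w /= np.linalg.norm(w)
            t_new = X @ w
            if np.linalg.norm(t_new - t) <= _NIPALS_TOL * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        else:
            raise RuntimeError(
                f"NIPALS PCA component {a + 1} failed to converge after {_NIPALS_MAX_ITER} iterations"
            )
        w = _fix_sign(w)
        t = X @ w
        scores[:, a] = t
        loadings[:, a] = w
        r2x[a] = float(t @ t) / ss_total if ss_total > 0 else 0.0
        X -= np.outer(t, w)
    return scores, loadings, r2x


def _fix_sign(w: np.ndarray) -> np.ndarray:
    """Resolve NIPALS sign indeterminacy: largest-|.| entry positive."""
    if w[np.argmax(np.abs(w))] < 0:
        return -w
    return w


# ---------------------------------------------------------------------------
# Core OPLS fit on preprocessed arrays
# ---------------------------------------------------------------------------

def _fit_opls_arrays(Xs: np.ndarray, yc: np.ndarray, n_pred: int, n_ortho: int) -> dict:
    """Fit OPLS on scaled X and centered y; returns component arrays.

    Orthogonal components are extracted first (Trygg-Wold orthogonal
    projection), then ``n_pred`` NIPALS PLS1 components on the filtered
    matrix. Everything is assembled into one coefficient vector ``b`` on
    the scaled-X scale.
    """
    n, p = Xs.shape
    ss_x = float(np.sum(Xs**2))
    ss_y = float(yc @ yc)
    if ss_y == 0:
        raise ValueError("response is constant; need two classes")

    # class-predictive direction used to split off orthogonal variation
    w = Xs.T @ yc
    w /= np.linalg.norm(w)

    W_o, T_o, P_o = [], [], []
    Xf = Xs.copy()
    for _ in range(n_ortho):
        t = Xf @ w
        pv = Xf.T @ t / (t @ t)
        w_o = pv - (w @ pv) * w
        norm_wo = np.linalg.norm(w_o)
        if norm_wo < 1e-12 * np.linalg.norm(pv):
            break  # no orthogonal variation left
        w_o = _fix_sign(w_o / norm_wo)
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)

    # predictive PLS1 components on the filtered matrix
    W, T, P, Q = [], [], [], []
    Xd, yd = Xf.copy(), yc.copy()
    for _ in range(n_pred):
        w_a = Xd.T @ yd
        norm_w = np.linalg.norm(w_a)
        if norm_w < 1e-14:
            break
        w_a = _fix_sign(w_a / norm_w)
        t_a = Xd @ w_a
        tt = float(t_a @ t_a)
        if tt < 1e-14:
            break
        q_a = float(yd @ t_a) / tt
        p_a = Xd.T @ t_a / tt
        Xd = Xd - np.outer(t_a, p_a)
        yd = yd - q_a * t_a
        W.append(w_a)
        T.append(t_a)
        P.append(p_a)
        Q.append(q_a)
    if not W:
        raise ValueError("no predictive component could be extracted")

    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    qv = np.asarray(Q)
    # PLS1 regression vector on the filtered scale
    b_pls = Wm @ np.linalg.solve(Pm.T @ Wm, qv)
    # fold the orthogonal filtering into the coefficients: x_f = x * prod(I - w_o p_o')
    b = b_pls.copy()
    for w_o, p_o in zip(reversed(W_o), reversed(P_o)):
        b = b - w_o * (p_o @ b)

    fitted = Xs @ b
    residuals = yc - fitted
    Tm = np.column_stack(T)
    r2x_pred = np.array([float(t @ t) * float(pv @ pv) / ss_x for t, pv in zip(T, P)])
    r2x_ortho = np.array([float(t @ t) * float(pv @ pv) / ss_x for t, pv in zip(T_o, P_o)])
    r2y = 1.0 - float(residuals @ residuals) / ss_y
    return {
        "W": Wm, "T": Tm, "P": Pm, "q": qv,
        "W_ortho": np.column_stack(W_o) if W_o else np.zeros((p, 0)),
        "T_ortho": np.column_stack(T_o) if T_o else np.zeros((n, 0)),
        "P_ortho": np.column_stack(P_o) if P_o else np.zeros((p, 0)),
        "coef": b, "fitted": fitted, "r2y": r2y,
        "r2x_pred": r2x_pred, "r2x_ortho": r2x_ortho,
    }


def _scale_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant feature after scaling; remove it before fitting")
    return mean, sd


# ---------------------------------------------------------------------------
# Diagnostics containers
# ---------------------------------------------------------------------------

@dataclass
class ModelDiagnostics:
    """Training and cross-validated quality of a fitted discriminant model."""

    r2x_pred: float
    r2x_ortho: float
    r2x_cum: float
    r2y_cum: float
    rmsee: float
    q2y_cum: float | None = None
    pq2: float | None = None

    @property
    def verdict(self) -> str:
        return model_quality(self.q2y_cum, self.pq2).verdict if self.q2y_cum is not None else "unknown"

    def to_dict(self) -> dict:
        d = {
            "R2X_pred": self.r2x_pred, "R2X_ortho": self.r2x_ortho, "R2X_cum": self.r2x_cum,
            "R2Y_cum": self.r2y_cum, "RMSEE": self.rmsee,
            "Q2Y_cum": self.q2y_cum, "pQ2": self.pq2,
        }
        if self.q2y_cum is not None:
            mq = model_quality(self.q2y_cum, self.pq2)
            d["verdict"] = mq.verdict
            d["rejected"] = mq.rejected
        return d


@dataclass
class ModelQuality:
    """Predictive-ability verdict derived from Q2Y (and optionally pQ2)."""

    q2y: float
    verdict: str
    rejected: bool


def model_quality(q2y: float, pq2: float | None = None) -> ModelQuality:
    """Map Q2Y to its verdict: > 0.5 good, (0, 0.5) some, < 0 none.

    A model is additionally flagged ``rejected`` when Q2Y < 0 or its
    permutation p-value pQ2 >= 0.05 — the rule under which an overfitted
    branch is discarded from further assessment.
    """
    if q2y > 1:
        raise ValueError(f"Q2Y cannot exceed 1 (got {q2y})")
    if q2y > 0.5:
        verdict = "good"
    elif q2y > 0:
        verdict = "some"
    else:
        verdict = "none"
    rejected = (q2y < 0) or (pq2 is not None and pq2 >= 0.05)
    return ModelQuality(q2y=q2y, verdict=verdict, rejected=rejected)


@dataclass
class PermutationReport:
    """Null distribution of (R2Y, Q2Y) under label permutation."""

    n_perm: int
    observed_r2y: float
    observed_q2y: float
    permuted_r2y: np.ndarray
    permuted_q2y: np.ndarray

    @property
    def p_q2(self) -> float:
        return (1 + int(np.sum(self.permuted_q2y >= self.observed_q2y))) / (self.n_perm + 1)

    @property
    def p_r2y(self) -> float:
        return (1 + int(np.sum(self.permuted_r2y >= self.observed_r2y))) / (self.n_perm + 1)

    def to_dict(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "observed_R2Y": self.observed_r2y,
            "observed_Q2Y": self.observed_q2y,
            "pQ2": self.p_q2,
            "pR2Y": self.p_r2y,
            "permuted_R2Y": self.permuted_r2y.tolist(),
            "permuted_Q2Y": self.permuted_q2y.tolist(),
        }


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class OPLSDA:
    """Two-class OPLS discriminant model.

    Parameters
    ----------
    endog : array-like of group labels (exactly two distinct values).
    exog : array-like or DataFrame, samples x features.
    feature_names : optional; inferred from DataFrame columns.
    positive : the label coded 1 (the "case"); defaults to the
        lexicographically larger label.

    Examples
    --------
    >>> model = OPLSDA(labels, X, feature_names=names)
    >>> res = model.fit(n_pred=1, n_ortho=1)
    >>> res.diagnostics.r2y_cum  # doctest: +SKIP
    """

    def __init__(self, endog, exog, feature_names=None, positive=None):
        if isinstance(exog, pd.DataFrame):
            if feature_names is None:
                feature_names = list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(self.exog.shape[1])]
        self.feature_names = list(feature_names)
        endog = np.asarray(endog)
        classes = sorted(map(str, np.unique(endog.astype(str))))
        if len(classes) != 2:
            raise ValueError(f"OPLS-DA requires exactly two classes, found {classes}")
        if positive is None:
            positive = classes[1]
        else:
            positive = str(positive)
            if positive not in classes:
                raise ValueError(f"positive class {positive!r} not among {classes}")
        negative = classes[0] if classes[1] == positive else classes[1]
        self.classes_ = (negative, positive)
        self.y01 = (endog.astype(str) == positive).astype(float)
        counts = np.bincount(self.y01.astype(int), minlength=2)
        if counts.min() < 3:
            raise ValueError("each class needs >= 3 samples")
        if np.isnan(self.exog).any():
            raise ValueError("predictor matrix contains missing values; impute or drop first")

    @classmethod
    def from_feature_table(cls, table: FeatureTable, positive=None) -> "OPLSDA":
        """Build from a :class:`FeatureTable`, excluding QC samples.

        The positive (coded-1) class defaults to the label ``"case"``
        when present, else the lexicographically larger label.
        """
        data = table.non_qc()
        labels = data.group_labels().to_numpy()
        if positive is None and "case" in set(map(str, labels)):
            positive = "case"
        return cls(labels, data.values, positive=positive)

    def fit(self, n_pred: int = 1, n_ortho: int = 1) -> "OPLSDAResults":
        """Fit with ``n_pred`` predictive and ``n_ortho`` orthogonal components."""
        n = self.exog.shape[0]
        if n_pred < 1:
            raise ValueError("need at least one predictive component")
        if n_ortho < 0 or n_ortho >= n - 2:
            raise ValueError(f"n_ortho must be in [0, n_samples - 2) = [0, {n - 2})")
        mean, sd = _scale_fit(self.exog)
        Xs = (self.exog - mean) / sd
        y_mean = float(self.y01.mean())
        yc = self.y01 - y_mean
        comps = _fit_opls_arrays(Xs, yc, n_pred, n_ortho)
        dof = n - 1 - comps["W"].shape[1]
        ssres = float(np.sum((yc - comps["fitted"]) ** 2))
        rmsee = float(np.sqrt(ssres / dof)) if dof > 0 else float("nan")
        return OPLSDAResults(self, mean, sd, y_mean, comps, rmsee)


class OPLSDAResults:
    """Fitted OPLS-DA state: scaling, components, coefficients, diagnostics."""

    def __init__(self, model: OPLSDA, x_mean, x_sd, y_mean, comps: dict, rmsee: float):
        self.model = model
        self.feature_names = model.feature_names
        self.classes_ = model.classes_
        self.x_mean = np.asarray(x_mean, dtype=float)
        self.x_sd = np.asarray(x_sd, dtype=float)
        self.y_mean = float(y_mean)
        self.weights = comps["W"]                 # p x n_pred, unit norm
        self.scores = comps["T"]                  # n x n_pred
        self.loadings = comps["P"]
        self.y_loadings = comps["q"]              # (n_pred,)
        self.weights_ortho = comps["W_ortho"]
        self.scores_ortho = comps["T_ortho"]
        self.loadings_ortho = comps["P_ortho"]
        self.coef = comps["coef"]                 # on the scaled-X scale
        self.intercept = self.y_mean
        self.fitted_values = comps["fitted"] + self.y_mean   # on the 0/1 coded scale
        self.rmsee = rmsee
        self._r2x_pred = comps["r2x_pred"]
        self._r2x_ortho = comps["r2x_ortho"]
        self._r2y = comps["r2y"]
        self.q2y: float | None = None
        self.permutation_report: PermutationReport | None = None

    # -- structure -------------------------------------------------------
    @property
    def n_pred(self) -> int:
        return self.weights.shape[1]

    @property
    def n_ortho(self) -> int:
        return self.weights_ortho.shape[1]

    @property
    def diagnostics(self) -> ModelDiagnostics:
        return ModelDiagnostics(
            r2x_pred=float(self._r2x_pred.sum()),
            r2x_ortho=float(self._r2x_ortho.sum()),
            r2x_cum=float(self._r2x_pred.sum() + self._r2x_ortho.sum()),
            r2y_cum=float(self._r2y),
            rmsee=self.rmsee,
            q2y_cum=self.q2y,
            pq2=self.permutation_report.p_q2 if self.permutation_report else None,
        )

    # -- prediction ------------------------------------------------------
    def _align(self, X_new) -> np.ndarray:
        if isinstance(X_new, FeatureTable):
            X_new = X_new.non_qc().values
        if isinstance(X_new, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X_new.columns]
            if missing:
                raise KeyError(f"prediction input lacks model features: {missing}")
            extra = [c for c in X_new.columns if c not in self.feature_names]
            if extra:
                warnings.warn(f"ignoring {len(extra)} features absent from the model")
            X_new = X_new[self.feature_names].to_numpy(dtype=float)
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X_new.shape[1]}"
            )
        return X_new

    def decision_function(self, X_new) -> np.ndarray:
        """Continuous score on the coded (0/1) scale after training scaling."""
        X = self._align(X_new)
        Xs = (X - self.x_mean) / self.x_sd
        return Xs @ self.coef + self.intercept

    def predict(self, X_new) -> tuple[np.ndarray, np.ndarray]:
        """Continuous scores and hard class labels (midpoint-0.5 rule)."""
        y_hat = self.decision_function(X_new)
        labels = np.where(y_hat >= 0.5, self.classes_[1], self.classes_[0])
        return y_hat, labels

    # -- validation ------------------------------------------------------
    def cross_validate(self, folds: int = 7, seed: int = 0) -> float:
        """Stratified K-fold Q2Y; stores and returns it."""
        self.q2y = cross_validate_q2(
            self.model.exog, self.model.y01, self.n_pred, self.n_ortho, folds=folds, seed=seed
        )
        return self.q2y

    def permutation_test(self, n_perm: int = 999, folds: int = 7, seed: int = 0) -> PermutationReport:
        """Label-permutation null for R2Y and Q2Y; stores and returns the report."""
        if self.q2y is None:
            self.cross_validate(folds=folds, seed=seed)
        report = permutation_test(
            self.model.exog, self.model.y01, self.n_pred, self.n_ortho,
            n_perm=n_perm, folds=folds, seed=seed,
            observed_r2y=self._r2y, observed_q2y=self.q2y,
        )
        self.permutation_report = report
        return report

    def vip(self) -> pd.Series:
        """Variable importance in the projection over predictive components.

        VIP_j = sqrt( p * sum_a SS_a w_aj^2 / sum_a SS_a ) with
        SS_a = q_a^2 t_a't_a; mean squared VIP equals 1 by construction.
        """
        p = len(self.feature_names)
        ss = self.y_loadings**2 * np.einsum("ia,ia->a", self.scores, self.scores)
        total = float(ss.sum())
        if total <= 0:
            raise ValueError("zero explained y-variance; VIP undefined")
        vip = np.sqrt(p * (self.weights**2 @ ss) / total)
        return pd.Series(vip, index=self.feature_names, name="VIP")

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            "OPLS-DA Results",
            "=" * 46,
            f"Classes (0/1):     {self.classes_[0]} / {self.classes_[1]}",
            f"Samples:           {self.model.exog.shape[0]}",
            f"Features:          {len(self.feature_names)}",
            f"Components:        {self.n_pred} predictive + {self.n_ortho} orthogonal",
            f"R2X (pred/ortho):  {d.r2x_pred:.3f} / {d.r2x_ortho:.3f} (cum {d.r2x_cum:.3f})",
            f"R2Y(cum):          {d.r2y_cum:.3f}",
            f"RMSEE:             {d.rmsee:.3f}",
        ]
        if self.q2y is not None:
            lines.append(f"Q2Y(cum):          {self.q2y:.3f}")
        if self.permutation_report is not None:
            lines.append(f"pQ2:               {self.permutation_report.p_q2:.3g}")
        if self.q2y is not None:
            mq = model_quality(self.q2y, self.permutation_report.p_q2 if self.permutation_report else None)
            flag = " (rejected)" if mq.rejected else ""
            lines.append(f"Verdict:           {mq.verdict}{flag}")
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": SERIALIZATION_VERSION,
            "classes": list(self.classes_),
            "feature_names": self.feature_names,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "n_pred": self.n_pred,
            "n_ortho": self.n_ortho,
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "weights_ortho": self.weights_ortho.tolist(),
            "loadings_ortho": self.loadings_ortho.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "rmsee": self.rmsee,
            "r2x_pred": self._r2x_pred.tolist(),
            "r2x_ortho": self._r2x_ortho.tolist(),
            "r2y": self._r2y,
            "q2y": self.q2y,
            "vip": self.vip().tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PortableModel":
        with open(path) as fh:
            doc = json.load(fh)
        return PortableModel(doc)


class PortableModel:
    """Deserialized linear form of a trained model, for cross-run prediction."""

    def __init__(self, doc: dict):
        if doc.get("format_version") != SERIALIZATION_VERSION:
            raise ValueError(f"unsupported model format version {doc.get('format_version')!r}")
        self.classes_ = tuple(doc["classes"])
        self.feature_names = doc["feature_names"]
        self.x_mean = np.asarray(doc["x_mean"])
        self.x_sd = np.asarray(doc["x_sd"])
        self.coef = np.asarray(doc["coef"])
        self.intercept = float(doc["intercept"])

    def predict(self, X_new) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X_new, pd.DataFrame):
            X_new = X_new[self.feature_names].to_numpy(dtype=float)
        Xs = (np.asarray(X_new, dtype=float) - self.x_mean) / self.x_sd
        y_hat = Xs @ self.coef + self.intercept
        labels = np.where(y_hat >= 0.5, self.classes_[1], self.classes_[0])
        return y_hat, labels


# ---------------------------------------------------------------------------
# Functional surface: CV, permutation, convenience fit
# ---------------------------------------------------------------------------

def fit_oplsda(X, y_labels, n_pred: int = 1, n_ortho: int = 1,
               feature_names=None, positive=None) -> OPLSDAResults:
    """Convenience wrapper: construct :class:`OPLSDA` and fit."""
    return OPLSDA(y_labels, X, feature_names=feature_names, positive=positive).fit(
        n_pred=n_pred, n_ortho=n_ortho
    )


def cross_validate_q2(X, y01, n_pred: int = 1, n_ortho: int = 1,
                      folds: int = 7, seed: int = 0) -> float:
    """Stratified K-fold cross-validated Q2Y = 1 - PRESS/SS.

    Scaling and the full component structure are refit inside every
    training split; PRESS accumulates squared out-of-fold errors of the
    coded response, and SS is the total sum of squares of the centered
    coded response.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y01, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n_min = int(np.bincount(y01.astype(int), minlength=2).min())
    folds = min(folds, n_min)  # every fold's training split must keep both classes
    if folds < 2:
        raise ValueError("too few samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = 0.0
    for train, test in skf.split(X, y01):
        mean, sd = _scale_fit(X[train])
        Xs_tr = (X[train] - mean) / sd
        y_mean = float(y01[train].mean())
        comps = _fit_opls_arrays(Xs_tr, y01[train] - y_mean, n_pred, n_ortho)
        Xs_te = (X[test] - mean) / sd
        y_hat = Xs_te @ comps["coef"] + y_mean
        press += float(np.sum((y01[test] - y_hat) ** 2))
    ss = float(np.sum((y01 - y01.mean()) ** 2))
    return 1.0 - press / ss


def permutation_test(X, y01, n_pred: int = 1, n_ortho: int = 1,
                     n_perm: int = 999, folds: int = 7, seed: int = 0,
                     observed_r2y: float | None = None,
                     observed_q2y: float | None = None) -> PermutationReport:
    """Permutation diagnostics: refit + cross-validate under shuffled labels.

    pQ2 uses the add-one estimator (1 + #{Q2_perm >= Q2_obs}) / (n_perm + 1),
    so it can never report zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y01, dtype=float)
    if observed_r2y is None or observed_q2y is None:
        mean, sd = _scale_fit(X)
        comps = _fit_opls_arrays((X - mean) / sd, y01 - y01.mean(), n_pred, n_ortho)
        if observed_r2y is None:
            observed_r2y = comps["r2y"]
        if observed_q2y is None:
            observed_q2y = cross_validate_q2(X, y01, n_pred, n_ortho, folds=folds, seed=seed)
    rng = np.random.default_rng(seed)
    perm_r2, perm_q2 = np.empty(n_perm), np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y01)
        mean, sd = _scale_fit(X)
        comps = _fit_opls_arrays((X - mean) / sd, y_perm - y_perm.mean(), n_pred, n_ortho)
        perm_r2[i] = comps["r2y"]
        perm_q2[i] = cross_validate_q2(X, y_perm, n_pred, n_ortho, folds=folds, seed=seed + 1 + i)
    return PermutationReport(
        n_perm=n_perm,
        observed_r2y=float(observed_r2y),
        observed_q2y=float(observed_q2y),
        permuted_r2y=perm_r2,
        permuted_q2y=perm_q2,
    )
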