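"""Orthogonal PLS discriminant analysis (OPLS-DA), from scratch.

For a binary class vector y, OPLS-DA splits the (autoscaled) data matrix
X into one predictive latent component aligned with y plus ``n_ortho``
orthogonal components that capture systematic variation uncorrelated
with y (orthogonal signal correction).  The algorithm is the standard
O-PLS sequence:

1. ``w ∝ X'y`` (normalised PLS weight);
2. for each orthogonal component: ``t = Xw``, ``p = X't/t't``,
   ``w_o ∝ p − (w'p)w`` (the part of the loading not collinear with the
   predictive weight), ``t_o = Xw_o``, ``p_o = X't_o/t_o't_o``, deflate
   ``X ← X − t_o p_o'``;
3. one predictive PLS component on the filtered X: ``t = Xw``,
   ``p = X't/t't``, ``q = y't/t't``.

Model statistics: R2X (fraction of autoscaled-X sum of squares carried
by predictive + orthogonal components), R2Y (fraction of centred-y sum
of squares described), Q2 (1 − PRESS/SS under leave-one-out refits), and
VIP with mean(VIP²) = 1.  With ``n_ortho=0`` the model is exactly
single-component PLS1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["OplsModel", "RocCurve", "fit_opls", "loo_cv_opls",
           "roc", "classify_at_cutoff", "youden_cutoff"]


@dataclass
class OplsModel:
    """Fitted OPLS-DA model (see module docstring for the algorithm)."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    w: np.ndarray            # predictive weight (unit norm)
    p: np.ndarray            # predictive loading
    t: np.ndarray            # predictive score
    q: float                 # y-loading
    W_o: np.ndarray          # orthogonal weights, columns unit norm
    P_o: np.ndarray          # orthogonal loadings
    T_o: np.ndarray          # orthogonal scores
    n_ortho: int
    R2X: float
    R2Y: float
    vip: np.ndarray
    vip_pred: np.ndarray
    Q2: float | None = None
    cutoff: float | None = None
    feature_names: list[str] = field(default_factory=list)

    def transform(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive and orthogonal scores for new samples."""
        X = np.asarray(X, dtype=float)
        Z = (X - self.x_mean) / self.x_sd
        T_o = np.zeros((Z.shape[0], self.n_ortho))
        for k in range(self.n_ortho):
            t_o = Z @ self.W_o[:, k]
            T_o[:, k] = t_o
            Z = Z - np.outer(t_o, self.P_o[:, k])
        return Z @ self.w, T_o

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted ŷ (continuous class score around 0/1)."""
        t, _ = self.transform(X)
        return t * self.q + self.y_mean


def _autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance column(s) at index {bad[:5]}")
    return (X - mean) / sd, mean, sd


def fit_opls(
    X: np.ndarray,
    y: np.ndarray,
    n_ortho: int = 0,
    feature_names: list[str] | None = None,
) -> OplsModel:
    """Fit OPLS-DA with one predictive and ``n_ortho`` orthogonal components.

    X is autoscaled column-wise (unit variance), y centred.  Requires two
    samples per class and ``n_ortho`` below the rank of the centred X.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("y must contain exactly two classes")
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class")
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    Z, x_mean, x_sd = _autoscale(X)
    rank = np.linalg.matrix_rank(Z)
    if n_ortho >= rank:
        raise ValueError(f"n_ortho={n_ortho} >= rank(X)={rank}")
    y_mean = float(y.mean())
    yc = y - y_mean
    ss_x_total = float(np.sum(Z**2))
    ss_y_total = float(np.sum(yc**2))

    Zf = Z.copy()
    n_feat = Z.shape[1]
    W_o = np.zeros((n_feat, n_ortho))
    P_o = np.zeros((n_feat, n_ortho))
    T_o = np.zeros((Z.shape[0], n_ortho))
    ss_x_ortho = 0.0
    for k in range(n_ortho):
        w = Zf.T @ yc
        w /= np.linalg.norm(w)
        t = Zf @ w
        p = Zf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            raise ValueError(
                f"no orthogonal variation left at component {k + 1}"
            )
        w_o /= nrm
        t_o = Zf @ w_o
        p_o = Zf.T @ t_o / (t_o @ t_o)
        Zf = Zf - np.outer(t_o, p_o)
        W_o[:, k], P_o[:, k], T_o[:, k] = w_o, p_o, t_o
        ss_x_ortho += float((t_o @ t_o) * (p_o @ p_o))

    w = Zf.T @ yc
    w /= np.linalg.norm(w)
    t = Zf @ w
    p = Zf.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    ss_x_pred = float((t @ t) * (p @ p))
    R2X = (ss_x_pred + ss_x_ortho) / ss_x_total
    resid_y = yc - t * q
    R2Y = 1.0 - float(np.sum(resid_y**2)) / ss_y_total

    vip = _vip(w, p, t, q, W_o, T_o, P_o, mode="total")
    vip_pred = _vip(w, p, t, q, W_o, T_o, P_o, mode="pred")
    return OplsModel(
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean,
        w=w, p=p, t=t, q=q, W_o=W_o, P_o=P_o, T_o=T_o,
        n_ortho=n_ortho, R2X=R2X, R2Y=R2Y,
        vip=vip, vip_pred=vip_pred,
        feature_names=list(feature_names) if feature_names else [],
    )


def _vip(w, p, t, q, W_o, T_o, P_o, mode: str) -> np.ndarray:
    """Variable importance in projection; mean(VIP²) = 1 by construction.

    ``mode="pred"`` is the classical PLS VIP restricted to the predictive
    component (y-variance weighting makes orthogonal weights drop out);
    ``mode="total"`` additionally credits orthogonal components through
    their explained X-variance (averaged y/X-variance weighting), so
    variables that shape the orthogonal structure are visible too.
    """
    n_feat = w.size
    comps = [w] + [W_o[:, k] for k in range(W_o.shape[1])]
    ssy = [float((t @ t) * q * q)] + [0.0] * W_o.shape[1]
    ssx = [float((t @ t) * (p @ p))]
    for k in range(W_o.shape[1]):
        ssx.append(float((T_o[:, k] @ T_o[:, k])
                         * (P_o[:, k] @ P_o[:, k])))
    ssy = np.array(ssy)
    ssx = np.array(ssx)
    if mode == "pred":
        weights = ssy
    else:
        wy = ssy / ssy.sum() if ssy.sum() > 0 else ssy
        wx = ssx / ssx.sum() if ssx.sum() > 0 else ssx
        weights = (wy + wx) / 2
    W = np.column_stack([c / np.linalg.norm(c) for c in comps])
    contrib = (W**2) @ weights
    return np.sqrt(n_feat * contrib / weights.sum())


def loo_cv_opls(
    X: np.ndarray,
    y: np.ndarray,
    n_ortho: int = 0,
) -> tuple[float, np.ndarray, list[int]]:
    """Leave-one-out cross-validation of the OPLS-DA fit.

    Each sample is predicted by a model refit (including rescaling) on
    the remaining samples.  Returns ``(Q2, cv_scores, skipped)`` where
    ``Q2 = 1 − PRESS/SS`` about the full-sample mean and ``skipped``
    lists fold indices whose training set lost an entire class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("need >= 3 samples for LOO")
    cv = np.full(n, np.nan)
    skipped: list[int] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.unique(y[mask]).size < 2 or np.bincount(
                y[mask].astype(int)).min() < 2:
            skipped.append(i)
            continue
        try:
            m = fit_opls(X[mask], y[mask], n_ortho)
        except ValueError:
            skipped.append(i)
            continue
        cv[i] = m.predict(X[i:i + 1])[0]
    ok = ~np.isnan(cv)
    press = float(np.sum((y[ok] - cv[ok])**2))
    ss = float(np.sum((y[ok] - y.mean())**2))
    q2 = 1.0 - press / ss
    return q2, cv, skipped


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve by threshold sweep over unique scores; trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float).ravel()
    if np.unique(labels).size != 2:
        raise ValueError("labels must contain both classes")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, sensitivity=tpr,
                    specificity=1.0 - fpr, auc=auc)


def classify_at_cutoff(
    scores: np.ndarray, labels: np.ndarray, cutoff: float
) -> tuple[float, float]:
    """Sensitivity and specificity for 'positive ⇔ score >= cutoff'."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float).ravel()
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if np.unique(labels).size != 2:
        raise ValueError("labels must contain both classes")
    pos = labels == labels.max()
    pred = scores >= cutoff
    sens = float(np.mean(pred[pos]))
    spec = float(np.mean(~pred[~pos]))
    return sens, spec


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Cutoff maximising Youden's J = sensitivity + specificity − 1.

    Candidates are the unique observed scores (decision rule
    ``score >= cutoff``); among ties the lowest cutoff is returned,
    favouring sensitivity — the usual screening preference.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float).ravel()
    cands = np.unique(scores)
    best_j, best_c = -np.inf, float(cands[0])
    for c in cands:
        sens, spec = classify_at_cutoff(scores, labels, float(c))
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, float(c)
    return best_c
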