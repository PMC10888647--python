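"""Stepwise logistic diagnostic models over expanded metabolite features.

The builder mirrors how small-cohort screening models are constructed:

1. expand the concentration matrix to bases ∪ squares ∪ pairwise
   products (2p + p(p−1)/2 features for p analytes);
2. prefilter by OPLS-DA variable importance (keep VIP > 1);
3. forward stepwise logistic selection by AIC from the intercept-only
   model, stopping when no addition lowers the criterion;
4. backward elimination of the largest-Wald-p coefficient until every
   retained coefficient has p < 0.05.

Maximum-likelihood fits use iteratively reweighted least squares with a
fixed iteration cap; perfect separation is detected and the offending
fit is ridge-stabilised (and flagged) rather than rejected.  Model
quality is assessed by leave-one-out cross-validation with the entire
builder re-run inside each fold (no leakage), and by repeated stratified
70/30 train/test splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleTable
from .opls import (RocCurve, classify_at_cutoff, fit_opls, loo_cv_opls,
                   roc, youden_cutoff)

__all__ = [
    "ExpandedFeatures", "LogisticFit", "DxLogisticModel",
    "SplitValidationReport", "expand_features", "logistic_irls",
    "vip_prefilter", "stepwise_aic", "backward_p_elimination",
    "DxBuilder", "loo_cv_logit", "split_validation",
]


@dataclass
class ExpandedFeatures:
    """Base, squared and pairwise-product concentration features."""

    base_codes: list[str]
    names: list[str]
    matrix: np.ndarray           # samples × features
    sample_ids: list[str]

    def __len__(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def subset(self, names: list[str]) -> "ExpandedFeatures":
        idx = [self.names.index(n) for n in names]
        return ExpandedFeatures(self.base_codes, list(names),
                                self.matrix[:, idx], self.sample_ids)

    def standardized(self) -> tuple["ExpandedFeatures", np.ndarray,
                                    np.ndarray]:
        """Column-standardized copy plus the (mu, sd) used.

        Zero-variance columns get sd 1 (they become constant zero).
        Squared/product features span orders of magnitude, so model
        fitting runs on this scale; the scaler travels with the model.
        """
        mu = self.matrix.mean(axis=0)
        sd = self.matrix.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        return (ExpandedFeatures(self.base_codes, list(self.names),
                                 (self.matrix - mu) / sd,
                                 self.sample_ids), mu, sd)


def expand_features(table: SampleTable) -> ExpandedFeatures:
    """Deterministic feature expansion: bases, squares, products (i<j)."""
    codes = table.panel.codes
    X = table.X
    cols = [X]
    names = list(codes)
    names += [f"{c}^2" for c in codes]
    cols.append(X**2)
    prods = []
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            names.append(f"{codes[i]}*{codes[j]}")
            prods.append(X[:, i] * X[:, j])
    if prods:
        cols.append(np.column_stack(prods))
    return ExpandedFeatures(list(codes), names, np.hstack(cols),
                            table.sample_ids)


# ---------------------------------------------------------------------------
# IRLS logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """A fitted logistic model on a fixed feature set."""

    features: list[str]
    coef: np.ndarray             # [intercept, features...]
    se: np.ndarray
    wald_p: np.ndarray           # aligned with coef
    loglik: float
    aic: float
    converged: bool
    separation: bool
    ridge: float

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xd = np.column_stack([np.ones(len(X)), X])
        eta = np.clip(Xd @ self.coef, -500, 500)
        return 1.0 / (1.0 + np.exp(-eta))


def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    ridge: float = 0.0,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> LogisticFit:
    """Logistic MLE by iteratively reweighted least squares.

    ``ridge`` adds an L2 penalty (excluding the intercept) to the
    normal equations.  Perfect separation is detected when the fit
    classifies every sample with fitted probabilities pinned at 0/1; the
    caller decides whether to re-fit with a small ridge.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(k + 1)
    pen = np.zeros(k + 1)
    pen[1:] = ridge
    converged = False
    for _ in range(max_iter):
        eta = np.clip(Xd @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        A = Xd.T @ (w[:, None] * Xd) + np.diag(pen)
        b = Xd.T @ (w * z)
        try:
            new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            new = np.linalg.lstsq(A, b, rcond=None)[0]
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            converged = True
            break
        beta = new
    eta = np.clip(Xd @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    loglik = float(np.sum(y * np.log(mu + eps)
                          + (1 - y) * np.log(1 - mu + eps)))
    # (quasi-)separation: the ML fit is degenerate — some fitted
    # probability is numerically 0/1 (the classical glm diagnostic;
    # |linear predictor| > ~9 for an observed sample) or a slope runs
    # away (|beta| > 10 ≈ odds ratio e^10 per predictor SD on
    # standardized features).  Wald p-values are meaningless out there
    # (Hauck–Donner collapse), so callers re-fit with a ridge.
    separation = bool(
        k > 0
        and ridge == 0.0
        and (np.max(np.abs(beta[1:])) > 10.0
             or np.any(np.minimum(mu, 1 - mu) < 1e-4))
    )
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    A = Xd.T @ (w[:, None] * Xd) + np.diag(pen)
    try:
        cov = np.linalg.inv(A)
        se = np.sqrt(np.maximum(np.diag(cov), 0))
    except np.linalg.LinAlgError:
        se = np.full(k + 1, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    wald_p = 2 * stats.norm.sf(np.abs(z))
    aic = 2 * (k + 1) - 2 * loglik
    return LogisticFit(
        features=list(feature_names) if feature_names else
        [f"x{i}" for i in range(k)],
        coef=beta, se=se, wald_p=wald_p, loglik=loglik, aic=aic,
        converged=converged, separation=separation, ridge=ridge,
    )


def _fit_with_separation_guard(
    X: np.ndarray, y: np.ndarray, names: list[str],
    ridge_fallback: float = 1.0,
) -> LogisticFit:
    """ML fit; on perfect separation or non-convergence, re-fit with a
    unit ridge penalty (features are standardized, so this is roughly a
    unit-information prior) and keep the separation flag raised."""
    fit = logistic_irls(X, y, names)
    if fit.separation or not fit.converged:
        fit = logistic_irls(X, y, names, ridge=ridge_fallback)
        fit.separation = True
    return fit


# ---------------------------------------------------------------------------
# Builder stages
# ---------------------------------------------------------------------------

def vip_prefilter(
    features: ExpandedFeatures,
    y: np.ndarray,
    n_ortho: int = 2,
    threshold: float = 1.0,
) -> ExpandedFeatures:
    """Keep features with OPLS-DA VIP above ``threshold``.

    Constant features (possible inside small CV folds) are excluded from
    the OPLS fit and never survive.
    """
    M = features.matrix
    sds = M.std(axis=0, ddof=1)
    usable = sds > 0
    model = fit_opls(M[:, usable], y, n_ortho)
    vip = np.zeros(len(features.names))
    vip[usable] = model.vip
    keep = [n for n, v in zip(features.names, vip) if v > threshold]
    if not keep:
        raise ValueError("no features passed VIP filter")
    return features.subset(keep)


def _batched_candidate_aic(
    Z: np.ndarray, y: np.ndarray, selected: list[int],
    remaining: list[int], max_iter: int = 30,
) -> np.ndarray:
    """AIC of logistic fits 'selected + {j}' for every j, in one batch.

    IRLS run in parallel over candidates (tiny ridge on the normal
    equations for solvability); used only to rank candidates — the
    accepted feature is refit exactly.
    """
    n = y.size
    m = len(remaining)
    k = len(selected)
    T = np.empty((m, n, k + 2))
    T[:, :, 0] = 1.0
    if k:
        T[:, :, 1:k + 1] = Z[:, selected]
    T[:, :, k + 1] = Z[:, remaining].T
    beta = np.zeros((m, k + 2))
    eye = np.eye(k + 2) * 1e-8
    for _ in range(max_iter):
        eta = np.clip(np.einsum("mnk,mk->mn", T, beta), -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        A = np.einsum("mnk,mn,mnl->mkl", T, w, T) + eye
        b = np.einsum("mnk,mn->mk", T, w * z)
        new = np.linalg.solve(A, b[..., None])[..., 0]
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            break
        beta = new
    eta = np.clip(np.einsum("mnk,mk->mn", T, beta), -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    ll = np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps),
                axis=1)
    return 2 * (k + 2) - 2 * ll


def stepwise_aic(
    features: ExpandedFeatures,
    y: np.ndarray,
    max_features: int | None = None,
) -> tuple[LogisticFit, list[dict]]:
    """Forward stepwise logistic selection by AIC.

    Starting from the intercept-only model, the feature whose addition
    minimises AIC is accepted while the criterion keeps decreasing.
    ``max_features`` (default n/5) caps the path length as a guard
    against runaway paths in near-separable small cohorts.  Returns the
    selected fit and the step-by-step path.
    """
    y = np.asarray(y, dtype=float).ravel()
    if len(features) == 0:
        raise ValueError("no candidate features")
    if y.size < 6:
        raise ValueError("need >= 6 samples for stepwise selection")
    if max_features is None:
        max_features = max(1, y.size // 5)
    Z = features.matrix
    selected: list[int] = []
    current = logistic_irls(np.empty((y.size, 0)), y, [])
    path = [{"step": 0, "added": None, "aic": current.aic}]
    remaining = list(range(len(features.names)))
    while remaining and len(selected) < max_features:
        aics = _batched_candidate_aic(Z, y, selected, remaining)
        j = remaining[int(np.argmin(aics))]
        cand = selected + [j]
        fit = _fit_with_separation_guard(
            Z[:, cand], y, [features.names[c] for c in cand]
        )
        if fit.aic >= current.aic - 1e-9:
            break
        current = fit
        selected.append(j)
        remaining.remove(j)
        path.append({"step": len(selected),
                     "added": features.names[j],
                     "aic": current.aic})
    return current, path


def backward_p_elimination(
    fit: LogisticFit,
    features: ExpandedFeatures,
    y: np.ndarray,
    alpha: float = 0.05,
) -> tuple[LogisticFit, list[str]]:
    """Drop the largest-Wald-p coefficient until all p < alpha.

    The intercept is exempt.  If everything is eliminated the
    intercept-only model is returned with a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    current = fit
    dropped: list[str] = []
    while current.features:
        pvals = current.wald_p[1:]
        worst = int(np.argmax(pvals))
        if pvals[worst] < alpha:
            break
        dropped.append(current.features[worst])
        keep = [f for i, f in enumerate(current.features) if i != worst]
        if not keep:
            warnings.warn("all features eliminated; intercept-only model")
            current = logistic_irls(np.empty((y.size, 0)), y, [])
            break
        sub = features.subset(keep)
        current = _fit_with_separation_guard(sub.matrix, y, keep)
    return current, dropped


@dataclass
class DxLogisticModel:
    """Final diagnostic model with its selection trace and CV metrics.

    Coefficients refer to column-standardized features; the scaler
    (``scale_mu``, ``scale_sd``, aligned with ``fit.features``) travels
    with the model so prediction on raw features is self-contained.
    """

    fit: LogisticFit
    vip_survivors: list[str]
    aic_path: list[dict]
    eliminated: list[str]
    scale_mu: np.ndarray
    scale_sd: np.ndarray
    cutoff: float | None = None
    cv_proba: np.ndarray | None = None
    roc_curve: RocCurve | None = None
    sensitivity: float | None = None
    specificity: float | None = None

    @property
    def features(self) -> list[str]:
        return self.fit.features

    def predict_proba(self, features: ExpandedFeatures) -> np.ndarray:
        sub = features.subset(self.fit.features)
        Z = (sub.matrix - self.scale_mu) / self.scale_sd
        return self.fit.predict_proba(Z)


@dataclass
class DxBuilder:
    """VIP prefilter → forward AIC → backward p-elimination pipeline."""

    vip_threshold: float = 1.0
    n_ortho: int = 2
    alpha: float = 0.05
    max_features: int | None = None

    def build(self, features: ExpandedFeatures,
              y: np.ndarray) -> DxLogisticModel:
        zfeats, mu, sd = features.standardized()
        survivors = vip_prefilter(zfeats, y, self.n_ortho,
                                  self.vip_threshold)
        fit, path = stepwise_aic(survivors, y, self.max_features)
        final, dropped = backward_p_elimination(fit, survivors, y,
                                                self.alpha)
        sel_idx = [features.names.index(f) for f in final.features]
        return DxLogisticModel(
            fit=final, vip_survivors=survivors.names,
            aic_path=path, eliminated=dropped,
            scale_mu=mu[sel_idx], scale_sd=sd[sel_idx],
        )


def loo_cv_logit(
    features: ExpandedFeatures,
    y: np.ndarray,
    builder: DxBuilder | None = None,
) -> DxLogisticModel:
    """Leave-one-out CV with the whole builder re-run inside each fold.

    The pooled out-of-fold probabilities give the ROC curve and the
    Youden-J cutoff; sensitivity/specificity are evaluated there.  Folds
    whose builder fails (e.g. empty VIP survivor set) are skipped and
    counted in the model's trace.
    """
    builder = builder or DxBuilder()
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 6:
        raise ValueError("need >= 6 samples")
    proba = np.full(n, np.nan)
    failures = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train = ExpandedFeatures(features.base_codes, features.names,
                                 features.matrix[mask],
                                 [features.sample_ids[j]
                                  for j in range(n) if mask[j]])
        try:
            m = builder.build(train, y[mask])
        except ValueError:
            failures += 1
            continue
        proba[i] = m.predict_proba(
            ExpandedFeatures(features.base_codes, features.names,
                             features.matrix[i:i + 1],
                             [features.sample_ids[i]])
        )[0]
    full = builder.build(features, y)
    ok = ~np.isnan(proba)
    curve = roc(proba[ok], y[ok])
    cutoff = youden_cutoff(proba[ok], y[ok])
    sens, spec = classify_at_cutoff(proba[ok], y[ok], cutoff)
    full.cutoff = cutoff
    full.cv_proba = proba
    full.roc_curve = curve
    full.sensitivity = sens
    full.specificity = spec
    full.aic_path.append({"step": "loo", "added": None,
                          "aic": float("nan"),
                          "skipped_folds": failures})
    return full


def _fixed_model_loo_proba(
    model: DxLogisticModel, features: ExpandedFeatures, y: np.ndarray
) -> np.ndarray:
    """LOO probabilities refitting only the coefficients of an already
    selected feature set (no re-selection); used for cutoff placement."""
    sub = features.subset(model.features)
    Z = (sub.matrix - model.scale_mu) / model.scale_sd
    n = y.size
    out = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.unique(y[mask]).size < 2:
            out[i] = np.nan
            continue
        f = _fit_with_separation_guard(Z[mask], y[mask], model.features)
        out[i] = f.predict_proba(Z[i:i + 1])[0]
    if model.features == []:
        out[:] = float(np.mean(y))
    return out


@dataclass
class SplitValidationReport:
    """Repeated stratified train/test split validation of both models."""

    n_repeats: int
    train_fraction: float
    seed: int
    per_repeat: pd.DataFrame     # columns: repeat, model, sens, spec
    redraws: int

    def mean(self, model: str, metric: str) -> float:
        sub = self.per_repeat[self.per_repeat["model"] == model]
        return float(sub[metric].mean())


def split_validation(
    table: SampleTable,
    negative: str,
    positive: str,
    n_repeats: int = 100,
    train_fraction: float = 0.7,
    seed: int = 0,
    n_ortho_opls: int = 4,
    builder: DxBuilder | None = None,
) -> SplitValidationReport:
    """100× stratified 70/30 split validation of the OPLS and logistic models.

    Per split, both models are rebuilt on the training part only.
    Cutoffs are chosen by Youden's J on training leave-one-out scores:
    full refits for the OPLS model, fixed-feature coefficient refits for
    the logistic model (re-running the whole selection inside every
    split-LOO fold would be quadratic in builder cost; the test split is
    never touched either way).  Splits leaving a class empty in train or
    test are redrawn (counted).
    """
    builder = builder or DxBuilder()
    sub = table.select_groups(negative, positive)
    y = sub.binary_labels(negative, positive)
    X = sub.X
    feats = expand_features(sub)
    n = y.size
    rng = np.random.default_rng(seed)
    rows = []
    redraws = 0
    for rep in range(n_repeats):
        for _ in range(100):
            idx_pos = np.flatnonzero(y == 1)
            idx_neg = np.flatnonzero(y == 0)
            rng.shuffle(idx_pos)
            rng.shuffle(idx_neg)
            n_tr_pos = int(round(train_fraction * idx_pos.size))
            n_tr_neg = int(round(train_fraction * idx_neg.size))
            train_idx = np.concatenate([idx_pos[:n_tr_pos],
                                        idx_neg[:n_tr_neg]])
            test_idx = np.concatenate([idx_pos[n_tr_pos:],
                                       idx_neg[n_tr_neg:]])
            if (np.unique(y[train_idx]).size == 2
                    and np.unique(y[test_idx]).size == 2
                    and np.bincount(y[train_idx].astype(int)).min() >= 3):
                break
            redraws += 1
        tr, te = np.sort(train_idx), np.sort(test_idx)

        opls = fit_opls(X[tr], y[tr], n_ortho_opls)
        _, cv_tr, _ = loo_cv_opls(X[tr], y[tr], n_ortho_opls)
        ok = ~np.isnan(cv_tr)
        cut_o = youden_cutoff(cv_tr[ok], y[tr][ok])
        sens_o, spec_o = classify_at_cutoff(opls.predict(X[te]),
                                            y[te], cut_o)
        rows.append({"repeat": rep, "model": "opls",
                     "sensitivity": sens_o, "specificity": spec_o})

        ftr = ExpandedFeatures(feats.base_codes, feats.names,
                               feats.matrix[tr],
                               [feats.sample_ids[i] for i in tr])
        fte = ExpandedFeatures(feats.base_codes, feats.names,
                               feats.matrix[te],
                               [feats.sample_ids[i] for i in te])
        try:
            m = builder.build(ftr, y[tr])
            p_tr = _fixed_model_loo_proba(m, ftr, y[tr])
            okl = ~np.isnan(p_tr)
            cut_l = youden_cutoff(p_tr[okl], y[tr][okl])
            sens_l, spec_l = classify_at_cutoff(m.predict_proba(fte),
                                                y[te], cut_l)
        except ValueError:
            sens_l, spec_l = float("nan"), float("nan")
        rows.append({"repeat": rep, "model": "logistic",
                     "sensitivity": sens_l, "specificity": spec_l})
    return SplitValidationReport(
        n_repeats=n_repeats, train_fraction=train_fraction, seed=seed,
        per_repeat=pd.DataFrame(rows), redraws=redraws,
    )
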