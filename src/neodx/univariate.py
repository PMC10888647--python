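"""Univariate screening: Mann–Whitney + BH FDR, time association, PCA.

Every analyte is compared between two groups with the two-sided
Mann–Whitney test; p-values are Benjamini–Hochberg-adjusted across the
panel within each pairwise comparison (not pooled across comparisons).
A Spearman test against hours post-insult captures time trends, and the
analytes significant in at least one pairwise comparison feed a
standardized PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SampleTable

__all__ = [
    "mann_whitney",
    "bh_adjust",
    "compare_groups",
    "spearman_time",
    "pca_on_significant",
    "significant_in_any",
    "GroupComparisonResult",
    "TimeAssociation",
    "PcaResult",
]


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Returns ``(U, p)`` with ``U`` the count-based statistic for ``x``.
    Uses the exact null distribution when ``min(n, m) <= 8`` and there are
    no ties across the pooled sample; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    exact = min(x.size, y.size) <= 8 and not ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} min(1, m p_(j) / j)`` on the sorted p-values,
    returned in the input order (delegates to
    :func:`statsmodels.stats.multitest.multipletests`).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GroupComparisonResult:
    """Per-analyte two-group comparison with FDR control.

    ``table`` columns: analyte, U, p, q, direction (sign of the
    median change in ``group_b`` relative to ``group_a``), significant
    (q < alpha) and raw_significant (p < 0.05, the panel-selection rule
    reported alongside the FDR-surviving subset).
    """

    group_a: str
    group_b: str
    alpha: float
    table: pd.DataFrame

    @property
    def significant(self) -> list[str]:
        return self.table.loc[self.table["significant"], "analyte"].tolist()

    @property
    def raw_significant(self) -> list[str]:
        return self.table.loc[
            self.table["raw_significant"], "analyte"
        ].tolist()

    def q(self, analyte: str) -> float:
        row = self.table[self.table["analyte"] == analyte]
        if row.empty:
            raise KeyError(analyte)
        return float(row["q"].iloc[0])


def compare_groups(
    table: SampleTable,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Mann–Whitney per analyte, BH-adjusted across the panel."""
    a = table.select_groups(group_a)
    b = table.select_groups(group_b)
    if len(a.sample_ids) < 2 or len(b.sample_ids) < 2:
        raise ValueError("each group needs >= 2 samples")
    rows = []
    for code in table.panel.codes:
        xa = a.data[code].to_numpy()
        xb = b.data[code].to_numpy()
        U, p = mann_whitney(xa, xb)
        diff = float(np.median(xb) - np.median(xa))
        rows.append({
            "analyte": code, "U": U, "p": p,
            "direction": "up" if diff > 0 else ("down" if diff < 0 else
                                                "none"),
        })
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] < alpha
    df["raw_significant"] = df["p"] < 0.05
    df["comparison"] = f"{group_a} vs {group_b}"
    return GroupComparisonResult(group_a, group_b, alpha, df)


def significant_in_any(
    results: list[GroupComparisonResult], adjusted: bool = False
) -> list[str]:
    """Analytes significant in at least one pairwise comparison.

    Raw p < 0.05 by default (the panel-selection rule for PCA); set
    ``adjusted=True`` for the FDR-surviving subset.
    """
    col = "significant" if adjusted else "raw_significant"
    out: list[str] = []
    for res in results:
        for code in res.table.loc[res.table[col], "analyte"]:
            if code not in out:
                out.append(code)
    return out


@dataclass
class TimeAssociation:
    """Spearman association of each analyte with hours post-insult."""

    table: pd.DataFrame  # analyte, rho, p, significant

    def rho(self, analyte: str) -> float:
        row = self.table[self.table["analyte"] == analyte]
        if row.empty:
            raise KeyError(analyte)
        return float(row["rho"].iloc[0])

    @property
    def significant(self) -> list[str]:
        return self.table.loc[self.table["significant"], "analyte"].tolist()


def spearman_time(table: SampleTable, alpha: float = 0.05) -> TimeAssociation:
    """Spearman rho of concentration vs sampling time (average-rank ties)."""
    t = table.meta["time_h"].to_numpy(dtype=float)
    mask = np.isfinite(t)
    t = t[mask]
    if np.unique(t).size < 2:
        raise ValueError("need >= 2 distinct time points")
    rows = []
    for code in table.panel.codes:
        x = table.data[code].to_numpy()[mask]
        rho, p = stats.spearmanr(x, t)
        rows.append({"analyte": code, "rho": float(rho), "p": float(p),
                     "significant": bool(p < alpha)})
    return TimeAssociation(pd.DataFrame(rows))


@dataclass
class PcaResult:
    analytes: list[str]
    dropped: list[str]
    loadings: np.ndarray          # analytes × components, orthonormal cols
    scores: np.ndarray            # samples × components
    explained_variance_ratio: np.ndarray
    sample_ids: list[str] = field(default_factory=list)


def pca_on_significant(
    table: SampleTable, selection: list[str]
) -> PcaResult:
    """SVD-based PCA on autoscaled concentrations of selected analytes.

    Zero-variance analytes are dropped with a warning (recorded in the
    result) rather than erroring, since a constant column carries no
    group information.
    """
    if len(selection) < 2:
        raise ValueError("need >= 2 selected analytes")
    if len(table.sample_ids) < 3:
        raise ValueError("need >= 3 samples")
    X = table.data.loc[:, selection].to_numpy()
    sds = X.std(axis=0, ddof=1)
    dropped = [c for c, s in zip(selection, sds) if s == 0]
    if dropped:
        warnings.warn(f"dropping zero-variance analytes: {dropped}")
    keep = [c for c in selection if c not in dropped]
    if len(keep) < 2:
        raise ValueError("fewer than 2 analytes with non-zero variance")
    X = table.data.loc[:, keep].to_numpy()
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    evr = s**2 / np.sum(s**2)
    return PcaResult(
        analytes=keep,
        dropped=dropped,
        loadings=Vt.T,
        scores=Z @ Vt.T,
        explained_variance_ratio=evr,
        sample_ids=table.sample_ids,
    )
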