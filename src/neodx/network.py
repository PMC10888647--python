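"""Differential correlation-network clustering.

For two experimental arms, each analyte pair gets an adjacency
``a_ij = |Spearman rho_ij|`` per arm; the change matrix
``c_ij = |a_ij(1) - a_ij(2)|`` captures how strongly the pair's coupling
is rewired between arms.  Compounds are then clustered on the
dissimilarity ``d_ij = 1 - c_ij / max(C)`` (strongly co-rewired pairs
end up close) with Ward linkage, and the cluster count is chosen by the
maximum mean silhouette width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .io import SampleTable

__all__ = ["AdjacencyChange", "ClusterAssignment",
           "adjacency_change", "ward_silhouette"]


@dataclass
class AdjacencyChange:
    """Per-arm adjacencies, their change matrix, and the dissimilarity."""

    analytes: list[str]
    excluded: list[str]          # zero-variance in either arm
    A1: np.ndarray               # |rho| within group_a, diag 1
    A2: np.ndarray               # |rho| within group_b, diag 1
    C: np.ndarray                # |A1 - A2|, diag 0
    D: np.ndarray | None         # 1 - C/max(C); None if no rewiring
    no_rewiring: bool


def _abs_spearman(X: np.ndarray) -> np.ndarray:
    rho = stats.spearmanr(X).statistic
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    A = np.abs(rho)
    np.fill_diagonal(A, 1.0)
    return A


def adjacency_change(
    table: SampleTable,
    group_a: str,
    group_b: str,
    dissimilarity: str = "co-rewired",
) -> AdjacencyChange:
    """Adjacency-change matrix between two arms.

    Analytes constant within either arm are excluded (rank correlation
    undefined) and listed in ``excluded``.  If the two correlation
    structures are identical (``max(C) == 0``) the dissimilarity is
    undefined and ``no_rewiring`` is set instead.

    ``dissimilarity="co-rewired"`` (default) sets ``d_ij = 1 - c_ij/max(C)``
    so strongly co-rewired pairs cluster together; ``"raw-change"`` uses
    ``d_ij = c_ij`` directly (the inverse convention).
    """
    if dissimilarity not in ("co-rewired", "raw-change"):
        raise ValueError(f"unknown dissimilarity mode {dissimilarity!r}")
    Xa = table.select_groups(group_a)
    Xb = table.select_groups(group_b)
    if len(Xa.sample_ids) < 4 or len(Xb.sample_ids) < 4:
        raise ValueError("each group needs >= 4 samples")
    codes = table.panel.codes
    sda = Xa.data.std(ddof=1)
    sdb = Xb.data.std(ddof=1)
    excluded = [c for c in codes if sda[c] == 0 or sdb[c] == 0]
    keep = [c for c in codes if c not in excluded]
    if len(keep) < 2:
        raise ValueError("fewer than 2 analytes with variance in both arms")
    A1 = _abs_spearman(Xa.data.loc[:, keep].to_numpy())
    A2 = _abs_spearman(Xb.data.loc[:, keep].to_numpy())
    C = np.abs(A1 - A2)
    np.fill_diagonal(C, 0.0)
    cmax = C.max()
    if cmax == 0:
        return AdjacencyChange(keep, excluded, A1, A2, C, None, True)
    if dissimilarity == "co-rewired":
        D = 1.0 - C / cmax
    else:
        D = C.copy()
    np.fill_diagonal(D, 0.0)
    # symmetrize away float noise from the correlation routine
    D = (D + D.T) / 2
    return AdjacencyChange(keep, excluded, A1, A2, C, D, False)


@dataclass
class ClusterAssignment:
    k: int
    labels: np.ndarray                 # per analyte, 0-based
    analytes: list[str]
    mean_silhouette: float
    silhouette_by_k: dict[int, float]

    def members(self, label: int) -> list[str]:
        return [a for a, l in zip(self.analytes, self.labels)
                if l == label]


def ward_silhouette(
    change: AdjacencyChange,
    k_range: range | list[int] | None = None,
) -> ClusterAssignment:
    """Ward clustering of the rewiring structure; k by max silhouette.

    The dendrogram is built once by Ward linkage on the condensed
    dissimilarity (Ward.D2 convention of the underlying Lance–Williams
    update) and cut at every ``k`` in ``k_range``; the mean silhouette
    width, computed against ``D`` as a precomputed distance, selects the
    returned ``k``.
    """
    if change.no_rewiring or change.D is None:
        raise ValueError("no rewiring: dissimilarity undefined")
    n = len(change.analytes)
    if n < 4:
        raise ValueError("need >= 4 analytes to cluster")
    if k_range is None:
        k_range = range(2, min(n - 1, 10) + 1)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    Z = linkage(squareform(change.D, checks=False), method="ward")
    best: tuple[float, int, np.ndarray] | None = None
    trace: dict[int, float] = {}
    for k in ks:
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
        if len(np.unique(labels)) < 2:
            trace[k] = float("nan")
            continue
        sil = float(silhouette_score(change.D, labels,
                                     metric="precomputed"))
        trace[k] = sil
        if best is None or sil > best[0]:
            best = (sil, k, labels)
    if best is None:
        # degenerate: every requested cut collapsed; return the first k
        labels = fcluster(Z, t=ks[0], criterion="maxclust") - 1
        return ClusterAssignment(ks[0], labels, change.analytes,
                                 float("nan"), trace)
    sil, k, labels = best
    return ClusterAssignment(k, labels, change.analytes, sil, trace)
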