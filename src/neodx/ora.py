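"""Pathway over-representation with ambiguity-aware marker expansion.

Screening assays report combined codes for isobaric species ("Gln/Lys",
"C3DC/C4OH"); a marker list containing such codes does not correspond to
one compound set but to a family of them.  The family is built by the
Cartesian expansion over identification variants; each expanded set is
scored by the hypergeometric upper tail against each pathway, and a
pathway counts as consensus-significant only if p < alpha for *every*
expanded set.  Enrichment ratios and p-values are averaged across the
sets and the marker-hit count is summarised by its median.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import PathwaySet
from .panel import MetabolitePanel

__all__ = ["MarkerSetFamily", "EnrichmentResult",
           "expand_markers", "ora", "consensus_enrich"]


@dataclass
class MarkerSetFamily:
    """All variant resolutions of an ambiguous marker list."""

    codes: list[str]
    sets: list[frozenset[str]]

    def __len__(self) -> int:
        return len(self.sets)


def expand_markers(
    codes: list[str], panel: MetabolitePanel
) -> MarkerSetFamily:
    """Cartesian expansion of marker codes over identification variants.

    One expanded set per combination of variant choices; each has the
    same cardinality as the original marker list.
    """
    for c in codes:
        if c not in panel:
            raise KeyError(f"unknown marker code {c!r}")
    variant_lists = [sorted(panel.variants(c)) for c in codes]
    sets = [frozenset(combo)
            for combo in itertools.product(*variant_lists)]
    return MarkerSetFamily(list(codes), sets)


def ora(
    markers: set[str], pathway: set[str], universe: set[str]
) -> tuple[float, float, int]:
    """Hypergeometric over-representation test.

    With population ``N = |universe|``, ``K = |pathway|`` successes and
    ``n = |markers ∩ universe|`` draws, returns the upper-tail
    ``p = P(X >= hits)``, the enrichment ratio ``hits / (nK/N)`` and the
    hit count.
    """
    if not universe:
        raise ValueError("empty universe")
    if not pathway <= universe:
        raise ValueError("pathway must be a subset of the universe")
    eff = set(markers) & universe
    if not eff:
        raise ValueError("no markers fall in the universe")
    N, K, n = len(universe), len(pathway), len(eff)
    if K == 0:
        return 1.0, 0.0, 0
    hits = len(eff & pathway)
    p = float(stats.hypergeom.sf(hits - 1, N, K, n))
    expected = n * K / N
    ratio = hits / expected
    return min(p, 1.0), ratio, hits


@dataclass
class EnrichmentResult:
    """Consensus enrichment over an expanded marker-set family.

    One row per pathway: ``consensus_significant`` (p < alpha in every
    expanded set), ``mean_p``, ``mean_enrichment`` and
    ``median_hits`` across the family; ``detail`` holds the per-set
    values.
    """

    library: str
    alpha: float
    table: pd.DataFrame
    detail: pd.DataFrame

    @property
    def significant(self) -> list[str]:
        return self.table.loc[
            self.table["consensus_significant"], "pathway"
        ].tolist()


def consensus_enrich(
    family: MarkerSetFamily,
    pathway_set: PathwaySet,
    alpha: float = 0.1,
    universe: set[str] | None = None,
) -> EnrichmentResult:
    """Run ORA per expanded set per pathway and aggregate.

    ``universe`` defaults to the pathway set's own universe; pass e.g.
    ``panel.all_variants() & pathway_set.universe`` to score against the
    panel's compound space.
    """
    if not family.sets:
        raise ValueError("empty marker-set family")
    uni = universe if universe is not None else pathway_set.universe
    detail_rows = []
    for si, mset in enumerate(family.sets):
        for pname, members in pathway_set.pathways.items():
            p, ratio, hits = ora(set(mset), members & uni, uni)
            detail_rows.append({
                "pathway": pname, "set_index": si,
                "p": p, "enrichment": ratio, "hits": hits,
            })
    detail = pd.DataFrame(detail_rows)
    agg = detail.groupby("pathway", sort=False).agg(
        mean_p=("p", "mean"),
        max_p=("p", "max"),
        mean_enrichment=("enrichment", "mean"),
        median_hits=("hits", "median"),
    ).reset_index()
    agg["consensus_significant"] = agg["max_p"] < alpha
    agg["library"] = pathway_set.library
    return EnrichmentResult(pathway_set.library, alpha, agg, detail)
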