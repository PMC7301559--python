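"""Overrepresentation testing and network-based target ranking.

A single 2x2 enrichment engine serves three analyses: ranking putative causal
genes by the overlap of their network descendants with GWAS-component genes,
phenotype enrichment against disease-model phenotype sets, and edge-overlap
comparisons between networks.  The contingency table over a background B is

    a = |S1 ∩ S2|, b = |S1 \\ S2|, c = |S2 \\ S1|, d = |B \\ (S1 ∪ S2)|,

with enrichment odds ratio OR = (a/b)/(c/d) and an exact one-sided
hypergeometric upper-tail p testing OR > 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .association import holm_sidak_adjust
from .datatypes import DirectedNetwork, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "TargetRanking",
    "descendants",
    "overrepresentation_test",
    "rank_targets",
    "phenotype_enrichment",
]


@dataclass
class EnrichmentResult:
    """2x2 contingency cells with odds ratio and exact tail p."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    point_prob: float
    s1_size: int
    s2_size: int
    background_size: int
    label: str = ""


@dataclass
class TargetRanking:
    """Ranked candidate drivers; ``table`` rows ordered by rank."""

    table: pd.DataFrame
    results: dict[str, EnrichmentResult]


def descendants(net: DirectedNetwork, g0: str) -> set[str]:
    """All nodes reachable from ``g0`` by directed paths, excluding ``g0``."""
    if g0 not in net:
        raise KeyError(f"node {g0!r} not in network")
    return set(nx.descendants(net.graph, g0))


def overrepresentation_test(s1: set, s2: set, background: set, label: str = "") -> EnrichmentResult:
    """Exact one-sided test for overrepresentation of ``s1`` by ``s2``.

    Returns the contingency cells, the odds ratio ((a/b)/(c/d), +inf when b
    or c is zero), the hypergeometric point probability of the observed
    table, and the upper-tail p (probability of an overlap >= a at fixed
    margins).
    """
    s1, s2, background = set(s1), set(s2), set(background)
    if not background:
        raise ValidationError("background set is empty")
    if not s1 <= background:
        raise ValidationError("s1 is not a subset of the background")
    if not s2 <= background:
        raise ValidationError("s2 is not a subset of the background")
    a = len(s1 & s2)
    b = len(s1 - s2)
    c = len(s2 - s1)
    d = len(background - (s1 | s2))
    n = a + b + c + d
    if b > 0 and c > 0:
        odds_ratio = (a * d) / (b * c)
    else:
        odds_ratio = np.inf
    point = float(hypergeom.pmf(a, n, a + b, a + c))
    p = float(hypergeom.sf(a - 1, n, a + b, a + c))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return EnrichmentResult(a, b, c, d, odds_ratio, p, point, len(s1), len(s2), n, label)


def rank_targets(
    net: DirectedNetwork,
    component_genes: set,
    model_genes: set,
    alpha: float = 0.05,
    direct_children_only: bool = False,
) -> TargetRanking:
    """Rank candidate driver genes by descendant overlap with component genes.

    Background B = ``model_genes`` ∩ network nodes; S1 = ``component_genes``
    ∩ B.  Every node whose downstream set (descendants, or direct children
    with ``direct_children_only``) intersects B is tested; p-values are
    Holm–Sidak adjusted across the candidates and significance requires
    adjusted p < alpha with OR > 1.  Ranks order by (p ascending, OR
    descending, candidate id) and do not depend on input ordering.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    background = set(model_genes) & net.nodes
    if not background:
        raise ValidationError("empty background: no model gene is in the network")
    s1 = set(component_genes) & background

    results: dict[str, EnrichmentResult] = {}
    for g0 in sorted(net.nodes):
        down = set(net.graph.successors(g0)) if direct_children_only else descendants(net, g0)
        s2 = down & background
        if not s2:
            continue
        results[g0] = overrepresentation_test(s1, s2, background, label=g0)
    if not results:
        logger.warning("no candidate has downstream genes in the background")
        return TargetRanking(pd.DataFrame(), {})

    candidates = sorted(results)
    p = [results[g].p_value for g in candidates]
    p_adj = holm_sidak_adjust(p)
    rows = []
    for g, pa in zip(candidates, p_adj):
        r = results[g]
        rows.append(
            dict(candidate=g, a=r.a, b=r.b, c=r.c, d=r.d,
                 odds_ratio=r.odds_ratio, p=r.p_value, p_adjusted=float(pa),
                 significant=bool(pa < alpha and r.odds_ratio > 1))
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["p", "odds_ratio", "candidate"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return TargetRanking(table, results)


def phenotype_enrichment(
    candidate_phenotypes: set,
    model_phenotypes_per_model: list,
    background: set,
    alpha: float = 0.05,
) -> tuple[bool, list[EnrichmentResult], np.ndarray]:
    """Test a candidate's phenotype set against several disease-model sets.

    One overrepresentation test per disease model, Holm–Sidak adjusted over
    the models; the candidate is a hit when any model survives with OR > 1.
    Returns (hit, per-model results, adjusted p-values).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not model_phenotypes_per_model:
        raise ValueError("no disease-model phenotype sets supplied")
    results = [
        overrepresentation_test(candidate_phenotypes, set(m), background, label=f"model_{k}")
        for k, m in enumerate(model_phenotypes_per_model)
    ]
    p_adj = holm_sidak_adjust([r.p_value for r in results])
    hit = bool(any(pa < alpha and r.odds_ratio > 1 for pa, r in zip(p_adj, results)))
    return hit, results, p_adj
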