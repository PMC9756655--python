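"""Auxiliary-domain analytics.

"Auxiliary" means every annotated domain on a c-di-GMP enzyme other than
its catalytic domain(s): GGDEF and EAL are never auxiliary, and HD is
excluded only on HD-GYP-class proteins (on any other class an HD domain is
auxiliary). Repeated occurrence of a domain within one sequence counts
once. Domains of unknown function (DUF*) are ordinary domains here — no
filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .model import CDG_CLASSES, CdgmapError, ClassifiedProtein, EnzymeClass

GROUP_ORDER = tuple(cls.value for cls in CDG_CLASSES)


# ---------------------------------------------------------------------------
# Venn partition over the four enzyme groups


def venn_partition(group_domains: Mapping[str, Iterable[str]]) -> dict[frozenset[str], int]:
    """Partition observed auxiliary domains into the 15 non-empty regions of
    the four-group Venn diagram by exact group-membership pattern.

    Keys of ``group_domains`` must be the four group names; each observed
    domain lands in exactly one region, so region counts sum to the number
    of distinct domains seen in at least one group.
    """
    groups = {name: set(doms) for name, doms in group_domains.items()}
    unknown = set(groups) - set(GROUP_ORDER)
    if unknown:
        raise CdgmapError(f"unknown enzyme group(s): {sorted(unknown)}")
    for name in GROUP_ORDER:
        groups.setdefault(name, set())
    regions: dict[frozenset[str], int] = {}
    for r in range(1, 5):
        for combo in combinations(GROUP_ORDER, r):
            regions[frozenset(combo)] = 0
    for dom in set(chain.from_iterable(groups.values())):
        member = frozenset(name for name in GROUP_ORDER if dom in groups[name])
        regions[member] += 1
    return regions


def venn_partition_weighted(
    classified: Iterable[ClassifiedProtein],
) -> tuple[dict[frozenset[str], int], dict[frozenset[str], int]]:
    """Both readings of the shared-domain diagram from classified proteins:
    the distinct-domain partition (primary) and a sequence-weighted variant
    where each region's count is the number of sequences carrying its
    domains (supplementary)."""
    group_domains: dict[str, set[str]] = {name: set() for name in GROUP_ORDER}
    domain_seqs: dict[tuple[str, str], int] = {}
    for cp in classified:
        if cp.enzyme_class is EnzymeClass.NONE:
            continue
        g = cp.enzyme_class.value
        for dom in cp.auxiliary_domains:
            group_domains[g].add(dom)
            domain_seqs[(g, dom)] = domain_seqs.get((g, dom), 0) + 1
    primary = venn_partition(group_domains)
    weighted = {region: 0 for region in primary}
    for dom in set(chain.from_iterable(group_domains.values())):
        member = frozenset(g for g in GROUP_ORDER if dom in group_domains[g])
        weighted[member] += sum(domain_seqs.get((g, dom), 0) for g in member)
    return primary, weighted


def venn_table(regions: Mapping[frozenset[str], int]) -> pd.DataFrame:
    rows = [
        {"region": "&".join(g for g in GROUP_ORDER if g in region), "n_domains": count}
        for region, count in regions.items()
    ]
    return pd.DataFrame(rows, columns=["region", "n_domains"]).sort_values(
        "region", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# none / one / >1 auxiliary-domain categories


@dataclass(frozen=True)
class AuxCategorySummary:
    group: str
    n_sequences: int
    pct_none: float
    pct_one: float
    pct_more: float


def aux_count_categories(classified: Sequence[ClassifiedProtein]) -> AuxCategorySummary:
    """Percentage of sequences of one group with none, one, or more than one
    distinct auxiliary domain (deduplicated before counting)."""
    if not classified:
        raise CdgmapError("aux-category percentages are undefined for an empty group")
    groups = {cp.enzyme_class for cp in classified}
    if len(groups) != 1:
        raise CdgmapError("aux_count_categories expects proteins of a single group")
    n = len(classified)
    none = sum(1 for cp in classified if len(cp.auxiliary_domains) == 0)
    one = sum(1 for cp in classified if len(cp.auxiliary_domains) == 1)
    more = n - none - one
    return AuxCategorySummary(
        group=groups.pop().value,
        n_sequences=n,
        pct_none=100.0 * none / n,
        pct_one=100.0 * one / n,
        pct_more=100.0 * more / n,
    )


# ---------------------------------------------------------------------------
# co-occurrence network


def build_cooccurrence_network(classified: Iterable[ClassifiedProtein]) -> nx.Graph:
    """Weighted auxiliary-domain co-occurrence graph for one (order, group)
    panel.

    Node attribute ``count`` = number of sequences carrying the domain; edge
    attribute ``weight`` = number of sequences in which the unordered pair
    co-occurs. Proteins need >= 2 distinct auxiliary domains to contribute
    edges; every aux-bearing protein contributes node counts. No self-edges
    by construction.
    """
    g = nx.Graph()
    for cp in classified:
        doms = sorted(cp.auxiliary_domains)
        for d in doms:
            if g.has_node(d):
                g.nodes[d]["count"] += 1
            else:
                g.add_node(d, count=1)
        for a, b in combinations(doms, 2):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return g


def network_edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"domain_a": min(a, b), "domain_b": max(a, b), "weight": d["weight"]}
        for a, b, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["domain_a", "domain_b", "weight"]).sort_values(
        ["domain_a", "domain_b"], kind="mergesort").reset_index(drop=True)


def write_network(g: nx.Graph, edge_tsv_path, graphml_path=None) -> None:
    network_edge_table(g).to_csv(edge_tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)


# ---------------------------------------------------------------------------
# protein-length threshold for auxiliary-domain detection


@dataclass(frozen=True)
class LengthThresholdResult:
    group: str
    min_len_with_aux: int
    pct_noaux_below: float
    pct_noaux_at_or_above: float


def length_threshold(classified: Sequence[ClassifiedProtein]) -> LengthThresholdResult:
    """Minimum length among aux-bearing sequences of a group, and the share
    of aux-free sequences shorter than that minimum.

    Aux-free sequences below the threshold plausibly carry auxiliary domains
    that annotation simply has not captured; the percentage quantifies that
    blind spot. Undefined (raises) when either side is empty.
    """
    if not classified:
        raise CdgmapError("length threshold undefined for an empty group")
    groups = {cp.enzyme_class for cp in classified}
    if len(groups) != 1:
        raise CdgmapError("length_threshold expects proteins of a single group")
    with_aux = [cp.protein.length for cp in classified if cp.auxiliary_domains]
    without = [cp.protein.length for cp in classified if not cp.auxiliary_domains]
    if not with_aux or not without:
        raise CdgmapError(
            "length threshold needs both aux-bearing and aux-free sequences"
        )
    min_len = min(with_aux)
    below = sum(1 for ln in without if ln < min_len)
    pct_below = 100.0 * below / len(without)
    return LengthThresholdResult(
        group=groups.pop().value,
        min_len_with_aux=min_len,
        pct_noaux_below=pct_below,
        pct_noaux_at_or_above=100.0 - pct_below,
    )
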