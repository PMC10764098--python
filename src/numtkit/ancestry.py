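"""Ortholog groups, ancestral NUMT counts on a tree, and insertion rates.

Groups are connected components of the cross-species ortholog-pair graph.
A group is counted as ancestral on an internal node when it has members in
both of the node's child clades (applied independently per node).  The
per-species insertion rate divides the count of individual NUMTs with no
ortholog in the species' sister clade by the age of its parent node (Myr).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .core import OrthologGroup, OrthologPair, Phylogeny

log = logging.getLogger(__name__)


def n_pairwise_comparisons(n_species: int) -> int:
    """Number of unordered species comparisons, C(n, 2)."""
    return n_species * (n_species - 1) // 2


def build_ortholog_groups(
    pairs: Mapping[tuple[str, str], Sequence[OrthologPair]],
    all_units: Mapping[str, Iterable[str]] | None = None,
    expectations: Mapping[tuple[str, str], float] | None = None,
    max_expectation: float = 1.0,
) -> list[OrthologGroup]:
    """Connected components of the pairwise ortholog graph.

    ``pairs`` maps each species pair to its accepted ortholog pairs.
    Comparisons whose false-assignment expectation E is >= ``max_expectation``
    are excluded (set ``max_expectation=math.inf`` to keep all).  When
    ``all_units`` is given, units in no pair become singleton groups.
    """
    graph: nx.Graph = nx.Graph()
    if all_units:
        for sp, units in all_units.items():
            for uid in units:
                graph.add_node((sp, uid))
    n_excluded = 0
    for key, pair_list in pairs.items():
        if expectations is not None and expectations.get(key, 0.0) >= max_expectation:
            n_excluded += 1
            log.warning(
                "species comparison %s excluded from grouping (E = %.3g >= %g)",
                key,
                expectations[key],
                max_expectation,
            )
            continue
        for p in pair_list:
            graph.add_edge((p.species_a, p.unit_a), (p.species_b, p.unit_b))
    groups: list[OrthologGroup] = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    for k, comp in enumerate(components, start=1):
        members: dict[str, list[str]] = {}
        for sp, uid in comp:
            members.setdefault(sp, []).append(uid)
        groups.append(
            OrthologGroup(
                id=f"og_{k}",
                members={sp: tuple(sorted(v)) for sp, v in members.items()},
            )
        )
    return groups


def ancestral_counts(
    groups: Sequence[OrthologGroup], tree: Phylogeny
) -> tuple[dict[str, int], dict[str, list[str]]]:
    """Groups ancestral to each internal node by the both-child-clades rule.

    Returns (node label -> count, node label -> supporting group ids).  A
    group may support several nested nodes; the rule is applied per node.
    """
    tips = set(tree.tips())
    for g in groups:
        missing = g.presence - tips
        if missing:
            raise KeyError(f"species {sorted(missing)} not in tree")
    counts: dict[str, int] = {}
    support: dict[str, list[str]] = {}
    for node in tree.internal_nodes():
        left, right = node.child_nodes()
        left_tips = Phylogeny.tip_set(left)
        right_tips = Phylogeny.tip_set(right)
        label = tree.node_label(node)
        hits = [
            g.id
            for g in groups
            if g.presence & left_tips and g.presence & right_tips
        ]
        counts[label] = len(hits)
        support[label] = hits
    return counts, support


def insertion_rate(
    species: str,
    unit_ids: Iterable[str],
    groups: Sequence[OrthologGroup],
    tree: Phylogeny,
) -> float:
    """Species-specific NUMT insertions per Myr.

    Numerator: individual NUMTs of the species belonging to no ortholog
    group that contains any species of its sister clade.  Denominator: age
    of the species' parent node.  Tandem duplicates are not subtracted.
    """
    divergence = tree.parent_age(species)
    if divergence <= 0:
        raise ValueError(f"zero divergence time for {species}")
    sisters = tree.sister_tips(species)
    shared_units: set[str] = set()
    for g in groups:
        if species in g.members and g.presence & sisters:
            shared_units.update(g.members[species])
    unit_ids = set(unit_ids)
    non_orthologous = len(unit_ids - shared_units)
    return non_orthologous / divergence


def insertion_rates(
    units_by_species: Mapping[str, Iterable[str]],
    groups: Sequence[OrthologGroup],
    tree: Phylogeny,
) -> dict[str, float]:
    return {
        sp: insertion_rate(sp, units, groups, tree)
        for sp, units in units_by_species.items()
    }
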