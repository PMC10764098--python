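"""Core domain types shared across the toolkit.

All genomic coordinates are 0-based half-open internally.  Emitted GFF3 is
1-based inclusive and emitted BED is 0-based half-open.  Mitogenome
coordinates live on the linearized molecule (tRNA-Phe first, D-loop last);
a footprint may wrap the linearization boundary, in which case it is stored
as two intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

PLUS = "+"
MINUS = "-"


@dataclass(frozen=True)
class Hsp:
    """One alignment hit between the mitogenome (query) and a nuclear scaffold."""

    mt_start: int
    mt_end: int
    scaffold: str
    n_start: int
    n_end: int
    orientation: str
    identity: float
    aln_length: int
    e_value: float
    bit_score: float
    mismatches: int = 0
    gap_opens: int = 0

    def __post_init__(self) -> None:
        if self.mt_end <= self.mt_start:
            raise ValueError(f"empty mt interval {self.mt_start}..{self.mt_end}")
        if self.n_end <= self.n_start:
            raise ValueError(f"empty nuclear interval {self.n_start}..{self.n_end}")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside 0-100")
        if self.e_value < 0:
            raise ValueError("negative E-value")
        if self.orientation not in (PLUS, MINUS):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass
class Numt:
    """A called NUMT: one nuclear interval with its mtDNA footprint.

    ``mt_intervals`` is ordered along the nuclear plus strand; it has two
    elements only when the footprint wraps the linearization boundary.
    """

    id: str | None
    scaffold: str
    n_start: int
    n_end: int
    orientation: str
    mt_intervals: tuple[tuple[int, int], ...]
    identity: float
    members: tuple[Hsp, ...] = ()
    species: str | None = None

    @property
    def length(self) -> int:
        return self.n_end - self.n_start

    @property
    def mt_footprint_length(self) -> int:
        return sum(e - s for s, e in self.mt_intervals)

    @property
    def mt_start(self) -> int:
        """Smallest mtDNA coordinate touched by the footprint."""
        return min(s for s, _ in self.mt_intervals)

    @property
    def mt_end(self) -> int:
        """Largest mtDNA coordinate touched by the footprint."""
        return max(e for _, e in self.mt_intervals)


@dataclass
class NumtBlock:
    """Cluster of NUMTs whose nuclear gaps are all below the block threshold."""

    id: str | None
    scaffold: str
    span: tuple[int, int]
    members: tuple[Numt, ...]

    @property
    def is_complex(self) -> bool:
        return len(self.members) >= 3

    @property
    def n_start(self) -> int:
        return self.span[0]

    @property
    def n_end(self) -> int:
        return self.span[1]

    @property
    def mt_intervals(self) -> tuple[tuple[int, int], ...]:
        return tuple(iv for m in self.members for iv in m.mt_intervals)


@dataclass
class NumtSummary:
    species: str | None
    n_numts: int
    n_blocks: int
    cumulative_length: int
    genome_fraction: float
    mean_identity: float
    median_identity: float
    fraction_above_cut: float
    identity_cut: float = 98.0


@dataclass(frozen=True)
class GeneModel:
    """Protein-coding gene span with its symbol."""

    symbol: str
    scaffold: str
    start: int
    end: int
    strand: str = PLUS

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class RepeatInterval:
    scaffold: str
    start: int
    end: int
    repeat_class: str = "Unknown"


class GenomeIndex:
    """Ordered scaffold table: ids and lengths, order as in the source file."""

    def __init__(self, items: Iterable[tuple[str, int]]):
        self._ids: list[str] = []
        self._lengths: dict[str, int] = {}
        for name, length in items:
            if name in self._lengths:
                raise ValueError(f"duplicate scaffold id {name!r}")
            if length < 1:
                raise ValueError(f"scaffold {name!r} has length {length}")
            self._ids.append(name)
            self._lengths[name] = int(length)

    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __len__(self) -> int:
        return len(self._ids)

    def length(self, name: str) -> int:
        return self._lengths[name]

    def total_length(self) -> int:
        return sum(self._lengths.values())

    def rank(self, name: str) -> int:
        return self._ids.index(name)

    def items(self) -> list[tuple[str, int]]:
        return [(i, self._lengths[i]) for i in self._ids]


@dataclass(frozen=True)
class SyntenyContext:
    """Up to k nearest protein-coding anchor genes on each side of a unit."""

    unit_id: str
    up_anchors: tuple[str, ...]
    down_anchors: tuple[str, ...]
    host: tuple[str, ...] = ()

    def anchor_set(self) -> frozenset[str]:
        return frozenset(self.up_anchors) | frozenset(self.down_anchors) | frozenset(self.host)


@dataclass(frozen=True)
class OrthologPair:
    species_a: str
    unit_a: str
    species_b: str
    unit_b: str
    shared_anchors: frozenset[str]
    overlap: float


@dataclass
class OrthologGroup:
    """Connected component of the cross-species ortholog-pair graph."""

    id: str
    members: dict[str, tuple[str, ...]]

    @property
    def presence(self) -> frozenset[str]:
        return frozenset(self.members)


class Phylogeny:
    """Rooted, ultrametric, strictly bifurcating species tree (ages in Myr)."""

    def __init__(self, tree: dendropy.Tree, ages: Mapping[int, float]):
        self.tree = tree
        self._ages = dict(ages)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, rel_tol: float = 1e-6) -> "Phylogeny":
        seen: set[str] = set()
        for leaf in tree.leaf_node_iter():
            name = leaf.taxon.label if leaf.taxon else None
            if not name:
                raise ValueError("tree has an unlabeled tip")
            if name in seen:
                raise ValueError(f"duplicate tip label {name!r}")
            seen.add(name)
        for node in tree.preorder_node_iter():
            kids = node.child_nodes()
            if kids and len(kids) != 2:
                raise ValueError(
                    f"tree is not strictly bifurcating (node with {len(kids)} children)"
                )
            if node.parent_node is not None and node.edge.length is None:
                raise ValueError("missing branch length")
        tree.calc_node_root_distances(return_leaf_distances_only=False)
        depths = {id(n): n.root_distance for n in tree.preorder_node_iter()}
        tip_depths = [depths[id(l)] for l in tree.leaf_node_iter()]
        height = max(tip_depths)
        if height <= 0:
            raise ValueError("tree has zero height")
        if max(tip_depths) - min(tip_depths) > rel_tol * height:
            raise ValueError("tree is not ultrametric within tolerance")
        ages = {id(n): height - depths[id(n)] for n in tree.preorder_node_iter()}
        return cls(tree, ages)

    def age(self, node) -> float:
        return self._ages[id(node)]

    @property
    def root(self):
        return self.tree.seed_node

    def tips(self) -> list[str]:
        return [l.taxon.label for l in self.tree.leaf_node_iter()]

    def leaf(self, species: str):
        for l in self.tree.leaf_node_iter():
            if l.taxon.label == species:
                return l
        raise KeyError(f"species {species!r} not in tree")

    def internal_nodes(self):
        return [n for n in self.tree.preorder_node_iter() if n.child_nodes()]

    @staticmethod
    def tip_set(node) -> frozenset[str]:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def node_label(self, node) -> str:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        if node.label:
            return node.label
        return "|".join(sorted(self.tip_set(node)))

    def parent_age(self, species: str) -> float:
        leaf = self.leaf(species)
        if leaf.parent_node is None:
            raise ValueError("single-tip tree has no divergence time")
        return self.age(leaf.parent_node)

    def sister_tips(self, species: str) -> frozenset[str]:
        """Tips of the sister clade of a species in this tree."""
        leaf = self.leaf(species)
        parent = leaf.parent_node
        if parent is None:
            raise ValueError("single-tip tree has no sister clade")
        sisters = [c for c in parent.child_nodes() if c is not leaf]
        out: set[str] = set()
        for s in sisters:
            out |= self.tip_set(s)
        return frozenset(out)


def footprint_union_length(intervals: Sequence[tuple[int, int]]) -> int:
    """Total bases covered by a union of (possibly overlapping) intervals."""
    if not intervals:
        return 0
    ivs = sorted(intervals)
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return total
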