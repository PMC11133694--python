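"""Energy-landscape structure: local minima, basins, disconnectivity tree.

The ``2**N`` activity patterns form the nodes of a hypercube graph in which
two patterns are adjacent when they differ in exactly one network.  A local
minimum (attractor) is a pattern whose energy is strictly below all N of its
neighbours'.  Every pattern is assigned to the basin of the minimum reached
by repeated steepest descent, and the hierarchy of minima is summarised by a
disconnectivity tree: the branch joining two minima sits at the lowest
energy threshold whose removal (of all patterns with energy >= threshold)
disconnects them, i.e. at the minimax saddle energy between their wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .mem import LandscapeTable

__all__ = [
    "BasinMap",
    "TreeNode",
    "DisconnectivityTree",
    "StateDefinition",
    "neighbors",
    "find_local_minima",
    "assign_basins",
    "build_disconnectivity_tree",
    "group_minima_into_states",
]


def neighbors(k: int, n_networks: int) -> np.ndarray:
    """The N pattern indices at Hamming distance 1 from pattern ``k``."""
    if not 0 <= k < 2 ** n_networks:
        raise ValueError(f"pattern index {k} out of range for N={n_networks}")
    return k ^ (1 << np.arange(n_networks))


def _neighbor_index_matrix(n_networks: int) -> np.ndarray:
    """(2**N, N) matrix of neighbour indices for every pattern."""
    k = np.arange(2 ** n_networks)
    return k[:, None] ^ (1 << np.arange(n_networks))


def find_local_minima(table: LandscapeTable) -> list[tuple[int, float]]:
    """Exhaustively scan for local minima, sorted by energy ascending.

    A pattern qualifies iff its energy is strictly smaller than the energies
    of all N single-flip neighbours.  A landscape with no strict minima
    (possible only with exact energy ties) yields an empty list and a
    warning.
    """
    e = table.energies
    nbr = _neighbor_index_matrix(table.n_networks)
    is_min = np.all(e[:, None] < e[nbr], axis=1)
    idx = np.flatnonzero(is_min)
    if idx.size == 0:
        warnings.warn("degenerate landscape: no strict local minima", stacklevel=2)
    order = np.argsort(e[idx], kind="stable")
    return [(int(k), float(e[k])) for k in idx[order]]


@dataclass(frozen=True)
class BasinMap:
    """Partition of all patterns into basins of attraction.

    ``minima`` lists (pattern index, energy) sorted by energy ascending;
    ``basin_of[k]`` is the minimum's pattern index reached from pattern ``k``
    by steepest descent; ``basin_sizes`` are fractions of the ``2**N``
    patterns per minimum, in the order of ``minima``.
    """

    minima: tuple[tuple[int, float], ...]
    basin_of: np.ndarray
    basin_sizes: np.ndarray
    n_networks: int

    def basin_size_of(self, minimum: int) -> float:
        for (k, _), s in zip(self.minima, self.basin_sizes):
            if k == minimum:
                return float(s)
        raise KeyError(minimum)


def assign_basins(table: LandscapeTable) -> BasinMap:
    """Assign every pattern to a local minimum by steepest descent.

    From each pattern, move to the strictly lower neighbour of lowest energy
    (ties among equally lowest neighbours broken by flipping the
    lowest-index network) and repeat until a local minimum is reached.  The
    resulting basin sizes partition the ``2**N`` patterns exactly.  The tie
    rule is deterministic and respects pattern-inversion symmetry, so a
    symmetric double well splits its basins evenly; ties have measure zero
    for generic parameters.
    """
    minima = find_local_minima(table)
    if not minima:
        raise ValueError("cannot assign basins: landscape has no strict local minima")
    e = table.energies
    nbr = _neighbor_index_matrix(table.n_networks)
    nbr_e = e[nbr]
    lowest = nbr_e.min(axis=1)
    # first column attaining the lowest energy = smallest flipped network
    first = np.argmax(nbr_e == lowest[:, None], axis=1)
    step = nbr[np.arange(e.size), first]
    stay = lowest >= e  # no strictly lower neighbour -> fixed point
    step = np.where(stay, np.arange(e.size), step)
    # pointer jumping: step is a functional graph whose cycles are fixed points
    dest = step
    while True:
        nxt = dest[dest]
        if np.array_equal(nxt, dest):
            break
        dest = nxt
    min_idx = np.array([k for k, _ in minima])
    fixed_points = np.flatnonzero(step == np.arange(e.size))
    if not np.array_equal(np.sort(min_idx), fixed_points):
        raise AssertionError("descent fixed points disagree with the minima scan")
    counts = np.array([(dest == k).sum() for k in min_idx])
    return BasinMap(
        minima=tuple(minima),
        basin_of=dest,
        basin_sizes=counts / e.size,
        n_networks=table.n_networks,
    )


# ---------------------------------------------------------------------------
# disconnectivity tree


@dataclass
class TreeNode:
    """Node of a disconnectivity tree.

    Leaves carry a local minimum's pattern index; internal nodes carry the
    separation threshold energy at which their two subtrees disconnect.
    """

    energy: float
    minimum: Optional[int] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.minimum is not None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def internal_nodes(self) -> list["TreeNode"]:
        if self.is_leaf:
            return []
        out = [self]
        for c in self.children:
            out.extend(c.internal_nodes())
        return out


@dataclass
class DisconnectivityTree:
    """Hierarchy of local minima with branch (separation) energies."""

    root: TreeNode
    n_networks: int

    @property
    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    @property
    def internal_nodes(self) -> list[TreeNode]:
        return self.root.internal_nodes()

    def branch_energy(self, min_a: int, min_b: int) -> float:
        """Separation threshold energy between two minima (their lowest
        common ancestor's energy)."""
        if min_a == min_b:
            raise ValueError("minima must differ")

        def walk(node: TreeNode) -> Optional[set[int]]:
            # returns the set of minima below, or None once the answer is found
            if node.is_leaf:
                return {node.minimum}
            below: set[int] = set()
            for c in node.children:
                sub = walk(c)
                if sub is None:
                    return None
                below |= sub
            if min_a in below and min_b in below:
                raise _Found(node.energy)
            return below

        class _Found(Exception):
            def __init__(self, e: float):
                self.e = e

        try:
            walk(self.root)
        except _Found as f:  # noqa: F821 - defined just above
            return float(f.e)
        raise KeyError(f"minima {min_a}, {min_b} not both in tree")

    def to_newick(self, names: Optional[Mapping[int, str]] = None) -> str:
        """Newick string with branch lengths = parent threshold - child energy.

        Leaf names default to ``min<pattern index>``.
        """

        def label(node: TreeNode) -> str:
            if names is not None and node.minimum in names:
                return names[node.minimum]
            return f"min{node.minimum}"

        def render(node: TreeNode, parent_energy: Optional[float]) -> str:
            if node.is_leaf:
                s = label(node)
            else:
                s = "(" + ",".join(render(c, node.energy) for c in node.children) + ")"
            if parent_energy is not None:
                s += f":{parent_energy - node.energy:.10g}"
            return s

        return render(self.root, None) + ";"


class _DisjointSet:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
        return ra


def build_disconnectivity_tree(
    table: LandscapeTable, minima: Optional[Sequence[tuple[int, float]]] = None
) -> DisconnectivityTree:
    """Build the disconnectivity tree of a landscape.

    Implements the threshold sweep: starting from the highest pattern energy,
    patterns with energy >= E_th are removed and E_th lowered through the
    sorted energy values until every pair of minima is disconnected; the
    branch energy of a pair is the threshold at which they first separate.
    The sweep is realised bottom-up as a union-find pass over patterns in
    ascending energy order, which records exactly those merge energies (the
    minimax saddle between the wells).
    """
    if minima is None:
        minima = find_local_minima(table)
    if not minima:
        raise ValueError("cannot build a tree without local minima")
    e = table.energies
    n = table.n_networks
    nbr = _neighbor_index_matrix(n)
    order = np.lexsort((np.arange(e.size), e))  # ascending energy, index tiebreak
    ds = _DisjointSet(e.size)
    subtree: dict[int, Optional[TreeNode]] = {}
    added = np.zeros(e.size, dtype=bool)
    leaf_at = {k: TreeNode(energy=en, minimum=k) for k, en in minima}

    for k in order:
        k = int(k)
        added[k] = True
        root = ds.find(k)
        subtree[root] = leaf_at.get(k)
        for j in nbr[k]:
            j = int(j)
            if not added[j]:
                continue
            ra, rb = ds.find(k), ds.find(j)
            if ra == rb:
                continue
            ta, tb = subtree.pop(ra, None), subtree.pop(rb, None)
            merged = ds.union(ra, rb)
            if ta is not None and tb is not None:
                subtree[merged] = TreeNode(energy=float(e[k]), children=[ta, tb])
            else:
                subtree[merged] = ta if ta is not None else tb

    roots = [t for t in subtree.values() if t is not None]
    if len(roots) != 1:
        raise AssertionError("hypercube is connected; expected a single tree")
    tree = DisconnectivityTree(root=roots[0], n_networks=n)
    assert len(tree.leaves) == len(minima)
    return tree


# ---------------------------------------------------------------------------
# grouping minima into brain states


@dataclass(frozen=True)
class StateDefinition:
    """Assignment of each local minimum to a brain-state label."""

    state_of_minimum: Mapping[int, Union[int, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_of_minimum", dict(self.state_of_minimum))
        if not self.state_of_minimum:
            raise ValueError("empty state mapping")

    @property
    def states(self) -> list:
        seen: list = []
        for s in self.state_of_minimum.values():
            if s not in seen:
                seen.append(s)
        return seen

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_of_pattern(self, basins: "BasinMap") -> np.ndarray:
        """Map every pattern to its state via its basin's minimum.

        Returns an integer array over the 2**N patterns, with states coded
        by their position in :attr:`states`.
        """
        code = {s: i for i, s in enumerate(self.states)}
        lut = np.empty(2 ** basins.n_networks, dtype=np.int64)
        min_state = np.empty(2 ** basins.n_networks, dtype=np.int64)
        min_state.fill(-1)
        for k, _ in basins.minima:
            min_state[k] = code[self.state_of_minimum[k]]
        lut = min_state[basins.basin_of]
        if np.any(lut < 0):
            raise ValueError("state mapping does not cover all minima")
        return lut


def group_minima_into_states(
    tree: DisconnectivityTree,
    mapping: Optional[Mapping[int, Union[int, str]]] = None,
    k: Optional[int] = None,
) -> StateDefinition:
    """Group the tree's minima into brain states.

    Either an explicit ``mapping`` from minimum pattern index to state label
    is honoured verbatim, or ``k``-cut mode removes the ``k - 1`` highest
    internal nodes and labels each remaining subtree a state (states are
    numbered 0.. in order of their lowest minimum energy).
    """
    leaf_ids = {leaf.minimum for leaf in tree.leaves}
    if (mapping is None) == (k is None):
        raise ValueError("provide exactly one of mapping or k")
    if mapping is not None:
        missing = leaf_ids - set(mapping)
        if missing:
            raise ValueError(f"mapping does not cover minima {sorted(missing)}")
        return StateDefinition({m: mapping[m] for m in sorted(leaf_ids)})

    if not 1 <= k <= len(leaf_ids):
        raise ValueError(f"k must be in [1, {len(leaf_ids)}]")
    internal = sorted(tree.internal_nodes, key=lambda nd: nd.energy, reverse=True)
    removed = set(id(nd) for nd in internal[: k - 1])

    groups: list[list[int]] = []

    def collect(node: TreeNode) -> None:
        if not node.is_leaf and id(node) in removed:
            for c in node.children:
                collect(c)
        else:
            groups.append([leaf.minimum for leaf in node.leaves()])

    collect(tree.root)
    # order states by the energy of their deepest minimum for stable labels
    energy_of = {leaf.minimum: leaf.energy for leaf in tree.leaves}
    groups.sort(key=lambda g: min(energy_of[m] for m in g))
    state_of = {m: i for i, g in enumerate(groups) for m in g}
    return StateDefinition(state_of)
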