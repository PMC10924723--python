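"""Rooted binary trees: chronograms (time) and phylograms (expected change).

Trees are stored as flat index arrays for fast likelihood computation.
Node ids are ``0 .. n_nodes-1`` with tips occupying ``0 .. n_tips-1`` in
label registration order; every non-root node carries the length of the
edge above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Topology",
    "Chronogram",
    "Phylogram",
    "TreeError",
    "UltrametricityError",
    "simulate_chronogram",
    "load_chronogram",
    "load_phylogram",
]

ULTRAMETRIC_RTOL = 1e-9


class TreeError(ValueError):
    """Malformed tree or inconsistent tree/data combination."""


class UltrametricityError(TreeError):
    """Root-to-tip path sums differ beyond tolerance."""


@dataclass(frozen=True)
class Topology:
    """Shape of a rooted binary tree, without branch lengths.

    Attributes
    ----------
    parent : ndarray of int
        ``parent[i]`` is the parent node id of node ``i`` (-1 for the root).
    children : tuple of tuple of int
        Child ids per node (empty for tips).
    labels : tuple of str
        Tip labels; tip ``i`` has label ``labels[i]``.
    """

    parent: np.ndarray
    children: tuple
    labels: tuple
    postorder: np.ndarray = field(init=False, repr=False)
    preorder: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        n = len(self.parent)
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        if len(order) != n:
            raise TreeError("disconnected topology")
        object.__setattr__(self, "preorder", np.asarray(order, dtype=np.intp))
        object.__setattr__(self, "postorder", self.preorder[::-1].copy())
        for v in range(n):
            k = len(self.children[v])
            if k not in (0, 2):
                raise TreeError(f"node {v} has {k} children; tree must be binary")

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    def splits(self) -> frozenset:
        """Set of tip-label bipartition halves, for topology comparison."""
        below = [set() for _ in range(self.n_nodes)]
        for v in self.postorder:
            if self.is_tip(v):
                below[v] = {self.labels[v]}
            else:
                for c in self.children[v]:
                    below[v] |= below[c]
        return frozenset(frozenset(below[v]) for v in range(self.n_nodes))


@dataclass(frozen=True)
class _BranchTree:
    """Common machinery for trees with per-edge lengths."""

    topology: Topology
    edge_lengths: np.ndarray  # indexed by child node; root entry is 0

    def __post_init__(self):
        el = np.asarray(self.edge_lengths, dtype=float).copy()
        if el.shape != (self.topology.n_nodes,):
            raise TreeError("edge_lengths must have one entry per node")
        el[self.topology.root] = 0.0
        el.setflags(write=False)
        object.__setattr__(self, "edge_lengths", el)

    @property
    def labels(self) -> tuple:
        return self.topology.labels

    @property
    def n_tips(self) -> int:
        return self.topology.n_tips

    def root_to_tip_distances(self) -> np.ndarray:
        """Patristic distance from root to each tip, in tip order."""
        top = self.topology
        depth = np.zeros(top.n_nodes)
        for v in top.preorder:
            p = top.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.edge_lengths[v]
        return depth[: top.n_tips]

    def total_length(self) -> float:
        return float(self.edge_lengths.sum())

    def newick(self, precision: int = 12) -> str:
        return _to_newick(self.topology, self.edge_lengths, precision)


class Phylogram(_BranchTree):
    """Tree with branch lengths in expected changes per site/character."""

    def __post_init__(self):
        super().__post_init__()
        if np.any(self.edge_lengths < 0):
            raise TreeError("phylogram branch lengths must be non-negative")

    def scaled(self, factor: float) -> "Phylogram":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return Phylogram(self.topology, self.edge_lengths * factor)


class Chronogram(_BranchTree):
    """Ultrametric tree with branch durations in Myr."""

    def __post_init__(self):
        super().__post_init__()
        top = self.topology
        nonroot = np.arange(top.n_nodes) != top.root
        if np.any(self.edge_lengths[nonroot] <= 0):
            raise TreeError("chronogram branch durations must be positive")
        ages = self.node_ages()
        root_age = ages[top.root]
        tip_depths = self.root_to_tip_distances()
        bad = np.flatnonzero(~np.isclose(tip_depths, root_age, rtol=ULTRAMETRIC_RTOL, atol=1e-9 * max(root_age, 1.0)))
        if bad.size:
            lbl = top.labels[bad[0]]
            raise UltrametricityError(
                f"tree is not ultrametric: tip {lbl!r} has root-to-tip depth "
                f"{tip_depths[bad[0]]:.6g} vs root age {root_age:.6g}"
            )

    def node_ages(self) -> np.ndarray:
        """Age of every node (tips at ~0), computed from tip paths upward."""
        top = self.topology
        age = np.zeros(top.n_nodes)
        for v in top.postorder:
            if not top.is_tip(v):
                c = top.children[v][0]
                age[v] = age[c] + self.edge_lengths[c]
        return age

    @property
    def root_age(self) -> float:
        return float(self.node_ages()[self.topology.root])

    def to_phylogram(self) -> Phylogram:
        return Phylogram(self.topology, self.edge_lengths)


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)


def _from_dendropy(tree: dendropy.Tree):
    tree.suppress_unifurcations()
    nodes = list(tree)
    tips = [nd for nd in nodes if nd.is_leaf()]
    internals = [nd for nd in nodes if not nd.is_leaf()]
    index = {}
    labels = []
    for i, nd in enumerate(tips):
        index[id(nd)] = i
        if nd.taxon is not None and nd.taxon.label:
            labels.append(str(nd.taxon.label))
        elif nd.label:
            labels.append(str(nd.label))
        else:
            raise TreeError("unlabelled tip in input tree")
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate tip labels")
    for j, nd in enumerate(internals):
        index[id(nd)] = len(tips) + j
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.intp)
    children = [[] for _ in range(n)]
    lengths = np.zeros(n)
    for nd in nodes:
        v = index[id(nd)]
        if nd.edge.length is not None:
            lengths[v] = float(nd.edge.length)
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[v] = p
            children[p].append(v)
    top = Topology(parent, tuple(tuple(c) for c in children), tuple(labels))
    return top, lengths


def _to_newick(top: Topology, lengths: np.ndarray, precision: int = 12) -> str:
    def rec(v: int) -> str:
        if top.is_tip(v):
            core = top.labels[v]
        else:
            core = "(" + ",".join(rec(c) for c in top.children[v]) + ")"
        if top.parent[v] < 0:
            return core
        return f"{core}:{lengths[v]:.{precision}g}"

    return rec(top.root) + ";"


def _parse_newick(text: str):
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True, rooting="force-rooted"
        )
    except Exception as err:
        raise TreeError(f"could not parse Newick input: {err}") from err
    return _from_dendropy(tree)


def load_phylogram(newick_text: str) -> Phylogram:
    """Parse a Newick string as a phylogram (no ultrametricity check)."""
    top, lengths = _parse_newick(newick_text)
    return Phylogram(top, lengths)


def load_chronogram(newick_text: str) -> Chronogram:
    """Parse a Newick string and validate it as an ultrametric chronogram."""
    top, lengths = _parse_newick(newick_text)
    return Chronogram(top, lengths)


# ---------------------------------------------------------------------------
# Birth-death chronogram simulation


def simulate_chronogram(
    n_taxa: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    root_age: float = 139.40,
    seed: int = 0,
) -> Chronogram:
    """Simulate an ultrametric birth-death tree conditioned on tip count.

    The tree is grown until ``n_taxa`` extant tips exist, extinct lineages
    are pruned, and all durations are rescaled so the root age equals
    ``root_age`` exactly.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be at least 2")
    if root_age <= 0:
        raise ValueError("root_age must be positive")
    if not birth_rate > death_rate >= 0:
        raise ValueError("require birth_rate > death_rate >= 0")
    if n_taxa == 2:
        # fully determined up to label order
        parent = np.array([2, 2, -1], dtype=np.intp)
        top = Topology(parent, ((), (), (0, 1)), ("t1", "t2"))
        return Chronogram(top, np.array([root_age, root_age, 0.0]))
    import random as _random

    from dendropy.model import birthdeath

    rng = _random.Random(int(seed))
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_taxa)])
    dtree = birthdeath.birth_death_tree(
        birth_rate,
        death_rate,
        num_extant_tips=n_taxa,
        taxon_namespace=taxa,
        rng=rng,
        is_retain_extinct_tips=False,
        repeat_until_success=True,
    )
    top, lengths = _from_dendropy(dtree)
    depth = np.zeros(top.n_nodes)
    for v in top.preorder:
        p = top.parent[v]
        if p >= 0:
            depth[v] = depth[p] + lengths[v]
    tip_depths = depth[: top.n_tips]
    # the process stops exactly at the n-th birth, leaving zero-length newborn
    # tips; extend all terminals by the waiting time to the next event, then
    # equalize paths (fixes float drift) before rescaling to the target age
    extra = rng.expovariate(n_taxa * (birth_rate + death_rate))
    target = tip_depths.max() + extra
    lengths = lengths.copy()
    lengths[: top.n_tips] += target - tip_depths
    scale = root_age / target
    return Chronogram(top, lengths * scale)
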