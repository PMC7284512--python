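"""Distance-based ITS phylogenetics: K2P distances, neighbor-joining,
bootstrap majority-rule consensus, clade assignment and the ITS SNP triplet.

Sequences enter as reference-anchored rows (equal length, gaps allowed).
Distances use the Kimura 2-parameter model with pairwise deletion of sites
where either base is not a plain A/C/G/T.  Trees are unrooted internally and
represented rooted at an arbitrary node for traversal; Newick output carries
bootstrap supports as internal node labels.

Neighbor-joining ties on the Q criterion are broken by the lowest (row,
column) index pair so results are reproducible across platforms.  Negative
branch length estimates are clamped to zero and the deficit logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .panel import ITSTriplet, IUPAC_CODES
from .seqio import GAP, SeqRecord

__all__ = [
    "K2PResult",
    "SaturationError",
    "TreeNode",
    "PhyloTree",
    "CladeAssignment",
    "k2p_distance",
    "k2p_matrix",
    "nj_tree",
    "bootstrap_consensus",
    "assign_clade",
    "triplet_call",
    "triplet_call_from_bases",
]

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class SaturationError(ValueError):
    """K2P distance undefined: substitution proportions exceed model range."""


# ---------------------------------------------------------------------------
# K2P distances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class K2PResult:
    P: float  # transition proportion
    Q: float  # transversion proportion
    L: int  # retained (comparable) site count
    d: float  # substitutions per site

    def __post_init__(self) -> None:
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1:
            raise ValueError("invalid substitution proportions")


def _encode(row: str) -> np.ndarray:
    return np.fromiter((_CODE.get(c, -1) for c in row), dtype=np.int8, count=len(row))


def _k2p_from_counts(transitions: int, transversions: int, L: int) -> K2PResult:
    if L == 0:
        raise ValueError("no comparable sites between sequences")
    P = transitions / L
    Q = transversions / L
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        raise SaturationError(
            f"K2P undefined for P={P:.4f}, Q={Q:.4f} (saturated divergence)"
        )
    d = -0.5 * math.log(a) - 0.25 * math.log(b)
    # guard against -0.0 from rounding
    return K2PResult(P=P, Q=Q, L=L, d=max(d, 0.0))


def k2p_distance(a: str, b: str) -> K2PResult:
    """Kimura 2-parameter distance between two equal-length aligned rows.

    Sites where either sequence has a gap or ambiguity are excluded
    (pairwise deletion).
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in length")
    xa, xb = _encode(a.upper()), _encode(b.upper())
    ok = (xa >= 0) & (xb >= 0)
    xa, xb = xa[ok], xb[ok]
    diff = xa != xb
    transitions = int((diff & ((xa & 1) == (xb & 1))).sum())
    transversions = int(diff.sum()) - transitions
    return _k2p_from_counts(transitions, transversions, int(ok.sum()))


def k2p_matrix(rows: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    """Pairwise K2P distance matrix over a dict of aligned rows."""
    names = list(rows)
    enc = np.stack([_encode(rows[n].upper()) for n in names])
    n = len(names)
    D = np.zeros((n, n))
    valid = enc >= 0
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            xa, xb = enc[i][ok], enc[j][ok]
            diff = xa != xb
            ts = int((diff & ((xa & 1) == (xb & 1))).sum())
            tv = int(diff.sum()) - ts
            D[i, j] = D[j, i] = _k2p_from_counts(ts, tv, int(ok.sum())).d
    return names, D


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None  # leaf label; None for internal nodes
    length: float = 0.0  # length of the edge above this node
    support: float | None = None  # bootstrap % for the edge above (internal only)
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterable["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class PhyloTree:
    """An unrooted tree stored rooted at an arbitrary internal node."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def bipartitions(self) -> list[tuple[frozenset[str], float | None, float]]:
        """Non-trivial splits as (leaf set below edge, support, length)."""
        all_leaves = frozenset(self.leaf_names())
        out = []
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            below = frozenset(l.name for l in node.walk() if l.is_leaf)
            if 1 < len(below) < len(all_leaves) - 1:
                out.append((below, node.support, node.length))
        return out

    def clades(self) -> list[tuple[frozenset[str], float | None]]:
        """Both sides of every internal edge, with that edge's support."""
        all_leaves = frozenset(self.leaf_names())
        out = []
        for below, support, _ in self.bipartitions():
            out.append((below, support))
            out.append((all_leaves - below, support))
        return out

    def patristic_distances(self, source: str) -> dict[str, float]:
        """Path lengths from a named leaf to every other leaf."""
        parent: dict[int, TreeNode | None] = {id(self.root): None}
        nodes: dict[int, TreeNode] = {id(self.root): self.root}
        start = None
        for node in self.root.walk():
            nodes[id(node)] = node
            for child in node.children:
                parent[id(child)] = node
            if node.name == source and node.is_leaf:
                start = node
        if start is None:
            raise KeyError(f"leaf {source!r} not in tree")
        # Dijkstra-free: tree has unique paths; BFS over the undirected graph.
        adj: dict[int, list[tuple[TreeNode, float]]] = {id(n): [] for n in nodes.values()}
        for node in nodes.values():
            for child in node.children:
                adj[id(node)].append((child, child.length))
                adj[id(child)].append((node, child.length))
        dist: dict[int, float] = {id(start): 0.0}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nxt, w in adj[id(cur)]:
                if id(nxt) not in dist:
                    dist[id(nxt)] = dist[id(cur)] + w
                    stack.append(nxt)
        return {
            n.name: dist[id(n)]
            for n in nodes.values()
            if n.is_leaf and n.name != source
        }

    def newick(self, *, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{_quote(node.name)}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.0f}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def _quote(name: str) -> str:
    if any(c in name for c in " (),:;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(names: Sequence[str], D: np.ndarray) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    ``D`` must be a symmetric matrix with zero diagonal over >= 2 taxa.
    Ties on the Q criterion resolve to the lowest (i, j) pair; negative
    branch-length estimates are clamped to zero with the deficit logged.
    """
    D = np.asarray(D, dtype=float)
    n = len(names)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if n < 2:
        raise ValueError("need at least two taxa")

    nodes = [TreeNode(name=nm) for nm in names]
    if n == 2:
        half = max(D[0, 1] / 2.0, 0.0)
        for node in nodes:
            node.length = half
        return PhyloTree(root=TreeNode(children=nodes))

    D = D.copy()
    active = list(range(n))

    def clamp(x: float, where: str) -> float:
        if x < 0:
            logger.debug("clamping negative branch length %.6g at %s", x, where)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major argmin -> lowest (i, j) on ties
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]

        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = clamp(li, names[i] if nodes[i].name else "internal")
        nodes[j].length = clamp(lj, names[j] if nodes[j].name else "internal")
        new = TreeNode(children=[nodes[i], nodes[j]])

        new_idx = len(nodes)
        nodes.append(new)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D[i, k] + D[j, k] - dij)
            D[new_idx, k] = D[k, new_idx] = max(dk, 0.0)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # final three-way join (three-point formulas)
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    nodes[a].length = clamp(la, "final")
    nodes[b].length = clamp(lb, "final")
    nodes[c].length = clamp(lc, "final")
    return PhyloTree(root=TreeNode(children=[nodes[a], nodes[b], nodes[c]]))


# ---------------------------------------------------------------------------
# Bootstrap + majority-rule consensus
# ---------------------------------------------------------------------------


def _split_key(below: frozenset[str], all_leaves: frozenset[str], anchor: str) -> frozenset[str]:
    """Canonical orientation of a split: the side NOT containing the anchor."""
    return all_leaves - below if anchor in below else below


def _compatible(a: frozenset[str], b: frozenset[str]) -> bool:
    return a <= b or b <= a or not (a & b)


def bootstrap_consensus(
    rows: Mapping[str, str],
    replicates: int = 100,
    threshold: float = 0.5,
    seed: int | None = None,
    *,
    distance_fn: Callable[[Mapping[str, str]], tuple[list[str], np.ndarray]] = k2p_matrix,
) -> PhyloTree:
    """Column bootstrap + NJ + >=threshold majority-rule consensus.

    Splits kept are those appearing in at least ``threshold`` of the replicate
    trees (ties at exactly the threshold are retained).  Supports are attached
    as percentages; branch lengths are the mean estimate over the replicates
    in which the edge appears (leaf edges average over all replicates).
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    names = list(rows)
    if len(names) < 3:
        raise ValueError("need at least three sequences")
    length = len(next(iter(rows.values())))
    if any(len(r) != length for r in rows.values()):
        raise ValueError("rows differ in length")

    rng = np.random.default_rng(seed)
    anchor = names[0]
    all_leaves = frozenset(names)
    counts: dict[frozenset[str], int] = {}
    length_sums: dict[frozenset[str], float] = {}
    leaf_lengths: dict[str, float] = {nm: 0.0 for nm in names}

    mat = np.stack([np.frombuffer(rows[nm].encode(), dtype=np.uint8) for nm in names])
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = {
            nm: mat[i, cols].tobytes().decode() for i, nm in enumerate(names)
        }
        rep_names, D = distance_fn(resampled)
        tree = nj_tree(rep_names, D)
        for below, _, blen in tree.bipartitions():
            key = _split_key(below, all_leaves, anchor)
            counts[key] = counts.get(key, 0) + 1
            length_sums[key] = length_sums.get(key, 0.0) + blen
        for leaf in tree.leaves():
            leaf_lengths[leaf.name] += leaf.length

    min_count = threshold * replicates
    kept = [
        (cnt, key)
        for key, cnt in counts.items()
        if cnt >= min_count - 1e-9
    ]
    # highest support first; greedy compatibility filter guards the exact-50% case
    kept.sort(key=lambda t: (-t[0], len(t[1]), sorted(t[1])))
    accepted: list[tuple[frozenset[str], float, float]] = []
    for cnt, key in kept:
        if all(_compatible(key, other) for other, _, _ in accepted):
            accepted.append((key, 100.0 * cnt / replicates, length_sums[key] / cnt))

    return _build_consensus_tree(names, anchor, accepted, leaf_lengths, replicates)


def _build_consensus_tree(
    names: list[str],
    anchor: str,
    accepted: list[tuple[frozenset[str], float, float]],
    leaf_lengths: dict[str, float],
    replicates: int,
) -> PhyloTree:
    # nest accepted clades (all exclude the anchor, pairwise compatible)
    accepted = sorted(accepted, key=lambda t: -len(t[0]))
    clade_nodes: list[tuple[frozenset[str], TreeNode]] = []
    leaf_nodes = {
        nm: TreeNode(name=nm, length=leaf_lengths[nm] / replicates) for nm in names
    }
    root = TreeNode()
    owner: dict[str, TreeNode] = {nm: root for nm in names}

    for members, support, blen in accepted:
        node = TreeNode(support=support, length=blen)
        # parent is the smallest already-placed clade strictly containing members
        parent = root
        for other_members, other_node in clade_nodes:
            if members < other_members:
                parent = other_node  # clade_nodes sorted big->small: keep last hit
        parent.children.append(node)
        clade_nodes.append((members, node))
        for nm in members:
            owner[nm] = node

    for nm in names:
        owner[nm].children.append(leaf_nodes[nm])
    return PhyloTree(root=root)


# ---------------------------------------------------------------------------
# Clade assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CladeAssignment:
    query_id: str
    label: str  # clade label or "unassigned"
    support: float | None
    nearest_reference: str | None
    nearest_distance: float | None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.label == "unassigned" and self.support is not None:
            raise ValueError("unassigned queries cannot carry support")


def assign_clade(
    tree: PhyloTree,
    query_id: str,
    reference_labels: Mapping[str, str],
    *,
    tie_tolerance: float = 1e-9,
) -> CladeAssignment:
    """Assign a query leaf to the label of its smallest uniform reference clade.

    The call is the shared label of the references in the smallest clade (side
    of an internal edge of the support-filtered tree) that contains the query
    plus at least two references all carrying one label.  If no such clade
    exists the nearest labelled reference by patristic distance decides,
    flagged low-confidence; a distance tie between differently-labelled
    references yields ``unassigned``.
    """
    leaf_names = set(tree.leaf_names())
    if query_id not in leaf_names:
        raise KeyError(f"query {query_id!r} is not a leaf of the tree")
    refs = {r for r in reference_labels if r in leaf_names}

    # patristic fallback data (also reported as evidence on clade hits)
    dists = tree.patristic_distances(query_id)
    ref_dists = sorted(
        ((dists[r], r) for r in refs), key=lambda t: (t[0], t[1])
    )
    nearest_ref = ref_dists[0][1] if ref_dists else None
    nearest_dist = ref_dists[0][0] if ref_dists else None

    candidates: list[tuple[int, str, float | None]] = []  # (size, label, support)
    for side, support in tree.clades():
        if query_id not in side:
            continue
        side_refs = side & refs
        if len(side_refs) < 2:
            continue
        labels = {reference_labels[r] for r in side_refs}
        if len(labels) != 1:
            continue
        candidates.append((len(side), labels.pop(), support))
    if candidates:
        min_size = min(size for size, _, _ in candidates)
        minimal = [c for c in candidates if c[0] == min_size]
        labels = {label for _, label, _ in minimal}
        if len(labels) > 1:
            # symmetric conflict: equally small clades support different labels
            return CladeAssignment(query_id, "unassigned", None, None, None)
        best = max(minimal, key=lambda c: (c[2] if c[2] is not None else -1.0))
        return CladeAssignment(
            query_id=query_id,
            label=best[1],
            support=best[2],
            nearest_reference=nearest_ref,
            nearest_distance=nearest_dist,
        )

    if not ref_dists:
        return CladeAssignment(query_id, "unassigned", None, None, None)
    if len(ref_dists) > 1:
        d0, r0 = ref_dists[0]
        tied_labels = {
            reference_labels[r] for d, r in ref_dists if d - d0 <= tie_tolerance
        }
        if len(tied_labels) > 1:
            return CladeAssignment(query_id, "unassigned", None, None, None)
    return CladeAssignment(
        query_id=query_id,
        label=reference_labels[nearest_ref],
        support=None,
        nearest_reference=nearest_ref,
        nearest_distance=nearest_dist,
        low_confidence=True,
    )


# ---------------------------------------------------------------------------
# ITS diagnostic triplet
# ---------------------------------------------------------------------------


def triplet_call_from_bases(bases: Mapping[int, str], triplet: ITSTriplet) -> tuple[str, bool]:
    """(pattern key or 'undetermined', partial flag) from observed bases.

    All three positions matching one pattern gives a clean call; two of three
    gives the majority pattern flagged partial; anything else is undetermined.
    Ambiguity codes containing the pattern base count as matches.
    """
    keys = list(triplet.patterns)
    scores = {}
    for key in keys:
        pattern = triplet.patterns[key]
        scores[key] = sum(
            1
            for pos in triplet.positions
            if pattern[pos] in IUPAC_CODES.get(bases.get(pos, "?"), set())
        )
    ranked = sorted(keys, key=lambda k: -scores[k])
    top = ranked[0]
    if scores[top] == 3:
        return top, False
    if scores[top] == 2 and scores[ranked[1]] <= 1:
        return top, True
    return "undetermined", False


def triplet_call(
    record: SeqRecord,
    triplet: ITSTriplet,
    reference: SeqRecord,
    *,
    min_identity: float = 0.70,
) -> tuple[str, bool]:
    """Align the query to the ITS reference and evaluate the triplet."""
    from . import seqio as _seqio

    cmap = _seqio.align_to_reference(record, reference, min_identity=min_identity)
    bases = {
        pos: _seqio.base_at(cmap, record, pos) for pos in triplet.positions
    }
    return triplet_call_from_bases(bases, triplet)
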