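"""Mitogenome distances, neighbour-joining trees and bootstrap support.

Distances: uncorrected p (pairwise deletion of gaps/N) and the Tamura-Nei
1993 correction, which models the two transition classes (A<->G, C<->T)
separately from transversions with empirical base frequencies taken from
the sequence pair.  Trees: Saitou-Nei neighbour joining with deterministic
tie-breaking (lowest taxon index pair), negative branch lengths clamped to
zero, optional rooting on an outgroup.  Bootstrap support resamples
alignment columns with replacement and reports, for each internal edge of
the point-estimate tree, the percentage of replicate trees containing the
same bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "p_distance",
    "tn93_distance",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
]

_BASES = "ACGT"
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _comparable(a: str, b: str) -> list[tuple[str, str]]:
    return [(x, y) for x, y in zip(a, b) if x in _BASES and y in _BASES]


def p_distance(seq_a: str, seq_b: str) -> float:
    """Mismatch proportion over sites where both sequences have a base."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    pairs = _comparable(seq_a, seq_b)
    if not pairs:
        return np.nan
    mism = sum(1 for x, y in pairs if x != y)
    return mism / len(pairs)


def tn93_distance(seq_a: str, seq_b: str) -> float:
    """Tamura-Nei (1993) distance with base frequencies from the pair.

    Returns ``inf`` (saturation) when any logarithm argument is
    non-positive.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    pairs = _comparable(seq_a, seq_b)
    n = len(pairs)
    if n == 0:
        return np.nan
    counts = {b: 0.0 for b in _BASES}
    p1 = p2 = q = 0
    for x, y in pairs:
        counts[x] += 0.5
        counts[y] += 0.5
        if x != y:
            s = {x, y}
            if s == _PURINES:
                p1 += 1
            elif s == _PYRIMIDINES:
                p2 += 1
            else:
                q += 1
    g = {b: counts[b] / n for b in _BASES}
    gr = g["A"] + g["G"]
    gy = g["C"] + g["T"]
    p1, p2, q = p1 / n, p2 / n, q / n
    if p1 == 0 and p2 == 0 and q == 0:
        return 0.0
    terms = 0.0
    k_ag = g["A"] * g["G"]
    k_ct = g["C"] * g["T"]
    if p1 > 0 or (k_ag > 0 and q > 0):
        w1 = 1.0 - gr * p1 / (2.0 * k_ag) - q / (2.0 * gr) if k_ag > 0 else None
        if w1 is not None:
            if w1 <= 0:
                return np.inf
            terms += -(2.0 * k_ag / gr) * np.log(w1)
    if p2 > 0 or (k_ct > 0 and q > 0):
        w2 = 1.0 - gy * p2 / (2.0 * k_ct) - q / (2.0 * gy) if k_ct > 0 else None
        if w2 is not None:
            if w2 <= 0:
                return np.inf
            terms += -(2.0 * k_ct / gy) * np.log(w2)
    w3 = 1.0 - q / (2.0 * gr * gy)
    if w3 <= 0:
        return np.inf
    terms += -2.0 * (gr * gy - k_ag * gy / gr - k_ct * gr / gy) * np.log(w3)
    return float(terms)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray
    model: str  # 'p' or 'TN93'

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("nonzero diagonal")
        finite = np.isfinite(m)
        if not np.allclose(m[finite & finite.T], m.T[finite & finite.T]):
            raise ValueError("matrix not symmetric")
        self.matrix = m


def distance_matrix(seqs: dict[str, str], model: str = "p") -> DistanceMatrix:
    taxa = list(seqs)
    n = len(taxa)
    fn = p_distance if model == "p" else tn93_distance
    if model not in ("p", "TN93"):
        raise ValueError("model must be 'p' or 'TN93'")
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = fn(seqs[taxa[i]], seqs[taxa[j]])
            m[i, j] = m[j, i] = d
    return DistanceMatrix(taxa=taxa, matrix=m, model=model)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c.newick() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}:{self.length:.10g}"


@dataclass
class PhyloTree:
    root: TreeNode
    taxa: list[str]

    def newick(self) -> str:
        inner = ",".join(c.newick() for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> set[frozenset[str]]:
        """Internal-edge bipartitions, each given as the leaf side not
        containing the first taxon (a canonical orientation)."""
        ref = self.taxa[0]
        all_taxa = frozenset(self.taxa)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(self.taxa) - 1:
                side = below if ref not in below else all_taxa - below
                out.add(side)
            return below

        walk(self.root)
        return out


def nj_tree(dist: DistanceMatrix, outgroup: str | None = None) -> PhyloTree:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lowest (i, j) taxon-index
    pair; negative branch lengths are clamped to 0.  With an outgroup the
    tree is rooted on the outgroup's edge (split at its midpoint).
    """
    n = len(dist.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.all(np.isfinite(dist.matrix)):
        raise ValueError("non-finite distances")
    if outgroup is not None and outgroup not in dist.taxa:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")
    d = dist.matrix.copy()
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dist.taxa]
    active = list(range(n))
    D = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    next_id = n
    node_of = {i: nodes[i] for i in range(n)}

    def get(i: int, j: int) -> float:
        return 0.0 if i == j else D[(min(i, j), max(i, j))]

    while len(active) > 2:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                qv = (m - 2) * get(i, j) - r[i] - r[j]
                if qv < best_q - 1e-12:
                    best_q = qv
                    best = (i, j)
        i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        node_of[i].length = li
        node_of[j].length = lj
        new = TreeNode(children=[node_of[i], node_of[j]])
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (get(i, k) + get(j, k) - dij)
            D[(min(k, next_id), max(k, next_id))] = max(dk, 0.0)
        node_of[next_id] = new
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    # final join: connect the last two nodes by an edge of length d(i, j);
    # the unrooted tree is represented with the internal one as a
    # trifurcating nominal root
    i, j = active
    dij = get(i, j)
    a, b = node_of[i], node_of[j]
    if not a.is_leaf:
        root, other = a, b
    else:
        root, other = b, a
    other.length = max(dij, 0.0)
    root.length = 0.0
    root.children.append(other)
    tree = PhyloTree(root=root, taxa=list(dist.taxa))
    if outgroup is not None:
        tree = _root_on_outgroup(tree, outgroup)
    return tree


def _root_on_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Reroot on the outgroup's edge, split at its midpoint.

    The rooted tree is rebuilt from the unrooted adjacency, so the result is
    independent of where the nominal NJ root happened to sit.
    """
    adj: dict[int, list[tuple[int, float]]] = {}
    nodes: dict[int, TreeNode] = {}

    def collect(n: TreeNode) -> None:
        nodes[id(n)] = n
        adj.setdefault(id(n), [])
        for c in n.children:
            adj[id(n)].append((id(c), c.length))
            adj.setdefault(id(c), []).append((id(n), c.length))
            collect(c)

    collect(tree.root)
    og = next(
        (n for n in nodes.values() if n.is_leaf and n.name == outgroup), None
    )
    if og is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    (parent_id, edge_len), = adj[id(og)]

    def build(nid: int, from_id: int, length: float) -> TreeNode:
        src = nodes[nid]
        out = TreeNode(name=src.name if src.is_leaf else None, length=max(length, 0.0))
        for wid, wlen in adj[nid]:
            if wid != from_id:
                out.children.append(build(wid, nid, wlen))
        return out

    half = edge_len / 2.0
    root = TreeNode(
        children=[build(id(og), parent_id, half), build(parent_id, id(og), half)]
    )
    return PhyloTree(root=root, taxa=list(tree.taxa))


def bootstrap_support(
    seqs: dict[str, str],
    n_reps: int = 1000,
    model: str = "TN93",
    seed: int | None = None,
    outgroup: str | None = None,
) -> PhyloTree:
    """NJ tree with bootstrap support (%) on internal edges.

    Columns are resampled with replacement; support for each internal
    bipartition of the point-estimate tree is the percentage of replicate
    trees containing it.  Fixed seed -> identical supports across runs.
    """
    rng = np.random.default_rng(seed)
    point = nj_tree(distance_matrix(seqs, model=model), outgroup=outgroup)
    target_bips = point.bipartitions()
    counts = {b: 0 for b in target_bips}
    taxa = list(seqs)
    arr = np.array([list(seqs[t]) for t in taxa])
    length = arr.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, length, length)
        res = {t: "".join(arr[k, cols]) for k, t in enumerate(taxa)}
        try:
            rep = nj_tree(distance_matrix(res, model=model))
        except ValueError:
            continue  # saturated replicate distances
        bips = rep.bipartitions()
        for b in target_bips:
            if b in bips:
                counts[b] += 1

    def annotate(node: TreeNode, tree: PhyloTree) -> None:
        ref = tree.taxa[0]
        all_taxa = frozenset(tree.taxa)
        for c in node.children:
            if not c.is_leaf:
                below = frozenset(c.leaves())
                side = below if ref not in below else all_taxa - below
                if side in counts:
                    c.support = 100.0 * counts[side] / n_reps
                annotate(c, tree)

    annotate(point.root, point)
    return point
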