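"""Maximum-likelihood allele trees under the HKY85 substitution model.

The HKY85 model has unequal stationary base frequencies and a
transition/transversion rate ratio kappa; the rate matrix is normalized so
branch lengths are expected substitutions per site.  Likelihoods use
Felsenstein pruning over site patterns with analytic transition
probabilities; tree search starts from a neighbor-joining tree on pairwise
ML distances and hill-climbs with nearest-neighbor interchanges (NNI) and
per-branch Brent optimization (exhaustive topology search for small taxon
sets).  Columns containing gaps or missing data are eliminated before any
likelihood computation.  Nonparametric bootstrap supports are percentages
of column-resampled replicate trees containing each bipartition; trees are
rooted by a user-designated (monophyletic) outgroup.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from ._msa import AlignedRow, project_rows
from .io_formats import ValidationError

__all__ = [
    "HkyParams",
    "TreeNode",
    "PhyloTree",
    "MultipleAlignment",
    "build_alignment",
    "strip_gap_columns",
    "estimate_hky_params",
    "hky_transition_matrix",
    "hky_log_likelihood",
    "build_ml_tree",
    "bootstrap_supports",
    "root_with_outgroup",
    "simulate_hky",
]

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class HkyParams:
    freqs: np.ndarray  # piA, piC, piG, piT
    kappa: float

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,) or (self.freqs <= 0).any():
            raise ValidationError("base frequencies must be 4 positive values")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValidationError("base frequencies must sum to 1")
        if self.kappa <= 0:
            raise ValidationError("kappa must be positive")


class TreeNode:
    __slots__ = ("name", "length", "support", "children")

    def __init__(self, name=None, length=None, support=None, children=None):
        self.name = name
        self.length = length
        self.support = support
        self.children = children if children is not None else []

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> set[str]:
        return {l.name for l in self.leaves()}

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def copy(self) -> "TreeNode":
        return TreeNode(
            name=self.name,
            length=self.length,
            support=self.support,
            children=[c.copy() for c in self.children],
        )


@dataclass
class PhyloTree:
    root: TreeNode
    params: HkyParams | None = None
    log_likelihood: float | None = None
    rooted: bool = False

    @property
    def children(self):  # duck-typing for the Newick writer
        return self.root.children

    def leaf_names(self) -> set[str]:
        return self.root.leaf_names()


@dataclass
class MultipleAlignment:
    names: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise ValidationError("names and rows differ in number")
        if len({len(r) for r in self.rows}) > 1:
            raise ValidationError("alignment rows differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("duplicate taxon names")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0


# ---------------------------------------------------------------------------
# Alignment preparation


def build_alignment(sequences: Mapping[str, str], reference_key: str | None = None) -> MultipleAlignment:
    """Star alignment of near-identical sequences via one reference.

    Every sequence is globally aligned to the reference sequence (the first
    entry by default) and the pairwise alignments are projected into common
    columns.  Adequate for allele sets differing by scattered substitutions
    and short indels.
    """
    from .allele_typing import global_align  # local import avoids a cycle

    items = list(sequences.items())
    if len(items) < 2:
        raise ValidationError("need at least two sequences")
    ref_key = reference_key if reference_key is not None else items[0][0]
    ref = dict(items)[ref_key]
    rows = []
    for name, seq in items:
        if name == ref_key:
            continue
        aln = global_align(seq, ref)
        ops = []
        for qc, sc in zip(aln.query, aln.subject):
            if sc != "-" and qc != "-":
                op = "M"
            elif sc == "-":
                op = "I"
            else:
                op = "D"
            if ops and ops[-1][0] == op:
                ops[-1][1] += 1
            else:
                ops.append([op, 1])
        rows.append(AlignedRow(row_id=name, ref_start=0, ops=[(o, n) for o, n in ops], query=seq))
    proj = project_rows(ref, rows, ref_id=ref_key)
    gapped = proj.gapped_strings()
    order = {name: i for i, (name, _) in enumerate(items)}
    gapped.sort(key=lambda t: order[t[0]])
    return MultipleAlignment(names=[n for n, _ in gapped], rows=[r for _, r in gapped])


def strip_gap_columns(alignment: MultipleAlignment) -> MultipleAlignment:
    """Remove every column containing '-' or 'N' in any row (complete
    deletion of gapped and missing positions)."""
    if alignment.n_cols == 0:
        raise ValidationError("empty alignment")
    mat = np.array([list(r) for r in alignment.rows])
    keep = ~np.any((mat == "-") | (mat == "N"), axis=0)
    if not keep.any():
        raise ValidationError("no columns remain after removing gaps and missing data")
    rows = ["".join(row) for row in mat[:, keep]]
    return MultipleAlignment(names=list(alignment.names), rows=rows)


def _pattern_matrix(alignment: MultipleAlignment) -> tuple[np.ndarray, np.ndarray]:
    mat = np.array(
        [[_BASE_INDEX[c] for c in row] for row in alignment.rows], dtype=np.int8
    )
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return patterns, counts.astype(float)


# ---------------------------------------------------------------------------
# HKY transition probabilities and likelihood


def hky_transition_matrix(params: HkyParams, t: float) -> np.ndarray:
    """Analytic P(t) for HKY85 with the rate matrix normalized to one
    expected substitution per unit branch length."""
    pi = params.freqs
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    kappa = params.kappa
    beta = 0.5 / (piR * piY + kappa * (piA * piG + piC * piT))
    e2 = math.exp(-beta * t)
    eR = math.exp(-t * beta * (piR * kappa + piY))
    eY = math.exp(-t * beta * (piY * kappa + piR))
    P = np.empty((4, 4))
    groups = (piR, piY, piR, piY)  # A C G T
    es = (eR, eY, eR, eY)
    purine = (True, False, True, False)
    for i in range(4):
        for j in range(4):
            pj = pi[j]
            gj = groups[j]
            if purine[i] == purine[j]:
                ej = es[j]
                other = piY if purine[j] else piR
                if i == j:
                    P[i, j] = pj + pj * (other / gj) * e2 + ((gj - pj) / gj) * ej
                else:
                    P[i, j] = pj + pj * (other / gj) * e2 - (pj / gj) * ej
            else:
                P[i, j] = pj * (1.0 - e2)
    return P


def estimate_hky_params(alignment: MultipleAlignment, tree: TreeNode | None = None) -> HkyParams:
    """Empirical base frequencies plus a kappa estimate.

    Frequencies are pooled over all rows (absent bases floored at 1e-6 and
    renormalized).  kappa starts from the pairwise transition/transversion
    count ratio scaled by its kappa=1 expectation; if a tree is supplied,
    kappa is refined by 1-D ML optimization on log kappa.
    """
    counts = np.zeros(4)
    for row in alignment.rows:
        for c in row:
            if c in _BASE_INDEX:
                counts[_BASE_INDEX[c]] += 1
    freqs = np.maximum(counts / max(counts.sum(), 1.0), 1e-6)
    freqs = freqs / freqs.sum()

    mat = np.array([[_BASE_INDEX[c] for c in row] for row in alignment.rows], dtype=np.int8)
    ts = tv = 0
    n = mat.shape[0]
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    for i in range(n):
        for j in range(i + 1, n):
            diff = mat[i] != mat[j]
            for a, b in zip(mat[i][diff], mat[j][diff]):
                if (int(a), int(b)) in transitions:
                    ts += 1
                else:
                    tv += 1
    piA, piC, piG, piT = freqs
    piR, piY = piA + piG, piC + piT
    expected_ratio = (piA * piG + piC * piT) / max(piR * piY, 1e-12)
    if tv == 0:
        kappa = 4.0 if ts else 2.0
    else:
        kappa = max((ts / tv) / max(expected_ratio, 1e-12), 0.05)
    params = HkyParams(freqs=freqs, kappa=float(kappa))
    if tree is not None:
        params = _optimize_kappa(tree, alignment, params)
    return params


def _partials_down(node: TreeNode, patterns: np.ndarray, name_row: dict[str, int],
                   cache: dict[int, np.ndarray], params: HkyParams) -> np.ndarray:
    """Downward (postorder) partial likelihoods, (npat, 4) per node."""
    if node.is_leaf():
        codes = patterns[name_row[node.name]]
        part = np.zeros((patterns.shape[1], 4))
        part[np.arange(len(codes)), codes] = 1.0
        cache[id(node)] = part
        return part
    part = np.ones((patterns.shape[1], 4))
    for child in node.children:
        down = _partials_down(child, patterns, name_row, cache, params)
        P = hky_transition_matrix(params, max(child.length or 0.0, 0.0))
        part = part * (down @ P.T)
    cache[id(node)] = part
    return part


def _log_likelihood_from_patterns(root: TreeNode, patterns, counts, name_row, params) -> float:
    cache: dict[int, np.ndarray] = {}
    part = _partials_down(root, patterns, name_row, cache, params)
    site = part @ params.freqs
    if (site <= 0).any() or not np.isfinite(site).all():
        raise ValidationError("non-finite likelihood")
    return float(np.log(site) @ counts)


def hky_log_likelihood(tree: TreeNode | PhyloTree, alignment: MultipleAlignment,
                       params: HkyParams) -> float:
    """Felsenstein pruning log-likelihood with site-pattern compression."""
    root = tree.root if isinstance(tree, PhyloTree) else tree
    if root.leaf_names() != set(alignment.names):
        raise ValidationError("tree leaves do not match alignment taxa")
    patterns, counts = _pattern_matrix(alignment)
    name_row = {n: i for i, n in enumerate(alignment.names)}
    return _log_likelihood_from_patterns(root, patterns, counts, name_row, params)


# ---------------------------------------------------------------------------
# Branch length and kappa optimization


def _edge_list(root: TreeNode) -> list[tuple[TreeNode, TreeNode]]:
    out = []

    def walk(node):
        for c in node.children:
            out.append((node, c))
            walk(c)

    walk(root)
    return out


def _partials_above(root: TreeNode, down: dict[int, np.ndarray], params: HkyParams) -> dict[int, np.ndarray]:
    """Outside partials: for each node, the likelihood of the rest of the
    tree seen from its parent edge (stationary frequencies included)."""
    above: dict[int, np.ndarray] = {}
    npat = next(iter(down.values())).shape[0]

    def m_vec(child):
        P = hky_transition_matrix(params, max(child.length or 0.0, 0.0))
        return down[id(child)] @ P.T

    def walk(node, node_above):
        mvecs = [m_vec(c) for c in node.children]
        for i, c in enumerate(node.children):
            prod = node_above.copy()
            for j, mv in enumerate(mvecs):
                if j != i:
                    prod = prod * mv
            above[id(c)] = prod
            if not c.is_leaf():
                P = hky_transition_matrix(params, max(c.length or 0.0, 0.0))
                walk(c, above[id(c)] @ P)

    root_above = np.tile(params.freqs, (npat, 1))
    walk(root, root_above)
    return above


def _optimize_branch_lengths(root, patterns, counts, name_row, params,
                             sweeps: int = 2, tol: float = 1e-6) -> float:
    """Coordinate ascent over branch lengths; returns the final log-likelihood."""
    best = _log_likelihood_from_patterns(root, patterns, counts, name_row, params)
    for _ in range(sweeps):
        improved = False
        for parent, child in _edge_list(root):
            cache: dict[int, np.ndarray] = {}
            _partials_down(root, patterns, name_row, cache, params)
            above = _partials_above(root, cache, params)
            A = above[id(child)]
            D = cache[id(child)]

            def neg(t):
                P = hky_transition_matrix(params, t)
                site = np.einsum("pi,ij,pj->p", A, P, D)
                if (site <= 0).any():
                    return 1e12
                return -float(np.log(site) @ counts)

            res = minimize_scalar(neg, bounds=(1e-9, 10.0), method="bounded",
                                  options={"xatol": 1e-7, "maxiter": 60})
            if -res.fun > best + tol:
                child.length = float(res.x)
                best = -res.fun
                improved = True
            elif -res.fun >= best - 1e-9:
                child.length = float(res.x)
                best = max(best, -res.fun)
        if not improved:
            break
    return best


def _optimize_kappa(root, alignment_or_patterns, params, counts=None, name_row=None) -> HkyParams:
    if isinstance(alignment_or_patterns, MultipleAlignment):
        patterns, counts = _pattern_matrix(alignment_or_patterns)
        name_row = {n: i for i, n in enumerate(alignment_or_patterns.names)}
    else:
        patterns = alignment_or_patterns

    def neg(logk):
        p = HkyParams(freqs=params.freqs, kappa=float(math.exp(logk)))
        try:
            return -_log_likelihood_from_patterns(root, patterns, counts, name_row, p)
        except ValidationError:
            return 1e12

    res = minimize_scalar(neg, bounds=(math.log(0.05), math.log(100.0)), method="bounded",
                          options={"xatol": 1e-4, "maxiter": 60})
    return HkyParams(freqs=params.freqs, kappa=float(math.exp(res.x)))


# ---------------------------------------------------------------------------
# Distances, NJ start tree, adjacency utilities


def _pairwise_ml_distance(a: np.ndarray, b: np.ndarray, counts: np.ndarray, params: HkyParams) -> float:
    cat = np.asarray(a) * 4 + np.asarray(b)
    joint = np.bincount(cat, weights=counts, minlength=16).reshape(4, 4)
    if np.trace(joint) == joint.sum():
        return 1e-8

    def neg(t):
        P = hky_transition_matrix(params, t)
        probs = params.freqs[:, None] * P
        return -float((joint * np.log(np.maximum(probs, 1e-300))).sum())

    res = minimize_scalar(neg, bounds=(1e-8, 5.0), method="bounded",
                          options={"xatol": 1e-7, "maxiter": 80})
    return float(res.x)


def _nj_start(patterns, counts, names, params) -> TreeNode:
    from skbio import DistanceMatrix
    from skbio.tree import nj

    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _pairwise_ml_distance(patterns[i], patterns[j], counts, params)
            dm[i, j] = dm[j, i] = d
    sk = nj(DistanceMatrix(dm, list(names)))

    def convert(node) -> TreeNode:
        length = None if node.length is None else max(float(node.length), 1e-9)
        if node.is_tip():
            return TreeNode(name=str(node.name), length=length)
        return TreeNode(length=length, children=[convert(c) for c in node.children])

    root = convert(sk)
    root.length = None
    # collapse a redundant binary root into a trifurcation (unrooted form)
    while len(root.children) == 2 and not all(c.is_leaf() for c in root.children):
        keep = root.children[0] if root.children[0].children else root.children[1]
        other = root.children[1] if keep is root.children[0] else root.children[0]
        other.length = (other.length or 0.0) + (keep.length or 0.0)
        root = TreeNode(children=keep.children + [other])
    return root


def _to_adjacency(root: TreeNode):
    adj: dict[int, dict[int, float]] = {}
    names: dict[int, str] = {}
    supports: dict[frozenset[int], float | None] = {}
    counter = [0]

    def new_id():
        counter[0] += 1
        return counter[0]

    def walk(node, my_id):
        adj.setdefault(my_id, {})
        if node.is_leaf():
            names[my_id] = node.name
        for c in node.children:
            cid = new_id()
            length = max(float(c.length or 0.0), 0.0)
            adj[my_id][cid] = length
            adj.setdefault(cid, {})[my_id] = length
            supports[frozenset((my_id, cid))] = c.support
            walk(c, cid)

    walk(root, new_id())
    return adj, names, supports


def _from_adjacency(adj, names, supports=None, root_id=None) -> TreeNode:
    if root_id is None:
        root_id = next((nid for nid in adj if len(adj[nid]) >= 3), next(iter(adj)))

    def build(nid, parent):
        node = TreeNode(name=names.get(nid))
        for other, length in adj[nid].items():
            if other == parent:
                continue
            child = build(other, nid)
            child.length = length
            if supports is not None:
                child.support = supports.get(frozenset((nid, other)))
            node.children.append(child)
        return node

    root = build(root_id, None)
    return root


def _nni_neighbors(root: TreeNode):
    """Yield NNI rearrangements of the unrooted tree (as new TreeNodes)."""
    adj, names, _ = _to_adjacency(root)
    internal_edges = [
        (u, v)
        for u in adj
        for v in adj[u]
        if u < v and len(adj[u]) >= 3 and len(adj[v]) >= 3
    ]
    for u, v in internal_edges:
        nu = [x for x in adj[u] if x != v]
        nv = [x for x in adj[v] if x != u]
        a = nu[0]
        for c in nv:
            adj2 = {k: dict(d) for k, d in adj.items()}
            # swap subtree a (attached to u) with subtree c (attached to v)
            la = adj2[u].pop(a)
            adj2[a].pop(u)
            lc = adj2[v].pop(c)
            adj2[c].pop(v)
            adj2[u][c] = lc
            adj2[c][u] = lc
            adj2[v][a] = la
            adj2[a][v] = la
            yield _from_adjacency(adj2, names)


# ---------------------------------------------------------------------------
# Tree search


def _all_topologies(names: Sequence[str]):
    """Every unrooted binary topology by sequential leaf insertion."""
    if len(names) < 3:
        raise ValidationError("need at least 3 taxa")
    base = TreeNode(children=[TreeNode(name=n, length=0.05) for n in names[:3]])
    stack = [base]
    for name in names[3:]:
        new_stack = []
        for tree in stack:
            adj, nm, _ = _to_adjacency(tree)
            edges = [(u, v) for u in adj for v in adj[u] if u < v]
            for u, v in edges:
                adj2 = {k: dict(d) for k, d in adj.items()}
                nm2 = dict(nm)
                mid = max(adj2) + 1
                leaf = mid + 1
                length = adj2[u].pop(v)
                adj2[v].pop(u)
                adj2[mid] = {u: length / 2, v: length / 2, leaf: 0.05}
                adj2[u][mid] = length / 2
                adj2[v][mid] = length / 2
                adj2[leaf] = {mid: 0.05}
                nm2[leaf] = name
                new_stack.append(_from_adjacency(adj2, nm2))
        stack = new_stack
    return stack


def build_ml_tree(
    alignment: MultipleAlignment,
    params: HkyParams | None = None,
    seed: int | None = None,
    exhaustive_max_taxa: int = 5,
    optimize_params: bool = True,
) -> PhyloTree:
    """ML tree search under HKY85.

    Taxon sets up to ``exhaustive_max_taxa`` are solved by scoring every
    unrooted topology; larger sets start from neighbor joining on pairwise
    ML distances and hill-climb with NNI plus per-branch Brent length
    optimization until no rearrangement improves the log-likelihood by more
    than 1e-6.  Deterministic: ties are broken by enumeration order
    (``seed`` is accepted for interface stability).
    """
    if len(alignment.names) < 3:
        raise ValidationError("need at least 3 taxa")
    aln = strip_gap_columns(alignment)
    if params is None:
        params = estimate_hky_params(aln)
    patterns, counts = _pattern_matrix(aln)
    name_row = {n: i for i, n in enumerate(aln.names)}

    def score(tree, sweeps=2):
        return _optimize_branch_lengths(tree, patterns, counts, name_row, params, sweeps=sweeps)

    if len(aln.names) <= exhaustive_max_taxa:
        best_tree, best_ll = None, -math.inf
        for cand in _all_topologies(aln.names):
            ll = score(cand)
            if ll > best_ll + 1e-9:
                best_tree, best_ll = cand, ll
        if optimize_params:
            params = _optimize_kappa(best_tree, patterns, params, counts, name_row)
        best_ll = score(best_tree, sweeps=6)
        return PhyloTree(root=best_tree, params=params, log_likelihood=best_ll)

    tree = _nj_start([patterns[name_row[n]] for n in aln.names], counts, aln.names, params)
    # recompute pattern rows in alignment order for the generic scorer
    ll = score(tree)
    if optimize_params:
        params = _optimize_kappa(tree, patterns, params, counts, name_row)
        ll = score(tree)
    while True:
        best_neighbor, best_ll = None, ll
        for cand in _nni_neighbors(tree):
            cand_ll = score(cand, sweeps=1)
            if cand_ll > best_ll + 1e-6:
                best_neighbor, best_ll = cand, cand_ll
        if best_neighbor is None:
            break
        tree, ll = best_neighbor, best_ll
    ll = score(tree, sweeps=6)
    return PhyloTree(root=tree, params=params, log_likelihood=ll)


# ---------------------------------------------------------------------------
# Bootstrap and rooting


def _bipartitions(root: TreeNode, all_leaves: frozenset[str]) -> dict[frozenset[str], TreeNode]:
    out: dict[frozenset[str], TreeNode] = {}

    def canon(side: frozenset[str]) -> frozenset[str]:
        comp = all_leaves - side
        return side if (len(side), tuple(sorted(side))) <= (len(comp), tuple(sorted(comp))) else comp

    def walk(node):
        for c in node.children:
            below = frozenset(c.leaf_names())
            if c.children and 1 < len(below) < len(all_leaves) - 1:
                out[canon(below)] = c
            walk(c)

    walk(root)
    return out


def bootstrap_supports(
    alignment: MultipleAlignment,
    params: HkyParams | None = None,
    n_replicates: int = 500,
    seed: int = 0,
    tree: PhyloTree | None = None,
    exhaustive_max_taxa: int = 5,
) -> PhyloTree:
    """Attach nonparametric bootstrap supports to the ML tree.

    Columns are resampled with replacement; each replicate is re-searched
    with the same protocol; an internal edge's support is the percentage of
    replicate trees containing the same bipartition.  ``n_replicates=0``
    returns the tree without supports.
    """
    aln = strip_gap_columns(alignment)
    if tree is None:
        tree = build_ml_tree(aln, params=params, exhaustive_max_taxa=exhaustive_max_taxa)
    params = tree.params if params is None else params
    if n_replicates == 0:
        return tree
    all_leaves = frozenset(aln.names)
    edges = _bipartitions(tree.root, all_leaves)
    hits = {bp: 0 for bp in edges}
    rng = np.random.default_rng(seed)
    cols = np.array([list(r) for r in aln.rows])
    for _ in range(n_replicates):
        idx = rng.integers(0, aln.n_cols, aln.n_cols)
        rep = MultipleAlignment(names=list(aln.names), rows=["".join(r) for r in cols[:, idx]])
        rep_tree = build_ml_tree(rep, params=params, exhaustive_max_taxa=exhaustive_max_taxa,
                                 optimize_params=False)
        rep_bps = _bipartitions(rep_tree.root, all_leaves)
        for bp in hits:
            if bp in rep_bps:
                hits[bp] += 1
    for bp, node in edges.items():
        node.support = round(100.0 * hits[bp] / n_replicates)
    return tree


def root_with_outgroup(tree: PhyloTree | TreeNode, outgroup_taxa: Sequence[str]) -> PhyloTree:
    """Root on the edge separating a monophyletic outgroup from the ingroup.

    The root splits that edge at its midpoint; bootstrap supports are
    carried over onto the corresponding edges of the rooted tree.
    """
    root = tree.root if isinstance(tree, PhyloTree) else tree
    params = tree.params if isinstance(tree, PhyloTree) else None
    og = frozenset(outgroup_taxa)
    all_leaves = frozenset(root.leaf_names())
    if not og or not og <= all_leaves:
        raise ValidationError("outgroup taxa missing from the tree")
    if og == all_leaves:
        raise ValidationError("outgroup cannot contain every taxon")

    adj, names, supports = _to_adjacency(root)
    leaf_ids = {nid for nid in adj if nid in names}

    def side_leaves(u, v) -> frozenset[str]:
        seen = set()

        def walk(x, parent):
            if x in names:
                seen.add(names[x])
            for other in adj[x]:
                if other != parent:
                    walk(other, x)

        walk(v, u)
        return frozenset(seen)

    target = None
    closest = all_leaves
    for u in adj:
        for v in adj[u]:
            if u < v:
                for a, b in ((u, v), (v, u)):
                    below = side_leaves(a, b)
                    if below == og:
                        target = (a, b)
                    if og < below < closest:
                        closest = below
    if target is None:
        raise ValidationError(
            f"outgroup {sorted(og)} is not monophyletic; smallest containing clade is {sorted(closest)}"
        )
    u, v = target  # v side is the outgroup
    length = adj[u][v]
    sup = supports.get(frozenset((u, v)))
    mid = max(adj) + 1
    adj[u].pop(v)
    adj[v].pop(u)
    adj[mid] = {u: length / 2, v: length / 2}
    adj[u][mid] = length / 2
    adj[v][mid] = length / 2
    supports[frozenset((mid, u))] = sup
    supports[frozenset((mid, v))] = sup
    new_root = _from_adjacency(adj, names, supports, root_id=mid)
    return PhyloTree(root=new_root, params=params, rooted=True)


# ---------------------------------------------------------------------------
# Sequence simulation (model-based; used for parameter-recovery checks)


def simulate_hky(
    tree: TreeNode | PhyloTree,
    n_sites: int,
    params: HkyParams,
    rng: np.random.Generator | None = None,
) -> MultipleAlignment:
    """Simulate an alignment by evolving sites along the tree under HKY85."""
    rng = rng or np.random.default_rng(0)
    root = tree.root if isinstance(tree, PhyloTree) else tree
    states = {id(root): rng.choice(4, size=n_sites, p=params.freqs)}
    rows: dict[str, np.ndarray] = {}

    def walk(node):
        parent_state = states[id(node)]
        for c in node.children:
            P = hky_transition_matrix(params, max(c.length or 0.0, 0.0))
            cum = P.cumsum(axis=1)
            u = rng.random(n_sites)
            child_state = (u[:, None] > cum[parent_state]).sum(axis=1)
            states[id(c)] = child_state
            if c.is_leaf():
                rows[c.name] = child_state
            else:
                walk(c)

    walk(root)
    if root.is_leaf():
        rows[root.name] = states[id(root)]
    lookup = np.array(list("ACGT"))
    names = [l.name for l in root.leaves()]
    return MultipleAlignment(
        names=names, rows=["".join(lookup[rows[n]]) for n in names]
    )
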