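"""Distances, neighbor joining, pruning likelihood, NNI search, bootstrap
support and reference-anchored clade labelling.

Nucleotide distances implement the Kimura 2-parameter model (transitions P
and transversions Q corrected separately) and the Tamura 3-parameter model
(K2P with a G+C-content correction h = 2*theta*(1-theta)).  Trees are
dendropy objects throughout: neighbor joining builds them from distance
matrices, a Felsenstein pruning engine scores them under K2P- or
Tamura-style rate matrices with a discrete-gamma plus invariant-sites rate
mixture, and nearest-neighbour-interchange hill climbing refines the NJ
topology.  Bootstrap support resamples alignment columns and counts
recurring bipartitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, FrozenSet, List, Optional, Tuple

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.optimize import minimize_scalar

from .align import GAP, Alignment

TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class SaturationWarning(UserWarning):
    """A pairwise distance was undefined (substitution saturation)."""


@dataclass
class DistanceModelParams:
    """Parameters of the substitution models.

    ``theta`` is the G+C content used by the Tamura 3-parameter model,
    ``kappa`` the transition/transversion rate ratio of the likelihood
    engine, ``alpha`` the discrete-gamma shape and ``p_inv`` the proportion
    of invariant sites.
    """

    model: str = "k2p"  # 'k2p' or 't92'
    theta: float = 0.5
    kappa: float = 2.0
    alpha: float = 1.0
    p_inv: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must lie in [0, 1)")
        if self.model not in ("k2p", "t92"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class DistanceMatrix:
    labels: List[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(self.d)[np.isfinite(np.diag(self.d))], 0.0):
            raise ValueError("diagonal must be zero")

    @property
    def finite(self) -> bool:
        return bool(np.isfinite(self.d).all())


# ---------------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------------

def count_PQ(a: str, b: str) -> Tuple[float, float, int]:
    """Observed transition (P) and transversion (Q) proportions.

    Columns with a gap or N in either row are skipped; raises if no
    comparable columns remain.
    """
    if len(a) != len(b):
        raise ValueError("rows must have equal length")
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in (GAP, "N") or y in (GAP, "N"):
            continue
        n += 1
        if x != y:
            if frozenset((x, y)) in TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable columns")
    return ts / n, tv / n, n


def k2p_distance(a: str, b: str) -> float:
    """Kimura 2-parameter distance; NaN when saturated."""
    P, Q, _ = count_PQ(a, b)
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return math.nan
    return -0.5 * math.log(arg1 * math.sqrt(arg2))


def _pair_gc(a: str, b: str) -> float:
    bases = [c for c in (a + b).upper() if c in _BASES]
    if not bases:
        return 0.5
    return sum(c in "GC" for c in bases) / len(bases)


def tamura3_distance(a: str, b: str, theta: Optional[float] = None) -> float:
    """Tamura 3-parameter distance with G+C correction h = 2*theta*(1-theta).

    ``theta`` defaults to the mean G+C content of the two sequences; NaN on
    saturation.
    """
    P, Q, _ = count_PQ(a, b)
    if theta is None:
        theta = _pair_gc(a, b)
    h = 2.0 * theta * (1.0 - theta)
    arg1 = 1.0 - P / h - Q if h > 0 else 0.0
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return math.nan
    return -h * math.log(arg1) - 0.5 * (1.0 - h) * math.log(arg2)


def distance_matrix(al: Alignment, model: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix from a gapped nucleotide alignment."""
    fn = {"k2p": k2p_distance, "t92": tamura3_distance}[model]
    labels = al.ids
    n = len(labels)
    d = np.zeros((n, n))
    rows = [seq for _, seq in al.rows]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(rows[i], rows[j])
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Standard NJ agglomeration; deterministic tie-breaking.

    Saturated (non-finite) pairs are rejected; the caller is expected to
    drop the offending taxa first.  Returns an unrooted dendropy tree with
    branch lengths clamped at zero.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    if not D.finite:
        bad = [
            (D.labels[i], D.labels[j])
            for i in range(n)
            for j in range(i + 1, n)
            if not math.isfinite(D.d[i, j])
        ]
        raise ValueError(f"non-finite (saturated) distances for pairs: {bad}")

    taxa = dendropy.TaxonNamespace(D.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = False

    nodes: Dict[str, dendropy.Node] = {}
    for label in D.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes[label] = node
    # representative label of each active cluster = min leaf label under it
    active: List[str] = sorted(D.labels)
    dist: Dict[FrozenSet[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((D.labels[i], D.labels[j]))] = float(D.d[i, j])

    def d(x: str, y: str) -> float:
        return dist[frozenset((x, y))]

    while len(active) > 3:
        m = len(active)
        r = {x: sum(d(x, y) for y in active if y != x) for x in active}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                x, y = active[i], active[j]
                q = (m - 2) * d(x, y) - r[x] - r[y]
                key = (q, x, y)  # lexicographic label-pair tie-break
                if best is None or key < best:
                    best = key
        _, x, y = best
        dxy = d(x, y)
        lx = 0.5 * dxy + (r[x] - r[y]) / (2.0 * (m - 2))
        ly = dxy - lx
        parent = dendropy.Node()
        nodes[x].edge.length = max(0.0, lx)
        nodes[y].edge.length = max(0.0, ly)
        parent.add_child(nodes[x])
        parent.add_child(nodes[y])
        rep = min(x, y)
        for z in active:
            if z in (x, y):
                continue
            dist[frozenset((rep, z))] = 0.5 * (d(x, z) + d(y, z) - dxy)
        active = sorted(set(active) - {x, y} | {rep})
        nodes[rep] = parent

    x, y, z = active
    lx = 0.5 * (d(x, y) + d(x, z) - d(y, z))
    ly = 0.5 * (d(x, y) + d(y, z) - d(x, z))
    lz = 0.5 * (d(x, z) + d(y, z) - d(x, y))
    center = tree.seed_node
    for label, length in ((x, lx), (y, ly), (z, lz)):
        nodes[label].edge.length = max(0.0, length)
        center.add_child(nodes[label])
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------

def stationary_freqs(m: DistanceModelParams) -> np.ndarray:
    """Stationary base frequencies in A,C,G,T order."""
    if m.model == "k2p":
        return np.full(4, 0.25)
    t = m.theta
    return np.array([(1 - t) / 2, t / 2, t / 2, (1 - t) / 2])


def rate_matrix(m: DistanceModelParams) -> np.ndarray:
    """Mean-rate-1 instantaneous rate matrix (A,C,G,T order)."""
    pi = stationary_freqs(m)
    Q = np.zeros((4, 4))
    for i, x in enumerate(_BASES):
        for j, y in enumerate(_BASES):
            if i == j:
                continue
            rate = m.kappa if frozenset((x, y)) in TRANSITIONS else 1.0
            Q[i, j] = rate * pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    return Q / scale


def transition_matrix(m: DistanceModelParams, t: float) -> np.ndarray:
    """P(t) = exp(Q t) for branch length t (expected substitutions/site).

    The K2P case uses its closed form; the Tamura case exponentiates the
    rate matrix numerically.
    """
    if t <= 0:
        return np.eye(4)
    if m.model == "k2p":
        # per-base total rate beta*(kappa+2) = 1  =>  beta = 1/(kappa+2)
        beta = 1.0 / (m.kappa + 2.0)
        e4 = math.exp(-4.0 * beta * t)
        e2 = math.exp(-2.0 * (m.kappa + 1.0) * beta * t)
        same = 0.25 + 0.25 * e4 + 0.5 * e2
        ts = 0.25 + 0.25 * e4 - 0.5 * e2
        tv = 0.25 - 0.25 * e4
        P = np.full((4, 4), tv)
        np.fill_diagonal(P, same)
        for x, y in (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")):
            P[_BASE_INDEX[x], _BASE_INDEX[y]] = ts
        return P
    return expm(rate_matrix(m) * t)


def gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability discrete-gamma categories,
    normalised to overall mean 1."""
    if ncat == 1:
        return np.ones(1)
    from scipy.stats import gamma as _gamma

    bounds = _gamma.ppf(np.linspace(0, 1, ncat + 1), a=alpha, scale=1.0 / alpha)
    # mean within each bin via the regularised incomplete gamma recurrence
    upper = gammainc(alpha + 1, bounds[1:] * alpha)
    lower = gammainc(alpha + 1, bounds[:-1] * alpha)
    rates = ncat * (upper - lower)
    return rates / rates.mean() * 1.0


def mixture_rates(m: DistanceModelParams, ncat: int) -> Tuple[np.ndarray, np.ndarray]:
    """(rates, weights) of the invariant + discrete-gamma mixture.

    Variable-class rates are scaled by 1/(1-p_inv) so the overall mean rate
    stays 1.
    """
    g = gamma_rates(m.alpha, ncat)
    if m.p_inv == 0.0:
        return g, np.full(ncat, 1.0 / ncat)
    rates = np.concatenate([[0.0], g / (1.0 - m.p_inv)])
    weights = np.concatenate(
        [[m.p_inv], np.full(ncat, (1.0 - m.p_inv) / ncat)]
    )
    return rates, weights


def _leaf_partial(symbol: str) -> np.ndarray:
    if symbol in _BASE_INDEX:
        v = np.zeros(4)
        v[_BASE_INDEX[symbol]] = 1.0
        return v
    return np.ones(4)  # gap or N: missing data


def tree_log_likelihood(
    tree: dendropy.Tree,
    al: Alignment,
    m: DistanceModelParams,
    ncat: int = 4,
) -> float:
    """Felsenstein pruning log-likelihood over alignment sites.

    The rate mixture is ``p_inv`` invariant sites plus ``ncat``
    mean-normalised discrete-gamma categories.
    """
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    rows = dict(al.rows)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in rows]
    if missing:
        raise ValueError(f"leaves without alignment rows: {missing}")

    cols = np.array(
        [[rows[label][j] for label in leaves] for j in range(al.ncol)]
    )
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    npat = len(patterns)
    leaf_partials = {
        label: np.array(
            [_leaf_partial(patterns[p][k]) for p in range(npat)]
        )
        for k, label in enumerate(leaves)
    }

    pi = stationary_freqs(m)
    rates, weights = mixture_rates(m, ncat)
    site_like = np.zeros(npat)
    for rate, weight in zip(rates, weights):
        pmats = {}

        def partial(node) -> np.ndarray:
            if node.is_leaf():
                return leaf_partials[node.taxon.label]
            out = np.ones((npat, 4))
            for child in node.child_nodes():
                t = (child.edge.length or 0.0) * rate
                key = round(t, 12)
                if key not in pmats:
                    pmats[key] = transition_matrix(m, t)
                out *= partial(child) @ pmats[key].T
            return out

        root_partial = partial(tree.seed_node)
        site_like += weight * (root_partial @ pi)
    return float(counts @ np.log(site_like))


def optimize_branch_lengths(
    tree: dendropy.Tree,
    al: Alignment,
    m: DistanceModelParams,
    ncat: int = 4,
    rounds: int = 1,
    max_len: float = 10.0,
) -> float:
    """Coordinate-descent branch-length optimisation; returns final logL."""
    edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
    best = tree_log_likelihood(tree, al, m, ncat)
    for _ in range(rounds):
        for edge in edges:
            def neg(t: float, _edge=edge) -> float:
                _edge.length = t
                return -tree_log_likelihood(tree, al, m, ncat)

            res = minimize_scalar(
                neg, bounds=(0.0, max_len), method="bounded",
                options={"xatol": 1e-3},
            )
            edge.length = float(res.x)
        best = tree_log_likelihood(tree, al, m, ncat)
    return best


def _internal_edge_indices(tree: dendropy.Tree) -> List[int]:
    out = []
    for idx, edge in enumerate(tree.preorder_edge_iter()):
        head = edge.head_node
        if head is tree.seed_node or head.is_leaf():
            continue
        if edge.tail_node is None:
            continue
        out.append(idx)
    return out


def _nni_neighbors(tree: dendropy.Tree) -> List[dendropy.Tree]:
    """All trees one nearest-neighbour interchange away."""
    neighbors = []
    for edge_idx in _internal_edge_indices(tree):
        for child_choice in (0, 1):
            clone = tree.clone(depth=1)
            edges = list(clone.preorder_edge_iter())
            edge = edges[edge_idx]
            v = edge.head_node
            u = edge.tail_node
            siblings = [c for c in u.child_nodes() if c is not v]
            if not siblings or len(v.child_nodes()) < 2:
                continue
            s = siblings[0]
            c = v.child_nodes()[child_choice]
            u.remove_child(s)
            v.remove_child(c)
            u.add_child(c)
            v.add_child(s)
            neighbors.append(clone)
    return neighbors


def nni_search(
    tree: dendropy.Tree,
    al: Alignment,
    m: DistanceModelParams,
    ncat: int = 4,
    max_rounds: int = 10,
    opt_lengths: bool = True,
) -> Tuple[dendropy.Tree, List[float]]:
    """Hill-climbing NNI topology search from a starting tree.

    Applies the best score-improving interchange until none improves or
    ``max_rounds`` is reached.  Returns the tree and the (non-decreasing)
    log-likelihood trace of accepted states.
    """
    current = tree.clone(depth=1)
    if opt_lengths:
        score = optimize_branch_lengths(current, al, m, ncat)
    else:
        score = tree_log_likelihood(current, al, m, ncat)
    trace = [score]
    for _ in range(max_rounds):
        best_tree, best_score = None, score
        for cand in _nni_neighbors(current):
            if opt_lengths:
                cand_score = optimize_branch_lengths(cand, al, m, ncat)
            else:
                cand_score = tree_log_likelihood(cand, al, m, ncat)
            if cand_score > best_score + 1e-9:
                best_tree, best_score = cand, cand_score
        if best_tree is None:
            break
        current, score = best_tree, best_score
        trace.append(score)
    return current, trace


# ---------------------------------------------------------------------------
# Bootstrap and clade assignment
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree) -> Dict[FrozenSet[str], dendropy.Node]:
    """Non-trivial bipartitions as frozensets of the smaller leaf-label side,
    mapped to the subtending node."""
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: Dict[FrozenSet[str], dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_labels - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = min(side, other, key=lambda s: (len(s), sorted(s)))
        out[key] = node
    return out


def nj_builder(model: str = "k2p") -> Callable[[Alignment], dendropy.Tree]:
    """Tree builder (alignment -> NJ tree) for bootstrapping."""

    def build(al: Alignment) -> dendropy.Tree:
        return neighbor_joining(distance_matrix(al, model=model))

    return build


def resample_columns(al: Alignment, rng: np.random.Generator) -> Alignment:
    idx = rng.integers(0, al.ncol, size=al.ncol)
    return Alignment(
        rows=[(rid, "".join(seq[j] for j in idx)) for rid, seq in al.rows]
    )


def bootstrap_support(
    al: Alignment,
    B: int,
    seed: int,
    builder: Optional[Callable[[Alignment], dendropy.Tree]] = None,
) -> dendropy.Tree:
    """Point-estimate tree with bootstrap percentages on internal nodes.

    Columns are resampled with replacement ``B`` times; each replicate tree
    is rebuilt with ``builder`` (NJ on K2P distances by default) and the
    percentage of replicates containing each point-estimate bipartition is
    stored as ``node.support`` (float in [0, 100]) and as the node label.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    builder = builder or nj_builder()
    rng = np.random.default_rng(seed)
    point = builder(al)
    target = _bipartitions(point)
    counts = {key: 0 for key in target}
    for _ in range(B):
        try:
            rep = builder(resample_columns(al, rng))
        except ValueError:
            continue  # saturated replicate: counts unchanged
        rep_bips = _bipartitions(rep)
        for key in counts:
            if key in rep_bips:
                counts[key] += 1
    for key, node in target.items():
        support = 100.0 * counts[key] / B
        node.support = support
        node.label = f"{support:.0f}"
    return point


def format_newick(tree: dendropy.Tree, min_support: Optional[float] = None) -> str:
    """Newick string; supports below ``min_support`` are suppressed
    (the reporting convention for values under 75%)."""
    out = tree.clone(depth=1)
    if min_support is not None:
        for node in out.preorder_node_iter():
            support = getattr(node, "support", None)
            if support is not None and support < min_support:
                node.label = None
    return out.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(text: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=text, schema="newick")
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
    return tree


def assign_clade(
    tree: dendropy.Tree,
    candidate_label: str,
    labelled_refs: Dict[str, str],
    min_support: float = 0.0,
    outgroup: Optional[str] = None,
) -> Optional[str]:
    """Clade label for a candidate leaf, or ``None`` when unassigned.

    The tree is rooted at the outgroup leaf when given, else at its
    midpoint.  The smallest clade containing the candidate and at least one
    labelled reference supplies the label iff all labelled references
    inside agree and the clade's support is at least ``min_support``
    (nodes without recorded support pass only when ``min_support == 0``).
    """
    work = tree.clone(depth=1)
    leaf_labels = {lf.taxon.label for lf in work.leaf_node_iter()}
    if candidate_label not in leaf_labels:
        raise ValueError(f"candidate {candidate_label!r} not in tree")
    if outgroup is not None:
        og = next(
            lf for lf in work.leaf_node_iter() if lf.taxon.label == outgroup
        )
        length = og.edge.length or 0.0
        work.reroot_at_edge(og.edge, length1=length / 2, length2=length / 2,
                            update_bipartitions=False)
    else:
        work.reroot_at_midpoint(update_bipartitions=False)
    node = next(
        lf for lf in work.leaf_node_iter() if lf.taxon.label == candidate_label
    )
    node = node.parent_node
    while node is not None:
        inside = {lf.taxon.label for lf in node.leaf_iter()}
        refs_inside = {labelled_refs[l] for l in inside if l in labelled_refs}
        if refs_inside:
            if len(refs_inside) > 1:
                return None  # conflicting labels in the smallest clade
            support = getattr(node, "support", None)
            if min_support > 0 and (support is None or support < min_support):
                return None
            return next(iter(refs_inside))
        node = node.parent_node
    return None
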