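"""Graphlet catalog and weighted graphlet-interaction census.

A graphlet is a small connected graph pattern; restricted to 2-4 nodes
there are exactly 9 of them (G0..G8) carrying 15 automorphism orbits (node
positions up to symmetry). A *graphlet interaction isomer* is an ordered
pair of positions (source, target) inside one graphlet, counted up to the
automorphisms that fix both positions; swapping source and target yields a
different isomer, and the full catalog has 28 of them.

Given a weighted graph with symmetric edge weights ``a`` in [0, 1], the
number of occurrences of isomer ``k`` from node ``i`` to node ``j`` is a
sum over ordered tuples of distinct auxiliary nodes of a product of
factors ``b``: ``b_st = a_st`` for slot pairs joined in the template and
``b_st = 1 - a_st`` for slot pairs that are not. This is an *induced*
(exact-pattern) weighted count: with binary weights it equals the number
of induced embeddings of the graphlet mapping ``i`` to the source orbit
and ``j`` to the target orbit. Templates symmetric in their two auxiliary
slots carry a symmetry factor of 2 so each unordered auxiliary
configuration is counted once.

Two counting routes are provided: a contraction-based vectorised census
(:func:`count_isomers_weighted`) and a direct enumeration oracle
(:func:`count_isomers_oracle`) used to cross-check it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .exceptions import GimdaError

__all__ = [
    "Graphlet",
    "IsomerTemplate",
    "IsomerCatalog",
    "IsomerCountTensor",
    "build_catalog",
    "count_isomers_weighted",
    "count_isomers_oracle",
    "normalize_counts",
]

ORACLE_MAX_NODES = 15


@dataclass(frozen=True)
class Graphlet:
    """One connected pattern on 2-4 nodes in canonical labelling."""

    index: int
    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    orbit_of_node: tuple[int, ...]  # global orbit id per node

    @property
    def orbit_ids(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.orbit_of_node)))


@dataclass(frozen=True)
class IsomerTemplate:
    """An ordered (source, target) interaction inside one graphlet.

    Slots are numbered 0 (source), 1 (target), then 2 and 3 for auxiliary
    nodes; ``edges`` is the induced edge set of the graphlet over those
    slots. ``symmetry_factor`` is the number of automorphisms of the
    template fixing both source and target (2 when the two auxiliary slots
    are exchangeable, else 1).
    """

    index: int
    graphlet: int
    source_orbit: int
    target_orbit: int
    n_aux: int
    edges: tuple[tuple[int, int], ...]
    symmetry_factor: int


@dataclass
class IsomerCatalog:
    graphlets: list[Graphlet]
    n_orbits: int
    isomers: list[IsomerTemplate]


@dataclass
class IsomerCountTensor:
    """Per-template ordered-pair counts, shape (n_templates, n, n)."""

    counts: np.ndarray
    normalized: np.ndarray | None = None


def _canonical_edges(n: int, edges: frozenset[frozenset[int]]) -> tuple:
    """Lexicographically minimal edge list over all node relabelings."""
    best = None
    for perm in itertools.permutations(range(n)):
        relabeled = tuple(
            sorted(tuple(sorted((perm[a], perm[b]))) for a, b in (tuple(e) for e in edges))
        )
        if best is None or relabeled < best:
            best = relabeled
    return best


def _is_connected(n: int, edges: frozenset[frozenset[int]]) -> bool:
    adj = {v: set() for v in range(n)}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == n


def _automorphisms(n: int, edge_set: set[tuple[int, int]]) -> list[tuple[int, ...]]:
    autos = []
    for perm in itertools.permutations(range(n)):
        mapped = {tuple(sorted((perm[a], perm[b]))) for a, b in edge_set}
        if mapped == edge_set:
            autos.append(perm)
    return autos


def build_catalog() -> IsomerCatalog:
    """Enumerate graphlets on 2-4 nodes, their orbits and the 28 isomers.

    Ordering is deterministic: graphlets by (node count, edge count,
    canonical edge code); orbits by first canonical node; isomers by
    (graphlet, source orbit, target orbit, canonical template code).
    """
    canon_seen: set[tuple] = set()
    raw: list[tuple[int, tuple]] = []
    for n in (2, 3, 4):
        all_pairs = list(itertools.combinations(range(n), 2))
        for r in range(1, len(all_pairs) + 1):
            for chosen in itertools.combinations(all_pairs, r):
                edges = frozenset(frozenset(e) for e in chosen)
                if not _is_connected(n, edges):
                    continue
                canon = _canonical_edges(n, edges)
                if canon in canon_seen:
                    continue
                canon_seen.add(canon)
                raw.append((n, canon))
    raw.sort(key=lambda item: (item[0], len(item[1]), item[1]))

    graphlets: list[Graphlet] = []
    isomers: list[IsomerTemplate] = []
    orbit_counter = 0
    for g_index, (n, edges) in enumerate(raw):
        edge_set = {tuple(sorted(e)) for e in edges}
        autos = _automorphisms(n, edge_set)
        # node orbits under the automorphism group
        orbit_of_node: list[int] = [-1] * n
        for v in range(n):
            if orbit_of_node[v] != -1:
                continue
            members = {perm[v] for perm in autos}
            for w in members:
                orbit_of_node[w] = orbit_counter
            orbit_counter += 1
        graphlets.append(Graphlet(g_index, n, tuple(sorted(edge_set)), tuple(orbit_of_node)))

        # ordered (source, target) pairs up to automorphism
        pair_seen: set[tuple[int, int]] = set()
        templates: list[tuple] = []
        for u, v in itertools.permutations(range(n), 2):
            if (u, v) in pair_seen:
                continue
            orbit_pairs = {(perm[u], perm[v]) for perm in autos}
            pair_seen.update(orbit_pairs)
            # canonical slot labelling: source -> 0, target -> 1, auxiliary
            # nodes ordered to minimise the template edge code
            aux = [w for w in range(n) if w not in (u, v)]
            best_edges = None
            for aux_perm in itertools.permutations(aux):
                slot = {u: 0, v: 1}
                slot.update({w: 2 + k for k, w in enumerate(aux_perm)})
                t_edges = tuple(
                    sorted(tuple(sorted((slot[a], slot[b]))) for a, b in edge_set)
                )
                if best_edges is None or t_edges < best_edges:
                    best_edges = t_edges
            sym = sum(1 for perm in autos if perm[u] == u and perm[v] == v)
            templates.append(
                (
                    orbit_of_node[u],
                    orbit_of_node[v],
                    best_edges,
                    n - 2,
                    sym,
                )
            )
        templates.sort()
        for src_orbit, tgt_orbit, t_edges, n_aux, sym in templates:
            isomers.append(
                IsomerTemplate(
                    index=len(isomers),
                    graphlet=g_index,
                    source_orbit=src_orbit,
                    target_orbit=tgt_orbit,
                    n_aux=n_aux,
                    edges=t_edges,
                    symmetry_factor=sym,
                )
            )
    return IsomerCatalog(graphlets, orbit_counter, isomers)


def _validate_weights(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise GimdaError("weight matrix must be square")
    if np.max(np.abs(w - w.T), initial=0.0) > 1e-9:
        raise GimdaError("weight matrix must be symmetric")
    if np.max(np.abs(np.diag(w)), initial=0.0) > 0:
        raise GimdaError("weight matrix must have zero diagonal (no self-loops)")
    if w.size and (w.min() < 0 or w.max() > 1):
        raise GimdaError("weights must lie in [0, 1]")
    return w


def _slot_matrices(template: IsomerTemplate, a: np.ndarray, c: np.ndarray) -> dict:
    """Map slot pair -> factor matrix (a for template edges, 1-a otherwise)."""
    edge_set = set(template.edges)
    n_slots = 2 + template.n_aux
    out = {}
    for s, t in itertools.combinations(range(n_slots), 2):
        out[(s, t)] = a if (s, t) in edge_set else c
    return out


def count_isomers_weighted(
    weights: np.ndarray, catalog: IsomerCatalog
) -> IsomerCountTensor:
    """Vectorised weighted isomer census over all ordered node pairs.

    Each template is evaluated as a tensor contraction over the full node
    set followed by exact subtraction of the tuples that reuse the source,
    the target, or repeat an auxiliary node; cost is O(n^4) per 2-auxiliary
    template with O(n^2)/O(n^3) memory.
    """
    a = _validate_weights(weights)
    n = a.shape[0]
    c = 1.0 - a
    np.fill_diagonal(c, 1.0)  # diagonal never contributes; fixed for consistency
    counts = np.zeros((len(catalog.isomers), n, n))
    offdiag = ~np.eye(n, dtype=bool)
    for template in catalog.isomers:
        mats = _slot_matrices(template, a, c)
        b01 = mats[(0, 1)]
        if template.n_aux == 0:
            nt = b01.copy()
        elif template.n_aux == 1:
            x, y = mats[(0, 2)], mats[(1, 2)]
            dx, dy = np.diag(x), np.diag(y)
            full = x @ y.T
            full -= dx[:, None] * y.T  # auxiliary node = source
            full -= x * dy[None, :]  # auxiliary node = target
            nt = b01 * full
        else:
            x, y = mats[(0, 2)], mats[(1, 2)]  # (i,l), (j,l)
            p, q = mats[(0, 3)], mats[(1, 3)]  # (i,m), (j,m)
            w = mats[(2, 3)]  # (l,m)
            dx, dy = np.diag(x), np.diag(y)
            dp, dq = np.diag(p), np.diag(q)
            dw = np.diag(w)
            f = np.einsum("il,jl,lm,im,jm->ij", x, y, w, p, q, optimize=True)
            # tuples where the first auxiliary slot hits source/target
            f_li = dx[:, None] * y.T * ((w * p) @ q.T)
            f_lj = (x * dy[None, :]) * (p @ (w * q).T)
            # tuples where the second auxiliary slot hits source/target
            f_mi = dp[:, None] * q.T * ((x * w.T) @ y.T)
            f_mj = (p * dq[None, :]) * (x @ (y * w.T).T)
            # doubly-degenerate tuples added back (inclusion-exclusion)
            f_ii = (dx * dp * dw)[:, None] * (y.T * q.T)
            f_ij = dx[:, None] * y.T * p * dq[None, :] * w
            f_ji = x * dy[None, :] * dp[:, None] * q.T * w.T
            f_jj = x * p * (dy * dq * dw)[None, :]
            restricted = f - f_li - f_lj - f_mi - f_mj + f_ii + f_ij + f_ji + f_jj
            # remove coincident auxiliary nodes (l == m), excluding l in {i, j}
            d0 = ((x * p) * dw[None, :]) @ (y * q).T
            d0 -= (dx * dp * dw)[:, None] * (y * q).T
            d0 -= (x * p) * (dy * dq * dw)[None, :]
            nt = b01 * (restricted - d0) / template.symmetry_factor
        nt = np.where(offdiag, nt, 0.0)
        # exact zeros can come out as tiny negatives after subtraction
        np.clip(nt, 0.0, None, out=nt)
        counts[template.index] = nt
    return IsomerCountTensor(counts)


def count_isomers_oracle(
    weights: np.ndarray, catalog: IsomerCatalog
) -> IsomerCountTensor:
    """Direct enumeration census: loops over every ordered auxiliary tuple.

    Identical contract to :func:`count_isomers_weighted`; intended as an
    independent verification path and guarded to small graphs.
    """
    a = _validate_weights(weights)
    n = a.shape[0]
    if n > ORACLE_MAX_NODES:
        raise GimdaError(
            f"oracle census limited to {ORACLE_MAX_NODES} nodes, got {n}"
        )
    c = 1.0 - a
    np.fill_diagonal(c, 1.0)
    counts = np.zeros((len(catalog.isomers), n, n))
    nodes = range(n)
    for template in catalog.isomers:
        mats = _slot_matrices(template, a, c)
        pairs = sorted(mats)
        for i in nodes:
            for j in nodes:
                if i == j:
                    continue
                total = 0.0
                if template.n_aux == 0:
                    total = mats[(0, 1)][i, j]
                elif template.n_aux == 1:
                    for l in nodes:
                        if l in (i, j):
                            continue
                        slot = (i, j, l)
                        prod = 1.0
                        for s, t in pairs:
                            prod *= mats[(s, t)][slot[s], slot[t]]
                        total += prod
                else:
                    for l, m in itertools.permutations(
                        [v for v in nodes if v not in (i, j)], 2
                    ):
                        slot = (i, j, l, m)
                        prod = 1.0
                        for s, t in pairs:
                            prod *= mats[(s, t)][slot[s], slot[t]]
                        total += prod
                counts[template.index, i, j] = total / template.symmetry_factor
    return IsomerCountTensor(counts)


def normalize_counts(tensor: IsomerCountTensor) -> IsomerCountTensor:
    """Normalise each (template, source) row over targets.

    Every row becomes a distribution over targets (sums to 1) or stays
    all-zero when the source has no occurrences of that template.
    """
    counts = tensor.counts
    denom = counts.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(denom > 0, counts / denom, 0.0)
    tensor.normalized = normalized
    return tensor
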