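"""Disease and miRNA similarity constructions.

Four similarity sources feed the predictor:

1. DAG-based semantic similarity, model 1: each ancestor of a disease
   contributes to the disease's semantic value, attenuated by a decay
   factor ``delta`` per layer of distance; two diseases are similar in
   proportion to the contributions of the shared part of their DAGs.
2. DAG-based semantic similarity, model 2: the contribution of a term is
   instead ``-log`` of the fraction of corpus DAGs containing it, so rare
   (specific) terms weigh more than common ones.
3. Gaussian interaction-profile (GIP) kernel similarity, computed from the
   rows (diseases) or columns (miRNAs) of the binary association matrix.
4. Precomputed miRNA functional similarity, consumed as a matrix.

The integrated disease similarity takes the average of the two semantic
models where both diseases own a DAG and falls back to the GIP kernel
elsewhere; the integrated miRNA similarity does the same with the
functional matrix as the primary source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .exceptions import GimdaError
from .io import DiseaseDAG, SimilarityMatrix

__all__ = [
    "SemanticContribution",
    "semantic_value_1",
    "semantic_similarity_1",
    "semantic_value_2",
    "semantic_similarity_2",
    "semantic_similarity_matrix",
    "gip_kernel",
    "integrate_disease_similarity",
    "integrate_mirna_similarity",
]


@dataclass
class SemanticContribution:
    """Per-node semantic contributions to one disease and their sum."""

    disease: str
    contributions: dict[str, float]
    semantic_value: float


def semantic_value_1(dag: DiseaseDAG, delta: float) -> SemanticContribution:
    """Decay-model semantic contributions of a disease's ancestors.

    The disease itself contributes 1; any other node ``d`` contributes
    ``delta`` times the largest contribution among its children, so a node
    ``k`` layers above the disease contributes ``delta**k`` along its best
    path down.
    """
    if not 0 < delta < 1:
        raise GimdaError("delta must lie strictly between 0 and 1")
    contrib: dict[str, float] = {}
    # Children lie closer to the root disease, so walk nodes in reverse
    # topological order (root disease first).
    import networkx as nx

    order = list(nx.topological_sort(dag.graph))[::-1]
    for node in order:
        if node == dag.root:
            contrib[node] = 1.0
            continue
        kids = dag.children(node)
        if not kids:
            raise GimdaError(
                f"node {node!r} has no path to disease {dag.root!r}"
            )
        contrib[node] = delta * max(contrib[c] for c in kids)
    return SemanticContribution(dag.root, contrib, float(sum(contrib.values())))


def semantic_similarity_1(dag_i: DiseaseDAG, dag_j: DiseaseDAG, delta: float) -> float:
    """Shared-ancestor similarity under the decay contribution model."""
    ci = semantic_value_1(dag_i, delta)
    cj = semantic_value_1(dag_j, delta)
    shared = dag_i.nodes & dag_j.nodes
    num = sum(ci.contributions[t] + cj.contributions[t] for t in shared)
    return num / (ci.semantic_value + cj.semantic_value)


def _corpus_counts(dag_corpus: Mapping[str, DiseaseDAG]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for dag in dag_corpus.values():
        for node in dag.nodes:
            counts[node] = counts.get(node, 0) + 1
    return counts


def semantic_value_2(
    dag: DiseaseDAG, dag_corpus: Mapping[str, DiseaseDAG]
) -> SemanticContribution:
    """Information-content contributions relative to a DAG corpus.

    A node appearing in ``c`` of the ``N`` corpus DAGs contributes
    ``-log(c / N)``; nodes found in every DAG contribute nothing, and the
    contribution grows as the node becomes rarer. ``N`` is the number of
    diseases that own a DAG in the corpus.
    """
    if not dag_corpus:
        raise GimdaError("empty DAG corpus")
    counts = _corpus_counts(dag_corpus)
    n = len(dag_corpus)
    contrib: dict[str, float] = {}
    for node in dag.nodes:
        c = counts.get(node, 0)
        if c == 0:
            raise GimdaError(f"node {node!r} appears in no corpus DAG")
        contrib[node] = -float(np.log(c / n))
    return SemanticContribution(dag.root, contrib, float(sum(contrib.values())))


def semantic_similarity_2(
    dag_i: DiseaseDAG,
    dag_j: DiseaseDAG,
    dag_corpus: Mapping[str, DiseaseDAG],
) -> float:
    ci = semantic_value_2(dag_i, dag_corpus)
    cj = semantic_value_2(dag_j, dag_corpus)
    if dag_i.nodes == dag_j.nodes:
        return 1.0
    denom = ci.semantic_value + cj.semantic_value
    if denom == 0.0:
        # Every node of both DAGs occurs in all corpus DAGs; there is no
        # information to compare on, so distinct diseases get 0.
        return 0.0
    shared = dag_i.nodes & dag_j.nodes
    num = sum(ci.contributions[t] + cj.contributions[t] for t in shared)
    return num / denom


def semantic_similarity_matrix(
    dag_corpus: Mapping[str, DiseaseDAG],
    delta: float,
    model: int,
    ids: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Assemble a full semantic similarity matrix over the corpus diseases.

    ``ids`` fixes the output ordering (default: sorted corpus diseases);
    diseases in ``ids`` without a DAG get zero rows.
    """
    if model not in (1, 2):
        raise GimdaError("model must be 1 or 2")
    corpus_ids = sorted(dag_corpus)
    if model == 1:
        contribs = {d: semantic_value_1(dag_corpus[d], delta) for d in corpus_ids}
    else:
        contribs = {d: semantic_value_2(dag_corpus[d], dag_corpus) for d in corpus_ids}
    k = len(corpus_ids)
    values = np.eye(k)
    for a in range(k):
        ca = contribs[corpus_ids[a]]
        na = dag_corpus[corpus_ids[a]].nodes
        for b in range(a + 1, k):
            cb = contribs[corpus_ids[b]]
            denom = ca.semantic_value + cb.semantic_value
            if model == 2 and na == dag_corpus[corpus_ids[b]].nodes:
                values[a, b] = values[b, a] = 1.0
                continue
            if denom == 0.0:
                continue
            shared = na & dag_corpus[corpus_ids[b]].nodes
            num = sum(ca.contributions[t] + cb.contributions[t] for t in shared)
            values[a, b] = values[b, a] = num / denom
    if values.max(initial=0.0) > 1.0 + 1e-12:
        warnings.warn("semantic similarity above 1 clipped", stacklevel=2)
    values = np.clip(values, 0.0, 1.0)
    kind = "semantic1" if model == 1 else "semantic2"
    sim = SimilarityMatrix(values, corpus_ids, kind)
    if ids is not None:
        sim = sim.reindex(ids)
    return sim


def gip_kernel(
    profiles: np.ndarray,
    gamma_prime: float,
    ids: Sequence[str],
    kind: str = "gip_disease",
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over binary profile rows.

    The bandwidth is ``gamma_prime`` divided by the mean squared profile
    norm, so the kernel scale adapts to the overall density of the
    association matrix.
    """
    if gamma_prime <= 0:
        raise GimdaError("gamma_prime must be positive")
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] == 0:
        raise GimdaError("profiles must be a non-empty 2-D array")
    mean_sq = float(np.mean(np.sum(profiles**2, axis=1)))
    if mean_sq == 0.0:
        raise GimdaError("bandwidth undefined: all interaction profiles are zero")
    gamma = gamma_prime / mean_sq
    if profiles.shape[0] > 1:
        sq = squareform(pdist(profiles, metric="sqeuclidean"))
    else:
        sq = np.zeros((1, 1))
    values = np.exp(-gamma * sq)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, [str(x) for x in ids], kind)


def _integrate(
    primary: SimilarityMatrix,
    fallback: SimilarityMatrix,
    has_primary: np.ndarray,
    kind: str,
) -> SimilarityMatrix:
    if primary.values.shape != fallback.values.shape:
        raise GimdaError("similarity matrices have mismatched shapes")
    if primary.ids != fallback.ids:
        raise GimdaError("similarity matrices have mismatched id order")
    has_primary = np.asarray(has_primary, dtype=bool)
    if has_primary.shape != (len(primary.ids),):
        raise GimdaError("membership flag length does not match ids")
    pair_mask = np.outer(has_primary, has_primary)
    values = np.where(pair_mask, primary.values, fallback.values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, primary.ids, kind)


def integrate_disease_similarity(
    ss1: SimilarityMatrix,
    ss2: SimilarityMatrix,
    kd: SimilarityMatrix,
    has_semantic: np.ndarray,
) -> SimilarityMatrix:
    """Average the two semantic models where both diseases own a DAG, else
    fall back to the GIP kernel."""
    if ss1.values.shape != ss2.values.shape or ss1.ids != ss2.ids:
        raise GimdaError("semantic similarity matrices disagree")
    semantic = SimilarityMatrix((ss1.values + ss2.values) / 2.0, ss1.ids, "semantic1")
    return _integrate(semantic, kd, has_semantic, "integrated_disease")


def integrate_mirna_similarity(
    fs: SimilarityMatrix,
    km: SimilarityMatrix,
    has_functional: np.ndarray,
) -> SimilarityMatrix:
    """Functional similarity where both miRNAs are covered, else GIP."""
    return _integrate(fs, km, has_functional, "integrated_mirna")
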