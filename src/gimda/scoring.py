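"""Association scoring from graphlet-interaction features.

For a candidate pair (disease *i*, miRNA *j*) the miRNA-graph score is

    S_m(i, j) = sum_k v_k * sum_{p in P(i)} norm(N_pj(I_k))

where P(i) is the set of miRNAs already known for disease *i*, N_pj(I_k)
is the normalised count of graphlet-interaction isomer k from p to j in
the miRNA similarity graph, and v is a 28-long weight vector fitted by
linear regression against the known association labels. The disease-graph
score S_d mirrors this with Q(j), the diseases known for miRNA *j*, on the
disease similarity graph. The final score is the average of the two, so a
disease with no known miRNAs (or a miRNA with no known diseases) still
receives a usable ranking from the other side.

The weight fit is the closed-form normal-equations solution
``V = (X X^T + lambda I)^{-1} X s``; ``lambda = 0`` reproduces the plain
least-squares formula when the Gram matrix is invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .census import (
    IsomerCatalog,
    IsomerCountTensor,
    build_catalog,
    count_isomers_weighted,
    normalize_counts,
)
from .exceptions import GimdaError
from .io import AssociationMatrix, Config, DiseaseDAG, SimilarityMatrix
from .similarity import (
    gip_kernel,
    integrate_disease_similarity,
    integrate_mirna_similarity,
    semantic_similarity_matrix,
)

__all__ = [
    "FeatureMatrix",
    "WeightVector",
    "ScoreMatrix",
    "build_feature_matrix",
    "fit_weights",
    "score_all",
    "rank_candidates",
    "SemanticCache",
    "precompute_semantic",
    "predict",
]


@dataclass
class FeatureMatrix:
    """Isomer features for every (disease, miRNA) pair, shape (28, n*m).

    Pair columns are laid out row-major over (disease, miRNA); ``side``
    records which similarity graph the counts came from.
    """

    values: np.ndarray
    pair_index: list[tuple[str, str]]
    side: str  # "mirna_graph" or "disease_graph"


@dataclass
class WeightVector:
    values: np.ndarray
    side: str
    ridge_lambda: float


@dataclass
class ScoreMatrix:
    """Final scores with the two per-graph components and known-pair flags."""

    s_m: np.ndarray
    s_d: np.ndarray
    s: np.ndarray
    known: np.ndarray
    disease_ids: list[str]
    mirna_ids: list[str]
    v_m: WeightVector | None = None
    v_d: WeightVector | None = None


def _pair_index(assoc: AssociationMatrix) -> list[tuple[str, str]]:
    return [(d, m) for d in assoc.disease_ids for m in assoc.mirna_ids]


def build_feature_matrix(
    tensor: IsomerCountTensor, assoc: AssociationMatrix, side: str
) -> FeatureMatrix:
    """Sum normalised isomer counts from a pair's known partners.

    On the miRNA side the tensor is a census of the miRNA graph and the
    column for pair (i, j) is ``sum_{p in P(i)} norm(N[k, p, j])``; on the
    disease side it is the census of the disease graph summed over Q(j).
    """
    if tensor.normalized is None:
        raise GimdaError("tensor must be normalised before feature assembly")
    norm = tensor.normalized
    a = assoc.values.astype(float)
    n, m = a.shape
    if side == "mirna_graph":
        if norm.shape[1] != m:
            raise GimdaError("miRNA-graph tensor size does not match associations")
        # feats[k, i, j] = sum_p A[i, p] * norm[k, p, j]
        feats = np.einsum("ip,kpj->kij", a, norm)
    elif side == "disease_graph":
        if norm.shape[1] != n:
            raise GimdaError("disease-graph tensor size does not match associations")
        # feats[k, i, j] = sum_q A[q, j] * norm[k, q, i]
        feats = np.einsum("qj,kqi->kij", a, norm)
    else:
        raise GimdaError(f"unknown side {side!r}")
    values = feats.reshape(feats.shape[0], n * m)
    return FeatureMatrix(values, _pair_index(assoc), side)


def fit_weights(
    features: FeatureMatrix, labels: np.ndarray, ridge_lambda: float
) -> WeightVector:
    """Closed-form (ridge) regression of labels on the isomer features."""
    if ridge_lambda < 0:
        raise GimdaError("ridge_lambda must be non-negative")
    x = features.values
    s = np.asarray(labels, dtype=float).ravel()
    if s.shape[0] != x.shape[1]:
        raise GimdaError("labels are not aligned with the feature pair index")
    gram = x @ x.T
    if ridge_lambda > 0:
        gram = gram + ridge_lambda * np.eye(gram.shape[0])
    else:
        cond = np.linalg.cond(gram)
        if not np.isfinite(cond) or cond > 1e12:
            raise GimdaError(
                "normal equations are singular at lambda=0; set ridge_lambda > 0"
            )
    v = np.linalg.solve(gram, x @ s)
    return WeightVector(v, features.side, ridge_lambda)


def score_all(
    assoc: AssociationMatrix,
    sm_tensor: IsomerCountTensor,
    sd_tensor: IsomerCountTensor,
    v_m: WeightVector,
    v_d: WeightVector,
) -> ScoreMatrix:
    """Combine the two per-graph scores into the final average score."""
    fm = build_feature_matrix(sm_tensor, assoc, "mirna_graph")
    fd = build_feature_matrix(sd_tensor, assoc, "disease_graph")
    n, m = assoc.values.shape
    s_m = (fm.values.T @ v_m.values).reshape(n, m)
    s_d = (fd.values.T @ v_d.values).reshape(n, m)
    s = (s_m + s_d) / 2.0
    return ScoreMatrix(
        s_m,
        s_d,
        s,
        assoc.values.astype(bool),
        list(assoc.disease_ids),
        list(assoc.mirna_ids),
        v_m,
        v_d,
    )


def rank_candidates(scores: ScoreMatrix, disease: str) -> list[tuple[str, float]]:
    """Candidate miRNAs of a disease, best first.

    Only miRNAs without a known association to the disease are candidates;
    ties are broken lexicographically by miRNA id so the ranking is stable.
    """
    try:
        i = scores.disease_ids.index(disease)
    except ValueError:
        raise GimdaError(f"unknown disease {disease!r}") from None
    rows = [
        (scores.mirna_ids[j], float(scores.s[i, j]))
        for j in range(len(scores.mirna_ids))
        if not scores.known[i, j]
    ]
    rows.sort(key=lambda t: (-t[1], t[0]))
    return rows


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class SemanticCache:
    """Association-independent disease similarity, reusable across CV folds."""

    semantic_avg: SimilarityMatrix  # (SS1 + SS2) / 2 over assoc disease order
    has_semantic: np.ndarray


def precompute_semantic(
    dags: Mapping[str, DiseaseDAG],
    disease_ids: list[str],
    delta: float,
) -> SemanticCache:
    """Compute both semantic models over the corpus once.

    The result depends only on the DAGs, never on the association matrix,
    so cross-validation can reuse it across folds.
    """
    ss1 = semantic_similarity_matrix(dags, delta, model=1, ids=disease_ids)
    ss2 = semantic_similarity_matrix(dags, delta, model=2, ids=disease_ids)
    avg = SimilarityMatrix((ss1.values + ss2.values) / 2.0, ss1.ids, "semantic1")
    have = set(dags)
    mask = np.array([d in have for d in disease_ids], dtype=bool)
    return SemanticCache(avg, mask)


def predict(
    assoc: AssociationMatrix,
    config: Config | None = None,
    *,
    dags: Mapping[str, DiseaseDAG] | None = None,
    semantic: SemanticCache | None = None,
    disease_sim: SimilarityMatrix | None = None,
    mirna_sim: SimilarityMatrix | None = None,
    catalog: IsomerCatalog | None = None,
) -> ScoreMatrix:
    """Run the whole predictor on a (training) association matrix.

    Disease similarity comes from, in order of precedence: a precomputed
    ``semantic`` cache, disease ``dags`` (both semantic models averaged),
    or a direct ``disease_sim`` matrix; pairs not covered fall back to the
    GIP kernel computed from ``assoc``. The miRNA side uses ``mirna_sim``
    where available with the same GIP fallback. Weight vectors are fitted
    on all pairs of ``assoc`` with its entries as labels.
    """
    config = config or Config()
    catalog = catalog or build_catalog()

    kd = gip_kernel(
        assoc.values, config.gamma_d_prime, assoc.disease_ids, "gip_disease"
    )
    km = gip_kernel(
        assoc.values.T, config.gamma_m_prime, assoc.mirna_ids, "gip_mirna"
    )

    if semantic is None and dags is not None:
        semantic = precompute_semantic(dags, assoc.disease_ids, config.delta)
    if semantic is not None:
        sd = integrate_disease_similarity(
            semantic.semantic_avg, semantic.semantic_avg, kd, semantic.has_semantic
        )
    elif disease_sim is not None:
        aligned = disease_sim.reindex(assoc.disease_ids)
        mask = disease_sim.membership(assoc.disease_ids)
        sd = integrate_disease_similarity(aligned, aligned, kd, mask)
    else:
        sd = SimilarityMatrix(kd.values, kd.ids, "integrated_disease")

    if mirna_sim is not None:
        fs = mirna_sim.reindex(assoc.mirna_ids)
        mmask = mirna_sim.membership(assoc.mirna_ids)
        sm = integrate_mirna_similarity(fs, km, mmask)
    else:
        sm = SimilarityMatrix(km.values, km.ids, "integrated_mirna")

    wm = sm.values.copy()
    np.fill_diagonal(wm, 0.0)
    wd = sd.values.copy()
    np.fill_diagonal(wd, 0.0)
    sm_tensor = normalize_counts(count_isomers_weighted(wm, catalog))
    sd_tensor = normalize_counts(count_isomers_weighted(wd, catalog))

    labels = assoc.values.astype(float).ravel()
    fm = build_feature_matrix(sm_tensor, assoc, "mirna_graph")
    fd = build_feature_matrix(sd_tensor, assoc, "disease_graph")
    v_m = fit_weights(fm, labels, config.ridge_lambda)
    v_d = fit_weights(fd, labels, config.ridge_lambda)
    return score_all(assoc, sm_tensor, sd_tensor, v_m, v_d)
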