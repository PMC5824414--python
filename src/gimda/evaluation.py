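"""Cross-validation and ROC/AUC machinery.

Two leave-one-out protocols are supported. In *global* LOOCV each known
association is held out in turn, the model is retrained without it, and
the held-out pair's score is ranked against every pair with no known
association anywhere in the matrix. In *local* LOOCV the candidate set is
restricted to the unknown miRNAs of the same disease. k-fold CV partitions
the known associations into k disjoint near-equal parts and holds each out
in turn, repeating the random partition to obtain a mean and standard
deviation of the AUC.

Each held-out association is reduced to its *percentile*: the fraction of
candidate pairs it outscores (ties count one half). The AUC is the mean
percentile, which coincides with the Mann-Whitney statistic when all tests
share one candidate set, and the ROC curve is the empirical distribution
of the percentiles.

By default the model is retrained for every held-out unit so the held-out
cells influence neither the GIP kernels nor the fitted weights; the
``recompute`` flag can be dropped to reuse one full-data model as a fast
approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .census import IsomerCatalog, build_catalog
from .exceptions import GimdaError
from .io import AssociationMatrix, Config, DiseaseDAG, SimilarityMatrix
from .scoring import ScoreMatrix, SemanticCache, precompute_semantic, predict

__all__ = ["CVResult", "compute_auc", "roc_from_percentiles", "loocv", "kfold_cv"]


@dataclass
class CVResult:
    mode: str
    auc: float
    percentiles: list[float]
    roc_points: list[tuple[float, float]]
    k: int | None = None
    repeats: int = 1
    auc_sd: float | None = None
    auc_per_repeat: list[float] = field(default_factory=list)


def compute_auc(
    positive_scores: Sequence[float], negative_scores: Sequence[float]
) -> float:
    """Probability that a random positive outscores a random negative.

    Mann-Whitney statistic scaled to [0, 1] with ties counted one half;
    equals the area under the trapezoidal ROC curve of the two samples.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise GimdaError("both score lists must be non-empty")
    order = np.sort(neg)
    below = np.searchsorted(order, pos, side="left")
    ties = np.searchsorted(order, pos, side="right") - below
    return float(np.mean((below + 0.5 * ties) / neg.size))


def roc_from_percentiles(percentiles: Sequence[float]) -> list[tuple[float, float]]:
    """Empirical ROC curve of held-out percentile ranks.

    A test with percentile p is retrieved once the false-positive rate
    reaches 1 - p; the curve steps through the sorted values and is closed
    at (0, 0) and (1, 1).
    """
    q = np.sort(1.0 - np.asarray(percentiles, dtype=float))
    n = q.size
    points = [(0.0, 0.0)]
    for x in np.unique(q):
        points.append((float(x), float(np.mean(q <= x))))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def _percentile(score: float, candidates: np.ndarray) -> float:
    order = np.sort(candidates)
    below = np.searchsorted(order, score, side="left")
    ties = np.searchsorted(order, score, side="right") - below
    return (below + 0.5 * ties) / candidates.size


def _make_predictor(
    config: Config | None,
    dags: Mapping[str, DiseaseDAG] | None,
    semantic: SemanticCache | None,
    disease_sim: SimilarityMatrix | None,
    mirna_sim: SimilarityMatrix | None,
    catalog: IsomerCatalog | None,
    disease_ids: list[str],
) -> Callable[[AssociationMatrix], ScoreMatrix]:
    config = config or Config()
    catalog = catalog or build_catalog()
    if semantic is None and dags is not None:
        # semantic similarity never depends on the associations: share it
        # across every retraining
        semantic = precompute_semantic(dags, disease_ids, config.delta)

    def _run(assoc: AssociationMatrix) -> ScoreMatrix:
        return predict(
            assoc,
            config,
            semantic=semantic,
            disease_sim=disease_sim,
            mirna_sim=mirna_sim,
            catalog=catalog,
        )

    return _run


def loocv(
    assoc: AssociationMatrix,
    config: Config | None = None,
    mode: str = "global",
    *,
    dags: Mapping[str, DiseaseDAG] | None = None,
    semantic: SemanticCache | None = None,
    disease_sim: SimilarityMatrix | None = None,
    mirna_sim: SimilarityMatrix | None = None,
    catalog: IsomerCatalog | None = None,
    recompute: bool = True,
) -> CVResult:
    """Leave-one-out cross-validation over the known associations."""
    if mode not in ("global", "local"):
        raise GimdaError("mode must be 'global' or 'local'")
    positives = np.argwhere(assoc.values == 1)
    if len(positives) < 2:
        raise GimdaError("LOOCV needs at least two known associations")
    run = _make_predictor(
        config, dags, semantic, disease_sim, mirna_sim, catalog, assoc.disease_ids
    )
    full_scores = None if recompute else run(assoc)
    unknown = assoc.values == 0
    percentiles: list[float] = []
    for i, j in positives:
        if mode == "local" and not unknown[i].any():
            warnings.warn(
                f"disease {assoc.disease_ids[i]!r} has no candidate miRNAs; "
                "test association skipped",
                stacklevel=2,
            )
            continue
        if recompute:
            train = assoc.copy()
            train.values[i, j] = 0
            result = run(train)
        else:
            result = full_scores
        if mode == "global":
            candidates = result.s[unknown]
        else:
            candidates = result.s[i, unknown[i]]
        percentiles.append(_percentile(float(result.s[i, j]), candidates))
    if not percentiles:
        raise GimdaError("no test associations could be evaluated")
    auc = float(np.mean(percentiles))
    return CVResult(
        mode=f"{mode}_loocv",
        auc=auc,
        percentiles=percentiles,
        roc_points=roc_from_percentiles(percentiles),
    )


def kfold_cv(
    assoc: AssociationMatrix,
    config: Config | None = None,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    *,
    dags: Mapping[str, DiseaseDAG] | None = None,
    semantic: SemanticCache | None = None,
    disease_sim: SimilarityMatrix | None = None,
    mirna_sim: SimilarityMatrix | None = None,
    catalog: IsomerCatalog | None = None,
) -> CVResult:
    """Repeated k-fold cross-validation over the known associations.

    Positives are partitioned uniformly at random into k disjoint
    near-equal parts; each part is held out in turn, the model is
    retrained on the rest, and the held-out scores are ranked against all
    unknown pairs. One AUC is produced per repeat; the result reports
    their mean and standard deviation.
    """
    if k < 2:
        raise GimdaError("k must be at least 2")
    positives = np.argwhere(assoc.values == 1)
    if len(positives) < k:
        raise GimdaError(f"k={k} exceeds the {len(positives)} known associations")
    run = _make_predictor(
        config, dags, semantic, disease_sim, mirna_sim, catalog, assoc.disease_ids
    )
    unknown = assoc.values == 0
    rng = np.random.default_rng(seed)
    aucs: list[float] = []
    all_percentiles: list[float] = []
    for _ in range(repeats):
        perm = rng.permutation(len(positives))
        folds = np.array_split(perm, k)
        percentiles: list[float] = []
        for fold in folds:
            train = assoc.copy()
            test_pairs = positives[fold]
            train.values[test_pairs[:, 0], test_pairs[:, 1]] = 0
            result = run(train)
            candidates = result.s[unknown]
            for i, j in test_pairs:
                percentiles.append(_percentile(float(result.s[i, j]), candidates))
        aucs.append(float(np.mean(percentiles)))
        all_percentiles.extend(percentiles)
    return CVResult(
        mode="kfold",
        auc=float(np.mean(aucs)),
        percentiles=all_percentiles,
        roc_points=roc_from_percentiles(all_percentiles),
        k=k,
        repeats=repeats,
        auc_sd=float(np.std(aucs, ddof=1)) if repeats > 1 else None,
        auc_per_repeat=aucs,
    )
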