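"""Self-contained synthetic benchmarks with planted structure.

The generator emulates the premise behind similarity-based association
prediction: functionally related miRNAs tend to be associated with
phenotypically similar diseases. Diseases and miRNAs are assigned to
blocks; similarities are drawn high within a block (Beta(5, 1)) and low
between blocks (Beta(1, 5)); associations appear preferentially between
aligned blocks; and a fraction of the generated associations is hidden
from the visible matrix as a recoverable ground truth. A ``noise``
parameter in [0, 1] interpolates towards a structureless null world in
which similarities are i.i.d. uniform and associations are uniformly
random, where no method should beat chance.

Each disease also receives a small MeSH-like ancestor DAG hanging off a
shared global root through a per-block branch node, so the DAG-based
semantic similarity sees the same block structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import GimdaError
from .io import (
    AssociationMatrix,
    DiseaseDAG,
    SimilarityMatrix,
    write_associations,
    write_dags,
    write_similarity_matrix,
)

__all__ = [
    "PlantedWorldParams",
    "PlantedWorld",
    "generate_planted_world",
    "generate_random_dag_corpus",
]


@dataclass
class PlantedWorldParams:
    """Study conditions of the planted benchmark.

    Defaults describe a 30 x 30 world split into two blocks with aligned
    associations at density 0.9 and one fifth of them hidden as truth. The
    high within-block density is what makes the noise-free world
    *identifiable*: with sparser aligned associations a hidden positive is
    statistically indistinguishable from a within-block negative given the
    visible matrix, which caps the achievable AUC of any method (see the
    methods note).
    """

    n_diseases: int = 30
    n_mirnas: int = 30
    n_blocks: int = 2
    within_block_sim: tuple[float, float] = (5.0, 1.0)  # Beta shape parameters
    between_block_sim: tuple[float, float] = (1.0, 5.0)
    assoc_density: float = 0.9
    hidden_fraction: float = 0.2
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diseases < 1 or self.n_mirnas < 1 or self.n_blocks < 1:
            raise GimdaError("entity and block counts must be positive")
        if not 0 <= self.noise <= 1:
            raise GimdaError("noise must lie in [0, 1]")
        if not 0 < self.assoc_density <= 1:
            raise GimdaError("assoc_density must lie in (0, 1]")
        if not 0 <= self.hidden_fraction < 1:
            raise GimdaError("hidden_fraction must lie in [0, 1)")


@dataclass
class PlantedWorld:
    assoc: AssociationMatrix
    mirna_sim: SimilarityMatrix
    disease_sim: SimilarityMatrix
    dags: dict[str, DiseaseDAG]
    truth: set[tuple[str, str]]
    params: PlantedWorldParams

    def write(self, outdir: str | Path) -> None:
        """Write the visible inputs plus the hidden-truth list as TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_associations(self.assoc, outdir / "associations.tsv")
        write_similarity_matrix(self.mirna_sim, outdir / "mirna_similarity.tsv")
        write_similarity_matrix(self.disease_sim, outdir / "disease_similarity.tsv")
        write_dags(self.dags, outdir / "disease_dags.tsv")
        with (outdir / "truth.tsv").open("w", encoding="utf-8") as fh:
            for d, m in sorted(self.truth):
                fh.write(f"{d}\t{m}\n")


def _block_similarity(
    blocks: np.ndarray, params: PlantedWorldParams, rng: np.random.Generator
) -> np.ndarray:
    n = blocks.size
    same = blocks[:, None] == blocks[None, :]
    a_in, b_in = params.within_block_sim
    a_out, b_out = params.between_block_sim
    structured = np.where(
        same, rng.beta(a_in, b_in, (n, n)), rng.beta(a_out, b_out, (n, n))
    )
    values = (1.0 - params.noise) * structured + params.noise * rng.random((n, n))
    values = np.triu(values, 1)
    values = values + values.T
    np.fill_diagonal(values, 1.0)
    return values


def generate_planted_world(params: PlantedWorldParams | None = None) -> PlantedWorld:
    """Draw one world: similarities, visible associations, hidden truth."""
    params = params or PlantedWorldParams()
    rng = np.random.default_rng(params.seed)
    disease_ids = [f"disease{i:03d}" for i in range(params.n_diseases)]
    mirna_ids = [f"mirna{j:03d}" for j in range(params.n_mirnas)]
    d_blocks = np.arange(params.n_diseases) % params.n_blocks
    m_blocks = np.arange(params.n_mirnas) % params.n_blocks

    disease_values = _block_similarity(d_blocks, params, rng)
    mirna_values = _block_similarity(m_blocks, params, rng)

    aligned = d_blocks[:, None] == m_blocks[None, :]
    p_structured = np.where(aligned, params.assoc_density, 0.0)
    p_null = params.assoc_density / params.n_blocks
    p = (1.0 - params.noise) * p_structured + params.noise * p_null
    full = rng.random((params.n_diseases, params.n_mirnas)) < p

    hidden = full & (rng.random(full.shape) < params.hidden_fraction)
    visible = full & ~hidden
    truth = {
        (disease_ids[i], mirna_ids[j]) for i, j in np.argwhere(hidden)
    }

    dags = _block_dag_corpus(disease_ids, d_blocks, params.noise, rng)
    return PlantedWorld(
        assoc=AssociationMatrix(visible.astype(np.int8), disease_ids, mirna_ids),
        mirna_sim=SimilarityMatrix(mirna_values, mirna_ids, "functional"),
        disease_sim=SimilarityMatrix(disease_values, disease_ids, "semantic1"),
        dags=dags,
        truth=truth,
        params=params,
    )


def _block_dag_corpus(
    disease_ids: list[str],
    blocks: np.ndarray,
    noise: float,
    rng: np.random.Generator,
) -> dict[str, DiseaseDAG]:
    n_blocks = int(blocks.max()) + 1 if blocks.size else 1
    dags: dict[str, DiseaseDAG] = {}
    for disease, block in zip(disease_ids, blocks):
        b = int(block)
        if noise > 0 and rng.random() < noise:
            b = int(rng.integers(n_blocks))
        branch = f"branch{b:02d}"
        dags[disease] = DiseaseDAG.from_edges(
            disease, [("root", branch), (branch, disease)]
        )
    return dags


def generate_random_dag_corpus(
    n_diseases: int,
    depth: int,
    branching: int,
    seed: int = 0,
) -> dict[str, DiseaseDAG]:
    """Random MeSH-like ancestor DAGs sharing one global root.

    Every disease hangs off a chain of ``depth`` internal vocabulary terms
    chosen from levels of width ``branching ** level``; ``depth == 0``
    yields singleton DAGs. The shared root makes corpus term counts
    nontrivial for the information-content semantic model.
    """
    if depth < 0:
        raise GimdaError("depth must be non-negative")
    if depth > 0 and branching < 1:
        raise GimdaError("branching must be positive when depth > 0")
    rng = np.random.default_rng(seed)
    dags: dict[str, DiseaseDAG] = {}
    for i in range(n_diseases):
        disease = f"disease{i:03d}"
        if depth == 0:
            dags[disease] = DiseaseDAG.from_edges(disease, [])
            continue
        chain = ["root"]
        for level in range(1, depth):
            width = branching**level
            chain.append(f"term_l{level}_{rng.integers(width):03d}")
        edges = [(chain[k], chain[k + 1]) for k in range(len(chain) - 1)]
        edges.append((chain[-1], disease))
        dags[disease] = DiseaseDAG.from_edges(disease, edges)
    return dags
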