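"""Input/output and the core data containers.

The predictor consumes three kinds of files, all plain TSV:

* an association list: two columns ``disease<TAB>miRNA``, one known
  association per row;
* a disease-DAG edge list: three columns ``disease<TAB>parent<TAB>child``
  describing, per disease, the ancestor graph of that disease in a
  MeSH-style vocabulary (a row with only the disease column declares a
  disease whose DAG is the singleton ``{disease}``);
* square similarity matrices: first row and first column carry the entity
  identifiers, the body is numeric.

Entity labels are lower-cased and whitespace-trimmed on input so that the
same entity named with different capitalisation in different files still
lands on the same matrix row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import GimdaError

__all__ = [
    "AssociationMatrix",
    "DiseaseDAG",
    "SimilarityMatrix",
    "Config",
    "normalize_label",
    "read_associations",
    "read_disease_dags",
    "read_similarity_matrix",
    "write_associations",
    "write_similarity_matrix",
    "write_scores",
]

SYMMETRY_TOL = 1e-6


def normalize_label(label: str) -> str:
    """Canonical form of an entity identifier: stripped and lower-cased."""
    return str(label).strip().lower()


@dataclass
class AssociationMatrix:
    """Binary disease x miRNA adjacency matrix with identifier registries.

    ``values[i, j] == 1`` iff disease ``disease_ids[i]`` is known to be
    associated with miRNA ``mirna_ids[j]``.
    """

    values: np.ndarray
    disease_ids: list[str]
    mirna_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, m = self.values.shape
        if n != len(self.disease_ids) or m != len(self.mirna_ids):
            raise GimdaError("association matrix shape does not match id registries")
        if len(set(self.disease_ids)) != n or len(set(self.mirna_ids)) != m:
            raise GimdaError("duplicate labels in association matrix registries")
        vals = np.unique(self.values)
        if not np.all(np.isin(vals, (0, 1))):
            raise GimdaError("association matrix entries must be 0 or 1")

    @property
    def n_diseases(self) -> int:
        return self.values.shape[0]

    @property
    def n_mirnas(self) -> int:
        return self.values.shape[1]

    def disease_index(self, disease: str) -> int:
        try:
            return self.disease_ids.index(normalize_label(disease))
        except ValueError:
            raise GimdaError(f"unknown disease {disease!r}") from None

    def mirna_index(self, mirna: str) -> int:
        try:
            return self.mirna_ids.index(normalize_label(mirna))
        except ValueError:
            raise GimdaError(f"unknown miRNA {mirna!r}") from None

    def known_mirnas(self, i: int) -> np.ndarray:
        """P(i): column indices of the miRNAs known for disease row ``i``."""
        return np.flatnonzero(self.values[i, :])

    def known_diseases(self, j: int) -> np.ndarray:
        """Q(j): row indices of the diseases known for miRNA column ``j``."""
        return np.flatnonzero(self.values[:, j])

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.disease_ids), list(self.mirna_ids)
        )


@dataclass
class DiseaseDAG:
    """Ancestor DAG of one disease.

    ``graph`` holds directed parent->child edges; every node can reach the
    root disease by following child edges, i.e. the node set is the disease
    itself plus its ancestors in the vocabulary.
    """

    root: str
    graph: nx.DiGraph

    def __post_init__(self) -> None:
        self.root = normalize_label(self.root)
        if self.root not in self.graph:
            self.graph.add_node(self.root)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise GimdaError(f"DAG for disease {self.root!r} contains a cycle")
        reaches = set(nx.ancestors(self.graph, self.root)) | {self.root}
        stray = set(self.graph.nodes) - reaches
        if stray:
            raise GimdaError(
                f"DAG for disease {self.root!r} has nodes with no path to it: "
                f"{sorted(stray)}"
            )

    @property
    def nodes(self) -> set[str]:
        """T(D): the disease and all of its ancestors."""
        return set(self.graph.nodes)

    def children(self, node: str) -> list[str]:
        return sorted(self.graph.successors(node))

    @classmethod
    def from_edges(cls, root: str, edges: Iterable[tuple[str, str]]) -> "DiseaseDAG":
        g = nx.DiGraph()
        g.add_node(normalize_label(root))
        for parent, child in edges:
            g.add_edge(normalize_label(parent), normalize_label(child))
        return cls(normalize_label(root), g)


_SIM_KINDS = {
    "semantic1",
    "semantic2",
    "gip_disease",
    "gip_mirna",
    "functional",
    "integrated_disease",
    "integrated_mirna",
}


@dataclass
class SimilarityMatrix:
    """Symmetric similarity among one entity class, values in [0, 1]."""

    values: np.ndarray
    ids: list[str]
    kind: str = "functional"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise GimdaError("similarity matrix must be square")
        if self.values.shape[0] != len(self.ids):
            raise GimdaError("similarity matrix shape does not match ids")
        if len(set(self.ids)) != len(self.ids):
            raise GimdaError("duplicate ids in similarity matrix")
        if self.kind not in _SIM_KINDS:
            raise GimdaError(f"unknown similarity kind {self.kind!r}")
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > 1e-9:
            raise GimdaError("similarity matrix is not symmetric")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise GimdaError("similarity values must lie in [0, 1]")

    def reindex(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Restrict/embed onto ``ids``; entities absent here get zero rows."""
        ids = [normalize_label(x) for x in ids]
        pos = {x: k for k, x in enumerate(self.ids)}
        out = np.zeros((len(ids), len(ids)))
        present = [k for k, x in enumerate(ids) if x in pos]
        src = [pos[ids[k]] for k in present]
        out[np.ix_(present, present)] = self.values[np.ix_(src, src)]
        return SimilarityMatrix(out, list(ids), self.kind)

    def membership(self, ids: Sequence[str]) -> np.ndarray:
        """Boolean vector: which of ``ids`` this matrix has an entry for."""
        have = set(self.ids)
        return np.array([normalize_label(x) in have for x in ids], dtype=bool)


@dataclass
class Config:
    """Tunable parameters of the predictor.

    delta
        Semantic contribution decay factor per DAG layer, in (0, 1).
    gamma_d_prime / gamma_m_prime
        Original bandwidths of the Gaussian interaction-profile kernels for
        diseases and miRNAs; the effective bandwidth is obtained by dividing
        by the mean squared profile norm.
    ridge_lambda
        Tikhonov regulariser of the isomer-weight regression; 0 reproduces
        the plain normal-equations solution when it is well posed.
    """

    delta: float = 0.5
    gamma_d_prime: float = 1.0
    gamma_m_prime: float = 1.0
    ridge_lambda: float = 1e-6
    seed: int = 0
    cv_folds: int = 5
    cv_repeats: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise GimdaError("delta must lie strictly between 0 and 1")
        if self.gamma_d_prime <= 0 or self.gamma_m_prime <= 0:
            raise GimdaError("kernel bandwidths must be positive")
        if self.ridge_lambda < 0:
            raise GimdaError("ridge_lambda must be non-negative")
        if self.cv_folds < 2:
            raise GimdaError("cv_folds must be at least 2")


# ---------------------------------------------------------------------------
# readers


def read_associations(path: str | Path) -> AssociationMatrix:
    """Read a two-column TSV of (disease, miRNA) pairs into a binary matrix.

    Identifiers are sorted lexicographically so matrix layout is independent
    of row order in the file. Duplicate pairs are dropped with a warning.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise GimdaError(
                    f"{path}: malformed association row at line {lineno}: {line!r}"
                )
            pairs.append((normalize_label(fields[0]), normalize_label(fields[1])))
    if not pairs:
        raise GimdaError(f"{path}: no associations")
    if len(set(pairs)) != len(pairs):
        warnings.warn(
            f"{path}: {len(pairs) - len(set(pairs))} duplicate association pair(s) "
            "dropped",
            stacklevel=2,
        )
        seen: set[tuple[str, str]] = set()
        pairs = [p for p in pairs if not (p in seen or seen.add(p))]
    diseases = sorted({d for d, _ in pairs})
    mirnas = sorted({m for _, m in pairs})
    drow = {d: i for i, d in enumerate(diseases)}
    mcol = {m: j for j, m in enumerate(mirnas)}
    values = np.zeros((len(diseases), len(mirnas)), dtype=np.int8)
    for d, m in pairs:
        values[drow[d], mcol[m]] = 1
    return AssociationMatrix(values, diseases, mirnas)


def read_disease_dags(
    path: str | Path, diseases: Iterable[str] | None = None
) -> dict[str, DiseaseDAG]:
    """Read per-disease parent->child edge lists.

    Rows are ``disease<TAB>parent<TAB>child``; a row carrying only the
    disease column declares a disease with a singleton DAG. ``diseases``
    optionally lists extra diseases that should receive singleton DAGs even
    though the file has no row for them.
    """
    path = Path(path)
    edges: dict[str, list[tuple[str, str]]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if len(fields) == 1 and fields[0]:
                edges.setdefault(normalize_label(fields[0]), [])
                continue
            if len(fields) != 3 or not all(fields):
                raise GimdaError(
                    f"{path}: malformed DAG row at line {lineno}: {line!r}"
                )
            disease, parent, child = (normalize_label(f) for f in fields)
            edges.setdefault(disease, []).append((parent, child))
    for d in diseases or ():
        edges.setdefault(normalize_label(d), [])
    dags: dict[str, DiseaseDAG] = {}
    for disease in sorted(edges):
        dags[disease] = DiseaseDAG.from_edges(disease, edges[disease])
    return dags


def read_similarity_matrix(path: str | Path, kind: str = "functional") -> SimilarityMatrix:
    """Read a square TSV similarity matrix with id header row and column.

    Mild asymmetry (above 1e-6) is repaired by averaging with the transpose,
    and values outside [0, 1] are clipped; both repairs emit a warning.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    row_ids = [normalize_label(x) for x in frame.index]
    col_ids = [normalize_label(x) for x in frame.columns]
    if len(row_ids) != len(col_ids):
        raise GimdaError(f"{path}: similarity matrix is not square")
    if set(row_ids) != set(col_ids):
        raise GimdaError(f"{path}: row and column identifiers disagree")
    frame.index = row_ids
    frame.columns = col_ids
    frame = frame.loc[row_ids, row_ids]
    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise GimdaError(
            f"{path}: NaN at row {row_ids[i]!r}, column {row_ids[j]!r}"
        )
    asym = float(np.max(np.abs(values - values.T), initial=0.0))
    if asym > SYMMETRY_TOL:
        warnings.warn(
            f"{path}: asymmetry up to {asym:.3g} symmetrised by averaging",
            stacklevel=2,
        )
    values = (values + values.T) / 2.0
    if values.size and (values.min() < 0 or values.max() > 1):
        warnings.warn(f"{path}: values clipped to [0, 1]", stacklevel=2)
        values = np.clip(values, 0.0, 1.0)
    return SimilarityMatrix(values, row_ids, kind)


# ---------------------------------------------------------------------------
# writers


def write_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for i, d in enumerate(assoc.disease_ids):
            for j in np.flatnonzero(assoc.values[i]):
                fh.write(f"{d}\t{assoc.mirna_ids[j]}\n")


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids)
    frame.to_csv(path, sep="\t")


def write_dags(dags: Mapping[str, DiseaseDAG], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for disease in sorted(dags):
            dag = dags[disease]
            if dag.graph.number_of_edges() == 0:
                fh.write(f"{disease}\n")
            for parent, child in sorted(dag.graph.edges):
                fh.write(f"{disease}\t{parent}\t{child}\n")


def write_scores(
    scores: np.ndarray,
    assoc: AssociationMatrix,
    path: str | Path,
    matrix_path: str | Path | None = None,
) -> None:
    """Write scores in long form (disease, miRNA, score, known_flag)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("disease\tmirna\tscore\tknown\n")
        for i, d in enumerate(assoc.disease_ids):
            for j, m in enumerate(assoc.mirna_ids):
                fh.write(f"{d}\t{m}\t{scores[i, j]:.10g}\t{int(assoc.values[i, j])}\n")
    if matrix_path is not None:
        frame = pd.DataFrame(scores, index=assoc.disease_ids, columns=assoc.mirna_ids)
        frame.to_csv(matrix_path, sep="\t")
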