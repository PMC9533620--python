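"""Core containers and plain-text I/O for association, similarity and DAG data.

The package works on three kinds of input:

* a binary miRNA x disease association matrix (``AssociationMatrix``),
  read from a two-column edge list or a dense 0/1 CSV;
* square similarity matrices in [0, 1] (``SimilarityMatrix``) for miRNA
  functional similarity, disease semantic similarity, Gaussian
  interaction-profile (GIP) kernels, and the integrated variants;
* a corpus of per-disease MeSH-style ancestor DAGs (``DagCorpus``) from
  which disease semantic similarity is derived.

All file formats are plain text (TSV/CSV); identifiers are matched
exactly after case-folding and whitespace trimming.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "EntityIndex",
    "AssociationMatrix",
    "SimilarityMatrix",
    "DagCorpus",
    "Params",
    "read_association_edgelist",
    "read_association_dense",
    "write_association_edgelist",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_dag_corpus",
    "write_scores",
    "read_scores",
]

SIMILARITY_KINDS = ("functional", "semantic", "gip", "integrated")

#: Kinds whose diagonal must be exactly 1 (functional input is taken as-is).
_UNIT_DIAGONAL_KINDS = ("semantic", "gip", "integrated")

_SYMMETRY_TOL = 1e-8


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A container invariant was violated."""


def normalize_id(raw: str) -> str:
    """Canonical identifier form: whitespace-trimmed and case-folded."""
    return raw.strip().casefold()


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntityIndex:
    """Ordered miRNA and disease identifiers defining matrix axes.

    The position of an identifier in ``mirna_ids`` / ``disease_ids`` is the
    row / column it occupies in every matrix of the run.
    """

    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mirna_ids", tuple(self.mirna_ids))
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))
        for label, ids in (("miRNA", self.mirna_ids), ("disease", self.disease_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {label} identifiers in index")

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def mirna_position(self, mirna_id: str) -> int:
        try:
            return self.mirna_ids.index(mirna_id)
        except ValueError:
            raise KeyError(f"unknown miRNA identifier: {mirna_id!r}") from None

    def disease_position(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(disease_id)
        except ValueError:
            raise KeyError(f"unknown disease identifier: {disease_id!r}") from None


@dataclass
class AssociationMatrix:
    """Binary n_m x n_d matrix of known miRNA-disease links.

    Rows are miRNA interaction profiles, columns disease interaction
    profiles; entry (g, h) is 1 iff miRNA g is a verified partner of
    disease h.
    """

    values: np.ndarray
    index: EntityIndex

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValidationError("association matrix must be 2-D")
        if values.shape != (self.index.n_mirnas, self.index.n_diseases):
            raise ValidationError(
                f"association shape {values.shape} does not match index "
                f"({self.index.n_mirnas}, {self.index.n_diseases})"
            )
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("association entries must be exactly 0 or 1")
        self.values = values.astype(np.int8, copy=False)

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())

    def positive_pairs(self) -> np.ndarray:
        """(row, col) coordinates of all known links, row-major order."""
        return np.argwhere(self.values == 1)

    def with_masked(self, pairs: np.ndarray) -> "AssociationMatrix":
        """Copy with the given (row, col) pairs set to 0 (held-out links)."""
        masked = self.values.copy()
        pairs = np.atleast_2d(np.asarray(pairs, dtype=int))
        masked[pairs[:, 0], pairs[:, 1]] = 0
        return AssociationMatrix(masked, self.index)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1]."""

    values: np.ndarray
    ids: tuple[str, ...]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in SIMILARITY_KINDS:
            raise ValidationError(
                f"kind must be one of {SIMILARITY_KINDS}, got {self.kind!r}"
            )
        self.ids = tuple(self.ids)
        values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if values.shape != (n, n):
            raise ValidationError(
                f"similarity shape {values.shape} does not match {n} ids"
            )
        asym = np.abs(values - values.T)
        if asym.size and asym.max() > _SYMMETRY_TOL:
            g, h = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"similarity asymmetric beyond {_SYMMETRY_TOL:g}: worst cell "
                f"({self.ids[g]!r}, {self.ids[h]!r}) differs by {asym[g, h]:.3g}"
            )
        if values.size and (values.min() < 0.0 or values.max() > 1.0):
            raise ValidationError(
                f"similarity values outside [0, 1]: range "
                f"[{values.min():.6g}, {values.max():.6g}]"
            )
        if self.kind in _UNIT_DIAGONAL_KINDS and n:
            if not np.allclose(np.diag(values), 1.0, atol=1e-12):
                raise ValidationError(
                    f"{self.kind} similarity must have unit diagonal"
                )
        self.values = values

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class DagCorpus:
    """Per-disease ancestor DAGs plus corpus-level descriptor frequencies.

    ``dags`` maps each disease id to a directed graph whose edges run
    parent -> child, with the disease's own descriptor as the unique sink.
    ``descriptor_df`` counts, for each descriptor, the number of disease
    DAGs in the corpus containing it; ``corpus_size`` is the number of
    diseases N used as the denominator of the information-content
    contribution -log(N_l / N).  ``corpus_size`` defaults to the number
    of DAGs but may be set larger to reflect frequencies drawn from a
    bigger vocabulary than the working disease set.
    """

    dags: dict[str, nx.DiGraph]
    descriptor_df: dict[str, int] = field(default_factory=dict)
    corpus_size: int = 0

    def __post_init__(self) -> None:
        if not self.descriptor_df:
            self.descriptor_df = self.recount_descriptor_df()
        if self.corpus_size == 0:
            self.corpus_size = len(self.dags)
        for disease, dag in self.dags.items():
            if disease not in dag:
                raise ValidationError(
                    f"DAG for {disease!r} lacks the disease's own descriptor"
                )
            if not nx.is_directed_acyclic_graph(dag):
                raise ValidationError(f"cycle detected in DAG for {disease!r}")
            for node in dag.nodes:
                if node != disease and not nx.has_path(dag, node, disease):
                    raise ValidationError(
                        f"descriptor {node!r} in DAG for {disease!r} has no "
                        f"descendant path to the disease node"
                    )
        for descriptor, df in self.descriptor_df.items():
            if not 1 <= df <= self.corpus_size:
                raise ValidationError(
                    f"descriptor frequency for {descriptor!r} ({df}) outside "
                    f"[1, {self.corpus_size}]"
                )

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return tuple(self.dags)

    def recount_descriptor_df(self) -> dict[str, int]:
        """Recompute descriptor document frequencies from the stored DAGs."""
        counts: dict[str, int] = {}
        for dag in self.dags.values():
            for node in dag.nodes:
                counts[node] = counts.get(node, 0) + 1
        return counts


@dataclass(frozen=True)
class Params:
    """Model parameters.

    T
        Weak-similarity threshold: similarity entries below T are zeroed
        in the numerator of the information property.  0.02 is the value
        at which cross-validated AUC peaks.
    delta
        Per-edge semantic contribution decay of the decay-based
        similarity frame.
    beta_star_d, beta_star_m
        Original GIP kernel bandwidths before normalisation by the mean
        squared profile norm.
    """

    T: float = 0.02
    delta: float = 0.5
    beta_star_d: float = 1.0
    beta_star_m: float = 1.0

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValidationError("T must be >= 0")
        if not 0 < self.delta <= 1:
            raise ValidationError("delta must be in (0, 1]")
        if self.beta_star_d <= 0 or self.beta_star_m <= 0:
            raise ValidationError("beta_star values must be > 0")


# ---------------------------------------------------------------------------
# association matrix I/O
# ---------------------------------------------------------------------------


def _data_lines(path) -> list[tuple[int, str]]:
    with open(path, encoding="utf-8") as handle:
        lines = [
            (number, line.rstrip("\n"))
            for number, line in enumerate(handle, start=1)
            if line.strip() and not line.lstrip().startswith("#")
        ]
    return lines


def read_association_edgelist(
    path,
    mirna_ids: list[str] | None = None,
    disease_ids: list[str] | None = None,
) -> AssociationMatrix:
    """Read a two-column (miRNA-id TAB disease-id) edge list.

    Lines starting with ``#`` and blank lines are ignored; duplicate edges
    collapse to a single link.  Unless explicit id lists are supplied the
    index is built from the sorted unique identifiers in the file.
    """
    lines = _data_lines(path)
    if not lines:
        raise ParseError(f"{path}: no association edges found")
    edges: list[tuple[str, str]] = []
    for number, line in lines:
        fields = line.split("\t")
        if len(fields) == 1:  # tolerate whitespace-separated files
            fields = line.split()
        if len(fields) != 2:
            raise ParseError(
                f"{path}:{number}: expected 2 columns, got {len(fields)}"
            )
        edges.append((normalize_id(fields[0]), normalize_id(fields[1])))

    if mirna_ids is None:
        mirna_ids = sorted({m for m, _ in edges})
    else:
        mirna_ids = [normalize_id(m) for m in mirna_ids]
    if disease_ids is None:
        disease_ids = sorted({d for _, d in edges})
    else:
        disease_ids = [normalize_id(d) for d in disease_ids]

    index = EntityIndex(tuple(mirna_ids), tuple(disease_ids))
    m_pos = {m: i for i, m in enumerate(index.mirna_ids)}
    d_pos = {d: j for j, d in enumerate(index.disease_ids)}
    values = np.zeros((index.n_mirnas, index.n_diseases), dtype=np.int8)
    dropped = 0
    for mirna, disease in edges:
        if mirna in m_pos and disease in d_pos:
            values[m_pos[mirna], d_pos[disease]] = 1
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"{dropped} edge(s) referenced identifiers absent from the "
            f"supplied id lists and were dropped",
            stacklevel=2,
        )
    return AssociationMatrix(values, index)


def read_association_dense(path) -> AssociationMatrix:
    """Read a dense 0/1 CSV with miRNA-id rows and disease-id columns."""
    frame = pd.read_csv(path, index_col=0)
    values = frame.to_numpy()
    index = EntityIndex(
        tuple(normalize_id(str(i)) for i in frame.index),
        tuple(normalize_id(str(c)) for c in frame.columns),
    )
    return AssociationMatrix(values, index)


def write_association_edgelist(assoc: AssociationMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# miRNA-id\tdisease-id\n")
        for g, h in assoc.positive_pairs():
            handle.write(
                f"{assoc.index.mirna_ids[g]}\t{assoc.index.disease_ids[h]}\n"
            )


# ---------------------------------------------------------------------------
# similarity matrix I/O
# ---------------------------------------------------------------------------


def read_similarity_matrix(path, kind: str = "functional") -> SimilarityMatrix:
    """Read a square similarity CSV (id header row, id first column)."""
    frame = pd.read_csv(path, index_col=0)
    row_ids = [normalize_id(str(i)) for i in frame.index]
    col_ids = [normalize_id(str(c)) for c in frame.columns]
    if row_ids != col_ids:
        raise ParseError(
            f"{path}: header ids do not match first-column ids "
            f"(matrix must be square with identical orderings)"
        )
    return SimilarityMatrix(frame.to_numpy(dtype=float), tuple(row_ids), kind)


def write_similarity_matrix(sim: SimilarityMatrix, path) -> None:
    pd.DataFrame(sim.values, index=list(sim.ids), columns=list(sim.ids)).to_csv(
        path, float_format="%.12g"
    )


def subset_similarity(
    sim: SimilarityMatrix, ids: tuple[str, ...]
) -> tuple[SimilarityMatrix, np.ndarray]:
    """Align a similarity matrix to an id ordering.

    Returns the realigned matrix together with a boolean coverage mask
    (True where the id pair was present in ``sim``).  Missing ids get
    zero rows/columns and are reported with a warning; similarity for
    those entities must come from the kernel fallback.
    """
    pos = {v: i for i, v in enumerate(sim.ids)}
    n = len(ids)
    values = np.zeros((n, n))
    present = np.array([i in pos for i in ids])
    missing = [i for i in ids if i not in pos]
    if missing:
        warnings.warn(
            f"{len(missing)} id(s) absent from {sim.kind} similarity input "
            f"(e.g. {missing[0]!r}); their similarities fall back to the "
            f"kernel",
            stacklevel=2,
        )
    src = [pos[i] for i in ids if i in pos]
    sel = np.where(present)[0]
    if sel.size:
        values[np.ix_(sel, sel)] = sim.values[np.ix_(src, src)]
    # a missing entity is still perfectly similar to itself
    values[~present, ~present] = 1.0
    coverage = np.outer(present, present)
    return SimilarityMatrix(values, ids, sim.kind), coverage


# ---------------------------------------------------------------------------
# DAG corpus I/O
# ---------------------------------------------------------------------------


def read_dag_corpus(path, dialect: str = "edge-list") -> DagCorpus:
    """Read per-disease ancestor DAGs.

    dialect ``edge-list``
        Three-column TSV ``disease-id TAB parent-descriptor TAB
        child-descriptor``; one-column lines declare a disease whose DAG
        is just its own descriptor.
    dialect ``mesh-tree-numbers``
        Lines ``descriptor-name;tree-number``.  Every descriptor becomes
        a disease; ancestry follows tree-number prefix truncation at the
        ``.`` separators (C01.100 is a child of C01).
    """
    if dialect not in ("edge-list", "mesh-tree-numbers"):
        raise ValueError(f"unknown DAG corpus dialect: {dialect!r}")
    lines = _data_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty DAG corpus")
    if dialect == "edge-list":
        dags: dict[str, nx.DiGraph] = {}
        for number, line in lines:
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) == 1:
                disease = normalize_id(fields[0])
                dags.setdefault(disease, nx.DiGraph()).add_node(disease)
                continue
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{number}: expected 3 columns "
                    f"(disease, parent, child), got {len(fields)}"
                )
            disease, parent, child = (normalize_id(f) for f in fields)
            dag = dags.setdefault(disease, nx.DiGraph())
            dag.add_node(disease)
            dag.add_edge(parent, child)
        corpus_dags = dags
    else:
        tree_to_name: dict[str, str] = {}
        name_trees: dict[str, list[str]] = {}
        for number, line in lines:
            if ";" not in line:
                raise ParseError(
                    f"{path}:{number}: expected 'descriptor-name;tree-number'"
                )
            name, _, tree = line.partition(";")
            name = normalize_id(name)
            tree = tree.strip()
            if not name or not tree:
                raise ParseError(f"{path}:{number}: empty descriptor or tree number")
            tree_to_name[tree] = name
            name_trees.setdefault(name, []).append(tree)
        corpus_dags = {}
        for name, trees in name_trees.items():
            dag = nx.DiGraph()
            dag.add_node(name)
            stack = list(trees)
            while stack:
                tree = stack.pop()
                child_name = tree_to_name[tree]
                if "." not in tree:
                    continue
                parent_tree = tree.rsplit(".", 1)[0]
                if parent_tree not in tree_to_name:
                    raise ParseError(
                        f"{path}: tree number {parent_tree!r} (ancestor of "
                        f"{tree!r}) has no descriptor line"
                    )
                parent_name = tree_to_name[parent_tree]
                dag.add_edge(parent_name, child_name)
                stack.append(parent_tree)
            corpus_dags[name] = dag

    for disease, dag in corpus_dags.items():
        if not nx.is_directed_acyclic_graph(dag):
            raise ParseError(f"{path}: cycle detected in DAG for {disease!r}")
        if disease not in dag:
            raise ParseError(
                f"{path}: DAG for {disease!r} lacks its own descriptor"
            )
    return DagCorpus(dags=corpus_dags)


# ---------------------------------------------------------------------------
# score output
# ---------------------------------------------------------------------------

_SCORE_COLUMNS = ["mirna_id", "disease_id", "score", "association_type", "known"]


def write_scores(bundle, index: EntityIndex, path) -> None:
    """Write final scores as a 5-column TSV sorted by score descending.

    Columns: miRNA id, disease id, final score Sf, association type
    (strong / potential / none, where 'potential' means at least one
    direction found a linked nearest neighbour), and a 0/1 known flag.
    Scores are printed at 12 significant digits so the file round-trips
    through :func:`read_scores` exactly at that precision.
    """
    from .scoring import combined_type_labels  # local import: avoid cycle

    sf = np.asarray(bundle.Sf, dtype=float)
    if np.isnan(sf).any():
        raise ValidationError("refusing to write scores containing NaN")
    labels = combined_type_labels(bundle)
    known = np.asarray(bundle.known, dtype=int)
    rows = []
    for g in range(index.n_mirnas):
        for h in range(index.n_diseases):
            rows.append(
                (
                    index.mirna_ids[g],
                    index.disease_ids[h],
                    sf[g, h],
                    labels[g, h],
                    known[g, h],
                )
            )
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(_SCORE_COLUMNS) + "\n")
        for mirna, disease, score, label, flag in rows:
            handle.write(f"{mirna}\t{disease}\t{score:.12g}\t{label}\t{flag}\n")


def read_scores(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _SCORE_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing score columns {missing}")
    return frame
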