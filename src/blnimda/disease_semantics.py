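"""Disease semantic similarity from MeSH-style ancestor DAGs.

Two complementary frames quantify how much each ancestor descriptor
contributes to a disease's semantics:

* frame I (decay-based): the disease's own descriptor contributes 1 and
  every ancestor contributes ``delta`` times the best contribution among
  its children inside the disease's DAG, so contributions decay
  geometrically with distance from the disease node;
* frame II (information-content): a descriptor contributes
  ``-log(N_l / N)`` where ``N_l`` of the ``N`` disease DAGs in the
  corpus contain it, so descriptors shared by many diseases contribute
  little and rare ones a lot.

Each frame turns contributions into a pairwise similarity by summing the
two diseases' contributions over their shared descriptors and dividing
by the sum of their total semantic values; the reported disease semantic
similarity is the average of the two frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data_io import DagCorpus, SimilarityMatrix, ValidationError

__all__ = [
    "ContributionMap",
    "ds1_contributions",
    "semantic_value_frame1",
    "similarity_frame1",
    "ds2_contributions",
    "semantic_value_frame2",
    "similarity_frame2",
    "semantic_similarity_matrix",
]


@dataclass(frozen=True)
class ContributionMap:
    """Per-descriptor semantic contribution values for one disease DAG."""

    disease: str
    values: dict[str, float]
    frame: str  # "decay" or "information-content"

    def total(self) -> float:
        """Semantic value of the disease: sum of all contributions."""
        return float(sum(self.values.values()))


def _check_dag(dag: nx.DiGraph, disease: str) -> None:
    if disease not in dag:
        raise ValidationError(
            f"DAG for {disease!r} lacks the disease's own descriptor"
        )
    if not nx.is_directed_acyclic_graph(dag):
        raise ValidationError(f"cycle detected in DAG for {disease!r}")


def ds1_contributions(
    dag: nx.DiGraph, disease: str, delta: float = 0.5
) -> ContributionMap:
    """Decay-based contributions: 1 at the disease, delta-attenuated above.

    Evaluated in reverse-topological order from the disease node; every
    non-disease descriptor takes ``delta`` times the maximum contribution
    among its children *within this disease's DAG*.
    """
    _check_dag(dag, disease)
    values: dict[str, float] = {}
    for node in reversed(list(nx.topological_sort(dag))):
        if node == disease:
            values[node] = 1.0
            continue
        children = [c for c in dag.successors(node) if c in values]
        if not children:
            raise ValidationError(
                f"descriptor {node!r} in DAG for {disease!r} has no "
                f"descendant path to the disease node (malformed ancestor DAG)"
            )
        values[node] = delta * max(values[c] for c in children)
    return ContributionMap(disease, values, "decay")


def semantic_value_frame1(
    dag: nx.DiGraph, disease: str, delta: float = 0.5
) -> float:
    """Total decay-based semantic value DV1 of a disease."""
    return ds1_contributions(dag, disease, delta).total()


def _shared_ratio(cm_g: ContributionMap, cm_h: ContributionMap) -> float:
    shared = cm_g.values.keys() & cm_h.values.keys()
    denominator = cm_g.total() + cm_h.total()
    if denominator == 0.0:
        return 0.0
    numerator = sum(cm_g.values[c] + cm_h.values[c] for c in shared)
    return numerator / denominator


def similarity_frame1(
    dag_g: nx.DiGraph,
    disease_g: str,
    dag_h: nx.DiGraph,
    disease_h: str,
    delta: float = 0.5,
) -> float:
    """Decay-frame similarity: shared-descriptor contributions over DV1 sum."""
    return _shared_ratio(
        ds1_contributions(dag_g, disease_g, delta),
        ds1_contributions(dag_h, disease_h, delta),
    )


def ds2_contributions(
    dag: nx.DiGraph, disease: str, corpus: DagCorpus
) -> ContributionMap:
    """Information-content contributions -log(N_l / N), natural log."""
    _check_dag(dag, disease)
    values: dict[str, float] = {}
    for node in dag.nodes:
        df = corpus.descriptor_df.get(node)
        if df is None or df <= 0:
            raise ValidationError(
                f"descriptor {node!r} has no frequency in the corpus"
            )
        values[node] = -math.log(df / corpus.corpus_size)
    return ContributionMap(disease, values, "information-content")


def semantic_value_frame2(dag: nx.DiGraph, disease: str, corpus: DagCorpus) -> float:
    """Total information-content semantic value DV2 of a disease."""
    return ds2_contributions(dag, disease, corpus).total()


def similarity_frame2(
    dag_g: nx.DiGraph,
    disease_g: str,
    dag_h: nx.DiGraph,
    disease_h: str,
    corpus: DagCorpus,
) -> float:
    """Information-content-frame similarity.

    When both diseases consist solely of ubiquitous descriptors (every
    contribution 0) the ratio is 0/0 and the similarity is defined as 0.
    """
    return _shared_ratio(
        ds2_contributions(dag_g, disease_g, corpus),
        ds2_contributions(dag_h, disease_h, corpus),
    )


def semantic_similarity_matrix(
    corpus: DagCorpus, delta: float = 0.5
) -> SimilarityMatrix:
    """Average of the two frames over all disease pairs in the corpus.

    The diagonal is reported as 1: both frames give 1 on identical DAGs,
    except the degenerate all-ubiquitous-descriptor case of frame II
    (self similarity (1 + 0)/2); the diagonal is forced to 1 regardless.
    """
    ids = corpus.disease_ids
    n = len(ids)
    cm1 = {d: ds1_contributions(corpus.dags[d], d, delta) for d in ids}
    cm2 = {d: ds2_contributions(corpus.dags[d], d, corpus) for d in ids}
    values = np.eye(n)
    for g in range(n):
        for h in range(g + 1, n):
            sd1 = _shared_ratio(cm1[ids[g]], cm1[ids[h]])
            sd2 = _shared_ratio(cm2[ids[g]], cm2[ids[h]])
            values[g, h] = values[h, g] = 0.5 * (sd1 + sd2)
    return SimilarityMatrix(values, ids, "semantic")
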