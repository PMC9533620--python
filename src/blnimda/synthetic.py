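"""Planted-structure synthetic data for end-to-end testing.

The generator emulates the working premise of association prediction:
functionally similar miRNAs tend to partner with semantically similar
diseases.  miRNAs and diseases are partitioned into aligned blocks;
links are dense inside matched blocks and sparse elsewhere, miRNA
functional similarity is high within blocks and low across them (plus
clipped symmetric noise), and the disease DAG corpus gives same-block
diseases a shared ancestor chain (root -> block node -> disease) while
cross-block diseases share only the root.  A fraction of similarity
entries is marked unavailable to exercise the kernel fallback of the
integration step.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import networkx as nx
import numpy as np

from .data_io import (
    AssociationMatrix,
    DagCorpus,
    EntityIndex,
    Params,
    SimilarityMatrix,
    ValidationError,
)

__all__ = ["SyntheticSpec", "SyntheticData", "generate", "worked_example", "WorkedExample"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-block generator.

    Defaults describe a small but clearly structured problem: 30 miRNAs
    and 20 diseases in 3 aligned blocks, dense (0.6) within-block links
    over a sparse (0.02) background, well-separated similarity levels
    (0.8 within vs 0.1 between, noise 0.05) and 20% of functional
    similarity entries withheld so the kernel fallback is exercised.
    Setting ``within_sim == between_sim`` together with
    ``density == background_density`` yields a signal-free null.
    """

    n_m: int = 30
    n_d: int = 20
    n_blocks: int = 3
    within_sim: float = 0.8
    between_sim: float = 0.1
    density: float = 0.6
    background_density: float = 0.02
    sim_noise: float = 0.05
    missing_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_density <= self.density <= 1:
            raise ValidationError(
                "need 0 <= background_density <= density <= 1"
            )
        if not 0 <= self.between_sim <= self.within_sim <= 1:
            raise ValidationError("need 0 <= between_sim <= within_sim <= 1")
        if min(self.n_m, self.n_d) < self.n_blocks or self.n_blocks < 1:
            raise ValidationError("entity counts must be >= n_blocks >= 1")
        if self.sim_noise < 0 or not 0 <= self.missing_frac <= 1:
            raise ValidationError("sim_noise >= 0 and missing_frac in [0, 1]")


@dataclass
class SyntheticData:
    """One generated dataset plus the spec it came from."""

    associations: AssociationMatrix
    mirna_similarity: SimilarityMatrix
    mirna_availability: np.ndarray
    corpus: DagCorpus
    spec: SyntheticSpec

    def manifest(self) -> dict:
        return {"generator": "planted-block", "spec": asdict(self.spec)}


def _block_assignment(n: int, n_blocks: int) -> np.ndarray:
    assignment = np.empty(n, dtype=int)
    for block, chunk in enumerate(np.array_split(np.arange(n), n_blocks)):
        assignment[chunk] = block
    return assignment


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Draw one dataset from the planted-block model."""
    rng = np.random.default_rng(spec.seed)
    mirna_ids = tuple(f"mir-{i + 1:03d}" for i in range(spec.n_m))
    disease_ids = tuple(f"dis-{j + 1:03d}" for j in range(spec.n_d))
    index = EntityIndex(mirna_ids, disease_ids)
    m_block = _block_assignment(spec.n_m, spec.n_blocks)
    d_block = _block_assignment(spec.n_d, spec.n_blocks)

    same_block = m_block[:, None] == d_block[None, :]
    link_prob = np.where(same_block, spec.density, spec.background_density)
    A = AssociationMatrix(
        (rng.random((spec.n_m, spec.n_d)) < link_prob).astype(np.int8), index
    )

    # functional similarity: block levels + symmetric noise, clipped, diag 1
    base = np.where(
        m_block[:, None] == m_block[None, :], spec.within_sim, spec.between_sim
    ).astype(float)
    noise = rng.normal(0.0, spec.sim_noise, size=base.shape)
    noise = np.triu(noise, 1)
    noise = noise + noise.T
    sims = np.clip(base + noise, 0.0, 1.0)
    np.fill_diagonal(sims, 1.0)
    mirna_similarity = SimilarityMatrix(sims, mirna_ids, "functional")

    # symmetric availability mask dropping missing_frac of off-diagonal pairs
    upper = np.triu_indices(spec.n_m, 1)
    drop = rng.random(len(upper[0])) < spec.missing_frac
    availability = np.ones((spec.n_m, spec.n_m), dtype=bool)
    availability[upper[0][drop], upper[1][drop]] = False
    availability[upper[1][drop], upper[0][drop]] = False

    # DAG corpus: root -> block node -> disease (depth-3 ancestry)
    dags: dict[str, nx.DiGraph] = {}
    for j, disease in enumerate(disease_ids):
        dag = nx.DiGraph()
        block_node = f"block-{d_block[j]}"
        dag.add_edge("root", block_node)
        dag.add_edge(block_node, disease)
        dags[disease] = dag
    corpus = DagCorpus(dags=dags)

    return SyntheticData(A, mirna_similarity, availability, corpus, spec)


@dataclass(frozen=True)
class WorkedExample:
    """A hand-checkable 3 miRNA x 2 disease instance with frozen expectations.

    Inputs are the integrated similarities and association matrix of the
    smallest instance that exercises every scoring branch; the expected
    intermediates were computed once with the naive per-pair reference
    scorer and are frozen here as regression anchors.
    """

    associations: AssociationMatrix
    fms: SimilarityMatrix
    fds: SimilarityMatrix
    params: Params
    expected_S1: np.ndarray
    expected_S2: np.ndarray
    expected_Wr: np.ndarray
    expected_Wd: np.ndarray
    expected_Sd: np.ndarray
    expected_Sr: np.ndarray
    expected_Sf: np.ndarray


def worked_example() -> WorkedExample:
    """The fixed 3x2 instance: one potential pair per direction, T = 0.5."""
    e = np.e
    index = EntityIndex(("m1", "m2", "m3"), ("d1", "d2"))
    A = AssociationMatrix(np.array([[0, 1], [1, 1], [1, 0]]), index)
    fms = SimilarityMatrix(
        np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]]),
        index.mirna_ids,
        "integrated",
    )
    fds = SimilarityMatrix(
        np.array([[1.0, 0.3], [0.3, 1.0]]), index.disease_ids, "integrated"
    )
    params = Params(T=0.5)
    expected_S1 = np.array([[0.9, 1.0], [5.0 / 6.0, 1.0], [5.0 / 6.0, 0.0]])
    expected_S2 = np.array([[0.0, 1.0 / 1.3, 1.0], [1.0, 1.0 / 1.3, 0.0]])
    expected_Wr = np.array(
        [[np.exp(0.9), e], [e, e], [e, np.exp(0.2)]]
    )
    expected_Wd = np.array([[np.exp(0.3), e, e], [e, e, np.exp(0.3)]])
    expected_Sd = expected_S1 * expected_Wr
    expected_Sr = (expected_S2 * expected_Wd).T
    expected_Sf = 0.5 * (expected_Sd + expected_Sr)
    return WorkedExample(
        associations=A,
        fms=fms,
        fds=fds,
        params=params,
        expected_S1=expected_S1,
        expected_S2=expected_S2,
        expected_Wr=expected_Wr,
        expected_Wd=expected_Wd,
        expected_Sd=expected_Sd,
        expected_Sr=expected_Sr,
        expected_Sf=expected_Sf,
    )
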