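"""Gaussian interaction-profile (GIP) kernels and similarity integration.

A miRNA's interaction profile is its row of the binary association
matrix (a disease's profile is its column).  The GIP kernel between two
entities is ``exp(-beta * ||profile difference||^2)`` with the bandwidth
``beta = beta_star / mean(||profile||^2)`` adapted to the density of the
current association matrix.  Because profiles are binary the squared
norm is simply the entity's degree, and the kernel decreases with the
Hamming distance between profiles.

Functional (miRNA) or semantic (disease) similarity, where available,
takes precedence; pairs without it fall back to the kernel.  That
cell-wise selection is the similarity "integration" step, driven by a
symmetric availability mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import (
    AssociationMatrix,
    DagCorpus,
    Params,
    SimilarityMatrix,
    ValidationError,
    subset_similarity,
)
from .disease_semantics import semantic_similarity_matrix

__all__ = [
    "DegenerateBandwidthError",
    "KernelBandwidth",
    "gip_bandwidth",
    "gip_similarity",
    "default_availability",
    "integrate_similarity",
    "SimilarityInputs",
    "integrated_similarities",
]


class DegenerateBandwidthError(ValueError):
    """All interaction profiles are empty, so the bandwidth is undefined."""


@dataclass(frozen=True)
class KernelBandwidth:
    """Effective GIP bandwidth beta = beta_star / mean squared profile norm."""

    beta: float
    beta_star: float
    mean_profile_norm: float


def _profiles(A: AssociationMatrix, axis: str) -> np.ndarray:
    if axis == "mirna":
        return A.values.astype(float)
    if axis == "disease":
        return A.values.T.astype(float)
    raise ValueError(f"axis must be 'mirna' or 'disease', got {axis!r}")


def gip_bandwidth(
    A: AssociationMatrix, axis: str, beta_star: float = 1.0
) -> KernelBandwidth:
    """Adaptive bandwidth over the rows (miRNAs) or columns (diseases) of A."""
    profiles = _profiles(A, axis)
    mean_norm = float((profiles**2).sum() / profiles.shape[0])
    if mean_norm == 0.0:
        raise DegenerateBandwidthError(
            "all interaction profiles are empty (association matrix has no "
            "links); supply at least one association or a precomputed "
            "similarity matrix instead of the kernel"
        )
    return KernelBandwidth(beta_star / mean_norm, beta_star, mean_norm)


def gip_similarity(
    A: AssociationMatrix, axis: str, beta_star: float = 1.0
) -> SimilarityMatrix:
    """GIP kernel matrix exp(-beta * ||IP(x) - IP(y)||^2) for one axis."""
    bandwidth = gip_bandwidth(A, axis, beta_star)
    profiles = _profiles(A, axis)
    norms = (profiles**2).sum(axis=1)
    # binary profiles: squared distance = deg(x) + deg(y) - 2 <x, y>
    sq_dist = norms[:, None] + norms[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(sq_dist, 0.0, out=sq_dist)
    values = np.exp(-bandwidth.beta * sq_dist)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    ids = A.index.mirna_ids if axis == "mirna" else A.index.disease_ids
    return SimilarityMatrix(values, ids, "gip")


def default_availability(primary: SimilarityMatrix) -> np.ndarray:
    """Pairs considered to *have* primary similarity: stored value > 0.

    Public similarity releases encode "unknown" as 0, so a strictly
    positive entry is taken as evidence the pair was actually scored.
    """
    return primary.values > 0.0


def integrate_similarity(
    primary: SimilarityMatrix | None,
    kernel: SimilarityMatrix,
    availability: np.ndarray | None = None,
) -> SimilarityMatrix:
    """Cell-wise selection: primary where available, kernel elsewhere."""
    if primary is None:
        return SimilarityMatrix(kernel.values.copy(), kernel.ids, "integrated")
    if primary.ids != kernel.ids:
        raise ValidationError(
            "primary and kernel similarity matrices index different entities"
        )
    if availability is None:
        availability = default_availability(primary)
    availability = np.asarray(availability, dtype=bool)
    if availability.shape != primary.values.shape:
        raise ValidationError(
            f"availability mask shape {availability.shape} does not match "
            f"similarity shape {primary.values.shape}"
        )
    if not np.array_equal(availability, availability.T):
        raise ValidationError("availability mask must be symmetric")
    values = np.where(availability, primary.values, kernel.values)
    return SimilarityMatrix(values, kernel.ids, "integrated")


@dataclass
class SimilarityInputs:
    """The fixed (association-independent) similarity inputs of a run.

    Exactly one of ``disease_semantic`` / ``corpus`` should normally be
    supplied; when a corpus is given the semantic matrix is derived from
    it once.  Either primary similarity may be absent, in which case the
    corresponding integrated similarity is the pure GIP kernel.
    """

    mirna_functional: SimilarityMatrix | None = None
    mirna_availability: np.ndarray | None = None
    disease_semantic: SimilarityMatrix | None = None
    disease_availability: np.ndarray | None = None

    @classmethod
    def from_corpus(
        cls,
        corpus: DagCorpus,
        index,
        mirna_functional: SimilarityMatrix | None = None,
        mirna_availability: np.ndarray | None = None,
        delta: float = 0.5,
    ) -> "SimilarityInputs":
        semantic = semantic_similarity_matrix(corpus, delta)
        semantic, coverage = subset_similarity(semantic, index.disease_ids)
        availability = coverage & default_availability(semantic)
        np.fill_diagonal(availability, True)
        return cls(
            mirna_functional=mirna_functional,
            mirna_availability=mirna_availability,
            disease_semantic=semantic,
            disease_availability=availability,
        )


def integrated_similarities(
    A: AssociationMatrix,
    inputs: SimilarityInputs,
    params: Params | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Integrated miRNA (FMS) and disease (FDS) similarity for the given A.

    The kernels are recomputed from the association matrix passed in, so
    cross-validation callers that mask held-out links get bandwidths and
    profiles free of those links.
    """
    params = params or Params()
    km = gip_similarity(A, "mirna", params.beta_star_m)
    kd = gip_similarity(A, "disease", params.beta_star_d)
    fms = integrate_similarity(inputs.mirna_functional, km, inputs.mirna_availability)
    fds = integrate_similarity(inputs.disease_semantic, kd, inputs.disease_availability)
    return fms, fds
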