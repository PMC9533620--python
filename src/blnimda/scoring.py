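"""The weighted bi-level network score.

Each miRNA-disease pair is scored from two directions.  In the
miRNA-to-disease direction the *information property* of pair (g, h) is

    S1(g, h) = sum_k HM(g, k) A(k, h)  /  sum_k FMS(g, k) A(k, h)

where FMS is the integrated miRNA similarity and HM is FMS with entries
below the weak-similarity threshold T zeroed; it measures how much of
the similarity mass connecting g to the known partners of h survives
the threshold.  Every pair is also assigned an association *type*:

* strong     -- (g, h) is itself a known link; type weight exp(1) = e,
* potential  -- g's most similar other miRNA m_s is linked to h; type
                weight exp(FMS(g, m_s)),
* none       -- otherwise; type weight 0.

The directional affinity is the elementwise product of information
property and type weight; the final score Sf is the average of the two
directional affinities, so Sf lies in [0, e] and is 0 exactly when
neither direction finds any supporting link.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .data_io import AssociationMatrix, Params, SimilarityMatrix, ValidationError

__all__ = [
    "AssociationType",
    "ScoreBundle",
    "threshold_filter",
    "info_property",
    "nearest_neighbor",
    "nearest_neighbors",
    "type_weight",
    "affinity",
    "final_score",
    "score_pipeline",
    "combined_type_labels",
]


class AssociationType(IntEnum):
    """Per-direction association category of a miRNA-disease pair."""

    NONE = 0
    POTENTIAL = 1
    STRONG = 2

    @property
    def label(self) -> str:
        return self.name.lower()


def _values(F) -> np.ndarray:
    return F.values if isinstance(F, SimilarityMatrix) else np.asarray(F, float)


def threshold_filter(F, T: float) -> np.ndarray:
    """Zero out entries below the weak-similarity threshold T (inclusive keep)."""
    if T < 0:
        raise ValidationError("threshold T must be >= 0")
    values = _values(F)
    return np.where(values >= T, values, 0.0)


def info_property(A_view: np.ndarray, F, T: float) -> np.ndarray:
    """Information property S over source-rows x target-columns.

    ``A_view`` is the association matrix oriented so that rows are the
    source axis of ``F`` (miRNAs for S1, diseases for S2).  Targets with
    no known source partner yield 0/0, defined as 0: no evidence
    contributes no affinity.  The sums include k = g; the self term only
    enters for already-known pairs.
    """
    A_view = np.asarray(A_view, float)
    F_values = _values(F)
    if F_values.shape[0] != A_view.shape[0]:
        raise ValidationError(
            f"similarity rows ({F_values.shape[0]}) do not match association "
            f"source rows ({A_view.shape[0]})"
        )
    H = threshold_filter(F_values, T)
    numerator = H @ A_view
    denominator = F_values @ A_view
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denominator > 0.0, numerator / np.where(denominator > 0, denominator, 1.0), 0.0)
    return S


def nearest_neighbors(F) -> np.ndarray:
    """Index of the most similar *other* entity for every row of F.

    Self-similarity is excluded (it is 1 by construction and would make
    the potential branch unsatisfiable); ties break to the smallest
    index for determinism.
    """
    values = _values(F)
    n = values.shape[0]
    if n < 2:
        raise ValidationError("nearest neighbour needs at least 2 entities")
    masked = values.astype(float).copy()
    np.fill_diagonal(masked, -np.inf)
    return np.argmax(masked, axis=1)


def nearest_neighbor(F, g: int) -> int:
    """Most similar entity to g, excluding g itself (ties: smallest index)."""
    return int(nearest_neighbors(F)[g])


def type_weight(A_view: np.ndarray, F) -> tuple[np.ndarray, np.ndarray]:
    """Exponential type weights and association types, source x target.

    Returns ``(W, types)`` where W(g, h) is e for known links,
    exp(F(g, s_g)) when the nearest neighbour s_g of g is linked to h,
    and 0 otherwise; ``types`` holds the matching AssociationType codes.
    The nearest neighbour is taken over the unthresholded similarity.
    """
    A_view = np.asarray(A_view)
    F_values = _values(F)
    neighbors = nearest_neighbors(F_values)
    strong = A_view != 0
    neighbor_linked = A_view[neighbors, :] != 0
    potential = ~strong & neighbor_linked
    neighbor_sim = F_values[np.arange(F_values.shape[0]), neighbors]
    W = np.where(
        strong, np.e, np.where(potential, np.exp(neighbor_sim)[:, None], 0.0)
    )
    types = np.zeros(A_view.shape, dtype=np.int8)
    types[potential] = AssociationType.POTENTIAL
    types[strong] = AssociationType.STRONG
    return W, types


def affinity(S: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Directional affinity: elementwise product of S and W."""
    S = np.asarray(S, float)
    W = np.asarray(W, float)
    if S.shape != W.shape:
        raise ValidationError(
            f"information property shape {S.shape} does not match type "
            f"weight shape {W.shape}"
        )
    return S * W


def final_score(Sd: np.ndarray, Sr: np.ndarray) -> np.ndarray:
    """Average of the two directional affinities (both miRNA x disease)."""
    Sd = np.asarray(Sd, float)
    Sr = np.asarray(Sr, float)
    if Sd.shape != Sr.shape:
        raise ValidationError(
            f"affinity shapes differ after realignment: {Sd.shape} vs {Sr.shape}"
        )
    return 0.5 * (Sd + Sr)


@dataclass
class ScoreBundle:
    """All intermediates of one scoring run.

    ``S2``, ``Wd`` and ``types_d2m`` are stored in their native
    disease x miRNA orientation; ``Sr`` is the disease-to-miRNA affinity
    already transposed to miRNA x disease so that ``Sf = (Sd + Sr) / 2``
    holds elementwise.
    """

    S1: np.ndarray
    S2: np.ndarray
    Wr: np.ndarray
    Wd: np.ndarray
    Sd: np.ndarray
    Sr: np.ndarray
    Sf: np.ndarray
    types_m2d: np.ndarray
    types_d2m: np.ndarray
    known: np.ndarray = field(default=None)  # type: ignore[assignment]


def score_pipeline(
    A: AssociationMatrix,
    FMS: SimilarityMatrix,
    FDS: SimilarityMatrix,
    params: Params | None = None,
) -> ScoreBundle:
    """Run the full bidirectional scoring pass and return all intermediates."""
    params = params or Params()
    if FMS.n != A.index.n_mirnas:
        raise ValidationError("miRNA similarity size does not match association rows")
    if FDS.n != A.index.n_diseases:
        raise ValidationError("disease similarity size does not match association columns")

    # miRNA -> disease direction
    S1 = info_property(A.values, FMS, params.T)
    Wr, types_m2d = type_weight(A.values, FMS)
    Sd = affinity(S1, Wr)

    # disease -> miRNA direction on the transposed association view
    A_t = A.values.T
    S2 = info_property(A_t, FDS, params.T)
    Wd, types_d2m = type_weight(A_t, FDS)
    Sr = affinity(S2, Wd).T  # realigned to miRNA rows x disease columns

    Sf = final_score(Sd, Sr)
    return ScoreBundle(
        S1=S1,
        S2=S2,
        Wr=Wr,
        Wd=Wd,
        Sd=Sd,
        Sr=Sr,
        Sf=Sf,
        types_m2d=types_m2d,
        types_d2m=types_d2m,
        known=A.values.copy(),
    )


def combined_type_labels(bundle: ScoreBundle) -> np.ndarray:
    """Direction-combined type label per pair.

    A pair is ``strong`` iff it is a known link (both directions agree),
    ``potential`` if at least one direction found a linked nearest
    neighbour, ``none`` otherwise.
    """
    m2d = np.asarray(bundle.types_m2d)
    d2m = np.asarray(bundle.types_d2m).T
    combined = np.maximum(m2d, d2m)
    labels = np.empty(combined.shape, dtype=object)
    for code in AssociationType:
        labels[combined == code] = code.label
    return labels
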