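"""Fixed-size evolutionary features from variable-length PSSMs.

A protein of length L yields an L x 20 PSSM; the cross-product P^T . P is a
20 x 20 summary of co-occurring substitution propensities that no longer
depends on L.  Flattened row-major it gives a 400-dimensional protein
vector; a pair of proteins is represented by the 800-dimensional
concatenation of the two protein vectors.

Raw log-odds products grow quadratically with sequence length and
unboundedly with score magnitude, which destabilizes downstream
autoencoder training, so by default each score is squashed through the
logistic function before the cross-product and the result is divided by L.
Both steps can be switched off to recover the literal cross-product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import PairTable, PSSMatrix

PROTEIN_DIM = 400
PAIR_DIM = 800


@dataclass(frozen=True)
class FeaturizationSettings:
    """How PSSM scores are preprocessed around the cross-product.

    elementwise_transform
        ``"logistic"`` squashes each score x to 1/(1+e^-x) before the
        cross-product (bounded features); ``"none"`` uses raw scores.
    length_normalization
        ``"divide_by_L"`` divides the 20 x 20 cross-product by sequence
        length (length-comparable features); ``"none"`` leaves it raw.
    """

    elementwise_transform: str = "logistic"
    length_normalization: str = "divide_by_L"

    def __post_init__(self) -> None:
        if self.elementwise_transform not in ("none", "logistic"):
            raise ValueError(
                f"unknown elementwise_transform {self.elementwise_transform!r}"
            )
        if self.length_normalization not in ("none", "divide_by_L"):
            raise ValueError(
                f"unknown length_normalization {self.length_normalization!r}"
            )

    def to_dict(self) -> dict:
        return {
            "elementwise_transform": self.elementwise_transform,
            "length_normalization": self.length_normalization,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeaturizationSettings":
        return cls(**dict(d))


#: The literal cross-product with no preprocessing.
RAW_SETTINGS = FeaturizationSettings("none", "none")


@dataclass(frozen=True)
class ProteinFeatureVector:
    """The 400-dimensional row-major flattening of the 20 x 20 cross-product."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (PROTEIN_DIM,):
            raise ValueError(f"expected shape ({PROTEIN_DIM},), got {values.shape}")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class PairFeatureVector:
    """Concatenation A || B of two protein vectors, in pair-table order."""

    pair_id: tuple[str, str]
    values: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (PAIR_DIM,):
            raise ValueError(f"expected shape ({PAIR_DIM},), got {values.shape}")
        object.__setattr__(self, "values", values)


def transform_pssm(
    pssm: PSSMatrix, settings: FeaturizationSettings = FeaturizationSettings()
) -> ProteinFeatureVector:
    """Map one PSSM to its 400-dimensional cross-product feature vector.

    With Q the (optionally logistic-squashed) score matrix, the feature
    matrix is M = Q^T . Q, optionally divided by L, flattened row-major.
    """
    P = pssm.scores
    bad = ~np.isfinite(P)
    if bad.any():
        t, j = np.argwhere(bad)[0]
        raise ValueError(
            f"PSSM {pssm.protein_id!r}: non-finite score at position "
            f"{t}, column {j}"
        )
    if settings.elementwise_transform == "logistic":
        Q = 1.0 / (1.0 + np.exp(-P))
    else:
        Q = P
    M = Q.T @ Q
    if settings.length_normalization == "divide_by_L":
        M = M / pssm.length
    return ProteinFeatureVector(protein_id=pssm.protein_id, values=M.ravel(order="C"))


def build_pair_vector(
    a: ProteinFeatureVector,
    b: ProteinFeatureVector,
    label: int | None = None,
) -> PairFeatureVector:
    """Concatenate two protein vectors into an 800-dimensional pair vector."""
    if a.values.shape != (PROTEIN_DIM,) or b.values.shape != (PROTEIN_DIM,):
        raise ValueError("both protein vectors must have length 400")
    return PairFeatureVector(
        pair_id=(a.protein_id, b.protein_id),
        values=np.concatenate([a.values, b.values]),
        label=label,
    )


def featurize_dataset(
    pairs: PairTable,
    pssm_lookup: Mapping[str, PSSMatrix],
    settings: FeaturizationSettings = FeaturizationSettings(),
) -> list[PairFeatureVector]:
    """One pair vector per pair-table row, order preserved.

    Each protein's cross-product transform is computed once and cached.
    Unresolvable ids raise a ``KeyError`` listing every missing id.
    """
    needed = pairs.protein_ids()
    missing = [pid for pid in needed if pid not in pssm_lookup]
    if missing:
        raise KeyError(f"pairs reference unknown protein ids: {sorted(missing)}")
    cache: dict[str, ProteinFeatureVector] = {
        pid: transform_pssm(pssm_lookup[pid], settings) for pid in needed
    }
    return [
        build_pair_vector(cache[row.id_a], cache[row.id_b], row.label)
        for row in pairs
    ]


def augment_with_swaps(
    vectors: Sequence[PairFeatureVector],
) -> list[PairFeatureVector]:
    """Append the B || A copy of every pair vector (labels carried over).

    The pair representation is order-dependent; this symmetrizes TRAINING
    data only — never apply it to evaluation pairs, or metrics would
    count each pair twice.
    """
    out = list(vectors)
    for v in vectors:
        out.append(
            PairFeatureVector(
                pair_id=(v.pair_id[1], v.pair_id[0]),
                values=np.concatenate(
                    [v.values[PROTEIN_DIM:], v.values[:PROTEIN_DIM]]
                ),
                label=v.label,
            )
        )
    return out


def feature_matrix(
    vectors: Sequence[PairFeatureVector],
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Stack pair vectors into (X, y, pair ids) arrays for model fitting."""
    X = np.stack([v.values for v in vectors]) if vectors else np.empty((0, PAIR_DIM))
    y = np.array([-1 if v.label is None else v.label for v in vectors], dtype=int)
    ids = [v.pair_id for v in vectors]
    return X, y, ids
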