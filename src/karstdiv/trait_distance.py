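"""Species x species trait dissimilarity matrices bounded in [0, 1].

Trait columns are first range-standardized to [0, 1] over the whole
species pool, so that distances are comparable across restoration stages
and the pairwise dissimilarity d_ij is guaranteed to lie in [0, 1] —
the bound Rao's quadratic entropy needs for functional redundancy
(SD - FD) to be nonnegative.

Two dissimilarities are provided:

* ``gower`` (default): d_ij = mean over traits of |x_it - x_jt|
  (Gower's coefficient for purely quantitative traits);
* ``scaled-euclidean``: Euclidean distance on standardized traits
  divided by sqrt(T), which also maps into [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .community_model import TraitTable, ValidationError

METHODS = ("gower", "scaled-euclidean")


@dataclass
class DistanceMatrix:
    """Symmetric species dissimilarity matrix with entries in [0, 1]."""

    species: list[str]
    d: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.species)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix must be square over the species axis")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix must have a zero diagonal")
        if (self.d < -1e-12).any() or (self.d > 1 + 1e-12).any():
            raise ValidationError("distances must lie in [0, 1]")
        self.d = np.clip(self.d, 0.0, 1.0)

    def subset(self, species: list[str]) -> "DistanceMatrix":
        idx = {s: i for i, s in enumerate(self.species)}
        missing = [s for s in species if s not in idx]
        if missing:
            raise ValidationError(f"species missing from distance matrix: {missing}")
        rows = np.array([idx[s] for s in species])
        return DistanceMatrix(list(species), self.d[np.ix_(rows, rows)], self.method)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.species, columns=self.species)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="species")


def range_standardize(traits: TraitTable) -> TraitTable:
    """Map every trait column to [0, 1] via (x - min) / (max - min).

    A constant column carries no contrast and is mapped to all zeros
    with a warning. Standardization pools all species in the study so
    distances remain comparable across stages.
    """
    if len(traits.species) < 2:
        raise ValidationError("need at least 2 species to standardize for pairwise distances")
    x = traits.traits.astype(float).copy()
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = hi - lo
    const = span <= 0
    if const.any():
        from .community_model import TRAIT_COLUMNS

        names = [TRAIT_COLUMNS[i] for i in np.where(const)[0]]
        warnings.warn(
            f"constant trait column(s) {names} mapped to all-zeros (no contrast)",
            stacklevel=2,
        )
    span = np.where(const, 1.0, span)
    out = (x - lo) / span
    out[:, const] = 0.0
    return replace(traits, traits=out, provenance="range-standardized")


def _check_standardized(traits: TraitTable) -> np.ndarray:
    if traits.provenance != "range-standardized":
        raise ValidationError(
            "distance computation expects a range-standardized TraitTable; "
            "call range_standardize() first (or use compute_distance())"
        )
    x = traits.traits
    if np.isnan(x).any():
        raise ValidationError("NaN trait value in standardized table")
    return x


def gower_distance(traits: TraitTable) -> DistanceMatrix:
    """Gower dissimilarity: mean absolute difference over the T traits."""
    x = _check_standardized(traits)
    diff = np.abs(x[:, None, :] - x[None, :, :])
    d = diff.mean(axis=2)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(traits.species), d, "gower")


def scaled_euclidean_distance(traits: TraitTable) -> DistanceMatrix:
    """Euclidean distance on standardized traits, scaled by sqrt(T)."""
    x = _check_standardized(traits)
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2)) / np.sqrt(x.shape[1])
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(traits.species), d, "scaled-euclidean")


def compute_distance(traits: TraitTable, method: str = "gower") -> DistanceMatrix:
    """Standardize raw traits (if needed) and build the chosen distance."""
    if method not in METHODS:
        raise ValidationError(f"unknown distance method {method!r}; expected one of {METHODS}")
    if traits.provenance != "range-standardized":
        traits = range_standardize(traits)
    if method == "gower":
        return gower_distance(traits)
    return scaled_euclidean_distance(traits)
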