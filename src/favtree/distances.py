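"""The F distance family and symmetric distance matrices.

A calibrated distance F is the 16S-substitution-scale value assigned to one
ordered genome pair. Because similarity search is asymmetric, each unordered
pair {X, Y} carries two values, F_XY and F_YX; the five indices combine them:

    F_AV = (F_XY + F_YX) / 2      F_H = max(F_XY, F_YX)
    F_L  = min(F_XY, F_YX)        F_XY, F_YX = the named orientation

F_AV/F_H/F_L are symmetric by construction. For the orientation indices the
matrix is made symmetric by convention: "X" is the taxon that comes first in
the matrix label ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INDEX_TAGS = ("F_AV", "F_XY", "F_YX", "F_H", "F_L")


@dataclass
class FPair:
    """Calibrated distances for the two orientations of one genome pair."""

    f_xy: float
    f_yx: float

    def __post_init__(self) -> None:
        if self.f_xy < 0 or self.f_yx < 0:
            raise ValueError(f"F values must be non-negative: {self.f_xy}, {self.f_yx}")


def combine_F(pair: FPair, index_tag: str) -> float:
    """Collapse an orientation pair into one scalar distance."""
    if index_tag == "F_AV":
        return (pair.f_xy + pair.f_yx) / 2.0
    if index_tag == "F_H":
        return max(pair.f_xy, pair.f_yx)
    if index_tag == "F_L":
        return min(pair.f_xy, pair.f_yx)
    if index_tag == "F_XY":
        return pair.f_xy
    if index_tag == "F_YX":
        return pair.f_yx
    raise ValueError(f"unknown index tag {index_tag!r}; expected one of {INDEX_TAGS}")


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix for one F index (or any metric)."""

    labels: list[str]
    values: np.ndarray
    index_tag: str = "F_AV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def validate(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate taxon labels")
        if np.any(np.isnan(self.values)):
            raise ValueError("matrix contains NaN")
        if np.any(self.values < 0):
            raise ValueError("matrix contains negative distances")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.values, ids=self.labels)


def build_distance_matrix(
    f_values: dict[tuple[str, str], float],
    index_tag: str = "F_AV",
    labels: list[str] | None = None,
) -> DistanceMatrix:
    """Assemble a symmetric matrix from per-ordered-pair F values.

    ``f_values`` must hold every ordered pair (X, Y), X != Y. For the
    orientation indices F_XY / F_YX, "X" is the label earlier in ``labels``.
    """
    if index_tag not in INDEX_TAGS:
        raise ValueError(f"unknown index tag {index_tag!r}; expected one of {INDEX_TAGS}")
    if labels is None:
        labels = sorted({t for pair in f_values for t in pair})
    n = len(labels)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = labels[i], labels[j]
            for pair in ((x, y), (y, x)):
                if pair not in f_values:
                    raise KeyError(f"missing F value for ordered pair {pair}")
            d = combine_F(FPair(f_xy=f_values[(x, y)], f_yx=f_values[(y, x)]), index_tag)
            values[i, j] = values[j, i] = d
    dm = DistanceMatrix(labels=labels, values=values, index_tag=index_tag)
    dm.validate()
    return dm


def f_values_from_similarity(sims: dict[tuple[str, str], "SimilarityResult"], model) -> dict[tuple[str, str], float]:
    """Map each ordered pair's tan(theta) through the calibration model."""
    return {pair: model.predict(res.tan_theta) for pair, res in sims.items()}


def indices_long_table(f_values: dict[tuple[str, str], float], labels: list[str] | None = None) -> pd.DataFrame:
    """Long-format dump of all five indices per unordered pair (diagnostics)."""
    if labels is None:
        labels = sorted({t for pair in f_values for t in pair})
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            x, y = labels[i], labels[j]
            pair = FPair(f_xy=f_values[(x, y)], f_yx=f_values[(y, x)])
            for tag in INDEX_TAGS:
                rows.append({"taxon_x": x, "taxon_y": y, "index": tag, "value": combine_F(pair, tag)})
    return pd.DataFrame(rows)
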