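"""The two-dimensional averaged-coordinate similarity statistic.

Each query gene of genome X contributes one point: its self best-match
log10 E-value (x, X queried against X — the best match is the gene itself)
and its cross best-match log10 E-value against genome Y (y). Averaging the
coordinates and shifting the origin to the cut-off point (C_OV, C_OV) gives
a slope

    m = (AvE_Y - C_OV) / (AvE_X - C_OV)

which is 1 for identical genomes and 0 when no cross similarity survives the
cut-off. The dissimilarity statistic tan(theta) measures the departure of
the averaged-coordinate line from the diagonal:

    angle convention:       tan(theta) = (1 - m) / (1 + m)
    complement convention:  tan(theta) = 1 - m

Both vanish at m = 1 and equal 1 at m = 0; the angle convention is the
tangent of the actual angle between the two lines and is the default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import BestMatchTable

logger = logging.getLogger(__name__)

#: log10 of the default raw E-value cut-off (10).
DEFAULT_LOG_CUTOFF = 1.0

CONVENTIONS = ("angle", "complement")


class NoComparablePointsError(ValueError):
    """A genome pair shares no query gene with both coordinates."""


@dataclass
class PairPoints:
    """Two-dimensional best-match points for one ordered genome pair."""

    query_taxon: str
    subject_taxon: str
    genes: list[str]
    x: np.ndarray  # self log10 E-values
    y: np.ndarray  # cross log10 E-values

    @property
    def n(self) -> int:
        return len(self.genes)


@dataclass
class SimilarityResult:
    """AvE_X, AvE_Y, slope and tan(theta) for one ordered genome pair."""

    query_taxon: str
    subject_taxon: str
    av_e_x: float
    av_e_y: float
    n: int
    m: float
    tan_theta: float
    convention: str = "angle"


def pair_points(self_table: BestMatchTable, cross_table: BestMatchTable) -> PairPoints:
    """Join a self-table (X vs X) with a cross-table (X vs Y) on query gene.

    Only genes present in both tables contribute a point; a query with no
    admitted cross-genome hit has no y coordinate and is excluded.
    """
    if not self_table.is_self:
        raise ValueError(
            f"self_table must compare a taxon to itself, got {self_table.query_taxon} vs {self_table.subject_taxon}"
        )
    if cross_table.query_taxon != self_table.query_taxon:
        raise ValueError(
            f"taxon mismatch: self table is for {self_table.query_taxon!r}, "
            f"cross table queries {cross_table.query_taxon!r}"
        )
    genes = [g for g in self_table.records if g in cross_table.records]
    if not genes:
        raise NoComparablePointsError(
            f"no comparable points for pair ({cross_table.query_taxon}, {cross_table.subject_taxon})"
        )
    x = np.array([self_table.records[g][1] for g in genes], dtype=float)
    y = np.array([cross_table.records[g][1] for g in genes], dtype=float)
    return PairPoints(cross_table.query_taxon, cross_table.subject_taxon, genes, x, y)


def average_coordinates(points: PairPoints) -> tuple[float, float]:
    """(AvE_X, AvE_Y): arithmetic means of the point coordinates."""
    if points.n == 0:
        raise ValueError("cannot average an empty point set")
    return float(points.x.mean()), float(points.y.mean())


def slope_m(av_e_x: float, av_e_y: float, c_ov: float = DEFAULT_LOG_CUTOFF) -> float:
    """Origin-shifted slope of the averaged coordinates.

    The cut-off C_OV (on the log scale) is subtracted from both averages so
    the no-similarity point (C_OV, C_OV) becomes the origin. The result is
    clamped to [0, 1]; sampling noise can push it marginally outside for
    near-identical or near-dissimilar genomes.
    """
    if av_e_x == c_ov:
        raise ValueError("AvE_X equals the cut-off: degenerate self-comparison")
    m = (av_e_y - c_ov) / (av_e_x - c_ov)
    if m < -1e-9 or m > 1 + 1e-9:
        warnings.warn(f"slope m = {m:.6g} outside [0, 1]; clamping", stacklevel=2)
    return float(min(max(m, 0.0), 1.0) + 0.0)  # + 0.0 normalizes -0.0


def tan_theta(m: float, convention: str = "angle") -> float:
    """Dissimilarity statistic derived from the slope m."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"slope m must lie in [0, 1], got {m}")
    if convention == "angle":
        return (1.0 - m) / (1.0 + m)
    return 1.0 - m


def similarity_for_pair(
    self_table: BestMatchTable,
    cross_table: BestMatchTable,
    c_ov: float = DEFAULT_LOG_CUTOFF,
    convention: str = "angle",
) -> SimilarityResult:
    """Full statistic for one ordered pair: points -> averages -> m -> tan(theta)."""
    points = pair_points(self_table, cross_table)
    av_x, av_y = average_coordinates(points)
    m = slope_m(av_x, av_y, c_ov)
    return SimilarityResult(
        query_taxon=points.query_taxon,
        subject_taxon=points.subject_taxon,
        av_e_x=av_x,
        av_e_y=av_y,
        n=points.n,
        m=m,
        tan_theta=tan_theta(m, convention),
        convention=convention,
    )


def tantheta_matrix(
    tables: dict[tuple[str, str], BestMatchTable],
    c_ov: float = DEFAULT_LOG_CUTOFF,
    convention: str = "angle",
) -> dict[tuple[str, str], SimilarityResult]:
    """Similarity results for every ordered pair of taxa.

    Both orientations are computed and reported separately — the search is
    asymmetric and no averaging happens at this stage. A pair with zero
    shared points yields tan(theta) = 1 (maximal dissimilarity) with a
    logged warning instead of aborting the whole run.
    """
    taxa = sorted({t for t, s in tables if t == s})
    if not taxa:
        raise ValueError("no self-tables found; one (X, X) table per taxon is required")
    missing = [
        (x, y)
        for x in taxa
        for y in taxa
        if x != y and (x, y) not in tables
    ]
    if missing:
        raise ValueError(f"missing best-match tables for ordered pairs: {missing}")
    results: dict[tuple[str, str], SimilarityResult] = {}
    for x in taxa:
        for y in taxa:
            if x == y:
                continue
            try:
                results[(x, y)] = similarity_for_pair(tables[(x, x)], tables[(x, y)], c_ov, convention)
            except NoComparablePointsError:
                logger.warning("pair (%s, %s) has no comparable points; reporting tan(theta) = 1", x, y)
                results[(x, y)] = SimilarityResult(x, y, float("nan"), float("nan"), 0, 0.0, 1.0, convention)
    return results


def reciprocal_best_hits(
    xy: BestMatchTable, yx: BestMatchTable
) -> tuple[BestMatchTable, BestMatchTable]:
    """Restrict both orientations of a pair to reciprocal best matches.

    A record g -> h in the X-vs-Y table survives iff the Y-vs-X table maps
    h -> g; the filter is applied symmetrically.
    """
    if xy.query_taxon != yx.subject_taxon or xy.subject_taxon != yx.query_taxon:
        raise ValueError(
            f"tables are not the two orientations of one pair: "
            f"({xy.query_taxon}, {xy.subject_taxon}) vs ({yx.query_taxon}, {yx.subject_taxon})"
        )
    fwd = {g: (h, e) for g, (h, e) in xy.records.items() if yx.records.get(h, (None,))[0] == g}
    rev = {h: (g, e) for h, (g, e) in yx.records.items() if xy.records.get(g, (None,))[0] == h}
    return (
        BestMatchTable(xy.query_taxon, xy.subject_taxon, fwd),
        BestMatchTable(yx.query_taxon, yx.subject_taxon, rev),
    )


def apply_rbh_filter(
    tables: dict[tuple[str, str], BestMatchTable]
) -> dict[tuple[str, str], BestMatchTable]:
    """Reciprocal-best-hit variant: filter every cross-pair of tables."""
    out = dict(tables)
    taxa = sorted({t for t, s in tables if t == s})
    for i, x in enumerate(taxa):
        for y in taxa[i + 1 :]:
            fwd, rev = reciprocal_best_hits(tables[(x, y)], tables[(y, x)])
            out[(x, y)] = fwd
            out[(y, x)] = rev
    return out


def similarity_table(sims: dict[tuple[str, str], SimilarityResult]):
    """Per-pair diagnostics as a DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "query_taxon": r.query_taxon,
                "subject_taxon": r.subject_taxon,
                "AvE_X": r.av_e_x,
                "AvE_Y": r.av_e_y,
                "n": r.n,
                "m": r.m,
                "tan_theta": r.tan_theta,
            }
            for r in sims.values()
        ]
    )
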