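"""Tree inference and the resampling experiments.

Neighbor joining, majority-rule consensus, Robinson-Foulds comparison and
Newick handling are delegated to scikit-bio; this module owns what is
specific to the averaged best-hit E-value method:

* the bootstrap, which resamples (query gene, E-value) best-match points
  with replacement independently within each ordered genome pair and
  rebuilds tan(theta) -> F -> matrix -> NJ per replicate;
* the gene-reduction experiment, which subsamples one taxon's gene set and
  checks whether each distance index still yields the same topology;
* Jukes-Cantor 16S distances for the reference tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import TreeNode
from skbio.tree import nj

from .calibration import CalibrationModel
from .distances import INDEX_TAGS, DistanceMatrix, build_distance_matrix
from .io import BestMatchTable
from .similarity import (
    DEFAULT_LOG_CUTOFF,
    NoComparablePointsError,
    PairPoints,
    pair_points,
    slope_m,
    tan_theta,
)

logger = logging.getLogger(__name__)


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    Negative branch-length estimates (possible on non-additive input) are
    clamped to zero. A 2-taxon matrix yields the single-edge tree with the
    full distance split evenly.
    """
    matrix.validate()
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        d = float(matrix.values[0, 1])
        tips = [TreeNode(name=name, length=d / 2) for name in matrix.labels]
        return TreeNode(children=tips)
    return nj(matrix.to_skbio(), neg_as_zero=True)


def jukes_cantor_distance(
    sequences: Sequence[tuple[str, str]], index_tag: str = "JC"
) -> DistanceMatrix:
    """Jukes-Cantor corrected pairwise distances from an alignment.

    Columns with a gap or ambiguity code in either member of a pair are
    excluded pairwise; d = -(3/4) ln(1 - 4p/3) with p the mismatch
    proportion over the compared columns.
    """
    from .calibration import substitution_rate

    names = [name for name, _ in sequences]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sequence names")
    n = len(names)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            rate = substitution_rate(sequences[i][1], sequences[j][1], pair=(names[i], names[j]))
            p = rate.s / 100.0
            if p >= 0.75:
                raise ValueError(
                    f"JC distance undefined (saturation) for pair ({names[i]}, {names[j]}): p = {p:.4f}"
                )
            values[i, j] = values[j, i] = -0.75 * np.log1p(-4.0 * p / 3.0)
    return DistanceMatrix(labels=list(names), values=values, index_tag=index_tag)


def _leaf_set(tree: TreeNode) -> frozenset[str]:
    return frozenset(tip.name for tip in tree.tips())


def _bipartitions(tree: TreeNode, leaves: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each as the side without the
    lexicographically smallest leaf (a rooting-independent normalization)."""
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if ref in side:
            side = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


def majority_consensus(
    trees: Sequence[TreeNode], cutoff: float = 0.5, extended: bool = False
) -> TreeNode:
    """Unrooted majority-rule consensus with per-bipartition counts.

    Bipartitions present in strictly more than ``cutoff`` of the input trees
    are retained (a 50/50 split is excluded under the default strict
    majority), so the result may be multifurcating. With ``extended=True``,
    minority bipartitions are greedily added in frequency order when
    compatible with everything already accepted. Internal nodes carry
    ``support`` (occurrence count) and ``support_percent``; branch lengths
    are not defined for a consensus and are left unset.
    """
    if not trees:
        raise ValueError("no trees to build a consensus from")
    leaf_sets = {_leaf_set(t) for t in trees}
    if len(leaf_sets) != 1:
        raise ValueError("trees have different leaf sets; cannot build a consensus")
    leaves = leaf_sets.pop()
    total = len(trees)

    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for bp in _bipartitions(t, leaves):
            counts[bp] = counts.get(bp, 0) + 1

    # deterministic order: frequency desc, then size, then labels
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], len(kv[0]), sorted(kv[0])))
    accepted: list[tuple[frozenset[str], int]] = []

    def compatible(clade: frozenset[str]) -> bool:
        return all(
            clade.isdisjoint(other) or clade <= other or other <= clade
            for other, _ in accepted
        )

    for clade, count in ranked:
        if count > cutoff * total:
            accepted.append((clade, count))  # strict majorities are mutually compatible
        elif extended and compatible(clade):
            accepted.append((clade, count))

    # build the (rooted representation of the) consensus by nesting clades
    active: list[tuple[frozenset[str], TreeNode]] = [
        (frozenset([name]), TreeNode(name=name)) for name in sorted(leaves)
    ]
    for clade, count in sorted(accepted, key=lambda kv: (len(kv[0]), sorted(kv[0]))):
        children = [(ls, nd) for ls, nd in active if ls <= clade]
        node = TreeNode(children=[nd for _, nd in children])
        node.support = count
        node.support_percent = 100.0 * count / total
        active = [(ls, nd) for ls, nd in active if not ls <= clade]
        active.append((clade, node))
    return TreeNode(children=[nd for _, nd in active])


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Unrooted Robinson-Foulds symmetric difference (bipartition count)."""
    if _leaf_set(t1) != _leaf_set(t2):
        raise ValueError("trees have different leaf sets")
    return int(t1.compare_rfd(t2, rooted=False))


def cophenetic_correlation(tree: TreeNode, matrix: DistanceMatrix) -> float:
    """Pearson correlation between tree path lengths and matrix distances."""
    td = tree.tip_tip_distances()
    order = [list(td.ids).index(name) for name in matrix.labels]
    tree_d = td.data[np.ix_(order, order)]
    iu = np.triu_indices(len(matrix.labels), k=1)
    return float(np.corrcoef(tree_d[iu], matrix.values[iu])[0, 1])


def root_with_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Display rooting on the edge leading to the named out-group tip."""
    tip = tree.find(outgroup)
    try:
        return tree.root_at(tip, above=True)
    except TypeError:  # older root_at signature
        return tree.root_at(tip.parent)


# -- pipeline composition -----------------------------------------------------

def _pair_points_cache(
    tables: dict[tuple[str, str], BestMatchTable]
) -> tuple[list[str], dict[tuple[str, str], PairPoints | None]]:
    taxa = sorted({t for t, s in tables if t == s})
    missing = [(x, y) for x in taxa for y in taxa if x != y and (x, y) not in tables]
    if missing:
        raise ValueError(f"missing best-match tables for ordered pairs: {missing}")
    cache: dict[tuple[str, str], PairPoints | None] = {}
    for x in taxa:
        for y in taxa:
            if x == y:
                continue
            try:
                cache[(x, y)] = pair_points(tables[(x, x)], tables[(x, y)])
            except NoComparablePointsError:
                logger.warning("pair (%s, %s): no comparable points; using tan(theta) = 1", x, y)
                cache[(x, y)] = None
    return taxa, cache


def _f_from_means(
    av_x: float, av_y: float, model: CalibrationModel, c_ov: float, convention: str
) -> float:
    return model.predict(tan_theta(slope_m(av_x, av_y, c_ov), convention))


def matrix_from_tables(
    tables: dict[tuple[str, str], BestMatchTable],
    model: CalibrationModel,
    index_tag: str = "F_AV",
    c_ov: float = DEFAULT_LOG_CUTOFF,
    convention: str = "angle",
) -> DistanceMatrix:
    """Point-estimate distance matrix: tables -> tan(theta) -> F -> matrix."""
    taxa, cache = _pair_points_cache(tables)
    f_values: dict[tuple[str, str], float] = {}
    for pair, pts in cache.items():
        if pts is None:
            f_values[pair] = model.predict(1.0)
        else:
            f_values[pair] = _f_from_means(float(pts.x.mean()), float(pts.y.mean()), model, c_ov, convention)
    return build_distance_matrix(f_values, index_tag, labels=taxa)


def tree_from_tables(
    tables: dict[tuple[str, str], BestMatchTable],
    model: CalibrationModel,
    index_tag: str = "F_AV",
    c_ov: float = DEFAULT_LOG_CUTOFF,
    convention: str = "angle",
) -> TreeNode:
    return neighbor_joining(matrix_from_tables(tables, model, index_tag, c_ov, convention))


# -- bootstrap ----------------------------------------------------------------

@dataclass
class BootstrapSpec:
    """Replicate count B, per-pair resample size k, seed and distance index."""

    b: int = 100
    k: int = 1000
    seed: int = 0
    index_tag: str = "F_AV"

    def __post_init__(self) -> None:
        if self.b < 1:
            raise ValueError("bootstrap replicate count B must be >= 1")
        if self.k < 1:
            raise ValueError("resample size k must be >= 1")
        if self.index_tag not in INDEX_TAGS:
            raise ValueError(f"unknown index tag {self.index_tag!r}")


def bootstrap_trees(
    tables: dict[tuple[str, str], BestMatchTable],
    model: CalibrationModel,
    spec: BootstrapSpec,
    c_ov: float = DEFAULT_LOG_CUTOFF,
    convention: str = "angle",
) -> tuple[list[TreeNode], TreeNode]:
    """Best-hit-pair resampling bootstrap.

    Each replicate draws, independently for every ordered genome pair, k of
    its (query gene, E-value) points with replacement, recomputes
    tan(theta) -> F for that pair, assembles the matrix and infers an NJ
    tree. Replicate r uses the seed stream (seed, r), so any single
    replicate is individually reproducible. Returns the B trees and their
    strict-majority consensus with supports out of B.
    """
    taxa, cache = _pair_points_cache(tables)
    trees: list[TreeNode] = []
    for r in range(spec.b):
        rng = np.random.default_rng([spec.seed, r])
        f_values: dict[tuple[str, str], float] = {}
        for pair, pts in cache.items():
            if pts is None:
                f_values[pair] = model.predict(1.0)
                continue
            idx = rng.integers(0, pts.n, size=spec.k)
            f_values[pair] = _f_from_means(
                float(pts.x[idx].mean()), float(pts.y[idx].mean()), model, c_ov, convention
            )
        matrix = build_distance_matrix(f_values, spec.index_tag, labels=taxa)
        trees.append(neighbor_joining(matrix))
    return trees, majority_consensus(trees)


def support_table(consensus: TreeNode):
    """Bipartition support dump (one row per supported internal node)."""
    import pandas as pd

    rows = []
    for node in consensus.non_tips(include_self=False):
        sup = getattr(node, "support", None)
        if sup is None:
            continue
        clade = sorted(tip.name for tip in node.tips())
        rows.append(
            {
                "clade": ",".join(clade),
                "support": sup,
                "support_percent": getattr(node, "support_percent", float("nan")),
            }
        )
    return pd.DataFrame(rows)


# -- gene-reduction experiment ------------------------------------------------

@dataclass
class ReductionResult:
    index_tag: str
    trees: list[TreeNode]
    consensus: TreeNode  # agreement counts out of R on internal nodes


def _reduce_tables(
    tables: dict[tuple[str, str], BestMatchTable],
    target_taxon: str,
    keep: frozenset[str],
) -> dict[tuple[str, str], BestMatchTable]:
    reduced: dict[tuple[str, str], BestMatchTable] = {}
    for (q, s), table in tables.items():
        if q == target_taxon:
            records = {g: rec for g, rec in table.records.items() if g in keep}
        elif s == target_taxon:
            # the removed genes are gone from the subject database, so best
            # matches pointing at them no longer exist under the cut-off
            records = {g: rec for g, rec in table.records.items() if rec[0] in keep}
        else:
            records = table.records
        reduced[(q, s)] = BestMatchTable(q, s, records)
    return reduced


def gene_reduction_experiment(
    tables: dict[tuple[str, str], BestMatchTable],
    target_taxon: str,
    fraction: float,
    replicates: int = 10,
    index_tags: Sequence[str] = INDEX_TAGS,
    seed: int = 0,
    model: CalibrationModel | None = None,
    c_ov: float = DEFAULT_LOG_CUTOFF,
    convention: str = "angle",
) -> dict[str, ReductionResult]:
    """Rebuild trees after randomly shrinking one taxon's gene set.

    Each of ``replicates`` runs keeps floor(fraction * N) of the target
    taxon's genes (drawn without replacement), restricts every table
    involving that taxon accordingly, and re-infers the tree for each
    requested distance index. Per index, the replicate trees are summarized
    by a strict-majority consensus whose supports are agreement counts out
    of ``replicates``.
    """
    if model is None:
        from .calibration import preset

        model = preset()
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    self_table = tables.get((target_taxon, target_taxon))
    if self_table is None:
        raise ValueError(f"no self-table for target taxon {target_taxon!r}")
    genes = list(self_table.records)
    keep_n = int(len(genes) * fraction)
    if keep_n < 10:
        raise ValueError(
            f"fraction {fraction} keeps only {keep_n} of {len(genes)} genes; need at least 10"
        )
    per_index_trees: dict[str, list[TreeNode]] = {tag: [] for tag in index_tags}
    for r in range(replicates):
        rng = np.random.default_rng([seed, r])
        keep = frozenset(rng.choice(genes, size=keep_n, replace=False))
        reduced = _reduce_tables(tables, target_taxon, keep)
        for tag in index_tags:
            per_index_trees[tag].append(tree_from_tables(reduced, model, tag, c_ov, convention))
    return {
        tag: ReductionResult(tag, trees, majority_consensus(trees))
        for tag, trees in per_index_trees.items()
    }
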