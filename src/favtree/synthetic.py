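"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here with controlled
parameters: best-match tables whose slope m is set by construction (so the
similarity statistic can be checked against its generating value),
calibration point clouds with known constants, additive distance matrices
read off a tree, and nucleotide alignments evolved under Jukes-Cantor along
a known tree.

The best-hit generator synthesizes E-value geometry directly rather than
emulating a search engine: self log-E values are drawn uniformly in
[-180, -5] (mirroring the length-dependent spread of real self matches) and
cross values are placed on the line of slope ``target_m`` through the
cut-off point, plus optional Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .calibration import CalibrationModel, preset
from .distances import DistanceMatrix
from .io import BestMatchTable, HitRow, ProteomeSet

_AMINO = "ACDEFGHIKLMNPQRSTVWY"
_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    """Parameters of one synthetic best-hit fixture."""

    taxa: Sequence[str]
    seed: int = 0
    gene_count: int = 300
    target_m: float | dict[tuple[str, str], float] | None = None
    tree: TreeNode | None = None
    model: CalibrationModel | None = None
    noise_sd: float = 0.0
    c_ov: float = 1.0
    convention: str = "angle"
    self_range: tuple[float, float] = (-180.0, -5.0)

    def __post_init__(self) -> None:
        if self.gene_count < 1:
            raise ValueError("gene_count must be >= 1")
        if self.target_m is None and self.tree is None:
            raise ValueError("either target_m or a generating tree is required")


def m_from_tan_theta(t: float, convention: str = "angle") -> float:
    """Invert the tan(theta) convention back to a slope."""
    if not 0 <= t <= 1:
        raise ValueError(f"tan_theta must lie in [0, 1], got {t}")
    if convention == "angle":
        return (1.0 - t) / (1.0 + t)
    if convention == "complement":
        return 1.0 - t
    raise ValueError(f"unknown convention {convention!r}")


def target_m_from_tree(
    tree: TreeNode,
    model: CalibrationModel | None = None,
    convention: str = "angle",
) -> dict[tuple[str, str], float]:
    """Per-pair slopes whose calibrated distances equal the tree's path lengths.

    The tip-to-tip path length is taken as the F value (percent-substitution
    scale), inverted through the calibration model to tan(theta) and then to
    m. Path lengths must not exceed the model's value at tan(theta) = 1.
    """
    if model is None:
        model = preset()
    td = tree.tip_tip_distances()
    ids = list(td.ids)
    s_max = model.predict(1.0)
    out: dict[tuple[str, str], float] = {}
    for i, x in enumerate(ids):
        for j, y in enumerate(ids):
            if i == j:
                continue
            d = float(td.data[i, j])
            if d > s_max:
                raise ValueError(
                    f"tree distance {d:.4g} for pair ({x}, {y}) exceeds the calibration "
                    f"range (model value at tan_theta=1 is {s_max:.4g})"
                )
            out[(x, y)] = m_from_tan_theta(model.inverse(d), convention)
    return out


def _resolve_target_m(spec: FixtureSpec) -> dict[tuple[str, str], float]:
    taxa = list(spec.taxa)
    if spec.target_m is None:
        m_map = target_m_from_tree(spec.tree, spec.model, spec.convention)
        missing = [
            (x, y) for x in taxa for y in taxa if x != y and (x, y) not in m_map
        ]
        if missing:
            raise ValueError(f"generating tree lacks leaves for pairs: {missing}")
        return m_map
    if isinstance(spec.target_m, dict):
        return dict(spec.target_m)
    m = float(spec.target_m)
    return {(x, y): m for x in taxa for y in taxa if x != y}


def gen_best_hit_tables(spec: FixtureSpec) -> dict[tuple[str, str], BestMatchTable]:
    """Best-match tables for all ordered pairs of ``spec.taxa``.

    Self tables map each gene to itself with a log-E drawn uniformly from
    ``self_range``. The cross table (X, Y) places gene i of X at
    y_i = C_OV + m * (x_i - C_OV) + Normal(0, noise_sd), clipped to
    [-180, C_OV], matched to gene i of Y. With noise_sd = 0 the recomputed
    slope equals the target exactly.
    """
    m_map = _resolve_target_m(spec)
    for pair, m in m_map.items():
        if not 0 <= m <= 1:
            raise ValueError(f"target_m for pair {pair} must lie in [0, 1], got {m}")
    rng = np.random.default_rng(spec.seed)
    taxa = list(spec.taxa)
    gene_ids = {t: [f"{t}_g{i:04d}" for i in range(spec.gene_count)] for t in taxa}
    self_logE: dict[str, np.ndarray] = {
        t: rng.uniform(spec.self_range[0], spec.self_range[1], size=spec.gene_count) for t in taxa
    }
    tables: dict[tuple[str, str], BestMatchTable] = {}
    for t in taxa:
        tables[(t, t)] = BestMatchTable(
            t, t, {g: (g, float(e)) for g, e in zip(gene_ids[t], self_logE[t])}
        )
    for x in taxa:
        for y in taxa:
            if x == y:
                continue
            m = m_map[(x, y)]
            base = spec.c_ov + m * (self_logE[x] - spec.c_ov)
            if spec.noise_sd > 0:
                base = base + rng.normal(0.0, spec.noise_sd, size=spec.gene_count)
            yvals = np.clip(base, -180.0, spec.c_ov)
            records = {
                gx: (gene_ids[y][i], float(yvals[i]))
                for i, gx in enumerate(gene_ids[x])
            }
            tables[(x, y)] = BestMatchTable(x, y, records)
    return tables


def gen_calibration_pairs(
    n: int,
    const1: float = 5.0112,
    const2: float = 2.2223,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """(tan_theta, S) point cloud from the exp-minus-one calibration curve.

    tan(theta) ~ Uniform[0, 1]; S gets multiplicative Gaussian noise of the
    given relative magnitude and is floored at 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, size=n)
    s = const1 * (np.exp(const2 * t) - 1.0)
    if noise_fraction > 0:
        s = s * (1.0 + rng.normal(0.0, noise_fraction, size=n))
    s = np.maximum(s, 0.0)
    return list(zip(t.tolist(), s.tolist()))


def gen_additive_matrix(tree: TreeNode, index_tag: str = "F_AV") -> DistanceMatrix:
    """Tip-to-tip path-length matrix of a tree (the additive oracle)."""
    import warnings

    for node in tree.non_tips(include_self=False):
        if node.length is not None and node.length <= 0:
            warnings.warn(f"non-positive internal branch length {node.length}", stacklevel=2)
    td = tree.tip_tip_distances()
    return DistanceMatrix(labels=list(td.ids), values=np.array(td.data, dtype=float), index_tag=index_tag)


def random_tree(
    n_leaves: int,
    seed: int | np.random.Generator = 0,
    branch_range: tuple[float, float] = (0.1, 2.0),
    prefix: str = "T",
) -> TreeNode:
    """Random binary topology with i.i.d. uniform positive branch lengths."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = branch_range
    nodes = [TreeNode(name=f"{prefix}{i}", length=float(rng.uniform(lo, hi))) for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b], length=float(rng.uniform(lo, hi)))
        nodes.append(parent)
    root = TreeNode(children=nodes)
    return root


def evolve_sequences(
    tree: TreeNode, length: int, seed: int = 0
) -> list[tuple[str, str]]:
    """Evolve a gapless alignment down a tree under Jukes-Cantor.

    Branch lengths are expected substitutions per site. The root sequence is
    uniform over ACGT; along a branch of length b each site changes with
    probability (3/4)(1 - exp(-4b/3)) to one of the three other bases
    uniformly.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length)
    out: list[tuple[str, str]] = []

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            b = child.length or 0.0
            p_change = 0.75 * (1.0 - math.exp(-4.0 * b / 3.0))
            child_seq = seq.copy()
            mask = rng.random(length) < p_change
            if mask.any():
                # uniform over the three other bases
                shift = rng.integers(1, 4, size=int(mask.sum()))
                child_seq[mask] = (child_seq[mask] + shift) % 4
            if child.is_tip():
                out.append((child.name, "".join(_BASES[child_seq])))
            else:
                descend(child, child_seq)

    descend(tree, root_seq)
    return out


# -- file-producing helpers (exercise the real parsers) -----------------------

def gen_proteome(taxon: str, n_genes: int, seed: int = 0, mean_length: int = 120) -> ProteomeSet:
    """Random amino-acid sequences; for format round-trips and demos only."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(_AMINO))
    sequences = []
    for i in range(n_genes):
        ln = max(10, int(rng.poisson(mean_length)))
        sequences.append((f"{taxon}_g{i:04d}", "".join(rng.choice(letters, size=ln))))
    return ProteomeSet(taxon, sequences)


def hit_rows_from_table(table: BestMatchTable) -> list[HitRow]:
    """Re-express a best-match table as 12-column tabular hit rows."""
    rows = []
    for q, (s, logE) in table.records.items():
        evalue = 0.0 if logE <= -180 else 10.0 ** logE
        extra = ("100.00", "100", "0", "0", "1", "100", "1", "100", "200.0")
        rows.append(HitRow(q, s, evalue, extra))
    return rows


def write_hit_rows(rows: Sequence[HitRow], path) -> None:
    """Write rows in the standard 12-column tabular layout (E-value col 11)."""
    with open(path, "w") as fh:
        for r in rows:
            e = r.extra
            pident, length, mism, gap, qs, qe, ss, se = e[0], e[1], e[2], e[3], e[4], e[5], e[6], e[7]
            bit = e[8] if len(e) > 8 else "0.0"
            fh.write(
                f"{r.query_gene}\t{r.subject_gene}\t{pident}\t{length}\t{mism}\t{gap}"
                f"\t{qs}\t{qe}\t{ss}\t{se}\t{r.evalue:.3g}\t{bit}\n"
            )
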