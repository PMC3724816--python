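"""Readers, writers and E-value preprocessing.

External formats handled here: FASTA proteomes (via Biopython), 12-column
tabular similarity-search output (E-value in column 11), PHYLIP square
distance matrices, Newick trees (via scikit-bio), and the package's own
3-column best-match tables.
"""

from __future__ import annotations

import math
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from skbio import TreeNode

from .distances import DistanceMatrix

#: Common-log sentinel assigned to E-values reported as exactly zero.
LOG_FLOOR = -180.0

#: Default search cut-off: raw E-value 10, i.e. +1 on the common-log scale.
DEFAULT_CUTOFF = 10.0


class FormatError(ValueError):
    """Malformed input file or record."""


@dataclass
class ProteomeSet:
    """All protein sequences of one taxon."""

    taxon_id: str
    sequences: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.sequences]


@dataclass
class HitRow:
    """One row of tabular search output; non-essential columns kept opaquely."""

    query_gene: str
    subject_gene: str
    evalue: float
    extra: tuple = ()

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue!r} for query {self.query_gene!r}")


@dataclass
class BestMatchTable:
    """Best-matched protein per query gene for one ordered genome pair.

    ``records`` maps each query gene to ``(subject_gene, logE)`` where logE is
    the common logarithm of the lowest E-value among that query's admitted
    hits. A self-table (query_taxon == subject_taxon) maps each gene to
    itself.
    """

    query_taxon: str
    subject_taxon: str
    records: dict[str, tuple[str, float]] = field(default_factory=dict)

    @property
    def is_self(self) -> bool:
        return self.query_taxon == self.subject_taxon

    def __len__(self) -> int:
        return len(self.records)


def read_fasta(path: str | Path, taxon_id: str | None = None) -> ProteomeSet:
    """Read a FASTA file into a :class:`ProteomeSet`.

    The header token before the first whitespace is the gene id. Duplicate
    ids and empty sequences are rejected.
    """
    path = Path(path)
    sequences: list[tuple[str, str]] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        gene_id = record.id
        residues = str(record.seq)
        if gene_id in seen:
            raise FormatError(f"duplicate gene id {gene_id!r} in {path}")
        if not residues:
            raise FormatError(f"empty sequence for {gene_id!r} in {path}")
        seen.add(gene_id)
        sequences.append((gene_id, residues))
    return ProteomeSet(taxon_id=taxon_id or path.stem, sequences=sequences)


def write_fasta(proteome: ProteomeSet, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for gene_id, residues in proteome.sequences:
            fh.write(f">{gene_id}\n")
            for i in range(0, len(residues), width):
                fh.write(residues[i : i + width] + "\n")


def log_transform_evalue(evalue: float, floor: float = LOG_FLOOR) -> float:
    """Common logarithm of an E-value; zero maps to the floor sentinel.

    Underflowing positive values are clipped to the floor as well, so the
    result is always >= ``floor``.
    """
    if evalue < 0:
        raise ValueError(f"E-value must be non-negative, got {evalue}")
    if evalue == 0:
        return floor
    return max(math.log10(evalue), floor)


def read_hit_rows(path: str | Path) -> Iterator[HitRow]:
    """Stream 12-column tabular hits (query, subject, ..., E-value in col 11)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise FormatError(f"{path}:{lineno}: expected >=11 tab-separated columns, got {len(fields)}")
            try:
                evalue = float(fields[10])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric E-value {fields[10]!r}") from None
            if evalue < 0:
                raise FormatError(f"{path}:{lineno}: negative E-value {evalue}")
            yield HitRow(fields[0], fields[1], evalue, tuple(fields[2:10] + fields[11:]))


def parse_best_hits(
    rows: Iterable[HitRow],
    query_taxon: str,
    subject_taxon: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> BestMatchTable:
    """Extract the best (lowest-E) hit per query gene.

    Rows with E-value above ``cutoff`` are discarded before selection, so the
    cut-off acts as an admission filter. Ties at the minimum keep the first
    row in input order (search tools emit their best hits first).
    """
    best: dict[str, tuple[str, float]] = {}
    for row in rows:
        if row.evalue > cutoff:
            continue
        prev = best.get(row.query_gene)
        if prev is None or row.evalue < prev[1]:
            best[row.query_gene] = (row.subject_gene, row.evalue)
    records = {q: (s, log_transform_evalue(e)) for q, (s, e) in best.items()}
    return BestMatchTable(query_taxon, subject_taxon, records)


# -- best-match table serialization (3-column TSV) ---------------------------

def write_best_match_table(table: BestMatchTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# query_taxon={table.query_taxon}\tsubject_taxon={table.subject_taxon}\n")
        fh.write("query_gene\tsubject_gene\tlog10_evalue\n")
        for q, (s, logE) in table.records.items():
            fh.write(f"{q}\t{s}\t{logE:.10g}\n")


def read_best_match_table(path: str | Path) -> BestMatchTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing taxon header line")
        meta = dict(part.split("=", 1) for part in header[1:].strip().split("\t"))
        fh.readline()  # column names
        records: dict[str, tuple[str, float]] = {}
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            q, s, logE = line.split("\t")
            if q in records:
                raise FormatError(f"{path}:{lineno}: duplicate query gene {q!r}")
            records[q] = (s, float(logE))
    return BestMatchTable(meta["query_taxon"], meta["subject_taxon"], records)


def table_filename(query_taxon: str, subject_taxon: str) -> str:
    return f"{query_taxon}__{subject_taxon}.bm.tsv"


def write_tables_dir(tables: dict[tuple[str, str], BestMatchTable], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (q, s), table in tables.items():
        write_best_match_table(table, outdir / table_filename(q, s))


def read_tables_dir(indir: str | Path) -> dict[tuple[str, str], BestMatchTable]:
    indir = Path(indir)
    tables: dict[tuple[str, str], BestMatchTable] = {}
    for path in sorted(indir.glob("*.bm.tsv")):
        table = read_best_match_table(path)
        tables[(table.query_taxon, table.subject_taxon)] = table
    if not tables:
        raise FormatError(f"no *.bm.tsv best-match tables found in {indir}")
    return tables


# -- PHYLIP square distance matrix -------------------------------------------

def write_distance_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    """Write a PHYLIP square matrix (names padded/truncated to 10 chars).

    Long names are truncated with a collision check; when any truncation
    happens a sidecar ``<path>.labels.tsv`` maps short names back to full
    ones.
    """
    matrix.validate()
    path = Path(path)
    short = [name[:10] for name in matrix.labels]
    if len(set(short)) != len(short):
        clashes = sorted({s for s in short if short.count(s) > 1})
        raise FormatError(f"taxon names collide after 10-character truncation: {clashes}")
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.labels)}\n")
        for name, row in zip(short, matrix.values):
            vals = "  ".join(f"{v:.10g}" for v in row)
            fh.write(f"{name:<10}{vals}\n")
    if any(len(name) > 10 for name in matrix.labels):
        with open(path.with_suffix(path.suffix + ".labels.tsv"), "w") as fh:
            for s, full in zip(short, matrix.labels):
                fh.write(f"{s}\t{full}\n")


def read_distance_matrix(path: str | Path, index_tag: str = "F_AV") -> DistanceMatrix:
    import numpy as np

    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        try:
            n = int(first)
        except ValueError:
            raise FormatError(f"{path}: first line must be the taxon count, got {first!r}") from None
        labels: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            if not line.strip():
                continue
            labels.append(line[:10].strip())
            rows.append([float(tok) for tok in line[10:].split()])
    if len(labels) != n:
        raise FormatError(f"{path}: header says {n} taxa, found {len(labels)} rows")
    values = np.asarray(rows, dtype=float)
    sidecar = path.with_suffix(path.suffix + ".labels.tsv")
    if sidecar.exists():
        mapping = dict(line.rstrip("\n").split("\t") for line in open(sidecar))
        labels = [mapping.get(name, name) for name in labels]
    dm = DistanceMatrix(labels=labels, values=values, index_tag=index_tag)
    dm.validate()
    return dm


# -- Newick -------------------------------------------------------------------

def read_newick(source: str | Path) -> TreeNode:
    """Parse Newick from a string or a file path."""
    text = source if isinstance(source, str) and source.lstrip().startswith("(") else Path(source).read_text()
    try:
        return TreeNode.read([text], convert_underscores=False)
    except Exception as exc:  # skbio raises NewickFormatError
        raise FormatError(f"invalid Newick: {exc}") from exc


def write_newick(tree: TreeNode, path: str | Path | None = None, supports: bool = False) -> str:
    """Serialize a tree to Newick; optionally put supports as internal labels."""
    out = tree.copy()
    for node in out.traverse():
        sup = getattr(node, "support", None)
        if supports and sup is not None and not node.is_tip() and not node.is_root():
            if node.name is None:
                node.name = f"{sup:g}"
        node.support = None
    text = str(out)
    if path is not None:
        Path(path).write_text(text)
    return text


# -- optional blastp convenience ----------------------------------------------

def run_blastp(
    query_fasta: str | Path,
    subject_fasta: str | Path,
    out_path: str | Path,
    cutoff: float = DEFAULT_CUTOFF,
    extra_args: tuple[str, ...] = (),
) -> Path:
    """Shell out to a locally installed ``blastp`` and write tabular output.

    Convenience only: the pipeline consumes tabular hit files from any
    search tool; nothing in the package requires blastp to be installed.
    Defaults follow common practice (BLOSUM62, low-complexity filtering,
    E <= cutoff).
    """
    out_path = Path(out_path)
    cmd = [
        "blastp",
        "-query", str(query_fasta),
        "-subject", str(subject_fasta),
        "-evalue", str(cutoff),
        "-matrix", "BLOSUM62",
        "-seg", "yes",
        "-outfmt", "6",
        "-out", str(out_path),
        *extra_args,
    ]
    subprocess.run(cmd, check=True)
    return out_path
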