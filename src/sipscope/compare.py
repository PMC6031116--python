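"""Per-genome statistics and comparative tables across complete genomes.

Computes the standard genome-statistics columns (size, gene counts,
annotation status, coding density, carbohydrate-active-enzyme content) from
a FASTA sequence and a gene table, and two comparative summaries used when
placing a focal genome among its relatives:

* *difference from average*: how much larger (in % of the focal value) the
  focal genome's statistic is than the mean over all genomes, focal
  included;
* *percent larger than largest*: how much the focal genome exceeds the
  largest of the other genomes, again denominated by the focal value.

A reference table of the seven published complete Saccharibacteria genomes
ships with the package for use as comparison input.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import CoordinateError, DomainError, FormatError

#: GenomeStats columns on which comparative percentages are defined.
NUMERIC_COLUMNS = (
    "genome_size",
    "gene_number",
    "unannotated_genes",
    "average_gene_size",
    "total_coding",
    "coding_density",
    "cazy_genes",
    "unduplicated_cazy",
)


@dataclass(frozen=True)
class GenomeStats:
    """One genome's row of the comparison table."""

    genome_id: str
    environment: str
    genome_size: int
    gene_number: int
    unannotated_genes: int
    average_gene_size: float
    total_coding: int
    coding_density: float
    cazy_genes: int
    unduplicated_cazy: int

    def __post_init__(self) -> None:
        if self.total_coding > self.genome_size:
            raise DomainError(
                f"{self.genome_id}: total coding {self.total_coding} exceeds "
                f"genome size {self.genome_size}"
            )
        if self.unannotated_genes > self.gene_number:
            raise DomainError(
                f"{self.genome_id}: unannotated genes exceed gene number"
            )
        if self.unduplicated_cazy > self.cazy_genes:
            raise DomainError(
                f"{self.genome_id}: distinct CAZy families exceed CAZy gene count"
            )
        recomputed = 100.0 * self.total_coding / self.genome_size
        if abs(recomputed - self.coding_density) > 0.5:
            raise DomainError(
                f"{self.genome_id}: coding density {self.coding_density} "
                f"inconsistent with recomputed {recomputed:.1f}"
            )


def _union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total bases covered by 1-based inclusive intervals, overlaps counted once."""
    order = np.argsort(starts)
    total = 0
    cur_lo, cur_hi = None, None
    for lo, hi in zip(starts[order], ends[order]):
        if cur_hi is None or lo > cur_hi + 1:
            if cur_hi is not None:
                total += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        total += cur_hi - cur_lo + 1
    return int(total)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a gene table from TSV or GFF3.

    The normalized frame has columns ``gene_id``, ``start``, ``end``
    (1-based inclusive), ``annotated`` (0/1) and ``cazy_family`` (empty
    string when none).  GFF3 rows of type gene/CDS are used; a feature is
    unannotated when it carries ``annotated=0`` or lacks a ``product``
    other than a hypothetical protein, and CAZy families are read from a
    ``cazy_family`` attribute.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path)
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: gene table missing {sorted(missing)}")
    if "annotated" not in df.columns:
        df["annotated"] = 1
    if "cazy_family" not in df.columns:
        df["cazy_family"] = ""
    df["cazy_family"] = df["cazy_family"].fillna("").astype(str)
    return df[["gene_id", "start", "end", "annotated", "cazy_family"]]


def _read_gff3(path: Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        attrs = feat.attributes
        if "annotated" in attrs:
            annotated = int(attrs["annotated"][0])
        else:
            product = (attrs.get("product") or [""])[0].lower()
            annotated = int(bool(product) and "hypothetical" not in product)
        cazy = (attrs.get("cazy_family") or [""])[0]
        rows.append(
            {
                "gene_id": feat.id,
                "start": feat.start,
                "end": feat.end,
                "annotated": annotated,
                "cazy_family": cazy,
            }
        )
    if not rows:
        raise FormatError(f"{path.name}: no gene/CDS features found")
    return pd.DataFrame(rows)


def stats_from_inputs(
    fasta: str | Path,
    gene_table: str | Path | pd.DataFrame,
    genome_id: str | None = None,
    environment: str = "",
) -> GenomeStats:
    """Compute a :class:`GenomeStats` row from a FASTA and a gene table.

    Genome size sums all sequence records; total coding length is the union
    of gene intervals (overlaps counted once); coding density is
    100 × total_coding / genome_size.
    """
    fasta = Path(fasta)
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if not records:
        raise FormatError(f"{fasta.name}: no FASTA records")
    genome_size = sum(len(r.seq) for r in records)
    genome_id = genome_id or records[0].id

    genes = gene_table if isinstance(gene_table, pd.DataFrame) else read_gene_table(gene_table)
    starts = genes["start"].to_numpy(dtype=np.int64)
    ends = genes["end"].to_numpy(dtype=np.int64)
    if (starts < 1).any() or (ends > genome_size).any() or (starts > ends).any():
        bad = genes.index[(starts < 1) | (ends > genome_size) | (starts > ends)][0]
        raise CoordinateError(
            f"gene interval out of bounds at table row {bad} "
            f"(genome size {genome_size})"
        )
    cazy = genes["cazy_family"].fillna("").astype(str)
    has_cazy = cazy.str.len() > 0
    total_coding = _union_length(starts, ends)
    return GenomeStats(
        genome_id=genome_id,
        environment=environment,
        genome_size=int(genome_size),
        gene_number=len(genes),
        unannotated_genes=int((genes["annotated"] == 0).sum()),
        average_gene_size=float(np.mean(ends - starts + 1)),
        total_coding=total_coding,
        coding_density=100.0 * total_coding / genome_size,
        cazy_genes=int(has_cazy.sum()),
        unduplicated_cazy=int(cazy[has_cazy].nunique()),
    )


def diff_from_average(values: Mapping[str, float], focal_id: str) -> float:
    """Percent by which the focal value exceeds the all-genome mean.

    ``100 × (focal − mean(all, focal included)) / focal``; requires at
    least two genomes and a non-zero focal value.
    """
    if focal_id not in values:
        raise DomainError(f"focal genome {focal_id!r} not among values")
    if len(values) < 2:
        raise DomainError("need at least two genomes to compare")
    focal = values[focal_id]
    if focal == 0:
        raise DomainError(f"focal value for {focal_id!r} is zero")
    mean = float(np.mean(list(values.values())))
    return 100.0 * (focal - mean) / focal


def pct_larger_than_largest(values: Mapping[str, float], focal_id: str) -> float:
    """Percent by which the focal value exceeds the largest of the others."""
    if focal_id not in values:
        raise DomainError(f"focal genome {focal_id!r} not among values")
    others = [v for k, v in values.items() if k != focal_id]
    if not others:
        raise DomainError("need at least one non-focal genome")
    focal = values[focal_id]
    if focal == 0:
        raise DomainError(f"focal value for {focal_id!r} is zero")
    return 100.0 * (focal - max(others)) / focal


@dataclass
class ComparisonTable:
    """Comparison rows plus the focal genome's comparative percentages."""

    rows: list[GenomeStats]
    focal_id: str
    diff_from_average: dict[str, float]
    pct_larger_than_largest: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        diff_row = {c: "" for c in df.columns}
        diff_row["genome_id"] = "Difference from average"
        for col, pct in self.diff_from_average.items():
            diff_row[col] = f"{pct:.1f}%"
        out = pd.concat([df, pd.DataFrame([diff_row])], ignore_index=True)
        out.to_csv(path, sep="\t", index=False)


def build_comparison(rows: Sequence[GenomeStats], focal_id: str) -> ComparisonTable:
    """Assemble the comparison table with its difference-from-average row."""
    ids = [r.genome_id for r in rows]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate genome_id in comparison rows")
    if focal_id not in ids:
        raise DomainError(f"focal genome {focal_id!r} not among rows")
    if len(rows) < 2:
        raise DomainError("need at least two rows to compare")
    diffs = {
        col: diff_from_average(
            {r.genome_id: getattr(r, col) for r in rows}, focal_id
        )
        for col in NUMERIC_COLUMNS
    }
    pct = pct_larger_than_largest(
        {r.genome_id: r.genome_size for r in rows}, focal_id
    )
    return ComparisonTable(
        rows=list(rows),
        focal_id=focal_id,
        diff_from_average=diffs,
        pct_larger_than_largest=pct,
    )


def load_reference_table() -> list[GenomeStats]:
    """The seven published complete Saccharibacteria genomes, as stats rows."""
    with resources.files("sipscope.data").joinpath(
        "saccharibacteria_complete_genomes.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        GenomeStats(
            genome_id=row.genome_id,
            environment=row.environment,
            genome_size=int(row.genome_size),
            gene_number=int(row.gene_number),
            unannotated_genes=int(row.unannotated_genes),
            average_gene_size=float(row.average_gene_size),
            total_coding=int(row.total_coding),
            coding_density=float(row.coding_density),
            cazy_genes=int(row.cazy_genes),
            unduplicated_cazy=int(row.unduplicated_cazy),
        )
        for row in df.itertuples(index=False)
    ]
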