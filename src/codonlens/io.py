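"""Reading CDS FASTA and abundance tables, dataset filtering, table writers.

The dataset-construction protocol: read in-frame CDS records, read a
delimited protein-abundance table (replicate columns averaged into one
copies-per-cell value per gene), then keep only genes that occur exactly
once among the CDS records, have a matched abundance record, and have
non-zero expression.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CodingSequence, GeneDataset, validate_coding_sequence

logger = logging.getLogger("codonlens")

FLOAT_FORMAT = "%.6g"


@dataclass
class ExpressionRecord:
    """One gene's protein abundance; replicates averaged into e_k."""

    gene_id: str
    replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.replicates):
            raise ValueError(f"{self.gene_id}: negative abundance")
        if not self.replicates:
            raise ValueError(f"{self.gene_id}: no replicate values")

    @property
    def expression(self) -> float:
        return float(np.mean(self.replicates))


def read_cds_fasta(path) -> list[CodingSequence]:
    """Read a CDS FASTA; invalid records are dropped with logged counts.

    A record is kept when its length is a positive multiple of 3 and it
    contains no internal in-frame stop codon (a terminal stop is fine).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes: list[CodingSequence] = []
    n_dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = CodingSequence(rec.id, str(rec.seq))
        problems = validate_coding_sequence(seq)
        if problems:
            n_dropped += 1
            logger.warning("dropping record %r: %s", rec.id, "; ".join(problems))
            continue
        genes.append(seq)
    if not genes and n_dropped == 0:
        raise ValueError(f"no FASTA records in {path}")
    if n_dropped:
        logger.warning("dropped %d invalid CDS record(s); kept %d", n_dropped, len(genes))
    return genes


def write_cds_fasta(path, genes: Sequence[CodingSequence]) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.gene_id, description="") for g in genes]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_expression_table(
    path, id_column: str = "gene_id", value_columns: Sequence[str] | None = None, sep: str = "\t"
) -> list[ExpressionRecord]:
    """Read a delimited abundance table; replicate columns are averaged.

    ``value_columns`` defaults to every non-id column. Rows with any
    unparseable replicate value are dropped with a warning.
    """
    df = pd.read_csv(path, sep=sep)
    if id_column not in df.columns:
        raise ValueError(f"id column {id_column!r} not in table (have {list(df.columns)})")
    cols = list(value_columns) if value_columns else [c for c in df.columns if c != id_column]
    if not cols:
        raise ValueError("no value columns")
    vals = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = vals.isna().any(axis=1)
    if bad.any():
        logger.warning("dropping %d row(s) with unparseable abundance values", int(bad.sum()))
    records = [
        ExpressionRecord(str(gid), tuple(row))
        for gid, row in zip(df.loc[~bad, id_column], vals.loc[~bad].to_numpy())
    ]
    return records


def read_id_map(path) -> dict[str, str]:
    """Optional two-column (gene id -> abundance id) mapping table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "record_id"], dtype=str)
    return dict(zip(df["gene_id"], df["record_id"]))


@dataclass
class FilterReport:
    """Bookkeeping of how many genes each dataset filter removed."""

    n_input: int
    n_duplicate: int
    n_unmatched: int
    n_zero: int
    n_kept: int


def match_and_filter(
    genes: Sequence[CodingSequence],
    records: Sequence[ExpressionRecord],
    require_unique: bool = True,
    require_nonzero: bool = True,
    id_map: dict[str, str] | None = None,
) -> tuple[GeneDataset, FilterReport]:
    """Match genes to abundance records and apply the dataset filters.

    Keeps genes whose identifier occurs exactly once among the CDS
    records (when ``require_unique``; duplicated ids are removed
    entirely), that have a matched abundance record, and whose expression
    is strictly positive (when ``require_nonzero``).
    """
    id_counts = Counter(g.gene_id for g in genes)
    by_record = {r.gene_id: r.expression for r in records}
    kept, expr = [], []
    n_dup = n_unmatched = n_zero = 0
    seen = set()
    for g in genes:
        if require_unique and id_counts[g.gene_id] > 1:
            n_dup += 1
            continue
        if g.gene_id in seen:
            n_dup += 1
            continue
        key = id_map.get(g.gene_id, g.gene_id) if id_map else g.gene_id
        if key not in by_record:
            n_unmatched += 1
            continue
        e = by_record[key]
        if require_nonzero and e <= 0:
            n_zero += 1
            continue
        seen.add(g.gene_id)
        kept.append(g)
        expr.append(e)
    report = FilterReport(len(genes), n_dup, n_unmatched, n_zero, len(kept))
    logger.info(
        "match_and_filter: %d in, %d duplicated, %d unmatched, %d zero-expression, %d kept",
        report.n_input, n_dup, n_unmatched, n_zero, report.n_kept,
    )
    if not kept:
        raise ValueError("no genes left after matching and filtering")
    return GeneDataset(kept, np.array(expr)), report


# ---------------------------------------------------------------- writers


def write_table(df: pd.DataFrame, path) -> None:
    """All result tables are tab-separated with a header, 6 sig. digits."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_expression_table(path, dataset: GeneDataset) -> None:
    write_table(
        pd.DataFrame({"gene_id": dataset.gene_ids, "expression": dataset.expressions}), path
    )


def write_class_distributions(path, classes, columns) -> None:
    df = pd.DataFrame({"codon": list(columns)})
    for cls in classes:
        df[f"class_{cls.label}"] = cls.distribution
    write_table(df, path)


def write_model(path, model) -> None:
    """Persist a fitted regression as a small key-value text file."""
    with open(path, "w") as fh:
        fh.write(f"index_kind\t{model.index_kind}\n")
        fh.write(f"a\t{model.a!r}\n")
        fh.write(f"b\t{model.b!r}\n")
        fh.write(f"log_base\t{model.log_base}\n")


def write_manifest(path, config: dict) -> None:
    """Echo the run configuration (and package version) next to outputs."""
    from . import __version__

    payload = {"codonlens_version": __version__, **config}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
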