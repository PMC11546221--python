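"""Genetic-code tables, codon/codon-pair counting and expression classes.

The standard genetic code (translation table 1) has 61 sense codons and
3 stop codons; all counting in this package is over sense codons (or the
3721 ordered pairs of sense codons) in a fixed alphabetical column order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

logger = logging.getLogger("codonlens")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class GeneticCode:
    """Immutable sense/stop codon tables for translation table 1.

    ``sense_codons`` fixes the column order used by every count and
    frequency matrix in the package (alphabetical over A<C<G<T).
    """

    sense_codons: tuple[str, ...]
    stop_codons: frozenset[str]
    codon_to_aa: dict[str, str]
    synonym_groups: dict[str, tuple[str, ...]]
    codon_index: dict[str, int] = field(repr=False)
    pair_index: dict[str, int] = field(repr=False)

    @property
    def sense_pairs(self) -> tuple[str, ...]:
        return tuple(sorted(self.pair_index, key=self.pair_index.get))

    @property
    def n_codons(self) -> int:
        return len(self.sense_codons)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_index)


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    """The standard genetic code: 61 sense codons, stops TAA/TAG/TGA."""
    table = CodonTable.unambiguous_dna_by_id[1]
    codon_to_aa = {c: aa for c, aa in table.forward_table.items()}
    sense = tuple(sorted(codon_to_aa))
    groups: dict[str, list[str]] = {}
    for codon in sense:
        groups.setdefault(codon_to_aa[codon], []).append(codon)
    pairs = {a + b: i for i, (a, b) in enumerate(product(sense, repeat=2))}
    return GeneticCode(
        sense_codons=sense,
        stop_codons=frozenset(table.stop_codons),
        codon_to_aa=codon_to_aa,
        synonym_groups={aa: tuple(cs) for aa, cs in groups.items()},
        codon_index={c: i for i, c in enumerate(sense)},
        pair_index=pairs,
    )


@dataclass
class CodingSequence:
    """An in-frame coding sequence (CDS) with its gene identifier.

    The stored sequence may keep its terminal stop codon; counting
    operations strip it. Internal in-frame stops are invalid.
    """

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def codons(self) -> list[str]:
        """In-frame codons with any terminal stop codon stripped."""
        seq = self.sequence
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id!r}: length {len(seq)} is not a positive multiple of 3"
            )
        cods = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if cods and cods[-1] in STOP_CODONS:
            cods = cods[:-1]
        if not cods:
            raise ValueError(f"gene {self.gene_id!r}: no codons left after stop stripping")
        return cods


def validate_coding_sequence(seq: CodingSequence) -> list[str]:
    """Return a list of invariant violations (empty when valid)."""
    problems = []
    try:
        cods = seq.codons()
    except ValueError as exc:
        return [str(exc)]
    for pos, c in enumerate(cods, start=1):
        if c in STOP_CODONS:
            problems.append(f"internal stop codon {c} at codon {pos}")
    return problems


def count_codons(seq: CodingSequence, code: GeneticCode | None = None) -> np.ndarray:
    """Count sense-codon occurrences of a CDS over the 61 columns.

    The terminal stop is stripped; an internal in-frame stop is a hard
    error. Codons containing non-ACGT letters are skipped with a warning.
    """
    code = code or standard_code()
    counts = np.zeros(code.n_codons, dtype=np.int64)
    for pos, c in enumerate(seq.codons(), start=1):
        if c in code.stop_codons:
            raise ValueError(f"gene {seq.gene_id!r}: internal stop codon at codon {pos}")
        idx = code.codon_index.get(c)
        if idx is None:
            logger.warning("gene %r: skipping non-ACGT codon %r at codon %d", seq.gene_id, c, pos)
            continue
        counts[idx] += 1
    return counts


def count_codon_pairs(seq: CodingSequence, code: GeneticCode | None = None) -> np.ndarray:
    """Count overlapping adjacent in-frame sense-codon pairs (3721 columns).

    A gene of l sense codons contributes l - 1 pairs. Pairs touching a
    skipped (non-ACGT) codon are themselves skipped.
    """
    code = code or standard_code()
    counts = np.zeros(code.n_pairs, dtype=np.int64)
    cods = seq.codons()
    for pos, c in enumerate(cods, start=1):
        if c in code.stop_codons:
            raise ValueError(f"gene {seq.gene_id!r}: internal stop codon at codon {pos}")
    for i in range(len(cods) - 1):
        idx = code.pair_index.get(cods[i] + cods[i + 1])
        if idx is None:
            logger.warning(
                "gene %r: skipping pair with non-ACGT codon at codons %d-%d",
                seq.gene_id, i + 1, i + 2,
            )
            continue
        counts[idx] += 1
    return counts


@dataclass
class CodonCountMatrix:
    """K x M table of unit counts n_kc (M = 61 codons or 3721 pairs)."""

    gene_ids: list[str]
    unit: str  # "codon" or "pair"
    counts: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.gene_ids), len(self.columns)):
            raise ValueError("count matrix shape does not match gene_ids/columns")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def K(self) -> int:
        return len(self.gene_ids)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def rows(self, idx) -> "CodonCountMatrix":
        idx = np.asarray(idx)
        return CodonCountMatrix(
            [self.gene_ids[i] for i in idx], self.unit, self.counts[idx], self.columns
        )


@dataclass
class CodonFrequencyMatrix:
    """K x M table of per-gene unit fractions p_kc; rows sum to 1."""

    gene_ids: list[str]
    unit: str
    values: np.ndarray
    columns: tuple[str, ...]

    @property
    def K(self) -> int:
        return len(self.gene_ids)


def build_count_matrix(
    genes: Sequence[CodingSequence], code: GeneticCode | None = None, unit: str = "codon"
) -> CodonCountMatrix:
    """Stack per-gene codon (or pair) counts into a K x M matrix."""
    code = code or standard_code()
    if unit == "codon":
        counter, columns = count_codons, code.sense_codons
    elif unit == "pair":
        counter, columns = count_codon_pairs, code.sense_pairs
    else:
        raise ValueError(f"unknown unit {unit!r}")
    counts = np.vstack([counter(g, code) for g in genes]) if genes else np.zeros((0, len(columns)), dtype=np.int64)
    return CodonCountMatrix([g.gene_id for g in genes], unit, counts, columns)


def to_frequencies(counts: CodonCountMatrix) -> CodonFrequencyMatrix:
    """Convert counts to per-gene fractions p_kc = n_kc / sum_c n_kc."""
    totals = counts.row_totals
    if (totals == 0).any():
        bad = [counts.gene_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"genes with zero counted units: {bad[:5]}")
    return CodonFrequencyMatrix(
        counts.gene_ids, counts.unit, counts.counts / totals[:, None], counts.columns
    )


@dataclass
class GeneDataset:
    """Matched coding sequences and per-gene expression values e_k."""

    genes: list[CodingSequence]
    expressions: np.ndarray

    def __post_init__(self) -> None:
        self.expressions = np.asarray(self.expressions, dtype=float)
        if len(self.genes) != len(self.expressions):
            raise ValueError("genes and expressions must have equal length")

    @property
    def K(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class ExpressionClass:
    """A contiguous expression class with its pooled codon distribution."""

    label: int | str
    gene_ids: list[str]
    distribution: np.ndarray


def class_distribution(counts: CodonCountMatrix, row_idx=None) -> np.ndarray:
    """Pooled codon frequencies of a set of genes (sums to 1).

    Counts are pooled over the class and divided by the pooled total --
    long genes weigh more than short ones, as in a per-class tally.
    """
    sub = counts.counts if row_idx is None else counts.counts[np.asarray(row_idx, dtype=np.intp)]
    if sub.shape[0] == 0:
        raise ValueError("empty class")
    pooled = sub.sum(axis=0)
    total = pooled.sum()
    if total == 0:
        raise ValueError("class has no counted codons")
    return pooled / total


def split_into_classes(
    dataset: GeneDataset,
    counts: CodonCountMatrix | None = None,
    n_classes: int = 4,
    code: GeneticCode | None = None,
) -> list[ExpressionClass]:
    """Partition genes into expression classes of (near-)equal size.

    Genes are sorted by decreasing expression (ties keep input order) and
    cut into ``n_classes`` contiguous blocks; any remainder goes to the
    earliest (highest-expression) classes. Class 1 holds the
    highest-expressed genes. Each class carries its pooled, normalised
    codon distribution.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    if dataset.K < n_classes:
        raise ValueError(f"need at least {n_classes} genes, got {dataset.K}")
    if counts is None:
        counts = build_count_matrix(dataset.genes, code)
    order = np.argsort(-dataset.expressions, kind="stable")
    base, rem = divmod(dataset.K, n_classes)
    sizes = [base + (1 if j < rem else 0) for j in range(n_classes)]
    classes, start = [], 0
    for j, size in enumerate(sizes, start=1):
        idx = order[start : start + size]
        start += size
        classes.append(
            ExpressionClass(
                label=j,
                gene_ids=[dataset.gene_ids[i] for i in idx],
                distribution=class_distribution(counts, idx),
            )
        )
    return classes


def distribution_correlation(d1: np.ndarray, d2: np.ndarray) -> float:
    """Pearson correlation between two codon-frequency distributions."""
    d1, d2 = np.asarray(d1, dtype=float), np.asarray(d2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("distributions must have equal length")
    if np.ptp(d1) == 0 or np.ptp(d2) == 0:
        raise ValueError("zero-variance distribution")
    return float(stats.pearsonr(d1, d2).statistic)


def class_correlation_matrix(classes: Sequence[ExpressionClass]) -> np.ndarray:
    """Symmetric Pearson-correlation matrix between class distributions."""
    n = len(classes)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = distribution_correlation(classes[i].distribution, classes[j].distribution)
            mat[i, j] = mat[j, i] = r
    return mat
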