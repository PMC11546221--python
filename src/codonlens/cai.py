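"""Codon Adaptation Index with a top-quartile training reference set.

CAI scores a gene by the geometric mean of each codon's relative
adaptiveness w_c = f_c / max(f_synonym) computed from a reference set of
highly expressed genes. Here the reference set is the top quarter (by
expression) of each cross-validation training fold, so CAI is evaluated
under exactly the same harness as the codon-index predictors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CodonCountMatrix,
    GeneDataset,
    GeneticCode,
    build_count_matrix,
    standard_code,
)
from .predict import PredictionReport, pooled_cv


@dataclass
class CAIWeights:
    """Per-sense-codon relative adaptiveness in (0, 1]."""

    weights: np.ndarray  # aligned with code.sense_codons
    columns: tuple[str, ...]
    reference_gene_ids: list[str]

    def to_frame(self, code: GeneticCode) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon": list(self.columns),
                "amino_acid": [code.codon_to_aa[c] for c in self.columns],
                "w": self.weights,
            }
        )


def cai_weights(
    reference: CodonCountMatrix, code: GeneticCode | None = None
) -> CAIWeights:
    """Relative adaptiveness from pooled reference-set codon counts.

    Within each synonym group w_c = count_c / max synonymous count, so the
    preferred codon gets w = 1 (single-codon amino acids ATG/TGG always
    do). Codons unseen in the reference get a pseudo-weight of
    0.5 / max-count so the geometric mean never collapses to zero.
    """
    code = code or standard_code()
    if reference.K == 0:
        raise ValueError("empty reference set")
    pooled = reference.counts.sum(axis=0).astype(float)
    w = np.empty_like(pooled)
    missing = []
    for aa, codons in code.synonym_groups.items():
        idx = [code.codon_index[c] for c in codons]
        mx = pooled[idx].max()
        if mx == 0:
            missing.append(aa)
            continue
        grp = pooled[idx] / mx
        grp[grp == 0] = 0.5 / mx
        w[idx] = grp
    if missing:
        raise ValueError(f"amino acid(s) absent from reference set: {sorted(missing)}")
    return CAIWeights(w, reference.columns, list(reference.gene_ids))


def cai_score(counts_row: np.ndarray, weights: CAIWeights) -> float:
    """Geometric mean of w over a gene's codons, computed in log space."""
    n = np.asarray(counts_row, dtype=float)
    total = n.sum()
    if total == 0:
        raise ValueError("gene has no sense codons")
    return math.exp(float(n @ np.log(weights.weights)) / total)


def evaluate_cai(
    dataset: GeneDataset,
    n_folds: int = 11,
    code: GeneticCode | None = None,
    counts: CodonCountMatrix | None = None,
    rescale: bool = True,
) -> PredictionReport:
    """CAI under the interleaved cross-validation harness.

    Per fold: reference set = the floor(K_train / 4) highest-expressed
    training genes (minimum 2); CAI scored on the test genes; the same
    affine regression step as the codon-index predictors is applied for
    comparability (Pearson r is unaffected by it).
    """
    code = code or standard_code()
    if counts is None:
        counts = build_count_matrix(dataset.genes, code, unit="codon")
    e = dataset.expressions

    def factory(train_idx: np.ndarray):
        order = train_idx[np.argsort(-e[train_idx], kind="stable")]
        n_ref = max(2, len(train_idx) // 4)
        weights = cai_weights(counts.rows(order[:n_ref]), code)
        logw = np.log(weights.weights)

        def scorer(rows_idx: np.ndarray):
            sub = counts.counts[rows_idx].astype(float)
            totals = sub.sum(axis=1)
            if (totals == 0).any():
                raise ValueError("gene(s) with no sense codons")
            scores = np.exp(sub @ logw / totals)
            return scores, np.zeros(len(rows_idx))

        return scorer

    return pooled_cv(counts, e, factory, "cai", n_folds, rescale)
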