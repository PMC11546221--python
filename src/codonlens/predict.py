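"""Gene-level expression prediction from codon indices (CEIS / CPS / CPEIS).

A gene's score C_k is the mean index value over its codon occurrences
(count-weighted mean over the 61 codons, identical to averaging over the
codon sequence). Scores are mapped to log abundance log(e_k + 1), natural
log, by ordinary least squares P_k = a C_k + b, and accuracy is the
Pearson correlation between pooled out-of-fold predictions and actual log
values under interleaved 11-fold cross-validation: genes are sorted by
decreasing expression and every 11th gene forms a test fold, so each fold
spans the full expression range and every gene is tested exactly once.
Index values (and CAI reference sets) are always computed from the
training fold only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CodonCountMatrix,
    GeneDataset,
    GeneticCode,
    build_count_matrix,
    standard_code,
    to_frequencies,
)
from .indices import compute_cei, compute_cp

logger = logging.getLogger("codonlens")


def log_expression(e) -> np.ndarray | float:
    """Natural log of (e + 1); maps 0 copies per cell to 0."""
    arr = np.asarray(e, dtype=float)
    if (arr < 0).any():
        raise ValueError("expression values must be non-negative")
    out = np.log1p(arr)
    return float(out) if np.isscalar(e) or arr.ndim == 0 else out


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors with at least 2 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    return float(stats.pearsonr(x, y).statistic)


def gene_score(counts_row: np.ndarray, index_values: np.ndarray) -> float:
    """Count-weighted mean of an index over one gene's codon occurrences.

    Units with an undefined index value (NaN) are skipped and the
    denominator renormalised to the remaining occurrences.
    """
    counts_row = np.asarray(counts_row, dtype=float)
    index_values = np.asarray(index_values, dtype=float)
    defined = np.isfinite(index_values)
    denom = counts_row[defined].sum()
    if denom == 0:
        raise ValueError("gene has no codon with a defined index value")
    return float(counts_row[defined] @ index_values[defined] / denom)


def _gene_scores(counts: np.ndarray, index_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised gene_score over matrix rows; also returns the skipped
    fraction of each gene's counted units."""
    defined = np.isfinite(index_values)
    denom = counts[:, defined].sum(axis=1).astype(float)
    total = counts.sum(axis=1).astype(float)
    if (denom == 0).any():
        raise ValueError("gene(s) with no codon carrying a defined index value")
    scores = counts[:, defined] @ index_values[defined] / denom
    return scores, 1.0 - denom / total


@dataclass
class RegressionModel:
    """Affine map P = a*C + b from gene score to log expression."""

    index_kind: str
    a: float
    b: float
    index_values: np.ndarray | None = None
    log_base: str = "natural"

    def predict(self, scores) -> np.ndarray:
        return self.a * np.asarray(scores, dtype=float) + self.b


def fit_regression(scores, log_expressions, index_kind: str = "cei") -> RegressionModel:
    """Ordinary least squares fit of log expression on gene scores."""
    C = np.asarray(scores, dtype=float)
    y = np.asarray(log_expressions, dtype=float)
    if C.size < 2 or C.shape != y.shape:
        raise ValueError("need at least 2 matched (score, log expression) points")
    var = np.var(C)
    if var == 0:
        raise ValueError("zero score variance: regression is degenerate")
    a = float(np.cov(C, y, bias=True)[0, 1] / var)
    b = float(y.mean() - a * C.mean())
    return RegressionModel(index_kind, a, b)


@dataclass
class CVPlan:
    """Interleaved fold assignment over the expression-sorted gene order."""

    n_folds: int
    fold_assignments: np.ndarray  # per-gene (input order) test-fold id

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments != fold)


def make_cv_plan(expressions, n_folds: int = 11) -> CVPlan:
    """Sort genes by decreasing expression (stable) and deal them round-
    robin into ``n_folds`` test folds, so each fold spans the range."""
    e = np.asarray(expressions, dtype=float)
    if e.size < n_folds:
        raise ValueError(f"need at least {n_folds} genes, got {e.size}")
    order = np.argsort(-e, kind="stable")
    folds = np.empty(e.size, dtype=int)
    folds[order] = np.arange(e.size) % n_folds
    return CVPlan(n_folds, folds)


@dataclass
class PredictionReport:
    """Pooled out-of-fold predictions and their accuracy."""

    index_kind: str
    gene_ids: list[str]
    scores: np.ndarray  # raw gene scores C_k (out-of-fold)
    predicted_log: np.ndarray  # P_k
    actual_log: np.ndarray  # log(e_k + 1)
    fold: np.ndarray
    r: float
    skipped_fraction: np.ndarray | None = None
    strata: pd.DataFrame | None = None

    @property
    def predicted_copies(self) -> np.ndarray:
        """Back-transformed predictions, exp(P) - 1 clamped at 0."""
        return np.maximum(np.expm1(self.predicted_log), 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "score": self.scores,
                "predicted_log": self.predicted_log,
                "actual_log": self.actual_log,
                "fold": self.fold,
            }
        )


# index providers: train-rows counts + expressions -> per-unit values (NaN = undefined)


def _cei_values(counts: CodonCountMatrix, e: np.ndarray) -> np.ndarray:
    res = compute_cei(to_frequencies(counts), e)
    vals = res.z.copy()
    vals[res.undefined] = np.nan  # unobserved units never enter gene scores
    return vals


def _cp_values(counts: CodonCountMatrix, e: np.ndarray) -> np.ndarray:
    return compute_cp(counts, e).productivity


_PROVIDERS: dict[str, tuple[str, Callable]] = {
    "cei": ("codon", _cei_values),
    "cp": ("codon", _cp_values),
    "cpei": ("pair", _cei_values),
}


def pooled_cv(
    counts: CodonCountMatrix,
    expressions: np.ndarray,
    score_factory: Callable[[np.ndarray], Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]],
    index_kind: str,
    n_folds: int = 11,
    rescale: bool = True,
) -> PredictionReport:
    """Generic interleaved-CV engine shared by CEIS/CPS/CPEIS and CAI.

    ``score_factory(train_idx)`` returns a scorer mapping row indices to
    (gene scores, skipped-unit fractions), fitted on the training rows
    only. With ``rescale=False`` the raw scores are reported as
    predictions (Pearson r is unaffected by a common affine map; per-fold
    maps can differ minutely between folds).
    """
    e = np.asarray(expressions, dtype=float)
    y = log_expression(e)
    plan = make_cv_plan(e, n_folds)
    P = np.empty(e.size)
    C = np.empty(e.size)
    skipped = np.zeros(e.size)
    for j in range(n_folds):
        train, test = plan.train_indices(j), plan.test_indices(j)
        scorer = score_factory(train)
        c_train, _ = scorer(train)
        try:
            model = fit_regression(c_train, y[train], index_kind)
        except ValueError as exc:
            raise ValueError(f"fold {j}: {exc}") from exc
        c_test, skip_test = scorer(test)
        C[test] = c_test
        skipped[test] = skip_test
        P[test] = model.predict(c_test) if rescale else c_test
    if skipped.any():
        logger.info("mean fraction of skipped (train-unobserved) units: %.4g", skipped.mean())
    return PredictionReport(
        index_kind=index_kind,
        gene_ids=list(counts.gene_ids),
        scores=C,
        predicted_log=P,
        actual_log=y,
        fold=plan.fold_assignments,
        r=pearson_r(P, y),
        skipped_fraction=skipped,
    )


def cross_validate(
    dataset: GeneDataset,
    index_kind: str = "cei",
    n_folds: int = 11,
    rescale: bool = True,
    code: GeneticCode | None = None,
    counts: CodonCountMatrix | None = None,
) -> PredictionReport:
    """Cross-validated expression prediction (CEIS, CPS or CPEIS).

    For each fold the index (CEI Z-values, CP values, or pair-CEI) and
    the affine regression are fitted on the training genes only;
    predictions for the test genes are pooled and scored by Pearson r
    against log(e + 1).
    """
    if index_kind not in _PROVIDERS:
        raise ValueError(f"unknown index kind {index_kind!r}")
    unit, provider = _PROVIDERS[index_kind]
    code = code or standard_code()
    if counts is None:
        counts = build_count_matrix(dataset.genes, code, unit=unit)
    e = dataset.expressions

    def factory(train_idx: np.ndarray):
        vals = provider(counts.rows(train_idx), e[train_idx])

        def scorer(rows_idx: np.ndarray):
            return _gene_scores(counts.counts[rows_idx], vals)

        return scorer

    return pooled_cv(counts, e, factory, index_kind, n_folds, rescale)


def stratified_accuracy(report: PredictionReport, log_thresholds) -> pd.DataFrame:
    """Prediction accuracy restricted to genes above each log-expression
    threshold: rows of (log range, copies range, gene count, r).

    Strata with fewer than 3 genes (or constant values) are flagged with
    an unset r.
    """
    y = report.actual_log
    top = float(y.max())
    rows = []
    for t in log_thresholds:
        mask = y >= t
        n = int(mask.sum())
        r = np.nan
        flagged = True
        if n >= 3 and np.ptp(y[mask]) > 0 and np.ptp(report.predicted_log[mask]) > 0:
            r = pearson_r(report.predicted_log[mask], y[mask])
            flagged = False
        rows.append(
            {
                "log_min": float(t),
                "log_max": top,
                "copies_min": max(math.expm1(t), 0.0) if t < 700 else math.inf,
                "n_genes": n,
                "r": r,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)
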