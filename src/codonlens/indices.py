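"""Codon Expression Index (CEI), its shuffle null, and Codon Productivity (CP).

CEI assigns each sense codon (or codon pair) a Z-score of the Kendall
rank correlation between the unit's per-gene frequency and per-gene
protein abundance:

    tau_c = 2 / (K(K-1)) * sum_{j<k} sgn(p_jc - p_kc) * sgn(e_j - e_k)
    Z_c   = 3 tau_c sqrt(K(K-1)) / sqrt(2(2K+5))

This is Kendall's tau-a: tied pairs contribute zero and no tie correction
is applied. |Z| > 3 marks a codon whose frequency co-varies with
expression beyond what independent rankings would produce.

Codon Productivity is the abundance-weighted mean expression of the genes
a codon occurs in: CP_c = (sum_k e_k n_kc) / (sum_k n_kc) -- the average
number of amino-acid copies the cell produces per occurrence of codon c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CodonCountMatrix, CodonFrequencyMatrix

SIGNIFICANCE_BOUNDARY = 3.0


def _tie_term(x: np.ndarray) -> int:
    """sum over tie groups of t*(t-1)/2."""
    _, counts = np.unique(x, return_counts=True)
    return int((counts * (counts - 1) // 2).sum())


def kendall_tau_a(x, y) -> float:
    """Kendall's tau-a: (concordant - discordant) / (K choose 2).

    Tied pairs in either vector contribute zero to the numerator and are
    NOT removed from the denominator (no tau-b tie correction). Computed
    in O(K log K) by recovering the concordant-minus-discordant count
    from SciPy's tau-b statistic and the tie counts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    K = x.size
    if K < 2:
        raise ValueError("need at least 2 observations")
    n0 = K * (K - 1) // 2
    n1, n2 = _tie_term(x), _tie_term(y)
    if n1 == n0 or n2 == n0:
        return 0.0  # one vector constant: every sign product is zero
    tau_b = stats.kendalltau(x, y).statistic
    if np.isnan(tau_b):
        return 0.0
    s = round(tau_b * math.sqrt((n0 - n1) * (n0 - n2)))  # concordant - discordant
    return s / n0


def z_value(tau: float, K: int) -> float:
    """Z-score of a Kendall tau under the independence null.

    Z = 3 tau sqrt(K(K-1)) / sqrt(2(2K+5)); the number of standard
    deviations tau sits from what independent rankings would give.
    """
    if K < 2:
        raise ValueError("need at least 2 observations")
    return 3.0 * tau * math.sqrt(K * (K - 1)) / math.sqrt(2.0 * (2 * K + 5))


@dataclass
class CEIResult:
    """Per-unit tau and Z (the Codon Expression Index)."""

    unit: str
    columns: tuple[str, ...]
    tau: np.ndarray
    z: np.ndarray
    K: int
    undefined: np.ndarray  # units absent from every gene (tau = Z = 0)

    @property
    def significant(self) -> np.ndarray:
        return np.abs(self.z) > SIGNIFICANCE_BOUNDARY

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.unit: list(self.columns),
                "tau": self.tau,
                "z": self.z,
                "significant": self.significant,
                "unobserved": self.undefined,
            }
        )


def compute_cei(freqs: CodonFrequencyMatrix, expressions) -> CEIResult:
    """Codon Expression Index: per-unit Kendall tau-a and Z versus expression.

    One (tau_c, Z_c) per column of the frequency matrix (61 codons or
    3721 pairs). Units absent from every gene get tau = Z = 0 and are
    flagged as unobserved.
    """
    e = np.asarray(expressions, dtype=float)
    if freqs.K != e.size:
        raise ValueError(f"{freqs.K} frequency rows but {e.size} expression values")
    if freqs.K < 2:
        raise ValueError("need at least 2 genes")
    M = len(freqs.columns)
    tau = np.zeros(M)
    undefined = np.zeros(M, dtype=bool)
    vals = freqs.values
    for c in range(M):
        col = vals[:, c]
        if not col.any():
            undefined[c] = True
            continue
        tau[c] = kendall_tau_a(col, e)
    z = 3.0 * tau * math.sqrt(freqs.K * (freqs.K - 1)) / math.sqrt(2.0 * (2 * freqs.K + 5))
    return CEIResult(freqs.unit, freqs.columns, tau, z, freqs.K, undefined)


@dataclass
class NullDistribution:
    """Z-scores obtained against randomly shuffled expression vectors."""

    z_values: np.ndarray  # (n_shuffles, M)
    n_shuffles: int
    seed: int

    @property
    def max_abs_z(self) -> float:
        return float(np.abs(self.z_values).max())


def shuffle_null(
    freqs: CodonFrequencyMatrix, expressions, n_shuffles: int = 1, seed: int = 0
) -> NullDistribution:
    """Null Z-scores from seeded uniform permutations of the expressions.

    Calibrates the |Z| > 3 significance boundary: with frequencies and
    expressions made independent by shuffling, Z should behave like a
    standard normal and stay within +/-3.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    e = np.asarray(expressions, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_shuffles):
        perm = rng.permutation(e.size)
        rows.append(compute_cei(freqs, e[perm]).z)
    return NullDistribution(np.vstack(rows), n_shuffles, seed)


@dataclass
class CPResult:
    """Per-codon Codon Productivity and its building blocks."""

    unit: str
    columns: tuple[str, ...]
    amino_acid_totals: np.ndarray  # A_c = sum_k e_k n_kc
    appearance_totals: np.ndarray  # N_c = sum_k n_kc
    productivity: np.ndarray  # CP_c = A_c / N_c, NaN where N_c = 0
    undefined: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.unit: list(self.columns),
                "A": self.amino_acid_totals,
                "N": self.appearance_totals,
                "CP": self.productivity,
                "undefined": self.undefined,
            }
        )


def compute_cp(counts: CodonCountMatrix, expressions) -> CPResult:
    """Codon Productivity: CP_c = sum_k e_k n_kc / sum_k n_kc.

    A count-weighted mean of expression over the genes each codon occurs
    in, so min(e) <= CP_c <= max(e). Codons never observed (N_c = 0) are
    flagged undefined and their CP left unset (NaN).
    """
    e = np.asarray(expressions, dtype=float)
    if counts.K != e.size:
        raise ValueError(f"{counts.K} count rows but {e.size} expression values")
    A = counts.counts.T.astype(float) @ e
    N = counts.counts.sum(axis=0).astype(float)
    undefined = N == 0
    cp = np.full_like(A, np.nan)
    np.divide(A, N, out=cp, where=~undefined)
    return CPResult(counts.unit, counts.columns, A, N, cp, undefined)
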