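"""Synthetic CDS + abundance datasets with planted per-codon expression effects.

The generator isolates the signal the codon indices are built to detect:
each gene draws a latent expression propensity u ~ Uniform(0, 1); its
amino-acid backbone is uniform (independent of u), and within every
synonym group codons are chosen with probabilities linearly tilted by the
planted weights, p_c = (1 + tilt * u * w_c) / m (group weights sum to 0,
so the group's total mass and every zero-weight codon's share are exactly
independent of u). Log expression is then an affine function of the
gene's realised mean planted weight plus Gaussian noise:

    log(e + 1) = intercept + effect_scale * mean_w + Normal(0, noise_sd)

so positive-weight codons are enriched in highly expressed genes,
negative-weight codons depleted, and zero-weight codons carry no signal
-- giving known ground truth for sign recovery and null calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CodingSequence, GeneDataset, GeneticCode, standard_code

STOPS = ("TAA", "TAG", "TGA")

# pair preset: extra planted effects on adjacent pairs of codon-neutral codons
PAIR_PLUS = ("GCT", "GGT")
PAIR_MINUS = ("GCG", "GGG")


def full_preset_weights(code: GeneticCode | None = None) -> dict[str, float]:
    """One +1 and one -1 codon per multi-codon synonym group (alphabetical
    first two), remaining synonyms and single-codon amino acids at 0."""
    code = code or standard_code()
    w = {}
    for codons in code.synonym_groups.values():
        for i, c in enumerate(sorted(codons)):
            w[c] = 1.0 if i == 0 and len(codons) > 1 else (-1.0 if i == 1 else 0.0)
    return w


def pair_preset_weights() -> dict[str, float]:
    """Planted weights on specific adjacent codon pairs (added on top of
    the full codon-level preset to exercise the pair index)."""
    pw = {}
    for c1 in PAIR_PLUS:
        for c2 in PAIR_PLUS:
            pw[c1 + c2] = 1.0
    for c1 in PAIR_MINUS:
        for c2 in PAIR_MINUS:
            pw[c1 + c2] = -1.0
    return pw


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``effect_scale`` defaults to the value that maps the expected mean
    planted weight at u = 1 onto the top of ``expression_range``, so
    generated abundances span roughly the range quantitative proteomics
    reports for E. coli (a fraction of a copy up to tens of thousands of
    copies per cell). ``noise_sd`` is on the ln(e + 1) scale.
    """

    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (50, 500)
    preset: str = "full"  # "full" or "pair"
    codon_weights: dict[str, float] | None = None
    pair_weights: dict[str, float] | None = None
    tilt: float = 0.9
    effect_scale: float | None = None
    noise_sd: float = 1.0
    expression_range: tuple[float, float] = (0.0, 38022.0)
    seed: int = 0

    def resolved_weights(self, code: GeneticCode) -> tuple[dict[str, float], dict[str, float]]:
        cw = dict(self.codon_weights) if self.codon_weights is not None else full_preset_weights(code)
        if self.pair_weights is not None:
            pw = dict(self.pair_weights)
        elif self.preset == "pair":
            pw = pair_preset_weights()
        else:
            pw = {}
        return cw, pw

    def resolved_scale(self, code: GeneticCode, cw: dict[str, float]) -> tuple[float, float]:
        """(intercept, effect_scale) honouring expression_range."""
        lo, hi = self.expression_range
        intercept = math.log1p(lo)
        if self.effect_scale is not None:
            return intercept, self.effect_scale
        # expected per-codon planted weight at u = 1 under the linear tilt
        groups = list(code.synonym_groups.values())
        exp_w = 0.0
        for codons in groups:
            w = np.array([cw.get(c, 0.0) for c in codons])
            p = 1.0 + self.tilt * w
            exp_w += float((p * w).sum() / p.sum())
        exp_w /= len(groups)
        if exp_w <= 0:
            raise ValueError("cannot derive effect_scale: planted weights have no positive drift")
        return intercept, (math.log1p(hi) - intercept) / exp_w


@dataclass
class GroundTruth:
    """Planted parameters and per-gene latents of a generated dataset."""

    u: np.ndarray
    mean_weight: np.ndarray  # realised mean planted weight per gene
    codon_weights: dict[str, float]
    pair_weights: dict[str, float]
    intercept: float
    effect_scale: float

    def to_frame(self, gene_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": gene_ids, "u": self.u, "mean_weight": self.mean_weight}
        )


def _validate(config: SyntheticConfig, cw: dict[str, float]) -> None:
    lo, hi = config.gene_length_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid gene_length_range")
    if config.n_genes < 1:
        raise ValueError("n_genes must be positive")
    if not (0 <= config.tilt < 1):
        raise ValueError("tilt must be in [0, 1)")
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if any(abs(w) > 1 for w in cw.values()):
        raise ValueError("codon weights must lie in [-1, 1]")


def generate_dataset(config: SyntheticConfig) -> tuple[GeneDataset, GroundTruth]:
    """Generate a matched CDS + abundance dataset with known ground truth.

    Deterministic for a fixed config (one seeded generator drives every
    draw). Each CDS gets a terminal stop codon and satisfies all coding
    sequence invariants.
    """
    code = standard_code()
    cw, pw = config.resolved_weights(code)
    _validate(config, cw)
    intercept, scale = config.resolved_scale(code, cw)
    rng = np.random.default_rng(config.seed)
    aas = sorted(code.synonym_groups)
    group_codons = {aa: sorted(code.synonym_groups[aa]) for aa in aas}
    group_w = {aa: np.array([cw.get(c, 0.0) for c in group_codons[aa]]) for aa in aas}

    lo, hi = config.gene_length_range
    genes: list[CodingSequence] = []
    u_arr = np.empty(config.n_genes)
    mw_arr = np.empty(config.n_genes)
    log_e = np.empty(config.n_genes)
    width = len(str(config.n_genes))
    for g in range(config.n_genes):
        l = int(rng.integers(lo, hi + 1))
        u = float(rng.uniform())
        aa_idx = rng.integers(0, len(aas), size=l)
        codons = _draw_codons(rng, aa_idx, aas, group_codons, group_w, pw, config.tilt, u)
        w_sum = sum(cw.get(c, 0.0) for c in codons)
        if pw:
            w_sum += sum(pw.get(codons[i] + codons[i + 1], 0.0) for i in range(l - 1))
        mean_w = w_sum / l
        noise = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0
        stop = STOPS[int(rng.integers(0, 3))]
        gene_id = f"gene_{g + 1:0{width}d}"
        genes.append(CodingSequence(gene_id, "".join(codons) + stop))
        u_arr[g] = u
        mw_arr[g] = mean_w
        log_e[g] = intercept + scale * mean_w + noise
    e = np.maximum(np.expm1(log_e), 0.0)
    truth = GroundTruth(u_arr, mw_arr, cw, pw, intercept, scale)
    return GeneDataset(genes, e), truth


def _draw_codons(rng, aa_idx, aas, group_codons, group_w, pw, tilt, u) -> list[str]:
    if not pw:
        # no pair effects: draw all positions of each amino acid at once
        codons = [""] * len(aa_idx)
        for a in range(len(aas)):
            pos = np.flatnonzero(aa_idx == a)
            if pos.size == 0:
                continue
            cods = group_codons[aas[a]]
            p = 1.0 + tilt * u * group_w[aas[a]]
            p = p / p.sum()
            picks = rng.choice(len(cods), size=pos.size, p=p)
            for j, k in zip(pos, picks):
                codons[j] = cods[k]
        return codons
    # sequential draw: each codon's odds also tilted by the planted weight
    # of the pair it would complete with the previous codon
    codons = []
    prev = None
    for a in aa_idx:
        cods = group_codons[aas[a]]
        p = 1.0 + tilt * u * group_w[aas[a]]
        if prev is not None:
            p = p * np.array([1.0 + tilt * u * pw.get(prev + c, 0.0) for c in cods])
        p = p / p.sum()
        prev = cods[int(rng.choice(len(cods), p=p))]
        codons.append(prev)
    return codons


def shuffle_labels(dataset: GeneDataset, seed: int = 0) -> GeneDataset:
    """Permute the expression vector (seeded); gene order is kept.

    A pipeline-level null: any predictor trained on shuffled labels
    should score near zero.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dataset.K)
    return GeneDataset(list(dataset.genes), dataset.expressions[perm])
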