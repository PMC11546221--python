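"""Score every sense codon's influence on protein expression.

Generates a synthetic dataset with planted per-codon effects, computes
the Codon Expression Index (Kendall-tau Z-score per codon) and Codon
Productivity (abundance-weighted mean expression per codon), and shows
that the planted signs are recovered.
"""

import numpy as np

import codonlens as cl

code = cl.standard_code()
dataset, truth = cl.generate_dataset(cl.SyntheticConfig(n_genes=500, seed=42))
counts = cl.build_count_matrix(dataset.genes)
freqs = cl.to_frequencies(counts)

cei = cl.compute_cei(freqs, dataset.expressions)
cp = cl.compute_cp(counts, dataset.expressions)

print(f"dataset: K = {dataset.K} genes, expression "
      f"{dataset.expressions.min():.2f}-{dataset.expressions.max():.0f} copies/cell")
print(f"codons with |Z| > 3 (significant influence): {cei.significant.sum()} of 61")

w = np.array([truth.codon_weights[c] for c in code.sense_codons])
for label, mask in [("planted +", w > 0), ("planted -", w < 0), ("planted 0", w == 0)]:
    print(f"  {label}: mean Z = {cei.z[mask].mean():+6.2f}   "
          f"mean CP = {cp.productivity[mask].mean():8.1f}")

# Z and CP rank codons almost identically: two views of the same signal
from scipy.stats import spearmanr

print(f"rank correlation between CEI Z and CP values: "
      f"{spearmanr(cei.z, cp.productivity).statistic:.3f}")
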