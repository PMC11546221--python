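# codonlens

Codon-level expression indices and protein-abundance prediction from
coding sequences.

`codonlens` is for researchers studying codon usage bias and for anyone
who wants a sequence-only estimate of how well a gene will express in a
host: it scores each of the 61 sense codons (or each of the 3721
stop-free codon pairs) for its influence on protein expression, and turns
those scores into a cross-validated per-gene abundance predictor.

## The indices

Given K genes with per-gene codon frequencies p_kc and protein abundances
e_k (copies per cell):

- **CEI (Codon Expression Index)** — the Z-score of the Kendall rank
  correlation (tau-a, ties contribute zero) between a codon's frequency
  array and the expression array:

      tau_c = 2/(K(K-1)) Σ_{j<k} sgn(p_jc − p_kc) · sgn(e_j − e_k)
      Z_c   = 3 tau_c √(K(K−1)) / √(2(2K+5))

  |Z_c| > 3 marks codons whose usage co-varies with expression beyond
  chance (the boundary is calibrated by a seeded shuffle null).

- **CP (Codon Productivity)** — CP_c = Σ_k e_k n_kc / Σ_k n_kc, the
  abundance-weighted mean expression per occurrence of codon c.

- **CEIS / CPS / CPEIS** — per-gene predictors: score each gene by the
  mean index value of its codons, map scores to log(e+1) (natural log) by
  least squares, and evaluate with interleaved 11-fold cross-validation
  (every gene tested exactly once, each fold spanning the full expression
  range). A self-contained **CAI** baseline (top-quartile training
  reference, geometric-mean scoring) runs under the same harness.

A seeded synthetic-data generator plants known per-codon effects, so the
whole pipeline is testable end to end without any downloads.

## Worked example

```python
import codonlens as cl

dataset, truth = cl.generate_dataset(cl.SyntheticConfig(n_genes=500, seed=42))
counts = cl.build_count_matrix(dataset.genes)
cei = cl.compute_cei(cl.to_frequencies(counts), dataset.expressions)
cp = cl.compute_cp(counts, dataset.expressions)
print(cei.significant.sum())          # codons with |Z| > 3
report = cl.cross_validate(dataset, index_kind="cei")
print(report.r)                       # pooled prediction accuracy
```

Running `python examples/01_codon_indices.py` prints:

```
dataset: K = 500 genes, expression 0.00-312385 copies/cell
codons with |Z| > 3 (significant influence): 36 of 61
  planted +: mean Z =  +9.21   mean CP =  11308.3
  planted -: mean Z = -13.06   mean CP =   2820.9
  planted 0: mean Z =  +0.04   mean CP =   8414.6
rank correlation between CEI Z and CP values: 0.927
```

All 36 planted effect codons clear the |Z| > 3 boundary with the planted
sign, the zero-effect codons sit near Z = 0, and the two indices — one
rank-based, one a weighted mean — order the codons almost identically.
`examples/02_predict_expression.py` runs all four predictors on one
dataset:

```
  CEI score: pooled r = 0.952 over 500 genes
   CP score: pooled r = 0.951 over 500 genes
 CPEI score: pooled r = 0.936 over 500 genes
  CAI baseline: pooled r = 0.944
```

i.e. predicted and actual log abundances correlate at r ≈ 0.95, with
CEIS and CPS nearly interchangeable. The other examples cover expression
classes (`03_expression_classes.py`) and the shuffle-null calibration of
the significance boundary (`04_null_calibration.py`).

## Command line

Real data come in as a CDS FASTA plus a tab-separated abundance table
(replicate columns are averaged; genes duplicated in the FASTA or with
zero expression are filtered out, matching by identifier or an optional
`--id-map` table):

```bash
codonlens simulate --out-dir sim --n-genes 1000 --seed 1
codonlens indices  --cds sim/cds.fasta --abundance sim/abundance.tsv --out-dir out
codonlens predict  --cds sim/cds.fasta --abundance sim/abundance.tsv \
                   --method ceis --out-dir out
codonlens classes  --cds sim/cds.fasta --abundance sim/abundance.tsv --out-dir out
```

Every run writes TSV tables and a `manifest.json` echoing the
configuration and seed, so runs are exactly reproducible.

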