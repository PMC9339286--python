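# pertpred

Predicting which genes will respond to the perturbation of a transcription
factor (TF) — knockdown, knockout, or overexpression — **using only data
from unperturbed cells**, and explaining what the trained models learned.

## The problem

Genome-scale TF binding maps (ChIP-seq, ChIP-exo, transposon calling cards)
were expected to reveal each TF's functional targets, but bound genes and
perturbation-responsive genes overlap poorly. `pertpred` frames target
prediction as supervised learning: every instance is a (TF, gene) pair,
the features describe the unperturbed cell —

- **binding location features**: the TF's peak signals (−log10 q-values)
  summed within positional bins of each gene's cis-regulatory regions,
- **epigenetic features**: histone-mark and chromatin-accessibility
  coverage (fold-change over control) in the same bins,
- **sequence features**: per-bin dinucleotide frequencies,
- **GEX features**: the gene's median log expression level and its
  expression variation (the residual of the coefficient of variation after
  a LOESS fit on level, so variation is independent of level),

and the binary label is whether the gene responded to that TF's
perturbation (adjusted *P* < 0.05 and |log2 fold-change| > 0.5 in
replicate designs; |log2FC| > 0.5 alone without replicates; any nonzero
shrunken fold-change for shrunken estimates).

Regulatory regions follow the published geometry: a yeast promoter of
(−1000, +500) bp around the TSS in fifteen 100-bp bins; a human promoter of
4 kb centred on the 5′-most TSS in forty 100-bp bins, with linked enhancers
within 500 kb either assigned to 32 growing distance bins per side (widths
1, 2, 3, … kb) or pooled into two upstream/downstream aggregates.

Gradient-boosted trees (XGBoost) are trained under **TF-grouped 10-fold
cross-validation**: each fold trains on 90% of TFs and predicts the held-out
TFs, so every prediction concerns a TF the model never saw. Accuracy is the
per-TF area under the precision–recall curve (AUPRC) against its random
expectation — the TF's response fraction. Significance comes from a
permutation null: labels are shuffled within each TF (preserving responder
counts), the full cross-validation is re-run, and the log of the permuted
AUPRC standard deviation is modelled linearly in the log response fraction
(the *LSD* fit); the per-TF *P*-value is the upper normal tail around the
analytic expectation. TFs with < 1% responders use their empirical permuted
SD instead of the modelled one.

Trained models are explained with TreeSHAP attributions (exact for tree
ensembles; base value + per-feature attributions = model output for every
instance) aggregated into signed per-feature-class sums, net influences
over gene groups, positional profiles over promoter bins of bound genes,
upstream/downstream importance contrasts, and input–SHAP rank correlations.

A synthetic-data generator writes complete file-backed datasets
(narrowPeak, bedGraph, FASTA, TSV) with planted response structure, in a
binding-dominant (`yeastlike`) and an expression-dominant (`humanlike`)
preset, so the entire pipeline is testable without any downloads.

## Worked example

```python
import dataclasses, tempfile
from pathlib import Path
from pertpred import TFResponseModel, RunConfig
from pertpred.model_cv import Hyperparams
from pertpred.synthetic_data import YEASTLIKE, simulate_dataset

work = Path(tempfile.mkdtemp())
sim = simulate_dataset(dataclasses.replace(YEASTLIKE, n_genes=300, n_tfs=4), work)

config = RunConfig(mode="yeast", fold_count=4, enhancer_scheme="none")
model = TFResponseModel.from_directory(
    work, config, chrom_length=sim.paths["chrom_length"]
)
results = model.fit(seed=1, hyperparams=Hyperparams(n_rounds=80, max_depth=4))
print(results.summary())
```

```
TF perturbation response prediction
=================================================================
mode: yeast   instances: 1200   features: 317
TFs: 4   folds: 4   boosting rounds: 80
-----------------------------------------------------------------
TF               AUPRC    random     ratio
G0000           0.0595    0.0400      1.49
G0001           0.1159    0.0400      2.90
G0002           0.1850    0.0500      3.70
G0003           0.1085    0.0600      1.81
-----------------------------------------------------------------
median AUPRC 0.1122   median ratio to random 2.35
```

Each row is one held-out TF: `AUPRC` is the precision–recall area of the
predictions made by the fold that never saw that TF, `random` is the TF's
response fraction (the AUPRC a random ranking would average), and `ratio`
is their quotient — here every TF beats chance, two of four by more than
2×, from 300 genes' worth of simulated unperturbed-cell data. From the same
results object, `results.significance(n_perm=5)` computes permutation-null
*P*-values, `results.explain()` returns the SHAP attribution matrix, and
`results.net_influence("responsive")` ranks feature classes by their net
influence on responsive genes (the binding signal, for this preset).

The same run is available from a shell:

```bash
pertpred all --config cfg.yaml --out run/ --quick
```

which writes `features.tsv`, `predictions.tsv`, `metrics.tsv`, `null.tsv`,
`significance.tsv`, `net_influence.tsv`, `positional_profile.tsv`, and a
`manifest.json` of seeds and artifact digests.

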