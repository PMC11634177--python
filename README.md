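# actin

Per-cell-line prediction of drug-induced gene expression changes, with
attention-based interpretability and signature-reversal drug screening.

## What this is

Transcriptional responses to chemical perturbation differ between cell
lines, and most deep models for L1000-style perturbation data pool all cell
lines into one training set and need very large corpora.  ACTIN (attention-
based convolution transpositional interfusion network) takes the opposite
route: one small model per cell line, trained on paired single-drug /
single-gene samples, so a usable model can be fit from a few hundred
perturbation instances.

For drug *i* and landmark gene *j* the network predicts a bounded
interaction score S(i,j) ∈ (−1, 1):

* **Drug encoder.**  The SMILES string becomes a molecular graph over a
  fixed 14-element vocabulary (C, N, O, Cl, Ca, S, F, Br, I, P, Au, B, Si,
  Hg).  One-hot atoms are embedded to d = 256, then passed through two
  rounds of GATv2 attention + TopK pooling; mean‖max readouts of both scales
  are concatenated and projected, giving the drug vector D_i.
* **Gene encoder.**  Genes carry 128-d node2vec embeddings of a PPI
  network, projected by an MLP into the same 256-d space, giving G_j.
* **Transpositional interfusion.**  The two-token sequence X = [G_j; D_i]
  passes through N = 6 pre-layer-norm transformer blocks (4 heads,
  d_k = 64): Q = X·W_Q, K = X·W_K, V = X·W_V,
  X′ = softmax(Q·Kᵀ/√d_k)·V, concatenated heads × W_o, with residual
  shortcuts and an FFN.  A tanh-squashed MLP head on the flattened tokens
  yields S(i,j).
* **Targets.**  Raw log₂ fold changes are mapped into (−1, 1) by an odd,
  monotone "step function" SF that damps |logFC| < 1 and saturates beyond
  it; training minimises smooth-L1 loss between S(i,j) and SF(logFC).

On top of the predictor sit the interpretability analyses (element-embedding
disparity across a family of cell-line models; per-attention-head element
importance) and a screening stage that ranks a drug library by how strongly
each drug's predicted transcriptional profile reverses a disease
differential-expression signature.

Because the real LINCS L1000 / STRING corpora are not bundled, the package
ships a synthetic-data generator that plants element → gene-module effects
(`logFC = Σ β·1[drug has element]·1[gene in module] + noise`), so the whole
pipeline is testable end to end.

## Worked example

```bash
# 1. simulate a synthetic cell line (200 drugs x 100 genes, planted S effect)
actin simulate --out sim/

# 2. embed the genes from the synthetic PPI network
actin embed-genes --edges sim/ppi.tsv --out sim/genes.tsv --seed 42

# 3. train the per-cell-line model (reduced dims for a quick run)
actin train --data sim/perturbations.tsv --genes sim/genes.tsv \
    --cell-line SYN1 --config examples/reduced.yaml --out sim/model.ckpt

# 4. evaluate and inspect attention importance
actin evaluate --model sim/model.ckpt --data sim/perturbations.tsv \
    --genes sim/genes.tsv --config examples/reduced.yaml --report sim/report.json
actin interpret attention --model sim/model.ckpt --smiles sim/library.smi \
    --out sim/attention.tsv
```

The same pipeline through the Python API, with the numbers it prints:

```python
>>> from actin.benchmark import run_recovery
>>> res = run_recovery(seed=42, epochs=25)
>>> round(res.report.roc_auc_up, 3)     # held-out up-regulation ROC-AUC
1.0
>>> round(res.report.mean_pearson, 3)   # per-instance Pearson r
0.289
```

A held-out up-regulation ROC-AUC of 1.0 means the model perfectly separates
the planted up-regulated (drug-carries-S x target-gene) pairs from all
others on drugs it never saw in training — the encoder has learned to
detect the sulfur substructure and route it to the right gene module.  The
modest mean Pearson reflects that off-target logFC is pure noise, which no
model can correlate with.

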