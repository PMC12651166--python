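# dtifuse

Binary drug–target interaction (DTI) prediction for small molecules and
protein sequences, built around three ideas: **coordinate attention** over a
2-D layout of the protein sequence (directional pooling with row/column
sigmoid gates, preserving N-to-C positional information), a shared
**grouped multi-scale fusion** block on both the drug and protein feature
maps (parallel 1×1 and 3×3 branches exchanging softmax-normalised global
descriptors), and bidirectional **cross-attention** that aligns drug
substructures with protein regions before classification.

It is aimed at method developers who want a fully inspectable, CPU-only
reference implementation of this architecture family: every stage is a
plain-NumPy computation with its own reverse-mode autodiff engine, every
operation is oracle-tested, and a synthetic-benchmark generator with a
planted decision rule makes end-to-end training reproducible offline.

## Model

Drugs enter as SMILES. Each molecule becomes a graph G=(V,E) with 74-dim
atom descriptors M_d ∈ R^{N_d×74}, projected to X_d = M_d W_dᵀ and refined by
three graph convolutions over the self-loop adjacency Ã (optionally
D^{-1/2}ÃD^{-1/2} normalised):

    H^(l+1) = σ(Ã H^(l) W^(l) + b^(l)),   l = 0, 1, 2

Proteins enter as residue strings over a 22-token vocabulary (20 amino
acids + unknown + pad), embedded through E_p ∈ R^{22×D_p}, passed through a
multi-order gated 1-D convolution encoder, and reshaped row-major to a
C×H×W map with H·W = θ_p. Coordinate attention pools the map along its two
axes,

    z^h_c(i) = mean_j x_c(i,j),   z^w_c(j) = mean_i x_c(i,j)

feeds the concatenated profiles through a shared 1×1 bottleneck, and
rescales y_c(i,j) = x_c(i,j)·g^h_c(i)·g^w_c(j) with sigmoid gates g.
Both branches then pass through the multi-scale fusion block (channel
groups, 1×1 gated path with per-channel normalisation, 3×3 context path,
descriptor-softmax cross-weighting, final sigmoid gate).

The interaction stage attends each modality over the other,
Z_D = softmax(Q_D K_Pᵀ/√d_k)(F_P W_P^v) and symmetrically Z_P, mixes
D_f = 0.5·Z_D + 0.5·F_D (and P_f likewise), max-pools over valid positions,
concatenates f = [D_f^r, P_f^r], and scores p = σ(Wf + b) through an MLP.
Training minimises mean binary cross-entropy. Three ablation variants
rewire the graph: `noco` (coordinate attention → linear layer), `single`
(no multi-scale fusion), `nocross` (no cross-attention; pooled features are
concatenated directly).

All masked statistics run over valid positions only, so predictions are
exactly invariant to how much padding surrounds a molecule or sequence.

## Worked example

Generate a planted-rule synthetic benchmark (a pair interacts iff the drug
contains a carboxylic acid group AND the protein contains the motif `HKH`,
with 5% label noise), train, and predict:

```
$ dtifuse synth --n 600 --seed 7 --out pairs.tsv
wrote 600 pairs to pairs.tsv
$ dtifuse train --data pairs.tsv --out model.npz --seed 7
saved checkpoint to model.npz
auroc     0.9126
auprc     0.8725
accuracy  0.8644
f1        0.8788
mcc       0.7581
threshold 0.5000
```

The held-out AUROC of 0.91 is against the *noisy* labels (5% flips cap the
achievable AUROC near 0.95 on this scale); against the noise-free planted
rule the same predictions rank essentially perfectly. The model has learned
the joint rule, not one branch of it:

```
$ dtifuse predict --checkpoint model.npz \
    --smiles "CCCCC(N)CCC(=O)O" --sequence "MKTAYIAKQRHKHISAEELVKQFG"
0.835750    # motif drug x motif protein
$ dtifuse predict --checkpoint model.npz \
    --smiles "CCCCC(N)CCO" --sequence "MKTAYIAKQRHKHISAEELVKQFG"
0.018192    # same protein, no carboxylic acid
```

Per-residue interpretation flags, in each response dimension of the fused
protein representation P_f, the top 30% of positions; a residue's intensity
is the fraction of dimensions flagging it. High-intensity runs export as
BED (0-based, half-open):

```
$ dtifuse interpret --checkpoint model.npz \
    --smiles "CCCCC(N)CCC(=O)O" --sequence "MKTAYIAKQRHKHISAEELVKQFG" \
    --out-prefix resp
$ cat resp.bed
protein  9   13
protein  18  19
```

The first interval (residues 10–13, 1-based) covers the planted `HKH`
motif at positions 11–13.

## Layout

- `src/dtifuse/mol_featurizer.py` — SMILES → padded molecular graph (74-dim atoms)
- `src/dtifuse/drug_encoder.py` — three-layer GCN + node-grid reshape
- `src/dtifuse/protein_encoder.py` — embedding, gated convs, coordinate attention
- `src/dtifuse/multiscale_fusion.py` — shared grouped multi-scale block
- `src/dtifuse/interaction_fusion.py` — cross-attention, residual mix, head, loss
- `src/dtifuse/training_eval.py` — pair I/O, splits, metrics, training, ablations
- `src/dtifuse/synthetic.py` — planted-rule benchmark generator
- `src/dtifuse/interpretation.py` — high-response regions, TSV/BED export
- `src/dtifuse/_autodiff.py` — minimal reverse-mode autodiff over NumPy
- `docs/methods.md` — modelling choices, defaults, limitations
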