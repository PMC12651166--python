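# Methods

## Problem and model

dtifuse treats drug–target interaction prediction as binary classification
of (SMILES, protein sequence) pairs. The architecture couples a molecular-
graph drug encoder and a sequence-grid protein encoder through
cross-attention; README.md gives the forward equations. This note records
the modelling decisions, defaults, and what the synthetic benchmark does
and does not establish.

## Numerical substrate

No deep-learning framework is used: the model runs on a small reverse-mode
autodiff engine over NumPy (`_autodiff.py`) with exactly the primitives the
architecture needs (broadcast arithmetic, batched matmul, grouped stride-1
convolution, embedding gather, reductions, inverted dropout) and an Adam
optimiser. Every primitive's gradient is verified against central finite
differences in float64 (`tests/test_autodiff.py`); training runs in
float32. Max-pooling routes gradient to the first argmax on ties; ReLU uses
the 0 subgradient at the kink.

## Padding, grids and invariance

Both branches pad to fixed sizes (`n_atoms_max`, `seq_len_max`) and lay the
per-position states on a 2-D grid of **fixed width** (`drug_grid_width`,
`protein_grid_width`); padding grows the grid by whole masked rows. This is
deliberate: with a fixed width, every valid position keeps the same grid
neighbourhood as padding grows, and because all spatial statistics
(directional pools, per-channel normalisation, descriptor means, max-pools,
attention softmaxes) are computed over valid positions only, the predicted
probability is exactly invariant to the amount of padding. The suite
asserts this end to end. A square grid re-derived per pad size would break
it, since reshaping to a different width relays which positions are
adjacent under the 3×3 branch.

The row-major sequence→grid reshape is itself not biologically grounded;
it is the device that makes coordinate attention applicable to a chain.
Sequence contiguity across grid row boundaries is restored by the gated
1-D convolution encoder, which runs *before* the reshape and is the only
sequence-contiguous operator in the protein branch. It is on by default
(depth 2, kernel 3, GLU-style `conv(x)·σ(conv(x))` gating); a config flag
disables it, and without it, motifs straddling a grid row boundary are
invisible to the 3×3 fusion branch.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| atom features | 74 dims | canonical descriptor set: atom type (42 symbols + other), degree 0–10, implicit valence 0–6, formal charge, radicals, hybridization (SP…SP3D2), aromatic flag, total-H 0–4 |
| `n_atoms_max` / grid | 290 / width 10 | accommodates typical drug-like molecules; oversize molecules are rejected, never truncated |
| adjacency | self-loops + symmetric normalisation | normalisation is the standard stabilisation; a flag restores the raw self-loop form |
| GCN widths | 74→128, then 128³ via the dense projection | the projection defines the model width; three layers are fixed by the architecture |
| `seq_len_max` / grid | 1024 / width 32 | covers most single-domain proteins; longer sequences truncate with a warning |
| vocabulary | 22 = 20 residues + `X` + pad | the only reading that preserves a padding index |
| coordinate-attention reduction r | 8 | standard bottleneck ratio for this attention family |
| fusion groups | 8 (protein), 4 (drug) | group width stays ≥ 16 channels at default widths |
| cross-attention | single head, d_k = 128 | value projections W^v restore the shape compatibility the residual mix requires |
| head | MLP (512, 256), ReLU, dropout 0.1 | sized to the concatenated 256-dim pooled feature |
| loss | mean BCE, probabilities clipped to (1e-7, 1−1e-7) | mean reduction decouples the learning rate from batch size |
| optimiser | Adam, lr 1e-4, batch 32, ≤50 epochs, patience 10 on validation AUROC | plain supervised recipe; the best-validation checkpoint is kept |
| split | stratified 8:1:1 by pair, seed-controlled | an optional unseen-pair hold-out supports generalization checks |
| threshold | 0.5 for Accuracy/F1/MCC | configurable |

`desk_config()` is the same architecture at CPU scale — pads 48/64, widths
32, head (64, 32), lr 1e-3 — used by the tests, the CLI default and the
worked example. Sizes chosen once so that a full training run on the
synthetic benchmark finishes in minutes on one core.

## Ablation variants

`noco` replaces coordinate attention with a position-independent linear
layer of matching shape; `single` removes both multi-scale fusion blocks
(their parameters do not exist in the checkpoint); `nocross` removes the
cross-attention stage and classifies the concatenated pooled branch
features (strictly fewer parameters; the attention code path is never
entered). Ablation modes rewire the architecture only — data handling,
splits and seeds are shared — so reports are directly comparable.

## Synthetic benchmark and what passing means

The generator plants a known rule: interaction ⇔ (drug has a carboxylic
acid group) AND (protein contains `HKH`), with independent label-flip noise
(default 0.05) and exact class balance. Drugs are random branched
single-bond C/N/O backbones (8–20 heavy atoms, ≤40 with the motif), so the
appended `C(=O)O` fragment is the only possible source of a substructure
match; proteins are uniform random 50–60-mers with the motif spliced at a
random offset. Motif presence is re-verified with an independent matcher
(RDKit SMARTS; substring) when labelling.

With flip rate ε on balanced classes, the Bayes-optimal AUROC against the
noisy labels is 1−ε = 0.95; learnability is therefore scored against the
noise-free rule labels on held-out pairs, where the Bayes optimum is 1.0.
The learnability test (2000 pairs, seed 0) requires clean-rule AUROC
≥ 0.95; the ablation-direction test (600 pairs, 3 seeds, 12 epochs)
requires the full model's mean AUROC to be within 0.02 of every variant's.

The benchmark establishes that the implementation can carry a cross-modal
AND signal end to end through every module. It does **not** emulate real
chemistry or biology: real binding depends on 3-D complementarity, the
label rule here is a single local motif per modality, the molecule grammar
is far narrower than drug-like chemical space, and random sequences lack
protein domain structure. Passing says the machinery is correct and
trainable, not that the architecture's comparative merits on public
benchmarks are reproduced here.

## Numerical details and degenerate inputs

- Fully masked pooling rows/columns yield 0 by convention; all-masked
  attention key sets and zero-valid-row max-pools raise.
- Per-channel (group) normalisation uses masked statistics with eps 1e-5.
- Attention logits at padded keys are offset by −1e9 before the softmax.
- Interpretation flags ⌈q·L⌉ positions per response dimension (q = 0.30),
  ties broken toward the lower position index via a stable sort; the
  response tensor is P_f by default, with the raw cross-attention output
  Z_P available behind a flag for comparison.
- Checkpoints are `.npz` archives of all parameters plus the full
  versioned config; loading re-validates the parameter set.
- Determinism: a single config seed drives initialisation, splits,
  batching and dropout; two runs with the same seed are bit-identical in
  a fixed-thread environment.

## Known limitations

- Single-head cross-attention only; no edge features, conformers or
  chirality in the drug graph; no pretrained protein embeddings.
- The ⌈√·⌉-free fixed-width grid means `n_atoms_max` and `seq_len_max`
  must be multiples of the configured widths (validated at construction).
- Oversize molecules are an error by design; oversize proteins truncate.
- Pure-NumPy training is CPU-bound; the full-width default config is
  practical for datasets in the tens of thousands of pairs, not millions.
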