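# Methods

This note records the modelling assumptions, parameter choices, numerical
decisions and known limitations of `dtagnn`.

## Model

### Drug branch

A SMILES string is parsed with RDKit into a heavy-atom graph; hydrogens are
implicit (the adjacent-hydrogen count is a node feature, so explicit H
nodes would double-count). Node features follow the DeepChem-style 78-wide
layout: 44 atom-symbol slots (43 common elements + a trailing "other"
slot), one-hot heavy-atom degree 0–10, one-hot adjacent-H count 0–10,
one-hot implicit valence 0–10, and one aromaticity bit. Counts above a
block's cap map to the cap slot; unknown symbols map to "other". Bond
types are deliberately not encoded: the graph layers consume node features
and connectivity only. The aromaticity information is carried as an
atom-level flag rather than an edge feature — with atom-level features and
no edge attributes this is the only consistent placement.

SMILES are parsed as given (no canonicalization), so node order is the
parser's atom order for the input string; all layer outputs are
permutation-equivariant and the pooled drug vector permutation-invariant,
which the tests assert, so this choice affects nothing but reproducibility
of intermediate arrays.

Two graph layers are used. The dynamic-attention layer scores edge j→i as

    e(d_i, d_j) = a_h^T LeakyReLU(W_left d_i + W_right d_j)

with per-head parameters W_left, W_right ∈ R^{d×d'} and a_h ∈ R^{d'}.
This is the standard well-typed reading of the "W applied to the
concatenation [d_i ‖ d_j]" formulation (W = [W_left | W_right]); messages
use W_right d_j so that the single-head update is exactly
Σ_j α_ij W_right d_j. Coefficients are a per-destination softmax; the
multi-head outputs are **averaged**, not concatenated, in both layers —
the update rule is implemented as written, although first-layer
concatenation is the more common convention in this layer family. The
static (GAT-style) baseline layer scores with
LeakyReLU(a_L^T W d_i + a_R^T W d_j) and shares all other machinery.

Self-inclusion: every node attends over its in-neighbourhood plus itself
(a self-edge added inside attention layers; Ã = A + I in the GCN). This
keeps the softmax defined for isolated atoms (e.g. methane's single node)
and mirrors the GCN's self-looped propagation. The softmax normalization
is taken as authoritative for the attention coefficients; shifting scores
by the per-destination maximum before exponentiation is mathematically
neutral (softmax shift invariance) and keeps the exponentials bounded.

Defaults: 10 heads per layer, LeakyReLU slope 0.2, layer widths (F, 2F)
with F = 78, attention dropout applied to the normalized coefficients at
the model's dropout rate during training only. Head counts and widths of
the two layers are independent configuration fields. ReLU follows each
graph layer; global max pooling is applied only after the second layer,
followed by a linear projection to the 128-wide drug vector.

### Protein branch

Sequences are mapped case-insensitively to integer codes over the 25
letters A–Z without J (alphabetical, codes 1–25, 0 reserved for padding);
this covers the 20 canonical residues and the common ambiguity /
non-standard codes (B, O, U, X, Z). Characters outside the alphabet map to
the code of 'X' rather than being dropped, so positions are never lost
silently; this unknown-residue policy is this implementation's choice.
Sequences are truncated to the first `max_len` residues (default 1000) or
right-padded with 0.

The padding row of the 128-wide embedding table is frozen at zero.
The Bi-LSTM (hidden width d₁ = 10 **per direction**, output width 2d₁ —
the per-position output p_i ∈ R^{2d₁} fixes this reading) runs over the
full padded length by default; padding positions are not masked. A
`mask_padding` flag (off by default) freezes the state across padded
positions for callers who want length-exact recurrences. The encoder that
follows is a stack of three 1D convolutions (filters 32→64→96, kernel
width 8, ReLU) — satisfying both the "multilayer convolutional" and
"one-dimensional convolutional layer" readings of this stage — with global
max pooling over positions and a linear projection to the 128-wide protein
vector.

### Head and training

The drug and protein vectors are concatenated (128 + 128) and passed
through fully connected stages 1024 → 512 → 1 with ReLU and dropout 0.2
after each hidden stage; configured with `fc_hidden=()` the model is the
exact single linear map y = W_output [D, P] + b_output, which the tests
use. Training minimizes MSE with Adam (default lr 5·10⁻⁴, 1000 epochs,
batch size 512 reduced automatically to the training-set size). No early
stopping and no LR schedule by default; a validation split, periodic
evaluation and patience-based stopping are available as options. Test
metrics are reported for the final-epoch model.

## Numerical backend

All layers run on a small in-package reverse-mode autodiff engine over
float64 numpy arrays (`dtagnn._nn`): dense matmul, pointwise
nonlinearities, gather/scatter by integer index for sparse message
passing, segment reductions, and sliding-window unfolding for the 1D
convolutions. The LSTM recurrence is a single fused op whose backward
pass is hand-written backpropagation through time; it is verified against
finite differences and against an independently coded plain recurrence.
Tie handling in max reductions: `max` along an axis routes the gradient to
the first argmax; the segment max used by global pooling splits the
gradient evenly among tied maxima (a valid subgradient — ties are
measure-zero for continuous activations). Adam uses bias-corrected
moments; with lr = 0 a step is bit-exact identity.

## Metrics

CI follows the DTA-literature convention: pairs tied in the true affinity
are excluded from the comparable set; tied predictions on comparable pairs
earn 0.5. r²m = r²·(1 − √|r² − r₀²|) with r² the squared Pearson
correlation and r₀² the through-origin determination coefficient
(k = Σyŷ/Σŷ², r₀² = 1 − Σ(y − kŷ)²/Σ(y − ȳ)²), the modified-r²m
formulation standard in affinity benchmarking. Both conventions are
declared here because the metric suite is referenced by name only in the
benchmarking literature this package follows. The bundled `evaluate`
reports an undefined component (e.g. r²m of a constant predictor) as NaN
instead of raising, so the defined metrics still come back.

## Synthetic benchmark

The generator emulates the *shape* of public DTA benchmarks — a modest
panel of drugs × targets with a real-valued affinity per sampled pair —
with a fully known ground truth:

* **Drugs**: sampled without replacement from ~90 built-in valid SMILES
  templates (alkanes, alcohols, amines, benzene/pyridine derivatives,
  fused aromatics, plus enumerated substituent variants), spanning 1–25
  heavy atoms and aromatic fractions 0–1.
* **Proteins**: seeded random strings over the 20 canonical residues,
  lengths 50–150, with per-protein hydrophobic (0.15–0.60) and aromatic
  (0.02–0.25) composition biases so the protein descriptors genuinely vary
  across targets.
* **Affinity law**: α·z(heavy atoms) + β·z(hydrophobic fraction) +
  γ·z(aromatic atoms × aromatic residue fraction), z-standardized per
  dataset — including the weighted sum, because the drug descriptors are
  mutually correlated; the final standardization is what makes the
  noiseless law exactly unit-variance, with α = β = γ (default 1/√3)
  acting as relative weights. Gaussian noise (default sd 0.1) is added on
  top, and the noiseless component is kept on each record.
* **Defaults**: 50 drugs × 25 proteins, 700 sampled pairs — giving the
  500-train / 200-test split used throughout at a size one CPU trains in
  under a minute.

What it does **not** emulate: real structure–activity relationships (the
law is linear in three coarse descriptors), assay noise structure, the
heavy label imbalance and censoring of real Kd panels, and cold-start
evaluation (random pair splits leave every drug and target seen during
training). Passing the scaled-down generalization test therefore shows
that the architecture can extract and combine drug- and protein-side
signal through its two branches — not that it reaches benchmark-grade
accuracy on real data.

## Desk-scale configuration

CPU experiments (tests and the acceptance script) use
`ModelConfig.desk_scale()` / `TrainConfig.desk_scale()`: graph widths
32/64 with 2 heads, 16-d protein embedding, LSTM hidden 8, two conv
stages (16, 16) with kernel 4, 64-wide branch vectors, FC head (128, 64),
`max_len` 150 (covering the generator's 50–150 residue range exactly),
dropout 0, full-batch Adam at lr 5·10⁻³ for ≤ 500 epochs. The larger step
size compensates for the short schedule; dropout is disabled because these
runs measure capacity and generalization on small noiseless/low-noise
data, not regularization. Problem sizes: 32 pairs (overfit check), 700
pairs (generalization), k = 8 (lookup probe).

## The expressiveness probe

Static attention's key score a_R^T W d_j is a single scalar per key inside
a monotone nonlinearity, so every query induces the same key ranking —
asserted analytically on raw scores. The dictionary-lookup probe gives
each of k = 8 query nodes a distinct assigned key in a complete bipartite
graph and resamples the key *values* every training step; the only policy
consistent across draws is to attend to the assigned key. A single trained
dynamic layer reaches ~100% query→key argmax accuracy on this task (the
test requires ≥ 90% over 3 seeds), which a static layer cannot express.

## Known limitations

* Pure-numpy training is single-threaded BLAS-bound; the full published
  configuration (78-wide features, 10 heads, 1000-length proteins, 1000
  epochs on tens of thousands of pairs) is out of desk-scale reach — the
  architecture is identical, only widths and sizes are reduced.
* No stereochemistry, 3D conformers, bond features or pretrained protein
  embeddings.
* Checkpoints store raw float64 weights; no quantization or
  cross-version weight migration.
* The benchmark-directory reader expects the package's documented
  text layout (drugs.json / proteins.json / affinities.tsv); affinity
  transforms are explicit (`identity` or `neg_log10_nanomolar`,
  Kd[nM] → −log₁₀(Kd/10⁹)) and never guessed from the data.
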