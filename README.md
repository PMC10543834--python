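# dtagnn

Drug–target binding-affinity (DTA) regression with **dynamic graph
attention** on molecular graphs and a **Bi-LSTM** protein-sequence encoder.

Predicting the continuous binding strength between a small-molecule drug
and a protein target (pKd, KIBA score, …) is a core step in computational
drug discovery: it ranks candidate compounds against a target long before
any assay is run. `dtagnn` is aimed at method developers and computational
chemists who want a compact, fully inspectable implementation of this model
family — every layer, gradient and metric is plain numpy, with no deep
learning framework behind it.

## The model

**Drug branch.** A SMILES string is parsed (RDKit) into a heavy-atom graph
G = (V, E): one node per atom with a 78-wide feature vector (one-hot atom
symbol, degree, adjacent-H count, implicit valence, aromaticity bit), two
directed edges per bond. Two graph layers update the node features; each
node attends over its neighbourhood 𝒩ᵢ ∪ {i} with *dynamic* (GATv2-style)
attention:

    e(dᵢ, dⱼ) = aᵀ LeakyReLU(W [dᵢ ‖ dⱼ]),   αᵢⱼ = softmax_{j∈𝒩ᵢ}(e(dᵢ, dⱼ))
    dᵢ' = σ( (1/H) Σₕ Σⱼ αᵢⱼʰ Wʰ dⱼ )          (H heads, averaged)

Because the attention vector `a` acts *after* the joint nonlinear transform
of (query, key), the key ranking can differ per query — unlike classic GAT
scoring `LeakyReLU(aᵀ[W dᵢ ‖ W dⱼ])`, which is monotone in the key term and
therefore ranks keys identically for every query. Two variants are built:

* `dual-attention` — both graph layers are dynamic attention;
* `attention-gcn` — the second layer is a GCN,
  `H⁽ˡ⁺¹⁾ = σ(D̃^{-1/2}(A+I)D̃^{-1/2} H⁽ˡ⁾ W⁽ˡ⁾)`.

Global **max pooling** over nodes then yields one order-independent drug
vector D.

**Protein branch.** The amino-acid sequence is integer-encoded (25-letter
alphabet, 0 = padding), cut/padded to length 1000, embedded (128-d), run
through a bidirectional LSTM (hidden 10 per direction, pᵢ = p⃗ᵢ ‖ p⃖ᵢ), and
condensed by stacked 1D convolutions with global max pooling into one
protein vector P.

**Head.** ŷ = W_output [D, P] + b_output (with optional hidden FC stages),
trained with MSE loss and Adam (lr 5·10⁻⁴, dropout 0.2 by default).

**Metrics.** Concordance index (CI, tie credit 0.5, tied truths excluded),
MSE, and the modified r²m = r²·(1 − √|r² − r₀²|).

Because no DTA benchmark download is bundled, the package ships a seeded
synthetic generator: valid drug-like SMILES, random protein sequences, and
affinities from a known unit-variance descriptor law (drug size, protein
hydrophobicity, an aromatic interaction term) plus Gaussian noise — enough
to train and validate the whole method on one CPU.

## Worked example

```python
from dtagnn import (SyntheticSpec, generate_synthetic_dataset, train_test_split,
                    ModelConfig, build_model, TrainConfig, train, evaluate_model)

records = generate_synthetic_dataset(SyntheticSpec(seed=7))   # 700 pairs
train_recs, test_recs = train_test_split(records, test_fraction=200/700, seed=7)
model = build_model(ModelConfig.desk_scale("dual-attention", seed=7))
model, history = train(model, train_recs, [], TrainConfig.desk_scale(seed=7, epochs=300))
result = evaluate_model(model, test_recs)
print(f"first-epoch loss {history.epoch_loss[0]:.3f}, last-epoch loss {history.epoch_loss[-1]:.3f}")
print(f"CI={result.ci:.3f}  MSE={result.mse:.3f}  r2m={result.rm2:.3f}")
```

prints (about a minute on one CPU):

```
first-epoch loss 1.012, last-epoch loss 0.017
CI=0.949  MSE=0.023  r2m=0.973
```

The training loss falls from the label variance (≈1, the affinity law is
unit-variance) to near the noise floor (noise_sd = 0.1 → MSE ≈ 0.01), and
on the 200 held-out pairs the model orders ~95% of comparable pairs
correctly (CI) with a test MSE close to the irreducible noise.

The same pipeline is available from the shell:

```
dtagnn simulate --seed 7 --out runs/sim
dtagnn train --train runs/sim/pairs.csv --test runs/sim/pairs.csv \
             --seed 7 --epochs 50 --out runs/fit
dtagnn predict --checkpoint runs/fit/checkpoint.npz \
               --pairs runs/sim/pairs.csv --out runs/pred
dtagnn evaluate --scores scores.csv --out runs/metrics
```

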