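# polysite

Residue-level, multiclass protein **active-site** classification from three
modalities: the 3D structure, the amino-acid sequence, and a free-text
description of the protein's function.

Most computational active-site predictors answer a binary question — is this
residue part of an active site? `polysite` instead assigns each residue one
of **seven** labels: `None` plus six functional categories of catalytic
residues — covalent reaction intermediates (CRI), sulfur-containing covalent
intermediates (SCI), phosphorylated intermediates (PI), proton transfer &
charge-relay systems (PTCR), isomerization activity (IA), and
substrate-specific activities (SSA). The target users are structural
bioinformaticians and enzyme engineers who want per-residue functional
hypotheses from a predicted structure, its sequence and whatever functional
annotation text exists.

Active-site labeling is extremely imbalanced — on curated corpora roughly
0.3 % of residues are active — so the package pairs the multimodal encoder
with an imbalance-aware compound loss, and ships a synthetic-corpus
generator that reproduces exactly this regime for development and testing
without any model downloads.

## The model

Each protein is a triple (S, G, T): sequence, residue graph, function text.

**Structure stream.** Residues are nodes of a graph G with an edge (i, j)
whenever the Cα–Cα distance is < 8 Å, the distance `a_ij` being the edge
attribute. Every node starts from a 62-dimensional feature vector
h⁰ᵢ ∈ ℝ⁶²: a 9-state secondary-structure one-hot (8 DSSP states +
unassigned), sin/cos of φ, ψ, ω, χ₁…χ₅ (16), seven atomic features (mean
atomic mass, B-factor, side-chain status, formal charge, H-bonding
capability, ring membership, mean vdW radius), two backbone hydrogen-bond
flags (Kabsch–Sander donor/acceptor), a pseudo-position (i+1)/L, six
z-scored physicochemical scales, and a 21-type amino-acid one-hot. An
E(3)-equivariant graph network (T = 2 layers) updates features and
coordinates,

    m_ij = φ_e(hᵢ, hⱼ, ‖xᵢ − xⱼ‖², a_ij)
    xᵢ ← xᵢ + (M−1)⁻¹ Σⱼ (xᵢ − xⱼ) φ_x(m_ij)
    mᵢ  = Σⱼ m_ij,     hᵢ ← φ_h(hᵢ, mᵢ)

giving `F_struct ∈ ℝ^{L×d_h}`; feature updates are rigid-motion invariant,
coordinate updates equivariant.

**Sequence and text streams.** A pluggable encoder yields per-residue
embeddings `F_seq ∈ ℝ^{L×d_s}` and token embeddings of the function text,
global-average-pooled to `F_text ∈ ℝ^{d_t}`. Deterministic dummy encoders
and HDF5 file adapters are built in; real protein/biomedical language models
plug in behind the same contract.

**Fusion.** Two symmetric cross-attention branches exchange information,
each conditioned on the function text:

    Z = Norm(Q + softmax(Q Kᵀ / √d) V),   O = Norm(Z + FFN([Z, proj(F_text)]))

with structure as query against sequence keys/values in branch one and the
roles swapped in branch two. An adaptive gate
ω\* = σ(MLP([F_fused, F_orig])) ∈ (0, 1) then blends the fused features with
the original concatenated ones per residue,
`F_final = ω* ⊙ F_fused + (1 − ω*) ⊙ F_orig`, and a small head emits
probabilities ŷᵢ over the K = 7 classes (rows sum to 1).

**Loss.** `L = L_CE + λ₁ L_center + λ₂ L_inter` with class-weighted cross
entropy (weights 0.01, 1.0, 0.7, 1.0, 0.5, 2.5, 2.0 for None, CRI, SCI, PI,
PTCR, IA, SSA), a center loss `(1/2B) Σ ‖F_final,i − c_{yᵢ}‖²` whose class
centers follow `c_k ← c_k + α (mean_k(F) − c_k)` after each optimizer step,
and an inter-center hinge `Σ_{i≠j} max(0, m − ‖cᵢ − cⱼ‖)`. Defaults:
α = 0.5, m = 0.1, λ₁ = 0.1, λ₂ = 0.001. Training uses Adam with a linear
warm-up over the first 10 % of steps and cosine annealing to zero.

The network runs on a compact reverse-mode autodiff engine over numpy
(float64, single-threaded), which keeps desk-scale training fast and
bit-reproducible; gradients are verified against finite differences in the
test suite.

## Worked example

```python
from polysite import ActiveSiteModel, SyntheticSpec, generate_corpus
from polysite.model import smoke_train_config

corpus = generate_corpus(SyntheticSpec(seed=1))   # 200 proteins, L in [40, 60]
model = ActiveSiteModel.from_corpus(corpus, smoke_train_config(seed=1))
results = model.fit()
print(results.summary())
test = results.evaluate("test")
print(f"test macro-F1 {test.f1:.4f}  MCC {test.mcc:.4f}  AUROC {test.auroc:.4f}")
print(f"test macro-F1 without function text "
      f"{results.evaluate('test', zero_text=True).f1:.4f}")
```

prints

```
Residue-level active-site classification results
====================================================
proteins: 200  (train 161, val 19, test 20)
classes: 7   d_s=32 d_h=32 d_t=32
epochs: 15  base_lr: 0.003  batch: 2 proteins  seed: 1
best epoch (validation macro-F1): 2

validation metrics (macro over classes present)
----------------------------------------------------
precision 0.7625  recall 0.9776  F1 0.8328
AUROC 0.9758  AUPRC 0.8522  MCC 0.6212

per-class validation table
----------------------------------------------------
class  precision   recall       f1    auroc    auprc  support
 None   0.998885 0.972856 0.985699 0.949369 0.998146      921
  CRI   1.000000 1.000000 1.000000 1.000000 1.000000        1
  SCI   0.666667 1.000000 0.800000 1.000000 1.000000        2
 PTCR   0.384615 0.937500 0.545455 0.954004 0.410639       16

test macro-F1 0.6314  MCC 0.4291  AUROC 0.9361
test macro-F1 without function text 0.3138
```

Reading this: the corpus is split 8:1:1 by similarity cluster (never
splitting a cluster); macro metrics average over the classes actually
present in the held-out labels, so with ~0.3 % active residues the rare
classes contribute with supports of a few residues and dominate the macro-F1
variance. Zeroing the pooled function text at evaluation time halves the
test macro-F1 — the text modality genuinely informs which site categories
to expect.

## Command line

```
polysite simulate OUT_DIR          # write a synthetic corpus
polysite featurize FILE -o PREFIX  # 62-dim node features + edge list (TSV)
polysite embed FASTA -o H5         # deterministic dummy embeddings
polysite split CLUSTERS -o TSV     # cluster-aware 8:1:1 manifest
polysite train CORPUS -o CKPT      # train, save best-validation checkpoint
polysite evaluate CORPUS --checkpoint CKPT
polysite predict FILE --embeddings H5 --checkpoint CKPT -o PREFIX
```

Structures are read as PDB or mmCIF (`--chain` selects a chain); tables are
TSV with 1-based residue numbers; training logs are JSON-lines.

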