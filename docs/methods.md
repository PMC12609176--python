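# Methods

## Problem and model

Each residue of a single protein chain is assigned one of K = 7 labels:
`None` or one of six active-site categories (CRI, SCI, PI, PTCR, IA, SSA).
The classifier fuses three per-residue information streams — a structural
embedding from an E(3)-equivariant graph network, a sequence-language-model
embedding, and a pooled function-text embedding — through two symmetric
text-conditioned cross-attention branches and a per-residue sigmoid gate,
followed by a feed-forward head with a row-wise softmax. Ties in the final
argmax resolve to the lowest class index, deterministically.

Assumptions worth making explicit:

* **Single chain, complete backbone.** Residues missing Cα are rejected at
  parse time (with a structured report); residues missing other backbone
  atoms are carried but flagged, receive the "unassigned" secondary-structure
  state, and have the affected torsions undefined.
* **Geometry only through invariants.** All structure-derived node features
  are functions of internal coordinates (distances, angles, H-bond
  energies), so the feature matrix is exactly invariant under rigid motion;
  the graph encoder preserves this by construction.
* **Encoders are exogenous.** Sequence and text embeddings come through an
  encoder contract (deterministic seeded dummies, HDF5 containers of
  precomputed arrays, or user-supplied adapters that must strip special
  tokens). No language model is trained or shipped.

## Structure featurization

* **Graph.** Edge iff Cα–Cα distance strictly < 8 Å (ties at exactly 8 Å
  excluded); the edge feature is the distance in Å. Construction is verified
  against a brute-force all-pairs oracle.
* **Torsions.** φ, ψ, ω and χ₁…χ₅ by the signed-dihedral formula; φ is
  undefined at the chain start, ψ/ω at the end; χ_k requires the standard
  atom quadruple (packaged table) to be fully present; collinear defining
  atoms flag the angle undefined. Undefined angles contribute (0, 0) to the
  sin/cos pairs, so s² + c² ∈ {0, 1} is an exact block invariant.
* **Hydrogen bonds.** Kabsch–Sander electrostatic energy
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, a bond when
  E < −0.5. Amide hydrogens are placed geometrically (1.01 Å from N along
  the bisector of N→C_prev and N→Cα) whenever the file has none, as with
  predicted-structure models; prolines and chain-start residues never
  donate. Donor–acceptor pairs closer than two positions along the chain
  are excluded (they are covalently constrained, not hydrogen-bonded), and
  pairs with Cα distance > 9 Å are pruned before the energy evaluation.
  The two node-feature dimensions are the residue's backbone donor and
  acceptor flags.
* **Secondary structure.** DSSP-style 8 states from the H-bond pattern —
  helices from two consecutive n-turns (n = 4 → H, 3 → G, 5 → I), strands
  from parallel/antiparallel bridge patterns (ladders ≥ 2 → E, isolated →
  B), then turns (T), bends (S, Cα kink > 70°), else coil. A ninth state
  "unassigned" covers residues whose backbone is incomplete; the one-hot is
  9-dimensional. The state inventory and the two H-bond dimensions are this
  package's declared conventions; the upstream design fixed only the
  dimensionalities.
* **Physicochemical block.** Kyte–Doolittle hydropathy, Grantham polarity,
  formal charge at pH 7, side-chain pKa (0 where none), vdW volume and
  monoisotopic residue mass, each z-scored across the 20 standard residues
  (z-scoring chosen over min-max so the block is centered; either is
  defensible). Unknown residue type ⇒ zero vector.
* **Pseudo-position.** (i + 1)/L ∈ (0, 1], 0-based i.
* **Altlocs** resolve to the highest occupancy (ties: first in file order).

## Network

Hidden sizes default to d_s = d_h = d_t = 32 at desk scale (the architecture
is size-agnostic). The EGNN has 2 layers; the first embeds the 62-dim node
features into d_h. φ_e, φ_x, φ_h are two-layer maps with SiLU (φ_x output
unclamped scalar); messages flow along both directions of each undirected
edge; isolated nodes receive zero messages; the coordinate update keeps the
printed (M − 1)⁻¹ normalization with M = L, and is skipped for M = 1.
Final-layer coordinates are computed but unused downstream, so the last
layer's φ_x receives no gradient — the gradient-flow test covers every other
parameter group.

Cross-attention is single-head by default (head count configurable); branch
one scales attention by √d_s exactly as the design prints it (even though
keys live in d_h), branch two mirrors with √d_h; a `key_dim` switch scales
by the true key width instead. The text vector enters each branch via a
linear projection to the branch width, broadcast over residues and
concatenated into the FFN input (width 2·branch dim). Normalization is layer
norm with learnable affine; FFNs use GELU. The fusion gate is a scalar per
residue (per-dimension gating available behind a flag). The head is
(d_s + d_h) → d_h → K. Initialization is uniform fan-in scaling from the
config seed.

## Objective and training

* **Cross entropy** uses the weighted-mean convention: Σ w_{yᵢ}·NLLᵢ / Σ
  w_{yᵢ} over valid residues — stated explicitly because frameworks differ.
  A fully-masked batch is an error, never a silent zero.
* **Centers** are state, not parameters: after each optimizer step,
  c_k ← c_k + α(mean_k(F_final) − c_k) on detached features for the classes
  present in the batch (α = 0.5). Repeated updates on a fixed batch contract
  geometrically to the class means with factor 1 − α. Consequently the
  inter-center hinge (ordered pairs, double-counted exactly as printed;
  an `unordered` flag halves it) contributes to the reported total but not
  to network gradients. The `None` class participates in both center and
  inter losses like any other class.
* **Batching** is by protein; each protein's forward runs on its own graph
  and the batch's residues are pooled into one loss — mathematically
  identical to padding plus masking, without the padding arithmetic. The
  "sample" unit of all losses is the residue.
* **Schedule.** Linear warm-up from base_lr/warmup_steps to base_lr over
  ⌈0.1·total⌉ steps, then cosine decay whose progress reaches 1 at the final
  step, so the last learning rate is exactly 0. Adam β = (0.9, 0.999),
  ε = 1e-8.
* **Model selection** is best validation macro-F1 (the design leaves the
  criterion open); checkpoints are single HDF5 containers with all parameter
  arrays, the center state, a config snapshot and a mandatory version field.
* **Determinism.** float64 numpy in one thread: identical (config, seed) ⇒
  bit-identical histories and metrics.

Default hyperparameters follow the published recipe — 100 epochs, Adam at
5e-5, the class weights above, α, m, λ₁, λ₂ = 0.5, 0.1, 0.1, 0.001, maximum
length 1024. The **desk-scale smoke configuration** (`smoke_train_config`)
instead uses 15 epochs, 2-protein batches and base lr 3e-3: a 200-protein
corpus yields only ~1200 optimizer steps, where a 5e-5 rate — sized for
corpora with orders of magnitude more steps — cannot move the parameters
materially.

## Evaluation

Macro one-vs-rest precision/recall/F1/AUROC/AUPRC over the classes present
in the labels (absent classes are excluded with a logged note; classes
lacking either label polarity skip the ranking metrics), plus multiclass
MCC in Gorodkin's generalization (checked against the binary closed form).
An `active-only` policy restricts the average to the six active classes.

## Synthetic corpus

The generator emulates the statistical regime of curated active-site
corpora, not their biochemistry:

* **Structures** are ideal-geometry backbones grown by natural-extension
  placement (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å) at motif torsions
  (helix −57/−47, strand −135/+135, ω = 180), which makes the generator an
  exact oracle for the torsion operator. Every 13th protein is a pair of
  antiparallel strands docked by a cached rigid transform (found once by
  minimizing Kabsch–Sander energies of a 6-residue pair) so strand states
  occur; every 10th carries full ideal side chains for Ser/Lys/Arg so
  χ₁…χ₅ code paths run; side chains otherwise stop at Cβ.
* **Labels** are iid draws from the empirical class frequencies of the
  curated corpus at its 10 % identity threshold (active fraction ≈ 0.3 %,
  PTCR dominant); at least one active residue per protein is forced so every
  protein is informative.
* **Embeddings** place the seven class means on a regular simplex with
  pairwise separation equal to `signal_strength` (default 4) in units of the
  unit Gaussian noise; text tokens sit near the direction of each active
  class present in the protein (noise SD 0.5), so the pooled text genuinely
  encodes which categories to expect.
* **Clusters** come from seeded k-means on protein-mean embeddings, standing
  in for sequence-similarity clustering in split tests.

What passing tests on this corpus do **not** show: real proteins have
correlated (not iid) site labels, embeddings whose class signal is neither
isotropic nor linearly separable, imperfect structures, and function text of
highly variable specificity. The corpus validates the machinery — geometry,
losses, training dynamics, modality ablations — not biological accuracy.

## Sizes, runtimes, known limitations

The shipped benchmark trains on the default corpus (200 proteins, length
40–60, d = 32) in under a minute per seed on one CPU; the acceptance script
runs three seeds in about two minutes. At these sizes the held-out split
holds ~20 proteins and ~2 900 residues, of which only a handful are active:
the rarer classes appear with supports of one or two residues, so a single
misclassified residue zeroes that class's F1 and the macro-F1 across
held-out splits is both noisy and support-limited even for a predictor with
access to the generator's true class-conditional distributions. Headline
comparisons at this scale should therefore weight MCC and the ranking
metrics (AUROC/AUPRC), which the acceptance script reports alongside the
3-seed median macro-F1 and the text-ablation delta.

Other limitations: no solvent accessibility or pLDDT features; no multi-chain
attention; the text modality enters only as one pooled vector per protein;
real-encoder adapters are interface-only (no pretrained weights shipped);
and training is CPU-bound numpy — appropriate for desk-scale corpora, not
for tens of thousands of proteins.
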