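# Methods

## The mechanism

Window multi-head self-attention restricts attention to non-overlapping
M×M token windows.  For each window and head, with queries Q, keys K and
values V of per-head width d_k = C / heads:

    A   = softmax( Q Kᵀ / √d_k )            (single Key)
    A_DA = softmax( Q K1ᵀ/√d_k + Q K2ᵀ/√d_k )  (dual Key)

K1 and V are projected from the block-input feature map x; K2 is
projected from `cyclic_shift(x, (⌊M/2⌋, ⌊M/2⌋))`, so every query can
score against keys that originate in the four windows adjacent to its
own.  The attention output is A·V per head, heads concatenated, then an
output projection.  Both score terms share the single 1/√d_k scale and
one softmax is applied to their sum.  Three variants are built from the
same code path: `WMSA` (no K2), `DA_N` (K2 from the unshifted map —
extra width, no cross-window flow) and `DA`.

Because the pre-softmax score is a *sum*, the loss gradient reaches Q
along two routes (through each Q·Kᵢᵀ term).  This is verified, not
re-derived: `gradcheck` compares every analytic gradient against central
finite differences and additionally confirms that detaching either score
term still leaves a nonzero ∂L/∂W_Q.

### Design choices at points the mechanism leaves open

- **Shift magnitude and source.** The shift is ⌊M/2⌋ = 3 tokens in both
  axes (the half-window convention), applied to the *block-input feature
  map* at every attention layer — after patch merging the raw image no
  longer exists at the layer's resolution, so shifting the feature map
  is the only construction that works in all stages.
- **No attention mask for wrapped regions.** Query–K2 pairs that wrap
  around the map edge are not masked: cross-window mixing is the purpose
  of the second Key, not an artifact to suppress.  (This differs from
  shifted-window attention, where the shifted *partition* makes masking
  necessary.)
- **K2 is a separate learnable C×C projection with bias in every
  attention layer.**  At Tiny depths this adds Σ_blocks (C²+C) =
  2,160,960 parameters, which is exactly the audited gap between the
  dual-Key and single-Key models.
- **Relative-position bias** is included Swin-style (one (2M−1)²×heads
  table per layer, indexed by in-window offset pairs) and added to the
  *summed* pre-softmax score; a `use_relpos` flag removes it.  Its ~23 K
  parameters sit below the 0.1 M print precision of the audit tables, so
  the tables cannot adjudicate its presence; it is kept because the
  backbone otherwise follows the hierarchical window-attention recipe.
- **Every block uses the configured variant.** There are no alternating
  shifted-window blocks anywhere; in the dual-Key variants the K2
  pathway carries all cross-window flow.

## The backbone

Stem: 4×4 patches, learned linear embedding to C=96, LayerNorm.  Four
stages at resolutions (input/4)/2^s and widths C·2^s; between stages a
patch-merging layer concatenates 2×2 neighborhoods (4C), normalizes and
projects to 2C (bias-free, as in the standard recipe).  Blocks are
pre-norm: y = x + Attn(LN(x)); out = y + MLP(LN(y)) with a two-layer
MLP (ratio 4, exact erf GELU).  Head: final LayerNorm, global average
pool over tokens, linear to the class count.  MLP internals,
initialization (truncated normal σ=0.02, zero biases, seeded generator)
and zero default dropout/stochastic-depth are standard-recipe choices
the audit tables cannot distinguish; dropout and drop-path are exposed
as config fields.

The implementation runs on a purpose-built reverse-mode autodiff engine
over NumPy (float64 throughout); model-level backward passes are never
hand-derived, and the engine's per-op gradients are finite-difference
tested.

## Complexity accounting

Closed forms for one attention application over an h×w×C token map:

    Ω(MSA)   = 4hwC² + 2(hw)²C
    Ω(W-MSA) = 4hwC² + 2M²hwC
    Ω(DA)    = 5hwC² + 3M²hwC
    Ω(GAA)   = 4hwC² + 2(h²+w²)C

evaluated in exact Python integers (no floating-point rounding at any
size).  Ω(DA) − Ω(W-MSA) = hwC² + M²hwC identically: one extra
projection and one extra windowed product.

Whole-model audits are pure shape arithmetic and are cross-checked
against instantiated models scalar-for-scalar.  MAC counts are reported
under two named conventions:

- **projections-only** counts one multiply–accumulate per scalar of
  every *learned affine* map: patch embedding, Q/K1/K2/V and output
  projections, MLPs, patch-merging reductions, the head, and the
  per-element scale-and-shift (γx+β) of each normalization layer.  The
  parameter-free score (QKᵀ) and aggregation (A·V) products are
  excluded.  Under this convention Tiny audits to 4.4 G (single Key)
  and 4.7 G (dual Key) at 224².
- **eq78** adds the windowed matrix products (2M²hwC per single-Key
  block, 3M²hwC per dual-Key block), giving 4.5 / 4.9 G — reported
  alongside so the convention choice is auditable.

Counting the normalization affines is deliberate: they are learned
multiply–accumulates, and the convention is stated rather than assumed.
Activations, softmax and bias additions count zero MACs.  Rounding onto
the printed scale is half-away-from-zero at one decimal, computed in
exact rational arithmetic.

## Synthetic tasks

`cross_window` stamps one motif into each of two horizontally adjacent
M×M-token windows (28×28 px at window 7, patch 4).  The motif carries a
binary attribute rendered as both shape and channel — red main-diagonal
vs blue anti-diagonal — and the class is 1 iff the two attributes
match.  Each window alone therefore contains an attribute that is
uniform regardless of class: a regularized logistic probe on single-
window pixels scores 0.5 (tested), while the same probe recovers the
window's own attribute, and only a model that combines the two windows
can beat chance.  Rendering the attribute into a color channel keeps it
readable after global average pooling; a purely geometric attribute
(line orientation alone) is not learnable by the mini backbone used in
the tests, which says something about tiny models, not about the
mechanism.  Motif positions are uniform within each window; labels are
balanced to within one; defaults are 56×56 images, motif 5, additive
Gaussian noise σ=0 (σ is a parameter; the independence probe is run at
σ=0.1).  Generation is integer-lattice stamping plus seeded noise and
is bit-reproducible.

`blob` is a linearly separable smoke test: one centered blob whose
amplitude (0.05–0.35 vs 0.65–0.95) encodes the class.

`split_622` shuffles with a seeded generator and takes
train = ⌊0.6n⌋, val = ⌊0.2n⌋, test = the remainder (remainder assignment
to test is a stated convention; for n = 14,249 this gives
8549/2849/2851).  Training-time augmentation is 90°-multiple rotations
and horizontal/vertical flips, each applied with probability 1/2 — all
label-preserving for the matching task since both attributes transform
together.

What the synthetic data does **not** emulate: tissue appearance,
intra-class texture statistics, resolution (real medical images are
~2000² vs 56–224² here), label noise, or class imbalance.  Passing the
desk-scale tests shows the mechanism and harness behave as specified on
data with a controlled cross-window dependency — not that the accuracy
ordering transfers to any clinical dataset.

## Training harness

Cross-entropy loss; optimizers `sgd` (the literal θ ← θ − η·∂L/∂θ
update, used by the fidelity tests) and `adamw` (default; decoupled
weight decay, optional cosine schedule with warmup).  After each epoch
the validation accuracy is computed and the best checkpoint retained;
ties go to the earliest epoch.  Runs are bit-deterministic for a fixed
(seed, config, data) on a given platform.  A non-finite loss aborts with
the epoch and step recorded.  `compare_variants` trains every variant
from bit-identical shared (non-K2) initial weights under identical
seeds, splits and batch orders, and reports per-seed and mean val/test
accuracies next to the parameter/MAC audit columns.

### Study conditions for the desk-scale comparison

The packaged comparison uses 240 noiseless 56² cross-window images
(6:2:2 split), the mini backbone (C=32, depths 1/1, heads 2/4, window
7), adamw at η=1e-3, batch 12, 40 epochs, seeds {0,1,2}.  These sizes
were chosen as the smallest configuration in which the matching rule is
actually *discovered* within the budget rather than memorized: with
added noise at this sample size both variants memorize noise patterns
instead (train accuracy 1.0, validation at chance), and with many more
epochs both variants converge and the comparison saturates.  In the
learning-onset regime the dual-Key model, which can compare the two
windows from the first layer, tends to discover the rule earlier than
the single-Key baseline, which must first funnel both windows through
patch merging into its second stage.  The breakthrough epoch is
seed-dependent; the packaged check compares seed-averaged validation
accuracy and asserts only the direction of the difference, not a
margin.

## Known limitations

- Pure-NumPy execution: desk-scale models only; the Tiny backbone is
  audited (built and counted) but not trained here.
- Global-attention (ViT-class) and axial-attention models are audited
  only via their closed-form Ω; they are not instantiated.
- The checkpoint loader skips name/shape mismatches and logs them; it
  does not remap parameters between variants.
- Degenerate inputs: all-equal attention scores yield exactly uniform
  rows (no special-casing); softmax uses detached-max subtraction, so
  scores are shift-invariant to double precision.
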