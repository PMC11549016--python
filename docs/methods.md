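# Methods

This note documents the models, conventions and numerical choices behind
`ac4cnet`, in the order data flows through the package.

## Input model

A sample is an odd-length RNA window with the candidate cytidine at the
center; both classes have a central C (in peak-derived datasets negatives
are drawn from non-peak regions but still centred on a cytidine), so the
center itself carries no label information. Input is normalized by
uppercasing and mapping T→U, since public ac4C datasets are often
distributed in the DNA alphabet. Residues outside {A, C, G, U, T} are
rejected with the offending record named.

Redundancy removal uses a greedy scan in input order: a record is kept iff
its ungapped positional identity to every already-kept record is below the
threshold (default 0.8). This reproduces the *effect* of clustering-based
tools ("no two retained sequences ≥ 80% identical") without alignment or
word-filter heuristics; it is deterministic, order-dependent in the same
way greedy clustering is, and idempotent. Splitting (default ratio 4:1)
and k-fold partitioning are label-stratified even though the datasets are
balanced overall, so each fold preserves balance; with 2758+2758 records a
4:1 split yields the familiar 2206/552 per class.

## Synthetic benchmark generator

`generate_synthetic` emulates the structure of curated ac4C benchmarks:

* fixed odd window length (default 201 nt) with a central C in both classes;
* i.i.d. background bases (default uniform);
* in positives only, each eligible position (room for a full trinucleotide
  that does not overlap the center) independently seeds a C-initiated
  trinucleotide ("CXX", X drawn from the background) with probability
  `motif_rate`. The planted signal is therefore purely an excess of
  C-initiated 3-mers/dinucleotides, mimicking the C-rich motif enrichment
  observed around acetylated sites.

All randomness flows from the single integer seed through one named
generator; identical specs give byte-identical output. What the generator
does **not** model: transcript context and codon structure, per-transcript
matching of negatives, positional clustering of motifs near the site, GC
heterogeneity, and the residual near-duplicate structure of real data.
Consequently, passing the synthetic benchmarks demonstrates that the
pipeline can learn a composition/positional signal and is calibrated under
the null — not that real-data performance numbers transfer.

## Encodings

* **Integer encoding** uses the fixed bijection A→0, U→1, C→2, G→3 (the
  alphabet enumerated as {A, U, C, G}). Any bijection yields the same
  model after embedding; the map is pinned for stable serialization.
* **k-mer counting** uses an overlapping window of step 1, so a length-L
  sequence yields L−k+1 k-mers; counts (not relative frequencies) populate
  the profile. The worked seven-base example (`AGCUUAG`, k=2 → counts
  2,1,1,1,1) fixes both conventions.
* **PseKNC** adds a per-k-mer weight (default 1) to each count elementwise
  and appends a correlation pair: the mean and *population* standard
  deviation over the **set of distinct nonzero counts** ({2,1} → 1.5, 0.5
  in the worked example; a sample std or a moment over the full count
  vector does not reproduce it). The model-facing variant enumerates all
  4^k k-mers so the feature width is fixed at 4^k + 2 (k defaults to 2,
  width 18); the observed-order variant exists for desk examples.
* **Positional encoding** is the standard sinusoidal matrix
  `PE[pos, 2x] = sin(pos·a^(−2x/d))`, `PE[pos, 2x+1] = cos(...)`, base
  a = 10000. The position multiplier is essential — without it the matrix
  is constant over positions and adds no information.

## Architecture

Defaults: `d_model = 512` (so d_k = d_v = 512/8 = 64 with 8 heads),
bidirectional GRU with 512 units per direction, convolution kernel 4 with
padding 2. Choices the architecture leaves genuinely open were fixed as
follows and are all config-overridable:

* CNN channel widths 32→64→128 with non-overlapping max-pool width 2 after
  each block, plus one extra max-pool after the third block.
* Both paths end in attention over `d_model`-wide vectors, so each path has
  a linear bridge into that space: path 1 from the 2·hidden Bi-GRU output,
  path 2 from the last conv block's channels (attention then runs over the
  surviving spatial positions).
* Per-position representations are reduced by **mean pooling** (max and
  flatten are selectable) before concatenation, order path1 ⊕ path2.
* Classifier hidden width 256, ReLU hidden activation, softmax output;
  dropout 0.2 between the classifier layers, active only in training mode.
* GRU gates follow the explicit update/reset formulation with separate
  hidden and input biases; the backward direction runs the same recurrence
  right-to-left (verified in tests against a reversed-forward oracle).

Parameter groups for a disabled path are never constructed, so the
parameter inventory is a pure function of the configuration — useful both
for ablation bookkeeping and as a correctness check.

All layers are built on the package's reverse-mode autodiff core
(`ac4cnet.autograd`): float64 tensors, a topologically sorted backward
pass, and exactly the primitives the model needs (batched matmul with
broadcasting-aware gradients, sigmoid/tanh/ReLU/softmax, embedding lookup
with scatter-add, im2col 1-D convolution, argmax-routed max-pooling, a
fused stable cross-entropy, and Adam). Gradients are validated against
central finite differences in the test suite.

## Training and evaluation protocol

Adam at learning rate 0.001 minimizes cross-entropy; epochs and batch size
default to 50 and 64. k-fold cross-validation (default k = 10) trains a
fresh model per fold from seed `master + fold_index` and reports
final-epoch validation metrics (no early stopping or best-epoch selection —
the simplest rule consistent with the protocol). Identical seeds and data
give bit-identical runs on one thread.

Confusion counts use threshold 0.5 on the positive-class probability.
MCC returns 0 when any denominator factor vanishes. AUROC is the pairwise
rank statistic with half credit for ties, computed via midranks; tests
verify equality with trapezoidal ROC integration and an O(n²) pairwise
count.

## FGM robustness

The attack is `δ = ε·sign(∇ₓJ(θ, x, y))` with sign(0) = 0, built
per example at the true label, so every component of δ lies in
{−ε, 0, +ε} and ‖δ‖∞ = ε wherever the gradient is nonzero. Integer codes
are not differentiable, so "input" means the embedding output on path 1
and the PseKNC vector on path 2; the target (either or both) is
selectable. Two modes are provided and labelled explicitly: a test-time
attack (clean and attacked metrics reported side by side, with no
monotonicity assumed) and adversarial training (a second loss term on
x + δ per batch). ε defaults to 0.1 and is a required flag on the CLI
`attack` command; no canonical value exists for this task.

## Benchmark problem sizes

The acceptance-level benchmark uses 200+200 windows of 51 nt, motif rate
0.5 (strong signal) or 0 (null), and a reduced architecture
(d_model 32, GRU hidden 32, 4 heads, channels 8/16/32, classifier 32),
trained 4 epochs per fold at batch size 32 — sizes chosen so a 10-fold run
completes in minutes on one CPU while the signal condition is comfortably
learnable, as certified by a cross-validated logistic regression on raw
2-mer counts reaching AUROC ≥ 0.9 on the same data before the network's
result is interpreted. The ablation grid (feature schemes, single paths,
no positional encoding, no attention) runs on a smaller 30+30, 21-nt set.

## Known limitations

* The synthetic generator's i.i.d. background understates the structure of
  real transcripts; real-data performance must be established on real data.
* The greedy identity filter is O(n²·L) and not a drop-in for clustering
  tools on very large corpora.
* Training is single-threaded NumPy; the defaults (d_model 512) are
  practical for full-scale datasets only with patience — the reduced
  configuration is recommended for experimentation.
* Checkpoints store raw float64 parameters; no quantization or pruning.
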