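# Methods

## Model

The predictor is a shared-trunk multi-task sequence labeller. Input is an
L×D per-residue encoding; D depends on the encoder (20 one-hot, 50
profile, 1280 language-model embedding — the two latter arrive as
precomputed matrices through the HDF5 archive loader; producing them is
outside this package's scope). The trunk is:

1. two **parallel** 1-D convolutions over the length axis, each consuming
   the raw encoding (32 channels; kernels 129 and 257 with paddings 64 and
   128, i.e. 'same'; ReLU; dropout 0.5). Parallel rather than stacked
   branches follow from the channel arithmetic of the concatenation step:
   the trunk concatenates [input, branch A, branch B] to D + 64 channels;
2. 1-D batch normalisation over channels. Statistics are computed over
   non-padded positions only, so batch composition and padding length
   cannot leak into predictions; running estimates (momentum 0.1, biased
   variance) are used at inference;
3. a 2-layer bidirectional LSTM, hidden 1024 per direction, dropout 0.5
   between layers. The backward direction reverses each sequence within
   its true length (gather/scatter by index), never across trailing
   padding;
4. a fully connected ReLU layer (default width 2048 — the original width
   is not documented; 2048 keeps the head input comparable to the biLSTM
   output) with dropout;
5. six linear heads: Q8 (8 logits), Q3 (3 logits), disorder (2 logits),
   RSA (1, sigmoid to keep [0, 1]), φ and ψ (2 each, tanh to keep
   [-1, 1], interpreted as sine/cosine).

Class probabilities are softmaxes of head logits, applied at readout; the
heads themselves emit logits because the loss consumes logits. Angles are
decoded as atan2(sin, cos) in degrees in (−180, 180]; an exactly-zero
(sin, cos) row has no defined angle and raises unless a sentinel is
configured (bundle decoding uses 0.0, which tanh outputs cannot produce
exactly in practice). ASA is derived exactly as RSA × ASA_max per residue
type, using the Tien et al. theoretical maxima by default; the table is
configuration, and unknown residues use the mean of the 20 canonical
values.

A transformer downstream variant replaces steps 1–4 with a linear
projection to `transformer_dim` (default 128; the encoder dimension is a
free choice here because one-hot inputs (D = 20) are not divisible by 8
heads), plus sinusoidal positional encoding and 2 post-norm encoder layers
with 8 heads; padded keys are masked out of attention. The positional
scheme of the original variant was described only as "cyclic"; the
standard sinusoidal encoding used here is periodic per dimension and is
the documented approximation. Head contract and decoding are identical.

## Objective

Weighted sum of per-task terms, weights (1, 5, 5, 100, 5, 5) for Q8, Q3,
disorder, RSA, φ, ψ. Cross-entropy terms are means over non-padded
positions; regression terms are means over positions that are non-padded
*and* valid for regression (not disordered, not 'X' — their reference
values are unreliable). Disorder itself is masked only by padding: the
disorder label is exactly what disordered regions do carry. Angle MSE sums
the squared sine and cosine errors per position before averaging (the
channel reduction is not fixed by the published description; summing keeps
the per-position error the squared chord distance). Each task averages
over its own unmasked positions — not sequence-then-batch — which makes
the padding-invariance property exact. A task with no unmasked position
contributes an exact zero; a batch with no unmasked position at all is an
error. The printed weights are exposed as configuration; no dynamic
re-balancing is performed.

## Training

Adam (lr 5e-4, eps 1e-8, betas 0.9/0.99, weight decay 0), mini-batches of
15 sequences padded to the batch maximum. The training set is reshuffled
every epoch from the run seed; validation order is fixed, and the
validation total is a residue-weighted mean over batches. Early stopping
compares each epoch's validation total to the best so far (strictly-less
counts as improvement) and stops after `patience` = 3 consecutive
non-improvements; the best epoch's parameters are restored and
checkpointed. `max_epochs` (default 100) is a hard cap. No learning-rate
schedule; optional global-norm gradient clipping is off by default.

## Long sequences

Encoders with a 1024-residue window limit are applied through a moving
window of size W = 1024 and stride S = 824 (200 residues of overlap).
Interior window edges are trimmed by T = 50 context-starved residues. The
remaining W − S − 2T = 100 doubly-covered residues are assigned at the
midpoint of the residual overlap, i.e. the boundary between windows i and
i+1 sits at start_{i+1} + T + (W−S−2T)/2 — symmetric, and keeping every
position maximally far from any window edge. The first window keeps from
position 0 and the last keeps to L: sequence termini have no artificial
context edge to trim. Window starts are 0, S, 2S, …; the last window is
the first whose end reaches L, clipped, never shifted. These rules make
the keep intervals an exact partition of [0, L), verified by brute-force
coverage counting in the tests. The per-edge trim guarantee of T requires
W − S ≥ 2T, which the defaults satisfy.

## Evaluation

Q3/Q8 accuracy over non-padded residues; disorder MCC, FPR and FNR from
the pooled 2×2 confusion table (both rates are computed because published
summaries have used the two labels inconsistently); Pearson correlation
for RSA and ASA and circular MAE (shorter arc, min(|Δ|, 360−|Δ|)) for φ/ψ
over regression-valid residues. Circular distance is essential: a naive
MAE near ±180° is meaningless. Dataset-level metrics pool residues across
proteins (micro-average); per-protein macro-averaging is an option since
the convention is not fixed. Undefined metrics (empty mask, zero variance,
empty confusion margin) are reported as absent, never as fabricated
zeros; a fully degenerate MCC table reports 0 by the usual convention.

## Numerical core

No deep-learning framework is used: `resprop.nn` is a compact
reverse-mode autodiff engine over float64 numpy arrays with exactly the
operations the model needs. Conv1d and the LSTM scan are single tape
primitives with hand-written vector-Jacobian products (keeping the tape
small and the loop fast); everything else is composed from differentiable
primitives. Every custom gradient is checked against central finite
differences in `tests/test_nn.py`. Log-softmax uses the standard max-shift
stabilisation with the shift treated as a constant.

## Synthetic data

`resprop.simdata` generates annotated records with the learnable
structure of real training sets, not their biology:

- Q8 is a first-order Markov chain (defaults: strong self-persistence,
  occupancy concentrated on H/E/C), giving segmental runs; Q3 is derived
  by the fixed collapse so the two label sets are always consistent.
- Amino acids come from state-conditional emissions: helix-, strand- and
  coil-type states favour disjoint residue groups with 85% of the mass.
  This is deliberately far cleaner than real sequence-structure
  correlation; it is a test fixture that makes Q3 learnable from sequence
  alone, not a biological claim.
- φ/ψ are state-conditional Gaussians wrapped to (−180, 180], centred on
  canonical basins (helix (−60, −45), strand (−120, 130), coil broad with
  SDs up to 55°).
- RSA is state-conditional Beta (strand most buried, coil most exposed).
- With probability 0.3 per terminus, a geometric-length (mean 8) stretch
  is relabelled as disordered exposed coil; residues become 'X' with
  probability 0.005. Both are excluded from the regression-validity mask.
- Sequence lengths are uniform on [50, 150]; all draws come from one
  seeded generator, so datasets are byte-reproducible.

Passing tests on this generator demonstrate that the architecture, loss,
masking, training loop and metrics are wired correctly and that the
pipeline can learn a strong sequence-to-structure signal. They say nothing
about accuracy on real proteins, which depends on pretrained embeddings
and large curated training sets outside this package's scope.

## Problem sizes used in tests and the acceptance script

Learning tests and the acceptance script use a reduced configuration —
one-hot input, 8 conv channels, kernels 9/17, biLSTM hidden 64, fc 64,
dropout 0.1, lr 1e-3 — chosen as a sensible optimisation setting for a
model of this size. The overfit check fits 8 sequences of length ≈100; the
generalisation check trains on 180 + 20 validation sequences and evaluates
40 held-out ones; generator-fidelity statistics use ~10⁵ residues. The
full-size configuration (32 channels, kernels 129/257, hidden 1024) is
exercised for its shape and output contracts.

## Known limitations

- CPU-only and float64: the engine favours correctness and testability
  over throughput; full-size training runs are impractical with it.
- The transformer variant's positional encoding approximates an
  under-specified original.
- Whether the original pipeline encoded 'X' as a 21st one-hot channel is
  unknown; here 'X' is an all-zero row (the "20 variables" reading), and
  any other non-canonical letter is an input error.
- Batch-norm running statistics use the biased variance; train/eval
  outputs therefore differ slightly by construction, as usual.
- The annotation CSV stores angles in degrees only; sub-ULP round-tripping
  relies on `repr`-precision floats and round-trip parsing.
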