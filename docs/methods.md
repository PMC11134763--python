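# Methods

## Spectral preprocessing

Raw peak lists are cleaned in a fixed order: (1) m/z rounded to two
decimals, merging equal-m/z peaks by keeping the larger intensity; (2)
intensities rescaled to percent of the base peak; (3) peaks below 0.1 %
relative intensity removed; (4) peaks outside 10–1000 Da removed; (5) a
3-Da denoising pass that walks peaks by descending intensity (ties broken
toward lower m/z) and keeps a peak only if no already-kept peak lies within
1.5 Da. The pass removes isotope satellites and chemical noise crowding a
large peak. This greedy non-maximum suppression was chosen over a literal
sliding window because it is deterministic and independent of walk
direction; the rescale precedes the percent threshold so "relative
intensity" is well defined when the threshold is applied, and a final
rescale keeps the base peak at exactly 100 % even when the original base
peak fell outside the m/z range. Preprocessing is idempotent.

## Pair encoding

All m/z arithmetic is done in integer hundredths of a Da, so nominal-mass /
mass-defect splits are exact. For a query of s_q fragments and a reference
of s_r fragments the mass-difference matrix (MDM) holds |q_i − r_j|. Each
query row is tokenized into a 300-column aligned row: a difference d < 300
Da contributes token round(100·(d − ⌊d⌋)) ∈ {0..99} in column ⌊d⌋; empty
columns hold PAD (100); a CLS row (token 101) is prepended. When two
reference fragments give the same nominal mass in one row, the defect of
the more intense reference fragment wins (ties: smaller m/z) — the paper-
independent choice here is deterministic and keeps the most informative
ion. The same construction is applied to the neutral-loss spectra
(precursor − fragment, non-positive losses dropped); the loss row/column ↔
fragment correspondence is retained so explanations can be mapped back to
product ions. Peak intensity enters only preprocessing and the collision
tie-break, never the tokens themselves.

## Model

Two towers (fragments, neutral losses) share an architecture but not
parameters. Row encoder: token embedding (vocabulary 102 → 32 dims),
flatten to a 9600-wide row, then two blocks; a block splits the row into k
equal heads (k = 100, then 20), applies dropout (0.1) and one affine map
shared across heads (96→128, then 640→128) with ReLU, and re-flattens; a
final affine maps to the 128-dim row vector. Head-sharing reads the block
as a local filter over the aligned row and keeps the parameter count small.
The transformer encoder is the standard post-norm architecture: 2 layers,
4 heads, feed-forward width 256, dropout 0.1, **no positional encoding** —
fragments are an unordered set, which makes the score provably invariant
under peak permutations. The CLS-row outputs of both towers (128 each) are
concatenated and a fusion head (256→128 ReLU, dropout 0.1, 128→1, sigmoid)
produces y_sim ∈ [0,1]. Sigmoid was chosen because the label (a similarity)
lives in [0,1]. Batches pad the row dimension and mask padded rows in
attention, so padding never leaks into CLS.

The network, Adam, and backprop run on a small reverse-mode autodiff core
(`transexion.nn`) written on numpy: float32 throughout, fused
affine(+ReLU) kernels, and gradients retained on intermediate tensors
because the explanation module consumes them. Gradients are verified
against central finite differences in the test suite. Embeddings are
initialized N(0,1), affine weights Glorot-uniform, biases zero.

## Training

Labels are structural similarities: Tanimoto on 2048-bit RDKit path-based
fingerprints (the Daylight-style stand-in; Daylight itself is proprietary)
for real structures, exact moiety-multiset Jaccard for synthetic molecules.
Because random pairs are dominated by low similarity, each epoch resamples
a balanced set: similarity is cut into B = 10 equal-width bins ([l, u),
last bin closed) and every spectrum contributes at most one random partner
per occupied bin; evaluation pairs are drawn the same way with at most
k = 3 partners per bin, after a guard that test/reference sets share no
structure keys. The loss is mean squared error (all downstream evaluation
is squared-error based), optimized by Adam at learning rate 1e-4, weight
decay 0, batch 64. Each sampled pair is used once per epoch with the first
spectrum in the query role; role symmetrization is available behind a flag
but off by default. Early stopping monitors validation MSE with a patience
counter and the best-validation parameters are restored. One practical
note: on desk-scale libraries the optimization shows a long plateau (the
output range stays compressed near the label mean) before calibration
spreads out, so patience should exceed ~20 epochs at this scale — the
bundled experiments run a fixed 50 epochs and keep the best checkpoint.

## Synthetic data

The generator stands in for a spectral library with known structure labels.
Molecules are linear chains of 3–12 moieties (total ≤ 1000 Da) drawn from a
26-mass alphabet of common residues and modifications (CH2 14.02, O 15.99,
H2O 18.01, amino-acid residues, ...). Families share a scaffold whose
moieties come from a family-specific 6-mass vocabulary — unrelated families
then rarely share substructure, as with real compound classes — and members
differ from the scaffold by 1–3 single-moiety swaps, or are an
adjacent-transposition isomer (same multiset, similarity 1, partly
different fragments). Spectra are fragment ladders: every proper contiguous
sub-chain, protonated (+1.01 Da). A fragment's base abundance is a stable
lognormal function of the cleaved bond positions — fragmentation propensity
travels with the backbone, so analog molecules produce corresponding
fragments at correlated abundances — multiplied by per-acquisition
lognormal jitter (σ = 0.3); the 10 strongest fragments are kept, a spurious
noise peak is added with probability 0.1, and the result is run through the
standard preprocessing. Ground truth is the multiset Jaccard of moiety
masses: exactly computable, symmetric, 1 iff the multisets coincide.

What the generator does *not* emulate: real fragmentation chemistry
(rearrangements, multiple bond cleavages), isotope envelopes, adducts other
than a fixed proton, negative mode, and instrument-dependent resolution.
Tests passing on this generator therefore demonstrate that the pipeline
recovers structure-similarity signal encoded as shared/shifted fragment
ladders — not that the trained toy model transfers to experimental data.

## Explanation

Relevance propagation follows gradient-weighted attention rollout in the
Deep Taylor spirit: after a forward/backward pass of one pair, each
encoder layer contributes Ā = mean over heads of (∂y/∂A ⊙ A) with negative
parts clamped to zero, composed across layers as R ← R + Ā·R starting from
the identity. The CLS row of R assigns each aligned-matrix data row a
relevance; each row's budget is distributed over its non-PAD cells
proportionally to the L2 gradient magnitude at the embedded tokens, and
each cell maps to the reference fragment recorded in its provenance (loss-
tower cells map through the loss ↔ fragment correspondence). Tower budgets
are the clamped gradient×input contributions of each tower's half of the
fusion input, normalized to sum to one, so the final matrix sums to 1
(up to rows whose cells are all PAD, which have nothing to attribute to).
The report ranks query ions by row-sum relevance (ties: higher m/z), keeps
the top q = 20, and per ion the top k = 3 reference ions (ties: smaller
|shift|, then lower m/z) with the signed shift (reference − query, 2 dp).
The exact propagation rule (clamping, head averaging, gradient-based cell
distribution) is one defensible instantiation of attention relevance;
each step is isolated so alternatives can be swapped in.

## Evaluation

Precision–recall sweeps treat "analog" as label > c for c ∈ {0.6, 0.7,
0.8, 0.9} and sweep the score threshold over all unique scores; per-bin
MSE uses the same B = 10 equal-width label bins (empty bins are reported
absent, never as zero); Pearson r uses scipy, with a guard returning 0
(with a warning) for degenerate constant inputs. Cosine and modified
cosine baselines match peaks greedily by descending intensity product
within 0.02 Da (modified: additionally at the precursor-difference shift),
each peak used once, normalized by the intensity-norm product; the greedy
matcher is cross-checked in tests against exhaustive optimal assignment
and against matchms. Molecular-network edges symmetrize scores by
averaging, keep edges > 0.6, keep an edge only if it ranks in the top
k = 10 of both endpoints (the usual library-networking convention), and
split components above 100 nodes by removing their weakest edge.

## Experiment sizes

The bundled end-to-end study trains the default architecture on a
200-molecule library (one spectrum per molecule, 170/10/20
train/validation/test split by molecule, seed 0) for 50 epochs — roughly
a quarter hour on one CPU — and evaluates on ~500 balanced held-out pairs.
Explanation fidelity uses 20 single-swap analog fixtures (+15.99 or
+14.02); self-retrieval queries each of the 170 training spectra against
the training library. These sizes were chosen so the whole study runs on a
laptop while leaving every similarity bin occupied.

## Known limitations

- The per-head affine shapes, output activation, loss, optimizer schedule
  and early-stopping rule are design choices where the underlying method
  description is silent; they are documented above and isolated in config.
- The score is asymmetric in (query, reference); library search always
  puts the query in the query role, and networking symmetrizes by
  averaging.
- Training at desk scale is CPU-bound through the 9600-wide row encoder;
  the implementation fuses the large GEMMs but does not exploit PAD
  sparsity.
- Checkpoints store raw parameter arrays plus config and are not portable
  to other implementations of the architecture.
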