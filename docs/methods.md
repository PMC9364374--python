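# Methods

This note records the models, conventions, parameter choices and known
limitations behind `shadowfold`, at the level of detail a user needs to
interpret its outputs.

## Problem setting

RNA secondary structure — the set of canonical base pairs (A–U, G–C, G–U) an
RNA forms with itself — is far more conserved within an RNA family than
sequence is. Benchmarks that split sequence–structure corpora randomly
(k-fold cross-validation) therefore place close structural homologs of every
test RNA in the training set. `shadowfold` provides a controlled apparatus for
measuring how much of a learned predictor's apparent accuracy is homology
recall: the same model, data and metrics are evaluated under random k-fold
splits (intra-family) and under leave-one-family-out, *family-fold*, splits
(inter-family), where no family ever crosses the train/test boundary.

## The shadow CNN

The demonstrative model predicts each nucleotide's paired/unpaired state (the
structure's *shadow*), not the partner identities. Sequences are one-hot
encoded as 4×512 matrices (rows A, C, G, U; T read as U; ambiguity codes such
as N/R/Y become all-zero columns, indistinguishable from padding — the most
conservative choice) and zero-padded at the 3′ end; targets are the 1×512
zero-padded binary shadows.

Architecture: conv(4→256, kernel 3, stride 1, same padding) + ReLU, spatial
dropout 0.25 (whole feature maps dropped), conv(256→256, kernel 3) + ReLU,
flatten, dense(512) + ReLU, dropout 0.25, dense(512) + sigmoid. The default
instantiation has 67,572,224 trainable parameters. Two wiring details are
genuinely open given only the layer list, and we fixed them as follows:

- **Dense head**: the dense layers act on the *flattened* convolution output,
  so the final 512 sigmoid units align one-to-one with the 512 padded target
  positions. A per-position head (the dense block applied independently at
  each position) is available via `fc_mode="per_position"` but is not the
  default.
- **Convolution padding**: same-padding, required for the flattened feature
  size to be fixed and for positions to align with targets.
- **Loss over padding**: binary cross-entropy is computed over all 512
  outputs; padded positions carry target 0 (labelled unpaired). Evaluation
  AUC excludes padding, which would otherwise trivially inflate it.
- **Early stopping** monitors validation loss with patience 5 and restores
  the best-epoch weights.

Training uses Adam (learning rate 10⁻³, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸),
mini-batches of 256, an epoch cap of 100. The network is implemented directly
in numpy with hand-written forward/backward passes: on the corpus sizes this
package targets, that is fast enough on one CPU, and it makes training
bit-reproducible under a fixed seed (one `numpy` Generator drives
initialization, shuffling and dropout).

## Pseudo-free energies

Shadow predictions convert to SHAPE-like reactivities α̂(i) = 1 − ŷ(i)
(high reactivity ⇒ likely unpaired, matching chemical probing conventions; no
further normalization), then to per-nucleotide pseudo-free-energy terms

    ΔG′(i) = m · ln(α(i) + 1) + b   [kcal/mol],

equivalently ΔG′(i) = m·ln(2 − ŷ(i)) + b — the two forms agree to machine
precision and a test asserts it. Defaults m = 1.8, b = −0.6 kcal/mol, the
conservative values established for experimental SHAPE data, deliberately not
refit: refitting (m, b) on a validation set that shares families with
training is itself an overfitting channel, which is part of what the package
measures.

With m = 0 the term is the uniform *nudge* ΔΔG′ = b applied at every
nucleotide. The nudge experiment folds each sequence at
b ∈ {−1.00, −0.98, …, 1.00} (101 folds per sequence), traces per-family mean
F1 curves, min–max normalizes them for cross-family comparison, and tests
each b against b = 0 with paired t-tests.

An exhaustive (m, b) grid search over an 11×11 grid is provided; the default
grid m ∈ {0.0, 0.3, …, 3.0}, b ∈ {−1.5, −1.3, …, 0.5} brackets both published
SHAPE optima ((1.8, −0.6) and (2.6, −0.8)). The exact historical search grid
is not public; ours is a configurable stand-in. Ties prefer the weakest
intervention (smallest |m|, then |b|). The objective is the unweighted
per-sequence mean F1 on the validation set — family aggregation is a
reporting concern, not a fitting concern.

## Folding backends

**External.** A thin wrapper around RNAstructure's `Fold` executable
(discovered on PATH, via `RNASTRUCTURE_FOLD`, or passed explicitly; a missing
binary raises an error naming all three options). Reactivities are written as
standard two-column SHAPE data files (−999 for missing) and passed with slope
and intercept options; the first (MFE) structure of the output CT is parsed.
The stock executable rounds SHAPE intercepts to tenths, so uniform-nudge runs
at hundredths resolution use the reference backend.

**Reference.** A built-in O(n³) interval dynamic program minimizing a
simplified energy: each canonical pair (i, j) with j − i > 3 contributes a
base term (GC/CG −3, AU/UA −2, GU/UG −1, model units) plus ΔG′(i) + ΔG′(j)
when a profile is supplied. Negative is stabilizing; positive ΔG′
destabilizes. Two deliberate properties:

- **Per-pair, not per-stack, ΔG′ application.** The nearest-neighbour scheme
  adds ΔG′ per base-pair stack; a stack-free energy model has no analogue, so
  the closest consistent rule — once per formed pair — is used. The external
  backend preserves the per-stack semantics.
- **Deterministic traceback**: at score ties the pairing branch is preferred,
  then the smallest partner index, so outputs are stable across runs.

The DP is numba-compiled; correctness is pinned by a brute-force enumeration
oracle (all non-crossing structures, sequences up to 12 nt, 200 random
instances, exact score equality). Neither backend can emit crossing pairs;
pseudoknot prediction is NP-hard under most energy models and out of scope.

## Splits

k-fold assignment is an unstratified seeded uniform shuffle (no family
stratification). Family-fold produces one fold per family with that family as
the test set. Both carve a validation set of round(0.10 × |train|) records
(floor 1), re-drawn per fold with seed = base_seed + fold index. For
family-fold plans the validation set intentionally still shares families with
training: that is the protocol under study, and it is why early stopping
cannot prevent inter-family overfitting. Plans serialize to JSON so external
predictors can consume identical splits.

## Scoring

Base-pair scoring allows ±1 slippage: predicted (i, j) is matched if the
reference contains (i, j), (i±1, j) or (i, j±1), and symmetrically for
reference pairs — two-sided independent matching with no one-to-one
assignment, following the standard scorer lineage. PPV = matched predicted /
predicted, sensitivity = matched reference / reference, F1 their harmonic
mean. Edge conventions: empty prediction against a nonempty reference scores
0; two empty sets score 1 (a correctly predicted unpaired molecule). Shadow
AUC is the rank statistic (ties ½), undefined (NaN, excluded from aggregates
with counts reported) when a sequence has no paired or no unpaired positions.
Per-sequence AUCs are averaged within family; pooling nucleotides across a
family is exposed as an option but not the default. Family reports take
per-family means and an **unweighted** grand mean across families — forced by
the published tables' arithmetic, where the Mean row is not sequence-weighted.
Paired t-tests are two-tailed on per-sequence differences; zero-variance
all-zero differences report (t = 0, p = 1), zero-variance nonzero differences
have no finite t and report (±inf, 0). No multiple-testing correction is
applied across the nudge grid; raw p-values are reported.

## Homology audit

Structures map to rooted ordered trees: virtual root, one internal node per
pair (nesting = ancestry), one leaf per unpaired base attached to its
innermost enclosing pair; children follow 5′→3′ order. Crossing pairs are
first reduced to a maximum-cardinality non-crossing subset (deterministic
interval DP). Distance is unit-cost ordered tree edit distance via the
Zhang–Shasha dynamic program (numba-compiled inner loops); the audit statistic
is the mean over test records of the minimum distance to any training record.
All-vs-all distances are expensive on large corpora, so the audit subsamples
(seeded) above configurable caps and reports the sizes used. The tree encoding
and costs are one reasonable instrument among several; absolute values are
comparable only within one encoding, so use the statistic to compare splits,
not against numbers produced by other encodings.

## Synthetic families

The generator reproduces the single statistical property the benchmarking
argument rests on: **conserved structure within families, diverged sequences,
unrelated structures across families.**

- Consensus structures are drawn by recursive stem/loop construction: stem
  lengths geometric with mean 4, loop sizes uniform on 3–8, branching
  probability 0.2, small (0–2 nt) bulge offsets between stacked helices.
  These constants were calibrated once so that the mean paired fraction at
  length 100 sits in [0.3, 0.8] (measured ≈ 0.68 over 500 draws).
- Members of a family share the consensus pair set *exactly* (no structural
  drift — the cleanest instantiation of the premise, and maximally
  interpretable; drift is a future knob). Sequences descend from a family
  ancestor with a per-member resample fraction (default 0.5) applied
  per position; paired positions are always re-drawn jointly as a canonical
  pair, with weights favouring G–C (0.25/0.25/0.15/0.15/0.10/0.10 over
  GC/CG/AU/UA/GU/UG) so the reference folder's MFE structures stay close
  enough to the consensus for the pseudo-energy stage to have signal. At the
  defaults the within-family mean pairwise identity measures ≈ 0.38–0.45,
  well inside the "low identity, identical structure" regime.
- The default fixture is 6 families × 40 members with lengths
  {60, 80, 100, 120, 150, 200} — 240 records, chosen so the complete
  two-regime experiment (11 model trainings) runs in about three minutes on
  one CPU.

What passing tests on this corpus do **not** show: real thermodynamic
parameters, real family structure statistics (multiloop geometry,
non-canonical pairs, pseudoknot frequency), realistic covariation or indels,
or the absolute accuracy numbers achievable on curated corpora. The synthetic
results are directional evidence about the *benchmarking methodology*, which
is the package's subject.

## Desk-scale experiment configuration

`fixture_experiment_config` scales the model to the fixture (48 conv filters,
256 dense units, pad 256, batch 32, ≤ 25 epochs, patience 5) while keeping the
architecture shape, loss, optimizer and stopping protocol identical to the
default configuration. On the 240-record fixture with this configuration the
package reproduces, directionally and stably across seeds: near-perfect
intra-family shadow AUC with F1 well above the no-model baseline; chance-level
inter-family AUC with F1 below baseline; a family-fold validation–test AUC
margin that stays large at every epoch; and a test→train structural distance
of 0 for k-fold splits versus tens of edits for family-fold splits.

## Known limitations

- The reference folder's energy model is intentionally minimal (no stacking,
  loop penalties or dangles); its absolute F1 levels are not comparable to
  nearest-neighbour folding, only its contrasts under identical inputs.
- The numpy CNN targets small corpora; training thousands of 512-nt sequences
  at the full 67M-parameter configuration is possible but slow.
- Tree-edit audit values depend on the chosen encoding and unit costs
  (see above).
- BPSEQ/Stockholm input, tertiary contacts, non-canonical pair classes and
  clan-aware splitting are out of scope.
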