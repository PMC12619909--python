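# Methods

## Problem and model

`tehier` classifies transposable-element (TE) consensus or instance
sequences into the standard Wicker-style hierarchy (Class I
retrotransposons vs Class II DNA transposons, their orders LTR / LINE /
SINE / TIR / ..., and their superfamilies). Two complementary signals
carry type information:

* **global composition** — the k-mer usage of the whole element, encoded
  as an L1-normalised frequency vector of length 4^k (default k = 7).
  Counting uses a rolling Horner update: the index of each window is a
  base-4 number maintained incrementally (`idx = (4·idx + digit) mod 4^k`),
  so a slide costs O(1) instead of O(k). Windows containing any
  non-ACGT symbol are skipped, and k-mers are counted on the given
  strand only, since repeat-library consensus orientation is meaningful.
* **local terminal structure** — LTR direct repeats, TIR inverted
  repeats, CACTA termini, poly(A)/poly(T) tails all live near the
  sequence ends. The first and last L bases (default L = 600) are
  concatenated into a "both ends" (BE) string and one-hot encoded
  (channels A, C, G, T; anything else, including padding, is a zero
  row, so padding carries no signal). Sequences shorter than L are
  padded with N; shorter than 2L, the two windows overlap.

Each parent node of the taxonomy (an internal node with ≥ 2 children;
nine of them in the shipped default tree) owns one classifier over its
children. The classifier runs two encoders in parallel:

* global branch: three 1-D convolution + max-pool blocks (64/128/256
  kernels, width 3, stride 1, same padding, pool width 2), flatten,
  dense 128, ReLU throughout, dropout 0.5;
* local branch: two stacked GRUs (128 and 64 units, full sequence
  output kept), flatten, dropout 0.5, dense 128, ReLU. The GRU gates
  follow the bias-free formulation (z, r gates with sigmoid, candidate
  state with tanh and reset-modified recurrent term).

A shared scalar attention head scores each branch feature h_s as
e_s = tanh(W·h_s); softmaxing the two scores yields weights
(α_cnn, α_rnn) with α_cnn + α_rnn = 1, and the context vector
c = α_cnn·h_cnn + α_rnn·h_rnn feeds the softmax output layer directly
(no further hidden layer). Training minimises categorical cross-entropy
with Adam at learning rate 5e-4.

Because the attention is a softmax over exactly two scalar scores, it is
computed as a logistic of the score difference — mathematically
identical and numerically stabler.

## Hierarchical prediction

Prediction is top-down, nonmandatory-leaf: starting at the root, the
current node's classifier scores the children and the query descends to
the argmax child iff the maximum probability is ≥ the stopping
threshold τ (default 0.60); a maximum strictly below τ terminates at
the current node. Ties at the argmax descend into the
lexicographically first tied child (logged). The threshold is also
applied at the root: a query whose root-level maximum falls below τ
keeps the bare root label, read as "TE, unspecified". Single-child
internal nodes are traversed without a classifier. Sweeps across the
standard grid (0.50 to 0.95 in 0.05 steps) reuse the greedy chain: the
argmax descent is threshold-independent, so one traversal per query is
truncated per threshold — provably identical to running the rule at
each grid value (and verified against an exhaustive oracle in tests).

## Evaluation

Flat per-node metrics: confusion matrix, accuracy, per-class
precision/recall/F1, unweighted macro averages, multiclass MCC (the
standard generalisation, reducing to the familiar binary formula at two
classes). Zero-division conventions: an unpredicted class has precision
0; an MCC with a zero denominator factor is 0; both are logged.

Hierarchical metrics use ancestor-closed label sets P_i (most specific
predicted label plus ancestors) and T_i (true label plus ancestors):
hP = Σ|P_i∩T_i| / Σ|P_i|, hR = Σ|P_i∩T_i| / Σ|T_i|, hF their harmonic
mean. The universal root is excluded by default — every sample shares
it, so including it inflates both scores uniformly; `include_root=True`
restores the strict form.

Monotonicity: higher thresholds can only truncate prediction paths, so
hR is weakly decreasing in τ by construction; hP is expected to
increase because the deepest (least confident) descents, where errors
concentrate, are cut first.

## Numerical core

No deep-learning framework is used: the networks run on a compact
reverse-mode autodiff engine over float64 numpy arrays
(`tehier/_autodiff.py`), supporting exactly the operations the
architecture needs (matmul, conv via sliding-window unfold, max pool,
GRU gate arithmetic, fused softmax/cross-entropy). Every operation is
gradient-checked against central finite differences in the test suite;
a full-model gradient matches finite differences to ~1e-7 relative
error. All randomness (initialisation, batch order, dropout) derives
from explicit integer seeds; a (config, seed) pair reproduces its
parameter trajectory bit-for-bit on a fixed platform. Parameters are
Glorot-uniform initialised, except the attention projection, which is
zero-initialised so training starts from the balanced convex
combination (α = 0.5/0.5): a randomly initialised attention head
begins with an arbitrary branch preference and, at small training-set
sizes, can lock onto whichever branch memorises the training data
first instead of the branch that generalises. k-mer frequencies
average 4^-k per entry,
so the global branch rescales its input by 4^k to keep early-layer
activations near unit scale.

## Default taxonomy

The exact child inventory of the reference hierarchy below superfamily
level is not fully published, so the tree is configuration-driven
(`node -> [children]` mappings in YAML) with a shipped default
reconstructed from the names that appear in the literature. The default
exposes exactly nine classifier sites (TE, ClassI, ClassII, LTR,
nonLTR, LINE, SINE, ERV, TIR). Helitron and Maverick sit directly under
ClassII rather than under an intermediate subclass-2 node: giving that
node both children would create a tenth classifier site, contradicting
the nine-classifier design, and the flat placement preserves both the
classifier count and the full leaf inventory. This default is a
reconstruction and should be replaced by a project-specific
configuration where a curated tree exists.

## Synthetic data

The simulator generates labelled repeat libraries whose class signal is
known by construction: per-class motif plans plant LTR-like direct
terminal repeats, TIR-like reverse-complement termini, fixed CACTA /
TAGTG ends, poly(A) or poly(T) tails, and interior composition bias
(designated 7-mers planted at a density of 2.5 expected occurrences per
word per kb of interior by default). Planted motifs are optionally
mutated at a per-base substitution rate. Background is uniform 25% per
base. Non-TE decoys cover the three-way TE/CDS/TR task: codon-structured
coding-like sequences (ATG, biased sense codons, stop) and tandem
repeats (short unit copied to length with per-copy mutations). All
outputs satisfy the preprocessing filters (length ≥ 80, no ambiguity).

A composition bias expressed as a small multiplicative factor on a
7-mer's background frequency is undetectable at realistic sample sizes
— a 7-mer's expected count in a 400–800 bp interior is only ~0.02–0.05,
so e.g. tripling it adds ~0.05 occurrences. The bias plan is therefore
parameterised as a planting *density* (occurrences per word per kb);
the 2.5/kb default yields a signature that a few hundred training
sequences resolve while occupying under ~10% of the sequence.

Two controlled contrasts in `tehier.experiments` isolate the feature
channels, mirroring the single-branch ablation logic:

* **terminal contrast** — class A carries motif M at the 5' end and
  revcomp(M) at the 3' end, class B the same two motifs swapped. The
  two classes share an identical terminal k-mer multiset, so global
  composition is uninformative *by construction* (a logistic-regression
  probe on k-mer features scores at chance) and only terminal order
  separates them.
* **composition contrast** — two classes with different designated-word
  sets planted only in the interior, outside the both-end windows, so
  the local branch sees identical statistics.

What passing these tests shows — and does not show: the pipeline
recovers planted signal of realistic type and strength under clean
conditions. Real repeat libraries add nested insertions, truncated
elements, diverged families, shared ancient domains and species-level
composition confounds, none of which the simulator models; desk-scale
results do not predict absolute accuracy on real data.

## Reduced-scale study sizes

The test suite and acceptance script train at reduced scale, chosen as
the smallest configuration that cleanly resolves the planted signal:
k = 5, L = 100, conv channels 8/16/32, GRU 12/8, shared dense width 32,
batch 64, learning rate 5e-3, 20 epochs, 200 sequences per class with
an 80/20 split (contrasts averaged over three seeds), and a three-level
mini-taxonomy (TE → ClassI/ClassII → Gypsy, L1, hAT, CACTA) with 100
sequences per leaf for the end-to-end sweep. The full-scale defaults
(k = 7, L = 600, 64/128/256 kernels, GRU 128/64, dense 128, lr 5e-4,
dropout 0.5) remain the package defaults for real libraries.

## Design choices on open points

* **Frequencies vs counts**: the global feature defaults to
  L1-normalised frequencies (length-invariant across TEs of very
  different sizes); raw counts sit behind a flag.
* **Convolution geometry** (width 3, stride 1, pool 2, same padding):
  chosen as the conventional minimal setting; reported experience is
  that these choices barely move performance.
* **Second GRU output**: the full sequence is kept before flattening
  (flattening a single final state would be vacuous).
* **Dropout** is applied after the dense/flatten stages only, not
  inside GRU recurrences.
* **GRU biases**: omitted, following the gate equations as printed in
  the formulation adopted here; conv/dense layers keep biases.
* **Descent comparison**: `max probability ≥ τ` descends; strictly
  below stops (0.57 < 0.60 stops).
* **Dedupe**: default exact-sequence deduplication (first occurrence
  kept); an optional greedy k-mer cosine-similarity mode with a
  threshold exists for clustered libraries. The boundary semantics of
  the filters are strict: exactly 80 bp is kept, exactly 20% ambiguity
  is kept.
* **Stratified split rounding**: per-leaf test count is
  `round(n·frac)`, at least 1 when the leaf has ≥ 2 members.
* **Attention dominance summaries** average a query's (α_cnn, α_rnn)
  over its descents; queries that never descended count as balanced.

## Known limitations

* Pure-numpy training is CPU-bound; the full-scale architecture on
  six-figure libraries would need hours-to-days, so the package is best
  suited to moderate libraries or reduced configurations on CPU.
* Backend determinism is platform-level: trajectories are bit-exact on
  one platform but may differ across BLAS builds; comparisons should be
  tolerance- or rank-based.
* Error propagation is inherent to top-down prediction: a wrong
  high-level descent cannot be recovered below.
* No protein/domain evidence is used; families conserved only at the
  protein level but divergent in DNA will be hard for this model, as
  for any alignment-free DNA-feature method.
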