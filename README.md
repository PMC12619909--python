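# tehier

Hierarchical classification of transposable elements (TEs) from
sequence alone, for genome-annotation and repeat-library curation work.
Repeat libraries mix retrotransposons and DNA transposons whose types
form a tree (Class I/II → orders like LTR, LINE, SINE, TIR →
superfamilies like Gypsy, L1, hAT); `tehier` assigns each query the
deepest label it can support with confidence, instead of forcing every
sequence to a leaf.

## Model

Each sequence is summarised by two fixed-size representations:

* a global k-mer frequency vector x ∈ R^(4^k) (default k = 7), counted
  with a rolling Horner update (`idx = (4·idx + digit) mod 4^k`, O(1)
  per slide);
* a local "both ends" one-hot matrix over the first and last L bases
  (default L = 600), where the diagnostic terminal structures (LTRs,
  TIRs, CACTA termini, poly(A)/poly(T) tails) live.

One classifier per parent node of the taxonomy learns to discriminate
that node's children: a CNN branch (three conv/max-pool blocks,
64/128/256 kernels, dense 128) encodes the global vector, a GRU branch
(two stacked GRUs, 128/64 units, dense 128) encodes the both-end
matrix, and a scalar attention head fuses them:

    e_s = tanh(W·h_s),   α_s = softmax over s ∈ {cnn, rnn},
    c   = α_cnn·h_cnn + α_rnn·h_rnn

with a softmax output over the child labels, trained by Adam on
categorical cross-entropy. At prediction time a query walks the tree
top-down, descending to the argmax child while the maximum child
probability stays ≥ a threshold τ (default 0.60) and stopping
otherwise — "nonmandatory leaf-node prediction". Flat metrics
(accuracy, macro P/R/F1, MCC) score each node classifier; hierarchical
precision/recall/F (hP/hR/hF over ancestor-closed label sets) score
whole predicted paths.

The networks run on a small, fully tested numpy autodiff core — no GPU
or deep-learning framework required.

## Worked example

Simulate a small labelled library over a three-node taxonomy, train at
reduced scale, predict and evaluate (about 90 seconds on one CPU):

```
cat > mini_tax.yaml <<'YAML'
TE: [ClassI, ClassII]
ClassI: [Gypsy, Copia]
ClassII: [hAT, TcMar]
YAML
tehier simulate --classes Gypsy=40,Copia=40,hAT=40,TcMar=40 \
       --taxonomy mini_tax.yaml --seed 7 --out demo.fasta
tehier train demo.fasta --taxonomy mini_tax.yaml \
       --kmer-size 5 --end-length 100 \
       --conv-channels 8,16,32 --gru-units 12,8 --dense-units 32 \
       --learning-rate 0.005 --epochs 12 --batch-size 32 \
       --seed 7 --model-dir models/
tehier predict demo.fasta --taxonomy mini_tax.yaml \
       --kmer-size 5 --end-length 100 \
       --model-dir models/ --threshold 0.6 --out preds.tsv
tehier evaluate --predictions preds.tsv --truth demo.truth.tsv \
       --taxonomy mini_tax.yaml --out eval.tsv
```

which trains the three parent-node classifiers and prints

```
trained TE on 160 sequences (2 classes)
trained ClassI on 80 sequences (2 classes)
trained ClassII on 80 sequences (2 classes)
wrote 160 predictions to preds.tsv
metric  value
    hP    1.0
    hR    1.0
    hF    1.0
```

Every simulated Gypsy/Copia record (LTR retrotransposons: direct
terminal repeats + composition bias) and hAT/TcMar record (DNA
transposons: terminal inverted repeats) is routed to its leaf, so the
predicted and true ancestor sets coincide and all three hierarchical
scores are 1 — this demo scores the training sequences themselves;
held-out evaluation at the same scale is what `scripts/acceptance.py`
measures. Each row of `preds.tsv` records the per-descent confidence
and attention weights, e.g.

```
sequence_id  predicted_path   stop_level  confidence         alpha_cnn          alpha_rnn          threshold
SIM000000    TE/ClassI/Gypsy  2           0.999973;1.000000  0.152661;0.136559  0.847339;0.863441  0.6
```

showing which branch (global CNN vs local GRU) drove each decision.

The same workflow applies to real repeat libraries in FASTA with
`ID|TE_type|Species_ID` headers, using the full-scale defaults
(`--kmer-size 7 --end-length 600`, 64/128/256 conv kernels, GRU 128/64).

## Layout

- `src/tehier/hierarchy.py` — taxonomy tree, validation, ancestor queries
- `src/tehier/features.py` — Horner k-mer vectors, both-end one-hot
- `src/tehier/model.py` — attention-fused CNN/GRU node classifier
- `src/tehier/_autodiff.py` — the numpy reverse-mode autodiff core
- `src/tehier/hier_predict.py` — threshold-stopped top-down traversal
- `src/tehier/metrics.py` — flat + hierarchical metrics
- `src/tehier/synthetic.py` — motif-planted sequence simulator
- `src/tehier/io.py` — FASTA I/O, filters, splits, node datasets
- `src/tehier/experiments.py` — reduced-scale contrast / pipeline studies
- `src/tehier/cli.py` — the `tehier` command
- `docs/methods.md` — modelling and design notes
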