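"""Desk-scale study designs tying the simulator to the classifier.

Two controlled contrasts isolate the two feature channels:

* **terminal contrast** — two classes share an *identical* terminal
  k-mer multiset (class A carries motif M at the 5' end and its reverse
  complement at the 3' end; class B the same two motifs swapped), so
  global k-mer composition is uninformative by construction and the
  classes are separable only through local terminal order;
* **composition contrast** — two classes differ only in which designated
  7-mers are overrepresented (3x) in the sequence *interior*, outside
  the both-end windows, so the local branch sees identical statistics
  and only the global branch carries signal.

A third design builds a three-level mini-taxonomy (root -> two classes
-> four leaves, using structurally distinct leaf plans) for end-to-end
hierarchical training and threshold sweeps.

These experiments run at a reduced scale (k=5, end length 100 bp,
conv channels 8/16/32, GRU 12/8, shared dense width 32, batch 64,
learning rate 2e-3) so a full contrast trains in well under a minute on
one CPU; the full-scale architecture defaults are unchanged.
"""

from __future__ import annotations

import numpy as np

from .features import featurize, reverse_complement
from .hier_predict import THRESHOLD_GRID, threshold_sweep
from .hierarchy import Taxonomy, load_taxonomy
from .io import build_node_datasets, stratified_split
from .metrics import flat_metrics, hier_metrics
from .model import ModelConfig, NodeClassifier
from .synthetic import MotifPlan, SimulationSpec, class_motif, default_plans, simulate_dataset

__all__ = ["reduced_config", "contrast_spec", "run_contrast",
           "mini_taxonomy", "run_hierarchical_experiment"]

REDUCED_K = 5
REDUCED_L = 100


def reduced_config(branch: str = "both", k: int = REDUCED_K,
                   L: int = REDUCED_L) -> ModelConfig:
    """The desk-scale architecture used throughout the experiments."""
    return ModelConfig(k=k, L=L, conv_channels=(8, 16, 32), gru_units=(12, 8),
                       dense_units=32, learning_rate=5e-3, branch=branch)


def contrast_spec(kind: str, seed: int, n_per_class: int = 200,
                  mutation_rate: float = 0.05) -> SimulationSpec:
    """Simulation spec for one two-class contrast.

    ``kind`` is ``"terminal"`` (classes hAT vs TcMar, local-only signal)
    or ``"composition"`` (classes Copia vs Gypsy, global-only signal).
    """
    if kind == "terminal":
        m = class_motif("terminal-contrast", 30)
        plans = {
            "hAT": MotifPlan(five_prime=m, three_prime=reverse_complement(m)),
            "TcMar": MotifPlan(five_prime=reverse_complement(m), three_prime=m),
        }
    elif kind == "composition":
        plans = {
            "Copia": MotifPlan(bias_words=_bias_words("Copia"), bias_margin=REDUCED_L),
            "Gypsy": MotifPlan(bias_words=_bias_words("Gypsy"), bias_margin=REDUCED_L),
        }
    else:
        raise ValueError(f"unknown contrast kind {kind!r}")
    return SimulationSpec(
        class_counts={c: n_per_class for c in plans},
        plans=plans,
        length_range=(400, 800),
        mutation_rate=mutation_rate,
        seed=seed,
    )


def _bias_words(label: str):
    from .synthetic import _designated_words

    return _designated_words(label)


def _featurize_all(records, k: int, L: int):
    kmers = np.stack([featurize(r.seq, k=k, L=L).kmer for r in records])
    onehots = np.stack([featurize(r.seq, k=k, L=L).onehot for r in records])
    return kmers, onehots


def run_contrast(kind: str, seed: int, branches=("both", "local", "global"),
                 n_per_class: int = 200, epochs: int = 30,
                 batch_size: int = 64, patience: int = 5) -> dict[str, float]:
    """Train branch variants on one contrast; held-out MCC per branch.

    An 80/20 stratified split is made with `seed`; a further 15% of the
    training side serves as the validation set for early stopping
    (patience on validation loss, the default training procedure).  Each
    variant trains on the same splits and is scored by MCC on the
    held-out 20%.
    """
    spec = contrast_spec(kind, seed, n_per_class=n_per_class)
    tax = load_taxonomy()
    records, _ = simulate_dataset(spec, tax)
    train, test = stratified_split(records, tax, test_frac=0.20, seed=seed)
    subtrain, val = stratified_split(train, tax, test_frac=0.15, seed=seed + 7)
    k, L = REDUCED_K, REDUCED_L
    tr_km, tr_oh = _featurize_all(subtrain, k, L)
    va_km, va_oh = _featurize_all(val, k, L)
    te_km, te_oh = _featurize_all(test, k, L)
    tr_y = [r.label for r in subtrain]
    va_y = [r.label for r in val]
    te_y = [r.label for r in test]
    child_labels = sorted(spec.class_counts)
    out: dict[str, float] = {}
    for branch in branches:
        model = NodeClassifier("contrast", child_labels,
                               reduced_config(branch), seed=seed)
        model.fit(tr_km, tr_oh, tr_y, epochs=epochs, batch_size=batch_size,
                  seed=seed, validation=(va_km, va_oh, va_y), patience=patience)
        probs, _ = model.predict_proba((te_km, te_oh))
        pred = [child_labels[i] for i in probs.argmax(axis=1)]
        out[branch] = flat_metrics(te_y, pred, child_labels).mcc
    return out


def mini_taxonomy() -> Taxonomy:
    """Three-level tree: TE -> ClassI/ClassII -> four structurally distinct leaves."""
    return load_taxonomy({
        "TE": ["ClassI", "ClassII"],
        "ClassI": ["Gypsy", "L1"],
        "ClassII": ["hAT", "CACTA"],
    })


def run_hierarchical_experiment(seed: int, n_per_leaf: int = 100,
                                epochs: int = 10, batch_size: int = 64,
                                grid=THRESHOLD_GRID):
    """End-to-end: simulate, train all parent nodes, sweep thresholds.

    Returns ``(per_threshold, classifiers, tax)`` where per_threshold is
    a list of dicts ``{"threshold", "hP", "hR", "hF"}`` on held-out data.
    """
    tax = mini_taxonomy()
    plans = default_plans()
    spec = SimulationSpec(
        class_counts={leaf: n_per_leaf for leaf in ("Gypsy", "L1", "hAT", "CACTA")},
        plans=plans,
        length_range=(400, 800),
        mutation_rate=0.05,
        seed=seed,
    )
    records, _ = simulate_dataset(spec, tax)
    train, test = stratified_split(records, tax, test_frac=0.20, seed=seed)
    k, L = REDUCED_K, REDUCED_L
    datasets = build_node_datasets(train, tax)
    classifiers: dict[str, NodeClassifier] = {}
    for parent, ds in datasets.items():
        children = sorted(set(ds.child_tags))
        model = NodeClassifier(parent, children, reduced_config(), seed=seed)
        km, oh = _featurize_all(ds.records, k, L)
        model.fit(km, oh, ds.child_tags, epochs=epochs, batch_size=batch_size,
                  seed=seed, patience=None)
        classifiers[parent] = model
    test_fps = [featurize(r.seq, k=k, L=L) for r in test]
    true_paths = [tax.ancestors(r.label) for r in test]
    results = threshold_sweep(test_fps, classifiers, tax, grid)
    per_threshold = []
    for t in grid:
        rep = hier_metrics([p.labels for p in results[t]], true_paths, tax)
        per_threshold.append({"threshold": t, "hP": rep.hP, "hR": rep.hR, "hF": rep.hF})
    return per_threshold, classifiers, tax
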