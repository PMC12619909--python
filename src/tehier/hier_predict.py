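"""Top-down, threshold-stopped hierarchical prediction.

A query descends from the taxonomy root: at each parent node the
attached classifier scores the children, and the query proceeds to the
argmax child only while the maximum probability is at or above the
stopping threshold tau (a maximum strictly below tau terminates at the
current node — "nonmandatory leaf-node prediction", so a sequence may
legitimately stop at ClassI or LTR rather than being forced to a
superfamily).  Internal nodes with a single child are traversed without
a classifier; a missing classifier at a multi-child node halts the
descent with a flagged status.

Ties at the argmax descend into the lexicographically first child and
are logged, keeping traversal deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .hierarchy import Taxonomy

__all__ = ["PredictionPath", "predict_topdown", "threshold_sweep",
           "summarize_attention", "paths_to_frame", "DEFAULT_THRESHOLD",
           "THRESHOLD_GRID"]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.60
#: The standard evaluation grid: 0.50 to 0.95 in steps of 0.05.
THRESHOLD_GRID = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))


@dataclass
class PredictionPath:
    """Root-to-stop label path with per-descent confidence and attention."""

    labels: list[str]
    confidences: list[float] = field(default_factory=list)
    attention_trace: list[tuple[float, float]] = field(default_factory=list)
    stopped_at_leaf: bool = False
    model_missing: bool = False

    def __post_init__(self):
        if len(self.confidences) != len(self.labels) - 1:
            raise ValueError("need one confidence per descent (len(labels) - 1)")

    @property
    def stop_label(self) -> str:
        return self.labels[-1]


def _node_decision(node: str, classifiers, feature_pair):
    """Query the classifier at `node`; returns (child, maxp, alphas, probs)."""
    model = classifiers[node]
    probs, alphas = model.predict_proba(feature_pair)
    maxp = float(probs.max())
    tied = [c for c, p in zip(model.child_labels, probs) if p == maxp]
    if len(tied) > 1:
        logger.info("argmax tie at node %r among %r; taking %r",
                    node, tied, min(tied))
    return min(tied), maxp, (float(alphas[0]), float(alphas[1])), probs


def predict_topdown(feature_pair, classifiers: dict, tax: Taxonomy,
                    threshold: float = DEFAULT_THRESHOLD) -> PredictionPath:
    """Assign the deepest label whose descent stayed at or above `threshold`."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    node = tax.root
    labels = [node]
    confidences: list[float] = []
    trace: list[tuple[float, float]] = []
    missing = False
    while True:
        kids = tax.children.get(node, [])
        if not kids:
            break
        if len(kids) == 1:       # pass-through node: no classifier needed
            node = kids[0]
            labels.append(node)
            confidences.append(1.0)
            continue
        if node not in classifiers:
            logger.warning("no classifier for parent node %r; halting descent", node)
            missing = True
            break
        child, maxp, alphas, _ = _node_decision(node, classifiers, feature_pair)
        if maxp < threshold:
            break
        node = child
        labels.append(node)
        confidences.append(maxp)
        trace.append(alphas)
    return PredictionPath(
        labels=labels,
        confidences=confidences,
        attention_trace=trace,
        stopped_at_leaf=not tax.children.get(node) and not missing,
        model_missing=missing,
    )


def threshold_sweep(feature_pairs, classifiers: dict, tax: Taxonomy,
                    grid=THRESHOLD_GRID) -> dict[float, list[PredictionPath]]:
    """Predictions for every query at every threshold of an ascending grid.

    The greedy chain (argmax child per node) is threshold-independent, so
    it is computed once per query and truncated per threshold; the result
    is identical to running `predict_topdown` at each grid value.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    if any(not (0 < t <= 1) for t in grid) or grid != sorted(grid):
        raise ValueError("grid values must be ascending and in (0, 1]")
    results: dict[float, list[PredictionPath]] = {t: [] for t in grid}
    for fp in feature_pairs:
        full = predict_topdown(fp, classifiers, tax, threshold=min(grid))
        for t in grid:
            labels = [full.labels[0]]
            confidences: list[float] = []
            trace: list[tuple[float, float]] = []
            ti = 0
            for lab, conf in zip(full.labels[1:], full.confidences):
                is_pass_through = len(tax.children.get(labels[-1], [])) == 1
                if not is_pass_through and conf < t:
                    break
                labels.append(lab)
                confidences.append(conf)
                if not is_pass_through:
                    trace.append(full.attention_trace[ti])
                if not is_pass_through:
                    ti += 1
            stop = labels[-1]
            results[t].append(PredictionPath(
                labels=labels,
                confidences=confidences,
                attention_trace=trace,
                stopped_at_leaf=not tax.children.get(stop) and not full.model_missing,
                model_missing=full.model_missing and stop == full.labels[-1],
            ))
    return results


def summarize_attention(paths, grouping=None, tie_tol: float = 1e-6) -> pd.DataFrame:
    """Per-group proportions of CNN-dominant, RNN-dominant and balanced queries.

    A query's branch weights are averaged over its descents; a path with
    an empty attention trace counts as balanced.  `grouping` maps each
    path to a group key (callable or a parallel list); default: one
    group "all".  Groups that end up empty are omitted with a warning.
    """
    paths = list(paths)
    if grouping is None:
        keys = ["all"] * len(paths)
    elif callable(grouping):
        keys = [grouping(p) for p in paths]
    else:
        keys = list(grouping)
        if len(keys) != len(paths):
            raise ValueError("grouping list must parallel the paths")
    buckets: dict[str, list[str]] = {}
    for path, key in zip(paths, keys):
        if path.attention_trace:
            a_c = sum(a for a, _ in path.attention_trace) / len(path.attention_trace)
            a_r = sum(r for _, r in path.attention_trace) / len(path.attention_trace)
            if abs(a_c - a_r) <= tie_tol:
                kind = "equal"
            elif a_c > a_r:
                kind = "cnn_dominant"
            else:
                kind = "rnn_dominant"
        else:
            kind = "equal"
        buckets.setdefault(key, []).append(kind)
    rows = []
    for key in buckets:
        kinds = buckets[key]
        if not kinds:
            warnings.warn(f"attention summary group {key!r} is empty; omitted")
            continue
        n = len(kinds)
        rows.append({
            "group": key,
            "n": n,
            "cnn_dominant": kinds.count("cnn_dominant") / n,
            "rnn_dominant": kinds.count("rnn_dominant") / n,
            "equal": kinds.count("equal") / n,
        })
    return pd.DataFrame(rows)


def paths_to_frame(ids, paths, threshold: float) -> pd.DataFrame:
    """Predictions table: one row per query, columns per the TSV contract."""
    rows = []
    for rid, p in zip(ids, paths):
        rows.append({
            "sequence_id": rid,
            "predicted_path": "/".join(p.labels),
            "stop_level": len(p.labels) - 1,
            "confidence": ";".join(f"{c:.6f}" for c in p.confidences),
            "alpha_cnn": ";".join(f"{a:.6f}" for a, _ in p.attention_trace),
            "alpha_rnn": ";".join(f"{r:.6f}" for _, r in p.attention_trace),
            "threshold": threshold,
        })
    return pd.DataFrame(rows)
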