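import numpy as np
import pytest

from tehier.hierarchy import load_taxonomy


@pytest.fixture(scope="session")
def default_tax():
    return load_taxonomy()


def brute_force_kmer_counts(seq: str, k: int) -> np.ndarray:
    """Independent oracle: substring dictionary count of canonical k-mers."""
    digits = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros(4**k)
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if all(b in digits for b in window):
            idx = sum(digits[b] * 4 ** (k - 1 - j) for j, b in enumerate(window))
            counts[idx] += 1
    return counts


def brute_force_topdown(probs_by_node: dict, child_order: dict, tax, threshold: float):
    """Independent oracle for the stopping rule: explicit rule re-application.

    `probs_by_node` maps parent node -> probability list over
    `child_order[node]`.  Returns the root-first label path.
    """
    path = [tax.root]
    node = tax.root
    while True:
        kids = tax.children.get(node, [])
        if not kids:
            return path
        if len(kids) == 1:
            node = kids[0]
            path.append(node)
            continue
        if node not in probs_by_node:
            return path
        probs = probs_by_node[node]
        maxp = max(probs)
        if maxp < threshold:
            return path
        tied = [c for c, p in zip(child_order[node], probs) if p == maxp]
        node = min(tied)
        path.append(node)


@pytest.fixture(scope="session")
def contrast_results():
    """Held-out MCC per branch for both contrasts over three seeds.

    Trained once per session and shared between the model-property and
    acceptance tests (the trainings dominate suite runtime).
    """
    from tehier.experiments import run_contrast

    seeds = (101, 102, 103)
    results = {"terminal": [], "composition": []}
    for seed in seeds:
        for kind in results:
            results[kind].append(run_contrast(kind, seed))
    return results


@pytest.fixture(scope="session")
def hierarchical_sweep():
    """Threshold-sweep hP/hR/hF of the end-to-end mini-taxonomy pipeline."""
    from tehier.experiments import run_hierarchical_experiment

    per_threshold, classifiers, tax = run_hierarchical_experiment(seed=11)
    return per_threshold
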