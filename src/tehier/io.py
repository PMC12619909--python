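"""FASTA input/output, preprocessing filters, and dataset assembly.

Repeat-library sequences arrive as FASTA whose headers follow the
``ID|TE_type|Species_ID`` nomenclature.  Preprocessing applies the
standard repeat-library hygiene rules: drop sequences shorter than 80 bp,
drop sequences with more than 20% non-canonical nucleotides, and
deduplicate.  Labelled records are then split 90/10 stratified at the
leaf level and aggregated upward into one training set per parent node,
each record tagged with the child of that parent its label path descends
through.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .features import kmer_vector
from .hierarchy import Taxonomy

__all__ = [
    "SequenceRecord",
    "NodeDataset",
    "read_fasta",
    "write_fasta",
    "preprocess",
    "dedupe",
    "stratified_split",
    "build_node_datasets",
]

logger = logging.getLogger(__name__)

_CANONICAL = frozenset("ACGT")


@dataclass
class SequenceRecord:
    """One labelled nucleotide sequence.

    `label` is a taxonomy label (leaf or internal) or None when the
    header carried no recognisable annotation; `extra` preserves any
    header fields beyond the third verbatim.
    """

    id: str
    seq: str
    label: str | None = None
    species: str | None = None
    extra: str = ""

    def __post_init__(self):
        self.seq = self.seq.upper()
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    @property
    def header(self) -> str:
        parts = [self.id]
        if self.label is not None or self.species is not None:
            parts.append(self.label or "")
            parts.append(self.species or "")
        if self.extra:
            parts.append(self.extra)
        return "|".join(parts)

    def ambiguity_fraction(self) -> float:
        bad = sum(1 for b in self.seq if b not in _CANONICAL)
        return bad / len(self.seq)


def read_fasta(path: str) -> list[SequenceRecord]:
    """Parse FASTA into SequenceRecords, splitting headers on ``|``.

    Headers without pipe structure yield records with no label (a
    warning is logged).  Duplicate ids are refused.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        header = rec.description.split()[0] if rec.description else rec.id
        fields = header.split("|")
        rid = fields[0]
        if rid in seen:
            raise ValueError(f"duplicate sequence id {rid!r} in {path}")
        seen.add(rid)
        if len(fields) >= 3:
            label, species = fields[1] or None, fields[2] or None
            extra = "|".join(fields[3:])
        else:
            label = species = None
            extra = "|".join(fields[1:])
            logger.warning("header %r lacks ID|TE_type|Species_ID structure; no label", header)
        records.append(SequenceRecord(id=rid, seq=str(rec.seq), label=label,
                                      species=species, extra=extra))
    if not records:
        logger.warning("no records parsed from %s", path)
    return records


def write_fasta(records, path: str, width: int = 80) -> None:
    bio = [
        _BioRecord(Seq(r.seq), id=r.header, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def preprocess(records, min_len: int = 80, max_ambig: float = 0.20):
    """Apply the library hygiene filters.

    Returns ``(survivors, rejection_log)`` where the log is a list of
    ``(record_id, rule)`` pairs; rules are ``"min_len"``, ``"ambiguity"``
    and ``"duplicate"``.  Boundary semantics: exactly `min_len` bp is
    kept ("<80 bp" drops), exactly `max_ambig` ambiguity is kept
    (">20%" drops).
    """
    survivors: list[SequenceRecord] = []
    rejections: list[tuple[str, str]] = []
    stage: list[SequenceRecord] = []
    for rec in records:
        if len(rec.seq) < min_len:
            rejections.append((rec.id, "min_len"))
        elif rec.ambiguity_fraction() > max_ambig:
            rejections.append((rec.id, "ambiguity"))
        else:
            stage.append(rec)
    kept, dup_ids = _dedupe_exact(stage)
    rejections.extend((rid, "duplicate") for rid in dup_ids)
    for rid, rule in rejections:
        logger.info("dropped %s: %s", rid, rule)
    return kept, rejections


def _dedupe_exact(records):
    seen: dict[str, str] = {}
    kept, dropped = [], []
    for rec in records:
        if rec.seq in seen:
            dropped.append(rec.id)
        else:
            seen[rec.seq] = rec.id
            kept.append(rec)
    return kept, dropped


def dedupe(records, identity_threshold: float | None = None, k: int = 4):
    """Remove duplicate sequences.

    Default mode drops exact duplicates, keeping the first occurrence in
    input order.  With `identity_threshold` t in (0, 1], records are
    greedily clustered by cosine similarity of their k-mer vectors: a
    record joins the first existing cluster whose representative it
    matches at >= t, and each cluster keeps its longest member.
    """
    records = list(records)
    if identity_threshold is None:
        kept, _ = _dedupe_exact(records)
        return kept
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity_threshold must be in (0, 1]")
    reps: list[tuple[np.ndarray, SequenceRecord]] = []
    for rec in records:
        v = kmer_vector(rec.seq, k=k, normalize=False)
        norm = np.linalg.norm(v)
        v = v / norm if norm else v
        for i, (rv, best) in enumerate(reps):
            if float(v @ rv) >= identity_threshold:
                if len(rec.seq) > len(best.seq):
                    reps[i] = (rv, rec)
                break
        else:
            reps.append((v, rec))
    chosen = {id(r) for _, r in reps}
    return [r for r in records if id(r) in chosen]


def stratified_split(records, tax: Taxonomy, test_frac: float = 0.10, seed: int = 0):
    """Per-leaf 90/10 split preserving group proportions.

    Each leaf's records are shuffled with `seed` and the last
    ``round(n * test_frac)`` (at least 1 when n >= 2) go to the test set.
    """
    by_leaf: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        if rec.label is None:
            raise ValueError(f"record {rec.id!r} is unlabeled; cannot stratify")
        by_leaf.setdefault(tax.resolve(rec.label), []).append(rec)
    rng = np.random.default_rng(seed)
    train: list[SequenceRecord] = []
    test: list[SequenceRecord] = []
    for leaf in sorted(by_leaf):
        group = by_leaf[leaf]
        order = rng.permutation(len(group))
        n = len(group)
        n_test = int(np.floor(n * test_frac + 0.5))
        if n >= 2:
            n_test = max(n_test, 1)
        else:
            n_test = 0
        test_idx = set(order[:n_test].tolist())
        train.extend(group[i] for i in range(n) if i not in test_idx)
        test.extend(group[i] for i in range(n) if i in test_idx)
    return train, test


@dataclass
class NodeDataset:
    """Training material for one parent-node classifier."""

    parent_label: str
    records: list[SequenceRecord] = field(default_factory=list)
    child_tags: list[str] = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for tag in self.child_tags:
            counts[tag] = counts.get(tag, 0) + 1
        return counts


def build_node_datasets(records, tax: Taxonomy) -> dict[str, NodeDataset]:
    """Aggregate records upward into one dataset per parent node.

    A record labelled at node X contributes to every multi-child ancestor
    A strictly above X, tagged with the child of A on the path toward X.
    """
    datasets = {p: NodeDataset(parent_label=p) for p in tax.parent_nodes()}
    for rec in records:
        if rec.label is None:
            raise ValueError(f"record {rec.id!r} is unlabeled")
        path = tax.ancestors(rec.label)   # raises KeyError if unresolvable
        for parent, child in zip(path[:-1], path[1:]):
            if parent in datasets:
                datasets[parent].records.append(rec)
                datasets[parent].child_tags.append(child)
    return datasets
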