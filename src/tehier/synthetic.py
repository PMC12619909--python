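"""Synthetic repeat libraries with class-specific structural signal.

Real TE superfamilies differ in two complementary ways that the
classifier exploits: *terminal structure* (LTR-like elements carry a
direct repeat at both ends, DNA transposons carry reverse-complement
terminal inverted repeats, CACTA elements start 5'-CACTA and end
TAGTG-3', L1-like LINEs end in a poly(A) tail, tRNA-derived SINEs end in
the poly(T) Pol III terminator) and *global composition* (k-mer usage
biases).  The generator plants exactly these signals into random
background sequence, per a configurable motif plan, so every downstream
module can be exercised on data whose class signal is known by
construction.

Non-TE decoys for the three-way TE / coding / tandem-repeat task are
also provided: codon-structured coding-like sequences (start codon,
biased sense codons, stop codon) and tandem repeats (a short unit copied
to length with per-copy mutations).

Every operation is deterministic given its seed.  Defaults keep all
output compatible with the preprocessing filters (length >= 80, no
ambiguous bases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import reverse_complement
from .hierarchy import Taxonomy
from .io import SequenceRecord

__all__ = ["MotifPlan", "SimulationSpec", "simulate_te", "simulate_dataset",
           "simulate_non_te", "default_plans"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MotifPlan:
    """Structural recipe for one class.

    Exactly the planted elements are class-informative; everything else
    is background.  `bias_words` are overrepresented words planted at a
    density of `bias_density` expected occurrences of each word per kb
    of plantable interior — densities of a few per kb give a composition
    signature that is strong enough to learn at a few hundred training
    sequences yet still occupies under ~10% of the sequence.  Planting
    at least `bias_margin` bases away from the ends keeps composition
    bias a *global* signal.
    """

    dtr_len: int = 0                  # direct terminal repeat (LTR-like)
    tir_len: int = 0                  # inverted terminal repeat (TIR-like)
    five_prime: str = ""              # fixed 5' terminus (e.g. "CACTA")
    three_prime: str = ""             # fixed 3' terminus (e.g. "TAGTG")
    polya_len: int = 0                # 3' homopolymer A tail
    polyt_len: int = 0                # 3' homopolymer T tail
    bias_words: tuple[str, ...] = ()
    bias_density: float = 2.5         # expected occurrences / word / kb
    bias_margin: int = 0

    def terminal_footprint(self) -> int:
        left = max(self.dtr_len, self.tir_len, len(self.five_prime))
        right = max(self.dtr_len, self.tir_len, len(self.three_prime),
                    self.polya_len, self.polyt_len)
        return left + right


@dataclass(frozen=True)
class SimulationSpec:
    """Study design for one simulated library."""

    class_counts: dict[str, int]
    plans: dict[str, MotifPlan]
    length_range: tuple[int, int] = (400, 800)
    mutation_rate: float = 0.0        # substitutions on planted motifs
    species: str = "synthSp1"
    seed: int = 0

    def __post_init__(self):
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if self.length_range[0] < 80:
            raise ValueError("minimum length must be >= 80 (preprocessing-compatible)")
        if not (0 <= self.mutation_rate < 1):
            raise ValueError("mutation rate must lie in [0, 1)")


def _random_motif(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def class_motif(class_label: str, length: int = 30, salt: int = 0) -> str:
    """A fixed, class-specific motif derived deterministically from the name."""
    h = np.frombuffer(class_label.encode(), dtype=np.uint8).sum()
    rng = np.random.default_rng(100_003 * int(h) + salt)
    return _random_motif(rng, length)


def default_plans() -> dict[str, MotifPlan]:
    """Motif plans for the default-taxonomy leaves used in examples/tests."""
    plans: dict[str, MotifPlan] = {}
    for ltr in ("Copia", "Gypsy", "Bel-Pao", "ERV1", "ERV2", "ERV3"):
        plans[ltr] = MotifPlan(dtr_len=30,
                               bias_words=_designated_words(ltr))
    for tir in ("hAT", "TcMar", "MULE", "PIF", "Merlin", "P"):
        plans[tir] = MotifPlan(tir_len=30)
    plans["CACTA"] = MotifPlan(five_prime="CACTA", three_prime="TAGTG", tir_len=0)
    plans["L1"] = MotifPlan(polya_len=25, bias_words=_designated_words("L1"))
    plans["SINE2/tRNA"] = MotifPlan(polyt_len=20)
    for other in ("CR1", "RTE", "Rex1", "Jockey", "I",
                  "SINE1/7SL", "SINE3/5S", "ID", "Helitron", "Maverick"):
        plans[other] = MotifPlan(bias_words=_designated_words(other))
    return plans


def _designated_words(class_label: str, n: int = 8, width: int = 7) -> tuple[str, ...]:
    """n class-specific k-mers to overrepresent (deterministic per class)."""
    h = np.frombuffer(class_label.encode(), dtype=np.uint8).sum()
    rng = np.random.default_rng(900_001 * int(h))
    return tuple(_random_motif(rng, width) for _ in range(n))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    hits = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hits):
        options = [b for b in "ACGT" if b != chars[i]]
        chars[i] = options[rng.integers(3)]
    return "".join(chars)


def _background(rng: np.random.Generator, length: int,
                plan: MotifPlan) -> np.ndarray:
    """Random background with the plan's interior composition bias."""
    seq = rng.choice(_BASES, size=length)
    if plan.bias_words:
        w = len(plan.bias_words[0])
        lo = plan.bias_margin
        hi = length - plan.bias_margin - w
        if hi > lo:
            n_slots = hi - lo
            # expected bias_density plantings per word per kb of interior
            per_word_rate = plan.bias_density / 1000.0
            for word in plan.bias_words:
                n_plant = rng.binomial(n_slots, per_word_rate)
                starts = rng.integers(lo, hi, size=n_plant)
                for s in starts:
                    seq[s : s + w] = list(word)
    return seq


def simulate_te(class_label: str, spec: SimulationSpec, seed: int) -> SequenceRecord:
    """One labelled TE-like sequence following the class's motif plan."""
    if class_label not in spec.plans:
        raise KeyError(f"class {class_label!r} has no motif plan in the spec")
    plan = spec.plans[class_label]
    rng = np.random.default_rng(seed)
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    if plan.terminal_footprint() > length:
        raise ValueError(
            f"length {length} too short for the planted elements of {class_label!r}"
        )
    seq = _background(rng, length, plan)

    def plant(pos: int, motif: str) -> None:
        seq[pos : pos + len(motif)] = list(_mutate(motif, spec.mutation_rate, rng))

    if plan.dtr_len:
        motif = class_motif(class_label, plan.dtr_len)
        plant(0, motif)
        plant(length - plan.dtr_len, motif)
    if plan.tir_len:
        motif = class_motif(class_label, plan.tir_len)
        plant(0, motif)
        plant(length - plan.tir_len, reverse_complement(motif))
    if plan.five_prime:
        plant(0, plan.five_prime)
    if plan.polya_len:
        plant(length - plan.polya_len, "A" * plan.polya_len)
    if plan.polyt_len:
        plant(length - plan.polyt_len, "T" * plan.polyt_len)
    if plan.three_prime:
        plant(length - len(plan.three_prime), plan.three_prime)
    return SequenceRecord(
        id=f"sim{seed}",
        seq="".join(seq),
        label=class_label,
        species=spec.species,
    )


def simulate_dataset(spec: SimulationSpec, tax: Taxonomy | None = None):
    """A full labelled library: records plus a truth table.

    Record ids are ``SIM<running index>``; headers follow the
    ``ID|TE_type|Species_ID`` nomenclature via `SequenceRecord.header`.
    When a taxonomy is given, every class label must resolve in it.
    Returns ``(records, truth)`` with `truth` a DataFrame of
    ``id, leaf_label, species``.
    """
    if tax is not None:
        for label in spec.class_counts:
            tax.resolve(label)   # raises KeyError on absent labels
    seeds = np.random.SeedSequence(spec.seed).generate_state(
        sum(spec.class_counts.values())
    ) >> 1   # keep derived seeds below 2**31
    records: list[SequenceRecord] = []
    i = 0
    for label in spec.class_counts:          # insertion order: deterministic
        for _ in range(spec.class_counts[label]):
            rec = simulate_te(label, spec, int(seeds[i]))
            rec.id = f"SIM{i:06d}"
            records.append(rec)
            i += 1
    truth = pd.DataFrame(
        [{"id": r.id, "leaf_label": r.label, "species": r.species} for r in records]
    )
    return records, truth


_SENSE_CODONS = [a + b + c
                 for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in ("TAA", "TAG", "TGA")]
_STOP_CODONS = ("TAA", "TAG", "TGA")


def simulate_non_te(kind: str, spec: SimulationSpec, seed: int,
                    unit_len: int = 5) -> SequenceRecord:
    """A non-TE decoy sequence: ``"coding-like"`` or ``"tandem-repeat"``.

    Coding-like sequences are codon-structured: ATG, in-frame sense
    codons drawn from a biased codon table, then a stop codon; length is
    a multiple of three.  Tandem repeats copy a random `unit_len`-base
    unit to the target length, mutating each copy at the spec's rate.
    """
    rng = np.random.default_rng(seed)
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    if kind == "coding-like":
        n_codons = length // 3
        # biased codon usage: a random but seed-stable preference profile
        weights = rng.dirichlet(np.full(len(_SENSE_CODONS), 0.3))
        body = rng.choice(_SENSE_CODONS, size=max(n_codons - 2, 1), p=weights)
        seq = "ATG" + "".join(body) + _STOP_CODONS[rng.integers(3)]
        label = "CDS"
    elif kind == "tandem-repeat":
        if unit_len > length:
            raise ValueError(f"unit length {unit_len} exceeds target length {length}")
        unit = _random_motif(rng, unit_len)
        copies = [_mutate(unit, spec.mutation_rate, rng)
                  for _ in range(-(-length // unit_len))]
        seq = "".join(copies)[:length]
        label = "TR"
    else:
        raise ValueError(f"unknown non-TE kind {kind!r}")
    return SequenceRecord(id=f"sim{kind}{seed}", seq=seq, label=label,
                          species=spec.species)
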