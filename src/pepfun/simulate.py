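"""Synthetic multi-label peptide datasets with planted class motifs.

The generator emulates the statistical structure of the multi-functional
therapeutic peptide benchmark without requiring any download: lengths in
5-50, heavy class-prevalence imbalance, multi-label co-occurrence, and short
class-associated sequence motifs (the synthetic analogue of motifs such as
"AGK" that occur frequently in real functional peptides).

Label vectors are drawn as independent Bernoulli variables at the configured
prevalences, passed once through a Gibbs-style sweep applying pairwise
co-occurrence odds (identity matrix = independent), and rejection-resampled
so every record carries at least one label. Motifs are written over
background residues in place, so sequence-length statistics are independent
of the labels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .io import AMINO_ACIDS, LabelSpace, PeptideRecord, build_label_space

__all__ = [
    "MotifSpec",
    "SyntheticSpec",
    "sample_dataset",
    "count_kmers_by_class",
    "default_fixture_spec",
    "load_spec",
    "save_spec",
]


@dataclass
class MotifSpec:
    """Motifs planted into sequences positive (or, rarely, negative) for a class.

    plant_probability: chance that a positive-label sequence carries one motif.
    decoy_probability: chance that a negative-label sequence carries one anyway.
    """

    class_index: int
    motifs: list[str]
    plant_probability: float = 1.0
    decoy_probability: float = 0.0

    def __post_init__(self):
        if not self.motifs:
            raise ValueError("motifs must be non-empty")
        for m in self.motifs:
            if not (2 <= len(m) <= 5):
                raise ValueError(f"motif {m!r} length must be 2-5")
            if any(ch not in AMINO_ACIDS for ch in m):
                raise ValueError(f"motif {m!r} contains non-canonical residues")
        if not (0 <= self.decoy_probability <= self.plant_probability <= 1):
            raise ValueError("need 0 <= decoy_probability <= plant_probability <= 1")


@dataclass
class SyntheticSpec:
    """Full description of one synthetic benchmark draw."""

    n_samples: int
    label_space: LabelSpace
    prevalence: np.ndarray
    co_occurrence: np.ndarray | None = None
    length_range: tuple[int, int] = (5, 50)
    background_frequencies: np.ndarray | None = None
    motif_specs: list[MotifSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        M = self.label_space.size
        self.prevalence = np.asarray(self.prevalence, dtype=float)
        if self.prevalence.shape != (M,):
            raise ValueError(f"prevalence must have length {M}")
        if not ((self.prevalence > 0) & (self.prevalence <= 1)).all():
            raise ValueError("prevalence entries must lie in (0, 1]")
        if self.co_occurrence is None:
            self.co_occurrence = np.eye(M)
        self.co_occurrence = np.asarray(self.co_occurrence, dtype=float)
        if self.co_occurrence.shape != (M, M):
            raise ValueError("co_occurrence must be M x M")
        if not np.allclose(self.co_occurrence, self.co_occurrence.T):
            raise ValueError("co_occurrence must be symmetric")
        if not np.allclose(np.diag(self.co_occurrence), 1.0):
            raise ValueError("co_occurrence diagonal must be 1")
        lo, hi = self.length_range
        if not (5 <= lo <= hi <= 50):
            raise ValueError("length_range must lie within [5, 50]")
        if self.background_frequencies is None:
            self.background_frequencies = np.full(20, 1 / 20)
        self.background_frequencies = np.asarray(self.background_frequencies, dtype=float)
        if self.background_frequencies.shape != (20,):
            raise ValueError("background_frequencies must have length 20")
        if (self.background_frequencies < 0).any():
            raise ValueError("background_frequencies must be nonnegative")
        if abs(self.background_frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("background_frequencies must sum to 1")
        for ms in self.motif_specs:
            if not (0 <= ms.class_index < M):
                raise ValueError(f"motif class_index {ms.class_index} out of range")
            if max(len(m) for m in ms.motifs) > lo:
                raise ValueError("motif longer than minimum sequence length")


def default_fixture_spec(seed: int = 7, n_samples: int = 2000) -> SyntheticSpec:
    """The shipped CPU-scale benchmark: 6 classes, 16:1 imbalance, planted motifs.

    Prevalences [0.40, 0.30, 0.20, 0.10, 0.05, 0.025], one length-3 motif per
    class planted with probability 0.9 (decoy rate 0.02), lengths 10-50.
    """
    label_space = build_label_space([f"C{i}" for i in range(6)])
    motifs = ["AGK", "LKK", "WWC", "HRD", "YPF", "MVT"]
    return SyntheticSpec(
        n_samples=n_samples,
        label_space=label_space,
        prevalence=np.array([0.40, 0.30, 0.20, 0.10, 0.05, 0.025]),
        length_range=(10, 50),
        motif_specs=[
            MotifSpec(class_index=i, motifs=[m], plant_probability=0.9,
                      decoy_probability=0.02)
            for i, m in enumerate(motifs)
        ],
        seed=seed,
    )


def _sample_labels(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    """One label vector: independent draws, one coupling sweep, reject all-zero."""
    M = spec.label_space.size
    prev = spec.prevalence
    base_odds = prev / np.maximum(1 - prev, 1e-12)
    coupled = not np.allclose(spec.co_occurrence, np.eye(M))
    while True:
        y = (rng.random(M) < prev).astype(np.int8)
        if coupled:
            for i in range(M):
                others = np.delete(np.arange(M), i)
                odds = base_odds[i] * np.prod(spec.co_occurrence[i, others] ** y[others])
                y[i] = 1 if rng.random() < odds / (1 + odds) else 0
        if y.any():
            return y


def sample_dataset(spec: SyntheticSpec) -> list[PeptideRecord]:
    """Draw ``spec.n_samples`` peptide records, reproducibly from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    by_class: dict[int, MotifSpec] = {ms.class_index: ms for ms in spec.motif_specs}
    records = []
    for idx in range(spec.n_samples):
        y = _sample_labels(rng, spec)
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(list(AMINO_ACIDS), size=length,
                              p=spec.background_frequencies))
        for ci, ms in by_class.items():
            p_plant = ms.plant_probability if y[ci] else ms.decoy_probability
            if rng.random() < p_plant:
                motif = ms.motifs[int(rng.integers(len(ms.motifs)))]
                start = int(rng.integers(0, length - len(motif) + 1))
                seq[start:start + len(motif)] = list(motif)
        rec = PeptideRecord(id=f"syn{idx:05d}", sequence="".join(seq), labels=y)
        rec.validate(spec.label_space, min_len=lo, max_len=hi)
        records.append(rec)
    return records


def count_kmers_by_class(records: Sequence[PeptideRecord], k: int,
                         class_index: int) -> dict[str, int]:
    """Counts of all length-``k`` substrings over records positive for a class."""
    if not (2 <= k <= 5):
        raise ValueError("k must be in 2..5")
    counts: Counter[str] = Counter()
    for rec in records:
        if not rec.labels[class_index]:
            continue
        if len(rec.sequence) < k:
            raise ValueError(
                f"k={k} larger than sequence {rec.id!r} of length {len(rec.sequence)}")
        for i in range(len(rec.sequence) - k + 1):
            counts[rec.sequence[i:i + k]] += 1
    return dict(counts)


# ---------------------------------------------------------------------------
# spec (de)serialization


def save_spec(spec: SyntheticSpec, path) -> None:
    doc = {
        "n_samples": spec.n_samples,
        "classes": list(spec.label_space.names),
        "prevalence": [float(p) for p in spec.prevalence],
        "co_occurrence": np.asarray(spec.co_occurrence).tolist(),
        "length_range": list(spec.length_range),
        "background_frequencies": [float(f) for f in spec.background_frequencies],
        "motifs": [
            {"class_index": ms.class_index, "motifs": ms.motifs,
             "plant_probability": ms.plant_probability,
             "decoy_probability": ms.decoy_probability}
            for ms in spec.motif_specs
        ],
        "seed": spec.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_spec(path) -> SyntheticSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SyntheticSpec(
        n_samples=int(doc["n_samples"]),
        label_space=build_label_space(doc["classes"]),
        prevalence=np.asarray(doc["prevalence"], dtype=float),
        co_occurrence=np.asarray(doc["co_occurrence"], dtype=float)
        if doc.get("co_occurrence") is not None else None,
        length_range=tuple(doc.get("length_range", (5, 50))),
        background_frequencies=np.asarray(doc["background_frequencies"], dtype=float)
        if doc.get("background_frequencies") is not None else None,
        motif_specs=[
            MotifSpec(class_index=m["class_index"], motifs=list(m["motifs"]),
                      plant_probability=float(m.get("plant_probability", 1.0)),
                      decoy_probability=float(m.get("decoy_probability", 0.0)))
            for m in doc.get("motifs", [])
        ],
        seed=int(doc.get("seed", 0)),
    )
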