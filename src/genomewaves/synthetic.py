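"""Seeded random binary and nucleotide sequence generators.

These provide the random baselines: Bernoulli(p) binary strings at
stated one-densities (50/50 and 70/30 are the canonical comparison
cases) and i.i.d. nucleotide strings with per-base weights. The
``omicron-like`` preset uses the rounded per-base percentages of a
published SARS-CoV-2 Omicron census (A 30%, C 18%, G 20%, T 32%,
N = 29613) so end-to-end runs resemble a real genome in composition
without requiring any download.

All draws come from numpy's default PCG64 generator with an explicit
seed, so identical specs give bitwise-identical output across runs and
platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .sequence_io import BASES, NucleotideSequence

__all__ = [
    "RandomSpec",
    "OMICRON_LIKE_WEIGHTS",
    "OMICRON_LIKE_LENGTH",
    "random_binary",
    "random_nucleotides",
    "write_binary_tsv",
    "write_fasta",
    "write_manifest",
]

# Rounded per-base one-densities of the reference Omicron census.
OMICRON_LIKE_WEIGHTS: dict[str, float] = {"A": 0.30, "C": 0.18, "G": 0.20, "T": 0.32}
OMICRON_LIKE_LENGTH = 29613


@dataclass(frozen=True)
class RandomSpec:
    """Parameters of one random draw.

    Exactly one of ``p_one`` (binary mode) or ``weights`` (nucleotide
    mode, per-base probabilities in A, C, G, T order) must be given.
    """

    length: int
    seed: int
    p_one: float | None = None
    weights: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if (self.p_one is None) == (self.weights is None):
            raise ValueError("give exactly one of p_one or weights")
        if self.p_one is not None and not 0.0 <= self.p_one <= 1.0:
            raise ValueError(f"p_one must lie in [0, 1], got {self.p_one}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != 4 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
                raise ValueError("weights must be 4 nonnegative values summing to 1")


def random_binary(spec: RandomSpec) -> np.ndarray:
    """Independent Bernoulli(p_one) draws as an int8 (0,1) vector."""
    if spec.p_one is None:
        raise ValueError("spec has no p_one; use random_nucleotides for weights")
    rng = np.random.default_rng(spec.seed)
    return (rng.random(spec.length) < spec.p_one).astype(np.int8)


def random_nucleotides(spec: RandomSpec, seq_id: str = "random") -> NucleotideSequence:
    """I.i.d. nucleotide string over {A,C,G,T} with the given weights."""
    if spec.weights is None:
        raise ValueError("spec has no weights; use random_binary for p_one")
    rng = np.random.default_rng(spec.seed)
    symbols = "".join(rng.choice(list(BASES), size=spec.length, p=list(spec.weights)))
    return NucleotideSequence(id=seq_id, symbols=symbols)


def write_binary_tsv(x: np.ndarray, path: str | Path) -> None:
    """Single-column TSV of a (0,1) vector (header ``X``)."""
    with open(path, "w") as fh:
        fh.write("X\n")
        fh.writelines(f"{int(v)}\n" for v in x)


def write_fasta(seq: NucleotideSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq.id}\n")
        for i in range(0, seq.length, width):
            fh.write(seq.symbols[i : i + width] + "\n")


def write_manifest(spec: RandomSpec, path: str | Path, **extra: object) -> None:
    """JSON record of the spec and seed so every draw is reproducible."""
    payload = {**asdict(spec), "generator": "numpy PCG64 (default_rng)", **extra}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
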