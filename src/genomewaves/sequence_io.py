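"""Reading, canonicalizing and binarizing nucleotide sequences.

A nucleotide sequence over {A, C, G, T} is mapped onto four binary
*projections*: for each base alpha, the indicator vector ``x`` with
``x[k] = 1`` exactly where position k carries alpha. RNA input (U) is
folded onto the T channel at canonicalization so a single code path
serves DNA and RNA. Characters outside {A, C, G, T} (IUPAC ambiguity
codes such as N, R, Y) are retained in the symbol string but score 0 in
all four projections; their count is tracked and a warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO

BASES = ("A", "C", "G", "T")

__all__ = [
    "BASES",
    "NucleotideSequence",
    "BinaryProjection",
    "BaseCounts",
    "canonicalize",
    "read_fasta",
    "project",
    "base_counts",
    "projection_table",
    "write_projection_tsv",
]


class AmbiguityWarning(UserWarning):
    """Raised when a sequence contains non-ACGT symbols."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A canonicalized nucleotide sequence with an identifier.

    ``symbols`` is uppercase with U already folded to T; any remaining
    non-ACGT characters are ambiguity placeholders.
    """

    id: str
    symbols: str
    n_ambiguous: int = 0

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class BinaryProjection:
    """The (0,1) indicator vector of one base along a sequence."""

    base: str
    x: np.ndarray = field(repr=False)
    n_zero: int
    n_one: int

    def __post_init__(self) -> None:
        if self.n_zero + self.n_one != self.x.size:
            raise ValueError("zero/one counts do not partition the sequence")


class BaseCounts(NamedTuple):
    n_zero: int
    n_one: int
    fraction_one: float
    percent_one: int  # rounded to whole percent, as reported


def canonicalize(raw: str) -> tuple[str, int]:
    """Uppercase, fold U onto T, and count ambiguity placeholders.

    Returns the canonical symbol string and the number of non-ACGT
    characters retained in it. Whitespace is stripped. Empty input is
    an error.
    """
    symbols = "".join(raw.split()).upper().replace("U", "T")
    if not symbols:
        raise ValueError("empty sequence")
    n_ambiguous = sum(1 for c in symbols if c not in BASES)
    if n_ambiguous:
        warnings.warn(
            f"{n_ambiguous} non-ACGT symbol(s) retained as ambiguity "
            "placeholders; they score 0 in every projection",
            AmbiguityWarning,
            stacklevel=2,
        )
    return symbols, n_ambiguous


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a FASTA file into canonicalized sequences, in file order.

    Multi-line records are concatenated. Raises FileNotFoundError for a
    missing file, ValueError for a file without records or a record
    with an empty sequence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        symbols, n_amb = canonicalize(str(rec.seq))
        records.append(NucleotideSequence(id=rec.id, symbols=symbols, n_ambiguous=n_amb))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def project(seq: NucleotideSequence, base: str) -> BinaryProjection:
    """Indicator vector for one base: x[k] = 1 iff symbol k equals base.

    Ambiguity placeholders score 0 in all four projections, so the four
    vectors sum positionwise to at most 1 (exactly 1 when the sequence
    is pure ACGT).
    """
    if base not in BASES:
        raise ValueError(f"base must be one of {BASES}, got {base!r}")
    arr = np.frombuffer(seq.symbols.encode("ascii"), dtype=np.uint8)
    x = (arr == ord(base)).astype(np.int8)
    n_one = int(x.sum())
    return BinaryProjection(base=base, x=x, n_zero=seq.length - n_one, n_one=n_one)


def base_counts(proj: BinaryProjection) -> BaseCounts:
    """Zero/one census of a projection, with the ones-fraction.

    The percentage is rounded to a whole percent, matching how such
    censuses are conventionally reported.
    """
    n = proj.x.size
    frac = proj.n_one / n
    return BaseCounts(proj.n_zero, proj.n_one, frac, round(100 * frac))


def projection_table(seq: NucleotideSequence) -> pd.DataFrame:
    """All four projections as a table with 1-based positions."""
    cols: dict[str, object] = {
        "position": np.arange(1, seq.length + 1),
        "symbol": list(seq.symbols),
    }
    for b in BASES:
        cols[f"X_{b}"] = project(seq, b).x
    return pd.DataFrame(cols)


def write_projection_tsv(seq: NucleotideSequence, path: str | Path) -> None:
    projection_table(seq).to_csv(path, sep="\t", index=False)
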