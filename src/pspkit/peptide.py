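"""Peptide data model, FASTA/TSV I/O and molecular-mass arithmetic.

Everything downstream — cleavage rules, the digestion engine, anchor
classification, ORF clustering — operates on :class:`Peptide`, an
identified chain of the 20 standard one-letter amino acid codes.
Ambiguity codes (B, J, X, Z) and the rare translated residues (U, O) are
rejected: substrate-specificity rules are defined only over the standard
alphabet, and an ambiguous residue would make a cleavage decision
undefined rather than merely uncertain.
"""

from __future__ import annotations

import io
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard one-letter amino acid codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Average residue (monomer) masses in daltons, i.e. the amino acid mass
#: minus one water. Summing residue masses and adding one water gives the
#: average molecular mass of the peptide.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: Mass of one water molecule (Da), added once per chain.
WATER_MASS = 18.02


class InvalidResidueError(ValueError):
    """A sequence contains a character outside the standard alphabet."""

    def __init__(self, record_id: str, position: int, char: str):
        self.record_id = record_id
        self.position = position  # 1-based
        self.char = char
        super().__init__(
            f"invalid residue {char!r} in record {record_id!r} at position {position}"
        )


@dataclass(frozen=True)
class ResidueMassTable:
    """Average residue masses (Da) plus the water mass added per chain."""

    masses: dict[str, float] = field(
        default_factory=lambda: dict(AVERAGE_RESIDUE_MASS)
    )
    water: float = WATER_MASS

    def __post_init__(self) -> None:
        missing = STANDARD_RESIDUES - set(self.masses)
        if missing:
            raise ValueError(f"mass table missing residues: {sorted(missing)}")
        if any(m <= 0 for m in self.masses.values()) or self.water <= 0:
            raise ValueError("all masses must be strictly positive")


DEFAULT_MASS_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class Peptide:
    """An identified amino acid sequence (uppercase, standard alphabet).

    An empty sequence is permitted at construction (the degenerate case
    for mass arithmetic) but is rejected by all operational entry points
    such as :func:`parse_fasta` and the digestion engine.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        for i, ch in enumerate(self.seq, start=1):
            if ch not in STANDARD_RESIDUES:
                raise InvalidResidueError(self.id, i, ch)

    def __len__(self) -> int:
        return len(self.seq)

    def composition(self) -> Counter:
        return Counter(self.seq)

    def fraction(self, residue: str) -> float:
        """Fraction of the chain made up of ``residue`` (0.0 if empty)."""
        if not self.seq:
            return 0.0
        return self.seq.count(residue) / len(self.seq)


def parse_fasta(stream: TextIO | str) -> list[Peptide]:
    """Read peptides from FASTA text or a file-like handle.

    Records are returned in file order, sequences uppercased. A record
    with an empty sequence or a non-standard residue raises, naming the
    record and the 1-based position of the offending character.
    """
    handle = io.StringIO(stream) if isinstance(stream, str) else stream
    peptides: list[Peptide] = []
    for rec in SeqIO.parse(handle, "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence in FASTA record {rec.id!r}")
        peptides.append(Peptide(rec.id, seq))
    if not peptides:
        raise ValueError("no FASTA records found")
    return peptides


def read_fasta(path: str) -> list[Peptide]:
    with open(path) as fh:
        return parse_fasta(fh)


def write_fasta(peptides: Iterable[Peptide], stream: TextIO | str) -> None:
    """Write peptides as FASTA, wrapped at 60 columns."""
    records = [SeqRecord(Seq(p.seq), id=p.id, description="") for p in peptides]
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        SeqIO.write(records, stream, "fasta")


def average_mass(p: Peptide, table: ResidueMassTable = DEFAULT_MASS_TABLE) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water.

    Additive up to water: mass(a + b) == mass(a) + mass(b) - water.
    The empty chain returns the water mass alone.
    """
    return sum(table.masses[ch] for ch in p.seq) + table.water


_REPEAT_RE = re.compile(r"\(([A-Z]+)\)_(\d+)_?")


def expand_repeats(notation: str) -> str:
    """Expand ``(MOTIF)_n_`` repeat notation into a plain sequence.

    ``"FLQP(PQQ)_2_PY"`` -> ``"FLQPPQQPQQPY"``. Sequences without repeat
    groups pass through unchanged.
    """
    return _REPEAT_RE.sub(lambda m: m.group(1) * int(m.group(2)), notation)


def peptide_report(peptides: Iterable[Peptide],
                   table: ResidueMassTable = DEFAULT_MASS_TABLE) -> pd.DataFrame:
    """Per-peptide summary table: id, length, average mass, %Q, %P."""
    rows = [
        {
            "id": p.id,
            "length": len(p),
            "mass_da": round(average_mass(p, table), 2),
            "pct_Q": round(100.0 * p.fraction("Q"), 1),
            "pct_P": round(100.0 * p.fraction("P"), 1),
        }
        for p in peptides
    ]
    return pd.DataFrame(rows, columns=["id", "length", "mass_da", "pct_Q", "pct_P"])
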