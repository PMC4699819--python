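"""Sequence records, FASTA I/O and charge-sequence statistics.

Charge conventions: lysine and arginine carry +1, aspartate and glutamate
carry -1, histidine is neutral, and the chain termini are excluded from the
sequence net charge (termini enter only the simulator's explicit terminal
charge sites).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .scales import STANDARD_AA

__all__ = [
    "SequenceRecord",
    "ChargeStats",
    "read_fasta",
    "write_fasta",
    "net_charge",
    "net_adjacent_charge",
    "charge_bias",
    "charge_stats",
]

POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence in one-letter code."""

    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        for pos, code in enumerate(self.residues):
            if code not in STANDARD_AA:
                raise ValueError(
                    f"non-standard residue {code!r} at position {pos} of {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n(self) -> int:
        return len(self.residues)


def read_fasta(path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [
        _BioSeqRecord(Seq(rec.residues), id=rec.id, description="")
        for rec in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def _residues(sequence) -> str:
    return getattr(sequence, "residues", sequence)


def net_charge(sequence) -> int:
    """Signed sequence net charge: (#K + #R) - (#D + #E)."""
    res = _residues(sequence)
    return sum(c in POSITIVE for c in res) - sum(c in NEGATIVE for c in res)


def net_adjacent_charge(sequence) -> int:
    """Net number of like-charged residues with a like-charged neighbour.

    Counts D/E residues having a D or E immediately before or after in
    sequence, counts K/R residues having a K or R neighbour the same way,
    and returns the absolute difference of the two counts.
    """
    res = _residues(sequence)

    def adjacent(group: frozenset) -> int:
        total = 0
        for i, c in enumerate(res):
            if c not in group:
                continue
            prev_in = i > 0 and res[i - 1] in group
            next_in = i < len(res) - 1 and res[i + 1] in group
            if prev_in or next_in:
                total += 1
        return total

    return abs(adjacent(POSITIVE) - adjacent(NEGATIVE))


def charge_bias(sequence) -> float | None:
    """Ratio of the more abundant charge type to the less abundant one.

    Negative count is #D + #E, positive is #K + #R; whichever ratio exceeds 1
    is reported (1.0 when equal).  ``None`` when either type is absent, since
    the ratio is then undefined rather than infinite.
    """
    res = _residues(sequence)
    n_neg = sum(c in NEGATIVE for c in res)
    n_pos = sum(c in POSITIVE for c in res)
    if n_neg == 0 or n_pos == 0:
        return None
    return max(n_neg, n_pos) / min(n_neg, n_pos)


@dataclass(frozen=True)
class ChargeStats:
    """Charge-sequence statistics of one protein.

    ``ncd`` is the net charge density |Q| / (random-coil Rh), the length
    normalisation used when correlating prediction error with charge;
    ``nacd`` normalises the net adjacent charge the same way.
    """

    net_charge: int
    abs_net_charge: int
    ncd: float
    net_adjacent_charge: int
    nacd: float
    charge_bias: float | None


def charge_stats(sequence, random_coil_rh: float) -> ChargeStats:
    """All charge statistics of a sequence, normalised by its random-coil Rh."""
    if random_coil_rh <= 0:
        raise ValueError("random_coil_rh must be > 0")
    q = net_charge(sequence)
    nadj = net_adjacent_charge(sequence)
    return ChargeStats(
        net_charge=q,
        abs_net_charge=abs(q),
        ncd=abs(q) / random_coil_rh,
        net_adjacent_charge=nadj,
        nacd=nadj / random_coil_rh,
        charge_bias=charge_bias(sequence),
    )
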