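"""Sequence domain types, FASTA I/O and elementary sequence operations.

Sequences are stored uppercase over the IUPAC DNA alphabet. FASTA parsing
and writing go through Biopython; translation and reverse complementation
use the standard nuclear genetic code and IUPAC complement tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import molecular_weight as _bio_molecular_weight

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Base sets encoded by each IUPAC DNA symbol.
IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

class FastaParseError(ValueError):
    """Raised for malformed FASTA input (bad alphabet, duplicate ids)."""


class TranslationError(ValueError):
    """Raised when a CDS cannot be translated under the requested rules."""


def _validate_residues(residues: str, seq_id: str) -> None:
    for offset, base in enumerate(residues):
        if base not in IUPAC_DNA:
            raise FastaParseError(
                f"record {seq_id!r}: non-IUPAC character {base!r} at offset {offset}"
            )


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified DNA sequence over the IUPAC alphabet, stored uppercase."""

    id: str
    residues: str
    description: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        _validate_residues(self.residues, self.id)

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int, *, id: Optional[str] = None) -> "NucleotideSequence":
        return NucleotideSequence(id or f"{self.id}:{start}-{end}", self.residues[start:end])


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20 one-letter codes (no stop symbol)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"protein {self.id!r}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: Union[str, Path]) -> List[NucleotideSequence]:
    """Read a FASTA file into an ordered list of :class:`NucleotideSequence`.

    Wrapped lines are concatenated, residues uppercased. Raises
    :class:`FileNotFoundError` for a missing file and
    :class:`FastaParseError` for non-IUPAC characters or duplicate ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: List[NucleotideSequence] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() or None
        records.append(NucleotideSequence(rec.id, str(rec.seq), desc))
    return records


def write_fasta(seqs: Iterable[NucleotideSequence], path: Union[str, Path],
                width: int = 70) -> None:
    """Write sequences as FASTA, wrapping residue lines at ``width`` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for seq in seqs:
            header = seq.id if not seq.description else f"{seq.id} {seq.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i:i + width] + "\n")


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """IUPAC-aware reverse complement; an involution on valid sequences."""
    return NucleotideSequence(seq.id, str(Seq(seq.residues).reverse_complement()),
                              seq.description)


def translate_cds(seq: NucleotideSequence, require_stop: bool = True,
                  strict: bool = True) -> ProteinSequence:
    """Translate a complete CDS with the standard nuclear code.

    The terminal stop codon is consumed and excluded from the protein, so a
    complete CDS of length L yields a protein of L/3 - 1 residues. In strict
    mode the CDS must begin with ATG and contain no internal stop codon.

    Parameters
    ----------
    require_stop:
        Demand a terminal stop codon (default). With ``False`` a stop-less
        open reading frame translates to L/3 residues.
    strict:
        Enforce an ATG start and reject internal stops (default).
    """
    n = len(seq)
    if n == 0 or n % 3 != 0:
        raise TranslationError(f"CDS {seq.id!r}: length {n} is not a positive multiple of 3")
    if strict and not seq.residues.startswith("ATG"):
        raise TranslationError(f"CDS {seq.id!r}: does not begin with ATG")
    aa = str(Seq(seq.residues).translate(table=1))
    has_stop = aa.endswith("*")
    if require_stop and not has_stop:
        raise TranslationError(f"CDS {seq.id!r}: missing terminal stop codon")
    body = aa[:-1] if has_stop else aa
    if "*" in body:
        if strict:
            raise TranslationError(
                f"CDS {seq.id!r}: internal stop codon at residue {body.index('*')}"
            )
        body = body  # non-strict: keep frame, report up to first internal stop
        body = body.split("*")[0]
    return ProteinSequence(seq.id, body)


def protein_weight_kda(protein: ProteinSequence) -> float:
    """Average molecular weight of the protein in kilodaltons."""
    return _bio_molecular_weight(protein.residues, seq_type="protein") / 1000.0
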