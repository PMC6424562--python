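"""Sequence primitives shared by every stage of the 3Cs toolkit.

DNA alphabet handling, IUPAC ambiguity semantics, reverse complement,
melting temperature, and FASTA/FASTQ streaming IO (gzip transparent by
filename suffix). Oligos are DNA only: lower case is upper-cased on
ingestion, ``U`` is rejected.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import MeltingTemp

DNA_ALPHABET = frozenset("ACGTN")

#: IUPAC ambiguity codes mapped to the set of concrete bases each denotes.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse lookup: set of bases -> IUPAC code.
IUPAC_FROM_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_EXPANSION.items()}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


class AlphabetError(ValueError):
    """A sequence contains characters outside the declared alphabet."""


class ParseError(ValueError):
    """A FASTA/FASTQ record could not be parsed."""


def clean_sequence(bases: str, alphabet: frozenset[str] = DNA_ALPHABET) -> str:
    """Upper-case ``bases`` and validate against ``alphabet``.

    Raises
    ------
    AlphabetError
        If any character is outside ``alphabet`` (``U`` is always rejected:
        this toolkit designs DNA oligonucleotides).
    """
    up = bases.upper()
    bad = set(up) - alphabet
    if bad:
        raise AlphabetError(
            f"invalid character(s) {sorted(bad)} for alphabet {''.join(sorted(alphabet))}"
        )
    return up


def degeneracy(code: str) -> int:
    """Number of concrete bases an IUPAC code denotes (1-4)."""
    try:
        return len(IUPAC_EXPANSION[code.upper()])
    except KeyError:
        raise AlphabetError(f"{code!r} is not an IUPAC nucleotide code") from None


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement, reversed. IUPAC codes map to their complements
    (N stays N, R<->Y, ...)."""
    up = seq.upper()
    bad = set(up) - set(IUPAC_EXPANSION)
    if bad:
        raise AlphabetError(f"cannot complement non-nucleotide character(s) {sorted(bad)}")
    return up.translate(_COMPLEMENT)[::-1]


def tm_wallace(seq: str) -> float:
    """Wallace-rule melting temperature in deg C: ``2*(A+T) + 4*(G+C)``.

    The rule of thumb used for short annealing arms; invariant under
    reverse complement.
    """
    up = clean_sequence(seq, frozenset("ACGT"))
    if not up:
        raise ValueError("empty sequence has no melting temperature")
    at = up.count("A") + up.count("T")
    gc = up.count("G") + up.count("C")
    return 2.0 * at + 4.0 * gc


def tm_nearest_neighbor(seq: str) -> float:
    """Nearest-neighbor melting temperature in deg C (SantaLucia 1997
    parameter set, 50 mM Na+, 25 nM oligo; Biopython defaults)."""
    up = clean_sequence(seq, frozenset("ACGT"))
    if len(up) < 2:
        raise ValueError("nearest-neighbor Tm needs length >= 2")
    return float(MeltingTemp.Tm_NN(Seq(up)))


def melting_temperature(seq: str, method: str = "wallace") -> float:
    """Melting temperature in deg C by ``wallace`` (default) or
    ``nearest_neighbor``."""
    if method == "wallace":
        return tm_wallace(seq)
    if method == "nearest_neighbor":
        return tm_nearest_neighbor(seq)
    raise ValueError(f"unknown Tm method {method!r}")


@dataclass(frozen=True)
class FastqRecord:
    """One FASTQ record; quality is carried verbatim and never interpreted."""

    id: str
    sequence: str
    quality: str = field(repr=False, default="")

    def __post_init__(self) -> None:
        if self.quality and len(self.quality) != len(self.sequence):
            raise ParseError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(id, sequence)`` from a (possibly gzipped) FASTA file.

    Sequences are upper-cased and validated over {A,C,G,T,N} plus IUPAC
    ambiguity codes (degenerate patterns are legitimate FASTA payloads here).
    """
    with _open_text(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fasta")):
            seq = str(rec.seq).upper()
            bad = set(seq) - set(IUPAC_EXPANSION)
            if bad:
                raise ParseError(f"record {i} ({rec.id}): invalid character(s) {sorted(bad)}")
            yield rec.id, seq


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Yield :class:`FastqRecord` from a (possibly gzipped) Sanger FASTQ file."""
    with _open_text(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fastq")):
            quality = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            try:
                yield FastqRecord(rec.id, str(rec.seq).upper(), quality)
            except ParseError as exc:
                raise ParseError(f"record {i}: {exc}") from None


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> int:
    """Write ``(id, sequence)`` pairs as FASTA; returns the record count."""
    n = 0
    with _open_text(path, "wt") as handle:
        for name, seq in records:
            SeqIO.write(SeqRecord(Seq(seq), id=name, description=""), handle, "fasta")
            n += 1
    return n


def write_fastq(path: str | Path, records: Iterable[FastqRecord]) -> int:
    """Write :class:`FastqRecord` s as Sanger FASTQ; returns the record count."""
    n = 0
    with _open_text(path, "wt") as handle:
        for rec in records:
            qual = rec.quality or "I" * len(rec.sequence)
            handle.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n
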