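"""Degenerate (IUPAC) gRNA libraries: diversity, matching, PAM-constrained
genome target-site scanning with mismatches, and screening-scale arithmetic.

A partially randomized library is written as an IUPAC string; its diversity
is the exact product of per-position degeneracies. Target sites are found by
a brute-force scan of both genome strands: a genome base *mismatches* a
pattern position iff it lies outside that position's allowed set (for a
concrete guide this is plain Hamming distance). The PAM is always matched
exactly against its own IUPAC pattern, immediately 3' of the protospacer.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator

import numpy as np

from .seqcore import IUPAC_EXPANSION, AlphabetError, reverse_complement

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i


@dataclass(frozen=True)
class DegeneratePattern:
    """An IUPAC string with derived diversity and a compiled matcher."""

    iupac: str

    def __post_init__(self) -> None:
        up = self.iupac.upper()
        bad = set(up) - set(IUPAC_EXPANSION)
        if bad:
            raise AlphabetError(f"invalid IUPAC code(s) {sorted(bad)}")
        object.__setattr__(self, "iupac", up)

    def __len__(self) -> int:
        return len(self.iupac)

    @cached_property
    def diversity(self) -> int:
        """Exact number of distinct concrete sequences (arbitrary precision)."""
        return math.prod(len(IUPAC_EXPANSION[c]) for c in self.iupac)

    @cached_property
    def _allowed(self) -> np.ndarray:
        """Boolean (L, 5) table: allowed[j, base_index]. Genome 'N' (index 4)
        matches nothing — masked regions yield no sites."""
        table = np.zeros((len(self.iupac), 5), dtype=bool)
        for j, code in enumerate(self.iupac):
            for base in IUPAC_EXPANSION[code]:
                table[j, _BASE_INDEX[base]] = True
        return table

    def matches(self, sequence: str) -> bool:
        """True iff ``sequence`` is a concrete realization of the pattern."""
        if len(sequence) != len(self.iupac):
            return False
        return all(
            b in IUPAC_EXPANSION[c] for b, c in zip(sequence.upper(), self.iupac)
        )

    def mismatches(self, sequence: str) -> int:
        """Number of positions of ``sequence`` outside the allowed set."""
        if len(sequence) != len(self.iupac):
            raise ValueError("length mismatch")
        return sum(
            b not in IUPAC_EXPANSION[c] for b, c in zip(sequence.upper(), self.iupac)
        )

    def enumerate(self, limit: int = 65536) -> Iterator[str]:
        """Yield every concrete realization (guard: diversity <= ``limit``)."""
        if self.diversity > limit:
            raise ValueError(
                f"diversity {self.diversity} exceeds enumeration limit {limit}"
            )
        pools = [sorted(IUPAC_EXPANSION[c]) for c in self.iupac]
        for combo in itertools.product(*pools):
            yield "".join(combo)

    def reverse_complement(self) -> "DegeneratePattern":
        return DegeneratePattern(reverse_complement(self.iupac))


def diversity(pattern: str | DegeneratePattern) -> int:
    """Exact sequence diversity of an IUPAC pattern (e.g. N*20 -> 4**20)."""
    if not isinstance(pattern, DegeneratePattern):
        pattern = DegeneratePattern(pattern)
    return pattern.diversity


def cells_required(d: int, coverage: float, moi: float) -> int:
    """Cells to transduce for a screen: ``ceil(diversity * coverage / MOI)``.

    MOI is lentiviral particles per cell, so MOI 0.2 means one particle per
    five cells and the cell number is diversity * coverage * 5.
    """
    if d < 1:
        raise ValueError("diversity must be >= 1")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if moi <= 0:
        raise ValueError("MOI must be > 0")
    return math.ceil(d * coverage / moi)


def genome_fraction(n_target_sites: float, d: int) -> float:
    """Percentage of a library's diversity that has a genomic target site."""
    if d < 1:
        raise ValueError("diversity must be >= 1")
    if n_target_sites < 0:
        raise ValueError("site count must be >= 0")
    return 100.0 * n_target_sites / d


@dataclass(frozen=True)
class ScreenScale:
    """Screening-scale summary for a library of diversity ``d``."""

    d: int
    coverage: float
    moi: float
    cells: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", cells_required(self.d, self.coverage, self.moi))


@dataclass(frozen=True)
class TargetSite:
    """A genomic protospacer+PAM match.

    Coordinates are 0-based half-open on the forward strand and span the
    protospacer only; the PAM is reported separately (immediately 3' on the
    site's strand).
    """

    contig: str
    start: int
    end: int
    strand: str
    protospacer: str
    pam: str
    mismatches: int

    def to_bed(self) -> str:
        """BED6 line: name = protospacer, score = mismatch count."""
        return (
            f"{self.contig}\t{self.start}\t{self.end}\t"
            f"{self.protospacer}\t{self.mismatches}\t{self.strand}"
        )


def _scan_pair(
    enc: np.ndarray,
    first: DegeneratePattern,
    second: DegeneratePattern,
    mm_on_first: bool,
    max_mm: int,
) -> Iterator[tuple[int, int]]:
    """Scan an encoded forward strand for ``first`` immediately followed by
    ``second``; the mismatch budget applies to one of the two (the
    protospacer half), the other is matched exactly.

    Yields ``(start_of_first, protospacer_mismatches)``.
    """
    lf, ls = len(first), len(second)
    n = enc.shape[0] - lf - ls + 1
    if n <= 0:
        return
    w1 = np.lib.stride_tricks.sliding_window_view(enc, lf)[:n]
    mm1 = (~first._allowed[np.arange(lf), w1]).sum(axis=1)
    w2 = np.lib.stride_tricks.sliding_window_view(enc, ls)[lf : lf + n]
    mm2 = (~second._allowed[np.arange(ls), w2]).sum(axis=1)
    if mm_on_first:
        keep = (mm1 <= max_mm) & (mm2 == 0)
        proto_mm = mm1
    else:
        keep = (mm1 == 0) & (mm2 <= max_mm)
        proto_mm = mm2
    for start in np.nonzero(keep)[0]:
        yield int(start), int(proto_mm[start])


def find_target_sites(
    genome: Iterable[tuple[str, str]],
    pattern: str | DegeneratePattern,
    pam: str | DegeneratePattern = "NGG",
    max_mismatches: int = 0,
) -> Iterator[TargetSite]:
    """Enumerate all protospacer+PAM sites on both strands of ``genome``.

    Parameters
    ----------
    genome
        Iterable of ``(contig_id, sequence)`` over {A,C,G,T,N}.
    pattern
        Guide pattern (concrete 20-mer or IUPAC string). Mismatches are
        counted on the protospacer only.
    pam
        PAM pattern (default NGG), matched exactly — no PAM mismatches.
    max_mismatches
        Maximum protospacer mismatches (0-2 typical).

    Yields sites in coordinate order per contig (ties: + before -);
    overlapping sites are all reported.
    """
    import warnings

    if not isinstance(pattern, DegeneratePattern):
        pattern = DegeneratePattern(pattern)
    if not isinstance(pam, DegeneratePattern):
        pam = DegeneratePattern(pam)
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")

    lp, la = len(pattern), len(pam)
    pattern_rc = pattern.reverse_complement()
    pam_rc = pam.reverse_complement()

    for contig, seq in genome:
        seq = seq.upper()
        if len(seq) < lp + la:
            warnings.warn(
                f"contig {contig!r} shorter than pattern+PAM; skipped", stacklevel=2
            )
            continue
        enc = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        hits: list[TargetSite] = []
        # Forward strand: protospacer then PAM (PAM exact).
        for start, mm in _scan_pair(enc, pattern, pam, True, max_mismatches):
            hits.append(
                TargetSite(
                    contig, start, start + lp, "+",
                    seq[start : start + lp], seq[start + lp : start + lp + la], mm,
                )
            )
        # Minus strand: forward-strand layout is revcomp(PAM) then
        # revcomp(protospacer); mismatch budget on the protospacer half.
        for start, mm in _scan_pair(enc, pam_rc, pattern_rc, False, max_mismatches):
            ps_start = start + la
            hits.append(
                TargetSite(
                    contig, ps_start, ps_start + lp, "-",
                    reverse_complement(seq[ps_start : ps_start + lp]),
                    reverse_complement(seq[start : start + la]),
                    mm,
                )
            )
        hits.sort(key=lambda s: (s.start, s.strand))
        yield from hits


def count_target_sites(
    genome: Iterable[tuple[str, str]],
    pattern: str | DegeneratePattern,
    pam: str | DegeneratePattern = "NGG",
    max_mismatches: int = 0,
) -> int:
    """Streaming count of :func:`find_target_sites`."""
    return sum(1 for _ in find_target_sites(genome, pattern, pam, max_mismatches))
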