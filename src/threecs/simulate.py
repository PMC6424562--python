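"""Synthetic data generation for pipeline testing and calibration.

Emulates the statistical structure of amplicon sequencing of a pooled
guide library: a member abundance vector (uniform, log-normally skewed, or
cytosine-biased as in partially randomized oligo pools), a wildtype
placeholder contamination fraction, and reads laid out as
``5' filler + protospacer + 3' adapter + filler`` at fixed read length.
It also plants protospacer+PAM sites into random genomes for scanner
validation. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .degenerate import DegeneratePattern
from .seqcore import FastqRecord, reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass
class SimSpec:
    """Specification of one simulated sequencing run.

    ``library`` is either an explicit member list or a degenerate pattern to
    sample members from. ``abundance_model`` is ``uniform``, ``lognormal``
    (member weights exp(Normal(0, sigma))), or ``c_biased`` (weight
    proportional to exp(beta * #C), reproducing synthesis C bias).
    """

    library: Sequence[str] | DegeneratePattern | str
    n_reads: int = 10000
    abundance_model: str = "uniform"
    sigma: float = 1.0
    beta: float = 0.0
    wildtype_fraction: float = 0.0
    wildtype: Optional[str] = None
    prefix: str = "ACTTGAAAGTATTTCGATTTCTTGGCTTTATATATCTTGTGGAAAGGACGAAACACCG"
    adapter: str = "GTTTTAGAGCTAGAAATAGCAAG"
    read_length: int = 75
    n_pattern_members: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.library, str):
            self.library = DegeneratePattern(self.library)
        if self.abundance_model not in ("uniform", "lognormal", "c_biased"):
            raise ValueError(f"unknown abundance model {self.abundance_model!r}")
        if not 0 <= self.wildtype_fraction < 1:
            raise ValueError("wildtype_fraction must be in [0, 1)")
        if self.wildtype_fraction > 0 and not self.wildtype:
            raise ValueError("wildtype_fraction > 0 needs a wildtype sequence")


def _sample_pattern_members(
    pattern: DegeneratePattern, n: int, rng: np.random.Generator
) -> list[str]:
    """Draw ``n`` distinct concrete realizations of ``pattern``."""
    if pattern.diversity <= 4 * n and pattern.diversity <= 65536:
        pool = list(pattern.enumerate())
        if n >= len(pool):
            return pool
        idx = rng.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in sorted(idx)]
    from .seqcore import IUPAC_EXPANSION

    members: set[str] = set()
    pools = [sorted(IUPAC_EXPANSION[c]) for c in pattern.iupac]
    while len(members) < n:
        draw = rng.integers(0, [len(p) for p in pools], size=(n, len(pools)))
        for row in draw:
            members.add("".join(p[i] for p, i in zip(pools, row)))
            if len(members) == n:
                break
    return sorted(members)


@dataclass
class SimResult:
    """Reads plus the generating truth."""

    reads: list[FastqRecord]
    truth: pd.Series  # member -> read count (wildtype under '__wildtype__')
    members: list[str]
    probabilities: pd.Series


def simulate_reads(spec: SimSpec) -> SimResult:
    """Generate reads and the exact truth table of per-member counts.

    The protospacer slot length must fit the read: reads are
    ``prefix + protospacer + adapter`` truncated (or padded with the
    repeated adapter tail) to ``read_length``; the prefix is cut from the
    left so the protospacer + adapter evidence always fits.
    """
    rng = np.random.default_rng(spec.seed)
    if isinstance(spec.library, DegeneratePattern):
        members = _sample_pattern_members(spec.library, spec.n_pattern_members, rng)
    else:
        members = [m.upper() for m in spec.library]
        if len(set(members)) != len(members):
            raise ValueError("duplicate library members")
    if not members:
        raise ValueError("empty library")
    proto_len = len(members[0])
    if any(len(m) != proto_len for m in members):
        raise ValueError("members must share one length")
    min_adapter = min(len(spec.adapter), 10)
    if spec.read_length < proto_len + min_adapter:
        raise ValueError(
            f"read_length {spec.read_length} cannot hold a {proto_len}-nt "
            f"protospacer plus {min_adapter} nt of adapter evidence"
        )

    if spec.abundance_model == "uniform":
        weights = np.ones(len(members))
    elif spec.abundance_model == "lognormal":
        weights = np.exp(rng.normal(0.0, spec.sigma, size=len(members)))
    else:  # c_biased
        c_counts = np.array([m.count("C") for m in members], dtype=float)
        weights = np.exp(spec.beta * c_counts)
    probs = weights / weights.sum()

    n_wt = int(rng.binomial(spec.n_reads, spec.wildtype_fraction))
    member_counts = rng.multinomial(spec.n_reads - n_wt, probs)

    truth = pd.Series(member_counts, index=members, dtype="int64")
    if spec.wildtype is not None:
        truth["__wildtype__"] = n_wt

    sequences: list[str] = []
    for member, count in zip(members, member_counts):
        sequences.extend([member] * int(count))
    if spec.wildtype:
        sequences.extend([spec.wildtype.upper()] * n_wt)
    order = rng.permutation(len(sequences))

    reads = []
    for i, idx in enumerate(order):
        proto = sequences[idx]
        tail = spec.adapter
        while len(proto) + len(tail) < spec.read_length:
            tail += spec.adapter
        body = spec.prefix + proto + tail
        # Keep the protospacer fully inside the read: cut from the left.
        start = max(0, len(body) - spec.read_length)
        start = min(start, len(spec.prefix))
        read = body[start : start + spec.read_length]
        reads.append(FastqRecord(f"read{i}", read, "I" * len(read)))
    return SimResult(reads, truth, members, pd.Series(probs, index=members))


def simulate_genome(
    length: int,
    gc: float = 0.41,
    planted_sites: Sequence[tuple[str, str, str]] = (),
    seed: int = 0,
    contig: str = "chrSim",
) -> tuple[list[tuple[str, str]], list[tuple[str, int, int, str, str, str]]]:
    """Random genome with planted protospacer+PAM sites.

    ``planted_sites`` are ``(protospacer, pam, strand)``; they are placed at
    non-overlapping random positions. Returns ``[(contig, sequence)]`` and a
    truth list of BED-like tuples
    ``(contig, start, end, protospacer, pam, strand)`` with protospacer
    coordinates 0-based half-open on the forward strand.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = rng.choice(_BASES, size=length, p=p)

    truth = []
    occupied: list[tuple[int, int]] = []
    for proto, pam, strand in planted_sites:
        proto, pam = proto.upper(), pam.upper()
        site_len = len(proto) + len(pam)
        if site_len > length:
            raise ValueError("planted site longer than genome")
        for _attempt in range(1000):
            start = int(rng.integers(0, length - site_len + 1))
            span = (start, start + site_len)
            if all(span[1] <= s or span[0] >= e for s, e in occupied):
                break
        else:
            raise ValueError("could not place planted site without overlap")
        occupied.append(span)
        if strand == "+":
            forward = proto + pam
            proto_start = start
        elif strand == "-":
            forward = reverse_complement(proto + pam)
            proto_start = start + len(pam)
        else:
            raise ValueError(f"strand must be + or -, got {strand!r}")
        genome[span[0] : span[1]] = list(forward)
        truth.append(
            (contig, proto_start, proto_start + len(proto), proto, pam, strand)
        )
    truth.sort(key=lambda t: (t[1], t[5]))
    return [(contig, "".join(genome))], truth
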