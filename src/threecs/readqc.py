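"""From raw amplicon reads to an assigned count table.

The pipeline mirrors how pooled-library amplicon sequencing is scored when
the protospacer sits directly upstream of a known vector sequence: locate a
prefix of the 3' homology (the scaffold head) in the read, cut it and
everything downstream, keep only the last ``keep_last`` nucleotides (20 for
20-mer libraries, 17 for 17-mer ones), drop any read with an ambiguous
base, then assign each surviving protospacer by exact match to the library,
to the wildtype placeholder, or to the degenerate pattern.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .degenerate import DegeneratePattern

#: Row classes of a count table.
CLASS_LIBRARY = "library"
CLASS_PATTERN_NOVEL = "pattern_novel"
CLASS_WILDTYPE = "wildtype"
CLASS_UNASSIGNED = "unassigned"

#: Rejection reasons of the trimming stage.
REJECT_NO_ADAPTER = "no_adapter"
REJECT_TOO_SHORT = "too_short"
REJECT_AMBIGUOUS = "ambiguous"

_ASSIGNED_CLASSES = (CLASS_LIBRARY, CLASS_PATTERN_NOVEL)
_RATE_CLASSES = (CLASS_LIBRARY, CLASS_PATTERN_NOVEL, CLASS_WILDTYPE)


@dataclass(frozen=True)
class TrimSpec:
    """How to carve the protospacer out of a read.

    ``adapter`` is a prefix of the 3' homology sequence; ``keep_last`` is the
    protospacer length retained after adapter removal; a partial adapter of
    at least ``min_overlap`` nt is accepted at the read's 3' end.
    """

    adapter: str
    keep_last: int = 20
    min_overlap: int = 3
    allow_untrimmed: bool = False

    def __post_init__(self) -> None:
        if self.min_overlap < 3:
            raise ValueError("min_overlap must be >= 3")
        if self.keep_last < 1:
            raise ValueError("keep_last must be >= 1")
        object.__setattr__(self, "adapter", self.adapter.upper())


def trim_read(read: str, spec: TrimSpec) -> tuple[Optional[str], Optional[str]]:
    """Trim one read; returns ``(protospacer, None)`` or ``(None, reason)``.

    The leftmost full-adapter occurrence wins; failing that, the longest
    adapter prefix (>= ``min_overlap``) flush with the read's 3' end. After
    adapter removal only the last ``keep_last`` nucleotides are kept, which
    discards any upstream vector sequence. Reads with ambiguous bases are
    rejected — only unambiguously sequenced protospacers are counted.
    """
    read = read.upper()
    pos = read.find(spec.adapter)
    if pos >= 0:
        kept = read[:pos]
    else:
        kept = None
        for k in range(min(len(spec.adapter) - 1, len(read)), spec.min_overlap - 1, -1):
            if read.endswith(spec.adapter[:k]):
                kept = read[: len(read) - k]
                break
        if kept is None:
            if not spec.allow_untrimmed:
                return None, REJECT_NO_ADAPTER
            kept = read
    if len(kept) < spec.keep_last:
        return None, REJECT_TOO_SHORT
    proto = kept[-spec.keep_last :]
    if set(proto) - set("ACGT"):
        return None, REJECT_AMBIGUOUS
    return proto, None


@dataclass
class CountTable:
    """Member -> per-sample raw counts with an assignment class per member.

    ``counts`` is a members x samples integer frame; ``classes`` maps each
    member to library / pattern_novel / wildtype / unassigned. Normalized
    counts divide the assigned classes (library + pattern_novel) by their
    per-sample total, so they sum to 1 per sample.
    """

    counts: pd.DataFrame
    classes: pd.Series
    rejections: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.classes.index):
            self.classes = self.classes.reindex(self.counts.index)
        if self.classes.isna().any():
            raise ValueError("every member needs an assignment class")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def of_class(self, *classes: str) -> pd.DataFrame:
        return self.counts.loc[self.classes.isin(classes)]

    def totals(self) -> pd.Series:
        """Column sums over all classes."""
        return self.counts.sum(axis=0)

    def assigned_totals(self) -> pd.Series:
        return self.of_class(*_ASSIGNED_CLASSES).sum(axis=0)

    def normalized(self) -> pd.DataFrame:
        """Assigned-class counts divided by per-sample assigned totals."""
        assigned = self.of_class(*_ASSIGNED_CLASSES)
        totals = assigned.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("a sample has zero assigned reads; cannot normalize")
        return assigned / totals

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: member, class, raw and normalized counts."""
        out = self.counts.copy()
        out.insert(0, "class", self.classes)
        norm = self.normalized()
        for s in self.samples:
            out[f"{s}_normalized"] = norm[s]
        return out

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, int] | pd.Series,
        classes: Mapping[str, str] | pd.Series | str = CLASS_LIBRARY,
        sample: str = "sample",
    ) -> "CountTable":
        """Build a single-sample table from a member -> count mapping."""
        series = pd.Series(counts, dtype="int64")
        if isinstance(classes, str):
            cls_series = pd.Series(classes, index=series.index)
        else:
            cls_series = pd.Series(classes).reindex(series.index)
        return cls(series.to_frame(sample), cls_series)


def assign_reads(
    trimmed_reads: Iterable[str],
    library: Optional[Sequence[str] | Mapping[str, str]] = None,
    pattern: Optional[DegeneratePattern | str] = None,
    wildtype: Optional[str] = None,
    sample: str = "sample",
) -> CountTable:
    """Classify trimmed protospacers into a :class:`CountTable`.

    Order of precedence per read: exact library member, wildtype
    placeholder, pattern conformance (counted under the read's own sequence
    as ``pattern_novel``), else ``unassigned``. Matching is exact; counts
    are independent of read order.
    """
    if library is None and pattern is None:
        raise ValueError("supply a library, a pattern, or both")
    if isinstance(pattern, str):
        pattern = DegeneratePattern(pattern)

    member_of: dict[str, str] = {}
    if library is not None:
        items = library.items() if isinstance(library, Mapping) else ((s, s) for s in library)
        for name, seq in items:
            seq = seq.upper()
            if seq in member_of:
                raise ValueError(f"duplicate library member sequence {seq!r}")
            member_of[seq] = name
    wildtype = wildtype.upper() if wildtype else None

    lib_counts: Counter = Counter()
    novel_counts: Counter = Counter()
    wt_count = 0
    unassigned_count = 0
    for read in trimmed_reads:
        read = read.upper()
        name = member_of.get(read)
        if name is not None:
            lib_counts[name] += 1
        elif wildtype is not None and read == wildtype:
            wt_count += 1
        elif pattern is not None and pattern.matches(read):
            novel_counts[read] += 1
        else:
            unassigned_count += 1

    rows: dict[str, int] = {}
    classes: dict[str, str] = {}
    if library is not None:
        for seq, name in member_of.items():
            rows[name] = lib_counts.get(name, 0)
            classes[name] = CLASS_LIBRARY
    for seq in sorted(novel_counts):
        rows[seq] = novel_counts[seq]
        classes[seq] = CLASS_PATTERN_NOVEL
    if wildtype is not None:
        rows["__wildtype__"] = wt_count
        classes["__wildtype__"] = CLASS_WILDTYPE
    if unassigned_count:
        rows["__unassigned__"] = unassigned_count
        classes["__unassigned__"] = CLASS_UNASSIGNED

    counts = pd.Series(rows, dtype="int64").to_frame(sample)
    return CountTable(counts, pd.Series(classes))


def count_reads(
    reads: Iterable[str],
    spec: TrimSpec,
    library: Optional[Sequence[str] | Mapping[str, str]] = None,
    pattern: Optional[DegeneratePattern | str] = None,
    wildtype: Optional[str] = None,
    sample: str = "sample",
) -> CountTable:
    """Trim then assign an iterable of raw reads (streaming, bounded memory
    per distinct protospacer); rejection reasons land in ``rejections``."""
    rejections: Counter = Counter()

    def trimmed() -> Iterable[str]:
        for read in reads:
            proto, reason = trim_read(read, spec)
            if proto is None:
                rejections[reason] += 1
            else:
                yield proto

    table = assign_reads(trimmed(), library, pattern, wildtype, sample)
    table.rejections = rejections
    return table


def wildtype_rate(table: CountTable, sample: Optional[str] = None) -> float:
    """Percentage of wildtype placeholder reads among classified reads
    (wildtype + library + pattern_novel)."""
    sample = sample or table.samples[0]
    classified = table.of_class(*_RATE_CLASSES)[sample]
    total = int(classified.sum())
    if total == 0:
        raise ValueError("no classified reads; wildtype rate undefined")
    wt = int(table.of_class(CLASS_WILDTYPE)[sample].sum())
    return 100.0 * wt / total


def unique_fraction(table: CountTable, sample: Optional[str] = None) -> float:
    """Percentage of observed members seen exactly once — the key saturation
    statistic for libraries whose diversity vastly exceeds read depth."""
    sample = sample or table.samples[0]
    counts = table.of_class(*_ASSIGNED_CLASSES)[sample]
    observed = counts[counts >= 1]
    if observed.empty:
        raise ValueError("no observed members; unique fraction undefined")
    return 100.0 * float((observed == 1).sum()) / float(len(observed))


def viral_titer(percent_positive: float, volume_ml: float, n_cells: int = 20000) -> float:
    """Lentiviral titer in transducing units per mL from a flow-cytometry
    titration: ``n_cells * (%positive/100) / volume``."""
    if not 0 <= percent_positive <= 100:
        raise ValueError("percent_positive must be in [0, 100]")
    if volume_ml <= 0:
        raise ValueError("supernatant volume must be > 0")
    return n_cells * (percent_positive / 100.0) / volume_ml
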