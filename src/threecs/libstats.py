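"""Distribution and composition statistics for gRNA count tables.

Covers the standard pooled-library QC battery: coefficient of variation,
Lorenz curve and its area under the curve, chi-squared uniformity testing,
position-wise nucleotide frequency matrices, IUPAC consensus recovery from
those matrices, and cytosine-content-versus-abundance profiles.

Lorenz orientation: members are ranked by *descending* abundance, so the
curve lies on or above the diagonal and a perfectly uniform library scores
an AUC of exactly 0.5; concentration pushes the AUC toward 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqcore import IUPAC_FROM_SET

_BASES = ("A", "C", "G", "T")


def _as_array(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def cv(counts, ddof: int = 1) -> float:
    """Coefficient of variation as a percentage: 100 * s / mean.

    Sample (n-1) standard deviation by default; scale-invariant, so raw and
    normalized counts give the same value.
    """
    arr = _as_array(counts)
    if arr.size < 2:
        raise ValueError("CV needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * arr.std(ddof=ddof) / mean


def lorenz_auc(counts) -> tuple[np.ndarray, float]:
    """Lorenz curve points and trapezoid AUC under the descending-rank
    convention.

    Points are ``(i/n, cumulative count fraction through rank i)`` for
    counts sorted descending, with (0, 0) prepended. Uniform counts give
    AUC 0.5 exactly; total concentration approaches ``1 - 1/(2n)``.
    """
    arr = _as_array(counts)
    if arr.size < 1:
        raise ValueError("need at least one count")
    total = arr.sum()
    if total == 0:
        raise ValueError("Lorenz curve undefined for all-zero counts")
    ranked = np.sort(arr)[::-1]
    x = np.arange(arr.size + 1) / arr.size
    y = np.concatenate([[0.0], np.cumsum(ranked) / total])
    points = np.column_stack([x, y])
    auc = float(np.trapezoid(y, x))
    return points, auc


def chisq_uniformity(counts) -> tuple[float, float]:
    """Pearson chi-squared goodness-of-fit against the uniform expectation.

    Returns (statistic, upper-tail p at n-1 degrees of freedom). Not
    scale-invariant: the statistic grows with read depth, so run it on raw
    counts. Warns when expected counts fall below 5.
    """
    arr = _as_array(counts)
    if arr.size < 2:
        raise ValueError("uniformity test needs at least two categories")
    total = arr.sum()
    if total == 0:
        raise ValueError("uniformity test undefined for zero total")
    expected = total / arr.size
    if expected < 5:
        warnings.warn(
            f"expected count per category is {expected:.2f} < 5; "
            "chi-squared approximation is weak",
            stacklevel=2,
        )
    stat, p = stats.chisquare(arr)
    return float(stat), float(p)


def position_frequencies(
    sequences: Sequence[str], counts: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Count-weighted nucleotide frequency at each position.

    Returns an L x 4 frame (columns A, C, G, T) whose rows sum to 1. All
    sequences must share one length; this is the heat-map matrix used to
    profile randomized libraries.
    """
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("no sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must all have the same length")
    weights = np.ones(len(seqs)) if counts is None else _as_array(counts)
    if weights.size != len(seqs):
        raise ValueError("counts and sequences differ in length")
    total = weights.sum()
    if total == 0:
        raise ValueError("total weight is zero")
    lookup = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        lookup[ord(b)] = i
    enc = lookup[np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)]
    if (enc < 0).any():
        raise ValueError("sequences must be over A, C, G, T")
    enc = enc.reshape(len(seqs), length)
    mat = np.zeros((length, 4))
    np.add.at(mat, (np.broadcast_to(np.arange(length), enc.shape), enc), weights[:, None])
    return pd.DataFrame(mat / total, columns=list(_BASES))


def consensus_iupac(matrix: pd.DataFrame | np.ndarray, min_freq: float = 0.10) -> str:
    """Translate a position-frequency matrix back into an IUPAC string.

    At each position the code is the one whose expansion equals the set of
    bases with frequency >= ``min_freq``; if nothing clears the threshold
    the single most frequent base is used. ``min_freq`` must sit between
    the sequencing-noise floor and the smallest legitimate allowed-base
    frequency (1/4 for an equimolar N position).
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("matrix must be L x 4 (A, C, G, T)")
    out = []
    for row in arr:
        allowed = frozenset(b for b, f in zip(_BASES, row) if f >= min_freq)
        if not allowed:
            allowed = frozenset({_BASES[int(np.argmax(row))]})
        out.append(IUPAC_FROM_SET[allowed])
    return "".join(out)


def c_content_by_rank(
    sequences: Sequence[str], counts: Sequence[float], top_fraction: float = 0.05
) -> tuple[pd.DataFrame, float]:
    """Cytosine content against abundance rank.

    Ranks members by descending count (ties broken lexicographically by
    sequence for determinism), computes each member's C fraction, and
    reports the mean C content (percent) over the top ``top_fraction`` of
    members — the diagnostic for synthesis C bias in randomized libraries.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if len(sequences) == 0:
        raise ValueError("empty table")
    frame = pd.DataFrame(
        {
            "sequence": [s.upper() for s in sequences],
            "count": _as_array(counts),
        }
    )
    frame["c_fraction"] = [
        s.count("C") / len(s) if s else 0.0 for s in frame["sequence"]
    ]
    frame = frame.sort_values(
        ["count", "sequence"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    top_n = math.ceil(top_fraction * len(frame))
    top_mean = 100.0 * float(frame["c_fraction"].iloc[:top_n].mean())
    return frame[["rank", "sequence", "count", "c_fraction"]], top_mean


@dataclass
class QCReport:
    """Bundle of distribution statistics for one library sample."""

    n_members: int
    cv_percent: float
    auc: float
    chi2_stat: float
    chi2_p: float
    wildtype_rate: Optional[float] = None
    unique_fraction: Optional[float] = None
    consensus: Optional[str] = None
    top_c_content: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


def qc_report(
    counts: Mapping[str, float] | pd.Series,
    wildtype_rate_percent: Optional[float] = None,
    consensus_min_freq: float = 0.10,
    top_fraction: float = 0.05,
    sequences_are_members: bool = True,
) -> tuple[QCReport, dict]:
    """Full QC battery on a member -> count mapping.

    When member ids are themselves protospacer sequences of equal length
    (``sequences_are_members``), the positional frequency matrix, IUPAC
    consensus and top-rank C content are included; the matrix and Lorenz
    points are returned in the companion dict.
    """
    series = pd.Series(counts, dtype=float)
    values = series.to_numpy()
    points, auc = lorenz_auc(values)
    stat, p = chisq_uniformity(values)
    report = QCReport(
        n_members=int(series.size),
        cv_percent=cv(values),
        auc=auc,
        chi2_stat=stat,
        chi2_p=p,
        wildtype_rate=wildtype_rate_percent,
    )
    extras: dict = {"lorenz_points": points}
    nonzero = series[series >= 1]
    if len(nonzero):
        report.unique_fraction = 100.0 * float((nonzero == 1).sum()) / len(nonzero)
    ids = [str(i) for i in series.index]
    if sequences_are_members and ids and len({len(i) for i in ids}) == 1 and all(
        set(i) <= set(_BASES) for i in ids
    ):
        matrix = position_frequencies(ids, values)
        report.consensus = consensus_iupac(matrix, consensus_min_freq)
        _, report.top_c_content = c_content_by_rank(ids, values, top_fraction)
        extras["position_freq"] = matrix
    return report, extras
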