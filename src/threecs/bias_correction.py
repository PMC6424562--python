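"""Correction of single-nucleotide synthesis bias in randomized libraries.

Partially randomized oligo pools show a cytosine excess at randomized
positions (incomplete phosphoramidite mixing), which inflates the abundance
of C-rich guides. The correction fits a per-position, per-base weight
matrix from the observed positional frequencies against the 25% expectation,
scores every guide by summing its positional weights, rescales each guide's
count by its score, and renormalizes.

Weight direction: the default weight is ``expected / observed``, which
*down-weights* overrepresented bases so C-rich guides are deflated and the
distribution flattens (the AUC drops toward 0.5). The opposite reading —
``observed / expected`` — is available through ``direction`` for
comparison, but amplifies the bias rather than removing it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .libstats import position_frequencies
from .readqc import CountTable, CLASS_LIBRARY, CLASS_PATTERN_NOVEL

DOWN_WEIGHT = "down_weight_overrepresented"
UP_WEIGHT = "up_weight_overrepresented"

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class BiasModel:
    """Per-position nucleotide weights fit from observed frequencies.

    ``weight(b, j)`` is ``expected/observed`` (default direction) or
    ``observed/expected``; a base never observed at a position gets weight 0
    with a warning (it cannot occur in any counted read anyway).
    """

    position_freq: pd.DataFrame
    direction: str = DOWN_WEIGHT
    expected: float = 0.25
    weights: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if self.direction not in (DOWN_WEIGHT, UP_WEIGHT):
            raise ValueError(f"unknown direction {self.direction!r}")
        freq = np.asarray(self.position_freq, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 4:
            raise ValueError("position_freq must be L x 4")
        with np.errstate(divide="ignore"):
            if self.direction == DOWN_WEIGHT:
                w = np.where(freq > 0, self.expected / np.where(freq > 0, freq, 1), 0.0)
            else:
                w = freq / self.expected
        if (freq == 0).any():
            warnings.warn(
                "some bases are unobserved at some positions; their weight is 0",
                stacklevel=2,
            )
        object.__setattr__(
            self, "weights", pd.DataFrame(w, columns=list(_BASES))
        )

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def fit(
        cls,
        sequences: Sequence[str],
        counts: Optional[Sequence[float]] = None,
        direction: str = DOWN_WEIGHT,
        expected: float = 0.25,
    ) -> "BiasModel":
        """Fit the model from the very reads/counts it will correct."""
        return cls(position_frequencies(sequences, counts), direction, expected)


def score_read(sequence: str, model: BiasModel) -> float:
    """Sum of positional weights for one concrete read.

    Under an unbiased model every weight is 1 and the score equals the read
    length; C-rich reads score below L when C is overrepresented.
    """
    seq = sequence.upper()
    if len(seq) != model.length:
        raise ValueError(
            f"read length {len(seq)} != model length {model.length}"
        )
    return float(_scores([seq], model)[0])


def _scores(sequences: Sequence[str], model: BiasModel) -> np.ndarray:
    """Vectorized positional-weight sums for equal-length reads."""
    lookup = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        lookup[ord(b)] = i
    enc = lookup[
        np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    ].reshape(len(sequences), model.length)
    if (enc < 0).any():
        raise ValueError("non-ACGT base in read")
    w = model.weights.to_numpy()
    return w[np.arange(model.length), enc].sum(axis=1)


def correct_counts(
    table: CountTable, model: Optional[BiasModel] = None, direction: str = DOWN_WEIGHT
) -> pd.DataFrame:
    """Bias-corrected normalized counts for the assigned members of a table.

    Member ids must be the protospacer sequences themselves (as produced by
    pattern-mode read assignment). If ``model`` is omitted it is fit on the
    table's own sequences and counts. Per sample: each raw count is
    multiplied by its read score and the products renormalized to sum to 1.
    Returns a members x samples frame of corrected normalized counts.
    """
    members = table.of_class(CLASS_LIBRARY, CLASS_PATTERN_NOVEL)
    if members.empty:
        raise ValueError("no assigned members to correct")
    sequences = [str(m) for m in members.index]
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("member sequences must share one length")
    out = {}
    for sample in members.columns:
        counts = members[sample].to_numpy(dtype=float)
        total = counts.sum()
        if total == 0:
            raise ValueError(f"sample {sample!r} has zero assigned reads")
        m = model or BiasModel.fit(sequences, counts, direction=direction)
        scores = _scores(sequences, m)
        corrected = counts * scores / total
        denom = corrected.sum()
        if denom == 0:
            raise ValueError("all corrected counts are zero")
        out[sample] = corrected / denom
    return pd.DataFrame(out, index=members.index)
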