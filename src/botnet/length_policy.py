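"""Fixed-length sequence generation.

Recurrent classifiers need equal-length inputs, but lncRNA lengths span two
orders of magnitude (hundreds to tens of thousands of residues).  Six
strategies are provided:

* the three traditional length-normalization baselines — pad everything to the
  corpus maximum (``MAX_PAD``), truncate everything to the corpus minimum
  (``MIN_TRUNC``), or pad-shorter / truncate-longer to the corpus average
  (``AVG_HYBRID``);
* the three positional sub-sequence settings — keep only the first X residues
  (``START``), the last Y residues (``END``), or the first X plus the last Y
  (``START_END``).

Padding and truncation act on the END of sequences throughout (the dominant
convention).  Sub-sequence budgets larger than a sequence are end-padded so
the fixed-length contract always holds.  Coordinates in logs are 1-based
inclusive; internal slicing is half-open.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

PAD_SYMBOL = "-"


class Strategy(str, enum.Enum):
    MAX_PAD = "max_pad"
    MIN_TRUNC = "min_trunc"
    AVG_HYBRID = "avg_hybrid"
    START = "start"
    END = "end"
    START_END = "start_end"


_REGION_STRATEGIES = {Strategy.START, Strategy.END, Strategy.START_END}


@dataclass(frozen=True)
class LengthPolicy:
    """A fixed-length strategy plus its residue budgets.

    X is the budget taken from the sequence start (START, START_END); Y the
    budget taken from the end (END, START_END).  The pad symbol must not be a
    member of any sequence alphabet.
    """

    strategy: Strategy
    X: int | None = None
    Y: int | None = None
    pad_symbol: str = PAD_SYMBOL

    def __post_init__(self) -> None:
        s = Strategy(self.strategy)
        object.__setattr__(self, "strategy", s)
        if s in (Strategy.START, Strategy.START_END) and (self.X is None or self.X < 1):
            raise ValueError(f"strategy {s.value} requires X >= 1")
        if s in (Strategy.END, Strategy.START_END) and (self.Y is None or self.Y < 1):
            raise ValueError(f"strategy {s.value} requires Y >= 1")
        if len(self.pad_symbol) != 1 or self.pad_symbol.isalpha():
            raise ValueError("pad_symbol must be a single non-alphabet character")

    @property
    def region_budget(self) -> int:
        """Target length for the sub-sequence strategies."""
        if self.strategy is Strategy.START:
            return self.X
        if self.strategy is Strategy.END:
            return self.Y
        if self.strategy is Strategy.START_END:
            return self.X + self.Y
        raise ValueError(f"{self.strategy.value} has no fixed region budget")


@dataclass(frozen=True)
class CorpusLengthStats:
    """min / max / mean residue length of one sequence side.

    Computed on the training split only, so data-dependent targets (corpus
    max, min, average) never leak information from held-out pairs.
    """

    min_len: int
    max_len: int
    mean_len: float

    def __post_init__(self) -> None:
        if not self.min_len <= self.mean_len <= self.max_len:
            raise ValueError("length stats must satisfy min <= mean <= max")

    @classmethod
    def from_lengths(cls, lengths: Sequence[int]) -> "CorpusLengthStats":
        arr = np.asarray(lengths)
        return cls(int(arr.min()), int(arr.max()), float(arr.mean()))

    @property
    def rounded_mean(self) -> int:
        # round-half-up; the average-length hybrid needs an integer target
        return int(np.floor(self.mean_len + 0.5))


def pad_to_length(seq: str, L: int, pad_symbol: str = PAD_SYMBOL) -> str:
    """Append pad symbols to the end of ``seq`` until it has length ``L``."""
    if len(seq) > L:
        raise ValueError(f"sequence of length {len(seq)} exceeds target {L}")
    return seq + pad_symbol * (L - len(seq))


def truncate_to_length(seq: str, L: int) -> str:
    """Keep the first ``L`` residues; shorter sequences pass through unchanged."""
    if L < 1:
        raise ValueError("target length must be >= 1")
    return seq[:L]


def take_region(seq: str, policy: LengthPolicy) -> str:
    """Extract the policy's positional sub-sequence at its exact budget.

    START keeps residues 1..X, END keeps the last Y, START_END concatenates
    first-X with last-Y.  A sequence shorter than the budget is end-padded to
    the exact target length; if X + Y exceeds the sequence length the start
    and end windows overlap (logged, then padded as usual).
    """
    s = policy.strategy
    if s not in _REGION_STRATEGIES:
        raise ValueError(f"take_region requires a sub-sequence strategy, got {s.value}")
    if s is Strategy.START:
        out = seq[: policy.X]
    elif s is Strategy.END:
        out = seq[-policy.Y:] if len(seq) >= policy.Y else seq
    else:
        if policy.X + policy.Y > len(seq):
            logger.warning(
                "start/end windows overlap: X+Y=%d > sequence length %d",
                policy.X + policy.Y, len(seq),
            )
        tail = seq[-policy.Y:] if len(seq) >= policy.Y else seq
        out = seq[: policy.X] + tail
    return pad_to_length(out, policy.region_budget, policy.pad_symbol)


def apply_policy(
    sequences: Iterable[str],
    policy: LengthPolicy,
    stats: CorpusLengthStats | None = None,
) -> list[str]:
    """Map every sequence to the policy's single fixed length.

    The data-dependent strategies (MAX_PAD, MIN_TRUNC, AVG_HYBRID) need
    ``stats`` computed on the training split; the sub-sequence strategies
    ignore it.
    """
    s = policy.strategy
    if s in _REGION_STRATEGIES:
        return [take_region(q, policy) for q in sequences]
    if stats is None:
        raise ValueError(f"strategy {s.value} requires corpus length stats")
    if s is Strategy.MAX_PAD:
        L = stats.max_len
        return [pad_to_length(truncate_to_length(q, L), L, policy.pad_symbol) for q in sequences]
    if s is Strategy.MIN_TRUNC:
        L = stats.min_len
        return [pad_to_length(truncate_to_length(q, L), L, policy.pad_symbol) for q in sequences]
    L = stats.rounded_mean
    return [pad_to_length(truncate_to_length(q, L), L, policy.pad_symbol) for q in sequences]


@dataclass(frozen=True)
class FusedPair:
    """One classifier instance: ordered (lncRNA segment, partner segment).

    Segments are kept distinct so tokenization never forms k-mers spanning
    the junction between the two molecules.
    """

    lnc_segment: str
    partner_segment: str

    @property
    def segment_lengths(self) -> tuple[int, int]:
        return len(self.lnc_segment), len(self.partner_segment)


def fuse_pair(lnc_fixed: str, partner_fixed: str) -> FusedPair:
    """Fuse the two fixed-length sides of a pair into a single instance."""
    return FusedPair(lnc_fixed, partner_fixed)
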