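"""Higher-order residue (k-mer) generation and integer encoding.

A window of k consecutive residues is slid over each sequence with a given
stride: stride < k yields overlapping k-mers, stride == k non-overlapping
ones.  The vocabulary enumerates all |alphabet|^k k-mers (4^k for RNA) in
lexicographic order so indices are corpus-independent, with two reserved
entries: PAD = 0 for k-mers that touch the padding symbol and UNK = 1 for
k-mers containing an ambiguity symbol.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from botnet.length_policy import FusedPair
from botnet.sequence_io import ALPHABETS, AMBIGUITY

PAD_INDEX = 0
UNK_INDEX = 1
N_RESERVED = 2


def generate_kmers(seq: str, k: int, stride: int = 1) -> list[str]:
    """All windows seq[i:i+k] for i = 0, stride, 2*stride, ... while i+k <= len.

    The number of windows is floor((L - k) / stride) + 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 1 <= stride <= k:
        raise ValueError("stride must satisfy 1 <= stride <= k")
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} is shorter than k={k}")
    return [seq[i : i + k] for i in range(0, len(seq) - k + 1, stride)]


@dataclass(frozen=True)
class KmerVocabulary:
    """Map from k-mers over one alphabet to contiguous integer indices >= 2."""

    alphabet: str  # "RNA" or "PROTEIN"
    k: int
    stride: int
    index_of: dict[str, int]

    @property
    def num_kmers(self) -> int:
        return len(self.index_of)

    @property
    def size(self) -> int:
        """Total index space including the PAD and UNK entries."""
        return self.num_kmers + N_RESERVED

    def lookup(self, kmer: str, pad_symbol: str = "-") -> int:
        if pad_symbol in kmer:
            return PAD_INDEX
        if AMBIGUITY[self.alphabet] in kmer:
            return UNK_INDEX
        try:
            return self.index_of[kmer]
        except KeyError:
            raise KeyError(f"k-mer {kmer!r} not in {self.alphabet} k={self.k} vocabulary") from None

    def save(self, path: str | Path) -> None:
        """Plain-text serialization: a JSON header line, then k-mer<TAB>index rows."""
        with open(path, "w") as fh:
            fh.write(json.dumps({"alphabet": self.alphabet, "k": self.k, "stride": self.stride}) + "\n")
            for kmer, idx in sorted(self.index_of.items(), key=lambda kv: kv[1]):
                fh.write(f"{kmer}\t{idx}\n")

    @classmethod
    def load(cls, path: str | Path) -> "KmerVocabulary":
        with open(path) as fh:
            header = json.loads(fh.readline())
            index_of = {}
            for line in fh:
                kmer, idx = line.rstrip("\n").split("\t")
                index_of[kmer] = int(idx)
        return cls(header["alphabet"], header["k"], header["stride"], index_of)


def build_vocab(alphabet: str, k: int, stride: int = 1) -> KmerVocabulary:
    """Enumerate all |alphabet|^k k-mers lexicographically, indices from 2."""
    if alphabet not in ALPHABETS:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    symbols = sorted(ALPHABETS[alphabet])
    index_of = {
        "".join(t): N_RESERVED + i
        for i, t in enumerate(itertools.product(symbols, repeat=k))
    }
    return KmerVocabulary(alphabet, k, stride, index_of)


@dataclass(frozen=True)
class TokenizedPair:
    """Integer token ids for one fused pair: lncRNA tokens then partner tokens."""

    token_ids: np.ndarray
    segment_lengths: tuple[int, int]
    label: int

    def __post_init__(self) -> None:
        if len(self.token_ids) != sum(self.segment_lengths):
            raise ValueError("token count does not match segment lengths")


class PairEncoder:
    """Encode fused pairs with one vocabulary per segment alphabet.

    For same-alphabet tasks (lncRNA–miRNA) a single shared vocabulary is used.
    For mixed-alphabet tasks (lncRNA–protein) the partner vocabulary is offset
    into a single contiguous index space so one embedding table covers both
    sides; PAD and UNK stay shared at indices 0 and 1.
    """

    def __init__(self, lnc_vocab: KmerVocabulary, partner_vocab: KmerVocabulary | None = None):
        self.lnc_vocab = lnc_vocab
        self.partner_vocab = partner_vocab or lnc_vocab
        self.shared = self.partner_vocab is self.lnc_vocab or (
            self.partner_vocab.alphabet == lnc_vocab.alphabet and self.partner_vocab.k == lnc_vocab.k
        )
        self._partner_offset = 0 if self.shared else lnc_vocab.num_kmers

    @property
    def vocab_size(self) -> int:
        if self.shared:
            return self.lnc_vocab.size
        return self.lnc_vocab.size + self.partner_vocab.num_kmers

    def _encode_segment(self, seq: str, vocab: KmerVocabulary, offset: int, pad_symbol: str) -> list[int]:
        ids = []
        for kmer in generate_kmers(seq, vocab.k, vocab.stride):
            idx = vocab.lookup(kmer, pad_symbol)
            ids.append(idx if idx < N_RESERVED else idx + offset)
        return ids

    def encode(self, instance: FusedPair, label: int, pad_symbol: str = "-") -> TokenizedPair:
        """Tokenize each segment independently (no junction-spanning k-mers)."""
        lnc_ids = self._encode_segment(instance.lnc_segment, self.lnc_vocab, 0, pad_symbol)
        partner_ids = self._encode_segment(
            instance.partner_segment, self.partner_vocab, self._partner_offset, pad_symbol
        )
        return TokenizedPair(
            token_ids=np.array(lnc_ids + partner_ids, dtype=np.int64),
            segment_lengths=(len(lnc_ids), len(partner_ids)),
            label=label,
        )
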