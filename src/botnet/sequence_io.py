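"""Sequence and pair-table I/O, alphabet canonicalization, negative-pair
sampling by random pairing, and stratified fold assignment.

Sequences are plain strings over either the RNA alphabet {A, C, G, U} with
ambiguity symbol N, or the 20-letter protein alphabet with ambiguity symbol X.
Interaction datasets are tables of (lncRNA id, partner id, label) rows; the
label is 1 for an interactive pair and 0 for a non-interactive one.  Negative
pairs are produced by random pairing of the observed sequences, following the
common benchmark construction: shuffle both id lists with the
Knuth–Durstenfeld algorithm, then draw random pairs and reject any that
collide with the positive set (or with an already drawn negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUITY = {"RNA": "N", "PROTEIN": "X"}
ALPHABETS = {"RNA": RNA_ALPHABET, "PROTEIN": PROTEIN_ALPHABET}


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One biological sequence with a canonicalized residue string."""

    id: str
    residues: str
    alphabet: str  # "RNA" or "PROTEIN"

    def __post_init__(self) -> None:
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if len(self.residues) < 1:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        allowed = ALPHABETS[self.alphabet] | {AMBIGUITY[self.alphabet]}
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(f"record {self.id!r} contains invalid symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class InteractionPair:
    """A labeled (lncRNA, partner) pair; label 1 = interactive."""

    a_id: str
    b_id: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class PairedCorpus:
    """A labeled interaction corpus: two record collections plus the pair table.

    ``lnc_records`` always holds the lncRNA side; ``partner_records`` holds the
    miRNA or protein side.  Positive and negative pair sets must be disjoint.
    """

    lnc_records: dict[str, SequenceRecord]
    partner_records: dict[str, SequenceRecord]
    pairs: list[InteractionPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for p in self.pairs:
            if p.a_id not in self.lnc_records:
                raise KeyError(f"unknown lncRNA id {p.a_id!r}")
            if p.b_id not in self.partner_records:
                raise KeyError(f"unknown partner id {p.b_id!r}")
            key = (p.a_id, p.b_id)
            if key in seen:
                raise ValueError(f"duplicate pair {key}")
            seen.add(key)

    @property
    def positives(self) -> list[InteractionPair]:
        return [p for p in self.pairs if p.label == 1]

    @property
    def negatives(self) -> list[InteractionPair]:
        return [p for p in self.pairs if p.label == 0]

    def length_stats(self, side: str) -> tuple[int, int, float]:
        """(min, max, mean) residue length for ``side`` in {"lnc", "partner"}."""
        recs = self.lnc_records if side == "lnc" else self.partner_records
        lengths = [r.length for r in recs.values()]
        return min(lengths), max(lengths), float(np.mean(lengths))


def _canonicalize(raw: str, alphabet: str, rec_id: str) -> str:
    residues = raw.upper()
    if alphabet == "RNA":
        residues = residues.replace("T", "U")
    allowed = ALPHABETS[alphabet] | {AMBIGUITY[alphabet]}
    if not set(residues) <= allowed:
        bad = sorted(set(residues) - allowed)
        logger.warning(
            "record %s: rewriting out-of-alphabet symbols %s to %s",
            rec_id, bad, AMBIGUITY[alphabet],
        )
        residues = "".join(c if c in allowed else AMBIGUITY[alphabet] for c in residues)
    return residues


def read_fasta(path: str | Path, alphabet: str) -> list[SequenceRecord]:
    """Read a (multi-record, possibly line-wrapped) FASTA file.

    Residues are uppercased; for RNA, T is rewritten to U (benchmark FASTA is
    typically DNA-alphabet); any remaining out-of-alphabet symbol is rewritten
    to the ambiguity symbol with a logged warning.
    """
    path = Path(path)
    if alphabet not in ALPHABETS:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first = text.lstrip().splitlines()[0]
        raise FastaParseError(f"{path}: sequence data before first header: {first[:30]!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FastaParseError(f"{path}: entry {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(rec.id, _canonicalize(seq, alphabet, rec.id), alphabet))
    if not records and text.strip():
        raise FastaParseError(f"{path}: no FASTA records parsed")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    bio = [_BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def load_pairs(
    path: str | Path,
    lnc_records: dict[str, SequenceRecord] | None = None,
    partner_records: dict[str, SequenceRecord] | None = None,
    positives_only: bool = False,
) -> list[InteractionPair]:
    """Load a headered TSV pair table (columns a_id, b_id[, label]).

    When record dictionaries are given, every id must resolve.  With
    ``positives_only`` all labels are forced to 1 (for files that list only
    known interactions).
    """
    df = pd.read_csv(path, sep="\t", dtype={"a_id": str, "b_id": str})
    required = {"a_id", "b_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: pair table must have columns a_id, b_id; got {list(df.columns)}")
    if positives_only or "label" not in df.columns:
        df = df.assign(label=1)
    pairs = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        if lnc_records is not None and row.a_id not in lnc_records:
            raise KeyError(f"unknown id {row.a_id}")
        if partner_records is not None and row.b_id not in partner_records:
            raise KeyError(f"unknown id {row.b_id}")
        key = (row.a_id, row.b_id)
        if key in seen:
            raise ValueError(f"duplicate pair {key}")
        seen.add(key)
        pairs.append(InteractionPair(row.a_id, row.b_id, int(row.label)))
    return pairs


def write_pairs(pairs: Iterable[InteractionPair], path: str | Path) -> None:
    """Write pairs as a headered TSV (a_id, b_id, label)."""
    df = pd.DataFrame([(p.a_id, p.b_id, p.label) for p in pairs], columns=["a_id", "b_id", "label"])
    df.to_csv(path, sep="\t", index=False)


def knuth_durstenfeld_shuffle(items: list, rng: np.random.Generator) -> list:
    """In-place Fisher–Yates (Knuth–Durstenfeld) shuffle; returns the list.

    Iterates i from the last index down to 1, swapping position i with a
    uniformly drawn position j <= i.  Every permutation is equally likely.
    """
    for i in range(len(items) - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        items[i], items[j] = items[j], items[i]
    return items


def generate_negatives(
    corpus: PairedCorpus,
    n: int,
    n_shuffles: int = 10,
    seed: int = 0,
) -> list[InteractionPair]:
    """Draw ``n`` non-interactive pairs by random pairing.

    Both id lists are shuffled ``n_shuffles`` times with the Knuth–Durstenfeld
    algorithm, then random (lncRNA, partner) combinations are drawn and
    rejected if they occur in the positive set or were already drawn.
    Rejection sampling is capped at 100 * n attempts.
    """
    rng = np.random.default_rng(seed)
    lnc_ids = sorted(corpus.lnc_records)
    partner_ids = sorted(corpus.partner_records)
    positives = {(p.a_id, p.b_id) for p in corpus.positives}
    capacity = len(lnc_ids) * len(partner_ids) - len(positives)
    if n > capacity:
        raise ValueError(f"requested {n} negatives but only {capacity} non-positive pairs exist")
    for _ in range(n_shuffles):
        knuth_durstenfeld_shuffle(lnc_ids, rng)
        knuth_durstenfeld_shuffle(partner_ids, rng)
    logger.info("generate_negatives: n=%d seed=%d n_shuffles=%d", n, seed, n_shuffles)
    negatives: list[InteractionPair] = []
    drawn: set[tuple[str, str]] = set()
    attempts = 0
    max_attempts = 100 * n
    while len(negatives) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"rejection sampling exceeded {max_attempts} attempts "
                f"({len(negatives)}/{n} negatives drawn)"
            )
        a = lnc_ids[int(rng.integers(len(lnc_ids)))]
        b = partner_ids[int(rng.integers(len(partner_ids)))]
        if (a, b) in positives or (a, b) in drawn:
            continue
        drawn.add((a, b))
        negatives.append(InteractionPair(a, b, 0))
    return negatives


@dataclass(frozen=True)
class FoldAssignment:
    """Index sets for one cross-validation fold over a fixed pair list."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


def split_folds(
    pairs: Sequence[InteractionPair],
    n_folds: int = 5,
    val_fraction: float = 0.1,
    seed: int = 0,
    stratify: bool = True,
) -> list[FoldAssignment]:
    """Partition pairs into ``n_folds`` disjoint test folds with a tagged
    validation subset inside each training split.

    Folds are stratified by label by default so per-fold metrics are stable;
    ``val_fraction`` of each training split (again stratified) is held out as
    the validation set used for early stopping and model selection.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if not 0 <= val_fraction < 1:
        raise ValueError("val_fraction must be in [0, 1)")
    if len(pairs) < n_folds:
        raise ValueError(f"cannot split {len(pairs)} pairs into {n_folds} folds")
    labels = np.array([p.label for p in pairs])
    idx = np.arange(len(pairs))
    if stratify:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(idx, labels)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(idx)
    folds = []
    for k, (train_all, test) in enumerate(splits):
        if val_fraction > 0:
            strat = labels[train_all] if stratify else None
            train, val = train_test_split(
                train_all, test_size=val_fraction, random_state=seed + k, stratify=strat
            )
        else:
            train, val = train_all, np.array([], dtype=int)
        folds.append(FoldAssignment(np.sort(train), np.sort(val), np.sort(test)))
    return folds
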