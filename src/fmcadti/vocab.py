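"""Fragment vocabularies and fixed-length integer encoding.

Vocabularies are built from a training corpus only; ids 0 and 1 are
reserved for padding and unknown fragments. Drugs and proteins get
separate vocabularies (their fragment alphabets are disjoint).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .fragments import FragmentSequence

PAD_ID = 0
UNK_ID = 1

__all__ = [
    "PAD_ID",
    "UNK_ID",
    "Vocab",
    "build_vocab",
    "encode",
    "EncodedPair",
    "read_interaction_table",
]


@dataclass
class Vocab:
    """Injective fragment-string -> contiguous integer-id mapping.

    Ids 0 (``pad``) and 1 (``unk``) are reserved and never collide with
    corpus tokens; corpus tokens occupy 2..size-1 in first-seen order.
    """

    token_to_id: dict[str, int] = field(default_factory=dict)

    pad_id: int = PAD_ID
    unk_id: int = UNK_ID

    @property
    def size(self) -> int:
        return len(self.token_to_id) + 2

    def id_for(self, token: str) -> int:
        return self.token_to_id.get(token, self.unk_id)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def decode(self, ids) -> list[str]:
        """Map ids back to fragment strings, dropping padding."""
        rev = {i: t for t, i in self.token_to_id.items()}
        out = []
        for i in ids:
            i = int(i)
            if i == self.pad_id:
                continue
            out.append(rev.get(i, "<unk>"))
        return out

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.token_to_id, indent=0))

    @classmethod
    def from_json(cls, path) -> "Vocab":
        return cls(token_to_id=json.loads(Path(path).read_text()))


def build_vocab(corpus: list[FragmentSequence], min_count: int = 1) -> Vocab:
    """Build a vocabulary from a fragment corpus.

    Tokens with corpus frequency >= ``min_count`` are assigned ids in
    first-seen order starting at 2; the result is deterministic for a
    fixed corpus order.
    """
    if not corpus:
        raise InvalidInputError("cannot build a vocabulary from an empty corpus")
    counts: dict[str, int] = {}
    order: list[str] = []
    for fragseq in corpus:
        for text in fragseq.texts():
            if text not in counts:
                counts[text] = 0
                order.append(text)
            counts[text] += 1
    token_to_id = {}
    next_id = 2
    for text in order:
        if counts[text] >= min_count:
            token_to_id[text] = next_id
            next_id += 1
    return Vocab(token_to_id=token_to_id)


def encode(fragseq: FragmentSequence, vocab: Vocab, max_len: int) -> np.ndarray:
    """Encode a fragment sequence as exactly ``max_len`` integer ids.

    The first ``max_len`` fragments are mapped (unknown -> unk id);
    shorter sequences are right-padded with the pad id.
    """
    if max_len < 1:
        raise InvalidInputError(f"max_len must be >= 1, got {max_len}")
    ids = np.full(max_len, vocab.pad_id, dtype=np.int64)
    for i, text in enumerate(fragseq.texts()[:max_len]):
        ids[i] = vocab.id_for(text)
    return ids


@dataclass
class EncodedPair:
    """One (drug, protein, label) sample as fixed-length id sequences."""

    drug_ids: np.ndarray
    protein_ids: np.ndarray
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise InvalidInputError(f"label must be 0 or 1, got {self.label}")


def read_interaction_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV interaction table with columns smiles, sequence, label.

    The separator is inferred from the extension (.tsv -> tab) unless
    given explicitly. Column names are matched case-insensitively.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"smiles", "sequence", "label"}
    if not required <= set(df.columns):
        raise InvalidInputError(
            f"interaction table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    df["label"] = df["label"].astype(int)
    if not df["label"].isin([0, 1]).all():
        raise InvalidInputError("labels must be binary 0/1")
    return df[["smiles", "sequence", "label"]]
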