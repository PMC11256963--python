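"""Shared fragment data types for the drug and protein fragmenters."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

TokenKind = Literal[
    "atom", "bracket_atom", "bond", "ring_digit", "branch_open", "branch_close"
]

DrugFragmentType = Literal["branch_chain", "common_substructure", "synthetic"]


@dataclass(frozen=True)
class SmilesToken:
    """One atomic SMILES token.

    Concatenating the ``text`` of a token list in order reproduces the
    input string exactly.
    """

    text: str
    kind: TokenKind

    def __post_init__(self):
        if not self.text:
            raise ValueError("token text must be non-empty")


@dataclass(frozen=True)
class DrugFragment:
    """A substring-level drug fragment with its mined type."""

    text: str
    ftype: DrugFragmentType

    def __post_init__(self):
        if not self.text:
            raise ValueError("fragment text must be non-empty")
        if self.ftype == "branch_chain" and self.text.count("(") != self.text.count(")"):
            raise ValueError("branch_chain fragment has unbalanced parentheses")


@dataclass(frozen=True)
class ProteinFragment:
    """A k-gram over the eight-letter category alphabet A-H."""

    text: str

    def __post_init__(self):
        if not self.text:
            raise ValueError("fragment text must be non-empty")

    @property
    def length(self) -> int:
        return len(self.text)


@dataclass
class FragmentSequence:
    """Ordered, deterministic fragment list produced from one drug or protein."""

    source_id: str
    fragments: list = field(default_factory=list)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def texts(self) -> list[str]:
        return [f.text for f in self.fragments]

    def __iter__(self):
        return iter(self.fragments)

    def __len__(self):
        return len(self.fragments)
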