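"""Category fragment mining (CFM): protein sequence fragmentation.

Amino acids are mapped onto eight chemical-property categories (letters
A-H), then the mapped chain is partitioned into non-overlapping k-grams.
The default grouping ships as an editable JSON table: A = small aliphatic
(A,G,V); B = large hydrophobic (I,L,F,P); C = polar/hydroxyl (Y,M,T,S);
D = amide/aromatic-N (H,N,Q,W); E = basic (R,K); F = acidic (D,E);
G = cysteine; H = fallback for nonstandard letters (B,J,O,U,X,Z).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from Bio import SeqIO

from .errors import InvalidParameterError, InvalidSequenceError
from .fragments import FragmentSequence, ProteinFragment

__all__ = [
    "CategoryTable",
    "map_categories",
    "kgram_split",
    "fragment_protein",
    "read_fasta",
    "default_category_table",
]

FALLBACK_CATEGORY = "H"
_NONSTANDARD = set("BJOUXZ")


@dataclass(frozen=True)
class CategoryTable:
    """Amino-acid letter -> category letter mapping over {A..H}."""

    mapping: dict[str, str] = field(default_factory=dict)
    fallback: str = FALLBACK_CATEGORY

    def __post_init__(self):
        cats = set(self.mapping.values()) | {self.fallback}
        if not cats <= set("ABCDEFGH"):
            raise InvalidParameterError(
                f"categories must be letters A-H, got {sorted(cats)}"
            )
        if len(cats) != 8:
            raise InvalidParameterError(
                f"category table must use exactly 8 categories, got {len(cats)}"
            )
        standard = set("ACDEFGHIKLMNPQRSTVWY")
        missing = standard - set(self.mapping)
        if missing:
            raise InvalidParameterError(
                f"category table is missing standard amino acids: {sorted(missing)}"
            )

    def category(self, aa: str) -> str:
        return self.mapping.get(aa, self.fallback)


def default_category_table() -> CategoryTable:
    with resources.files("fmcadti.data").joinpath("categories.json").open() as fh:
        return CategoryTable(mapping=json.load(fh))


def load_category_table(path) -> CategoryTable:
    """Load a category table from a JSON file {aa_letter: category_letter}."""
    with open(path) as fh:
        return CategoryTable(mapping=json.load(fh))


def map_categories(sequence: str, table: CategoryTable | None = None) -> str:
    """Map an amino-acid sequence onto its category string.

    Output length equals input length; nonstandard letters map to the
    fallback category. Raises :class:`InvalidSequenceError` for empty
    input or characters outside A-Z.
    """
    if table is None:
        table = default_category_table()
    if not sequence:
        raise InvalidSequenceError("empty protein sequence")
    out = []
    for pos, aa in enumerate(sequence):
        if not ("A" <= aa <= "Z"):
            raise InvalidSequenceError(
                f"character {aa!r} at position {pos} is not an uppercase letter"
            )
        out.append(table.category(aa))
    return "".join(out)


def kgram_split(catseq: str, k: int = 3) -> list[ProteinFragment]:
    """Partition a category string into consecutive windows of length k.

    Non-overlapping; a trailing remainder shorter than k is kept as a
    final fragment, so concatenating all fragments restores ``catseq``.
    """
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    if not catseq:
        raise InvalidSequenceError("empty category string")
    return [ProteinFragment(catseq[i : i + k]) for i in range(0, len(catseq), k)]


def fragment_protein(
    sequence: str,
    table: CategoryTable | None = None,
    k: int = 3,
    source_id: str | None = None,
) -> FragmentSequence:
    """Category-map then k-gram-split one protein sequence."""
    catseq = map_categories(sequence, table)
    return FragmentSequence(
        source_id=source_id or sequence[:16], fragments=kgram_split(catseq, k)
    )


def read_fasta(path) -> list[tuple[str, str]]:
    """Read (record id, uppercase sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
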