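"""Branch chain mining (BCM): rule-based SMILES fragmentation.

A drug SMILES string is decomposed into three typed fragment classes:

* ``branch_chain`` — maximal outermost parenthesized spans, parentheses
  stripped (nested parentheses are retained inside the fragment);
* ``common_substructure`` — literal matches against a configurable pattern
  table (benzene ring, oxygen chain, carboxyl group by default);
* ``synthetic`` — short residual token runs that cannot be split further.

Everything operates at the string/token level; no chemistry-aware graph
matching is performed (deliberately — see package docs).
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Iterable, Mapping

from .errors import MalformedSmilesError
from .fragments import DrugFragment, FragmentSequence, SmilesToken

__all__ = [
    "tokenize_smiles",
    "extract_branch_chains",
    "extract_common_substructures",
    "split_synthetic_fragments",
    "fragment_drug",
    "load_patterns",
    "default_patterns",
]

#: single-character atoms accepted outside brackets (organic subset + aromatic)
_SINGLE_ATOMS = set("BCNOPSFI") | set("bcnops")
#: two-character organic-subset atoms; must be checked before single letters
_TWO_LETTER_ATOMS = ("Cl", "Br")
_BOND_CHARS = set("-=#/\\:.")


def tokenize_smiles(smiles: str) -> list[SmilesToken]:
    """Split a SMILES string into atomic tokens.

    Tokens partition the input exactly: ``"".join(t.text for t in tokens)``
    reproduces ``smiles``. Two-letter organic-subset elements (``Cl``,
    ``Br``) are single atom tokens, bracket expressions ``[...]`` are single
    ``bracket_atom`` tokens, ring-closure digits (including ``%nn``) are
    ``ring_digit`` tokens.

    Raises
    ------
    MalformedSmilesError
        On unbalanced brackets or any character outside the accepted
        SMILES alphabet, with the offending position attached.
    """
    if not smiles:
        raise MalformedSmilesError("empty SMILES string")
    tokens: list[SmilesToken] = []
    i, n = 0, len(smiles)
    while i < n:
        c = smiles[i]
        if c == "[":
            j = smiles.find("]", i + 1)
            if j < 0:
                raise MalformedSmilesError("unclosed '['", position=i)
            if j == i + 1:
                raise MalformedSmilesError("empty bracket atom", position=i)
            tokens.append(SmilesToken(smiles[i : j + 1], "bracket_atom"))
            i = j + 1
        elif c == "]":
            raise MalformedSmilesError("unmatched ']'", position=i)
        elif smiles.startswith(_TWO_LETTER_ATOMS, i):
            tokens.append(SmilesToken(smiles[i : i + 2], "atom"))
            i += 2
        elif c in _SINGLE_ATOMS:
            tokens.append(SmilesToken(c, "atom"))
            i += 1
        elif c == "(":
            tokens.append(SmilesToken(c, "branch_open"))
            i += 1
        elif c == ")":
            tokens.append(SmilesToken(c, "branch_close"))
            i += 1
        elif c.isdigit():
            tokens.append(SmilesToken(c, "ring_digit"))
            i += 1
        elif c == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise MalformedSmilesError("'%' must be followed by two digits", position=i)
            tokens.append(SmilesToken(smiles[i : i + 3], "ring_digit"))
            i += 3
        elif c in _BOND_CHARS:
            tokens.append(SmilesToken(c, "bond"))
            i += 1
        else:
            raise MalformedSmilesError(f"character {c!r} outside SMILES alphabet", position=i)
    return tokens


def _branch_spans(tokens: list[SmilesToken]):
    """Split a token stream into top-level pieces.

    Returns a list of ``("main", tokens)`` / ``("branch", inner_tokens)``
    items in positional order. Only outermost-level parentheses delimit
    branches; nested parentheses stay inside the branch token list.
    """
    pieces = []
    current: list[SmilesToken] = []
    depth = 0
    branch: list[SmilesToken] = []
    pos = 0
    for tok in tokens:
        if tok.kind == "branch_open":
            depth += 1
            if depth == 1:
                if current:
                    pieces.append(("main", current))
                    current = []
                branch = []
            else:
                branch.append(tok)
        elif tok.kind == "branch_close":
            depth -= 1
            if depth < 0:
                raise MalformedSmilesError("unmatched ')'", position=pos)
            if depth == 0:
                if not branch:
                    raise MalformedSmilesError("empty branch '()'", position=pos)
                pieces.append(("branch", branch))
                branch = []
            else:
                branch.append(tok)
        elif depth > 0:
            branch.append(tok)
        else:
            current.append(tok)
        pos += len(tok.text)
    if depth != 0:
        raise MalformedSmilesError("unclosed '('", position=pos)
    if current:
        pieces.append(("main", current))
    return pieces


def extract_branch_chains(smiles: str) -> tuple[list[DrugFragment], str]:
    """Pull out outermost parenthesized spans as branch-chain fragments.

    The remaining top-level pieces are spliced in order into the main
    chain. Parentheses surrounding each branch are stripped; nested
    parentheses inside a branch are retained.
    """
    pieces = _branch_spans(tokenize_smiles(smiles))
    branches = [
        DrugFragment("".join(t.text for t in toks), "branch_chain")
        for kind, toks in pieces
        if kind == "branch"
    ]
    main_chain = "".join(
        t.text for kind, toks in pieces if kind == "main" for t in toks
    )
    return branches, main_chain


def _flatten_patterns(patterns) -> list[str]:
    if isinstance(patterns, Mapping):
        flat: Iterable[str] = (p for group in patterns.values() for p in group)
    else:
        flat = patterns
    out = []
    for p in flat:
        if p.count("(") != p.count(")"):
            raise ValueError(f"pattern {p!r} has unbalanced parentheses")
        out.append(p)
    # longest-first gives a deterministic greedy match at each position
    return sorted(set(out), key=lambda p: (-len(p), p))


def _common_segments(chain: str, patterns) -> list[tuple[str, str]]:
    """Left-to-right non-overlapping pattern scan over token boundaries.

    Returns ordered ``("common", text)`` / ``("span", text)`` segments.
    Matches are only accepted on whole-token boundaries so that the
    residual remains a token-valid SMILES substring (a pattern can never
    bite into half of a ``Cl`` or a bracket atom).
    """
    pats = _flatten_patterns(patterns)
    tokens = tokenize_smiles(chain) if chain else []
    segments: list[tuple[str, str]] = []
    span: list[str] = []
    i = 0
    while i < len(tokens):
        matched = None
        for p in pats:
            acc, j = "", i
            while j < len(tokens) and len(acc) < len(p):
                acc += tokens[j].text
                j += 1
            if acc == p:
                matched = (p, j)
                break
        if matched is not None:
            if span:
                segments.append(("span", "".join(span)))
                span = []
            segments.append(("common", matched[0]))
            i = matched[1]
        else:
            span.append(tokens[i].text)
            i += 1
    if span:
        segments.append(("span", "".join(span)))
    return segments


def extract_common_substructures(
    chain: str, patterns=None
) -> tuple[list[DrugFragment], str]:
    """Extract common-substructure fragments (benzene / oxygen chain /
    carboxyl by default) from a chain.

    Scans left to right without overlap; every match is removed and
    emitted, the unmatched spans are concatenated in order into the
    residual. No match means an empty fragment list and an untouched
    residual.
    """
    if patterns is None:
        patterns = default_patterns()
    segs = _common_segments(chain, patterns)
    frags = [DrugFragment(t, "common_substructure") for k, t in segs if k == "common"]
    residual = "".join(t for k, t in segs if k == "span")
    return frags, residual


def _atom_units(tokens: list[SmilesToken]) -> list[str]:
    """Group tokens into atom-level units.

    Bond symbols attach to the following atom; ring digits attach to the
    preceding unit. Keeps every unit a locally valid SMILES substring.
    """
    units: list[str] = []
    pending = ""
    for tok in tokens:
        if tok.kind == "bond":
            pending += tok.text
        elif tok.kind == "ring_digit":
            if units:
                units[-1] += pending + tok.text
            else:
                pending += tok.text
            pending = ""
        elif tok.kind in ("atom", "bracket_atom"):
            units.append(pending + tok.text)
            pending = ""
        else:  # pragma: no cover - guarded by caller
            raise MalformedSmilesError(f"unexpected token {tok.text!r} in residual")
    if pending:  # trailing bond symbols stick to the last unit
        if units:
            units[-1] += pending
        else:
            units.append(pending)
    return units


def split_synthetic_fragments(
    residual: str, max_synthetic_len: int = 3
) -> list[DrugFragment]:
    """Chunk a paren-free residual into synthetic fragments.

    The residual is grouped into atom-level units and chunked into
    consecutive windows of at most ``max_synthetic_len`` units, with a
    shorter tail. An empty residual yields an empty list.
    """
    if not residual:
        return []
    tokens = tokenize_smiles(residual)
    for pos, tok in enumerate(tokens):
        if tok.kind in ("branch_open", "branch_close"):
            raise MalformedSmilesError(
                "parentheses are not allowed in a synthetic residual", position=pos
            )
    units = _atom_units(tokens)
    return [
        DrugFragment("".join(units[i : i + max_synthetic_len]), "synthetic")
        for i in range(0, len(units), max_synthetic_len)
    ]


def _chunk_branch_residual(text: str, max_synthetic_len: int) -> list[DrugFragment]:
    """Branch residuals keep the branch_chain type.

    Paren-free residuals are chunked like synthetic runs; residuals with
    nested parentheses are kept whole (chunking could unbalance them).
    """
    if not text:
        return []
    if "(" in text or ")" in text:
        return [DrugFragment(text, "branch_chain")]
    units = _atom_units(tokenize_smiles(text))
    return [
        DrugFragment("".join(units[i : i + max_synthetic_len]), "branch_chain")
        for i in range(0, len(units), max_synthetic_len)
    ]


def fragment_drug(
    smiles: str,
    patterns=None,
    max_synthetic_len: int = 3,
    scan_main_chain: bool = True,
    scan_branches: bool = True,
    positional_order: bool = False,
    source_id: str | None = None,
) -> FragmentSequence:
    """Run the full BCM pipeline on one SMILES string.

    Branch chains are pulled out first, then the spliced main chain and
    each branch chain are scanned for common substructures, and the
    remaining residuals are chunked into synthetic fragments. Fragment
    order is deterministic: main-chain fragments in positional order,
    then branch fragments in positional order (``positional_order=True``
    interleaves branches at their original string positions instead, in
    which case main-chain pieces are scanned per-piece rather than
    spliced).

    The multiset of atom and bracket-atom tokens over all emitted
    fragments always equals that of the input.
    """
    if patterns is None:
        patterns = default_patterns()
    pieces = _branch_spans(tokenize_smiles(smiles))

    def main_fragments(text: str) -> list[DrugFragment]:
        if not text:
            return []
        if scan_main_chain:
            segs = _common_segments(text, patterns)
        else:
            segs = [("span", text)]
        out: list[DrugFragment] = []
        for kind, seg_text in segs:
            if kind == "common":
                out.append(DrugFragment(seg_text, "common_substructure"))
            else:
                out.extend(split_synthetic_fragments(seg_text, max_synthetic_len))
        return out

    def branch_fragments(text: str) -> list[DrugFragment]:
        if not scan_branches:
            return [DrugFragment(text, "branch_chain")]
        segs = _common_segments(text, patterns)
        out: list[DrugFragment] = []
        residual_parts: list[str] = []
        for kind, seg_text in segs:
            if kind == "common":
                out.append(DrugFragment(seg_text, "common_substructure"))
            else:
                residual_parts.append(seg_text)
        residual = "".join(residual_parts)
        return out + _chunk_branch_residual(residual, max_synthetic_len)

    fragments: list[DrugFragment] = []
    if positional_order:
        for kind, toks in pieces:
            text = "".join(t.text for t in toks)
            if kind == "main":
                fragments.extend(main_fragments(text))
            else:
                fragments.extend(branch_fragments(text))
    else:
        main_chain = "".join(
            t.text for kind, toks in pieces if kind == "main" for t in toks
        )
        fragments.extend(main_fragments(main_chain))
        for kind, toks in pieces:
            if kind == "branch":
                fragments.extend(branch_fragments("".join(t.text for t in toks)))

    return FragmentSequence(source_id=source_id or smiles, fragments=fragments)


def load_patterns(path) -> dict[str, list[str]]:
    """Load a pattern table from a JSON file mapping class name -> literal
    SMILES substrings."""
    with open(path) as fh:
        table = json.load(fh)
    _flatten_patterns(table)  # validates
    return table


def default_patterns() -> dict[str, list[str]]:
    """The built-in benzene / oxygen-chain / carboxyl pattern table."""
    with resources.files("fmcadti.data").joinpath("patterns.json").open() as fh:
        return json.load(fh)
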