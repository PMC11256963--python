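"""Branch chain mining: tokenizer and drug fragmentation."""

from collections import Counter

import pytest

from fmcadti.bcm import (
    default_patterns,
    extract_branch_chains,
    extract_common_substructures,
    fragment_drug,
    split_synthetic_fragments,
    tokenize_smiles,
)
from fmcadti.errors import MalformedSmilesError
from fmcadti.synth import generate_smiles


def token_texts(smiles):
    return [t.text for t in tokenize_smiles(smiles)]


class TestTokenizer:
    def test_single_char_atoms(self):
        assert token_texts("CCO") == ["C", "C", "O"]

    def test_two_letter_halogens(self):
        # hand-tokenized oracle: C, C, (, Cl, ), Br
        toks = tokenize_smiles("CC(Cl)Br")
        assert [t.text for t in toks] == ["C", "C", "(", "Cl", ")", "Br"]
        assert [t.kind for t in toks] == [
            "atom", "atom", "branch_open", "atom", "branch_close", "atom",
        ]

    def test_bracket_atom_is_single_token(self):
        toks = tokenize_smiles("[NH4+]")
        assert len(toks) == 1
        assert toks[0].text == "[NH4+]" and toks[0].kind == "bracket_atom"

    def test_ring_digits_and_percent(self):
        toks = tokenize_smiles("C1CC%12C1")
        kinds = [t.kind for t in toks]
        assert kinds == ["atom", "ring_digit", "atom", "atom", "ring_digit",
                         "atom", "ring_digit"]
        assert toks[4].text == "%12"

    @pytest.mark.parametrize(
        "smiles",
        ["CCO", "CC(=O)Oc1ccccc1", "[Na+].[Cl-]", "C/C=C\\C", "CC(Cl)(Br)C"],
    )
    def test_roundtrip_exact(self, smiles):
        assert "".join(token_texts(smiles)) == smiles

    def test_roundtrip_generated(self, rng):
        for _ in range(200):
            s = generate_smiles(rng, with_motif=bool(rng.integers(2)))
            assert "".join(token_texts(s)) == s

    @pytest.mark.parametrize("bad", ["C[NH", "C]O", "CC?", "", "%1C", "[]"])
    def test_malformed(self, bad):
        with pytest.raises(MalformedSmilesError):
            tokenize_smiles(bad)

    def test_error_carries_position(self):
        with pytest.raises(MalformedSmilesError) as exc:
            tokenize_smiles("CC?O")
        assert exc.value.position == 2


class TestBranchChains:
    def test_no_parentheses(self):
        assert extract_branch_chains("CCO") == ([], "CCO")

    def test_simple_branch(self):
        branches, main = extract_branch_chains("CC(=O)O")
        assert [b.text for b in branches] == ["=O"]
        assert main == "CCO"

    def test_nested_stays_inside(self):
        branches, main = extract_branch_chains("CC(C(=O)O)N")
        assert [b.text for b in branches] == ["C(=O)O"]
        assert main == "CCN"

    def test_multiple_branches_positional(self):
        branches, main = extract_branch_chains("C(N)C(O)C")
        assert [b.text for b in branches] == ["N", "O"]
        assert main == "CCC"

    @pytest.mark.parametrize("bad", ["C(C", "C)C", "C()C"])
    def test_unbalanced(self, bad):
        with pytest.raises(MalformedSmilesError):
            extract_branch_chains(bad)


class TestCommonSubstructures:
    def test_no_match(self):
        frags, residual = extract_common_substructures("CCC")
        assert frags == [] and residual == "CCC"

    def test_benzene(self):
        frags, residual = extract_common_substructures("c1ccccc1CCN")
        assert [f.text for f in frags] == ["c1ccccc1"]
        assert residual == "CCN"

    def test_oxygen_chain_leftmost(self):
        # leftmost non-overlapping scan by hand: "CCOCOC" matches "COC" at
        # index 1, leaving "C" + "OC" -> residual "COC"
        frags, residual = extract_common_substructures("CCOCOC")
        assert [f.text for f in frags] == ["COC"]
        assert residual == "COC"

    def test_carboxyl_inside_branch_text(self):
        frags, residual = extract_common_substructures("C(=O)O")
        assert [f.text for f in frags] == ["C(=O)O"]
        assert residual == ""

    def test_match_respects_token_boundaries(self):
        # "COC" must not bite into the "Cl" token
        frags, residual = extract_common_substructures("ClOC")
        assert frags == [] and residual == "ClOC"

    def test_all_fragments_typed(self):
        frags, _ = extract_common_substructures("c1ccccc1COC")
        assert {f.ftype for f in frags} == {"common_substructure"}


class TestSyntheticSplit:
    def test_empty(self):
        assert split_synthetic_fragments("") == []

    def test_within_limit(self):
        assert [f.text for f in split_synthetic_fragments("CCN")] == ["CCN"]

    def test_chunking(self):
        assert [f.text for f in split_synthetic_fragments("CCCCC")] == ["CCC", "CC"]

    def test_bond_attaches_forward(self):
        # units: C, =C, C, =C -> windows of 3 units
        assert [f.text for f in split_synthetic_fragments("C=CC=C")] == ["C=CC", "=C"]

    def test_ring_digit_attaches_backward(self):
        assert [f.text for f in split_synthetic_fragments("C1CCC1")] == ["C1CC", "C1"]

    def test_rejects_parentheses(self):
        with pytest.raises(MalformedSmilesError):
            split_synthetic_fragments("C(C)C")

    def test_custom_window(self):
        assert [f.text for f in split_synthetic_fragments("CCCCC", 2)] == [
            "CC", "CC", "C",
        ]


def atom_multiset(smiles):
    return Counter(
        t.text for t in tokenize_smiles(smiles) if t.kind in ("atom", "bracket_atom")
    )


class TestFragmentDrug:
    def test_plain_chain(self):
        seq = fragment_drug("CCO")
        assert [(f.ftype, f.text) for f in seq] == [("synthetic", "CCO")]

    def test_aspirin_like(self):
        seq = fragment_drug("CC(=O)Oc1ccccc1")
        got = {(f.ftype, f.text) for f in seq}
        assert got == {
            ("branch_chain", "=O"),
            ("common_substructure", "c1ccccc1"),
            ("synthetic", "CCO"),
        }

    def test_main_chain_first_then_branches(self):
        seq = fragment_drug("CC(N)c1ccccc1")
        types = [f.ftype for f in seq]
        assert types.index("branch_chain") > types.index("common_substructure")

    def test_positional_order_flag(self):
        seq = fragment_drug("CC(N)c1ccccc1", positional_order=True)
        texts = [f.text for f in seq]
        assert texts.index("N") < texts.index("c1ccccc1")

    def test_atom_conservation_generated(self, rng):
        for _ in range(300):
            s = generate_smiles(rng, with_motif=bool(rng.integers(2)))
            frags = fragment_drug(s)
            out = Counter()
            for f in frags:
                out += atom_multiset(f.text)
            assert out == atom_multiset(s), s

    def test_deterministic(self):
        s = "CC(C(=O)O)Cc1ccccc1OC"
        a = [(f.ftype, f.text) for f in fragment_drug(s)]
        b = [(f.ftype, f.text) for f in fragment_drug(s)]
        assert a == b

    def test_no_empty_fragments_and_balanced_branches(self, rng):
        for _ in range(100):
            s = generate_smiles(rng, with_motif=True)
            for f in fragment_drug(s):
                assert f.text
                if f.ftype == "branch_chain":
                    assert f.text.count("(") == f.text.count(")")

    def test_scan_flags(self):
        seq = fragment_drug("c1ccccc1", scan_main_chain=False)
        assert all(f.ftype == "synthetic" for f in seq)

    def test_propagates_malformed(self):
        with pytest.raises(MalformedSmilesError):
            fragment_drug("CC(C")

    def test_custom_pattern_table(self):
        patterns = {"amide": ["NC"]}
        seq = fragment_drug("CNCC", patterns=patterns)
        assert ("common_substructure", "NC") in [(f.ftype, f.text) for f in seq]


def test_default_patterns_structure():
    table = default_patterns()
    assert set(table) == {"benzene", "oxygen_chain", "carboxyl"}
    assert "c1ccccc1" in table["benzene"]
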