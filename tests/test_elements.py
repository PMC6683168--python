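"""Element-content core: composition table, per-sequence and proteome means."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stoichioprot.elements import (
    ELEMENTS,
    STANDARD_RESIDUES,
    CompositionTableError,
    ElementCompositionTable,
    element_content,
    element_content_many,
    load_composition_table,
    proteome_content,
    sequence_profile,
)
from conftest import element_content_oracle, side_chain_atoms_oracle

SEQS = st.text(alphabet=STANDARD_RESIDUES, min_size=1, max_size=200)


class TestCompositionTable:
    def test_builtin_matches_formula_oracle_for_all_entries(self, table):
        for res in STANDARD_RESIDUES:
            for elem in ELEMENTS:
                assert table.count(res, elem) == side_chain_atoms_oracle(res, elem), (
                    res,
                    elem,
                )

    @pytest.mark.parametrize(
        "res,elem,expected",
        [("G", "O", 0), ("D", "O", 2), ("W", "C", 9)],
    )
    def test_known_counts(self, table, res, elem, expected):
        assert table.count(res, elem) == expected

    def test_glycine_side_chain_is_a_lone_hydrogen(self, table):
        assert table.count("G", "H") == 1
        assert all(table.count("G", e) == 0 for e in "CNOS")

    def test_missing_entry_rejected(self):
        entries = {
            (r, e): 0 for r in STANDARD_RESIDUES for e in ELEMENTS
        }
        del entries[("W", "S")]
        with pytest.raises(CompositionTableError, match="W.*S"):
            ElementCompositionTable(entries)

    def test_tsv_roundtrip_and_bad_count(self, table, tmp_path):
        path = tmp_path / "table.tsv"
        with open(path, "w") as fh:
            fh.write("residue\telement\tcount\n")
            for (res, elem), n in table.entries.items():
                fh.write(f"{res}\t{elem}\t{n}\n")
        loaded = load_composition_table(path)
        assert loaded.entries == dict(table.entries)

        bad = tmp_path / "bad.tsv"
        bad.write_text("A\tC\tone\n")
        with pytest.raises(CompositionTableError, match="non-integer"):
            load_composition_table(bad)


class TestElementContent:
    @pytest.mark.parametrize(
        "seq,elem,expected",
        [
            ("GG", "O", 0.0),
            ("DDGG", "O", 1.0),
            ("GS", "O", 0.5),
            ("W", "C", 9.0),
        ],
    )
    def test_hand_counted_examples(self, seq, elem, expected):
        assert element_content(seq, elem) == pytest.approx(expected, abs=1e-15)

    def test_empty_and_all_invalid_sequences_error(self):
        with pytest.raises(ValueError):
            element_content("", "O")
        with pytest.raises(ValueError):
            element_content("XXBZ*-", "O")

    def test_nonstandard_letters_dropped_from_denominator(self):
        # X dropped: content of "DXG" equals content of "DG"
        assert element_content("DXG", "O") == element_content("DG", "O")
        profile = sequence_profile("p", "DXG")
        assert profile.length == 2
        assert profile.dropped == 1

    def test_selenocysteine_not_mapped_to_cysteine(self):
        # U is dropped entirely, so it contributes no sulfur
        assert element_content("UM", "S") == pytest.approx(1.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seq=SEQS, elem=st.sampled_from(ELEMENTS))
    def test_agrees_with_formula_expansion_oracle(self, seq, elem):
        assert element_content(seq, elem) == pytest.approx(
            element_content_oracle(seq, elem), abs=1e-12
        )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(a=SEQS, b=SEQS, elem=st.sampled_from(ELEMENTS))
    def test_concatenation_linearity(self, a, b, elem):
        la, lb = len(a), len(b)
        expected = (la * element_content(a, elem) + lb * element_content(b, elem)) / (
            la + lb
        )
        assert element_content(a + b, elem) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seq=SEQS, elem=st.sampled_from(ELEMENTS), seed=st.integers(0, 2**16))
    def test_permutation_invariance(self, seq, elem, seed):
        rng = np.random.default_rng(seed)
        shuffled = "".join(rng.permutation(list(seq)))
        assert element_content(shuffled, elem) == pytest.approx(
            element_content(seq, elem), abs=1e-12
        )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seq=SEQS)
    def test_content_bounds(self, seq):
        assert 0.0 <= element_content(seq, "O") <= 2.0
        assert 0.0 <= element_content(seq, "C") <= 9.0

    def test_vectorised_path_matches_scalar(self, table):
        rng = np.random.default_rng(5)
        seqs = [
            "".join(rng.choice(list(STANDARD_RESIDUES), size=rng.integers(1, 80)))
            for _ in range(50)
        ]
        for elem in ("O", "C", "S"):
            many = element_content_many(seqs, elem, table)
            single = [element_content(s, elem, table) for s in seqs]
            np.testing.assert_allclose(many, single, atol=1e-14)


class TestProteomeContent:
    def test_unweighted_mean_of_sequence_contents(self):
        profiles = [sequence_profile("a", "GG"), sequence_profile("b", "DDGG")]
        summary = proteome_content(profiles, "O")
        assert summary["mean"] == pytest.approx(0.5)
        assert summary["n"] == 2

    def test_long_sequence_does_not_dominate(self):
        # per-sequence average, not length-weighted pooling
        profiles = [sequence_profile("a", "D"), sequence_profile("b", "G" * 1000)]
        assert proteome_content(profiles, "O")["mean"] == pytest.approx(1.0)

    def test_single_profile_identity(self):
        p = sequence_profile("a", "DSTW")
        assert proteome_content([p], "O")["mean"] == pytest.approx(p.content["O"])

    def test_empty_collection_errors(self):
        with pytest.raises(ValueError):
            proteome_content([], "O")
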