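"""Unit and property tests for the AAC + CTD protein descriptors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtiscreen.protein import (
    ALPHABETS,
    INDEX_MAP,
    N_PROTEIN_FEATURES,
    PROPERTIES,
    NonStandardResidueError,
    STANDARD_AMINO_ACIDS,
    aac_vector,
    clean_sequence,
    composition,
    ctd_block,
    ctd_vector,
    distribution,
    encode_property,
    protein_feature_names,
    protein_features,
    transition,
)
from tests.conftest import EXAMPLE_ENCODING, EXAMPLE_SEQUENCE

sequences = st.text(alphabet=STANDARD_AMINO_ACIDS, min_size=2, max_size=300)


class TestWorkedExample:
    """The hand-verifiable hydrophobicity example, end to end."""

    def test_encoding(self):
        enc = encode_property(EXAMPLE_SEQUENCE, "hydrophobicity")
        assert enc.symbols == EXAMPLE_ENCODING
        assert (enc.n1, enc.n2, enc.n3) == (5, 10, 5)

    def test_composition(self):
        enc = encode_property(EXAMPLE_SEQUENCE, "hydrophobicity")
        assert composition(enc) == pytest.approx((25.0, 50.0, 25.0), abs=1e-9)

    def test_transition(self):
        enc = encode_property(EXAMPLE_SEQUENCE, "hydrophobicity")
        t12, t13, t23 = transition(enc)
        assert (t12, t13, t23) == pytest.approx(
            (2 / 19 * 100, 4 / 19 * 100, 3 / 19 * 100), abs=1e-9
        )
        assert [round(v, 2) for v in (t12, t13, t23)] == [10.53, 21.05, 15.79]

    def test_distribution(self):
        enc = encode_property(EXAMPLE_SEQUENCE, "hydrophobicity")
        d = distribution(enc)
        assert d[0:5] == pytest.approx((15.0, 15.0, 50.0, 55.0, 70.0), abs=1e-9)
        assert d[5:10] == pytest.approx((10.0, 25.0, 75.0, 85.0, 100.0), abs=1e-9)
        assert d[10:15] == pytest.approx((5.0, 5.0, 20.0, 40.0, 60.0), abs=1e-9)


class TestEncode:
    def test_single_group_sequence(self):
        enc = encode_property("AAAA", "hydrophobicity")
        assert enc.symbols == "2222" and enc.n2 == 4

    def test_unmapped_residue_rejected_with_position(self):
        with pytest.raises(NonStandardResidueError, match="'X'.*position 2"):
            encode_property("MTXI", "hydrophobicity")

    def test_all_alphabets_cover_all_residues(self):
        for prop in PROPERTIES:
            enc = encode_property(STANDARD_AMINO_ACIDS, prop)
            assert enc.n1 > 0 and enc.n2 > 0 and enc.n3 > 0
            assert enc.n1 + enc.n2 + enc.n3 == 20


class TestCTDComponents:
    def test_composition_trivial_and_order_free(self):
        assert composition(encode_property("KKK", "hydrophobicity")) == (100.0, 0.0, 0.0)
        fwd = composition(encode_property(EXAMPLE_SEQUENCE, "hydrophobicity"))
        rev = composition(encode_property(EXAMPLE_SEQUENCE[::-1], "hydrophobicity"))
        assert fwd == rev

    @pytest.mark.parametrize("symbols,expected", [
        ("1111", (0.0, 0.0, 0.0)),
        ("12", (100.0, 0.0, 0.0)),
    ])
    def test_transition_trivial(self, symbols, expected):
        # a residue string realizing the symbol pattern under hydrophobicity
        residue_of = {"1": "K", "2": "A", "3": "M"}
        seq = "".join(residue_of[s] for s in symbols)
        assert transition(encode_property(seq, "hydrophobicity")) == expected

    def test_transition_needs_two_residues(self):
        with pytest.raises(ValueError):
            transition(encode_property("A", "hydrophobicity"))

    def test_distribution_single_symbol_quantiles(self):
        # "222": quantile indices k = 1,1,1,2,3 -> positions 1,1,1,2,3 of 3
        d = distribution(encode_property("AAA", "hydrophobicity"))
        assert d[5:10] == pytest.approx(
            (100 / 3, 100 / 3, 100 / 3, 200 / 3, 100.0), abs=1e-9
        )
        assert d[0:5] == (0.0,) * 5 and d[10:15] == (0.0,) * 5  # absent groups


def _oracle_ctd(symbols: str):
    """Naive independent recomputation of C, T, D from first principles."""
    n = len(symbols)
    comp = tuple(symbols.count(g) * 100.0 / n for g in "123")
    trans = []
    for a, b in (("1", "2"), ("1", "3"), ("2", "3")):
        cnt = sum(
            1 for i in range(n - 1)
            if {symbols[i], symbols[i + 1]} == {a, b}
        )
        trans.append(cnt * 100.0 / (n - 1))
    dist = []
    for g in "123":
        pos = [i + 1 for i, c in enumerate(symbols) if c == g]
        if not pos:
            dist.extend([0.0] * 5)
            continue
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            k = max(1, math.floor(f * len(pos)))
            dist.append(pos[k - 1] * 100.0 / n)
    return comp, tuple(trans), tuple(dist)


def test_ctd_agrees_with_naive_oracle_on_random_sequences():
    rng = np.random.default_rng(42)
    aas = list(STANDARD_AMINO_ACIDS)
    for _ in range(1000):
        seq = "".join(rng.choice(aas, size=int(rng.integers(2, 501))))
        prop = PROPERTIES[int(rng.integers(len(PROPERTIES)))]
        enc = encode_property(seq, prop)
        expect = "".join(str(ALPHABETS[prop].groups[a]) for a in seq)
        assert enc.symbols == expect
        c_o, t_o, d_o = _oracle_ctd(enc.symbols)
        assert composition(enc) == pytest.approx(c_o, abs=1e-9)
        assert transition(enc) == pytest.approx(t_o, abs=1e-9)
        assert distribution(enc) == pytest.approx(d_o, abs=1e-9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(seq=sequences, prop=st.sampled_from(PROPERTIES))
def test_ctd_invariants(seq, prop):
    enc = encode_property(seq, prop)
    c = composition(enc)
    assert sum(c) == pytest.approx(100.0, abs=1e-9)
    t = transition(enc)
    assert sum(t) <= 100.0 + 1e-9
    d = distribution(enc)
    assert all(0.0 <= v <= 100.0 for v in d)
    for g in range(3):
        block = d[5 * g: 5 * g + 5]
        if enc.count(g + 1) > 0:
            assert all(a <= b + 1e-9 for a, b in zip(block, block[1:]))


class TestAAC:
    def test_single_residue_type(self):
        v = aac_vector("AAAA")
        assert v[0] == 100.0 and v[1:].sum() == 0.0

    def test_four_distinct_residues(self):
        v = aac_vector("ACDE")
        assert sorted(v[v > 0]) == [25.0] * 4

    def test_example_sequence_alanine_fraction(self):
        # 4 of the 20 residues are A
        v = aac_vector(EXAMPLE_SEQUENCE)
        assert v[STANDARD_AMINO_ACIDS.index("A")] == pytest.approx(20.0)

    def test_sums_to_100(self):
        assert aac_vector(EXAMPLE_SEQUENCE).sum() == pytest.approx(100.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aac_vector("")


class TestFullVector:
    def test_lengths(self):
        assert len(ctd_block("MK", "charge")) == 21
        assert len(ctd_vector("MK")) == 147
        assert len(protein_features(EXAMPLE_SEQUENCE)) == 167
        assert np.isfinite(protein_features("MK").values).all()

    def test_determinism(self):
        a = protein_features(EXAMPLE_SEQUENCE).values
        b = protein_features(EXAMPLE_SEQUENCE).values
        assert np.array_equal(a, b)

    def test_index_map_disjoint_and_exhaustive(self):
        covered = []
        for name, sl in INDEX_MAP.items():
            covered.extend(range(sl.start, sl.stop))
            assert (sl.stop - sl.start) == (20 if name == "aac" else 21)
        assert sorted(covered) == list(range(N_PROTEIN_FEATURES))

    def test_masking_one_property_slice(self):
        pf = protein_features(EXAMPLE_SEQUENCE)
        sl = pf.index_map["hydrophobicity"]
        remaining_ctd = 147 - (sl.stop - sl.start)
        assert remaining_ctd == 126
        assert len(pf.block("hydrophobicity")) == 21

    def test_feature_names(self):
        names = protein_feature_names()
        assert len(names) == 167 and len(set(names)) == 167
        assert names[3] == "hydrophobicity.T.1-2"
        assert names[-20] == "aac.A"


class TestCleanSequence:
    def test_reject_names_offender(self):
        with pytest.raises(NonStandardResidueError, match="'B'"):
            clean_sequence("MKB")

    def test_strip_removes_nonstandard(self):
        assert clean_sequence("MXK-B*Z", on_nonstandard="strip") == "MK"
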