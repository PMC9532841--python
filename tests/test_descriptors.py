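"""Descriptor calculus: charge, hydrophobicity, moment, wheel geometry.

The frozen expected values are the published descriptor table of the four
study peptides, which the Fauchère–Pliška convention reproduces exactly.
The hydrophobic-moment implementation is additionally checked against an
independent complex-exponential oracle.
"""

import cmath
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latamp.descriptors import (
    ALPHA_HELIX_DELTA,
    INCLUDE_TERMINI,
    SIDE_CHAINS,
    describe,
    hydrophobic_fraction,
    hydrophobic_moment,
    mean_hydrophobicity,
    net_charge,
    wheel_projection,
)
from latamp.peptides import validate_sequence
from latamp.scales import CANONICAL_RESIDUES, FAUCHERE_PLISKA

residue_strings = st.text(alphabet=CANONICAL_RESIDUES, min_size=1, max_size=30)


def moment_oracle(seq: str, delta: float = ALPHA_HELIX_DELTA) -> float:
    """Independent mu_H: complex-exponential summation."""
    z = sum(
        FAUCHERE_PLISKA[r] * cmath.exp(1j * math.radians(delta * n))
        for n, r in enumerate(seq)
    )
    return abs(z) / len(seq)


class TestNetCharge:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("LAKKLAKYLKKAL", 5),   # Lt-MAP3
            ("MAKKLKEYMEKLK", 3),   # parent helix core
            ("LAKKLKEYLEKLV", 2),   # Lt-MAP1
            ("LIKKLKEYLKKLI", 4),   # Lt-MAP2
            ("AAAAA", 0),
            ("HHHH", 0),            # histidine neutral at pH 7
        ],
    )
    def test_side_chain_model(self, seq, expected):
        assert net_charge(validate_sequence(seq), SIDE_CHAINS) == expected

    def test_n_terminus_inclusive_model(self, ltc3a):
        # side chains give +5; counting the protonated N-terminal amine
        # reproduces the database convention of +6 for the parent
        assert net_charge(ltc3a, SIDE_CHAINS) == 5
        assert net_charge(ltc3a, INCLUDE_TERMINI) == 6
        assert net_charge(ltc3a, INCLUDE_TERMINI, count_c_terminus=True) == 5


class TestHydrophobicity:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("SWKSMAKKLKEYMEKLKQRA", 0.058),
            ("LAKKLKEYLEKLV", 0.312),
            ("LIKKLKEYLKKLI", 0.444),
            ("LAKKLAKYLKKAL", 0.288),
        ],
    )
    def test_published_means(self, seq, expected):
        assert round(mean_hydrophobicity(validate_sequence(seq)), 3) == expected

    def test_single_residue_mean_is_scale_value(self):
        assert mean_hydrophobicity(validate_sequence("L")) == FAUCHERE_PLISKA["L"]

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("SWKSMAKKLKEYMEKLKQRA", 35),  # 7/20
            ("LAKKLKEYLEKLV", 46),         # 6/13 truncated
            ("LIKKLKEYLKKLI", 46),
            ("LAKKLAKYLKKAL", 53),         # 7/13 = 53.8 truncates to 53
            ("MAKKLKEYMEKLK", 38),         # 5/13
            ("KKKKK", 0),
        ],
    )
    def test_hydrophobic_percentage_truncates(self, seq, expected):
        assert hydrophobic_fraction(validate_sequence(seq)) == expected


class TestHydrophobicMoment:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("SWKSMAKKLKEYMEKLKQRA", 0.575),
            ("LAKKLKEYLEKLV", 0.740),
            ("LIKKLKEYLKKLI", 0.839),
            ("LAKKLAKYLKKAL", 0.701),
        ],
    )
    def test_published_moments(self, seq, expected):
        mu = hydrophobic_moment(validate_sequence(seq))
        assert round(mu, 3) == expected

    @pytest.mark.parametrize("res", ["L", "K", "W"])
    def test_homopolymer_null_at_full_turns(self, res):
        # 18 residues x 100 degrees = 5 full turns: vectors cancel exactly
        mu = hydrophobic_moment(validate_sequence(res * 18))
        assert mu == pytest.approx(0.0, abs=1e-9)

    @given(residue_strings)
    @settings(max_examples=100, deadline=None)
    def test_oracle_equivalence(self, seq):
        mu = hydrophobic_moment(validate_sequence(seq))
        assert mu == pytest.approx(moment_oracle(seq), abs=1e-9)

    @given(residue_strings)
    @settings(max_examples=100, deadline=None)
    def test_reversal_with_negated_delta_invariance(self, seq):
        fwd = hydrophobic_moment(validate_sequence(seq), delta=100.0)
        rev = hydrophobic_moment(validate_sequence(seq[::-1]), delta=-100.0)
        assert fwd == pytest.approx(rev, abs=1e-9)

    @given(residue_strings)
    @settings(max_examples=100, deadline=None)
    def test_moment_is_nonnegative(self, seq):
        assert hydrophobic_moment(validate_sequence(seq)) >= 0.0


class TestWheel:
    def test_first_residue_at_zero(self, map3):
        w = wheel_projection(map3)
        assert w.entries[0].angle == 0.0

    def test_angle_formula(self, map3):
        # residue 4 of a 13-mer at 100 deg/residue: 300 mod 360
        w = wheel_projection(map3)
        assert w.entries[3].angle == pytest.approx(300.0)
        for e in w.entries:
            assert e.angle == pytest.approx((100.0 * (e.index - 1)) % 360.0)

    def test_entries_cover_each_residue_once(self, ltc3a):
        w = wheel_projection(ltc3a)
        assert [e.index for e in w.entries] == list(range(1, len(ltc3a) + 1))
        assert "".join(e.residue for e in w.entries) == ltc3a.residues

    def test_leucines_on_hydrophobic_face(self, map3):
        # All four leucines of LAKKLAKYLKKAL must sit in the half-plane
        # centred on the moment direction (checked by hand from the per-
        # residue angles 0, 40, 80, 120 and the mu_H vector direction).
        w = wheel_projection(map3)
        leu_positions = [i + 1 for i, r in enumerate(map3.residues) if r == "L"]
        assert leu_positions == [1, 5, 9, 13]
        assert all(w.in_face(i) for i in leu_positions)

    def test_hydrophobic_flags_match_set(self, map2):
        w = wheel_projection(map2)
        for e in w.entries:
            assert e.hydrophobic == (e.residue in set("ACFILMVW"))


class TestDescribe:
    def test_bundles_published_values(self, map1, map3):
        d1 = describe(map1)
        assert (d1.Z, d1.H, d1.H_pct, d1.muH) == (2, 0.312, 46, 0.740)
        d3 = describe(map3)
        assert (d3.Z, d3.H, d3.H_pct, d3.muH) == (5, 0.288, 53, 0.701)

    def test_provenance_fields(self, map2):
        d = describe(map2)
        assert d.scale_name == "fauchere-pliska"
        assert d.charge_model == SIDE_CHAINS
        assert d.length == 13

    def test_two_glycines(self):
        d = describe(validate_sequence("GG"))
        assert d.Z == 0
        assert d.H == round(FAUCHERE_PLISKA["G"], 3)
        assert d.H_pct == 0
        assert d.muH >= 0
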