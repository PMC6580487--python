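"""Property-calculation tests.

The mass oracle here is deliberately independent of the package's residue
mass table: it sums *atomic* masses over per-residue elemental compositions
written out in this file.
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdpqc.peptide_props import (
    PeptideSequence,
    SequenceError,
    average_mass,
    find_duplicates,
    hydrophobicity,
    molecular_properties,
    monoisotopic_mass,
    net_charge,
    parse_sequence,
    theoretical_mz,
    validate_mz,
)

# ---- independent oracle data -------------------------------------------------
# residue formulas (C, H, N, O, S); atomic masses typed in from standard tables
ORACLE_FORMULAS = {
    "G": (2, 3, 1, 1, 0), "A": (3, 5, 1, 1, 0), "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0), "V": (5, 9, 1, 1, 0), "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1), "L": (6, 11, 1, 1, 0), "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0), "D": (4, 5, 1, 3, 0), "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0), "E": (5, 7, 1, 3, 0), "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0), "F": (9, 9, 1, 1, 0), "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0), "W": (11, 10, 2, 1, 0),
}
MONO_ATOM = {"C": 12.0, "H": 1.00782503, "N": 14.00307401, "O": 15.99491462,
             "S": 31.97207069}
AVG_ATOM = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=1, max_size=40)


def oracle_mass(seq: str, atom_masses: dict) -> float:
    """Atomic-composition sum incl. water and the disulfide H2 loss."""
    c = h = n = o = s = 0
    for aa in seq:
        dc, dh, dn, do, ds = ORACLE_FORMULAS[aa]
        c, h, n, o, s = c + dc, h + dh, n + dn, o + do, s + ds
    h += 2  # water
    o += 1
    h -= 2 * (seq.count("C") // 2)  # two H atoms per disulfide
    return (c * atom_masses["C"] + h * atom_masses["H"] + n * atom_masses["N"]
            + o * atom_masses["O"] + s * atom_masses["S"])


class TestParseSequence:
    def test_counts(self):
        pep = parse_sequence("ACDCK")
        assert (pep.n_cys, pep.n_disulfides) == (2, 1)

    def test_no_cysteines(self):
        pep = parse_sequence("GGGGG")
        assert (pep.n_cys, pep.n_disulfides) == (0, 0)

    def test_odd_cysteine_count_leaves_free_thiol(self):
        pep = parse_sequence("CCC")
        assert (pep.n_disulfides, pep.n_free_thiols) == (1, 1)

    def test_canonicalization(self):
        pep = parse_sequence("  ac d\nK ")
        assert pep.sequence == "ACDK"

    def test_invalid_residue_named(self):
        with pytest.raises(SequenceError, match="'X'"):
            parse_sequence("ACXDK")

    def test_ambiguity_code_message(self):
        with pytest.raises(SequenceError, match="selenocysteine"):
            parse_sequence("ACUDK")

    def test_empty_rejected(self):
        with pytest.raises(SequenceError, match="empty"):
            parse_sequence("   ")


class TestMasses:
    def test_glycine_monoisotopic(self):
        assert monoisotopic_mass("G") == pytest.approx(75.03203, abs=1e-4)

    def test_glycine_average(self):
        assert average_mass("G") == pytest.approx(75.067, abs=5e-3)

    def test_disulfide_correction_cc(self):
        uncorrected = monoisotopic_mass(
            PeptideSequence(sequence="CC", n_cys=2, n_disulfides=0)
        )
        assert monoisotopic_mass("CC") == pytest.approx(uncorrected - 2.01565, abs=1e-4)

    def test_correction_identity_exact(self):
        for seq, n in [("CC", 1), ("CCCC", 2), ("ACDCKCC", 2)]:
            for mass_fn, m_h in [(monoisotopic_mass, 1.0078250319), (average_mass, 1.008)]:
                uncorr = mass_fn(
                    PeptideSequence(sequence=seq, n_cys=seq.count("C"), n_disulfides=0)
                )
                assert mass_fn(seq) == pytest.approx(uncorr - 2 * n * m_h, abs=1e-12)

    def test_cysteine_free_unaffected(self):
        pep = parse_sequence("GAVLK")
        forced = PeptideSequence(sequence="GAVLK", n_cys=0, n_disulfides=0)
        assert monoisotopic_mass(pep) == monoisotopic_mass(forced)

    @given(sequences)
    @settings(max_examples=200, deadline=None)
    def test_against_composition_oracle(self, seq):
        assert monoisotopic_mass(seq) == pytest.approx(
            oracle_mass(seq, MONO_ATOM), abs=1e-4
        )
        assert average_mass(seq) == pytest.approx(oracle_mass(seq, AVG_ATOM), abs=0.05)

    @given(sequences)
    @settings(max_examples=200, deadline=None)
    def test_average_at_least_monoisotopic(self, seq):
        assert average_mass(seq) >= monoisotopic_mass(seq)


class TestNetCharge:
    def test_gg_matches_two_term_hand_sum(self):
        # EMBOSS: N-term 8.6, C-term 3.6
        for ph in (3.0, 7.4, 10.0):
            expected = 1.0 / (1.0 + 10.0 ** (ph - 8.6)) - 1.0 / (1.0 + 10.0 ** (3.6 - ph))
            assert net_charge("GG", ph=ph) == pytest.approx(expected, abs=1e-6)

    def test_half_charge_at_pka(self):
        # at pH == N-terminal pKa the basic term is exactly +0.5
        c_term = -1.0 / (1.0 + 10.0 ** (3.6 - 8.6))
        assert net_charge("GG", ph=8.6) - c_term == pytest.approx(0.5, abs=1e-12)
        # at pH == C-terminal pKa the acidic term is exactly -0.5
        n_term = 1.0 / (1.0 + 10.0 ** (3.6 - 8.6))
        assert net_charge("GG", ph=3.6) - n_term == pytest.approx(-0.5, abs=1e-12)

    def test_disulfide_cysteines_carry_no_thiol_charge(self):
        # 2 bonded Cys contribute nothing; compare against a Cys-free analog
        with_ss = net_charge("GCCG", ph=11.0)
        without = net_charge("GGGG", ph=11.0)
        assert with_ss == pytest.approx(without, abs=1e-9)

    def test_free_thiol_contributes(self):
        # odd Cys count: one thiol in the acidic set
        odd = net_charge("GCG", ph=11.0)
        none = net_charge("GGG", ph=11.0)
        assert odd < none

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_ph(self, seq):
        grid = [1 + 0.5 * k for k in range(25)]  # 1 .. 13
        values = [net_charge(seq, ph=ph) for ph in grid]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_acid_and_base_limits(self):
        for seq in ("GKRH", "GDEYC", "ACDCKRHEY", "W"):
            pep = parse_sequence(seq)
            lo = net_charge(pep, ph=0.5)
            hi = net_charge(pep, ph=13.5)
            n_basic = 1 + sum(seq.count(a) for a in "KRH")
            n_acidic = 1 + sum(seq.count(a) for a in "DEY") + pep.n_free_thiols
            assert lo == pytest.approx(n_basic, abs=0.2)
            assert hi == pytest.approx(-n_acidic, abs=0.2)

    def test_invalid_ph(self):
        with pytest.raises(ValueError):
            net_charge("GG", ph=0.0)

    def test_unknown_pka_table(self):
        with pytest.raises(ValueError, match="unknown pKa table"):
            net_charge("GG", pka_table="nope")


class TestHydrophobicity:
    def test_single_residue_exact(self):
        assert hydrophobicity("I") == 4.5  # Kyte-Doolittle I
        assert hydrophobicity("R") == -4.5

    def test_gg_equals_g_value(self):
        assert hydrophobicity("GG") == pytest.approx(-0.4)

    @given(sequences, sequences)
    @settings(max_examples=100, deadline=None)
    def test_concatenation_mean_decomposition(self, a, b):
        combined = hydrophobicity(a + b)
        expected = (len(a) * hydrophobicity(a) + len(b) * hydrophobicity(b)) / (
            len(a) + len(b)
        )
        assert combined == pytest.approx(expected, abs=1e-9)

    def test_unknown_scale(self):
        with pytest.raises(ValueError, match="unknown hydrophobicity scale"):
            hydrophobicity("GG", scale="nope")


class TestValidateMz:
    def test_round_trip_z2(self):
        mz = theoretical_mz("ACDCKGHW", 2)
        match = validate_mz(mz, "ACDCKGHW", max_charge=6, tol_ppm=20)
        assert match.valid
        assert match.matched_charge == 2

    def test_out_of_band(self):
        mz = theoretical_mz("ACDCKGHW", 2)
        off = mz * (1 + 10 * 20e-6)
        assert not validate_mz(off, "ACDCKGHW", max_charge=6, tol_ppm=20).valid

    def test_z1_is_mass_plus_proton(self):
        m = monoisotopic_mass("GAVLK")
        assert theoretical_mz("GAVLK", 1) == pytest.approx(m + 1.00728, abs=1e-4)

    @given(sequences, st.integers(1, 6))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_completeness(self, seq, z):
        match = validate_mz(theoretical_mz(seq, z), seq, max_charge=6, tol_ppm=20)
        assert match.valid
        assert match.matched_charge <= z  # smallest matching charge reported

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            validate_mz(-1.0, "GG")
        with pytest.raises(ValueError):
            validate_mz(100.0, "GG", max_charge=0)
        with pytest.raises(ValueError):
            theoretical_mz("GG", 0)


class TestDuplicates:
    def test_registry_duplicate(self):
        dups = find_duplicates(["ACD"], {"ACD"})
        assert len(dups) == 1
        assert dups[0].matches == "registry"

    def test_within_batch_duplicate(self):
        dups = find_duplicates(["ACD", "ACD"], set())
        assert len(dups) == 1
        assert dups[0].index == 1
        assert dups[0].matches == "batch"

    def test_case_insensitive(self):
        dups = find_duplicates(["acd"], {"ACD"})
        assert len(dups) == 1

    def test_no_duplicates(self):
        assert find_duplicates(["ACD", "ACE"], {"ACF"}) == []


def test_molecular_properties_bundle():
    props = molecular_properties("ACDCK")
    assert props.monoisotopic_mass == pytest.approx(
        oracle_mass("ACDCK", MONO_ATOM), abs=1e-4
    )
    assert props.average_mass > props.monoisotopic_mass
    assert math.isfinite(props.net_charge_ph74)
    assert props.hydrophobicity == pytest.approx(
        (1.8 + 2.5 - 3.5 + 2.5 - 3.9) / 5, abs=1e-9
    )
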