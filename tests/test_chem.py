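"""Mass/composition tests, checked against an independent residue-sum oracle.

The oracle uses literature monoisotopic residue masses (ExPASy values) typed
in independently of the package's element-composition route, so the two paths
cannot share a bug.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peptiquant import chem
from peptiquant.chem import (
    ADDUCTS,
    C_TERMINAL_AMIDE,
    PYROGLUTAMATE,
    Adduct,
    Modification,
    PeptideSpecies,
    ProhormoneAnnotation,
    adduct_mz,
    average_mass,
    elemental_composition,
    isotope_envelope,
    make_akh,
    make_akh_star,
    make_akhgk,
    monoisotopic_mass,
    process_prohormone,
)
from peptiquant.errors import InputError, ProcessingError

# --- independent oracle -----------------------------------------------------

ORACLE_RESIDUE_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
ORACLE_WATER = 18.010565
ORACLE_NH3 = 17.026549
ORACLE_AMIDE = -0.984016  # OH -> NH2
ORACLE_PROTON = 1.007276
ORACLE_LABEL_13C6_15N = 6 * 1.003355 + 0.997035  # 7.017165


def oracle_mass(sequence, pyroglu=False, amide=False, label=0.0):
    m = sum(ORACLE_RESIDUE_MONO[ch] for ch in sequence) + ORACLE_WATER
    if pyroglu:
        m -= ORACLE_NH3
    if amide:
        m += ORACLE_AMIDE
    return m + label


# --- elemental composition --------------------------------------------------


class TestElementalComposition:
    def test_free_glycine(self):
        comp = elemental_composition(PeptideSpecies("G", "G"))
        assert comp == {"C": 2, "H": 5, "N": 1, "O": 2}

    def test_peptide_bond_bookkeeping(self):
        gg = elemental_composition(PeptideSpecies("GG", "GG"))
        g = elemental_composition(PeptideSpecies("G", "G"))
        two_free = {el: 2 * n for el, n in g.items()}
        minus_water = dict(two_free)
        minus_water["H"] -= 2
        minus_water["O"] -= 1
        assert gg == minus_water

    def test_heavy_label_atoms(self):
        comp = elemental_composition(make_akh_star())
        assert comp["13C"] == 6
        assert comp["15N"] == 1
        light = elemental_composition(make_akh())
        assert comp["C"] == light["C"] - 6
        assert comp["N"] == light["N"] - 1

    def test_unknown_residue_names_offender(self):
        with pytest.raises(InputError, match="'Z'"):
            elemental_composition(PeptideSpecies("bad", "GZG"))

    def test_residue_table_matches_oracle(self):
        for code, mass in ORACLE_RESIDUE_MONO.items():
            assert chem.DEFAULT_RESIDUES.monoisotopic(code) == pytest.approx(mass, abs=1e-4)


# --- masses -----------------------------------------------------------------


class TestMasses:
    def test_native_akh(self):
        expected = oracle_mass("QLTFSPDW", pyroglu=True, amide=True)
        assert expected == pytest.approx(974.4498, abs=1e-3)
        assert monoisotopic_mass(make_akh()) == pytest.approx(expected, abs=1e-4)

    def test_akhgk(self):
        expected = oracle_mass("QLTFSPDWGK", pyroglu=True)
        assert expected == pytest.approx(1160.5502, abs=1e-3)
        assert monoisotopic_mass(make_akhgk()) == pytest.approx(expected, abs=1e-4)

    def test_labelled_standard_printed_mass(self):
        neutral = monoisotopic_mass(make_akh_star())
        oracle = oracle_mass("QLTFSPDW", pyroglu=True, amide=True, label=ORACLE_LABEL_13C6_15N)
        assert neutral == pytest.approx(oracle, abs=1e-3)
        protonated = neutral + ORACLE_PROTON
        assert protonated == pytest.approx(982.474, abs=1e-3)
        assert round(protonated, 1) == 982.5

    def test_label_delta(self):
        delta = monoisotopic_mass(make_akh_star()) - monoisotopic_mass(make_akh())
        assert delta == pytest.approx(7.0172, abs=5e-4)

    def test_water_average_mass(self):
        water = PeptideSpecies("g", "G")
        # average mass of water via element table
        avg_water = 2 * chem.AVERAGE_MASS["H"] + chem.AVERAGE_MASS["O"]
        assert avg_water == pytest.approx(18.015, abs=2e-3)

    def test_average_mass_against_formula_oracle(self):
        # independent average-mass oracle from the AKH* formula
        # C41(13C)6 H62 N9(15N) O13
        avg = (
            41 * 12.0107 + 6 * 13.00335 + 62 * 1.00794
            + 9 * 14.0067 + 15.00011 + 13 * 15.9994
        )
        assert average_mass(make_akh_star()) == pytest.approx(avg, abs=5e-3)
        # labelled vs unlabelled average differ by ~7.0 Da
        assert average_mass(make_akh_star()) - average_mass(make_akh()) == pytest.approx(
            6.949, abs=0.01
        )


# --- adducts ----------------------------------------------------------------


class TestAdducts:
    @pytest.mark.parametrize(
        "adduct,expected",
        [("[M+Na]+", 997.439), ("[M+K]+", 1013.413)],
    )
    def test_akh_adducts(self, adduct, expected):
        assert adduct_mz(974.4498, adduct) == pytest.approx(expected, abs=1e-3)

    def test_akhgk_protonated(self):
        assert adduct_mz(1160.5502, "[M+H]+") == pytest.approx(1161.557, abs=1e-3)

    def test_unknown_adduct(self):
        with pytest.raises(InputError):
            adduct_mz(1000.0, "[M+Cs]+")

    def test_nonpositive_mass(self):
        with pytest.raises(InputError):
            adduct_mz(0.0, "[M+H]+")

    def test_charge_and_shift_invariants(self):
        for adduct in ADDUCTS.values():
            assert adduct.charge == 1
            assert adduct.shift > 0
        with pytest.raises(InputError):
            Adduct("bad", 22.99, charge=2)


# --- isotope envelopes ------------------------------------------------------


def brute_force_envelope(composition, n_peaks):
    """Independent polynomial-convolution oracle (pure python lists)."""
    dist = [1.0]
    for el, n in composition.items():
        if el in chem.LABEL_REPLACES:
            continue
        single = list(chem.ISOTOPE_ABUNDANCE[el])
        for _ in range(n):
            new = [0.0] * min(n_peaks, len(dist) + len(single) - 1)
            for i, a in enumerate(dist):
                for j, b in enumerate(single):
                    if i + j < len(new):
                        new[i + j] += a * b
            dist = new
    return dist[:n_peaks]


class TestIsotopeEnvelope:
    def test_single_carbon(self):
        env = isotope_envelope({"C": 1}, 2)
        assert [a for _, a in env] == pytest.approx([0.9893, 0.0107], abs=1e-6)

    def test_pure_heavy_carbon(self):
        env = isotope_envelope({"13C": 10}, 3)
        abundances = [a for _, a in env]
        assert abundances[0] == pytest.approx(1.0)
        assert abundances[1:] == pytest.approx([0.0, 0.0])

    def test_akh_second_isotopologue_ratio(self):
        comp = elemental_composition(make_akh())
        env = isotope_envelope(comp, 4)
        ratio = env[1][1] / env[0][1]
        assert 0.55 <= ratio <= 0.60
        oracle = brute_force_envelope(comp, 4)
        assert [a for _, a in env] == pytest.approx(oracle, rel=1e-9)

    def test_offsets_are_isotope_spacings(self):
        env = isotope_envelope({"C": 10}, 3)
        assert env[0][0] == 0.0
        assert env[1][0] == pytest.approx(1.00335, abs=1e-4)

    def test_n_peaks_validation(self):
        with pytest.raises(InputError):
            isotope_envelope({"C": 1}, 1)

    def test_envelope_properties(self):
        for sp in (make_akh(), make_akhgk(), make_akh_star()):
            env = isotope_envelope(elemental_composition(sp), 8)
            abundances = np.array([a for _, a in env])
            assert np.all(abundances >= 0)
            assert abundances.sum() <= 1.0 + 1e-12

    def test_labelled_envelope_is_shifted_light_envelope(self):
        # positions: shifted by the label delta; shape: close (the label removes
        # six carbons from the spread, so abundances match only approximately)
        light = isotope_envelope(elemental_composition(make_akh()), 5)
        heavy = isotope_envelope(elemental_composition(make_akh_star()), 5)
        assert [o for o, _ in heavy] == pytest.approx([o for o, _ in light])
        for (_, a_l), (_, a_h) in zip(light, heavy):
            assert a_h == pytest.approx(a_l, abs=0.05)


# --- property tests ---------------------------------------------------------

_SEQ = st.text(alphabet=sorted(ORACLE_RESIDUE_MONO), min_size=1, max_size=30)


class TestProperties:
    @given(a=_SEQ, b=_SEQ)
    @settings(max_examples=100, deadline=None)
    def test_mass_additivity(self, a, b):
        m_ab = monoisotopic_mass(PeptideSpecies("ab", a + b))
        m_a = monoisotopic_mass(PeptideSpecies("a", a))
        m_b = monoisotopic_mass(PeptideSpecies("b", b))
        water = 2 * chem.MONOISOTOPIC_MASS["H"] + chem.MONOISOTOPIC_MASS["O"]
        assert m_ab == pytest.approx(m_a + m_b - water, abs=1e-4)

    @given(seq=_SEQ)
    @settings(max_examples=50, deadline=None)
    def test_oracle_agreement_random_sequences(self, seq):
        assert monoisotopic_mass(PeptideSpecies("s", seq)) == pytest.approx(
            oracle_mass(seq), abs=1e-3
        )


# --- species validation -----------------------------------------------------


class TestSpeciesValidation:
    def test_empty_sequence(self):
        with pytest.raises(InputError):
            PeptideSpecies("x", "")

    def test_two_nterm_mods(self):
        with pytest.raises(InputError):
            PeptideSpecies("x", "QW", (PYROGLUTAMATE, Modification("other", "nterm", {"H": -1})))

    def test_label_out_of_bounds(self):
        with pytest.raises(InputError):
            PeptideSpecies("x", "QW", labels={5: {"13C": 1}})

    def test_modification_mass_delta(self):
        assert C_TERMINAL_AMIDE.mass_delta == pytest.approx(ORACLE_AMIDE, abs=1e-4)
        assert PYROGLUTAMATE.mass_delta == pytest.approx(-ORACLE_NH3, abs=1e-4)


# --- prohormone processing --------------------------------------------------


def toy_annotation(precursor="MKLQLTFSPDWGKRAPE"):
    return ProhormoneAnnotation(
        precursor=precursor,
        signal_end=3,
        peptide_span=(3, 11),
        linker_span=(11, 14),
        cterm_span=(14, len(precursor)),
    )


class TestProhormoneProcessing:
    def test_maturation_chain(self):
        out = process_prohormone(toy_annotation())
        seqs = [sp.sequence for sp in out]
        assert seqs == [
            "QLTFSPDWGKRAPE",  # pro-peptide after SP removal
            "QLTFSPDWGKR",  # PC cleavage after the dibasic pair
            "QLTFSPDWGK",
            "QLTFSPDWG",
            "QLTFSPDW",  # amidated mature peptide
        ]
        mature = out[-1]
        mod_names = {m.name for m in mature.modifications}
        assert mod_names == {"amide", "pyroGlu"}

    def test_no_pyroglutamate_without_qn_terminus(self):
        ann = toy_annotation("MKLALTFSPDWGKRAPE".replace("Q", "A", 1))
        out = process_prohormone(ann)
        assert all(m.name != "pyroGlu" for m in out[-1].modifications)

    def test_masses_match_mass_module(self):
        out = process_prohormone(toy_annotation())
        akhgk_like = next(sp for sp in out if sp.sequence == "QLTFSPDWGK")
        # free acid, no pyroGlu yet in the chain intermediate
        assert monoisotopic_mass(akhgk_like) == pytest.approx(
            oracle_mass("QLTFSPDWGK"), abs=1e-3
        )
        mature = out[-1]
        assert monoisotopic_mass(mature) == pytest.approx(
            monoisotopic_mass(make_akh()), abs=1e-6
        )

    def test_carboxypeptidase_chain_masses_strictly_decrease(self):
        out = process_prohormone(toy_annotation())
        masses = [monoisotopic_mass(sp) for sp in out[1:]]
        assert all(a > b for a, b in zip(masses, masses[1:]))

    def test_no_pc_site(self):
        ann = ProhormoneAnnotation(
            precursor="MKLQLTFSPDWGAGAPE",
            signal_end=3,
            peptide_span=(3, 11),
            linker_span=(11, 14),
            cterm_span=(14, 17),
        )
        with pytest.raises(ProcessingError, match="no PC site"):
            process_prohormone(ann)

    def test_spans_must_tile(self):
        with pytest.raises(InputError):
            ProhormoneAnnotation(
                precursor="MKLQLTFSPDWGKRAPE",
                signal_end=3,
                peptide_span=(4, 11),
                linker_span=(11, 14),
                cterm_span=(14, 17),
            )
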