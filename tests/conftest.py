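import numpy as np
import pytest

from peptiquant import builtin_species
from peptiquant.process import process_spectrum
from peptiquant.quantify import quantify_sample, standard_amount
from peptiquant.simulate import GroundTruth, InstrumentModel, simulate_spectrum


@pytest.fixture(scope="session")
def species_map():
    return builtin_species()


@pytest.fixture(scope="session")
def species_list(species_map):
    return list(species_map.values())


@pytest.fixture(scope="session")
def instrument():
    return InstrumentModel()


@pytest.fixture(scope="session")
def quiet_instrument():
    """Noise-free, baseline-free instrument for exact-recovery tests."""
    return InstrumentModel(noise_sd=0.0, baseline_amplitude=0.0)


@pytest.fixture(scope="session")
def run_sample(species_list):
    """Simulate one CC spectrum and run the full processing + quantification."""

    def _run(amounts_fmol, instrument, seed=0, suppression_sigma=0.5, **truth_kwargs):
        truth = GroundTruth(
            amounts_fmol=amounts_fmol,
            suppression_sigma=suppression_sigma,
            **truth_kwargs,
        )
        spectrum = simulate_spectrum(truth, species_list, instrument, seed=seed)
        groups = process_spectrum(spectrum, species_list)
        std_fmol = standard_amount(truth.standard_nM, truth.matrix_nl)
        return quantify_sample(groups, truth.standard_name, std_fmol, "sample")

    return _run
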