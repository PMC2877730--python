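"""Synthetic direct-profiling MALDI-TOF spectra of single corpora cardiaca.

Generates profile spectra with known ground truth: Gaussian adduct peaks with
full isotope envelopes, a shared per-spectrum ion-suppression factor, optional
hyperbolic ionization saturation, exponential chemical baseline, detector
noise, subspectrum averaging and a low-mass gate. Everything is driven by a
numpy Generator so output is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import chem
from .chem import ADDUCT_ORDER, PeptideSpecies
from .errors import InputError
from .spectrum import Spectrum

#: peak area per nM of effective concentration (arbitrary intensity units)
INTENSITY_PER_NM = 10.0

#: default adduct partitions (fractions over [M+H]+/[M+Na]+/[M+K]+).
#: Generator conventions: the mature hormone ionizes almost exclusively as
#: Na/K adducts, the Gly-Lys-extended intermediate also protonates.
DEFAULT_ADDUCT_FRACTIONS: Dict[str, Tuple[float, float, float]] = {
    "AKH": (0.05, 0.55, 0.40),
    "AKH*": (0.05, 0.55, 0.40),
    "AKHGK": (0.35, 0.40, 0.25),
}


@dataclass(frozen=True)
class InstrumentModel:
    """Acquisition model of a reflectron MALDI-TOF instrument."""

    resolving_power: float = 8000.0  # m/Δm FWHM
    grid_step: float = 0.01  # Da
    mz_min: float = 850.0
    mz_max: float = 1250.0
    low_mass_gate: float = 850.0  # intensities below are zeroed
    noise_sd: float = 30.0  # per-subspectrum detector noise
    baseline_amplitude: float = 200.0
    baseline_decay: float = 150.0  # Da
    c_sat_nM: Optional[float] = None  # hyperbolic saturation; None = linear
    subspectra: int = 5
    envelope_peaks: int = 6

    def __post_init__(self):
        if self.resolving_power <= 0:
            raise InputError("resolving power must be positive")
        if self.low_mass_gate < 0:
            raise InputError("low-mass gate must be >= 0")
        if self.subspectra < 1:
            raise InputError("subspectra count must be >= 1")
        if self.grid_step <= 0 or self.mz_max <= self.mz_min:
            raise InputError("invalid m/z grid")

    def grid(self) -> np.ndarray:
        n = int(round((self.mz_max - self.mz_min) / self.grid_step)) + 1
        return self.mz_min + self.grid_step * np.arange(n)


@dataclass(frozen=True)
class GroundTruth:
    """True per-sample peptide amounts and acquisition chemistry.

    ``amounts_fmol`` covers the analytes; the internal standard is specified by
    concentration and is converted with the matrix volume.
    """

    amounts_fmol: Mapping[str, float]
    matrix_nl: float = 200.0
    standard_nM: float = 400.0
    standard_name: str = "AKH*"
    suppression_sigma: float = 0.5
    adduct_fractions: Mapping[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ADDUCT_FRACTIONS)
    )

    def __post_init__(self):
        if self.matrix_nl <= 0:
            raise InputError("matrix volume must be positive")
        if self.standard_nM < 0:
            raise InputError("standard concentration must be >= 0")
        for name, amount in self.amounts_fmol.items():
            if amount < 0:
                raise InputError(f"negative amount for {name!r}")
        for name, fr in self.adduct_fractions.items():
            fr = tuple(fr)
            if len(fr) != 3 or any(f < 0 for f in fr):
                raise InputError(f"adduct fractions for {name!r} must be 3 non-negative values")
            if abs(sum(fr) - 1.0) > 1e-9:
                raise InputError(f"adduct fractions for {name!r} must sum to 1")

    def concentration_nM(self, name: str) -> float:
        """Effective in-matrix concentration of a species, in nM."""
        if name == self.standard_name:
            return self.standard_nM
        # fmol / nl = µM; ×1000 → nM
        return self.amounts_fmol.get(name, 0.0) / self.matrix_nl * 1e3

    def standard_fmol(self) -> float:
        return self.standard_nM * self.matrix_nl * 1e-3


def amount_to_nM(amount_fmol: float, matrix_nl: float) -> float:
    return amount_fmol / matrix_nl * 1e3


def saturate(c_nM: float, c_sat_nM: Optional[float]) -> float:
    """Hyperbolic ionization saturation c_eff = c / (1 + c/c_sat)."""
    if c_sat_nM is None:
        return c_nM
    return c_nM / (1.0 + c_nM / c_sat_nM)


def _render_peak(grid: np.ndarray, signal: np.ndarray, center: float, area: float,
                 sigma: float, step: float) -> None:
    """Add a Gaussian of given area in place, evaluated only within ±6σ."""
    lo = int(np.searchsorted(grid, center - 6 * sigma))
    hi = int(np.searchsorted(grid, center + 6 * sigma))
    if hi <= lo:
        return
    x = grid[lo:hi]
    height = area / (sigma * np.sqrt(2 * np.pi))
    signal[lo:hi] += height * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def simulate_spectrum(
    truth: GroundTruth,
    species: Sequence[PeptideSpecies],
    instrument: InstrumentModel = InstrumentModel(),
    seed: int | np.random.Generator = 0,
    sample_id: str = "sample",
) -> Spectrum:
    """Simulate one averaged profile spectrum of a single corpus cardiacum.

    For each species and adduct a Gaussian envelope of isotopologue peaks is
    rendered with FWHM = m/z ÷ resolving power and total area proportional to
    effective concentration × adduct fraction × the spectrum's shared
    suppression factor. The output is the mean of ``instrument.subspectra``
    independent detector-noise realizations, gated below the low-mass cutoff.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = instrument.grid()
    signal = np.zeros_like(grid)

    suppression = 1.0
    if truth.suppression_sigma > 0:
        suppression = float(
            np.exp(rng.normal(-0.5 * truth.suppression_sigma**2, truth.suppression_sigma))
        )
    elif truth.suppression_sigma < 0:
        raise InputError("suppression sigma must be >= 0")

    for sp in species:
        c = truth.concentration_nM(sp.name)
        if c <= 0:
            continue
        c_eff = saturate(c, instrument.c_sat_nM)
        fractions = truth.adduct_fractions.get(sp.name)
        if fractions is None:
            raise InputError(f"no adduct partition for species {sp.name!r}")
        composition = chem.elemental_composition(sp)
        neutral = chem.monoisotopic_mass(sp)
        envelope = chem.isotope_envelope(composition, instrument.envelope_peaks)
        for adduct_name, fraction in zip(ADDUCT_ORDER, fractions):
            if fraction <= 0:
                continue
            mz0 = chem.adduct_mz(neutral, adduct_name)
            for offset, abundance in envelope:
                center = mz0 + offset
                if center < grid[0] or center > grid[-1]:
                    continue
                area = INTENSITY_PER_NM * c_eff * fraction * abundance * suppression
                sigma = (center / instrument.resolving_power) / 2.3548200450309493
                _render_peak(grid, signal, center, area, sigma, instrument.grid_step)

    baseline = instrument.baseline_amplitude * np.exp(
        -(grid - instrument.mz_min) / instrument.baseline_decay
    )
    clean = signal + baseline
    if instrument.noise_sd > 0:
        noise = rng.normal(
            0.0, instrument.noise_sd, size=(instrument.subspectra, grid.size)
        ).mean(axis=0)
        averaged = clean + noise
    else:
        averaged = clean
    averaged = np.clip(averaged, 0.0, None)
    averaged[grid < instrument.low_mass_gate] = 0.0

    metadata = {
        "sample_id": sample_id,
        "seed": int(seed) if not isinstance(seed, np.random.Generator) else None,
        "suppression": suppression,
        "subspectra": instrument.subspectra,
        "resolving_power": instrument.resolving_power,
        "low_mass_gate": instrument.low_mass_gate,
        "mode": "profile",
    }
    return Spectrum(grid, averaged, metadata)


def lognormal_amounts(
    rng: np.random.Generator, mean: float, sd: float, n: int, fix_mean: bool = False
) -> np.ndarray:
    """Draw n non-negative amounts log-normally matched to the given mean/sd.

    With ``fix_mean`` the draws are rescaled so the sample mean equals ``mean``
    exactly (log-normal shape retained).
    """
    if sd < 0:
        raise InputError("sd must be >= 0")
    if mean < 0:
        raise InputError("mean must be >= 0")
    if mean == 0:
        return np.zeros(n)
    if sd == 0:
        return np.full(n, float(mean))
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    draws = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    if fix_mean:
        draws *= mean / draws.mean()
    return draws


def simulate_cohort(
    group_amounts: Mapping[str, Tuple[float, float]],
    n: int,
    seed: int | np.random.Generator,
    species: Sequence[PeptideSpecies],
    instrument: InstrumentModel = InstrumentModel(),
    matrix_nl: float = 200.0,
    standard_nM: float = 400.0,
    standard_name: str = "AKH*",
    suppression_sigma: float = 0.5,
    adduct_fractions: Optional[Mapping[str, Tuple[float, float, float]]] = None,
    fix_mean: bool = False,
    label: str = "cohort",
) -> List[Tuple[Spectrum, GroundTruth]]:
    """Simulate a cohort of single-CC spectra with per-sample log-normal amounts.

    ``group_amounts`` maps analyte name → (mean, sd) in fmol per CC.
    """
    if n < 1:
        raise InputError("cohort size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = {
        name: lognormal_amounts(rng, mean, sd, n, fix_mean=fix_mean)
        for name, (mean, sd) in group_amounts.items()
    }
    fractions = dict(DEFAULT_ADDUCT_FRACTIONS)
    if adduct_fractions:
        fractions.update(adduct_fractions)
    out: List[Tuple[Spectrum, GroundTruth]] = []
    for i in range(n):
        truth = GroundTruth(
            amounts_fmol={name: float(vals[i]) for name, vals in draws.items()},
            matrix_nl=matrix_nl,
            standard_nM=standard_nM,
            standard_name=standard_name,
            suppression_sigma=suppression_sigma,
            adduct_fractions=fractions,
        )
        spec = simulate_spectrum(truth, species, instrument, rng, sample_id=f"{label}_{i:03d}")
        spec.metadata["cohort"] = label
        out.append((spec, truth))
    return out


def simulate_dilution_series(
    standard_concentrations_nM: Sequence[float],
    analyte_amount_fmol: float,
    instrument: InstrumentModel,
    seed: int | np.random.Generator,
    species: Sequence[PeptideSpecies],
    analyte_name: str = "AKH",
    matrix_nl: float = 200.0,
    standard_name: str = "AKH*",
    suppression_sigma: float = 0.5,
    adduct_fractions: Optional[Mapping[str, Tuple[float, float, float]]] = None,
) -> List[Spectrum]:
    """One spectrum per standard concentration, analyte amount held fixed."""
    if not standard_concentrations_nM:
        raise InputError("concentration list must be non-empty")
    if any(c <= 0 for c in standard_concentrations_nM):
        raise InputError("standard concentrations must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fractions = dict(DEFAULT_ADDUCT_FRACTIONS)
    if adduct_fractions:
        fractions.update(adduct_fractions)
    out: List[Spectrum] = []
    for i, conc in enumerate(standard_concentrations_nM):
        truth = GroundTruth(
            amounts_fmol={analyte_name: analyte_amount_fmol},
            matrix_nl=matrix_nl,
            standard_nM=float(conc),
            standard_name=standard_name,
            suppression_sigma=suppression_sigma,
            adduct_fractions=fractions,
        )
        spec = simulate_spectrum(truth, species, instrument, rng, sample_id=f"dilution_{i:02d}")
        spec.metadata["standard_nM"] = float(conc)
        out.append(spec)
    return out
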