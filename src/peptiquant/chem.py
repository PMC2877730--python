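"""Peptide chemistry: elemental compositions, masses, adducts, isotope envelopes,
and the prohormone maturation chain.

Masses are monoisotopic unless stated otherwise, in Da, and deterministic to
1e-4 Da. Heavy-isotope labels are modelled as exact atom substitutions (``C`` →
``13C``) rather than lump mass deltas, so isotope envelopes of labelled species
stay correct: a fully labelled atom population contributes a point mass with no
envelope spread.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import InputError, ProcessingError

# ---------------------------------------------------------------------------
# Atomic data (CODATA/IUPAC). Keys like "13C" denote enriched heavy atoms.
# ---------------------------------------------------------------------------

MONOISOTOPIC_MASS: Dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "2H": 2.0141017780,
    "13C": 13.0033548378,
    "15N": 15.0001088984,
}

AVERAGE_MASS: Dict[str, float] = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "S": 32.065,
    "2H": 2.0141018,
    "13C": 13.0033548,
    "15N": 15.0001089,
}

#: natural isotopic abundance by neutron offset, per light element
ISOTOPE_ABUNDANCE: Dict[str, Sequence[float]] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

#: heavy label symbol -> light element it replaces
LABEL_REPLACES: Dict[str, str] = {"13C": "C", "15N": "N", "2H": "H"}

ELECTRON_MASS = 0.000548579909
PROTON_MASS = 1.00782503207 - ELECTRON_MASS  # 1.007276

#: average isotopologue spacing used for envelope offsets and de-isotoping;
#: peptides are carbon-dominated so the 13C-12C delta is the right grid.
ISOTOPE_SPACING = MONOISOTOPIC_MASS["13C"] - MONOISOTOPIC_MASS["C"]

WATER = {"H": 2, "O": 1}

# ---------------------------------------------------------------------------
# Residues
# ---------------------------------------------------------------------------

#: elemental composition of each amino acid *residue* (i.e. minus water)
RESIDUE_COMPOSITION: Dict[str, Dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}


def _composition_mass(composition: Mapping[str, int], table: Mapping[str, float]) -> float:
    return float(sum(table[el] * n for el, n in composition.items()))


@dataclass(frozen=True)
class ResidueTable:
    """Per-residue elemental compositions with derived mono/average masses.

    The stored masses are computed from the compositions, so the invariant
    (composition mass == stored mass to 1e-4 Da) holds by construction; it is
    still asserted by the test suite against an independent residue-sum oracle.
    """

    compositions: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: dict(RESIDUE_COMPOSITION)
    )

    def composition(self, code: str) -> Mapping[str, int]:
        try:
            return self.compositions[code]
        except KeyError:
            raise InputError(f"unknown residue code {code!r}") from None

    def monoisotopic(self, code: str) -> float:
        return _composition_mass(self.composition(code), MONOISOTOPIC_MASS)

    def average(self, code: str) -> float:
        return _composition_mass(self.composition(code), AVERAGE_MASS)

    def __contains__(self, code: str) -> bool:
        return code in self.compositions


DEFAULT_RESIDUES = ResidueTable()

# ---------------------------------------------------------------------------
# Modifications and species
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Modification:
    """A terminal or residue modification expressed as a signed elemental delta."""

    name: str
    target: str  # "nterm" | "cterm" | a residue code
    delta: Mapping[str, int]

    @property
    def mass_delta(self) -> float:
        return _composition_mass(self.delta, MONOISOTOPIC_MASS)

    @property
    def average_mass_delta(self) -> float:
        return _composition_mass(self.delta, AVERAGE_MASS)


#: N-terminal Gln -> pyroglutamate (loss of NH3)
PYROGLUTAMATE = Modification("pyroGlu", "nterm", {"N": -1, "H": -3})
#: C-terminal amide (OH -> NH2)
C_TERMINAL_AMIDE = Modification("amide", "cterm", {"O": -1, "N": 1, "H": 1})


@dataclass(frozen=True)
class PeptideSpecies:
    """A peptide species: sequence, terminal modifications, and isotope labels.

    ``labels`` maps a 0-based residue index to counts of heavy atoms in that
    residue, e.g. ``{1: {"13C": 6, "15N": 1}}`` for a 13C6,15N leucine.
    """

    name: str
    sequence: str
    modifications: Tuple[Modification, ...] = ()
    labels: Mapping[int, Mapping[str, int]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sequence:
            raise InputError("sequence must be non-empty")
        object.__setattr__(self, "modifications", tuple(self.modifications))
        for term in ("nterm", "cterm"):
            if sum(1 for m in self.modifications if m.target == term) > 1:
                raise InputError(f"at most one {term} modification allowed")
        for idx in self.labels:
            if not 0 <= idx < len(self.sequence):
                raise InputError(f"label position {idx} outside sequence bounds")


@dataclass(frozen=True)
class Adduct:
    """Singly charged cation adduct; shift = cation mass − electron mass."""

    name: str
    shift: float
    charge: int = 1

    def __post_init__(self):
        if self.charge != 1:
            raise InputError("only singly charged adducts are supported")
        if self.shift <= 0:
            raise InputError("adduct shift must be positive")


ADDUCTS: Dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", 1.00782503207 - ELECTRON_MASS),
    "[M+Na]+": Adduct("[M+Na]+", 22.9897692809 - ELECTRON_MASS),
    "[M+K]+": Adduct("[M+K]+", 38.96370668 - ELECTRON_MASS),
}

ADDUCT_ORDER: Tuple[str, ...] = ("[M+H]+", "[M+Na]+", "[M+K]+")


# ---------------------------------------------------------------------------
# Composition and mass operations
# ---------------------------------------------------------------------------


def elemental_composition(
    species: PeptideSpecies, residues: ResidueTable = DEFAULT_RESIDUES
) -> Dict[str, int]:
    """Elemental composition of the neutral species, heavy atoms as distinct keys.

    Sum of residue compositions plus one water plus modification deltas; each
    labelled heavy atom replaces its light counterpart one-for-one.
    """
    comp: Counter = Counter()
    for ch in species.sequence:
        comp.update(residues.composition(ch))
    comp.update(WATER)
    for mod in species.modifications:
        for el, n in mod.delta.items():
            comp[el] += n
    for idx, heavy_counts in species.labels.items():
        for heavy, n in heavy_counts.items():
            if heavy not in LABEL_REPLACES:
                raise InputError(f"unknown isotope label {heavy!r}")
            light = LABEL_REPLACES[heavy]
            comp[light] -= n
            comp[heavy] += n
    result = {el: int(n) for el, n in comp.items() if n != 0}
    for el, n in result.items():
        if n < 0:
            raise InputError(
                f"composition of {species.name!r} has negative {el} count ({n})"
            )
    return result


def monoisotopic_mass(
    species: PeptideSpecies, residues: ResidueTable = DEFAULT_RESIDUES
) -> float:
    """Neutral monoisotopic mass in Da."""
    return _composition_mass(elemental_composition(species, residues), MONOISOTOPIC_MASS)


def average_mass(species: PeptideSpecies, residues: ResidueTable = DEFAULT_RESIDUES) -> float:
    """Neutral average mass in Da."""
    return _composition_mass(elemental_composition(species, residues), AVERAGE_MASS)


def adduct_mz(neutral_mass: float, adduct: Adduct | str) -> float:
    """m/z of the singly charged adduct ion."""
    if neutral_mass <= 0:
        raise InputError("neutral mass must be positive")
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise InputError(f"unknown adduct {adduct!r}") from None
    return neutral_mass + adduct.shift


def species_adduct_mz(
    species: PeptideSpecies, adduct: Adduct | str, residues: ResidueTable = DEFAULT_RESIDUES
) -> float:
    return adduct_mz(monoisotopic_mass(species, residues), adduct)


def _element_envelope(abundances: Sequence[float], n_atoms: int, n_peaks: int) -> np.ndarray:
    """Distribution of neutron offsets for ``n_atoms`` i.i.d. atoms, truncated."""
    base = np.asarray(abundances, dtype=float)
    # binary exponentiation of the convolution power, truncating as we go
    result = np.zeros(n_peaks)
    result[0] = 1.0
    power = base
    n = n_atoms
    while n:
        if n & 1:
            result = np.convolve(result, power)[:n_peaks]
        n >>= 1
        if n:
            power = np.convolve(power, power)[:n_peaks]
    return result


def isotope_envelope(
    composition: Mapping[str, int], n_peaks: int = 6
) -> List[Tuple[float, float]]:
    """Aggregated isotopologue envelope: list of (mass offset, abundance).

    The first entry is the monoisotopic peak; abundances are absolute
    probabilities and sum to ≤ 1 (truncation). Heavy-label atoms are treated as
    isotopically pure and contribute no spread.
    """
    if n_peaks < 2:
        raise InputError("n_peaks must be >= 2")
    env = np.zeros(n_peaks)
    env[0] = 1.0
    for el, n in composition.items():
        if n < 0:
            raise InputError(f"negative atom count for {el}")
        if el in LABEL_REPLACES:
            continue  # enriched atoms: single point mass
        if el not in ISOTOPE_ABUNDANCE:
            raise InputError(f"no isotope data for element {el!r}")
        env = np.convolve(env, _element_envelope(ISOTOPE_ABUNDANCE[el], n, n_peaks))[:n_peaks]
    return [(k * ISOTOPE_SPACING, float(env[k])) for k in range(n_peaks)]


# ---------------------------------------------------------------------------
# Prohormone processing
# ---------------------------------------------------------------------------

_BASIC = frozenset("KR")


@dataclass(frozen=True)
class ProhormoneAnnotation:
    """Annotated prohormone: signal peptide, mature-peptide span, dibasic linker,
    and the C-terminal remainder must tile the precursor contiguously."""

    precursor: str
    signal_end: int
    peptide_span: Tuple[int, int]
    linker_span: Tuple[int, int]
    cterm_span: Tuple[int, int]

    def __post_init__(self):
        n = len(self.precursor)
        spans = [(0, self.signal_end), self.peptide_span, self.linker_span, self.cterm_span]
        for (a, b) in spans:
            if not 0 <= a <= b <= n:
                raise InputError(f"span {(a, b)} outside precursor of length {n}")
        for (_, b1), (a2, _) in zip(spans, spans[1:]):
            if b1 != a2:
                raise InputError("spans must be contiguous, ordered and tile the precursor")
        if self.cterm_span[1] != n:
            raise InputError("spans must tile the full precursor")
        if self.peptide_span[1] <= self.peptide_span[0]:
            raise InputError("peptide span must be non-empty")

    @property
    def peptide(self) -> str:
        return self.precursor[slice(*self.peptide_span)]

    @property
    def linker(self) -> str:
        return self.precursor[slice(*self.linker_span)]


def process_prohormone(
    annotation: ProhormoneAnnotation, name_prefix: str = "peptide"
) -> List[PeptideSpecies]:
    """Enumerate maturation intermediates of an annotated prohormone.

    Returns, in order: the pro-peptide after signal-peptidase removal; the
    peptide+linker after convertase cleavage C-terminal to the dibasic pair;
    carboxypeptidase products trimming one basic residue at a time; and the
    amidated mature peptide (terminal Gly removed, C-terminal amide), with
    N-terminal Gln converted to pyroglutamate when present.
    """
    linker = annotation.linker
    if len(linker) < 2 or linker[-1] not in _BASIC or linker[-2] not in _BASIC:
        raise ProcessingError("no PC site: linker does not end in a dibasic pair")

    out: List[PeptideSpecies] = []
    propeptide = annotation.precursor[annotation.signal_end :]
    out.append(PeptideSpecies(f"{name_prefix}-pro", propeptide))

    seq = annotation.peptide + linker  # PC cleaves C-terminal to the dibasic pair
    out.append(PeptideSpecies(f"{name_prefix}+{linker}", seq))

    while seq[-1] in _BASIC:  # carboxypeptidase trims basics one at a time
        seq = seq[:-1]
        out.append(PeptideSpecies(f"{name_prefix}+{seq[len(annotation.peptide):] or ''}".rstrip("+"), seq))

    mods: List[Modification] = []
    mature = seq
    if mature.endswith("G"):  # amidating enzyme consumes the C-terminal Gly
        mature = mature[:-1]
        mods.append(C_TERMINAL_AMIDE)
    if mature.startswith("Q"):
        mods.append(PYROGLUTAMATE)
    out.append(PeptideSpecies(f"{name_prefix}-mature", mature, tuple(mods)))
    return out


# ---------------------------------------------------------------------------
# Built-in species of the AKH system
# ---------------------------------------------------------------------------

AKH_SEQUENCE = "QLTFSPDW"

#: heavy leucine label of the internal standard: 13C6, 15N
AKH_STAR_LABEL = {1: {"13C": 6, "15N": 1}}


def make_akh() -> PeptideSpecies:
    """Mature adipokinetic hormone: pGlu-LTFSPDW-amide."""
    return PeptideSpecies("AKH", AKH_SEQUENCE, (PYROGLUTAMATE, C_TERMINAL_AMIDE))


def make_akhgk() -> PeptideSpecies:
    """Processing intermediate: pGlu-LTFSPDWGK, free acid."""
    return PeptideSpecies("AKHGK", AKH_SEQUENCE + "GK", (PYROGLUTAMATE,))


def make_akh_star() -> PeptideSpecies:
    """Heavy-labelled internal standard: AKH with 13C6,15N leucine."""
    return PeptideSpecies(
        "AKH*", AKH_SEQUENCE, (PYROGLUTAMATE, C_TERMINAL_AMIDE), AKH_STAR_LABEL
    )


def builtin_species() -> Dict[str, PeptideSpecies]:
    sp = [make_akh(), make_akhgk(), make_akh_star()]
    return {s.name: s for s in sp}
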