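"""Run configuration: YAML schema with defaults, validation and hashing.

Every key has a default except ``seed``; unknown keys are rejected so typos
fail loudly. Species may be declared inline or default to the built-in AKH
system (AKH, AKHGK, and the heavy-labelled standard AKH*).
"""

from __future__ import annotations

import copy
import hashlib
import json
import zlib
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional

import numpy as np
import yaml

from . import chem
from .chem import C_TERMINAL_AMIDE, PYROGLUTAMATE, PeptideSpecies
from .errors import ConfigError
from .simulate import DEFAULT_ADDUCT_FRACTIONS, InstrumentModel

DEFAULTS: Dict[str, Any] = {
    "seed": None,  # mandatory
    "out_dir": "results",
    "format": "tsv",  # spectrum interchange format: tsv | mzml
    "standard_name": "AKH*",
    "standard_nM": 400.0,
    "matrix_nl": 200.0,
    "suppression_sigma": 0.5,
    "analytes": ["AKH", "AKHGK"],
    "species": None,  # None -> built-in AKH system
    "adduct_fractions": {k: list(v) for k, v in DEFAULT_ADDUCT_FRACTIONS.items()},
    "instrument": {
        "resolving_power": 8000.0,
        "grid_step": 0.01,
        "mz_min": 850.0,
        "mz_max": 1250.0,
        "low_mass_gate": 850.0,
        "noise_sd": 30.0,
        "baseline_amplitude": 200.0,
        "baseline_decay": 150.0,
        "c_sat_nM": None,
        "subspectra": 5,
        "envelope_peaks": 6,
    },
    "tolerances": {
        "mass_tol_da": 0.2,
        "spacing_tol_da": 0.05,
        "snr_threshold": 3.0,
        "baseline_window_da": 5.0,
        "linearity_tol": 0.15,
    },
    "cohorts": [
        {
            "label": "cohort",
            "n": 1,
            "amounts": {"AKH": {"mean": 174.0, "sd": 0.0}},
            "fix_mean": False,
        }
    ],
    "comparisons": [],
}

_COHORT_KEYS = {"label", "n", "amounts", "fix_mean"}
_AMOUNT_KEYS = {"mean", "sd"}


def _merge(defaults: Mapping[str, Any], overrides: Mapping[str, Any], path: str = "") -> Dict[str, Any]:
    out = copy.deepcopy(dict(defaults))
    for key, value in overrides.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key {where!r}")
        if isinstance(defaults[key], dict) and isinstance(value, Mapping):
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = copy.deepcopy(value)
    return out


class RunConfig:
    """Validated run configuration."""

    def __init__(self, overrides: Optional[Mapping[str, Any]] = None):
        data = _merge(DEFAULTS, overrides or {})
        # adduct_fractions and species are open mappings, merged leniently
        if overrides and "adduct_fractions" in overrides:
            fractions = {k: list(v) for k, v in DEFAULTS["adduct_fractions"].items()}
            fractions.update({k: list(v) for k, v in overrides["adduct_fractions"].items()})
            data["adduct_fractions"] = fractions
        if data["seed"] is None:
            raise ConfigError("config key 'seed' is mandatory")
        for cohort in data["cohorts"]:
            extra = set(cohort) - _COHORT_KEYS
            if extra:
                raise ConfigError(f"unknown cohort key(s) {sorted(extra)}")
            for sp, spec in cohort.get("amounts", {}).items():
                extra = set(spec) - _AMOUNT_KEYS
                if extra:
                    raise ConfigError(f"unknown amount key(s) {sorted(extra)} for {sp!r}")
        self.data = data

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls(loaded)

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def instrument(self) -> InstrumentModel:
        return InstrumentModel(**self.data["instrument"])

    def species(self) -> Dict[str, PeptideSpecies]:
        if self.data["species"] is None:
            return chem.builtin_species()
        out: Dict[str, PeptideSpecies] = {}
        for entry in self.data["species"]:
            mods = []
            if entry.get("pyroglutamate"):
                mods.append(PYROGLUTAMATE)
            if entry.get("amide"):
                mods.append(C_TERMINAL_AMIDE)
            labels = {
                int(idx): dict(counts) for idx, counts in (entry.get("labels") or {}).items()
            }
            out[entry["name"]] = PeptideSpecies(
                entry["name"], entry["sequence"], tuple(mods), labels
            )
        return out

    def adduct_fractions(self) -> Dict[str, tuple]:
        return {k: tuple(v) for k, v in self.data["adduct_fractions"].items()}

    def hash(self) -> str:
        """Stable content hash, logged so outputs are traceable to one config."""
        canonical = json.dumps(self.data, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def rng_for(self, stage: str, index: int = 0) -> np.random.Generator:
        """Documented seed-splitting scheme: (seed, crc32(stage), index)."""
        return np.random.default_rng([self.seed, zlib.crc32(stage.encode()), index])


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_yaml(path)
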