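"""Analyte/standard ratios, calibration curves, and unity-slope amounts.

Quantification deliberately bypasses the fitted calibration curve: with a
chemically identical heavy standard the response slope is assumed to be one,
so amount = ratio × standard amount. The fitted constant k of the calibration
model ratio = k / [standard] serves as a validity diagnostic (k should match
the analyte's effective concentration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import InputError, QuantificationError
from .process import PeakGroup

DEFAULT_LINEARITY_TOL = 0.15


def intensity_ratio(analyte: PeakGroup, standard: PeakGroup) -> float:
    """Summed-relative-intensity ratio analyte / internal standard."""
    if standard.summed_relative_intensity <= 0:
        raise QuantificationError("standard not detected")
    return analyte.summed_relative_intensity / standard.summed_relative_intensity


def standard_amount(concentration_nM: float, matrix_nl: float) -> float:
    """Spiked standard amount in fmol: nM × nl / 1000."""
    if concentration_nM <= 0 or matrix_nl <= 0:
        raise InputError("concentration and volume must be positive")
    return concentration_nM * matrix_nl * 1e-3


def ratio_to_amount(ratio: float, standard_fmol: float) -> float:
    """Absolute amount under the unity-slope assumption."""
    if ratio < 0:
        raise InputError("ratio must be >= 0")
    if standard_fmol <= 0:
        raise InputError("standard amount must be positive")
    return ratio * standard_fmol


@dataclass
class QuantResult:
    """Per-sample quantification outcome."""

    sample_id: str
    ratios: Dict[str, float]
    amounts_fmol: Dict[str, float]
    detected: Dict[str, bool]
    standard_fmol: float
    standard_detected: bool
    cohort: Optional[str] = None


def quantify_sample(
    groups: Sequence[PeakGroup],
    standard_name: str,
    standard_fmol: float,
    sample_id: str = "sample",
    cohort: Optional[str] = None,
) -> QuantResult:
    """Convert one sample's peak groups into ratios and unity-slope amounts.

    If the standard is undetected the sample is still returned (flagged) so the
    caller can count it in a QC report rather than silently dropping it; its
    ratios/amounts are NaN.
    """
    by_name = {g.species: g for g in groups}
    if standard_name not in by_name:
        raise InputError(f"no peak group for standard {standard_name!r}")
    standard = by_name[standard_name]
    ratios: Dict[str, float] = {}
    amounts: Dict[str, float] = {}
    detected: Dict[str, bool] = {}
    ok = standard.detected and standard.summed_relative_intensity > 0
    for name, group in by_name.items():
        if name == standard_name:
            continue
        detected[name] = group.detected
        if ok:
            r = intensity_ratio(group, standard)
            ratios[name] = r
            amounts[name] = ratio_to_amount(r, standard_fmol)
        else:
            ratios[name] = float("nan")
            amounts[name] = float("nan")
    return QuantResult(
        sample_id=sample_id,
        ratios=ratios,
        amounts_fmol=amounts,
        detected=detected,
        standard_fmol=standard_fmol,
        standard_detected=ok,
        cohort=cohort,
    )


@dataclass
class CalibrationCurve:
    """Fit of ratio = k / concentration with a detected linear range."""

    concentrations_nM: np.ndarray
    ratios: np.ndarray
    k: float
    deviations: np.ndarray  # relative deviation of each point from k/c
    linear_range: Optional[Tuple[float, float]]  # (nM, nM) or None

    def in_linear_range(self, concentration_nM: float) -> bool:
        if self.linear_range is None:
            return False
        lo, hi = self.linear_range
        return lo <= concentration_nM <= hi


def fit_calibration(
    points: Sequence[Tuple[float, float]], tolerance: float = DEFAULT_LINEARITY_TOL
) -> CalibrationCurve:
    """Fit k by least squares of ratio on 1/concentration through the origin.

    The linear range is the maximal contiguous subset of the (sorted)
    concentrations whose relative deviation from k/c is within ``tolerance``.
    """
    if tolerance <= 0:
        raise InputError("tolerance must be positive")
    pts = sorted(points)
    conc = np.array([c for c, _ in pts], dtype=float)
    ratio = np.array([r for _, r in pts], dtype=float)
    if np.unique(conc).size < 3:
        raise InputError("calibration requires at least 3 distinct concentrations")
    if np.any(conc <= 0):
        raise InputError("concentrations must be positive")
    x = 1.0 / conc
    k = float(np.sum(ratio * x) / np.sum(x * x))
    if k <= 0:
        raise InputError("fitted constant must be positive")
    predicted = k / conc
    deviations = np.abs(ratio - predicted) / predicted

    ok = deviations <= tolerance
    best: Optional[Tuple[int, int]] = None
    start = None
    for i, flag in enumerate(list(ok) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if best is None or (i - start) > (best[1] - best[0]):
                best = (start, i)
            start = None
    linear_range = None
    if best is not None:
        linear_range = (float(conc[best[0]]), float(conc[best[1] - 1]))
    return CalibrationCurve(conc, ratio, k, deviations, linear_range)
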