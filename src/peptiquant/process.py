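"""Raw profile spectrum → per-species summed relative adduct intensities.

Stages: morphological (top-hat) baseline correction, local-maximum peak
detection with MAD-based signal-to-noise, greedy left-to-right de-isotoping,
and nearest-match adduct assignment. Only the 850–1500 Da window is processed,
honouring the instrument's low-mass gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from . import chem
from .chem import ADDUCT_ORDER, PeptideSpecies
from .errors import InputError
from .spectrum import Spectrum

PROCESS_WINDOW = (850.0, 1500.0)
DEFAULT_SNR_THRESHOLD = 3.0
DEFAULT_MASS_TOL = 0.2  # Da, externally calibrated MALDI-TOF
DEFAULT_SPACING_TOL = 0.05  # Da


@dataclass
class Peak:
    """A detected peak: interpolated apex position, height, and S/N."""

    mz: float
    intensity: float
    snr: float

    def __post_init__(self):
        if self.intensity <= 0:
            raise InputError("peak intensity must be positive")
        if self.snr < 0:
            raise InputError("peak S/N must be >= 0")


@dataclass
class PeakGroup:
    """Adduct peaks assigned to one species, with summed relative intensity."""

    species: str
    adduct_peaks: Dict[str, Peak] = field(default_factory=dict)
    summed_relative_intensity: float = 0.0
    detected: bool = False
    warnings: List[str] = field(default_factory=list)


def baseline_correct(spectrum: Spectrum, window_da: float = 5.0) -> Spectrum:
    """Subtract a morphological top-hat baseline (rolling min, then rolling max).

    The window must exceed the peak FWHM so peaks are not absorbed into the
    baseline; intensities are clipped at zero, m/z is unchanged.
    """
    if window_da <= 0:
        raise InputError("baseline window must be positive")
    if len(spectrum) < 3:
        raise InputError("spectrum too short for baseline correction")
    step = float(np.median(np.diff(spectrum.mz)))
    size = max(3, int(round(window_da / step)))
    baseline = maximum_filter1d(
        minimum_filter1d(spectrum.intensity, size=size, mode="nearest"),
        size=size,
        mode="nearest",
    )
    corrected = np.clip(spectrum.intensity - baseline, 0.0, None)
    out = spectrum.copy_with(corrected)
    out.metadata["baseline_corrected"] = True
    return out


def _mad_noise(values: np.ndarray) -> float:
    if values.size == 0:
        return 0.0
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def spectrum_noise_floor(
    spectrum: Spectrum, window: Tuple[float, float] = PROCESS_WINDOW
) -> Tuple[float, float]:
    """Global noise floor (median) and noise sd (1.4826 × MAD) of the gated window.

    Peaks occupy ~1% of the trace, so the global median is an unbiased
    estimate of the residual pedestal a morphological baseline leaves under
    the noise; a per-peak local floor would be dragged upward near tall
    envelopes and bias integrated areas of small peaks low.
    """
    mask = (spectrum.mz >= window[0]) & (spectrum.mz <= window[1])
    values = spectrum.intensity[mask]
    if values.size == 0:
        return 0.0, 0.0
    return float(np.median(values)), _mad_noise(values)


def noise_floor_curve(
    spectrum: Spectrum,
    peak_mzs: Sequence[float],
    mask_half_da: float = 0.6,
    tile_da: float = 2.0,
    window: Tuple[float, float] = PROCESS_WINDOW,
) -> Tuple[np.ndarray, np.ndarray]:
    """Piecewise noise-floor estimate: tile-wise medians of peak-masked intensities.

    The morphological baseline leaves a pedestal under the noise that varies
    with the local baseline slope, so a single global floor under-corrects in
    steep regions. Returns (tile centers, floor values) for interpolation.
    """
    mz, y = spectrum.mz, spectrum.intensity
    mask = (mz >= window[0]) & (mz <= window[1])
    free = mask.copy()
    for p in peak_mzs:
        lo = int(np.searchsorted(mz, p - mask_half_da))
        hi = int(np.searchsorted(mz, p + mask_half_da))
        free[lo:hi] = False
    centers, values = [], []
    edges = np.arange(window[0], min(window[1], float(mz[-1])) + tile_da, tile_da)
    idx = np.searchsorted(mz, edges)
    for a, b, lo_edge in zip(idx[:-1], idx[1:], edges):
        seg = y[a:b][free[a:b]]
        if seg.size >= 10:
            centers.append(lo_edge + tile_da / 2)
            values.append(float(np.median(seg)))
    if not centers:  # fully masked: fall back to the global median
        med = float(np.median(y[mask])) if mask.any() else 0.0
        return np.array([window[0], window[1]]), np.array([med, med])
    return np.asarray(centers), np.asarray(values)


def detect_peaks(
    spectrum: Spectrum,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    flank_da: Tuple[float, float] = (0.75, 4.0),
    window: Tuple[float, float] = PROCESS_WINDOW,
    integration_half_da: float = 0.4,
    min_separation_da: float = 0.3,
) -> List[Peak]:
    """Local maxima with S/N ≥ threshold, apexes refined by parabolic interpolation.

    Peak intensity is the floor-subtracted area integrated over ±0.4 Da around
    the apex (kept below half the isotopologue spacing): peak width grows with
    m/z at fixed resolving power, so apex heights would systematically
    under-read higher-mass species relative to lower-mass ones.

    S/N is the apex height above the global noise floor divided by 1.4826 ×
    the median absolute deviation of intensities in flanking windows around
    (but excluding) the peak. Summit noise ripples produce multiple maxima per
    real peak, so candidates within ``min_separation_da`` of a stronger one
    are suppressed. On noise-free input the noise estimate can be 0, in which
    case S/N is reported as infinity.
    """
    if len(spectrum) < 3:
        raise InputError("spectrum must have at least 3 points")
    mz, y = spectrum.mz, spectrum.intensity
    step = float(np.median(np.diff(mz)))

    in_window = (mz >= window[0]) & (mz <= window[1])
    # candidate apexes: strictly greater than right neighbour, >= left (plateau-safe)
    idx = np.flatnonzero((y[1:-1] > 0) & (y[1:-1] >= y[:-2]) & (y[1:-1] > y[2:])) + 1
    idx = idx[in_window[idx]]
    if idx.size == 0:
        return []

    global_floor, global_noise = spectrum_noise_floor(spectrum, window)
    if global_noise > 0:
        # cheap prefilter; exact local S/N decides below
        idx = idx[y[idx] - global_floor >= 0.75 * snr_threshold * global_noise]

    # non-maximum suppression: strongest candidate wins within min separation
    order = idx[np.argsort(y[idx])[::-1]]
    accepted: List[int] = []
    min_sep = max(1, int(round(min_separation_da / step)))
    taken = np.zeros(len(y), dtype=bool)
    for i in order:
        if taken[max(0, i - min_sep) : i + min_sep + 1].any():
            continue
        taken[i] = True
        accepted.append(int(i))

    centers, floors = noise_floor_curve(spectrum, [float(mz[i]) for i in accepted], window=window)

    inner = max(1, int(round(flank_da[0] / step)))
    outer = max(inner + 1, int(round(flank_da[1] / step)))
    half = max(1, int(round(integration_half_da / step)))
    peaks: List[Peak] = []
    for i in accepted:
        local_floor = float(np.interp(mz[i], centers, floors))
        height = float(y[i]) - local_floor
        if height <= 0:
            continue
        left = y[max(0, i - outer) : max(0, i - inner)]
        right = y[i + inner : i + outer]
        flank = np.concatenate([left, right])
        noise = _mad_noise(flank) if flank.size else global_noise
        if noise <= 0:
            noise = global_noise
        snr = height / noise if noise > 0 else float("inf")
        if snr < snr_threshold:
            continue
        # 3-point parabolic apex refinement (position only)
        apex_mz = float(mz[i])
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            if denom < 0:
                delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
                if abs(delta) <= 0.5:
                    apex_mz = float(mz[i] + delta * step)
        segment = y[max(0, i - half) : i + half + 1]
        area = float(np.sum(segment - local_floor) * step)
        if area <= 0:
            continue
        if noise > 0:
            # matched-filter gate: a real peak spreads over ~FWHM, so its area
            # clears the same S/N bar; single-point noise spikes do not. The
            # sqrt(2) inflates the area sd for noise-floor estimation error.
            area_snr = area / (noise * step * np.sqrt(2.0 * segment.size))
            if area_snr < snr_threshold:
                continue
            # a real peak's immediate neighbours stand well off the floor
            if y[i - 1] - local_floor < 0.25 * height or y[i + 1] - local_floor < 0.25 * height:
                continue
        peaks.append(Peak(apex_mz, area, snr if np.isfinite(snr) else float("inf")))
    peaks.sort(key=lambda p: p.mz)
    return peaks


def _integrate_window(spectrum: Spectrum, center: float, half_da: float, floor: float) -> float:
    """Floor-subtracted area in a fixed window around ``center``."""
    mz, y = spectrum.mz, spectrum.intensity
    step = float(np.median(np.diff(mz)))
    lo = int(np.searchsorted(mz, center - half_da))
    hi = int(np.searchsorted(mz, center + half_da))
    if hi <= lo:
        return 0.0
    return float(np.sum(y[lo:hi] - floor) * step)


def deisotope(
    peaks: Sequence[Peak],
    spacing_tol: float = DEFAULT_SPACING_TOL,
    spacing: float = chem.ISOTOPE_SPACING,
    spectrum: Optional[Spectrum] = None,
    max_extension: int = 2,
    integration_half_da: float = 0.4,
    extend_near: Optional[Sequence[float]] = None,
    extend_tol: float = DEFAULT_MASS_TOL,
    block_snr: float = 6.0,
    max_rise: float = 5.0,
) -> List[Peak]:
    """Collapse isotopologue chains to their monoisotopic peak (summed intensity).

    Peaks are chained greedily left-to-right while consecutive spacing is
    ``spacing ± spacing_tol`` and intensity is non-increasing once the chain has
    passed its maximum; ties broken by smaller spacing error. Each chain is
    replaced by its first peak carrying the summed intensity.

    When the source ``spectrum`` is supplied, up to ``max_extension`` further
    isotopologue positions beyond the last detected chain member are integrated
    directly from the trace. Small high-order isotopologues fall under the
    detection threshold at low analyte amounts but not at high standard
    amounts, which would otherwise bias analyte/standard ratios in an
    amount-dependent way. Extension stops if the next window would encroach on
    any detected peak outside the chain (e.g. a heavy-labelled species sitting
    a few isotope spacings up).
    """
    if spacing_tol < 0:
        raise InputError("spacing tolerance must be >= 0")
    if spectrum is not None:
        centers, floors = noise_floor_curve(spectrum, [p.mz for p in peaks])
    remaining = sorted(peaks, key=lambda p: p.mz)
    used = [False] * len(remaining)
    out: List[Peak] = []
    for i, p in enumerate(remaining):
        if used[i]:
            continue
        chain = [p]
        used[i] = True
        last = p
        chain_max = p.intensity
        descending = False
        while True:
            candidates = [
                (abs(q.mz - last.mz - spacing), j, q)
                for j, q in enumerate(remaining)
                if not used[j] and abs(q.mz - last.mz - spacing) <= spacing_tol
            ]
            if not candidates:
                break
            _, j, q = min(candidates, key=lambda t: t[0])
            if descending and q.intensity > last.intensity:
                break  # envelope must be non-increasing past its maximum
            if q.intensity > last.intensity * max_rise:
                break  # rise too steep for a peptide envelope: not an isotopologue
            used[j] = True
            chain.append(q)
            if q.intensity < chain_max:
                descending = True
            chain_max = max(chain_max, q.intensity)
            last = q
        total = sum(c.intensity for c in chain)
        extendable = spectrum is not None and (
            extend_near is None
            or any(abs(chain[0].mz - t) <= extend_tol for t in extend_near)
        )
        if extendable:
            chain_mzs = {c.mz for c in chain}
            for e in range(1, max_extension + 1):
                pos = last.mz + e * spacing
                if pos + integration_half_da > spectrum.mz[-1]:
                    break
                # stop before encroaching on a solid peak outside this chain
                # (e.g. a heavy-labelled species a few spacings up); weak noise
                # maxima do not block
                blocked = any(
                    q.mz not in chain_mzs
                    and q.snr >= block_snr
                    and abs(q.mz - pos) < 0.5 * spacing + integration_half_da
                    for q in remaining
                )
                if blocked:
                    break
                pos_floor = float(np.interp(pos, centers, floors))
                total += _integrate_window(spectrum, pos, integration_half_da, pos_floor)
        mono = chain[0]
        out.append(Peak(mono.mz, max(total, mono.intensity * 1e-12), mono.snr))
    return out


def assign_adducts(
    mono_peaks: Sequence[Peak],
    species: Sequence[PeptideSpecies],
    mass_tol: float = DEFAULT_MASS_TOL,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
) -> List[PeakGroup]:
    """Match each species' candidate adduct m/z values to de-isotoped peaks.

    Every peak is assigned at most once; conflicts are resolved globally by
    smallest mass error. Relative intensities are normalized to the largest
    de-isotoped peak of the spectrum (cancels in analyte/standard ratios).
    """
    if mass_tol <= 0:
        raise InputError("mass tolerance must be positive")
    groups = {sp.name: PeakGroup(species=sp.name) for sp in species}

    candidates = []  # (abs error, species, adduct, peak index)
    expected: Dict[Tuple[str, str], float] = {}
    for sp in species:
        neutral = chem.monoisotopic_mass(sp)
        for adduct in ADDUCT_ORDER:
            target = chem.adduct_mz(neutral, adduct)
            expected[(sp.name, adduct)] = target
            for j, peak in enumerate(mono_peaks):
                err = abs(peak.mz - target)
                if err <= mass_tol:
                    candidates.append((err, sp.name, adduct, j))

    # ambiguity: one peak within tolerance of two different species
    peak_claims: Dict[int, set] = {}
    for _, name, _, j in candidates:
        peak_claims.setdefault(j, set()).add(name)
    for j, claimants in peak_claims.items():
        if len(claimants) > 1:
            msg = (
                f"peak at {mono_peaks[j].mz:.3f} within tolerance of "
                f"{sorted(claimants)}"
            )
            for name in claimants:
                groups[name].warnings.append(msg)

    base = max((p.intensity for p in mono_peaks), default=0.0)
    taken_peaks: set = set()
    taken_slots: set = set()
    for err, name, adduct, j in sorted(candidates, key=lambda t: t[0]):
        if j in taken_peaks or (name, adduct) in taken_slots:
            continue
        taken_peaks.add(j)
        taken_slots.add((name, adduct))
        groups[name].adduct_peaks[adduct] = mono_peaks[j]

    for group in groups.values():
        if base > 0:
            group.summed_relative_intensity = sum(
                p.intensity / base for p in group.adduct_peaks.values()
            )
        group.detected = any(p.snr >= snr_threshold for p in group.adduct_peaks.values())
    return [groups[sp.name] for sp in species]


def process_spectrum(
    spectrum: Spectrum,
    species: Sequence[PeptideSpecies],
    baseline_window_da: float = 5.0,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    mass_tol: float = DEFAULT_MASS_TOL,
    spacing_tol: float = DEFAULT_SPACING_TOL,
) -> List[PeakGroup]:
    """Full processing chain: baseline → peaks → de-isotoping → adduct groups."""
    corrected = baseline_correct(spectrum, baseline_window_da)
    peaks = detect_peaks(corrected, snr_threshold)
    targets = [
        chem.adduct_mz(chem.monoisotopic_mass(sp), adduct)
        for sp in species
        for adduct in ADDUCT_ORDER
    ]
    mono = deisotope(
        peaks, spacing_tol, spectrum=corrected, extend_near=targets, extend_tol=mass_tol
    )
    return assign_adducts(mono, species, mass_tol, snr_threshold)
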