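"""Cohort-level statistics: detection rates, medians, mean ± s.e.m., and
Mann-Whitney comparisons (exact by enumeration for small tie-free samples,
normal approximation with tie and continuity correction otherwise)."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import InputError
from .quantify import QuantResult

EXACT_LIMIT = 400  # exact enumeration when nA * nB <= this and no ties


def _exact_u_distribution(n_a: int, n_b: int) -> np.ndarray:
    """Counts of subsets by U value for tie-free samples (DP recurrence)."""
    max_u = n_a * n_b
    # Gaussian binomial [n_a+n_b, n_a]_q = prod_i (1 - q^(n_b+i)) / (1 - q^i):
    # coefficient of q^u is the number of labelings with statistic U = u.
    counts = np.zeros(max_u + 1, dtype=float)
    counts[0] = 1.0
    for i in range(1, n_a + 1):
        for u in range(i, max_u + 1):  # divide by (1 - q^i)
            counts[u] += counts[u - i]
        s = n_b + i  # multiply by (1 - q^s)
        if s <= max_u:
            counts = counts - np.concatenate([np.zeros(s), counts[:-s]])
    return counts


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> Tuple[float, float]:
    """Mann-Whitney U (midranks for ties) and two-sided p.

    Exact p by enumeration of the U distribution when nA·nB ≤ 400 and the
    pooled sample has no ties; otherwise a normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    r_a = float(ranks[:n_a].sum())
    u = r_a - n_a * (n_a + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if n_a * n_b <= EXACT_LIMIT and not has_ties:
        dist = _exact_u_distribution(n_a, n_b)
        total = dist.sum()
        ui = int(round(u))
        p_le = dist[: ui + 1].sum() / total
        p_ge = dist[ui:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u, float(p)

    n = n_a + n_b
    mean = n_a * n_b / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u, 1.0
    z = max(0.0, abs(u - mean) - 0.5) / math.sqrt(var)
    p = 2.0 * float(norm.sf(z))
    return u, min(1.0, p)


@dataclass
class CohortSummary:
    """Table-shaped per-group summary (detection %, median ratio, mean ± sem)."""

    label: str
    n: int
    detection_rate: Dict[str, float]  # percent, per species
    median_ratio: Dict[str, float]
    mean_amount: Dict[str, float]
    sem_amount: Dict[str, float]
    n_standard_detected: int = 0
    single_sample: bool = False
    # raw per-sample values retained for cohort comparisons
    sample_ratios: Dict[str, List[float]] = field(default_factory=dict)
    sample_amounts: Dict[str, List[float]] = field(default_factory=dict)


def summarize_cohort(
    results: Sequence[QuantResult], label: str = "cohort"
) -> CohortSummary:
    """Summarize per-sample quantification results for one cohort.

    Ratio medians and amount means run over samples whose internal standard was
    detected; undetected-standard samples count toward n and the QC tally only.
    """
    if not results:
        raise InputError("cohort must contain at least one sample")
    n = len(results)
    species = sorted({name for r in results for name in r.ratios})
    valid = [r for r in results if r.standard_detected]

    detection, median_ratio, mean_amount, sem_amount = {}, {}, {}, {}
    sample_ratios: Dict[str, List[float]] = {}
    sample_amounts: Dict[str, List[float]] = {}
    for sp in species:
        detection[sp] = 100.0 * sum(bool(r.detected.get(sp)) for r in results) / n
        ratios = [r.ratios[sp] for r in valid if sp in r.ratios]
        amounts = [r.amounts_fmol[sp] for r in valid if sp in r.amounts_fmol]
        sample_ratios[sp] = ratios
        sample_amounts[sp] = amounts
        median_ratio[sp] = float(np.median(ratios)) if ratios else float("nan")
        if amounts:
            mean_amount[sp] = float(np.mean(amounts))
            sem_amount[sp] = (
                float(np.std(amounts, ddof=1) / np.sqrt(len(amounts)))
                if len(amounts) > 1
                else 0.0
            )
        else:
            mean_amount[sp] = float("nan")
            sem_amount[sp] = float("nan")

    return CohortSummary(
        label=label,
        n=n,
        detection_rate=detection,
        median_ratio=median_ratio,
        mean_amount=mean_amount,
        sem_amount=sem_amount,
        n_standard_detected=len(valid),
        single_sample=(n == 1),
        sample_ratios=sample_ratios,
        sample_amounts=sample_amounts,
    )


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_cohorts(
    summaries: Mapping[str, CohortSummary],
    pairings: Sequence[Tuple[str, str]],
) -> pd.DataFrame:
    """One row per (species, pairing): medians, U, two-sided p, significance stars."""
    rows = []
    for label_a, label_b in pairings:
        for label in (label_a, label_b):
            if label not in summaries:
                raise InputError(f"unknown group label {label!r}")
        sa, sb = summaries[label_a], summaries[label_b]
        shared = sorted(set(sa.sample_ratios) & set(sb.sample_ratios))
        if not shared:
            raise InputError(f"groups {label_a!r} and {label_b!r} share no species")
        for sp in shared:
            u, p = mann_whitney(sa.sample_ratios[sp], sb.sample_ratios[sp])
            rows.append(
                {
                    "species": sp,
                    "group_a": label_a,
                    "group_b": label_b,
                    "n_a": len(sa.sample_ratios[sp]),
                    "n_b": len(sb.sample_ratios[sp]),
                    "median_a": sa.median_ratio[sp],
                    "median_b": sb.median_ratio[sp],
                    "U": u,
                    "p": p,
                    "significance": _stars(p),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "group_a", "group_b", "n_a", "n_b",
            "median_a", "median_b", "U", "p", "significance",
        ],
    )
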