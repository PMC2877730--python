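"""Pipeline orchestration: simulate → process → quantify → compare.

Each stage persists its artifacts as CSV/TSV under the output directory, logs
the config hash and seed, and is byte-deterministic for a fixed config.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as pqio
from .config import RunConfig
from .errors import InputError
from .process import process_spectrum
from .quantify import QuantResult, quantify_sample, standard_amount
from .simulate import GroundTruth, simulate_cohort
from .stats import compare_cohorts, summarize_cohort

logger = logging.getLogger("peptiquant")

MODES = ("simulate", "process", "quantify", "compare", "all")


def stage_simulate(config: RunConfig, out_dir: Path) -> Path:
    spectra_dir = out_dir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    species = list(config.species().values())
    instrument = config.instrument()
    fmt = config["format"]
    truth_rows = []
    for cohort in config["cohorts"]:
        label = cohort["label"]
        amounts = {
            name: (float(spec["mean"]), float(spec["sd"]))
            for name, spec in cohort["amounts"].items()
        }
        pairs = simulate_cohort(
            amounts,
            n=int(cohort["n"]),
            seed=config.rng_for(f"simulate:{label}"),
            species=species,
            instrument=instrument,
            matrix_nl=config["matrix_nl"],
            standard_nM=config["standard_nM"],
            standard_name=config["standard_name"],
            suppression_sigma=config["suppression_sigma"],
            adduct_fractions=config.adduct_fractions(),
            fix_mean=bool(cohort.get("fix_mean", False)),
            label=label,
        )
        for spectrum, truth in pairs:
            sample_id = spectrum.metadata["sample_id"]
            ext = "mzml" if fmt == "mzml" else "tsv"
            pqio.write_spectrum(spectrum, spectra_dir / f"{sample_id}.{ext}", fmt)
            for name, amount in truth.amounts_fmol.items():
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "cohort": label,
                        "species": name,
                        "amount_fmol": amount,
                        "suppression": spectrum.metadata["suppression"],
                    }
                )
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
    logger.info("simulate: wrote %d cohorts to %s", len(config["cohorts"]), spectra_dir)
    return spectra_dir


def stage_process(config: RunConfig, out_dir: Path) -> Path:
    spectra_dir = out_dir / "spectra"
    if not spectra_dir.is_dir():
        raise InputError(f"process: missing input directory {spectra_dir} (run simulate first)")
    truth_path = out_dir / "truth.csv"
    cohort_by_sample: Dict[str, str] = {}
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
        cohort_by_sample = dict(zip(truth["sample_id"].astype(str), truth["cohort"]))
    species = list(config.species().values())
    tol = config["tolerances"]
    rows = []
    paths = sorted(spectra_dir.iterdir())
    if not paths:
        raise InputError(f"process: no spectra found in {spectra_dir}")
    for path in paths:
        spectrum = pqio.read_spectrum(path)
        sample_id = str(spectrum.metadata.get("sample_id", path.stem))
        groups = process_spectrum(
            spectrum,
            species,
            baseline_window_da=tol["baseline_window_da"],
            snr_threshold=tol["snr_threshold"],
            mass_tol=tol["mass_tol_da"],
            spacing_tol=tol["spacing_tol_da"],
        )
        for group in groups:
            for adduct, peak in group.adduct_peaks.items():
                rows.append(
                    {
                        "sample_id": sample_id,
                        "cohort": cohort_by_sample.get(sample_id, ""),
                        "species": group.species,
                        "adduct": adduct,
                        "mz": peak.mz,
                        "intensity": peak.intensity,
                        "snr": peak.snr,
                        "detected": group.detected,
                        "summed_relative_intensity": group.summed_relative_intensity,
                    }
                )
            if not group.adduct_peaks:
                rows.append(
                    {
                        "sample_id": sample_id,
                        "cohort": cohort_by_sample.get(sample_id, ""),
                        "species": group.species,
                        "adduct": "",
                        "mz": np.nan,
                        "intensity": 0.0,
                        "snr": 0.0,
                        "detected": False,
                        "summed_relative_intensity": 0.0,
                    }
                )
    out = out_dir / "peakgroups.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    logger.info("process: wrote %s", out)
    return out


def _quant_results_from_peakgroups(config: RunConfig, out_dir: Path) -> List[QuantResult]:
    path = out_dir / "peakgroups.csv"
    if not path.exists():
        raise InputError(f"quantify: missing input {path} (run process first)")
    table = pd.read_csv(path, keep_default_na=False, na_values=["nan", ""])
    std_fmol = standard_amount(config["standard_nM"], config["matrix_nl"])
    standard_name = config["standard_name"]
    results = []
    for sample_id, sub in table.groupby("sample_id", sort=True):
        from .process import PeakGroup, Peak  # local import avoids cycle at module load

        groups = []
        for species_name, rows in sub.groupby("species"):
            g = PeakGroup(species=str(species_name))
            g.summed_relative_intensity = float(rows["summed_relative_intensity"].iloc[0])
            g.detected = bool(rows["detected"].iloc[0])
            for _, row in rows.iterrows():
                if row["adduct"] and not pd.isna(row["mz"]):
                    g.adduct_peaks[str(row["adduct"])] = Peak(
                        float(row["mz"]), float(row["intensity"]), float(row["snr"])
                    )
            groups.append(g)
        cohort = str(sub["cohort"].iloc[0]) if "cohort" in sub else None
        results.append(
            quantify_sample(groups, standard_name, std_fmol, str(sample_id), cohort)
        )
    return results


def stage_quantify(config: RunConfig, out_dir: Path) -> Path:
    results = _quant_results_from_peakgroups(config, out_dir)
    rows = []
    for r in results:
        for sp in sorted(r.ratios):
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "cohort": r.cohort or "",
                    "species": sp,
                    "ratio": r.ratios[sp],
                    "amount_fmol": r.amounts_fmol[sp],
                    "detected": r.detected[sp],
                    "standard_fmol": r.standard_fmol,
                    "standard_detected": r.standard_detected,
                }
            )
    out = out_dir / "quant.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    n_qc = sum(not r.standard_detected for r in results)
    if n_qc:
        logger.warning("quantify: %d sample(s) excluded (standard undetected)", n_qc)
    logger.info("quantify: wrote %s", out)
    return out


def stage_compare(config: RunConfig, out_dir: Path) -> Path:
    quant_path = out_dir / "quant.csv"
    if not quant_path.exists():
        raise InputError(f"compare: missing input {quant_path} (run quantify first)")
    results = _quant_results_from_peakgroups(config, out_dir)
    by_cohort: Dict[str, List[QuantResult]] = {}
    for r in results:
        by_cohort.setdefault(r.cohort or "cohort", []).append(r)
    summaries = {
        label: summarize_cohort(rs, label) for label, rs in by_cohort.items()
    }

    summary_rows = []
    for label, s in summaries.items():
        for sp in s.detection_rate:
            summary_rows.append(
                {
                    "cohort": label,
                    "species": sp,
                    "n": s.n,
                    "detection_rate_pct": s.detection_rate[sp],
                    "median_ratio": s.median_ratio[sp],
                    "mean_amount_fmol": s.mean_amount[sp],
                    "sem_amount_fmol": s.sem_amount[sp],
                    "n_standard_detected": s.n_standard_detected,
                }
            )
    pd.DataFrame(summary_rows).to_csv(out_dir / "summary.csv", index=False)

    pairings = [tuple(p) for p in config["comparisons"]]
    out = out_dir / "comparison.csv"
    if pairings:
        table = compare_cohorts(summaries, pairings)
        table.to_csv(out, index=False)
        report = out_dir / "report.txt"
        with report.open("w") as fh:
            fh.write(f"peptiquant comparison report (config {config.hash()})\n\n")
            fh.write(table.to_string(index=False))
            fh.write("\n\nstars: * p<0.05, ** p<0.01 (two-sided Mann-Whitney)\n")
    else:
        pd.DataFrame().to_csv(out, index=False)
    logger.info("compare: wrote %s", out)
    return out


def run_pipeline(config: RunConfig, mode: str, out_dir: Optional[str | Path] = None) -> Path:
    """Run one stage or the whole chain; returns the output directory."""
    if mode not in MODES:
        raise InputError(f"unknown mode {mode!r}; expected one of {MODES}")
    out = Path(out_dir) if out_dir is not None else Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run: mode=%s seed=%d config_hash=%s out=%s", mode, config.seed, config.hash(), out)
    stages = {
        "simulate": (stage_simulate,),
        "process": (stage_process,),
        "quantify": (stage_quantify,),
        "compare": (stage_compare,),
        "all": (stage_simulate, stage_process, stage_quantify, stage_compare),
    }[mode]
    for stage in stages:
        stage(config, out)
    return out
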