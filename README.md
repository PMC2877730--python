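# peptiquant

Quantitative direct MALDI-TOF peptide profiling of single insect corpora
cardiaca (CC) against a stable-isotope-labelled internal standard.

The package implements the complete desk-top pipeline around the measurement:

- **`peptiquant.chem`** — peptide elemental compositions, monoisotopic/average
  masses, singly charged H/Na/K adduct m/z values, aggregated isotope
  envelopes, and the prohormone maturation chain (signal-peptidase cut →
  convertase cleavage after the dibasic pair → stepwise carboxypeptidase
  trimming → Gly-consuming amidation with pyroglutamate formation). Built-in
  species: AKH (pGlu-LTFSPDW-amide), the processing intermediate AKHGK
  (pGlu-LTFSPDWGK free acid), and the heavy standard AKH* (¹³C₆,¹⁵N-Leu;
  [M+H]⁺ = 982.47 Da).
- **`peptiquant.simulate`** — synthetic single-CC profile spectra with known
  ground truth: Gaussian peaks with full isotope envelopes, per-species adduct
  partitions, one shared log-normal ion-suppression factor per spectrum,
  optional hyperbolic ionization saturation, exponential chemical baseline,
  detector noise, five-subspectrum averaging and an 850 Da low-mass gate.
  Cohort and dilution-series generators included.
- **`peptiquant.process`** — morphological (top-hat) baseline correction,
  MAD-based peak detection with matched-filter area gating, greedy
  de-isotoping with spectrum-integrated envelope completion, and adduct
  assignment into per-species summed relative intensities.
- **`peptiquant.quantify`** — analyte/standard intensity ratios, unity-slope
  absolute amounts (ratio × spiked standard fmol), and calibration fitting
  (ratio = k/[standard]) with automatic linear-range detection.
- **`peptiquant.stats`** — cohort summaries (detection rates, median ratios,
  mean ± s.e.m. amounts) and Mann-Whitney comparisons (exact enumeration for
  small tie-free cohorts, tie-corrected normal approximation otherwise).
- **`peptiquant.io` / `peptiquant.pipeline` / `peptiquant.cli`** — two-column
  TSV and minimal mzML 1.1 spectrum I/O, YAML run configuration with strict
  key validation and a single master seed, and the CLI.

## CLI

```bash
# full chain on the bundled day-5 control-vs-mutant configuration
peptiquant all --config src/peptiquant/configs/table1_day5.yaml --out results/demo

# individual stages (simulate | process | quantify | compare)
peptiquant simulate --config my_run.yaml --seed 7 --format mzml
```

Each run writes `spectra/` (TSV or mzML), `truth.csv`, `peakgroups.csv`,
`quant.csv`, `summary.csv`, `comparison.csv` and `report.txt` into the output
directory. Reruns with the same config and seed are byte-identical for the
deterministic stages; all randomness derives from the single config seed via a
documented per-stage splitting scheme.

Minimal config (every key except `seed` has a default; unknown keys are
rejected):

```yaml
seed: 1
standard_nM: 400      # internal standard in the matrix
matrix_nl: 200        # matrix volume per CC
cohorts:
  - label: control
    n: 15
    amounts: {AKH: {mean: 177, sd: 49}}
comparisons: []
```

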