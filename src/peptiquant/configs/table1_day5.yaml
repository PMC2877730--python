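# Day-5 adult cohorts: control (n=15) vs amon mutant (n=16).
# Ground-truth AKH means/sds pool the day-5 male and female table entries;
# AKHGK means are the reported ratio medians converted via unity slope x 80 fmol.
seed: 1
out_dir: results/table1_day5
standard_nM: 400
matrix_nl: 200
cohorts:
  - label: control
    n: 15
    fix_mean: true
    amounts:
      AKH: {mean: 177.0, sd: 49.0}
      AKHGK: {mean: 165.0, sd: 46.0}
  - label: amon
    n: 16
    fix_mean: true
    amounts:
      AKH: {mean: 21.6, sd: 10.0}
      AKHGK: {mean: 13.0, sd: 6.0}
comparisons:
  - [control, amon]
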