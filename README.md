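# cdpqc

Quality tools for cystine-dense peptide (CDP) liquid-chromatography
workflows:

* **Trace-pair classification** — automated four-category quality scoring
  (`Perfect`, `PerfectPartial`, `Simple`, `Complex`) of paired intact /
  DTT-reduced UV chromatograms: blank-run subtraction, robust noise
  estimation, SNR-gated peak detection with shoulder-peak flagging, and a
  total decision rule over the two peak lists.
* **In-silico peptide properties** — average and monoisotopic masses with
  the disulfide correction (two hydrogen atoms lost per formed bond, full
  oxidation assumed), net charge at pH 7.4 (Henderson–Hasselbalch, EMBOSS
  pKa set), Kyte–Doolittle hydrophobicity (GRAVY), duplicate-sequence
  detection, and ESI charge-state m/z validation.
* **WBA calibration** — linear standard-curve fit for whole-body
  autoradiography data and the raw-signal → decays-per-minute transform.
* **Synthetic data** — a labeled chromatogram-batch generator (Gaussian
  peaks, baseline drift, additive noise, blank run interleaved ahead of
  every three sample pairs) used for testing and benchmarking.

## CLI

All functionality is exposed through the `cdpqc` entry point:

```sh
# generate a labeled synthetic batch (trace CSVs + manifest + labels)
cdpqc simulate --out-dir batch/ --perfect 2 --perfect-partial 2 \
      --simple 2 --complex 2 --seed 7

# classify the batch; single-dash aliases -SN, -MinRTForPeak,
# -MaxRTForPeak, -Classification are accepted
cdpqc classify --manifest batch/manifest.csv --sn 10 \
      --min-rt-for-peak 5 --max-rt-for-peak 12 --classification 2 \
      --out report.csv

# peptide property table from FASTA and/or inline sequences
cdpqc props --fasta peptides.fasta --seq ACDCKGHW --out properties.csv

# standard-curve fit + dpm transform
cdpqc wba --standards standards.csv --tissues tissues.csv --out dpm.csv
```

Trace files are two-column `retention_time,absorbance` CSV (or TSV), with
an optional single header line; the batch manifest has columns
`run_index,sample_id,treatment,path`. Filenames following the
`<sampleid>_<INTACT|DTT|BLANK>.<ext>` convention are parsed automatically.
A `--config key=value` file can supply default flag values.

## Package layout

| module | contents |
| --- | --- |
| `cdpqc.trace_model` | `Trace`, batch layout / blank assignment, CSV I/O, filename parsing |
| `cdpqc.preprocess` | blank subtraction, MAD-based noise estimation |
| `cdpqc.peaks` | SNR-gated peak detection, shoulder flagging |
| `cdpqc.classify` | four-category pair decision rule, batch orchestration |
| `cdpqc.peptide_props` | masses, net charge, hydrophobicity, m/z validation, duplicates |
| `cdpqc.wba` | standard-curve fit, dpm transform |
| `cdpqc.synth` | synthetic trace/batch generator |
| `cdpqc.cli` | `cdpqc` command-line interface |
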