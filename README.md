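# ddrquant

Quantification toolkit for single-molecule TIRF experiments on motor-protein
activation: synthetic movie/kinetics simulation with ground truth, sub-pixel
spot localization and tracking, kymograph-based run-frequency and velocity
measurement, two-color colocalization/comigration and release-latency
analysis, dwell-time survival (1-CDF) fitting with right-censoring, and
mass-photometry skew-Gaussian mixture deconvolution.

Every analysis stage has a matching simulator with a recoverable truth, so
the pipeline is validated end-to-end by parameter recovery rather than by
eyeballing images.

## Modules

| module | purpose |
|---|---|
| `ddrquant.simulate` | synthetic movies (integrated-Gaussian PSF, EMCCD-style noise), motility/binding truth tables, labeling stoichiometry, mass sampling |
| `ddrquant.localization` | DoG spot detection, 2D Gaussian sub-pixel fitting, greedy nearest-neighbor track linking with gap closing |
| `ddrquant.motility` | microtubule path geometry, kymographs, processive-run detection, per-microtubule run frequency (runs µm⁻¹ s⁻¹) and normalization |
| `ddrquant.colocalization` | 300-nm one-to-one spot matching, chance-colocalization correction, comigration fraction, release latency |
| `ddrquant.kinetics` | dwell-event extraction, empirical 1-CDF, censored exponential MLE / least-squares survival fit, bleaching correction |
| `ddrquant.massphot` | contrast→mass calibration, skew-normal mixture EM, population percentages |
| `ddrquant.pipeline` | condition orchestration, labeling corrections (2p − p²), Welch t test, deterministic CSV/JSON reports |

## CLI

```bash
ddrquant simulate --config cfg.yaml --out sim/ --seed 1   # movie + truth tables
ddrquant detect   --movie sim/motility.tif --out spots.csv
ddrquant track    --spots spots.csv --out tracks.csv --max-disp 640
ddrquant runs     --tracks tracks.csv --paths sim/paths.csv --out runs.csv \
                  --frame-interval 0.5 --duration 300 --min-run-length 500
ddrquant coloc    --bait bait.csv --prey prey.csv --out coloc.csv --radius 300
ddrquant dwell    --events events.csv --out fit.json --method mle
ddrquant massfit  --samples masses.csv --out mixture.json --k 3 --plot fit.png
ddrquant report   --config tests/data/pipeline_config.yaml --out report/
```

All detection/linking/run thresholds are exposed as flags; defaults are
logged so a run is self-describing.

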