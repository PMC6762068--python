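# valvemonitor

Automated monitoring of prosthetic heart-valve function from pulsatile
flow-rate recordings.

A multi-beat flow recording is condensed into a standardized phase/flow
feature cloud (first-harmonic sinusoid fit → slicing at the fitted minima →
`tau = t mod T` phase wrapping → z-scoring). A patient-specific one-class
SVM — implemented from the dual formulation with an SMO-style pairwise
coordinate-ascent solver, RBF kernel — is trained on baseline (healthy-valve)
recordings. New recordings are scored with the **Model Compliance Index
(MCI)**: the fraction of samples the baseline model accepts as inliers.
Declining MCI indicates progressive valvular degradation such as aortic
regurgitation.

A pulsatile-flow simulator generates synthetic baseline and regurgitation
scenarios (half-sine systolic ejection, closure-reflux dip, constant
diastolic orifice leak with configurable area), so the entire pipeline is
testable without external data.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end calibration checks
(training-score calibration at 10,000 rows, QP-oracle equivalence of the
SMO solver, ν-property bounds, synthetic severity monotonicity with exact
rank-sum significance, sinusoid-fit recovery, Wilcoxon exactness).

## CLI

```sh
# 10 baseline recordings (60 BPM, 5 l/min, 60 Hz, 1000 samples each)
valvemonitor simulate --n-recordings 10 --seed 1 --scenario baseline --out base/

# severe regurgitation: 99.4 mm^2 leak orifice
valvemonitor simulate --n-recordings 8 --seed 2 --leak-area 99.4 --out severe/

# train the baseline model
valvemonitor train --in base/baseline_000.txt --in base/baseline_001.txt \
    --nu 0.05 --gamma 7.0 --model-out model.json

# score recordings -> MCI report (JSON or CSV)
valvemonitor score --model model.json --in severe/recording_000.txt --out report.json

# hyperparameter grid search, MCI monitoring over time
valvemonitor gridsearch --baseline base/*.txt --ar severe/*.txt --out grid.json
valvemonitor monitor --model model.json --in rec1.txt --in rec2.txt --out series.csv
```

Recordings are two-column text files (`time_s value`) with `#`-prefixed
metadata headers; the reader sniffs comma/semicolon/tab/whitespace
delimiters and accepts single-column files with a declared sample rate.
Models are versioned JSON documents. A `--config` YAML file can supply
per-subcommand option defaults; every subcommand is deterministic given
`--seed` and identical inputs.

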