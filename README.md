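# spikekin

Decoding hind-limb joint-angle trajectories (hip, knee, ankle) from
extracellular spike activity with a two-level stacked ensemble of
recurrent neural networks.

The pipeline covers:

- **`spikekin.synth`** — synthetic benchmark generator: stepping-like
  periodic joint kinematics, position-tuned spiking units (inhomogeneous
  Poisson thinning + refractory censoring), and optional raw extracellular
  traces rendered from waveform templates plus Gaussian noise.
- **`spikekin.signal`** — preprocessing of raw traces: 300–3000 Hz
  elliptic band-pass (order 4 high-pass + order 4 low-pass), robust noise
  estimation (MAD/0.6745), 4σ amplitude-threshold spike detection with
  peak alignment and dead-time merging, simplified PCA + k-means +
  silhouette spike sorting, and low-rate unit rejection.
- **`spikekin.features`** — the two decoder input streams: sliding-window
  firing rate (300 ms window, 50 ms hop → 20 Hz) smoothed by a
  linear-phase FIR low-pass, and the interspike-interval series resampled
  to 20 Hz through a natural cubic spline; plus time-aligned
  lagged-feature dataset assembly against decimated kinematics.
- **`spikekin.rnn`** — a recurrent multilayer perceptron with two sigmoid
  hidden layers, each receiving its own output delayed by one and two
  steps, and a linear 3-output readout; trained by a from-scratch
  Levenberg–Marquardt optimizer with an exact forward-propagated
  (RTRL-style) Jacobian, validated against finite differences.
- **`spikekin.stack`** — stacked generalization: FR-RNN and ISI-RNN
  level-0 decoders trained on the earlier half of the training rows, a
  level-1 RNN combiner trained on the later half from level-0 predictions,
  plus single-stream baselines.
- **`spikekin.evaluation`** — range-normalized RMS error and R² (percent),
  histogram mutual information (bits, equal-frequency bins),
  most-informative-unit selection, and law-of-cosines joint angles from
  five motion-capture markers.
- **`spikekin.pipeline` / `spikekin.cli`** — end-to-end orchestration with
  a schema-validated config, deterministic seeding and a re-run manifest.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (metric oracles,
feature correctness, gradient checks, LM teacher–student recovery, the
end-to-end synthetic benchmark, detection/sorting recovery, and MI
estimator checks). The end-to-end benchmark test takes a few minutes.

## CLI

```bash
# generate a synthetic session (spike trains + kinematics, optionally raw)
spikekin synth --duration 120 --units 4 --seed 1 --raw --out-dir data/

# raw trace -> unit-labelled spike trains
spikekin preprocess --in data/raw.bin --mult 4 --out data/sorted.tsv

# FR and ISI feature streams for one unit (0 = multiunit pool)
spikekin features --spikes data/spikes.tsv --unit 0 --out data/features.tsv

# train a single-stream decoder / the stacked decoder
spikekin train --spikes data/spikes.tsv --kin data/kinematics.tsv \
    --feature fr --epochs 40 --out data/fr_model.json
spikekin stack-train --spikes data/spikes.tsv --kin data/kinematics.tsv \
    --epochs 40 --out data/stack.json

# decode and score
spikekin predict --spikes data/spikes.tsv --kin data/kinematics.tsv \
    --model data/stack.json --stacked --out data/pred.tsv
spikekin evaluate --measured data/kinematics.tsv --predicted data/pred.tsv

# or run the whole synthetic experiment from one YAML config
spikekin run-all --config config.yaml --out-dir runs/exp1
```

`run-all` trains six decoder variants — {FR, ISI, stacked} × {multiunit,
most-informative single unit} — on the training trials and reports
per-joint NRMS/R² on the held-out test trials, writing `reports.json` and
a `manifest.json` (config hash, seed, versions) sufficient to re-run the
experiment bit-identically.

## Notes

- The recurrence is `y1(t) = σ(x(t)W1 + y1(t−1)V1 + y1(t−2)U1 + b1)`,
  `y2(t) = σ(y1(t)W2 + y2(t−1)V2 + y2(t−2)U2 + b2)`, `out(t) = y2(t)C`;
  hidden biases are included (interpretation), the readout is bias-free.
- All generators and trainers are pure functions of their arguments
  including seeds; repeated runs agree bit-for-bit.
- The first two output samples (zero initial hidden state) are excluded
  from the training loss and from scoring.
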