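# pursuitkit

Analysis and prediction of one-on-one chase/escape (pursuit–evasion)
trajectories on a bounded pitch. The package provides:

- **trajectory_io** — a trial data model (two synchronized 120 Hz position
  series per trial, condition label, outcome), CSV-per-trial + JSON-manifest
  persistence with bit-exact round trips, decimating downsampling, and
  forward-difference velocities.
- **synthetic_data** — an agent-based chase/escape simulator. The attacker
  reverses horizontal direction as a memoryless (Bernoulli) event with a
  refractory window; the defender pursues a delayed, linearly extrapolated
  percept of the attacker with configurable anticipation. Curated
  per-condition configs (`reference_configs`) reproduce the qualitative
  structure the analysis expects: heading-change entropy and short-latency
  response share both order narrow > square > wide, speed saturation > 90%,
  spatially uniform reversal frequency.
- **behavior_analysis** — direction-change detection (zero crossings of
  horizontal velocity), greedy response matching within a 0–500 ms window
  with a 150 ms short-latency criterion, heading-change histograms and
  Shannon entropy at 20 Hz, column-wise spatial statistics (4/8/16 columns),
  defender/attacker direction-change ratio, inter-change interval analysis
  with an exponential tail fit, speed saturation, and interpersonal-distance
  binning.
- **prediction_models** — parameter-free linear (L) and curvilinear (C)
  extrapolators, plus a NumPy implementation of seven trainable predictors
  (LN, NN, RNN, LSTM, DNN, DRNN, DLSTM; dims 6→64→128→5) with a bivariate
  Gaussian output head, trained by Adam (lr 3e-4, batch 16) on the Gaussian
  negative log-likelihood, with leave-one-participant-out cross-validation.
  All gradients are hand-derived and verified against finite differences.
- **rollout_eval** — one-step evaluation (relative-direction angular error,
  straight / gentle-curve / sharp-curve phase breakdown) and closed-loop
  sequential prediction up to 5 steps (250 ms) ahead with ADE/FDE, feeding
  predicted attacker state back as input while reading the defender's actual
  recorded state; recurrent models get a 2.5 s hidden-state warm-up.

## Command-line interface

```sh
pursuitkit simulate --out runs/square --condition square --seed 1
pursuitkit analyze runs/square --out runs/square_analysis
pursuitkit train runs/square --out runs/models --model NN --epochs 20
pursuitkit evaluate runs/square --out runs/eval --model L --model C --model runs/models/model_NN.npz
pursuitkit pipeline --out runs/demo --seed 1 --n-pairs 2 --trials-per-pair 10
pursuitkit ingest-figshare <download-dir> --out data/figshare
```

Every command writes a `run_manifest.json` (config hash, seed, package
version) beside its outputs.

## Conventions

- Coordinates: origin at pitch center; X horizontal (width axis), Y
  vertical. The attacker starts near the top edge, the defender at the
  center, and the end line is the bottom edge (Y = −height/2).
- Velocities are cm per sample interval (per-step displacements);
  `VelocityTrack.speed_cmps` converts to cm/s.
- Angles are signed degrees in (−180, 180], positive counterclockwise.
  Relative direction 0° means the target moves straight at the pursuer.
- Downsampling is plain decimation, so 20 Hz steps are exactly 50 ms.
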