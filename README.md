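# lapnet

Learned and exact linear-assignment solvers for frame-to-frame data
association in multi-target (cell) tracking.

The package implements:

- **Event-aware assignment** — an `(M+N)×(M+N)` augmented cost matrix whose
  dummy diagonal blocks price a track going *lost* or a measurement opening
  a *new* track at a fixed threshold, so track lifecycle decisions become
  part of a single square assignment problem (`lapnet.assignment`).
- **A residual convolutional score network** — a small fully-convolutional
  stack (Conv+ReLU, three Conv+BN+ReLU blocks, Conv) that maps a normalized
  cost matrix `C` to scores `Y = tanh(C − R(C))`, decoded into a permutation
  by a row-sequential masked softmax (pointing) decoder
  (`lapnet.policy`, `lapnet.layers`). Implemented in pure NumPy with an
  explicit, finite-difference-verified backward pass — no deep-learning
  framework required.
- **REINFORCE training** — advantage-weighted score-function gradients with
  persistent per-instance moving-average baselines and Adam on a
  step-decayed learning rate (`lapnet.training`).
- **A Kalman tracker** — constant-velocity prediction/update, Euclidean or
  Mahalanobis association distances, lost-track coasting and patience-based
  termination (`lapnet.tracking`).
- **Simulators and metrics** — seeded generators for planar
  maximum-weight-matching instances, two-frame association instances, and a
  five-target crossing scenario; OSPA-T, identity-switch counting, and
  optimality-ratio evaluation (`lapnet.simulate`, `lapnet.metrics`).

## CLI

```sh
# train a matching policy on generated instances
lapnet train --size 15 --samples 20000 --steps 4000 --temperature 0.2 \
             --objective maximize --out runs/policy_n15

# evaluate the median optimality ratio vs the Hungarian optimum
lapnet evaluate --checkpoint runs/policy_n15 --generate 1000 --size 15

# simulate a 5-target crossing scenario and track it with the exact solver
lapnet simulate --targets 5 --frames 40 --noise 0.01 --out-dir runs/scen
lapnet track --detections runs/scen/measurements.csv --tau 6 \
             --distance mahalanobis --sigma-accel 0.005 --out runs/tracks.csv

# full experiment drivers
lapnet experiment mwm --sizes 15,20,25 --out-dir runs/mwm
lapnet experiment tracking --noise-levels 0.01,0.05,0.1 --runs 100 \
             --out-dir runs/tracking
```

Detections are CSV `frame,x,y`; tracks are written as
`track_id,frame,x,y,status`. Checkpoints are an `.npz` parameter blob plus a
`.json` metadata sidecar.

## Notes on training

`TrainingConfig.schedule` optionally anneals the sampling temperature and
learning rate across evenly split phases (e.g.
`((0.3, 1e-3), (0.15, 5e-4), (0.08, 2e-4), (0.05, 1e-4))`) over one
persistent training set with persistent per-instance baselines. At desk
scale this noticeably outperforms a fixed temperature; the default (no
schedule, temperature 1.0) matches the base formulation.
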