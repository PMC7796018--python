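# raetrace

Hierarchical auto-encoder modelling of ambient smart-home sensor streams for
abnormal-behaviour detection. The package covers the full workflow:

- **event_io** — read/write plain-text sensor event logs (whitespace-separated
  `date time sensor value [activity begin|end]`), pair begin/end annotations
  into activity instances, and maintain a stable 34-sensor registry
  (31 motion + 3 door).
- **synthetic_data** — simulate a single-resident home: 11 activity classes on
  a jittered 24 h schedule, each emitting a first-order Markov chain of sensor
  activations, fully deterministic per seed.
- **anomaly_simulation** — inject ground-truth anomalies: whole activity
  instances copied into abnormal contexts (e.g. eating inside a sleeping
  span), or a characteristic sensor (work→M026, eating→M014,
  meal preparation→M018, bed to toilet→M004) repeated at random positions
  inside target instances.
- **features** — tumbling one-minute windows encoded two ways: a binary
  presence vector over the registry (BOS) and the ordered, repeat-preserving
  activation sequence with a one-hot matrix view (RSM).
- **rae_core** — recursive auto-encoder: shared encoder
  `p = tanh(W1 [c1;c2] + b1)` / decoder applied over a binary merge tree,
  built either as a right-to-left linear cascade or greedily (merge the
  adjacent pair with least reconstruction error at each level). Training is
  Adam on gradients backpropagated through the tree structure, unsupervised
  (reconstruction MSE) or semi-supervised (convex combination with a softmax
  cross-entropy per parent, weight `alpha`).
- **anomaly_detection** — per-window scores from node reconstruction errors
  (mean over parents or root only for token trees; mean parent error of a
  linear tree over 25 stacked presence rows), thresholding, and a
  mean-confidence wrapper for external classifiers.
- **metrics** — ROC/AUC over a full threshold sweep and macro-averaged
  precision/recall/F-measure plus accuracy.
- **patterns** — frequent sub-activity n-grams (n = 2, 3): the leaf tuples of
  the lowest-error subtrees across the training trees, ranked per activity.

## CLI

```bash
raetrace generate --days 20 --seed 1 --out log.txt
raetrace inject --mode subactivity --n 30 --seed 2 --in log.txt \
    --out log_abn.txt --truth truth.json
raetrace train --in log.txt --feature rsm --tree greedy --mode unsup \
    --checkpoint params.npz
raetrace score --checkpoint params.npz --in log_abn.txt --truth truth.json \
    --out scores.csv
raetrace evaluate --scores scores.csv --out roc.csv --plot roc.png
raetrace patterns --checkpoint params.npz --in log.txt --out patterns.csv
raetrace run --outdir demo_run --seed 1   # full pipeline, all artifacts
```

`raetrace run` writes train/test logs, ground truth, scores, the ROC table,
mined patterns, a report, and a manifest that reproduces the run byte for
byte.

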