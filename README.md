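# icbt-dynamics

Dynamic prediction of treatment outcomes in internet-delivered cognitive
behavioural therapy (iCBT), built around routine outcome monitoring of
depression (PHQ-9) and anxiety (GAD-7).

Clients in supported iCBT programs complete the PHQ-9 and GAD-7 at *review
periods* roughly every 1.8 weeks, for up to eight reviews. The clinically
established end-of-treatment outcome is **reliable improvement** (RI), a
reliable-change criterion: a decrease of ≥ 6 PHQ-9 points (depression) or
≥ 4 GAD-7 points (anxiety) between the first and last available measure,
with no disqualifying deterioration (≥ 4 GAD-7 / ≥ 6 PHQ-9 increase) on the
companion instrument. Because many clients stop early, the final score is
imputed by last observation carried forward (LOCF). The question this
package addresses: *given only the reviews observed so far, how well can
end-of-treatment reliable improvement be predicted at every review period —
and how early are those predictions reliable enough to act on?*

The package provides, for researchers in psychiatry/biostatistics and
ML-for-health:

- a **synthetic cohort generator** producing longitudinal clients with
  archetype-driven symptom trajectories, ordinal item scores, sparse
  platform-interaction counts, and informative early dropout, calibrated so
  RI prevalences match routinely reported service figures (~26% PHQ-9,
  ~38% GAD-7) and ~60% of clients have fewer than three reviews;
- **outcome labeling** (RI under LOCF, severity bands);
- four **featurizations** (total scores Q, item scores Qc, interaction
  counts I, combined I+Q) plus the fixed-length zero-fill + indicator
  encoding used by static classifiers;
- a **many-to-one LSTM sequence classifier** (numpy implementation with
  hand-written backpropagation through time, 50-dim hidden layer, dropout
  0.4, Adam) answering at any prefix length, and four benchmarks: logistic
  regression, random forest, gradient boosting, and an
  exponential-moving-average (EMA) trend follower;
- a **dynamic evaluation** layer: accuracy / sensitivity / specificity /
  AUROC and sensitivity at fixed specificities (90/95/97%), stratified by
  review period and baseline severity, with cluster-bootstrap intervals and
  Kaplan–Meier time-to-improvement curves;
- **error analysis** of false positives/negatives at a chosen prediction
  time, including near-threshold clustering of true changes.

## Worked example

```python
from icbt_dynamics.pipeline import ExperimentConfig, run_experiment, compare_models
from icbt_dynamics.models import RnnConfig

config = ExperimentConfig(
    n_clients=2000,
    generator_overrides={"n_interaction_types": 40},
    feature_sets=("Q",),
    targets=("phq9",),
    models=("rnn", "logistic_regression", "ema"),
    rnn=RnnConfig(seed=1, max_epochs=40),
    evaluate_on="validation",
    seed=7,
)
manifest = run_experiment(config)
print(compare_models({k.split("/")[0]: v for k, v in manifest.reports.items()}).round(3))
```

Output (accuracy per review period, 2000 synthetic clients):

```
       rnn  logistic_regression    ema
t
1    0.738                0.705  0.738
2    0.875                0.740  0.772
3    0.835                0.728  0.759
4    0.814                0.661  0.729
5    0.933                0.533  0.667
6    1.000                0.600  0.800
all  0.814                0.716  0.753
```

Each row is the accuracy of predictions made with exactly `t` reviews
observed (the `all` row pools every prediction time point). The sequence
model dominates the static benchmarks from the second review onward, and
its accuracy broadly rises as more measurements arrive — the
characteristic accuracy-vs-earliness trade-off of dynamic outcome
prediction. Late rows rest on few clients (heavy early dropout), hence the
noisier figures.

The same stages are exposed on the command line:

```bash
icbt-dynamics simulate --n-clients 1000 --seed 3 --out-dir cohort/
icbt-dynamics label    --in-dir cohort/ --out cohort/labels.csv
icbt-dynamics train    --in-dir cohort/ --labels cohort/labels.csv --model rnn --target phq9 --out model.pkl
icbt-dynamics evaluate --in-dir cohort/ --labels cohort/labels.csv --model-path model.pkl --target phq9 --out report.json
icbt-dynamics analyze-errors --in-dir cohort/ --labels cohort/labels.csv --model-path model.pkl --target phq9 --out-dir errors/
icbt-dynamics run      --seed 7 --out-dir experiment/
```

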