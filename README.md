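# popgrasp

Population analysis of factorial delayed-grasping experiments: per-unit
cluster-based permutation tuning tests, demixed PCA over task-factor
marginalizations, cross-dataset shared-component selection with
back-projection, and Monte-Carlo pseudo-trial decoding — validated end to
end on synthetic spiking populations with planted, known structure.

## The problem

In a delayed grasping task a subject is cued to grasp a handle in one of
five orientations, with a power or precision grip, using the left or right
hand — a balanced 2 × 2 × 5 design of 20 conditions. Single- and multi-units
recorded (non-simultaneously) from fronto-parietal areas carry mixtures of
these factors. The analysis questions are: *which units are tuned to which
factor, and when?* (a per-unit test with family-wise control over time),
*what are the population-level factor components?* (demixed dimensionality
reduction), *which components are genuinely shared across animals rather
than idiosyncratic artifacts?* (cross-dataset selection), and *can the
factors be decoded from single pseudo-trials?*.

## Methods at its core

- **CBPT** — per unit and factor, an independent-samples t-statistic over
  time; contiguous |t| > t_crit(α) runs form clusters scored by Σ|t|; the
  observed cluster mass is compared with the null distribution of the
  *largest* chance cluster over 1000 random trial partitions; Bonferroni
  correction over the three factors keeps the family-wise false-positive
  rate over all factors and time points below 5%.
- **dPCA** — the trial-averaged matrix X (units × condition·time) is split
  into additive marginalizations X_φ (time, hand, grip, orientation,
  interactions); per marginalization, encoder F_φ and decoder D_φ minimize
  ‖X_φ − F_φ D_φ X‖² + λ‖F_φ D_φ‖², solved by reduced-rank ridge regression;
  components pooled across φ and ranked by explained signal variance.
- **Shared-component selection** — pooled-dPCA components are retained only
  if their condition-time course correlates at |r| ≥ 0.6 with a component of
  dPCA fitted on *every* dataset separately; discarded dimensions are
  removed by back-projecting the retained ones into each dataset's unit
  space (using only that dataset's rows of the encoder/decoder).
- **Decoding** — 100 iterations of stratified Monte-Carlo leave-group-out
  cross-validation over pseudo-trials (one held-out trial per unit per
  condition), classifying on the factor's demixed axis, with a 100-shuffle
  chance distribution and a 200 ms contiguity rule for significance.

## Worked example

```python
import popgrasp as pg
from popgrasp.dpca import DemixedPCA

# two synthetic "animals" sharing hand/grip/orientation structure
cfg = pg.SynthConfig(
    n_units=30, n_datasets=2, trials_per_condition=10, baseline_hz=18.0,
    amplitudes={"time": 6.0, "hand": 4.0, "grip": 4.0, "orientation": 3.0},
    artifact=pg.ArtifactSpec(dataset_index=0, amplitude_hz=5.0),  # one animal only
    seed=33,
)
ds0 = pg.simulate_dataset(cfg, 0)
rates0 = pg.build_rate_tensor(ds0, mode="trial_averaged")
res = DemixedPCA(rates0).fit(n_components=5, reg=1e-6)
print(res.summary().to_string(index=False))
```

```
 component marginalization  explained_var_pct  cumulative_pct
         1            hand          28.322051       28.322051
         2            grip          23.947685       52.267576
         3     orientation           9.543505       61.785119
         4            hand           6.937224       68.558845
         5            time           6.409091       74.875354
```

The planted single-factor components and the condition-independent
component dominate, in amplitude order. The *second* hand component
(component 4) is the planted artifact: fitting both datasets and running
the shared-component test discards it — it correlates with a component of
dataset 0 only (|r| ≈ 0.99 vs ≈ 0.1 in dataset 1) and its decoder weights
load almost entirely on dataset-0 units. Back-projecting the retained
components removes ~90% of the artifact-window hand difference in dataset
0 while preserving the shared sustained hand signal within a few percent
(see `tests/test_acceptance.py`).

The same populations feed the per-unit test and the decoder:

```python
from popgrasp.cbpt import run_population_cbpt, task_related
results = run_population_cbpt(ds0, n_perm=1000, seed=1)
print(sum(task_related(r) for r in results), "of", len(results), "units task-related")

run = pg.decode_factor(pg.build_rate_tensor(ds0), "hand", n_iter=100, n_shuffles=100, seed=2)
print("peak accuracy %.2f, chance %.2f" % (run.mean_accuracy.max(), run.chance_level))
print("significant intervals:", run.intervals[:2])
```

```
29 of 30 units task-related
peak accuracy 1.00, chance 0.50
significant intervals: [(-500.0, 40.0), (220.0, 500.0)]
```

29 of 30 planted units are detected (the stragglers are units whose random
loadings happen to be near zero), hand is decoded perfectly while its
planted signal is active (the intervals cover the pre-movement and
movement epochs of the movement alignment), and the shuffle null sits at
the two-class chance level.

The full chain (synth → rates → cbpt → dpca → shared → decode) also runs
from one config via `popgrasp run --config demo.yaml --out results/`, or
stage by stage (`popgrasp synth`, `popgrasp rates`, `popgrasp cbpt`,
`popgrasp dpca`, `popgrasp shared`, `popgrasp decode`).

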