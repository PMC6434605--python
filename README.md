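# seabird-ethogram

Behavioral classification of seabird biologger data: from raw tri-axial
accelerometer records to per-second behavioral ethograms, validated
activity budgets and daily energy expenditure.

## Who this is for

Movement ecologists with back-mounted accelerometer (+ depth, + GPS)
deployments on central-place foraging seabirds — the package ships
presets for thick-billed murres (*Uria lomvia*; 25 Hz acceleration,
1 Hz depth, 60 s GPS) and black-legged kittiwakes (*Rissa tridactyla*;
25 Hz acceleration, 30 s GPS) — who want a daily activity budget
(colony / flying / swimming / diving) without direct observation of
the animals, and who want to know whether their choice of classifier
matters.

## What it does

**Metrics.** Static (gravity) acceleration is a 2-s moving mean per
axis; pitch is `atan(S_X/√(S_Y²+S_Z²))`; dynamic acceleration is the
residual, summarised by ODBA = `|D_X|+|D_Y|+|D_Z|` and its 2-s moving
SD (murres) or the 2-s SD of the heave axis (kittiwakes); wing-beat
frequency (WBF) is the dominant 5-s-window frequency of the heave axis
with sub-bin peak interpolation. Pitch is standardized to 0° during
flapping flight (WBF in 6–9 Hz for murres, 3–6 Hz for kittiwakes) to
remove logger mounting offsets.

**Six classifiers**, all emitting per-second ethograms: histogram
segregation (density-valley thresholds), neural network (5 hidden
units) and random forest (500 trees) trained on the histogram labels,
two-step k-means and Gaussian-mixture EM (flight from WBF, then
colony/swimming from segment pitch and activity), and a hidden Markov
model with behaviorally forbidden transitions pinned to zero and
mixed emission families, decoded by Viterbi.

**Validation.** Concurrent GPS tracks give rule-based reference labels
(ground speed, distance to nest, depth), with exclusion windows around
behavior transitions; accuracy is summarised per bird and pooled as
overall and per-behavior balanced accuracy. Budgets convert to daily
energy expenditure through behavior-specific coefficients
(e.g. DEE = 32.0·t_c + 532.8·t_f + 100.8·t_s + 97.2·t_d kJ/day for
murres).

**Synthetic deployments.** A semi-Markov simulator generates whole
deployments — behavior sequences respecting the behavioral adjacency
constraints, 25 Hz acceleration with the two species' class-conditional
signal structure, dive profiles, and GPS tracks consistent with the
labeling rules — so the entire pipeline is testable end to end without
field data. See `docs/methods.md` for the model details.

## Worked example

Simulate one murre deployment, classify it with the histogram method,
and score it against the GPS-rule reference:

```python
import ethogram as eg

config = eg.get_config("murre", "chick")
states, trace, gps = eg.simulate_deployment(config, duration_hours=24, seed=7)

features = eg.prepare_features(trace, config)      # 1-s grid, calibrated pitch
ethogram = eg.classify_hs(features, config)        # per-second behaviors
reference = eg.reference_labels(gps, features, config)
summary = eg.score(ethogram, reference, config)

budget = eg.activity_budget(ethogram)
print(f"overall accuracy: {summary.overall_accuracy:.3f}")
print(f"balanced accuracy: { {k: round(v, 3) for k, v in summary.balanced_accuracy.items()} }")
print(budget.round(2))
print(f"DEE: {float(eg.daily_energy(budget, config).iloc[0]):.0f} kJ/day")
```

Output:

```
overall accuracy: 1.000
balanced accuracy: {'colony': 1.0, 'diving': 1.0, 'flying': 1.0, 'swimming': 1.0}
behavior  colony  diving  flying  swimming
day
0           9.61    1.28    5.01      8.11
DEE: 3916 kJ/day
```

The confusion matrix is over the 1,312 usable GPS fixes (of 1,440;
the other 128 fall in transition windows around behavior changes).
This bird spent 9.6 h at the nest, 5.0 h flying, 8.1 h on the water
and 1.3 h under it, for an estimated 3,916 kJ/day — flight dominates
the budget at 532.8 kJ/h.

The same pipeline is scriptable from the shell:

```bash
ethogram simulate --species murre --hours 24 --birds 2 --seed 7 --out sim/
ethogram features sim/bird7_accel.csv --species murre --out feats.csv
ethogram classify --method hmm --species murre --in feats.csv --out eth.csv
ethogram validate --ethogram eth.csv --gps sim/bird7_gps.csv \
    --features feats.csv --species murre --out summary.json
```

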