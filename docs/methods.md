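# Methods

This note documents the models and procedures the package implements,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Problem and scope

Back-mounted biologgers on breeding seabirds record tri-axial
acceleration (25 Hz), depth (1 Hz, murres) and GPS fixes (60 s murres,
30 s kittiwakes). The package turns those records into a per-second
ethogram over the coarse behaviors that make up a daily activity
budget — nest attendance ("colony"), flapping flight, swimming, and
diving for murres — and converts the budget into daily energy
expenditure. Six classification methods are implemented so their
agreement can be assessed on a common footing: histogram segregation
(HS), neural network (NN), random forest (RF), k-means (KM),
Gaussian-mixture EM (EM), and a constrained hidden Markov model (HMM).
Concurrent GPS tracks supply reference labels for validation, so no
direct observation of the animals is required.

## Accelerometer metrics

Static acceleration is a 2-s centered moving mean per axis; the dynamic
component is the residual, so raw = static + dynamic holds exactly at
every sample. Pitch is `atan(S_X / sqrt(S_Y² + S_Z²))` in degrees.
ODBA is `|D_X| + |D_Y| + |D_Z|`; activity is summarised by the 2-s
moving standard deviation of ODBA (murres) or of `D_Z` (kittiwakes),
with the population denominator `N`. Wing-beat frequency (WBF) is the
dominant frequency of the heave axis over a centered 5-s window: the
window is demeaned, the periodogram peak located with the DC bin
excluded, and the peak refined by quadratic interpolation of the three
power values around it (the raw bin width at 25 Hz and 5 s is 0.2 Hz,
too coarse for the ~0.1 Hz structure of interest). Windows whose peak
power does not exceed **3× the window's median spectral power** report
0 Hz; this floor suppresses near-still windows while letting genuine
low-frequency motion (body movements, sea-surface waves) through to be
handled by classification. Moving windows are centered with truncated
edges, avoiding phase lag between features and labels. Everything is
computed at 25 Hz and subsampled to a 1-s grid, the resolution all
classifiers consume.

Pitch is calibrated per deployment: the mean pitch over presumed
flight (WBF inside the species band, 6–9 Hz murres, 3–6 Hz kittiwakes)
is an estimate of the logger mounting offset, because flying birds hold
a consistent, near-level body angle; it is subtracted from the whole
record. Deployments with under 60 s of presumed flight are left
uncalibrated with a warning. Calibration is an additive offset in the
pitch channel, not a full axis rotation — sufficient for its purpose of
removing device-orientation differences between birds.

## Segmentation

Diving (depth below −1 m, murres) and flying are identified on the 1-s
grid first; runs shorter than 3 s are re-assigned to the preceding
behavior (leading short runs absorb into the first surviving run, a
case the rule itself leaves open); maximal constant-label runs are then
cut left-to-right into segments of at most 120 s, with the remainder
last. The cap bounds the damage of a missed transition and keeps long
incubation bouts from dominating the segment population. Colony versus
swimming is decided per segment from mean pitch and mean activity.
Re-assigned short runs are merged in a single left-to-right pass; the
pass is idempotent.

## Classification methods

**HS** places thresholds at density valleys. The density of each
metric (Gaussian KDE, Silverman bandwidth, evaluated on a grid extended
three bandwidths past the data range) is scanned for local maxima and
the threshold is the minimum between the two highest peaks. This
automates what is otherwise a visual step, so two guards reject valleys
a human would: a WBF valley only counts if the values above it average
inside or above the flight band; an activity valley only if the two
sides differ by at least a factor of two (activity classes differ
multiplicatively); a pitch valley only if it actually separates upright
(> 15°) from prone (< 15°) postures. When a per-track valley is
rejected the pooled-population threshold is used; when that also fails,
segments fall back to the posture rule at 15°, roughly midway between
water (≈ −10–5°) and nest (≈ 30–40°) postures. Murres: diving by
depth, flying by WBF, then swimming by high activity and colony by high
pitch; kittiwakes: flying by WBF, colony by low SD_Z, then swimming by
low pitch.

**NN / RF** are trained on HS labels (never on GPS data): 10 randomly
chosen tracks, up to 1,000 rows per behavior per track. Inputs are
pitch, the activity metric, WBF, and depth for murres. The NN is a
single-hidden-layer softmax network with 5 logistic hidden units,
standardized inputs, up to 5 re-initializations on non-convergence; the
RF uses 500 trees with √p features per split. Depth below −1 m
overrides predictions to diving.

**KM / EM** are unsupervised and pooled over all tracks. Step 1
clusters per-second WBF into two classes (diving seconds removed
first); the higher-center class is flying. Step 2 clusters the
remaining segments on [pitch, ln(activity)], both min–max scaled, with
three classes for KM (two colony + one swimming) and 3–6 classes for EM
chosen by BIC (Gaussian mixtures, free proportions, full covariance).
Clusters map to behaviors through their feature means only, never their
indices: clusters are scored by scaled activity minus scaled pitch
(swimming is active and prone, colony quiet and upright) and split at
the largest score gap. An absolute-scale guard (activity contrast
below 2× and pitch spread below 25°) detects single-behavior pools and
falls back to the per-cluster posture rule, so degenerate tracks are
never force-split.

**HMM** observations are bin means over 5 s (murres; preserves short
inter-dive intervals) or 10 s (kittiwakes) of pitch, activity and WBF,
plus a binary below-−1 m depth indicator for murres. Emissions: Normal
for pitch; Exponential for murre SD_ODBA; zero-inflated log-normal (a
point mass at zero with probability π plus a log-normal on positive
values — the zeros come from the WBF noise floor) for WBF and kittiwake
SD_Z; Bernoulli for the depth indicator with probabilities 10⁻¹² and
1−10⁻¹², held fixed so diving stays anchored to the pressure sensor.
The log-normal location parameter is the median in natural units
(Hz or g); the scale is the log-space SD. Kittiwakes carry two colony
states (quiet and active nest attendance) merged after decoding.
Transitions that are behaviorally impossible — colony↔swimming,
colony↔diving, flying↔diving (and both colony states ↔ swimming for
kittiwakes) — are structurally zero: they start at zero and remain
exactly zero through Baum–Welch, because the expected count of a
zero-probability transition is zero. Starting transition matrices put
0.99 on self-transitions (bouts are long relative to the bin) with the
remainder uniform over allowed moves. The model is fitted jointly over
all tracks by at most 10 EM iterations (relative log-likelihood
tolerance 10⁻⁴; the starting values are close enough that this
converges in practice) and decoded per track by Viterbi; decoded bins
are expanded to the 1-s grid by repetition. The forward–backward and
Viterbi recursions are log-space numba kernels.

## GPS reference labels and scoring

Murres: fixes needing ground speed above 30 m/s are excluded as GPS
errors; depth below −1 m is diving; speed above 2 m/s is flying; within
250 m of the nest is colony; the rest is swimming — applied in that
order of precedence (all inequalities strict). Kittiwakes: speed above
20 m/s or a fix gap over 10 min is excluded; fixes within 500 m of the
island are excluded (loafing on tidal flats cannot be separated from
swimming there, so kittiwake references contain only flying and
swimming); speed above 3 m/s is flying; the rest swimming. Because a
fix interval cannot resolve the moment of a behavior change, every fix
within 60 s (murres) or 30 s (kittiwakes) of the midpoint between two
differently-labeled fixes is excluded; diving↔swimming changes are
exempt (depth is sampled at 1 Hz). Ethograms are subsampled to the fix
grid (nearest second) and summarised by the confusion matrix: overall
accuracy and one-vs-rest balanced accuracy per behavior, per bird and
pooled.

## Energetics

An activity budget is hours per behavior per successive 24-h block.
Daily energy expenditure is linear in the budget:
DEE = 32.0·t_c + 532.8·t_f + 100.8·t_s + 97.2·t_d kJ/day for murres and
DEE = 21.0·t_c + 99.9·t_f + 25.8·t_s for kittiwakes (coefficients in
kJ per hour of colony, flight, swimming, diving; the kittiwake values
derive from activity-specific CO₂ production converted at 27.33 kJ/L
CO₂ for a 416 g bird — the conversion is documentation, the
coefficients are what the code stores).

## Extended metric library and variable selection

The 42 accelerometer candidates are 12 statistics per axis — raw
value, static, dynamic, windowed SD, min, max, range, skew, excess
kurtosis, least-squares trend, lag-1 autocorrelation (all over the 2-s
window) and the 5-s dominant frequency (the heave-axis one being WBF) —
plus pitch, roll, ODBA, its windowed mean, SD_ODBA and windowed range.
Depth is appended for murres, giving 43 candidates for divers.
Statistics are evaluated over the window centered on each requested
time point, clamped inside the track at the edges, which makes sparse
evaluation (e.g. at GPS fix times) cheap.

Variable selection trains on GPS-labeled rows. Because GPS fixes are
sparse (few hundred per behavior per track, far fewer than the 1,000
rows per class the training recipe samples), the GPS-rule labels are
first carried onto the 1-s accelerometer grid: each usable fix labels
the seconds within half a fix interval of it, and for divers the 1 Hz
depth channel then resolves dive boundaries exactly — the same
information the reference rules themselves use. Transition exclusion
guarantees surviving fixes sit more than half an interval from any
behavior change, so the expanded labels are clean (measured purity
against simulator truth ≈ 99.8%).

A global forest on all candidates ranks Gini importance and keeps the
top 20. Forward selection then adds, at each step, the candidate with
the highest median held-out accuracy over resampled training sets (10
tracks, up to 1,000 rows per class per track); the held-out set of a
simulation is the rows not sampled into its training set (capped at
10,000 rows for evaluation). Training-set draws are shared across a
step's candidates, making the comparison paired. Candidate-evaluation
forests are deliberately small — 10 trees capped at 64 leaves, against
the production classifier's 500 unrestricted trees — because an
accuracy *estimate* for a 1–3 variable model neither needs nor
benefits from a large ensemble, while an unrestricted tree grown on a
single weakly-informative candidate can be enormous; the reported
interval is the 2.5th–97.5th percentile over simulations.

## The synthetic deployment generator

The generator emulates exactly the signal structure the classifiers
exploit, with defaults set from the two species' printed class
statistics; they are the study conditions, not tuning knobs.

*Behavior sequences* are semi-Markov: log-normal bout durations
arranged into central-place foraging trips (colony → flight out →
water → flight home → colony), with murre dives embedded inside
swimming. This enforces the behavioral adjacency constraints by
construction and produces no bout under 10 s, so the 3-s minimum-bout
rule is only ever triggered by classifier noise, as on real data. The
inbound flight duration is the outbound duration × U(0.92, 1.08): a
bird commutes home over the same distance, and this keeps the return
ground speed inside the species flight band given position continuity.
Bout-duration medians (colony 40 min chick / 80 min egg murre, 30/60
min kittiwake; flight 8 min; swimming 5–7 min) are field-plausible free
parameters; no test depends on them beyond the invariants above.

*Acceleration*: the static component realizes the bout's pitch (drawn
per bout from the class distribution — murre colony 37.6 ± 6.1°,
swimming −7.4 ± 2.5°; kittiwake colony 29.9 ± 11.7°, swimming
5.7 ± 2.9°; flight 0°) via rotation of the gravity vector, plus a slow
postural wander (SD 2°, ~30 s correlation) because birds shift
position within bouts. Dynamic body noise is a resonant AR(2) process
(pole radius 0.92) centered at a behavior-specific frequency — 0.6 Hz
for quiet colony shuffling, 1.3 Hz for paddling/wave motion on the
water, 1.5 Hz during dives, 1 Hz in flight — scaled per bout so the
species activity metric hits the class value (murre SD_ODBA
0.05 ± 0.02 g colony, 0.28 ± 0.08 g swimming; kittiwake SD_Z
0.04 ± 0.02 / 0.18 ± 0.04 g). The band-limited spectrum matters twice
over: white noise would scatter spurious spectral peaks uniformly up
to the Nyquist frequency, while noise red-shifted all the way to DC
would leak through the 2-s moving mean and corrupt the posture
estimate; real body motion concentrates between roughly 0.5 and 2 Hz,
above the static-estimation passband but at the bottom of the
spectrum, which is exactly the structure the non-flight WBF classes
and the pitch separation both assume. Flight adds a heave-axis sinusoid at the species wing-beat
frequency (8.1 Hz murre, 4.16 Hz kittiwake; amplitude 1.0 / 0.85 g)
with a per-bout offset (SD 0.1 Hz) and slow within-bout jitter (SD 0.15
Hz, ~10 s correlation); segment-level frequency spread is therefore
somewhat tighter than the printed ±0.25 Hz — a deliberate choice that
makes the population frequency a stable target for the estimator
benchmark. White sensor noise (0.01 g) overlays everything; it is what
makes lag-1 autocorrelation informative about activity level. Murre
dives get a V/U depth profile at 1 m/s vertical to a depth drawn from
−20.5 ± 9.0 m (clipped below −3 m), sampled at 1 Hz and step-filled; a
per-deployment mounting-pitch offset uniform in ±15° exercises the
calibration step.

*GPS*: colony positions jitter within tens of meters of the nest at the
origin; flight legs are straight commutes at 12 ± 1.5 m/s (murre) or
8 ± 1 m/s (kittiwake); water time is a mean-reverting drift (OU, 60 m
positional SD, 300 s relaxation) around the trip's offshore anchor, so
fix-to-fix swim speeds stay well under the flight thresholds; 2 m fix
noise overlays everything.

What the generator does **not** emulate: gliding or wind-assisted
flight (kittiwakes glide in the field, which blurs their WBF signal),
sea-surface wave spectra, temperature channels, GPS dropouts, axis
misalignment beyond a pitch offset, and fine-scale behaviors (prey
capture, preening). Accuracies on synthetic cohorts are therefore an
upper plausibility check of the pipeline's correctness — that every
method recovers behaviors whose class structure matches its
assumptions — not a field-accuracy estimate.

## Benchmark problem sizes

The shipped benchmarks use 10 birds × 48 h per species (seeds
`seed..seed+9`), scored at 60 s / 30 s; variable selection uses 3
forward steps × 20 simulations with the top-20 prefilter. These sizes
give stable summary statistics (60 method×bird accuracies per species)
on a single CPU in minutes.

## Known limitations

- The HS automation replaces a visual step; its guards encode the two
  species' postural geometry (the 15° upright cutoff) and would need
  revisiting for species with different nest postures.
- The HMM fixes the depth Bernoulli and fits everything else; a state
  collapsing to zero weight keeps its previous parameters rather than
  being pruned.
- Kittiwake validation cannot score colony behavior at all (the
  near-island exclusion removes it), so kittiwake accuracies describe
  flying/swimming discrimination only.
- `read_accel_csv` expects the package's own CSV dialect; vendor export
  formats must be converted first.
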