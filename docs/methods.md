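# Methods

## Pipeline model

One *recording* is a channels × samples monopolar HD-EMG matrix from three
electrode grids (A1 6×16 over anconeus / brachioradialis / pronator teres;
A2 and A3 6×12 over biceps and triceps brachii; 10 mm pitch; 240 channels),
with a torque trace in %MVC on the same 2048 Hz time base. Grid coordinates
are 1-based (i, j); flat channel indices are 0-based row-major. The
channel-to-muscle split of A1 is not recoverable from the experimental
description, so it is a configurable column partition (default 1–5 / 6–11 /
12–16).

Processing order: artifact screening on the raw monopolar signals; then the
zero-phase 15–350 Hz 4th-order Butterworth band-pass (applied
forward–backward, which squares the designed magnitude response); then LMS
cancellation of the power-line fundamental and its first 6 harmonics.
Screening inspects only the fundamental plus four harmonics — the two
stages intentionally differ, following the source protocol. The original
screening thresholds are unpublished; the defaults (low-frequency relative
power ≤ 0.25, power-line relative power ≤ 0.50, mean-square power within
[1e-4, 25] mV²) are calibration knobs, exposed in `QualityThresholds`.

Artifact repair happens in the *map* domain (cells of the 250 ms RMS
activation map replaced by Clough–Tocher triangle-based cubic
interpolation, nearest-neighbour outside the convex hull of good cells),
not on the raw signals; the protocol text attaches the replacement to map
calculation, and the choice is recorded in the API rather than hidden.

Windows are aligned to sample 0 and indexed identically everywhere
(mapping, torque epoching, features), so an epoch's features and its torque
summary describe the same span. Log features clamp their argument at
ε = 1e-6 mV: rest windows can be near-silent and the logarithm must stay
finite. The center of gravity of an all-zero map is undefined; the
feature-vector builder substitutes the grid centroid for such windows
(documented fallback, affects only silent rest epochs). The single
differential's site defaults to the middle row / central column of each
muscle region with the fiber direction along rows; both are configurable
because the original electrode pair is unrecoverable.

## Epoch selection

"Closest to the target force" is operationalised as the absolute difference
between window-mean torque and target, ties broken by earlier start time.
The rest-class selector ranks candidate windows (entirely inside the 3 s
rest prefix) by mean |torque| ascending — the original ranking among the
144 candidates is unstated; a seeded `random` mode is available. In the
13-class scheme the rest class is balanced down to the per-cell count (20)
by taking the best-ranked rest epochs, since the evaluator requires equal
class counts. TDC (total duration of contraction) starts when the 3 s rest
prefix ends and runs to the end of the recording; quintiles are contiguous
equal-count window ranges with the remainder assigned to the last.

## Classification and evaluation

`ShrinkageLDA` fits class means and a pooled within-class covariance plus
λ·I (λ = 1e-6 by default — the source specifies no regularisation; the
ridge guards rank-deficient feature sets) with uniform priors, since every
training set here is balanced by construction. Evaluation repeats a random
balanced 50/50 split (1000 iterations by default), computes one-vs-rest
indices per iteration from the validation confusion matrix, and averages
afterwards — matching mean ± sd reporting, rather than pooling confusions
first. Headline numbers are macro-averages over classes. Precision of a
never-predicted class is undefined and excluded from averages. All
randomness descends from one master seed through spawned substreams, so
results are bit-reproducible.

In the time-effect protocol, training takes half of every task×level cell
(levels mixed) plus half of the part-1 rest pool; condition A validates on
the held-out 50 %MVC epochs plus held-out part-1 rest, condition B on the
0–20 % TDC slice of the part-2 contractions plus part-2 rest. The rest
class is balanced to the per-task count. In the fatigue protocol the
per-class count is the smallest quintile size; quintile 1 validates on its
held-out half so training and validation never overlap.

## Synthetic sessions

The generator is the package's stand-in for patient recordings; it encodes
the phenomenology the pipeline is sensitive to, not motor-unit physiology.
Each muscle carries one band-limited (15–350 Hz) Gaussian source shared by
its grid channels through a 2-D Gaussian spatial profile; channels add
independent instrumentation noise (0.02 mV RMS) and optional power-line
harmonics. Key parameters, with defaults and rationale:

* **Gain table** — per (muscle, task) source RMS at 100 % MVC, 0.15–0.60 mV.
  Non-prime movers keep a substantial co-activation floor: task-specific
  *co-activation patterns* are what distinguishes classes in impaired motor
  control, and without them the classes are unrealistically separable.
* **Level law** — gain ∝ level^0.7: the EMG-amplitude/force relation is
  non-linear, which is also why the intensity feature is logarithmic.
* **Effort fluctuation** — slow (≤2 Hz) log-normal wander of each muscle's
  drive, CV 0.12. Force-matched contractions are not amplitude-stationary;
  without this term within-class feature variance collapses to windowing
  noise and every classifier saturates.
* **Torque** — target %MVC plus smooth noise (SD 1 %MVC), small enough that
  every submaximal contraction satisfies the epoching band by construction.
* **Fatigue** (endurance trials): amplitude slope +80 % of gain over the
  full contraction, scaled per muscle by its relative load (fatigue
  develops in the muscles doing the work — uniform drift would shift all
  log-intensities equally, a direction LDA is trivially invariant to);
  spectral compression of the source's upper band edge to half by the end
  of contraction (median frequency falls ~30–50 %, and since compression is
  not re-normalised it also curbs amplitude, as narrowing bandwidth does);
  spatial-spread growth +50 % of σ (fatigued motor-unit potentials are
  longer and spatially wider; this is the mechanism that erodes
  adjacent-channel differentials while leaving the map centroid intact).
* **Gel drift** (part-2 trials): per-channel log-gain offset N(0, 0.25)
  drawn once per recording (gel dries between protocol parts) plus a slow
  within-recording random walk (step SD 0.02 at 4 Hz nodes). Averaging over
  a grid protects map features; a single bipolar pair has no such
  protection.

Fixture presets run at reduced scale (five 5×5 single-muscle grids,
1024 Hz) to keep tests fast; `spatial_only` places the four task sources at
symmetric interior positions of each grid so the truncated profiles have
*identical* total mass — intensity is chance-level by construction while
the centroid separates tasks.

What a green test does **not** establish: the generator has no motor-unit
action potentials, no volume conductor, no real electrode artifacts beyond
the injected archetypes, and one source per muscle — so absolute index
values on synthetic sessions say nothing about patient-level performance;
only the *relative* behaviour of feature sets under the simulated
manipulations is meaningful.

## Numerical and statistical choices

The LMS canceller uses unit-variance sine/cosine reference pairs and step
1e-3: convergence within ~0.5 s against a notch bandwidth of well under
1 Hz per harmonic. A divergence detector (running output power > 10× input,
or non-finite) aborts adaptation. Zero-phase filtering means "4th order"
describes the designed filter, applied twice.

Paired t and the mixed (one within × one between factor) repeated-measures
ANOVA are computed from the classical sums-of-squares formulas;
Greenhouse–Geisser ε comes from the double-centred pooled within-group
covariance and Mauchly's W from its orthonormal-contrast transform with
Box's chi-square approximation (second-order term included). The GG
correction is applied only when Mauchly rejects at α = 0.05; Huynh–Feldt is
deliberately not offered. With two repeated measures sphericity is vacuous
(ε = 1, W = 1). Note the GG adjustment is conservative (raises p) only
where F ≥ 1; below that the question is moot since the unadjusted p is
already far from significance.

## Known limitations

* Subject-specific only: no pooled / inter-subject classification.
* No real-data readers beyond the package's own bundle format (an EDF
  adapter was considered and deferred).
* The fatigue model drives amplitude, spectrum, and spatial spread but not
  torque (simulated subjects hold the target until the recording ends).
* Frequency-domain features are out of scope.
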