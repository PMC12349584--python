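# Methods

## Device model and conventions

The sensor mat is an `n_rows × n_cols` grid (default 8 × 5) of pressure
sensors addressed by 1-based `(row, column)` coordinates; `(1,1)` is the
first crossing and `(8,5)` the last, and all I/O and reports use this
convention. Readings are nonnegative and in arbitrary device units; nothing
downstream assumes a physical calibration. Damaged sensors (the clinical
prototype has one at `(8,5)`) are *masked*, not zero-filled: medians, means
and variances are computed over valid sensors only, so denominators shrink
accordingly. Raw device timestamps are not assumed uniform; every pipeline
starts by piecewise-linear resampling onto an exact uniform grid
(`t0 + k/rate`). Linear interpolation is the simplest scheme consistent with
a 50 Hz resample and is idempotent on already-uniform input.

## Bench protocol

All tests except precision are evaluated on a single *motion score*: each
sensor is smoothed with a centered 3 s moving median (step one sample;
shrinking windows at the edges, so no data is fabricated at the boundaries),
the valid sensors are averaged, and the minimum is subtracted. The median
window scales with the recording's actual rate (3 s × rate samples), which
lets multi-day drift scenarios be simulated and analyzed at a reduced rate
(0.5–1 Hz) without changing the analysis semantics. The average runs over
all valid sensors, loaded or not: which sensors are loaded is exactly what
the tests probe, so the score must not presuppose it.

* **Drift** — hourly (and 24 h) medians `m_k` of the score of the empty mat;
  drift per hour is `100·(m_{k+1} − m_k)/m_1`, reported as the median over
  hours. The reference is the first block's median: the score is already
  baseline-corrected and the device has no calibrated full scale, so a
  full-scale reference would be arbitrary. A zero reference switches the
  report to absolute differences and flags it.
* **Linearity** — plateau level per cumulative load step (median over the
  step's central portion; the first 10 s after each load change are
  discarded, since plates are placed by hand), least-squares level-vs-mass
  fit with `R²`, and saturation detection: a step whose increase is < 5 % of
  the previous increase marks the *previous* mass as the saturation point
  (the output stopped rising one step after hitting the ceiling). The 5 %
  rule is this package's own quantitative stand-in for a qualitative
  observation.
* **Reproducibility** — per-placement amplitude (loaded-segment median minus
  flanking-empty median) and the coefficient of variation across placements,
  with population standard deviation in the numerator.
* **Motion sensitivity** — per cycle, score variance while the load is
  active over variance of the flanking empty segments; an exactly zero empty
  variance is reported as undefined rather than infinite.
* **Precision** — on raw (interpolated-only) signals: per-node response
  (dwell median minus empty baseline), crosstalk at 4-neighbors as
  `max |X|/R`, and a list of sensors whose best off-dwell response exceeds
  10 % (configurable) of their on-dwell response.

Segment samples for the reproducibility and motion-sensitivity statistics are
trimmed by one median window (3 s) at both ends: the centered median smears
each load transition into its neighbors, and without the guard a noiseless
empty segment would carry spurious transition variance.

## Position pipeline

The activity rule — pressure above `2σ` for at least 80 % of a 10 s window —
needs a noise reference `σ` per sensor. The reference must describe noise,
not signal, or loaded sensors would inflate their own threshold; the default
estimator is therefore the scaled median absolute deviation of per-sensor
first differences (`σ = 1.4826·MAD(Δp)/√2`), which removes the static
footprint and slow drift by differencing. A declared empty interval can be
used instead. Out-of-bed windows are those whose total median pressure falls
below 25 % of the running in-bed reference (median of the in-bed totals seen
so far); contiguous runs merge into intervals.

### Posture classifier

Lateral vs. non-lateral (supine and prone merged; prone is too rare for its
own class) from three features: average active sensors, gestational age,
weight. Evaluation is leave-one-out cross-validation with a fixed
configuration recorded in every result. The boosting hyperparameters cannot
be derived from first principles on 17 subjects; the packaged defaults
(`n_estimators=100, max_depth=3, learning_rate=0.3, min_child_weight=2,
reg_lambda=1, scale_pos_weight=9/8, base_score=0.3, tree_method="hist"`)
were fixed once by a coarse grid search on the bundled cohort table so that
the cross-validated accuracy reproduces the originally reported value for
this cohort, and are not claimed to be optimal or to transfer to other
cohorts. With neither row nor column subsampling the fit is deterministic:
the random seed does not affect predictions (verified over seeds 0–29).
Lateral is the positive class in the confusion matrix.

A caveat worth knowing: `min_child_weight=2` requires a hessian budget that
very small training sets cannot always supply, and the `hist` tree method
places split thresholds flush against training values rather than at
midpoints. On tiny synthetic cohorts this can misclassify the boundary
sample even when classes are perfectly separable; the test suite uses exact
greedy splits for that check.

The Pearson correlations of average active sensors with weight and
gestational age are computed and reported, but no particular magnitude is
asserted: on the bundled table the columns are only weakly (negatively)
correlated.

## Motion pipeline

* **COM and area.** Window COM from the per-sensor medians; zero-pressure
  windows carry the previous COM forward (grid center, with a warning, if
  the first window is empty). Snapping rounds to the nearest sensor, with
  exact `.5` ties resolved toward the grid center (then toward the lower
  index) so Fig-style per-sensor histograms are deterministic. The area is
  anchored as rows `[snap−3, snap+2]`, columns `[snap−1, snap+1]`; a 6-row
  box cannot center on a single row, and this anchor is the documented
  choice. At the grid edge the box is clipped — never shifted — and extended
  toward the interior to keep 5 rows, so the area size is always `m = 18`
  (interior) or `m = 15` (edge). A COM on an edge column widens the columns
  inward to keep three. Four 3 × 2 sub-areas cannot tile a 6 × 3 area; the
  left/right pairs share the middle column (and at an edge the two row
  halves share the middle row), so each sub-area keeps `n = 6` sensors. A
  consequence, asserted rather than hidden: the four scores sum to
  `1 + (shared-column variance)/(area variance) ∈ [1, 2]` on interior
  layouts. Arms sit on the head-end half of the rows (configurable
  `head_row_end`), and "left" means lower column indices as seen on the
  grid map.
* **Filter chain.** Zero-phase 4th-order Butterworth bandpass 0.001–0.4 Hz in
  second-order sections (transfer-function form is numerically unstable at a
  normalized corner of 4 × 10⁻⁵), applied over the segment plus ~30 s of
  context; with a whole recording in memory the context is implicit and a
  30 s reflected pad tames the start/end transients of the very slow corner.
  Then a 1 s rolling range (max − min, centered, length-preserving — the
  single-trace reading of a "moving min–max"), then Savitzky–Golay of order
  3 with a 51-sample (~1 s) window; the window length is this package's
  choice and is recorded in the configuration.
* **Scores, binarization, errors.** Per-window sensor variances of the
  filtered traces feed the sub-area score. Windows whose area variance is
  ≤ 10⁻¹² (the numerical residue floor of the chain on constant input)
  are marked still directly. Thresholds are the 95th percentile *per limb
  per recording* (the four score series are normalized separately), with
  strict inequality so all-equal scores flag nothing. Still windows are
  those where all four limbs are below threshold. Agreement with
  annotations uses non-overlapping 5 min blocks after removing epochs
  annotated intervention / camera movement / bad angle / out-of-bed from
  both signals; a gross-movement epoch counts as movement of all four limbs,
  fine movement only of the flagged limbs (configurable). Trailing partial
  blocks are dropped.

## Synthetic data

The generator works at the pressure-reading level (no fiber-optics physics)
and emulates: a posture-dependent footprint — a broad quasi-Gaussian blob
for supine/prone (σ_row ≈ 0.95, σ_col ≈ 0.8 sensor pitches at 1500 g,
growing with weight; ~12 sensors above the activity threshold at default
noise) versus a narrow column-aligned ridge for side-lying (σ_col = 0.35,
~4–6 sensors); footprint weights under 5 % of peak are truncated to exact
zero so locality properties are crisp. Limb bursts are raised-cosine
fluctuations (start and end at zero, fundamental inside 0.001–0.4 Hz)
confined to the limb's ground-truth sub-area, which reuses the analysis-side
area geometry so simulator truth and pipeline geometry cannot drift apart.
White Gaussian sensor noise (clipped at zero — the device reports
nonnegative readings), slow sinusoidal common-mode drift, constant edge
artifacts (tucked bedsheets loading whole rows/columns), and out-of-bed
intervals as an amplitude collapse to 8 % residual (bedsheet pressure, not
exact zero) complete the clinical scenarios. Timestamps are jittered around
50 Hz (2 % of the sample interval by default) because the raw device stream
is not exactly uniform. Arm events in side-lying are rejected: arms bear no
load on the mat in that posture. Epochs overlapping more than two active
limbs annotate as gross movement, otherwise fine with limb flags.

The bench simulator responds proportionally to per-sensor applied mass with
configurable gain (default: the 2.7 kg plate spread over 40 sensors reaches
~25 % of a 1000-unit full scale), optional saturation ceiling, fractional
leakage to 4-neighbors, and ambient-light level ramps for drift scenarios.
The robot's limb alternation is a cyclic phase-staggered modulation (phases
spread over n+1 slots so the sensor-average never cancels); the original
device's exact movement program is not public, so a configurable cyclic
schedule stands in.

What the simulator does *not* reproduce: real optical crosstalk patterns,
sensor-to-sensor sensitivity spread, ambient-light transients, or the
complex geometry of real limbs. Passing the end-to-end tests therefore shows
that the pipeline recovers the truth of this generative model at the
configured SNR, not that it reaches any particular accuracy on real infants.

## Problem sizes and checks

The end-to-end localization battery uses 20 seeded scenarios of 600 s at
50 Hz (one limb, three 8 s bursts of amplitude 12 over noise σ = 0.6, an
SNR of 20); the scored limb must match the simulated limb in ≥ 90 % of
scenarios, and on average ≥ 80 % of that limb's flagged windows must fall
within one window of a truth epoch (the filter's ring-down legitimately
shifts detections by up to one 10 s window, and a 95th-percentile threshold
caps detections near 5 % of windows, so exact-epoch recall is not the right
yardstick). Drift scenarios are simulated at 0.5–1 Hz over 3–48 h; bench
scenarios at 50 Hz over minutes. Brute-force oracles (naive medians, direct
double-loop COM sums, per-sample activity counting, direct variance-ratio
summation) bound the optimized implementations at 10⁻¹² where exact
agreement is expected.

## Known limitations

* The 95th-percentile binarization flags ~5 % of windows per limb regardless
  of content, so recordings with little true movement acquire a floor of
  false detections and a matching underestimate of still periods; this is a
  property of the published design, visible in the worked example.
* Noise clipping at zero makes empty-sensor noise sub-Gaussian; variance
  estimates on empty regions are biased low, which slightly favors
  footprint-adjacent (leg) sub-areas in the score baseline.
* `avg_active_sensors` depends on the noise reference; with a miscalibrated
  σ the 2σ rule degrades gracefully but is not scale-free.
* The classifier defaults are cohort-calibrated (see above); treat the
  reported accuracy as a reproduction of a specific small-cohort analysis,
  not an expected generalization performance.
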