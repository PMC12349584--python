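# fibermat

Analysis tooling for pressure-sensitive sensor-grid mattresses used in
non-obtrusive monitoring of preterm infants, plus a bench-test protocol for
qualifying such devices before clinical use.

The device is an 8 × 5 grid of pressure sensors formed by crossing polymer
optical fibers (one sensor per crossing, addressed as `(row, column)` with
`(1,1)` the first crossing), sampled at a nominal 50 Hz. From the
two-dimensional pressure distribution the package infers

* **posture** (supine/prone vs. side-lying) and **out-of-bed intervals** from
  the per-window pressure footprint, and
* **limb-level movement** from the variance distribution around the pressure
  center of mass,

and it implements a five-part bench protocol (drift, linearity,
reproducibility, motion sensitivity, precision/crosstalk) for the physical
device. A first-class synthetic-data generator stands in for both the device
and the clinical recordings, providing ground truth for every pipeline stage.

## The method

Recordings are resampled to a uniform 50 Hz grid and cut into non-overlapping
10 s windows. Per window the sensor medians `P_ij` give the pressure center
of mass

```
rowCOM = (1/P_tot) Σ_i Σ_j i · P_ij      colCOM = (1/P_tot) Σ_i Σ_j j · P_ij
```

with `P_tot = Σ P_ij`. Around the snapped COM a 6 × 3 sensor area (clipped to
5 × 3 at the grid edge) is split into four overlapping 3 × 2 limb sub-areas
(left/right pairs share the middle column). Each sensor's raw trace passes a
zero-phase 4th-order Butterworth bandpass (0.001–0.4 Hz, the infant-motion
band), a 1 s rolling range, and a 3rd-order Savitzky–Golay smoother; each
limb is then scored per window as

```
score_subarea = Σ_{i=1..n} var_subarea_i / Σ_{j=1..m} var_area_j ,   n = 6, m ∈ {15, 18}
```

binarized at the limb's 95th score percentile, and compared against 10 s
manual annotation epochs in 5 min blocks:
`error_avg = (1/N) Σ (FMm%_i − MAm%_i)`.

A sensor is *active* in a window when its reading exceeds twice its noise
standard deviation for ≥ 80 % of the window; the per-infant average active
count, together with gestational age and weight, feeds a gradient-boosted
tree classifier (lateral vs. non-lateral posture) evaluated with
leave-one-out cross-validation.

## Worked example

Simulate an infant with one left-leg movement burst, run the motion pipeline,
and score it against the generated ground-truth annotations:

```python
from fibermat import resample_uniform
from fibermat import synthetic as syn
from fibermat.motion import run_motion_pipeline

event = syn.MovementEvent(limb="LL", start_s=123.0, duration_s=8.0,
                          amplitude=12.0, freq_hz=0.15)
scenario = syn.InfantScenario(position="supine", duration_s=600.0,
                              noise_sd=0.6, movement_events=(event,), seed=5)
recording, annotations = syn.simulate_infant(scenario)
result = run_motion_pipeline(resample_uniform(recording), annotations)
print(result["errors_pct"])
```

```
{'LL': 1.67, 'RL': 5.0, 'LA': 5.0, 'RA': 5.0, 'still': -15.0}
```

The left-leg error is small (the burst is found); the other limbs show the
~5 % floor that a 95th-percentile threshold flags by construction, and the
still-period percentage is correspondingly underestimated.

The cohort-level summary of the bundled 17-infant table, including the
posture classifier, comes from the command line:

```
$ fm cohort --report report.json
median avg_active_sensors: 8.91
median err_la_pct: -13.38
median err_still_pct: -3.03
median ga_weeks: 30.3
median weight_g: 1810
...
LOOCV accuracy 76.47% (13/17)
```

`fm simulate`, `fm bench`, `fm position` and `fm motion` expose the other
stages; every report records its full configuration.

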