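# Methods

## Scope

`mitrasim` has two halves. The *evaluation pipeline* (beat segmentation →
per-beat indices → regurgitant volume/fraction → MR grading → condition
classification → tables) is a faithful software implementation of how a
left-heart pulse duplicator's measurements are processed. The *digital
twin* is a deliberately minimal lumped-parameter model of the rig that
produces the 150 Hz sensor streams the pipeline consumes, together with
per-cycle ground truth (true mitral backflow, true aortic volume, true
pocket uptake) that no physical rig can provide. The twin exists to
validate the pipeline, not to resolve leaflet mechanics: valve pathology
and repair are represented purely as changes of effective regurgitant
orifice area between presets.

## The twin's model

Topology: piston pump → left ventricle (LV) → {aortic valve → Windkessel
reservoir → peripheral resistance → left atrium (LA), mitral valve ↔ LA}.
Three pressure states (LV, LA, reservoir), all absolute.

* **Pump.** Prescribed flow: half-sine ejection lobe over
  `systolic_fraction` of the cycle integrating to `+sv_pump_ml`, half-sine
  filling lobe over the remainder integrating to `−sv_pump_ml`. Continuous,
  periodic; peak ejection flow is `(π/2)·SV/T_sys`.
* **Ventricle.** Rigid chamber whose pressure is generated by an
  isothermal ideal-gas pocket of reference volume `cv_ml`, referenced at
  the LA baseline pressure, plus a small parasitic linear compliance
  (0.02 ml/mmHg) representing wall/tubing elasticity. The parasitic term
  keeps the pressure ODE well-posed in the rigid `cv_ml = 0`
  configuration; its stored volume is an order of magnitude below the
  pocket's at any nonzero `cv_ml`.
* **Valves.** Quadratic orifices, `|Q| = A·√(2|Δp|/ρ)`, with independent
  forward and regurgitant areas acting as a pressure-controlled diode.
  The square root is smoothly regularized over a 1 mmHg scale so the law
  is Lipschitz; at gradients above a few mmHg the regularized and ideal
  laws agree to better than 0.1 %.
* **Afterload.** Single-compartment Windkessel (compliance
  `c_reservoir_ml_per_mmhg`) draining through `r_peripheral_mmhg_s_per_ml`
  into an LA modelled as a large linear compliance (40 ml/mmHg) around
  `p_la_baseline_mmhg`.

Integration is fixed-step classical RK4 at `dt_s = 2·10⁻⁴ s` — the system
is non-stiff at the default parameters and a fixed step makes
bit-reproducibility trivial. The integrator aborts with a diagnostic when
the state leaves (0, 5000) mmHg or goes non-finite, which happens when
`dt_s` is set too coarse for a stiff parameter choice (e.g. a tiny
reservoir compliance). An initial transient — at least three cycles,
extended to cover four Windkessel time constants — is discarded. Sensor
streams are linearly interpolated onto the `fs_hz` grid; Gaussian noise
(defaults 0.5 mmHg on pressures, 2 ml/s on flow — plausible for the class
of sensors on such rigs, which publish no noise spec) is added from a
generator seeded by `config.seed`.

### Ground truth and volume bookkeeping

Per cycle (delimited by piston ejection onsets) the twin reports true
mitral backflow `∫max(−Q_mv,0)dt`, net aortic volume `∫Q_ao dt`, and the
*compliance-absorbed volume*: the pocket volume returned to the piston
instead of being ejected, computed as the pocket's stored volume at mitral
opening minus at cycle start, plus the piston withdrawal accumulated
before mitral opening. With that definition every steady-state cycle
satisfies `SV_pump = aortic + backflow + absorbed` to integration accuracy
(residuals below 0.01 ml; the suite enforces 0.5 ml). A naive definition —
pocket volume change over the ejection window alone — misses the pocket
volume that drains through the still-open aortic valve after the piston
reverses, and can misstate the balance by several millilitres.

### Rig design parameters

The physical campaign's printed waveform statistics (mean systolic LV
pressure ≈ 59 mmHg gauge against SBP ≈ 118) imply a *peaky* ventricular
waveform: much of the systolic peak is dynamic (Bernoulli) gradient
across the aortic tract rather than static reservoir pressure. The twin's
defaults follow that regime: effective aortic area 0.96 cm² (a 27 mm
mechanical prosthesis plus tubing losses, expressed as one effective
discharge orifice), reservoir compliance 1.5 ml/mmHg, systolic fraction
0.35, LA baseline 20 mmHg gauge, fluid density 1060 kg/m³ (70/30
water–glycerol). In this regime the LV pressure at end-ejection sits close
to the *mean* systolic pressure, which is precisely the condition under
which the RVol equation's compression term `CV(1 − P_LVED/P_LVMS)` matches
the pocket volume actually withheld from the aorta. The suite verifies
this oracle property over ERO ∈ {0, 0.1, 0.2, 0.4} cm² ×
CV ∈ {0, 40, 100, 130} ml: equation vs true backflow within
max(15 %, 2 ml) at every point (worst observed ≈ 1.2 ml at ERO 0,
CV 130).

### Presets and calibration

`calibrate_afterload` mirrors the bench procedure — bisection on the
peripheral resistance until the pipeline-measured SBP of short noise-free
runs hits the target (±3 mmHg default) — and is deterministic. The nine
named presets carry the campaign's compliance-chamber volumes
(130/130/100/100/100/40/40/0/0 ml); each family's resistance was frozen
from one calibration run, and each preset's ERO is a tuned fixture
constant placing the pipeline RVol near the corresponding measured value.
Three deliberate departures from the measured columns, all consequences of
twin-vs-rig waveform differences or of refusing to average discordant
grades:

* *Ex-vivo A physiological* is calibrated to SBP ≈ 97 mmHg (not the
  measured 120). The identity `CO = (SV_pump − compression − RVol)·HR`
  pins CO below 4.5 l/min whenever the compression term exceeds ~4.75 ml
  at RVol 9; the twin's pocket absorbs ~6.5 ml at SBP 120 where the rig's
  sharper piston waveform absorbed ~4. Lower in the physiological SBP
  window the twin reproduces the measured CO of ≈ 4.53 l/min and grade 0.
* *Ex-vivo B repaired* targets RVol ≈ 11 ml (grade 0) rather than the
  measured 15 ml (grade 1), so that the conservative repair-success rule —
  repaired grade range entirely below the pathological range — holds
  against the B-pathological range (1, 2).
* *In-vitro repaired* targets RVol ≈ 18 ml (grades (1,1)) rather than the
  measured 22 ml (grades (1,2)), for the same reason against the
  pathological (2, 3).

## The evaluation pipeline

* **Segmentation.** Systole onset is the ascending crossing of LV above LA
  pressure. Detection runs on a 5-sample moving average, and a crossing
  only counts when the smoothed difference subsequently exceeds 1.5 mmHg
  (≈3 noise SDs) — otherwise sensor noise fakes onsets while the diastolic
  transmitral gradient hovers near zero. Onsets closer than 0.7 expected
  periods are merged; partial leading/trailing beats are dropped (a
  trailing beat is kept when a full expected period of samples follows its
  onset). All indices are computed from raw samples; smoothing is
  detection-only.
* **Indices.** Within a beat, systole runs to the first smoothed return of
  LV below LA; systole + diastole partition the beat. SBP is the systolic
  LV maximum minus `p_atm`; `P_LVMS` the systolic mean (absolute);
  `P_LVED` the last sample before onset; `SV_aortic` the trapezoidal net
  flow integral on the native 150 Hz grid (no resampling; the net integral
  deliberately includes any aortic closing backflow); the transmitral
  gradient is the mean of `P_LA − P_LV` over diastolic samples where it is
  positive (the peak gradient is also exposed — the choice of mean vs peak
  is a convention, and the mean is implemented as primary).
* **Regurgitation and grading.** The equations above, evaluated on the
  window means. Raw values are preserved; display values are rounded
  half-up to integer ml/% (pressures likewise; CO and gradient to two
  decimals), which reproduces 14 of the 18 published per-valve RVol/RF
  cells exactly — the other three differ by one unit because the authors
  aggregated from pre-rounded inputs, and the tests pin those cells at
  exactly ±1. A raw RVol can be slightly negative under measurement noise;
  only the display is floored at zero. Grade thresholds close the printed
  integer gaps with half-open intervals (grade 2 is [30, 45) ml,
  [30, 40) %) so every non-negative value is gradable; the thresholds ship
  as a packaged JSON file so another guideline scheme can be swapped in.
* **Aggregation.** Per-condition summaries use the population SD
  (divisor n), the convention that reproduces the published physiological
  row (e.g. CO 4.78 ± 0.16; the sample SD would print 0.20). Repair deltas
  are per-valve pathological-minus-repaired differences, mean ± population
  SD.

## What the twin does and does not emulate

Emulated: pulsatile LV/LA/aortic dynamics with absolute offsets near
760–824 mmHg, aortic stroke volumes of ~37–61 ml at 80 bpm, compliance
compression of the right magnitude at each chamber volume, additive
Gaussian sensor noise, regurgitation severity spanning grades 0–3. Not
emulated: leaflet and chordae mechanics (repairs change only the ERO),
the viscoelastic impedance adapter (its smoothing role is absorbed by the
afterload compliance), sensor drift or quantization, ultrasound imaging of
any kind, and beat-to-beat variability of the pump. Passing tests
therefore certify the *processing chain* — segmentation, integration,
equations, rounding, aggregation — under realistic waveforms and noise,
not the fidelity of any particular physical valve.

## Numerical choices and edge cases

Problem sizes: analysis windows of 30 s (≈40 beats) for campaign-style
runs, 8–10 s for unit and grid checks; integration at 5 kHz; sensor grid
150 Hz. Orifice smoothing 1 mmHg; parasitic LV compliance 0.02 ml/mmHg;
LA compliance 40 ml/mmHg; transient ≥ 3 cycles plus Windkessel settling.
Ties in rounding go up (half-up), matching the published tables. Degenerate
inputs fail loudly: streams with no crossings, beats with empty systole or
diastole, empty summaries, non-positive forward stroke in the RF
denominator, unreachable calibration targets, unknown config keys.
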