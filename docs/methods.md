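# Methods

## Respirometry

Oxygen consumption is estimated per closed measurement phase as
ṀO₂ = (ΔO₂/100)·DO_max·V/(BM·t). The percentage decline ΔO₂ is taken as
(−slope)·duration from an ordinary least-squares fit of %-saturation
against time, which is robust to the 2-s optode noise; the first and last
5% of samples are trimmed to avoid valve transients. Because slope and
duration enter multiplicatively, the estimate is independent of the exact
phase length. Phases with fewer than 30 samples or non-monotone timestamps
are rejected; a significantly rising oxygen trace (decline < −0.1%
saturation) returns a flagged zero rather than a negative rate. Background
(fish-free) respiration is normalised by the experimental fish's body mass
before subtraction, and negative corrected rates clamp to zero with a
warning.

Defaults encode the study chamber: measurement volume V = 30 l, DO_max =
8 mg l⁻¹ (13 °C seawater), BM = 0.46 kg, 0.15 m s⁻¹ speed steps every
30 min. The intermittent-flow cycle is 5 min acclimation / 15 min
measurement / 10 min flush, three replicate cycles per speed averaged with
the mean and reported with the s.e.m. Fulton's condition factor uses the
standard K = 100·BM[g]/SL[cm]³; the solid-blocking check is the <10%
cross-sectional-area rule only (no velocity correction).

The COT parabola requires ≥ 4 distinct speeds and an upward opening
(c₂ > 0) with the vertex inside the tested range; otherwise the fit is
flagged invalid. Note that with the generator's default (linear-in-speed)
ṀO₂ truth over 0.30–0.90 m s⁻¹, COT declines across most of the range and
the fitted vertex lands near the top of it — a U-shaped COT needs either
sub-0.3 m s⁻¹ points or super-linear ṀO₂ growth.

## ECG and heart rate

The onboard reduction of the archival tag is proprietary, so the detector
here is an explicit Pan-Tompkins-style chain sized for 7.5-s bursts:
zero-phase 5–40 Hz band-pass (2nd-order Butterworth, `sosfiltfilt`),
squared gradient, adaptive threshold at 0.4× the 98th percentile of the
transformed signal, 0.2-s refractory period, then refinement of each
candidate to the local extremum of the band-passed waveform (±50 ms).
Relative thresholds make the detector amplitude-invariant; flat signals
yield no peaks. HR uses the mean R–R interval rather than a peak count to
avoid edge-truncation bias in short windows; the residual quantization is
60/(7.5·200) ≈ 0.04 beats min⁻¹.

The quality index maps the coefficient of variation of R–R intervals to
QI0 (< 0.05), QI1 (< 0.15) and QI2, with QI3 for < 2 peaks. These
thresholds are calibration choices exposed as arguments; "manual review"
of QI1/QI2 is represented as a flag, not automated correction.

## Activity metrics

Static (gravity) acceleration is a 3-s centred running mean per axis —
long against tail-beat periods (~0.3–1 s), short against posture changes —
and dynamic = raw − static reconstructs the signal exactly. External
acceleration takes the Euclidean norm of the instantaneous dynamic vector
(the "vectorial sum" convention of the logger, in milli-g); ODBA takes the
L1 sum (the transmitter convention, converted to m s⁻² with g = 9.81).
L1 ≥ L2 pointwise, so ODBA·1000/9.81 always bounds external acceleration
from above. VAR is the ddof-1 sample variance of 1-s external-acceleration
sub-samples within an aggregation interval; the erratic-swimming flag
fires strictly above 222 m*g*².

## Flow

Unsteady flow is an ideal sinusoidal set-point plus Gaussian measurement
noise (PID dynamics are out of scope). Fitting uses the dominant FFT bin
and its two neighbours to seed a multi-start Levenberg–Marquardt fit of
mean + A·sin(2πt/T + φ); the best residual wins, amplitude is normalised
to ≥ 0 with phase in [0, 2π), and the period is flagged unidentifiable
when A < 5× its own standard error — a steady series with noise reports a
near-zero amplitude rather than a spurious period.

## Calibration models and regression transfer

The eight stored lines carry slope, intercept, R² and — crucially — their
x-convention: the acceleration-versus-speed lines only reproduce the
published free-swimming predictions (13.04 / 13.74 m*g* at 0.50 m s⁻¹)
with speed in m s⁻¹, while the ODBA-versus-speed lines only reproduce
theirs (1.06 / 1.33 m s⁻²) with speed as a 0.15 m s⁻¹ step index.
`predict` converts accordingly and flags extrapolation outside the
calibrated speed range (0.30–0.75 m s⁻¹ for acceleration, where the
speed–activity relation is linear before burst–glide sets in; 0.30–0.90
for ODBA). Fresh fits use OLS with R² as the squared Pearson correlation
on per-speed means. Chained predictions (speed → activity → ṀO₂) verify
that the intermediate unit matches the second model's regressor.

## Circadian analysis

Day is clock hours 06–17 inclusive and night 18–23 plus 00–05, making the
24-hour partition exhaustive. Summaries first reduce each fish to its own
cell mean, then report mean ± s.e.m. across fish, respecting the
repeated-measures structure. The mixed model
y ~ Treatment + Period_of_Day + (1 | fish) is fitted by REML through
statsmodels' MixedLM with night/steady as reference levels, so the period
coefficient is the day-minus-night difference. The interaction term is
pre-tested by an ML likelihood-ratio test at α = 0.05 and, if included,
refitted under REML. Boundary fits (random-intercept variance → 0) are
reported as converged-with-singular-flag; several optimizers are tried and
the best restricted likelihood kept, since gradient methods can return
degenerate solutions at the boundary.

## Synthetic data

The generators encode the study conditions as defaults and always return
their ground truth:

* **Respirometry** inverts the ṀO₂ formula for the decline slope, with
  true rates 213 → 307 mg kg⁻¹ h⁻¹ across 0.30–0.90 m s⁻¹ and 0.5%
  saturation sensor noise.
* **ECG** sums Gaussian P-QRS-T lobes; morphology is irrelevant to the
  contract (peak times are the truth). Noise is relative to the R wave;
  artifacts are dropouts or spikes.
* **Triaxial** places a sway sinusoid whose rectified mean (2A/π) matches
  the calibration line at the requested speed, tail-beat frequency
  f = 1 + 2·U Hz (2.0 Hz at 0.50 m s⁻¹ — an integer number of cycles per
  3-s window, so the running-mean filter leaks negligibly into the dynamic
  band at the speed where calibration fidelity is asserted), per-axis
  sensor noise 0.5 m*g*, and burst–glide attenuation above 0.75 m s⁻¹
  capped at the observed 0.90 m s⁻¹ means (14.30 / 15.31 m*g*).
* **Sentinel telemetry** draws 10-min epochs for 2 weeks of steady then 2
  weeks of unsteady flow, 10 fish, with treatment × period cell means set
  to the tank-study values (HR 71.10/60.50 and 73.20/62.50 beats min⁻¹;
  acceleration 12.90/10.10 and 14.60/11.80 m*g*; VAR 90/51 and
  128/86 m*g*²; ODBA 1.10/0.86 and 1.13/0.88 m s⁻²), Gaussian feeding
  bumps at 09:00 and 16:00 (σ = 1.5 h) mean-centred within each
  treatment × period cell so the cell means hold in expectation, per-fish
  random intercepts (HR sd 4 beats min⁻¹) and residual noise (HR sd
  6 beats min⁻¹). The implied marginal day–night HR effect is
  10.65 beats min⁻¹.
* **Transmitter detections** arrive with gaps uniform on [30, 50] s, each
  carrying the mean ODBA since the previous epoch.

What the generators do **not** emulate: oxygen-mixing/flush dynamics,
real ECG pathologies, turbulence or spatial flow structure, fish growth
across the trial (the real groups grew ~27% in mass), tag-burden effects,
and any dependence of HR on swimming speed (the study's striking finding
was its absence). Passing recovery tests therefore demonstrates that the
estimators are unbiased under the stated noise model, not that they are
robust to every field artifact.

## Problem sizes and tolerances

The default test-suite and analysis sizes were chosen so each stage's
sampling error is well inside its assertion: 3 respirometry replicates at
0.5% noise (≈0.5% s.e.), 3600 1-Hz flow samples (period s.e. ≪ 1 s),
24–50 ECG bursts, and the full 40 320-epoch sentinel design for the mixed
model (fixed-effect s.e. ≈ 0.06 beats min⁻¹). The null-calibration check
of the Treatment test uses 100 seeded runs of a 504-epoch × 10-fish
design. Group cell means vary across seeds with the fish-intercept term
(sd 4/√10 ≈ 1.3 beats min⁻¹), which is the dominant seed-to-seed
variability in recovered cell means.

## Known limitations

* The QI thresholds and the R-peak detector are plausible stand-ins for an
  unpublished onboard algorithm; absolute QI rates on real tags will
  differ.
* The treatment factor in the tank design is confounded with phase order
  (steady weeks precede unsteady weeks); the model estimates exactly the
  printed formula and does not attempt to de-confound time.
* The steady acceleration→ṀO₂ chain is sensitive to which condition's
  ṀO₂ line is applied; both routes are exposed (`mo2_vs_accel`,
  `mo2_vs_odba`, per condition) and the analysis script prints both rather
  than asserting one.
* No oxygen-solubility model: DO_max is an input, not derived from
  temperature/salinity.
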