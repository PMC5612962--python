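# Methods

This note documents the models, conventions and numerical choices behind
`spindleca`: what each stage computes, what the synthetic-data generator
emulates (and what it deliberately does not), and where the design was
genuinely open.

## Conventions

Time is in seconds, rates in Hz. Epoch indices are 0-based; all intervals
are half-open `[onset, offset)`. Epochs are 4 s unless configured
otherwise. Artefact epochs (`ART`) are excluded from every computation:
they never enter normalisation means, correlations or state statistics,
and inside behavioural episodes they count as interruptions.

## Vigilance-state scoring

The polygraphic criteria for rodents are qualitative ("high and variable
EMG", "high sigma activity"), so "high" is operationalised per recording
as a percentile cut-off on the epoch-power distribution: EMG high above
the 60th percentile, slow-wave activity (SWA, 0.5–4 Hz), sigma and
parietal theta high above their 65th percentiles. Ties count as high for
EEG bands and low for EMG so that degenerate flat recordings fall through
to the sleep-side rules. The decision rules, applied per epoch:

* low EMG and (high SWA or high sigma) → NREM;
* low EMG, high parietal theta, low SWA/sigma → REM;
* high EMG and high parietal theta → AW;
* any other epoch → QW.

IS is then assigned by a second pass: a maximal run of ≥ 6 consecutive
epochs flagged as IS candidates (elevated sigma *and* high parietal
theta) whose immediately preceding epoch is scored NREM is relabelled IS.
Runs at the recording start, shorter runs, or runs following any other
state keep their first-pass labels.

The percentile defaults assume a recording whose wake occupancy is
roughly the upper 40 % of the EMG distribution — i.e. a light-phase
session with a substantial sleep fraction. Recordings with very different
state budgets should adjust `ScoringThresholds`.

## Spectral analysis

Band power density (PD) per 4-s epoch is the mean of periodogram bins
inside the band; each epoch segment is mean-detrended and Hann-tapered
(a raw-periodogram mode exists). At 200 Hz and 4 s the frequency
resolution is 0.25 Hz, so the calcium band 0.1–1 Hz maps to the bins
0.25–1.0 Hz; a multi-epoch Welch estimate can be substituted where finer
resolution matters. Band edges are inclusive on both sides; a bin lying
exactly on a shared edge (e.g. 9 Hz between theta and sigma) is assigned
to the lower band only. The SO (0.5–1.5 Hz) and delta (1–4 Hz) bands
overlap by construction; each band is averaged independently. Because PD
is a *mean* over bins, band powers do not sum to the total spectrum
power; the `agg="sum"` mode restores additivity over a partition of the
spectrum (and is what the internal Parseval-style consistency test uses).

Normalisation divides each epoch PD by the mean of the per-state mean PDs
over the states present ("balanced" mode) so that states contribute
equally regardless of occupancy; a pooled-epoch mean is available via
`mode="pooled"`. The two differ only under unbalanced occupancy; balanced
is the default because the normalisation is defined *across behavioural
states*. Trendlines are a 24-s (six-epoch) centred moving average with
edge truncation, advancing one epoch at a time; the centred window is a
display choice, not used by any statistic.

Behavioural episodes pool AW+QW → WAKE and NREM+IS → SWS. An episode is
the *maximal* span starting at an epoch of the pooled state, ending at an
epoch of the same pooled state, with the fraction of non-matching epochs
over the whole span ≤ 0.30 and length ≥ 13 epochs. Maximality is global
(the longest valid end is taken even if the interruption fraction
transiently exceeds 30 % inside), because the rule is stated over the
span, not incrementally; the detector is verified against an exhaustive
span enumeration. Earlier-starting episodes win; scanning resumes after
each accepted episode. Episode thirds assign each member epoch by the
position of its midpoint in normalised episode time, with
ΔPD = mean PD(3rd) − mean PD(1st).

## Transient detection

The trace is globally min–max normalised to [0, 1]. The detector sweeps
pass levels 0.9, 0.8, … down to the 0.2 amplitude floor. At each level,
maximal segments of samples ≥ level are extended outward to the nearest
strict local minima; the extended extent is the candidate event. An event
is accepted when its extent lasts 0.5–6 s, does not touch the trace
boundary, and does not overlap (interior-wise) a previously accepted
event; accepted extents are masked for later passes, so large transients
are claimed at high levels before the low passes see the residue.
Amplitude is measured vertically: maximum of the segment minus minimum of
the extended extent. Two adjacent events may share the single boundary
minimum sample; half-open intervals keep them disjoint.

Measuring the extent at the local minima (rather than at the pass-level
crossing) makes the reported duration the event's support — a planted
half-sine of duration *d* is reported as *d* — which is what the
duration bounds are meant to bound, and keeps the amplitude's
"lowest-to-highest" semantics coherent at high detection levels. A
consequence worth knowing: on traces whose baseline oscillation is large
relative to the transients, baseline excursions above 0.2 of the global
range are reported as events. That is faithful to the amplitude-floor
semantics; the floor is a fraction of the global signal range, not an
SNR criterion.

## Time–frequency cross-correlation

The recording is scanned on a 250-ms grid (= 500-ms TFROI × 50 %
overlap). EEG band energy per position is the mean Hann-tapered |FFT|²
over band bins of the 500-ms TFROI; bands unresolvable at the 2-Hz TFROI
resolution (e.g. SO) raise rather than silently aliasing, so heatmaps
use the six resolvable bands. The calcium 0.1–1 Hz energy cannot be
estimated on 500 ms and is instead computed over the full 4-s search
window centred on the same grid position. For each band and each lag
ℓ ∈ ±2 s on the grid, Spearman ρ (with its two-sided p) is computed
between {ca(t)} and {eeg(t + ℓ)} over valid positions; the lag axis is
therefore *EEG time minus calcium time* — a peak at ℓ = −1 s means the
EEG event precedes the calcium event by one second. Position masks
(e.g. SWS-only) select on the calcium-window centre epoch. Cells with a
constant energy series are undefined (NaN), never zero. p-values are
reported raw per cell; Benjamini–Hochberg across cells is left to the
caller since the map is exploratory.

## Two-photon processing

ΔF/F₀ uses F₀ = mean of the lowest third of raw fluorescence in a 20-s
window re-evaluated every 5 ms (at typical frame rates that is every
sample), centred with edge truncation; a trailing-window mode exists.
Synchrony per 4-s epoch clips each pairwise Pearson r to ±(1 − 10⁻⁶)
before the Fisher transform so identical traces stay finite; the mean z
is mapped back with tanh and the *reported* series floors negative values
at 0 (the raw signed value is retained). For two ROIs this reduces
exactly to the clipped pairwise r. ROIs with zero variance within an
epoch drop out of that epoch's pairs. The sigma-sign partition
correlates each ROI's epoch-mean ΔF/F₀ with sigma PD over SWS epochs and
assigns r ≥ 0 to the positive group (exact zero ties go positive, since
only two groups are reported); the epoch summary statistic is the epoch
mean of the trace.

## Spike analyses

The instantaneous rate places a unit-area impulse per spike on the output
grid (the discrete analogue of an acquisition-frequency-scaled Dirac
delta) and convolves with a discretely unit-normalised Gaussian kernel of
s.d. 20 ms, so the rate integral equals the spike count to machine
precision and a single spike peaks at 1/(0.02·√(2π)) ≈ 19.95 Hz.
Peri-spindle comparisons use the 2 s immediately before and after each
spindle; spindles whose windows leave the recording or contain a
neighbouring spindle, or with a zero pre-window rate, are skipped and
logged. The rate–field cross-correlation band-pass filters the field
(zero-phase Butterworth; a band reaching Nyquist degenerates to a
high-pass), concatenates the selected state epochs, and reports the
signed maximum within ± 5 s divided by the s.d. of the full
cross-correlogram — a unitless statistic invariant to field rescaling.
The spindle-density regression uses consecutive 10-s windows whose starts
advance by 9.75 s (the stated 0.25-s *overlap* read literally; a dense
step-0.25-s mode is available via `overlap_s`), Welch power over 2-s
segments per band, cumulative annotated spindle seconds per window, and
an OLS fit of power on density. The slope is the headline measure; the
standardised slope (= Pearson r) is also reported because raw slopes are
not comparable across bands with different power scales. Spindle
annotation is treated as an input (it is a manual, visual procedure); a
sigma-RMS threshold detector is included as an explicitly non-canonical
convenience.

## Synthetic-data generator

The generator produces the study conditions all recovery tests run under:
a 2-h light-phase session digitised at 200 Hz.

* **Hypnogram**: a semi-Markov chain — geometric bout lengths around
  per-state means (AW 14, QW 9, NREM 16, IS 11, REM 18 epochs; the IS
  mean matches the ~44-s IS episodes typical of rats, with a hard 6-epoch
  minimum) and a bout-level transition matrix in which IS is reachable
  only from NREM and IS exits follow the empirically reported split
  (NREM 45 %, REM 31.3 %, QW 19.7 %, AW 4 %). The implied stationary
  occupancy is ≈ 23 % AW, 22 % QW, 39 % NREM, 11 % IS, 5 % REM — a
  sleep-dominant session whose wake fraction sits just above the
  scorer's 60th-percentile EMG rule. A trailing truncated IS run is
  folded back into NREM.
* **EEG/EMG**: sums of band-limited Gaussian noise components whose RMS
  is state-dependent (SWA large in NREM; parietal theta in AW/REM/IS;
  a sigma background elevated in IS; broadband noise everywhere; EMG
  white noise loud in wake, near-silent in REM). Spindles are
  Hann-enveloped bursts at 12 Hz (centre of the sigma band) inserted in
  NREM (6/min) and IS (12/min) with durations uniform on 0.5–3 s, and
  carry a weak second harmonic (0.3 relative amplitude) because real
  spindle waveforms are non-sinusoidal — this is what gives the beta
  band its spindle-locked energy. No 1/f spectral background or
  waveform asymmetries beyond band-level structure are modelled, so
  passing tests certify the *analysis logic*, not robustness to every
  property of real EEG.
* **Calcium channel**: a 0.1–1 Hz band-limited slow oscillation plus
  half-sine transients (durations 0.5–4 s, amplitudes 1–2.5 in units of
  the slow-oscillation scale) plus white noise. Baseline transients are
  Poisson at 3/min with optional per-state multipliers; with coupling
  strength *c*, each spindle independently adds a transient with
  probability *c* at a lag uniform in a configurable range (default
  0–1 s). The trace is transient-dominated (slow amplitude 0.05 of a
  unit-RMS band) so that the multi-pass detector's global amplitude
  floor separates events from the baseline, as in fibre-optic
  recordings where transients dwarf the resting fluctuation.
* **ROI matrices**: ROI = loading(state) × common factor + unit noise on
  a positive fluorescence baseline, giving theoretical pairwise
  correlation ρ = λ²/(λ² + σ²) per state; an identical-copy mode and an
  optional signed sigma-drive term (a configurable fraction of ROIs
  couples positively, the rest negatively) support the synchrony and
  partition tests.
* **Spikes**: per-sample Bernoulli thinning of
  rate(t) = state rate × (1 + depth · δ(t)), where δ is the 1–4-Hz
  filtered frontal EEG scaled to unit variance — i.e. *phase-locked*
  firing, clipped at zero (clipping is logged). The signed rate × field
  cross-correlation statistic is phase-sensitive; modulating by the
  delta *envelope* alone would leave that statistic at chance, so the
  generator models the physiologically standard phase preference
  (firing during depolarised phases of the slow rhythm).

Fixed seed ⇒ bit-identical output; one seed-derived stream drives all
stages in a fixed order.

Two validation fixtures depend on window-centroid reasoning: for the
TF-map lag-recovery checks, spindle and transient durations are both set
to 1.5–2 s so the centre-to-centre lag equals the planted onset-to-onset
lag (otherwise the recovered lag is offset by half the duration
difference); and the exact spindle-density slope fixture uses
non-overlapping windows with a coherent 12-Hz tone calibrated per window
so that measured Welch sigma power is an exact linear function of
planted density.

## Problem sizes used in validation

Recovery checks run on 2-h simulations for epoch-correlation
fingerprints (10 seeds, coupled and null), 1-h simulations for TF maps
and spindle-density dominance, 15-min spike sessions (10 seeds), 100
seeded planted-event traces for detector recall/precision, and a 10-min
20-ROI session for synchrony. These sizes put every statistic's sampling
error well inside its acceptance band while keeping the full suite in a
few minutes on one core.

## Known limitations

* The scorer's percentile thresholds presuppose a mixed recording; a
  session that is (almost) purely one state defeats per-recording
  percentiles by construction.
* The transient detector's amplitude floor is relative to the global
  min–max range, so a single huge event rescales every other event's
  normalised amplitude; per-window normalisation is available but
  non-default.
* TF heatmaps omit bands unresolvable on a 500-ms TFROI (SO); the
  calcium channel's full-window energy estimate smooths its effective
  time resolution to the 4-s search window.
* Microarousal handling inside episodes is entirely subsumed by the 30 %
  interruption rule; no separate microarousal logic exists.
* The generator does not model indicator kinetics (rise/decay
  asymmetry), movement artefacts, 1/f background, or inter-animal
  variability; cross-animal analyses (ΔPD correlation) are exercised
  with independently seeded sessions as pseudo-animals.
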