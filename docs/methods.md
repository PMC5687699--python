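# Methods

`pulsewave` re-implements, as a tested pipeline, a cardiac-frequency (CF)
phase analysis of the brain's ventricular system: vascular pulse waves (PWs)
mapped over the peri-ventricular surfaces by contrast-bolus wavelet
angiography in piglets, and CSF pressure waves measured inside the Lateral
and Third Ventricles of humans during neuro-endoscopy.  The scientific
claim the pipeline operationalizes is a shared ventral-to-dorsal phase
gradient: dorsal-minus-ventral CF phase differences near +0.7 rad
(vascular, peri-ventricular) and +0.8 rad (CSF pressure, endo-ventricular),
interpreted as PWs arriving at the ventral ventricular surfaces first.

## Complex wavelet machinery

Two analytic Gabor/Morlet continuous wavelet transforms are used, with
center-frequency parameters omega0 = 6 (high frequency resolution, written
C-tilde for the global signal) and omega0 = 1 (high temporal resolution,
written c-hat for per-pixel signals).  At omega0 = 1 the plain Morlet is
far from admissible, so both use the zero-mean-corrected form

    psi_hat(w) = pi^(-1/4) (e^(-(w - w0)^2 / 2) - e^(-w0^2/2) e^(-w^2/2)),  w > 0.

Transforms are computed in the FFT domain with Torrence–Compo-style
normalization.  Both are evaluated on a shared geometric *frequency* grid
(12 voices/octave by default); each converts frequency to its own scale via
the wavelet's spectral peak (6.0 for omega0 = 6; ~1.35 for the corrected
omega0 = 1).  A literally shared scale grid would put the two wavelets'
passbands five Gaussian widths apart at every scale and make the cross
products below vanish, so the shared-frequency reading is adopted.

Sign convention, fixed and tested as the package-wide law:
`cross_wavelet_phase(s, delay(s, dt)) = +2*pi*f*dt` — a positive phase
difference means the second signal lags.

The angiographic CF state of a cine is

    x_hat[i,j] = c_hat[i,j] * conj(C_tilde)               (global reference)
    y_hat[i,j] = c_hat[i,j] * conj(C_tilde) * M_tilde     (motion referenced)

elementwise per (frequency, time) bin, restricted to the cardiac band and
inverse-transformed over that band with complex values retained.  The
global reference C is the spatial mean of pixel signals over a user mask
(default: whole frame); M is the 1-D brain pulse-motion signal.  The
inverse transform is linear delta-reconstruction, `2 * sum_s W(s,t) /
sqrt(s) / K`, where K is the value of the reconstruction sum at the center
frequency of the selected scales — normalizing per selection makes
band-restricted reconstruction amplitude-true at band center, and
compensates the Nyquist-side truncation of the broadband omega0 = 1
wavelet's scale integral (whose full-grid reconstruction otherwise carries
a ~6% amplitude deficit; phases are unaffected).

Two numerical choices make the per-pixel construction usable on transient
bolus data:

* **Envelope detrending.**  The omega0 = 1 wavelet is broadband, so the
  bolus envelope transient (an order of magnitude larger than the CF
  modulation) leaks into the cardiac scales.  A moving average over one
  cardiac period has an exact spectral null at the cardiac frequency;
  subtracting it from pixel signals and from C removes the trend while
  leaving the CF component untouched.
* **Motion-locked companion field.**  The Eq-2 product keeps the CF
  carrier of c_hat — that is what animates the rendered PW cine — so its
  time-average over an analysis interval vanishes.  Scalar phase summaries
  therefore use a companion field accumulated per scale,
  `c_hat_s * conj(M_tilde_s) * |C_tilde_s|`, in which the carrier cancels
  scale-by-scale and the phase is the time-stable pixel-minus-motion CF
  phase ("vascular PW phase relative to brain pulse motion").  Quantities
  formed as ratios of Eq-2 values at equal times (e.g. the dorsal/ventral
  zone product below) need no demodulation because the carrier cancels.

**Cardiac band selection** integrates wavelet power over time (cone of
influence excluded, coefficient power normalized by scale), restricted to
a physiological band (0.5–5 Hz default), and requires a prominent
*interior* local maximum (prominence factor 2.5 on log power, calibrated
so broadband noise is rejected ~98% of the time while genuine cardiac
peaks exceed the threshold by orders of magnitude).  Broadband transients
such as the bolus envelope decay monotonically across the band and cannot
be selected.  The band is ±1/2 octave around the peak (or around an
explicit `f_hint`).  Samples within one wavelet e-folding time
(sqrt(2) * scale of the band's largest scale) of either record end are
flagged and excluded from all pooled statistics.

## Brain pulse motion

Frame-wise rigid translation of a user-selected region (>= 100 pixels) is
estimated by FFT cross-correlation against the first frame with quadratic
sub-pixel peak interpolation; per-frame means are removed, and no
apodization window is applied because a window anchored to the crop biases
sub-pixel shifts toward zero.  Averaging hundreds of pixels resolves net
displacements well below one pixel (0.4 px sinusoids recover to ±0.05 px).
The 2-D track is reduced to 1-D by projection onto the major eigenvector
of the displacement covariance; the axis sign is canonicalized (first
nonzero component positive), isotropic scattergrams (eigenvalue gap < 1%)
are rejected, and the caller chooses the cumulative track (pulse-motion
chronometer M) or frame-to-frame deltas (ventricle wall speed).
skimage's phase correlation is used only as an independent oracle in tests.

## Peri-ventricular band

A user-traced open contour over the ventricular surface is resampled to 30
segments of equal arc length (within 0.5%) and offset outward along
averaged vertex normals to form 30 contiguous quadrilaterals; default
thickness is one segment length (the physical thickness of the
peri-ventricular sampling region is an acknowledged free parameter).
Ventral zone = segments 1–10 and 21–30, dorsal = 11–20.  Pixel membership
is pixel-center-in-polygon with inclusive boundaries; ties go to the
lower polygon index (deterministic).  Per polygon and time the *mean*
complex CF value is taken (areas are unequal; the mean, not the sum).

* **Unfolded profile**: 30-row image, brightness = CF magnitude
  (99th-percentile normalized), hue = CF phase, with orange/turquoise zone
  keys in the margin.
* **Arterial vs venous phase**: the band time-intensity curve (smoothed
  over one cardiac period) locates the bolus peak; the arterial interval
  is 5 heartbeats ending there, the venous interval 5 heartbeats starting
  there.  Motion-locked complex data are time-averaged per polygon per
  interval; the phases of the 30 averages form two circular samples
  compared by Watson's two-sample test.
* **Dorsal–ventral relation**: per-time zone means V_dorsal, V_ventral;
  phase difference = angle(V_dorsal * conj(V_ventral)); samples below 5%
  of the zone's peak CF magnitude (no PW present outside bolus transit)
  or inside the cone of influence are excluded; pooled circular mean ± SD
  and Watson's one-sample test against 0 rad.

A known limitation, quantified by the generator tests: narrowband
filtering of a rapidly rising/falling AM envelope perturbs the analytic
phase by a few hundredths of a radian, coherently across pixels.  This
common-mode bias cancels in every *difference* the analysis reports
(dorsal minus ventral, arterial minus venous separation) but shifts each
interval's absolute phase sample slightly, so distribution-level tests
between intervals are anticonservative at effect sizes below ~0.05 rad.

## CSF pressure pipeline

Physiology CSVs (time_s, csf_mmHg, abp_mmHg, ecg_au) are validated
(monotone time, jitter < 1%, gaps <= 5% interpolated and flagged).  The
Lateral (dorsal) and Third (ventral) Ventricle epochs are recorded minutes
apart, so per-time pairing is impossible; instead, per record the
cross-wavelet phase of CSF pressure against the cardiac reference (ECG or
ABP) is reduced to one circular mean per detected heartbeat
(reference-channel peaks), and every dorsal-beat minus ventral-beat
difference is pooled.  This beat-level pairing is order-free and removes
absolute time: shifting an epoch by whole cardiac periods changes the
pooled mean by < 0.05 rad (tested).  Positive pooled mean = ventral
(Third Ventricle) pressure leads.

Video and pressure clocks are aligned from the "finger-flick" transient:
each trace must contain exactly one excursion beyond median + 8*MAD
(several candidates raise an error listing them); the onset is the first
half-peak crossing, linearly interpolated; the offset is pressure onset
minus motion onset, with one-video-frame uncertainty (recovered within
1/30 s in >= 95/100 random-offset trials).

## Circular statistics

Mean/SD via the resultant vector (SD = sqrt(-2 ln Rbar)); undefined-mean
error below Rbar = 1e-12.  The one-sample Watson test is the large-sample
mean-direction test (circular dispersion (1 - rho2) / (2 Rbar^2), normal
deviate, two-sided, p floored at 1e-16, n >= 25 enforced) — chosen because
the hypothesis tested is "mean equals 0 rad", which a goodness-of-fit U^2
does not address; it is cross-checked against a bootstrap-of-mean oracle
and its null p-values are uniform by KS over 2000 seeded replicates.  The
two-sample test is Watson's U^2 on the pooled ECDF difference evaluated
per tie group (identical samples give exactly 0), with a seeded
permutation p (default 10^4) and the asymptotic series value alongside;
heavy ties (> 25%) set a warning flag.  Angular Q-Q matching centers each
sample on its own circular mean (raw angular quantiles depend on an
arbitrary cut point), wraps, sorts, and interpolates quantiles at
k/(m+1).

A caveat inherited from the source analysis: pooled per-time cross-wavelet
phase samples are strongly autocorrelated (decorrelation time ~ one
cardiac period), so large-n Watson p-values on such pools are
anticonservative; the recovery tests therefore assert pooled means, and
the beat-level CSF pooling keeps samples closer to independent.

## Synthetic data: what it emulates and what it does not

The generator is the ground-truth instrument for every recovery test.

**Cine** (default 128x128, 30 Hz, 20 s, f_c = 2.5 Hz — a physiological
piglet heart rate; heart rates are configurable): an elliptical-arc
"ventricular" ring of vascular pixels around an open contour (traced
ventral tail -> dorsal crown -> ventral tail, so segments 1–10/21–30 are
ventral and 11–20 dorsal), split checkerboard-wise into arterial and
venous compartments so both are present in every polygon.  Each
compartment pixel carries a gamma-variate envelope (alpha = 8,
beta = 0.18 s; peak 1.44 s after arrival) modulated at CF with depth 0.25;
the venous envelope is the arterial one delayed by 7 cardiac periods
(2.8 s).  An unmodulated parenchymal blush (Gaussian, SD 1.2 s, peaking
1.7 s after the arterial peak, amplitude 2.5x a compartment envelope)
models capillary-phase contrast whose pulsatility is damped by the
microcirculation; it anchors a single time-intensity peak at the
arteriovenous crossover.  This geometry was designed so that the 5-beat
windows the interval rule prescribes are compartment-dominated (>= 80% of
each window's span; residual cross-compartment phase contamination
~0.02 rad) — with substantially shorter transit times the two windows
average over both compartments and the compartment phases are
unrecoverable by construction.  Arterial/venous CF phase offsets are
defined relative to the oscillating tracker blob (Gaussian, sigma 2.5 px,
amplitude 0.4 px) whose displacement is returned as the pulse-motion
reference; the ventral-dorsal gradient is laid along the contour with a
one-segment linear transition at each zone boundary, encoded so the
measured dorsal-minus-ventral angle equals the configured value (the sign
semantics follow the reported convention in which +0.7 rad means
ventral-leading, ventral-to-dorsal travel).  Noise is additive Gaussian
(SD 2 intensity units against a CF amplitude of ~7.5 at envelope peak).
Not emulated: ultrasound speckle and acoustics, endoscope optics, vessel
morphology, respiratory or motion artifacts beyond the tracker blob.
Passing recovery tests therefore demonstrate correctness of the phase
estimation chain, not robustness to every artifact of real cine.

**Physiology** (default 100 Hz, 20 s per epoch, f_c = 1.2 Hz human-like,
respiration 0.25 Hz): two CSF-pressure epochs on one continuous cardiac
clock, 120 s apart, with the configured dorsal-minus-ventral CF lag; a
shared impulse-train ECG (R peaks at the cardiac clock) and a two-harmonic
ABP.  The CSF CF component lags the R peak by a fixed 0.9 rad.  Morphology
of real ECG/ABP and heart-rate variability are non-goals.

**Flick pair**: background CF oscillation plus a step-exponential motion
transient (video clock) and a sharp pressure spike offset by the
configured clock offset.

Same seed and configuration give bit-identical outputs.

## Problem sizes in the shipped checks

Recovery runs use 128x128x600 cines with per-pixel transforms restricted
to the band's pixels (`band_roi_mask`), ~1 s per pipeline; the test suite
runs in ~1.5 minutes and the acceptance script (10-seed vascular and CSF
recoveries, 100 alignment trials, identity checks) in ~15 s.  These sizes
match the acquisition the analysis targets (tens of seconds at tens of Hz);
nothing in the method is specific to them.
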