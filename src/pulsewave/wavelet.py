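"""Complex continuous wavelet machinery for cardiac-frequency (CF) angiography.

Two analytic Gabor/Morlet transforms are used throughout:

* a high-frequency-resolution transform (center-frequency parameter
  ``omega0 = 6``), written with an over-tilde in the field's notation, and
* a high-temporal-resolution transform (``omega0 = 1``), written with an
  over-hat.

At ``omega0 = 1`` the plain Morlet is far from admissible, so the
zero-mean-corrected form ``psi_hat(w) = pi^-1/4 (e^{-(w-w0)^2/2} -
e^{-w0^2/2} e^{-w^2/2})`` (positive frequencies only) is used for both.

Both transforms are evaluated on a shared *frequency* grid; each converts
frequency to its own scale via the wavelet's spectral peak, so that the
elementwise cross products of the angiography equations

    x_hat[i,j] = c_hat[i,j] * conj(C_tilde)            (global reference)
    y_hat[i,j] = c_hat[i,j] * conj(C_tilde) * M_tilde  (motion referenced)

compare like frequencies.  Per-pixel phase of the resulting complex CF
field is ``phi(c) - phi(C) [+ phi(M)]`` at CF.

Sign convention (fixed and tested): the coefficients of ``e^{i w t}``
carry phase ``+w t``, so ``cross_wavelet_phase(s, delay(s, dt)) =
+2 pi f dt`` — a positive phase difference means the second signal lags.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .circular import wrap_angle

__all__ = [
    "WaveletSpec",
    "HIGH_FREQ_RES",
    "HIGH_TIME_RES",
    "frequency_grid",
    "WaveletCoefficients",
    "cwt",
    "reconstruct",
    "CardiacBand",
    "select_cardiac_scale",
    "cf_filter",
    "PhaseSeries",
    "cross_wavelet_phase",
    "ComplexCFField",
    "cf_angiogram",
    "edge_valid_mask",
]

_PI4 = np.pi ** -0.25


class NoCardiacPeakError(ValueError):
    """No usable power maximum in the physiological band."""


@dataclass(frozen=True)
class WaveletSpec:
    """Analytic zero-mean-corrected Gabor/Morlet wavelet, parameterized by omega0."""

    omega0: float
    name: str = ""

    def psi_hat(self, w) -> np.ndarray:
        """Frequency-domain wavelet (real, >= 0 support on positive frequencies)."""
        w = np.asarray(w, dtype=float)
        out = _PI4 * (
            np.exp(-0.5 * (w - self.omega0) ** 2)
            - np.exp(-0.5 * self.omega0**2) * np.exp(-0.5 * w**2)
        )
        return np.where(w > 0, out, 0.0)

    @property
    def peak_angular_frequency(self) -> float:
        """Location of the spectral peak (used for scale <-> frequency conversion)."""
        return _peak_angular_frequency(self.omega0)

    def scale_for_frequency(self, f) -> np.ndarray:
        """Scale (seconds) whose spectral peak sits at frequency ``f`` (Hz)."""
        return self.peak_angular_frequency / (2.0 * np.pi * np.asarray(f, dtype=float))

    def e_folding_time(self, f) -> np.ndarray:
        """Time distance over which the wavelet envelope decays by 1/e at frequency f."""
        return np.sqrt(2.0) * self.scale_for_frequency(f)


@lru_cache(maxsize=None)
def _peak_angular_frequency(omega0: float) -> float:
    w = np.linspace(1e-3, omega0 + 6.0, 200_001)
    spec = WaveletSpec(omega0)
    return float(w[np.argmax(spec.psi_hat(w))])


HIGH_FREQ_RES = WaveletSpec(omega0=6.0, name="high_frequency_resolution")  # "~"
HIGH_TIME_RES = WaveletSpec(omega0=1.0, name="high_temporal_resolution")  # "^"


def frequency_grid(f_min: float, f_max: float, voices_per_octave: int = 12) -> np.ndarray:
    """Geometric frequency grid (Hz, ascending) with >= 8 voices per octave."""
    if voices_per_octave < 8:
        raise ValueError("need at least 8 voices per octave")
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    n_oct = np.log2(f_max / f_min)
    n = int(np.ceil(n_oct * voices_per_octave)) + 1
    return f_min * 2.0 ** (np.arange(n) / voices_per_octave)


@dataclass
class WaveletCoefficients:
    """Scale x time complex coefficient grid on a frequency grid."""

    values: np.ndarray           # (n_freq, n_time) complex
    frequencies: np.ndarray      # (n_freq,) Hz, ascending
    spec: WaveletSpec
    sampling_rate: float

    def __post_init__(self):
        if self.values.shape != (len(self.frequencies), self.values.shape[1]):
            raise ValueError("coefficient grid does not match frequency grid")

    @property
    def scales(self) -> np.ndarray:
        return self.spec.scale_for_frequency(self.frequencies)

    def power_per_scale(self, valid: np.ndarray | None = None) -> np.ndarray:
        v = self.values if valid is None else self.values[:, valid]
        return np.mean(np.abs(v) ** 2, axis=1)


def _check_signal(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be 1-D with at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains NaN/inf; interpolate gaps before transforming")
    return x


def _filter_bank(n: int, fs: float, spec: WaveletSpec, freqs: np.ndarray) -> np.ndarray:
    """(n_freq, n) FFT-domain filters sqrt(2 pi s fs) * psi_hat(s * w)."""
    w = 2.0 * np.pi * np.fft.fftfreq(n, d=1.0 / fs)
    s = spec.scale_for_frequency(freqs)
    return np.sqrt(2.0 * np.pi * s[:, None] * fs) * spec.psi_hat(s[:, None] * w[None, :])


def cwt(x, fs: float, spec: WaveletSpec = HIGH_FREQ_RES,
        freqs: np.ndarray | None = None, voices_per_octave: int = 12) -> WaveletCoefficients:
    """Complex analytic CWT of a uniformly sampled series (FFT implementation).

    Linear by construction.  Default frequency grid spans 2/duration .. fs/2.
    """
    x = _check_signal(x)
    n = x.size
    if freqs is None:
        freqs = frequency_grid(max(2.0 * fs / n, 1e-3), fs / 2.0, voices_per_octave)
    freqs = np.asarray(freqs, dtype=float)
    bank = _filter_bank(n, fs, spec, freqs)
    xh = np.fft.fft(x)
    values = np.fft.ifft(xh[None, :] * bank, axis=1)
    return WaveletCoefficients(values=values, frequencies=freqs, spec=spec, sampling_rate=fs)


@lru_cache(maxsize=128)
def _recon_norm(spec_omega0: float, freq_key: tuple, fs: float) -> float:
    """Delta-reconstruction constant for the selected scales.

    Value of ``sum_j sqrt(2 pi s_j fs) psi_hat(s_j w) / sqrt(s_j)`` at the
    geometric center frequency of the selection, so a tone at the center of
    the selected (possibly truncated) scale band reconstructs with unit
    gain; for the full grid this is the plateau constant.
    """
    spec = WaveletSpec(spec_omega0)
    freqs = np.asarray(freq_key)
    scales = spec.scale_for_frequency(freqs)
    wc = 2.0 * np.pi * np.sqrt(freqs[0] * freqs[-1])
    k = np.sum(np.sqrt(2.0 * np.pi * scales * fs) * spec.psi_hat(scales * wc) / np.sqrt(scales))
    return float(k)


def reconstruct(coeffs: WaveletCoefficients, band: slice | None = None) -> np.ndarray:
    """Linear delta-reconstruction: sum over scales of W/sqrt(s), normalized.

    Returns the complex analytic series of a *real* input signal; its real
    part reproduces the band-limited signal content (the wavelet is
    analytic, so the positive-frequency sum is doubled).  ``band``
    restricts the sum to a scale band (e.g. the cardiac band), in which
    case out-of-band content is rejected.
    """
    sel = band if band is not None else slice(None)
    scales = coeffs.scales
    norm = _recon_norm(coeffs.spec.omega0, tuple(coeffs.frequencies[sel]),
                       coeffs.sampling_rate)
    return 2.0 * np.sum(coeffs.values[sel] / np.sqrt(scales[sel, None]), axis=0) / norm


def edge_valid_mask(n: int, fs: float, f_lowest: float, spec: WaveletSpec = HIGH_FREQ_RES) -> np.ndarray:
    """Cone-of-influence mask: False within one wavelet e-folding time of the ends.

    ``f_lowest`` is the lowest frequency of the band in use (largest scale).
    """
    n_edge = int(np.ceil(spec.e_folding_time(f_lowest) * fs))
    mask = np.ones(n, dtype=bool)
    n_edge = min(n_edge, n // 2)
    if n_edge > 0:
        mask[:n_edge] = False
        mask[-n_edge:] = False
    return mask


@dataclass(frozen=True)
class CardiacBand:
    """Contiguous scale band around the cardiac frequency on a frequency grid."""

    indices: slice
    frequencies: np.ndarray      # full grid the indices refer to
    f_center: float

    @property
    def band_frequencies(self) -> np.ndarray:
        return self.frequencies[self.indices]

    @property
    def f_low(self) -> float:
        return float(self.band_frequencies[0])

    @property
    def f_high(self) -> float:
        return float(self.band_frequencies[-1])


def select_cardiac_scale(reference: WaveletCoefficients, f_hint: float | None = None,
                         physio_band: tuple[float, float] = (0.5, 5.0),
                         half_width_octaves: float = 0.5,
                         prominence: float = 2.5) -> CardiacBand:
    """Locate the cardiac scale band from a reference signal's wavelet power.

    The band (default +-1/2 octave) is centered on the scale of maximal
    time-integrated power within the physiological frequency band
    (default 0.5-5 Hz), or on ``f_hint`` when supplied.  Raises
    :class:`NoCardiacPeakError` when no sufficiently prominent maximum
    exists (e.g. broadband noise), advising an explicit ``f_hint``.
    """
    freqs = reference.frequencies
    if f_hint is not None:
        fc = float(f_hint)
    else:
        from scipy.signal import find_peaks

        in_band = (freqs >= physio_band[0]) & (freqs <= physio_band[1])
        if not np.any(in_band):
            raise NoCardiacPeakError("frequency grid does not cover the physiological band")
        valid = edge_valid_mask(reference.values.shape[1], reference.sampling_rate,
                                physio_band[0], reference.spec)
        if not valid.any():
            valid = None
        # normalize out the sqrt(s) coefficient scaling so a tone's power
        # peaks at its own pseudo-frequency rather than one voice below
        power = (reference.power_per_scale(valid) / reference.scales)[in_band]
        # the cardiac peak must be a prominent *interior* local maximum:
        # broadband transients (e.g. the bolus envelope itself) decay
        # monotonically across the band and must not be mistaken for it
        peaks, _ = find_peaks(np.log(power + np.finfo(float).tiny),
                              prominence=np.log(prominence))
        if peaks.size == 0:
            raise NoCardiacPeakError(
                "no prominent interior power maximum in the physiological band "
                f"({physio_band[0]}-{physio_band[1]} Hz); pass an explicit f_hint"
            )
        i_peak = peaks[np.argmax(power[peaks])]
        fc = float(freqs[in_band][i_peak])
    n, fs = reference.values.shape[1], reference.sampling_rate
    if n / fs < 10.0 / fc:
        raise ValueError(
            f"reference spans {n / fs:.2f} s < 10 cardiac periods at {fc:.2f} Hz"
        )
    sel = np.abs(np.log2(freqs / fc)) <= half_width_octaves + 1e-12
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise NoCardiacPeakError("cardiac band empty on this frequency grid")
    return CardiacBand(indices=slice(int(idx[0]), int(idx[-1]) + 1),
                       frequencies=freqs, f_center=fc)


def cf_filter(x, fs: float, band: CardiacBand,
              spec: WaveletSpec = HIGH_FREQ_RES) -> np.ndarray:
    """Wavelet-filter a 1-D series to its complex analytic CF component.

    The real part reproduces the signal's cardiac-band content; magnitude
    and angle give the CF envelope and phase.
    """
    coeffs = cwt(x, fs, spec, band.frequencies)
    return reconstruct(coeffs, band.indices)


@dataclass
class PhaseSeries:
    """Per-time phase difference (radians in (-pi, pi]) with validity flags."""

    values: np.ndarray
    valid: np.ndarray
    sampling_rate: float

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


def cross_wavelet_phase(a, b, fs: float, band: CardiacBand,
                        spec: WaveletSpec = HIGH_FREQ_RES,
                        power_floor: float = 1e-10) -> PhaseSeries:
    """Per-time CF phase of ``a`` relative to ``b``.

    angle( sum_band W_a * conj(W_b) ); positive when ``b`` lags ``a``.
    Samples within one wavelet e-folding time of either end, or with
    cross power below ``power_floor`` of the peak, are flagged invalid
    and excluded from pooled statistics downstream.
    """
    a = _check_signal(a)
    b = _check_signal(b)
    if a.size != b.size:
        raise ValueError("series lengths differ")
    wa = cwt(a, fs, spec, band.frequencies).values[band.indices]
    wb = cwt(b, fs, spec, band.frequencies).values[band.indices]
    cross = np.sum(wa * np.conj(wb), axis=0)
    valid = edge_valid_mask(a.size, fs, band.f_low, spec)
    mag = np.abs(cross)
    interior_peak = mag[valid].max() if valid.any() else mag.max()
    valid = valid & (mag > power_floor * interior_peak)
    return PhaseSeries(values=wrap_angle(np.angle(cross)), valid=valid, sampling_rate=fs)


@dataclass
class ComplexCFField:
    """Per-pixel complex CF state: magnitude = pulse-wave strength, angle = phase.

    Carries the CF-filtered global reference (and motion, when Eq-2
    referencing was used) so downstream phase summaries can demodulate the
    CF carrier consistently.
    """

    values: np.ndarray               # (H, W, T) complex
    cardiac_freq: float
    reference: str                   # "global" or "pulse_motion"
    sampling_rate: float
    valid: np.ndarray                # (T,) cone-of-influence mask
    band: CardiacBand
    reference_cf: np.ndarray         # CF-filtered global reference C (complex, T)
    motion_cf: np.ndarray | None = None   # CF-filtered pulse motion M (complex, T)
    roi_mask: np.ndarray | None = None    # (H, W) bool; pixels actually transformed
    # motion-locked companion field: per-scale cross-wavelet of each pixel
    # against M (|C|-weighted), so the CF carrier cancels scale-by-scale and
    # the phase is the time-stable pixel-minus-motion CF phase
    motion_locked: np.ndarray | None = None

    @property
    def phase(self) -> np.ndarray:
        return wrap_angle(np.angle(self.values))

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


def cf_angiogram(cine, motion=None, band: CardiacBand | None = None,
                 reference_mask: np.ndarray | None = None,
                 roi_mask: np.ndarray | None = None,
                 f_hint: float | None = None) -> ComplexCFField:
    """Cross-correlated wavelet angiography of a cine sequence.

    Per pixel, high-temporal-resolution coefficients ``c_hat`` are
    multiplied elementwise by the conjugate high-frequency-resolution
    coefficients of the global reference ``C`` (spatial mean over
    ``reference_mask``, default whole frame), and additionally by the
    coefficients of the pulse-motion signal when ``motion`` is given.
    The product is restricted to the cardiac band and inverse-transformed
    over that band, retaining complex values, so each voxel carries a
    complex CF state (phase ``phi(c) - phi(C) [+ phi(M)]`` at CF).

    ``motion`` may be a :class:`~pulsewave.motion.PulseMotionSignal` or a
    plain 1-D array sampled at the cine rate.  ``roi_mask`` limits the
    per-pixel transforms to a region of interest (other pixels are zero).
    """
    frames = cine.frames
    h, w, t = frames.shape
    fs = cine.sampling_rate

    if reference_mask is None:
        reference_mask = np.ones((h, w), dtype=bool)
    c_global = frames[reference_mask].mean(axis=0)

    m = None
    if motion is not None:
        m = np.asarray(getattr(motion, "values", motion), dtype=float)
        if m.size != t:
            raise ValueError("motion signal length does not match cine length "
                             f"({m.size} vs {t})")

    if band is None:
        ref_coeffs = cwt(c_global, fs, HIGH_FREQ_RES)
        band = select_cardiac_scale(ref_coeffs, f_hint=f_hint)

    freqs = band.band_frequencies
    sub = CardiacBand(indices=slice(0, len(freqs)), frequencies=freqs, f_center=band.f_center)

    # The omega0=1 wavelet is broadband in frequency, so the angiographic
    # envelope transient (which dwarfs the CF modulation) would leak into
    # the cardiac scales.  A moving average over one cardiac period has an
    # exact null at f_center — subtracting it removes the bolus trend while
    # leaving the CF component untouched.
    from scipy.ndimage import uniform_filter1d

    k_ma = max(1, int(round(fs / band.f_center)))
    c_detr = c_global - uniform_filter1d(c_global, k_ma, mode="nearest")

    wc_ref = cwt(c_detr, fs, HIGH_FREQ_RES, freqs).values         # C tilde on the band
    wm = cwt(m, fs, HIGH_FREQ_RES, freqs).values if m is not None else None

    if roi_mask is None:
        roi_mask = np.ones((h, w), dtype=bool)
    pix = frames[roi_mask]                                        # (n_pix, T)
    pix = pix - uniform_filter1d(pix, k_ma, axis=1, mode="nearest")
    n_pix = pix.shape[0]

    bank = _filter_bank(t, fs, HIGH_TIME_RES, freqs)              # (n_f, T)
    scales_hat = HIGH_TIME_RES.scale_for_frequency(freqs)
    norm = _recon_norm(HIGH_TIME_RES.omega0, tuple(freqs), fs)

    xh = np.fft.fft(pix, axis=1)
    acc = np.zeros((n_pix, t), dtype=complex)
    acc_locked = np.zeros((n_pix, t), dtype=complex) if wm is not None else None
    for j in range(len(freqs)):                                   # scale-by-scale to bound memory
        base = np.fft.ifft(xh * bank[j][None, :], axis=1)         # c_hat at this scale
        wj = base * np.conj(wc_ref[j])[None, :]
        if wm is not None:
            wj = wj * wm[j][None, :]
            # carrier cancels within each scale; |C| keeps the reference weighting
            acc_locked += (base * (np.conj(wm[j]) * np.abs(wc_ref[j]))[None, :]
                           / np.sqrt(scales_hat[j]))
        acc += wj / np.sqrt(scales_hat[j])
    acc /= norm
    if acc_locked is not None:
        acc_locked /= norm

    values = np.zeros((h, w, t), dtype=complex)
    values[roi_mask] = acc
    motion_locked = None
    if acc_locked is not None:
        motion_locked = np.zeros((h, w, t), dtype=complex)
        motion_locked[roi_mask] = acc_locked
    valid = edge_valid_mask(t, fs, band.f_low, HIGH_FREQ_RES)
    return ComplexCFField(
        values=values,
        cardiac_freq=band.f_center,
        reference="pulse_motion" if m is not None else "global",
        sampling_rate=fs,
        valid=valid,
        band=sub,
        reference_cf=reconstruct(
            WaveletCoefficients(wc_ref, freqs, HIGH_FREQ_RES, fs), slice(None)
        ),
        motion_cf=(
            reconstruct(WaveletCoefficients(wm, freqs, HIGH_FREQ_RES, fs), slice(None))
            if wm is not None else None
        ),
        roi_mask=roi_mask,
        motion_locked=motion_locked,
    )
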