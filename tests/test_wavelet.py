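"""Wavelet machinery: transforms, band selection, phase conventions, identities."""

import numpy as np
import pytest

import pulsewave as pw
from pulsewave import wavelet as wv
from pulsewave.wavelet import NoCardiacPeakError

FS = 30.0
N = 600
T = np.arange(N) / FS
FC = 2.5
INTERIOR = slice(120, 480)   # several wavelet e-folding times from both ends


def tone(f, phase=0.0):
    return np.cos(2 * np.pi * f * T + phase)


def test_canonical_specs_parameters():
    assert wv.HIGH_FREQ_RES.omega0 == 6.0
    assert wv.HIGH_TIME_RES.omega0 == 1.0
    # corrected Morlet at omega0=1 peaks above omega0 (zero-mean correction)
    assert 1.2 < wv.HIGH_TIME_RES.peak_angular_frequency < 1.6
    assert wv.HIGH_FREQ_RES.peak_angular_frequency == pytest.approx(6.0, abs=0.01)


def test_frequency_grid_spacing():
    g = wv.frequency_grid(0.5, 8.0, 12)
    ratios = np.diff(np.log2(g))
    assert np.allclose(ratios, 1 / 12)
    with pytest.raises(ValueError):
        wv.frequency_grid(0.5, 8.0, 4)


@pytest.mark.parametrize("spec", [wv.HIGH_FREQ_RES, wv.HIGH_TIME_RES])
def test_cwt_concentrates_at_tone_frequency(spec):
    c = wv.cwt(tone(FC), FS, spec)
    # normalize out the sqrt(s) coefficient scaling: the wavelet response
    # itself peaks at the scale whose pseudo-frequency matches the tone
    power = np.mean(np.abs(c.values[:, INTERIOR]) ** 2, axis=1) / c.scales
    f_peak = c.frequencies[np.argmax(power)]
    assert abs(np.log2(f_peak / FC)) <= 1 / 12 + 1e-9


def test_cwt_zero_signal_and_errors():
    c = wv.cwt(np.zeros(N), FS)
    assert np.all(c.values == 0)
    with pytest.raises(ValueError):
        wv.cwt(np.array([1.0]), FS)
    with pytest.raises(ValueError):
        wv.cwt(np.r_[np.ones(50), np.nan], FS)


def test_cwt_linearity():
    a, b = tone(FC), tone(1.1, 0.7)
    ca = wv.cwt(a, FS).values
    cb = wv.cwt(b, FS).values
    cab = wv.cwt(2.0 * a - 0.5 * b, FS).values
    err = np.max(np.abs(cab - (2.0 * ca - 0.5 * cb))) / np.max(np.abs(cab))
    assert err < 1e-9


def test_select_cardiac_scale_on_tone_and_hint():
    c = wv.cwt(tone(FC), FS)
    band = wv.select_cardiac_scale(c)
    assert abs(np.log2(band.f_center / FC)) <= 1 / 12 + 1e-9
    hinted = wv.select_cardiac_scale(c, f_hint=2.2)
    assert hinted.f_center == 2.2
    # default band width: +-1/2 octave
    assert band.f_high / band.f_low == pytest.approx(2.0, rel=0.1)


def test_select_cardiac_scale_rejects_white_noise():
    rng = np.random.default_rng(0)
    c = wv.cwt(rng.normal(size=N), FS)
    with pytest.raises(NoCardiacPeakError, match="f_hint"):
        wv.select_cardiac_scale(c)


def test_select_cardiac_scale_needs_ten_periods():
    short = np.cos(2 * np.pi * 0.6 * np.arange(200) / FS)  # 4 periods
    c = wv.cwt(short, FS)
    with pytest.raises(ValueError, match="periods"):
        wv.select_cardiac_scale(c)


def test_cf_filter_reconstruction_and_stopband():
    band = wv.select_cardiac_scale(wv.cwt(tone(FC), FS))
    valid = wv.edge_valid_mask(N, FS, band.f_low)
    z = wv.cf_filter(tone(FC), FS, band)
    x = tone(FC)
    rel = np.sqrt(np.mean((z.real[valid] - x[valid]) ** 2) / np.mean(x[valid] ** 2))
    assert rel < 0.05
    z_out = wv.cf_filter(tone(0.4), FS, band)
    assert np.max(np.abs(z_out[valid])) < 0.05 * np.max(np.abs(z[valid]))
    assert np.all(wv.cf_filter(np.zeros(N), FS, band) == 0)


def test_full_grid_reconstruction():
    c = wv.cwt(tone(FC), FS, wv.HIGH_FREQ_RES)
    z = wv.reconstruct(c)
    valid = wv.edge_valid_mask(N, FS, 1.0)
    x = tone(FC)
    rel = np.sqrt(np.mean((z.real[valid] - x[valid]) ** 2) / np.mean(x[valid] ** 2))
    assert rel < 0.02


@pytest.mark.parametrize("lag_samples", [1, 3, 5, 9, 14])
def test_cross_wavelet_delay_law(lag_samples):
    """Global sign convention: a delayed second argument gives +2 pi f dt."""
    x = tone(FC)
    y = np.roll(x, lag_samples)          # y lags x by lag_samples
    band = wv.select_cardiac_scale(wv.cwt(x, FS))
    ps = wv.cross_wavelet_phase(x, y, FS, band)
    expected = pw.wrap_angle(2 * np.pi * FC * lag_samples / FS)
    got = ps.values[ps.valid & np.isin(np.arange(N), np.arange(N)[INTERIOR])]
    assert np.max(np.abs(pw.wrap_angle(got - expected))) < 0.05


def test_cross_wavelet_identity_and_antisymmetry():
    a = tone(FC)
    b = tone(FC, -np.pi / 4)
    band = wv.select_cardiac_scale(wv.cwt(a, FS))
    same = wv.cross_wavelet_phase(a, a, FS, band)
    assert np.allclose(same.values[same.valid], 0.0, atol=1e-12)
    ab = wv.cross_wavelet_phase(a, b, FS, band)
    ba = wv.cross_wavelet_phase(b, a, FS, band)
    assert np.allclose(ab.values, -ba.values, atol=1e-12)
    got = ab.values[INTERIOR][ab.valid[INTERIOR]]
    assert np.max(np.abs(got - np.pi / 4)) < 0.02


def _flat_cine(signal):
    frames = np.broadcast_to(signal, (8, 8, N)).copy()
    return pw.CineSequence(frames, FS)


def test_eq1_self_reference_gives_zero_phase():
    cine = _flat_cine(10 + 3 * tone(FC))
    field = wv.cf_angiogram(cine, f_hint=FC)
    ph = np.angle(field.values[4, 4, INTERIOR])
    assert np.max(np.abs(ph)) < 0.02


def test_eq1_delayed_pixel_phase():
    """A pixel delayed by dt carries phase -2 pi f dt in the Eq-1 field."""
    sig = 10 + 3 * tone(FC)
    frames = np.broadcast_to(sig, (8, 8, N)).copy()
    lag = 2
    frames[2, 2, :] = np.roll(sig, lag)
    cine = pw.CineSequence(frames, FS)
    field = wv.cf_angiogram(cine, f_hint=FC)
    ph = np.angle(field.values[2, 2, INTERIOR])
    expected = pw.wrap_angle(-2 * np.pi * FC * lag / FS)
    assert np.max(np.abs(pw.wrap_angle(ph - expected))) < 0.05


def test_eq2_minus_eq1_is_motion_phase():
    cine = _flat_cine(10 + 3 * tone(FC))
    motion = tone(FC, 0.6)
    f1 = wv.cf_angiogram(cine, f_hint=FC)
    f2 = wv.cf_angiogram(cine, motion=motion, f_hint=FC)
    assert f1.reference == "global" and f2.reference == "pulse_motion"
    dphi = (np.angle(f2.values[3, 3, :] * np.conj(f1.values[3, 3, :]))
            - np.angle(f2.motion_cf))
    dphi = pw.wrap_angle(dphi)[INTERIOR]
    assert np.ptp(dphi) < 1e-5


def test_cf_angiogram_rejects_mismatched_motion():
    cine = _flat_cine(10 + 3 * tone(FC))
    with pytest.raises(ValueError, match="length"):
        wv.cf_angiogram(cine, motion=np.ones(N // 2), f_hint=FC)


def test_cwt_agrees_with_pywt_oracle():
    """Independent check of scale localization and phase convention vs pywt."""
    pywt = pytest.importorskip("pywt")
    freqs = wv.frequency_grid(1.0, 6.0, 12)
    ours = wv.cwt(tone(FC), FS, wv.HIGH_FREQ_RES, freqs)
    name = f"cmor2.0-{6.0 / (2 * np.pi)}"
    scales = pywt.frequency2scale(name, freqs / FS)
    coef, _ = pywt.cwt(tone(FC), scales, name, sampling_period=1 / FS)
    i = np.argmax(np.mean(np.abs(ours.values[:, INTERIOR]) ** 2, axis=1))
    j = np.argmax(np.mean(np.abs(coef[:, INTERIOR]) ** 2, axis=1))
    assert abs(i - j) <= 1
    d = pw.wrap_angle(np.angle(ours.values[i, INTERIOR]) - np.angle(coef[j, INTERIOR]))
    assert np.std(d) < 0.01          # same carrier (phase differs by a constant)
    assert abs(np.mean(d)) < 0.15
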