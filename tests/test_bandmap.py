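"""Polygon band geometry, band series extraction, and the phase analyses."""

import numpy as np
import pytest
from shapely.geometry import Point

import pulsewave as pw
from pulsewave.bandmap import (
    _polygon_pixel_index,
    av_phase,
    band_signal,
    build_band,
    dorsoventral_phase,
    render_unfolded,
    segment_contour,
    select_av_intervals,
    time_intensity_curve,
    TimeIntensityCurve,
)
from pulsewave.wavelet import CardiacBand, ComplexCFField


def _straight_contour(length=300.0, y=20.0):
    return segment_contour(np.array([[10.0, y], [10.0 + length, y]]))


def _field_from(values, fs=30.0, fc=2.5):
    t = values.shape[2]
    freqs = np.array([fc])
    return ComplexCFField(
        values=values, cardiac_freq=fc, reference="global", sampling_rate=fs,
        valid=np.ones(t, bool),
        band=CardiacBand(indices=slice(0, 1), frequencies=freqs, f_center=fc),
        reference_cf=np.ones(t, complex),
    )


def test_segment_contour_equal_lengths():
    rng = np.random.default_rng(0)
    th = np.linspace(0, np.pi, 40)
    wiggly = np.column_stack([50 + 30 * np.cos(th) + rng.normal(0, 0.3, 40),
                              50 - 30 * np.sin(th)])
    sc = segment_contour(wiggly)
    assert sc.n_segments == 30
    # independent oracle: walk the original polyline densely and measure the
    # arc length between consecutive segment endpoints
    seg = np.linalg.norm(np.diff(wiggly, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    dense_s = np.linspace(0, arc[-1], 20001)
    dense = np.column_stack([np.interp(dense_s, arc, wiggly[:, 0]),
                             np.interp(dense_s, arc, wiggly[:, 1])])
    step = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(step)])
    lengths = np.diff(np.interp(sc.arc_positions, dense_s, cum))
    assert (lengths.max() - lengths.min()) / lengths.mean() < 0.005
    assert np.allclose(lengths, sc.segment_lengths, rtol=1e-4)


def test_segment_contour_rejects_closed_and_self_intersecting():
    th = np.linspace(0, 2 * np.pi, 30)
    closed = np.column_stack([np.cos(th), np.sin(th)])
    with pytest.raises(ValueError, match="open"):
        segment_contour(closed)
    bowtie = np.array([[0.0, 0.0], [10.0, 10.0], [10.0, 0.0], [0.0, 10.0]])
    with pytest.raises(ValueError, match="self-intersect"):
        segment_contour(bowtie)


def test_build_band_straight_contour_gives_square_polygons():
    band = build_band(_straight_contour(), thickness=10.0)
    assert band.n_polygons == 30
    for poly in band.polygons:
        assert poly.area == pytest.approx(100.0, rel=1e-9)
        x0, y0, x1, y1 = poly.bounds
        assert (x1 - x0, y1 - y0) == (pytest.approx(10.0), pytest.approx(10.0))
    # zone labels follow the 1-10/21-30 ventral, 11-20 dorsal convention
    assert list(band.zone[:10]) == ["ventral"] * 10
    assert list(band.zone[10:20]) == ["dorsal"] * 10
    assert list(band.zone[20:]) == ["ventral"] * 10


def test_build_band_semicircle_positive_unequal_areas():
    th = np.linspace(np.pi, 0, 80)
    semi = np.column_stack([60 + 40 * np.cos(th), 60 - 40 * np.sin(th)])
    band = build_band(segment_contour(semi), thickness=8.0, outward="left")
    areas = np.array([p.area for p in band.polygons])
    assert np.all(areas > 0)
    inner = band.contour.segment_lengths
    assert (inner.max() - inner.min()) / inner.mean() < 0.005


def test_build_band_concave_offset_errors():
    vee = np.array([[0.0, 0.0], [50.0, 50.0], [100.0, 0.0]])
    with pytest.raises(ValueError, match="concave|self-intersect"):
        build_band(segment_contour(vee), thickness=45.0, outward="left")


def test_band_signal_constant_field():
    z0 = 2.0 - 1.5j
    field = _field_from(np.full((40, 320, 6), z0, dtype=complex))
    series = band_signal(field, build_band(_straight_contour(), 10.0))
    assert series.values.shape == (30, 6)
    assert np.allclose(series.values, z0)


def test_band_signal_matches_shapely_membership_oracle():
    """Pixel-center membership agrees with direct shapely point queries."""
    band = build_band(_straight_contour(length=60.0), thickness=7.0)
    idx = _polygon_pixel_index(band, (40, 90))
    for i in (0, 13, 29):
        ours = {tuple(p) for p in idx[i]}
        poly = band.polygons[i]
        brute = set()
        x0, y0, x1, y1 = poly.bounds
        for x in range(int(x0) - 1, int(x1) + 2):
            for y in range(int(y0) - 1, int(y1) + 2):
                if poly.buffer(1e-9).contains(Point(x, y)):
                    brute.add((x, y))
        # boundary pixels may be claimed by the lower-index neighbor
        claimed_earlier = {tuple(p) for j in range(i) for p in idx[j]}
        assert ours == brute - claimed_earlier


def test_band_signal_phase_monotone_along_gradient(gradient_run):
    series = gradient_run["series"]
    k = np.argmax(np.abs(series.values).sum(axis=0))
    rel = np.angle(series.values[:, k] * np.conj(series.values[0, k]))
    dorsal_mean = rel[10:20].mean()
    ventral_mean = np.r_[rel[:10], rel[20:]].mean()
    assert dorsal_mean - ventral_mean == pytest.approx(0.7, abs=0.1)
    # transition is monotone ventral -> dorsal on the first flank
    flank = rel[6:14]
    assert np.all(np.diff(flank) > -0.08)


def test_band_series_p3_sizing(pipeline_factory):
    """10 Hz for 14.0 s gives a 30 x 140 complex table."""
    run = pipeline_factory(seed=6, sampling_rate=10.0, duration=14.0, f_hint=2.5)
    assert run["series"].values.shape == (30, 140)


def test_time_intensity_curve_shapes_and_examples(av_run):
    cine, band, truth = av_run["cine"], av_run["band"], av_run["truth"]
    fc = truth.cardiac_freq
    tic = time_intensity_curve(cine, band, fc)
    assert abs(tic.peak_time - truth.bolus_peak_time) <= 0.5 / fc
    flat = pw.CineSequence(np.full((40, 320, 20), 7.0), 30.0)
    tflat = time_intensity_curve(flat, build_band(_straight_contour(), 10.0), 2.5)
    assert np.allclose(tflat.values, 7.0)
    ramp = pw.CineSequence(
        np.broadcast_to(np.linspace(1, 9, 60), (40, 320, 60)).copy(), 30.0)
    tramp = time_intensity_curve(ramp, build_band(_straight_contour(), 10.0), 2.5)
    assert tramp.smoothed.argmax() >= 50


def test_select_av_intervals_arithmetic():
    fs = 30.0
    n = int(20 * fs)
    vals = np.exp(-((np.arange(n) / fs - 10.0) ** 2))
    tic = TimeIntensityCurve(values=vals, smoothed=vals, sampling_rate=fs)
    (a0, a1), (v0, v1) = select_av_intervals(tic, cardiac_freq=2.5, n_beats=5)
    assert (a0, a1) == (pytest.approx(8.0), pytest.approx(10.0))
    assert (v0, v1) == (pytest.approx(10.0), pytest.approx(12.0))


def test_select_av_intervals_peak_at_edge_errors():
    fs = 30.0
    vals = np.linspace(5, 1, int(20 * fs))  # peak at the first frame
    tic = TimeIntensityCurve(values=vals, smoothed=vals, sampling_rate=fs)
    with pytest.raises(ValueError, match="too short"):
        select_av_intervals(tic, cardiac_freq=2.5)


def test_av_interval_is_compartment_dominated(av_run):
    """The arterial window is arterial-dominated over >= 80% of its span."""
    truth, cine = av_run["truth"], av_run["cine"]
    series = av_run["series"]
    fc = truth.cardiac_freq
    tic = time_intensity_curve(cine, av_run["band"], fc)
    (a0, a1), (v0, v1) = select_av_intervals(tic, fc, valid=series.valid)
    from pulsewave.synthetic import BolusConfig, gamma_variate

    b = BolusConfig()
    t = cine.times
    t0 = truth.bolus_peak_time  # TIC peak ~ blush center
    onset = t0 - b.peak_delay - b.blush_delay
    art = gamma_variate(t, onset, b.alpha, b.beta)
    ven = gamma_variate(t, onset + b.transit_periods / fc, b.alpha, b.beta)
    in_a = (t >= a0) & (t < a1)
    in_v = (t >= v0) & (t < v1)
    assert np.mean(art[in_a] >= ven[in_a]) >= 0.8
    assert np.mean(ven[in_v] >= art[in_v]) >= 0.8


def test_av_phase_recovers_compartment_offsets(av_run):
    series, truth, cine = av_run["series"], av_run["truth"], av_run["cine"]
    tic = time_intensity_curve(cine, av_run["band"], truth.cardiac_freq)
    intervals = select_av_intervals(tic, truth.cardiac_freq, valid=series.valid)
    res = av_phase(series, intervals, n_perm=999, seed=0)
    assert res.arterial_summary.mean == pytest.approx(0.5, abs=0.1)
    assert res.venous_summary.mean == pytest.approx(-0.5, abs=0.1)
    assert res.arterial_phases.size == 30 and res.venous_phases.size == 30
    assert res.watson.p <= 1e-2


def test_av_phase_identical_offsets_give_equal_means(pipeline_factory):
    """With equal compartment offsets the arterial and venous circular means
    coincide (within the envelope-dynamics bias, far below the 1 rad
    arteriovenous separation the distinct-offset configuration shows)."""
    gaps = []
    for seed in range(3):
        run = pipeline_factory(seed=20 + seed, arterial_phase_offset=0.3,
                               venous_phase_offset=0.3)
        tic = time_intensity_curve(run["cine"], run["band"], run["truth"].cardiac_freq)
        iv = select_av_intervals(tic, run["truth"].cardiac_freq, valid=run["series"].valid)
        res = av_phase(run["series"], iv, n_perm=499, seed=seed)
        assert res.arterial_summary.mean == pytest.approx(0.3, abs=0.1)
        assert res.venous_summary.mean == pytest.approx(0.3, abs=0.1)
        gaps.append(abs(pw.wrap_angle(res.arterial_summary.mean
                                      - res.venous_summary.mean)))
    assert max(gaps) < 0.1


def test_av_phase_needs_motion_reference(av_run):
    series = av_run["series"]
    from dataclasses import replace

    global_series = replace(series, reference="global", motion_cf=None)
    with pytest.raises(ValueError, match="pulse-motion"):
        av_phase(global_series, ((0.0, 1.0), (1.0, 2.0)))


def test_dorsoventral_recovery_and_zone_swap(gradient_run):
    series = gradient_run["series"]
    res = dorsoventral_phase(series)
    assert res.summary.mean == pytest.approx(0.7, abs=0.1)
    assert res.watson.p <= 1e-5
    # swapping zone labels negates the phase-difference series exactly
    from dataclasses import replace

    swapped_zone = np.where(series.zone == "dorsal", "ventral", "dorsal").astype(object)
    res_sw = dorsoventral_phase(replace(series, zone=swapped_zone))
    assert np.allclose(res_sw.phase_difference, -res.phase_difference, atol=1e-12)


def test_dorsoventral_recovery_across_gradient_grid(pipeline_factory):
    """Recovery error <= 0.1 rad across gradients {-pi/2, -0.7, 0, 0.7, pi/2}
    at the default noise level, 10 seeds each; the null gradient also stays
    within the bias bound."""
    for g in (-np.pi / 2, -0.7, 0.0, 0.7, np.pi / 2):
        errs = []
        for seed in range(10):
            run = pipeline_factory(seed=40 + seed, gradient=g)
            res = dorsoventral_phase(run["series"])
            errs.append(abs(pw.wrap_angle(res.summary.mean - g)))
        assert max(errs) <= 0.1, f"gradient {g}: errors {np.round(errs, 3)}"


def test_dorsoventral_rejects_degenerate_zone(gradient_run):
    from dataclasses import replace

    series = gradient_run["series"]
    vals = series.values.copy()
    vals[10:20, :] = 0.0
    with pytest.raises(ValueError, match="dorsal zone"):
        dorsoventral_phase(replace(series, values=vals))


def test_band_series_rigid_rotation_invariance(quiet_run):
    """Rotating contour and field together leaves the band series unchanged."""
    field, band = quiet_run["field"], quiet_run["band"]
    h, w, _ = field.values.shape
    series = quiet_run["series"]
    # rotate the frame grid by 90 degrees (exact pixel permutation):
    # (x, y) -> (h - 1 - y, x)
    from dataclasses import replace

    rot_values = np.rot90(field.values, k=-1, axes=(0, 1))
    rot_roi = np.rot90(field.roi_mask, k=-1)
    rot_field = replace(field, values=rot_values, roi_mask=rot_roi)
    pts = quiet_run["truth"].contour
    rot_contour = np.column_stack([h - 1 - pts[:, 1], pts[:, 0]])
    rot_band = pw.build_band(pw.segment_contour(rot_contour),
                             float(np.mean(band.contour.segment_lengths)),
                             outward="left")
    rot_series = band_signal(rot_field, rot_band)
    a = dorsoventral_phase(series)
    b = dorsoventral_phase(rot_series)
    assert abs(pw.wrap_angle(a.summary.mean - b.summary.mean)) < 0.05


def test_render_unfolded_rows_and_hue(gradient_run):
    series = gradient_run["series"]
    img = render_unfolded(series, key_width=2)
    assert img.shape[0] == 30
    assert img.shape[1] == series.values.shape[1] + 2
    # constant-phase field renders a single hue
    const = np.full((30, 40), 3.0 * np.exp(0.4j))
    from dataclasses import replace

    img_c = render_unfolded(replace(series, values=const), key_width=0)
    flat = img_c.reshape(-1, 3)
    assert np.allclose(flat, flat[0], atol=1e-9)
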