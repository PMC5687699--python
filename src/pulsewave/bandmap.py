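"""Peri-ventricular polygon band: contour segmentation, unfolding and phase analyses.

A user-traced open contour over the outer surface of the Lateral and Third
Ventricles is divided into 30 segments of equal arc length; offsetting each
segment outward along averaged vertex normals yields 30 contiguous
quadrilaterals.  Segment order gives a one-to-one correspondence between
the ventricular perimeter and the vertical axis of the unfolded space-time
profile.  Ventral surface polygons are sequence numbers 1-10 and 21-30;
dorsal polygons are 11-20 (1-based, as displayed).

Per polygon and time, the *mean* (not sum — polygon areas are unequal) of
the complex CF angiographic field over contained pixel centers gives the
30 x T band series used for:

* the unfolded pulse-wave profile (brightness = magnitude, hue = phase);
* arterial vs venous phase relative to brain pulse motion, from 5-beat
  intervals before/after the time-intensity peak (Watson two-sample test);
* the dorsal-ventral relation: per-time ``angle(V_dorsal * conj(V_ventral))``
  of the two zone means (Watson one-sample test against 0 rad).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import LineString, Polygon as ShPolygon

from .cine import CineSequence
from .circular import (
    CircularSummary,
    WatsonOneSampleResult,
    WatsonTwoSampleResult,
    circ_summary,
    watson_one_sample,
    watson_two_sample,
    wrap_angle,
)
from .wavelet import ComplexCFField

__all__ = [
    "SegmentedContour",
    "load_contour",
    "PolygonBand",
    "build_band",
    "BandSeries",
    "band_signal",
    "TimeIntensityCurve",
    "time_intensity_curve",
    "select_av_intervals",
    "AvPhaseResult",
    "av_phase",
    "DvPhaseResult",
    "dorsoventral_phase",
    "render_unfolded",
    "complex_to_rgb",
]

N_SEGMENTS_DEFAULT = 30


@dataclass
class SegmentedContour:
    """Open simple contour resampled to equal-arc-length segment endpoints."""

    vertices: np.ndarray          # original (n, 2) x,y vertices
    n_segments: int
    endpoints: np.ndarray         # (n_segments + 1, 2) equal-arc-length points
    arc_positions: np.ndarray     # (n_segments + 1,) arc length along the polyline

    @property
    def segment_lengths(self) -> np.ndarray:
        """Arc length of each segment along the traced polyline."""
        return np.diff(self.arc_positions)

    @property
    def chord_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.endpoints, axis=0), axis=1)


def segment_contour(vertices, n_segments: int = N_SEGMENTS_DEFAULT) -> SegmentedContour:
    """Divide an open contour into segments of equal arc length.

    The contour must be simple (non-self-intersecting) and open.  Equal
    length holds within 0.5% by arc-length interpolation of the polyline.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
        raise ValueError("contour must be an (n, 2) vertex array with n >= 2")
    if np.allclose(v[0], v[-1]):
        raise ValueError("contour must be open (first and last vertices differ)")
    line = LineString(v)
    if not line.is_simple:
        raise ValueError("contour is self-intersecting")
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n_segments + 1)
    pts = np.column_stack([np.interp(targets, arc, v[:, 0]),
                           np.interp(targets, arc, v[:, 1])])
    return SegmentedContour(vertices=v, n_segments=n_segments, endpoints=pts,
                            arc_positions=targets)


def load_contour(path) -> np.ndarray:
    """Vertex list from CSV (x,y columns) or JSON ([[x, y], ...]); 0-based pixels,
    origin top-left, y down."""
    path = Path(path)
    if path.suffix == ".json":
        return np.asarray(json.loads(path.read_text()), dtype=float)
    import pandas as pd

    df = pd.read_csv(path)
    cols = [c for c in ("x", "y") if c in df.columns]
    if len(cols) == 2:
        return df[["x", "y"]].to_numpy(dtype=float)
    return df.iloc[:, :2].to_numpy(dtype=float)


def _zone_labels(n_segments: int) -> np.ndarray:
    """'ventral' for (1-based) 1-10 and 21-30, 'dorsal' for 11-20, scaled to n."""
    idx = np.arange(n_segments)
    third = n_segments / 3.0
    labels = np.where((idx >= third) & (idx < 2 * third), "dorsal", "ventral")
    return labels.astype(object)


@dataclass
class PolygonBand:
    """Contiguous quadrilaterals spanning the contour's outward offset."""

    contour: SegmentedContour
    thickness: float
    polygons: list                 # shapely Polygons, inner edge = contour segment
    zone: np.ndarray               # per-polygon 'ventral' | 'dorsal'

    @property
    def n_polygons(self) -> int:
        return len(self.polygons)

    def zone_indices(self, zone: str) -> np.ndarray:
        return np.flatnonzero(self.zone == zone)


def build_band(contour: SegmentedContour, thickness: float,
               outward: str = "left") -> PolygonBand:
    """Offset the segmented contour by ``thickness`` along averaged vertex normals.

    ``outward`` picks the offset side relative to the direction of travel
    ('left' in image coordinates, y down, suits a contour traced with the
    structure on its right).  Raises when the offset self-intersects
    (contour too concave for the requested thickness).
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    pts = contour.endpoints
    tangents = np.diff(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    if outward == "left":
        seg_normals = np.column_stack([tangents[:, 1], -tangents[:, 0]])
    elif outward == "right":
        seg_normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    else:
        raise ValueError("outward must be 'left' or 'right'")
    # averaged vertex normals (ends use their single adjacent segment)
    vnorm = np.empty_like(pts)
    vnorm[0] = seg_normals[0]
    vnorm[-1] = seg_normals[-1]
    mid = seg_normals[:-1] + seg_normals[1:]
    norms = np.linalg.norm(mid, axis=1, keepdims=True)
    if np.any(norms < 1e-9):
        raise ValueError("contour folds back on itself; cannot form vertex normals")
    vnorm[1:-1] = mid / norms
    outer = pts + thickness * vnorm

    polys = []
    for i in range(contour.n_segments):
        quad = ShPolygon([pts[i], pts[i + 1], outer[i + 1], outer[i]])
        if (not quad.is_valid) or quad.area <= 0:
            raise ValueError(
                f"offset self-intersects at segment {i + 1}: contour too "
                f"concave for thickness {thickness}"
            )
        polys.append(quad)
    return PolygonBand(contour=contour, thickness=thickness, polygons=polys,
                       zone=_zone_labels(contour.n_segments))


@dataclass
class BandSeries:
    """Per-polygon spatial means of a complex CF field, with time indexing.

    Inherits the field's reference mode, validity (cone of influence) and
    the CF-filtered motion/global-reference series needed to demodulate
    the CF carrier in scalar phase summaries.
    """

    values: np.ndarray             # (n_polygons, T) complex
    sampling_rate: float
    cardiac_freq: float
    reference: str
    valid: np.ndarray              # (T,) bool
    zone: np.ndarray
    reference_cf: np.ndarray
    motion_cf: np.ndarray | None = None
    motion_locked: np.ndarray | None = None   # carrier-free pixel-vs-motion phase

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) / self.sampling_rate


def _polygon_pixel_index(band: PolygonBand, shape: tuple[int, int]) -> list[np.ndarray]:
    """Pixel-center membership per polygon; boundary ties go to the lower index."""
    h, w = shape
    taken = np.zeros((h, w), dtype=bool)
    out = []
    for i, poly in enumerate(band.polygons):
        x0, y0, x1, y1 = poly.bounds
        xa, ya = max(int(np.floor(x0)), 0), max(int(np.floor(y0)), 0)
        xb, yb = min(int(np.ceil(x1)) + 1, w), min(int(np.ceil(y1)) + 1, h)
        if xa >= xb or ya >= yb:
            raise ValueError(f"polygon {i + 1} lies outside the field bounds")
        yy, xx = np.mgrid[ya:yb, xa:xb]
        cand = np.column_stack([xx.ravel(), yy.ravel()])
        path = MplPath(np.asarray(poly.exterior.coords))
        # inclusive boundary regardless of path orientation (the sign of
        # matplotlib's radius dilates or erodes depending on winding)
        inside = path.contains_points(cand, radius=1e-9) | path.contains_points(cand, radius=-1e-9)
        sel = cand[inside]
        keep = ~taken[sel[:, 1], sel[:, 0]]
        sel = sel[keep]
        if sel.shape[0] == 0:
            raise ValueError(f"polygon {i + 1} contains no pixel centers")
        taken[sel[:, 1], sel[:, 0]] = True
        out.append(sel)
    return out


def band_roi_mask(band: PolygonBand, shape: tuple[int, int], pad: int = 2) -> np.ndarray:
    """Boolean mask of pixels needed to evaluate the band (polygons + padding).

    Restricting :func:`~pulsewave.wavelet.cf_angiogram` to this mask avoids
    transforming pixels the band series never reads.
    """
    from scipy.ndimage import binary_dilation

    mask = np.zeros(shape, dtype=bool)
    for sel in _polygon_pixel_index(band, shape):
        mask[sel[:, 1], sel[:, 0]] = True
    if pad > 0:
        mask = binary_dilation(mask, iterations=pad)
    return mask


def band_signal(field: ComplexCFField, band: PolygonBand) -> BandSeries:
    """30 x T complex band series: per-polygon mean of the CF field over time."""
    h, w, _ = field.values.shape
    index = _polygon_pixel_index(band, (h, w))
    if field.roi_mask is not None:
        for i, sel in enumerate(index):
            if not np.all(field.roi_mask[sel[:, 1], sel[:, 0]]):
                raise ValueError(
                    f"polygon {i + 1} includes pixels outside the transformed ROI"
                )
    values = np.stack([
        field.values[sel[:, 1], sel[:, 0], :].mean(axis=0) for sel in index
    ])
    locked = None
    if field.motion_locked is not None:
        locked = np.stack([
            field.motion_locked[sel[:, 1], sel[:, 0], :].mean(axis=0) for sel in index
        ])
    return BandSeries(
        values=values,
        sampling_rate=field.sampling_rate,
        cardiac_freq=field.cardiac_freq,
        reference=field.reference,
        valid=field.valid.copy(),
        zone=band.zone.copy(),
        reference_cf=field.reference_cf,
        motion_cf=field.motion_cf,
        motion_locked=locked,
    )


@dataclass
class TimeIntensityCurve:
    """Raw and cardiac-period-smoothed mean band intensity per frame."""

    values: np.ndarray
    smoothed: np.ndarray
    sampling_rate: float

    @property
    def peak_time(self) -> float:
        return float(np.argmax(self.smoothed) / self.sampling_rate)


def time_intensity_curve(cine: CineSequence, band: PolygonBand,
                         cardiac_freq: float) -> TimeIntensityCurve:
    """Mean raw intensity over all band pixels per frame, plus a smoothed copy.

    Smoothing is a moving average over one cardiac period, for peak finding.
    """
    index = _polygon_pixel_index(band, cine.frames.shape[:2])
    pix = np.concatenate(index, axis=0)
    tic = cine.frames[pix[:, 1], pix[:, 0], :].mean(axis=0)
    k = max(1, int(round(cine.sampling_rate / cardiac_freq)))
    kernel = np.ones(k) / k
    smoothed = np.convolve(tic, kernel, mode="same")
    return TimeIntensityCurve(values=tic, smoothed=smoothed,
                              sampling_rate=cine.sampling_rate)


def select_av_intervals(tic: TimeIntensityCurve, cardiac_freq: float,
                        n_beats: float = 5.0,
                        valid: np.ndarray | None = None):
    """Arterial and venous intervals of ``n_beats`` heartbeats around the TIC peak.

    The arterial interval ends at the smoothed peak, the venous interval
    begins there; both are clipped away from cone-of-influence edges when
    a validity mask is given.  Returns ``((t_a0, t_a1), (t_v0, t_v1))`` in
    seconds.  Raises when the recording cannot hold both intervals.
    """
    fs = tic.sampling_rate
    n = tic.values.size
    length = n_beats / cardiac_freq
    lo = 0.0 if valid is None else float(np.argmax(valid) / fs)
    hi = n / fs if valid is None else float((n - np.argmax(valid[::-1])) / fs)
    t_peak = tic.peak_time
    t_a0, t_v1 = t_peak - length, t_peak + length
    t_a0 = max(t_a0, lo)
    t_v1 = min(t_v1, hi)
    if t_peak - t_a0 < 0.6 * length or t_v1 - t_peak < 0.6 * length:
        raise ValueError(
            f"recording too short around the TIC peak at {t_peak:.2f} s for "
            f"{n_beats:g}-beat arterial/venous intervals"
        )
    return (t_a0, t_peak), (t_peak, t_v1)


def _demodulated(series: BandSeries) -> np.ndarray:
    """Carrier-free motion-referenced band data.

    The Eq-2 product keeps the per-pixel CF carrier ``e^{i w t}`` (that is
    what animates the rendered pulse-wave cine); its time-average over an
    interval would vanish.  The angiogram therefore carries a motion-locked
    companion (per-scale cross-wavelet of each pixel against the pulse
    motion), whose phase is the time-stable pixel-minus-motion CF phase the
    circular histograms summarize.
    """
    if series.reference != "pulse_motion" or series.motion_locked is None:
        raise ValueError("band series must be built with the pulse-motion reference")
    return series.motion_locked


def _interval_slice(interval, fs: float, n: int) -> slice:
    a = int(np.ceil(interval[0] * fs))
    b = int(np.floor(interval[1] * fs))
    if not (0 <= a < b <= n):
        raise ValueError(f"interval {interval} outside the series")
    return slice(a, b)


@dataclass
class AvPhaseResult:
    """Arterial and venous PW phase relative to brain pulse motion."""

    arterial_phases: np.ndarray       # per-polygon, radians
    venous_phases: np.ndarray
    arterial_summary: CircularSummary
    venous_summary: CircularSummary
    watson: WatsonTwoSampleResult
    intervals: tuple


def av_phase(series: BandSeries, intervals, n_perm: int = 10_000,
             seed: int | None = 0) -> AvPhaseResult:
    """Per-polygon PW phase in the arterial and venous bolus intervals.

    The motion-referenced complex band data are demodulated to
    pixel-minus-motion CF phase, time-averaged over each interval per
    polygon, and the phases of these averages form two 30-element circular
    samples compared by Watson's two-sample test.
    """
    demod = _demodulated(series)
    n = demod.shape[1]
    out = []
    for interval in intervals:
        sl = _interval_slice(interval, series.sampling_rate, n)
        sel = series.valid[sl]
        seg = demod[:, sl][:, sel]
        if seg.shape[1] == 0:
            raise ValueError(f"interval {interval} has no valid samples")
        means = seg.mean(axis=1)
        if np.any(np.abs(means) < 1e-300):
            raise ValueError("zero-magnitude polygon average: phase undefined")
        out.append(wrap_angle(np.angle(means)))
    art, ven = out
    return AvPhaseResult(
        arterial_phases=art,
        venous_phases=ven,
        arterial_summary=circ_summary(art),
        venous_summary=circ_summary(ven),
        watson=watson_two_sample(art, ven, n_perm=n_perm, seed=seed),
        intervals=tuple(intervals),
    )


@dataclass
class DvPhaseResult:
    """Dorsal-ventral pulse-wave phase relation."""

    v_dorsal: np.ndarray              # complex zone means over time
    v_ventral: np.ndarray
    phase_difference: np.ndarray      # per-time angle(V_D conj(V_V)), valid only
    valid: np.ndarray
    summary: CircularSummary
    watson: WatsonOneSampleResult


def dorsoventral_phase(series: BandSeries, magnitude_floor: float = 0.05) -> DvPhaseResult:
    """Pooled dorsal-minus-ventral CF phase difference of the band series.

    ``V_dorsal`` and ``V_ventral`` are per-time complex means over the zone
    polygons; their per-time phase difference is the angle of
    ``V_dorsal * conj(V_ventral)`` (the CF carrier cancels).  Samples where
    either zone magnitude falls below ``magnitude_floor`` of its own peak
    (outside the bolus there is no pulse-wave signal and the phase is
    undefined) or inside the cone of influence are excluded from pooling.
    Positive pooled mean: ventral leads — pulse waves travel ventral to
    dorsal.
    """
    d_idx = np.flatnonzero(series.zone == "dorsal")
    v_idx = np.flatnonzero(series.zone == "ventral")
    if d_idx.size == 0 or v_idx.size == 0:
        raise ValueError("band series lacks zone labels")
    v_d = series.values[d_idx].mean(axis=0)
    v_v = series.values[v_idx].mean(axis=0)
    mag_d = np.abs(v_d)
    mag_v = np.abs(v_v)
    # a zone that stays ~zero while the band carries signal is degenerate
    active = np.maximum(mag_d, mag_v) > 1e-9 * max(mag_d.max(), mag_v.max(), 1e-300)
    for name, mag in (("dorsal", mag_d), ("ventral", mag_v)):
        dead = 1e-9 * max(mag.max(), 1e-300)
        if np.count_nonzero(mag[active] > dead) < 0.5 * np.count_nonzero(active):
            raise ValueError(f"{name} zone has ~zero magnitude at > 50% of samples")
    peak_d = mag_d[series.valid].max() if series.valid.any() else mag_d.max()
    peak_v = mag_v[series.valid].max() if series.valid.any() else mag_v.max()
    ok = (mag_d > magnitude_floor * peak_d) & (mag_v > magnitude_floor * peak_v)
    valid = series.valid & ok
    if np.count_nonzero(valid) < 10:
        raise ValueError("fewer than 10 valid interior samples")
    diff = wrap_angle(np.angle(v_d * np.conj(v_v)))
    pooled = diff[valid]
    return DvPhaseResult(
        v_dorsal=v_d,
        v_ventral=v_v,
        phase_difference=pooled,
        valid=valid,
        summary=circ_summary(pooled),
        watson=watson_one_sample(pooled, mu0=0.0),
    )


def complex_to_rgb(z: np.ndarray, clip_percentile: float = 99.0) -> np.ndarray:
    """Brightness-hue rendering of complex CF data.

    Value = magnitude normalized to its ``clip_percentile`` (clipped),
    hue = ``(phase + pi) / 2 pi`` on the cyclic HSV colormap, saturation 1.
    """
    from matplotlib.colors import hsv_to_rgb

    mag = np.abs(z)
    scale = np.percentile(mag, clip_percentile)
    v = np.clip(mag / scale, 0.0, 1.0) if scale > 0 else np.zeros_like(mag)
    hue = (wrap_angle(np.angle(z)) + np.pi) / (2.0 * np.pi)
    hsv = np.stack([hue, np.ones_like(v), v], axis=-1)
    return hsv_to_rgb(hsv)


ZONE_COLORS = {"ventral": (1.0, 0.55, 0.0), "dorsal": (0.25, 0.88, 0.82)}  # orange / turquoise


def render_unfolded(series: BandSeries, key_width: int = 2) -> np.ndarray:
    """Unfolded pulse-wave profile image: rows = segments 1..30, columns = time.

    Brightness encodes CF magnitude (99th-percentile normalized), hue the
    CF phase; a margin on the left keys the ventral (orange) / dorsal
    (turquoise) zones.
    """
    rgb = complex_to_rgb(series.values)
    key = np.zeros((series.n_segments, key_width, 3))
    for i, z in enumerate(series.zone):
        key[i, :, :] = ZONE_COLORS[str(z)]
    return np.concatenate([key, rgb], axis=1)
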