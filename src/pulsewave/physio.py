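"""CSF pressure / ABP / ECG waveform records and the CSF phase pipeline.

During neuro-endoscopy, ~10-heartbeat epochs of CSF pressure are recorded
separately in the (dorsal) Lateral Ventricle and the (ventral) Third
Ventricle, together with ABP and ECG on a shared clock.  Because the two
epochs are minutes apart, their CF phases are compared only *relative to
the cardiac reference*: per record, the cross-wavelet phase of CSF
pressure against ECG (or ABP) is reduced to one circular mean per detected
heartbeat, and all dorsal-beat minus ventral-beat differences are pooled.

Video and pressure instruments run on unsynchronized clocks; a deliberate
catheter tap ("finger flick") seen by both provides the offset, estimated
here to about one video frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .circular import CircularSummary, WatsonOneSampleResult, circ_summary, watson_one_sample, wrap_angle
from .wavelet import (
    HIGH_FREQ_RES,
    CardiacBand,
    PhaseSeries,
    cf_filter,
    cross_wavelet_phase,
    cwt,
    select_cardiac_scale,
)

__all__ = [
    "Trace",
    "PhysiologyRecord",
    "load_physio",
    "ClockAlignment",
    "TransientError",
    "align_clocks",
    "cardiac_reference_phase",
    "CsfPhaseResult",
    "dorsoventral_csf_phase",
]

DEFAULT_COLUMNS = {"time": "time_s", "csf": "csf_mmHg", "abp": "abp_mmHg", "ecg": "ecg_au"}

DORSAL_SITE = "lateral_ventricle"
VENTRAL_SITE = "third_ventricle"


@dataclass
class Trace:
    """A plain uniformly sampled series on its instrument's clock."""

    values: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace must be 1-D with >= 2 samples")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.sampling_rate


@dataclass
class PhysiologyRecord:
    """Uniformly sampled CSF pressure / ABP / ECG epoch with site metadata."""

    time: np.ndarray            # seconds, uniform
    csf_pressure: np.ndarray    # mmHg
    abp: np.ndarray             # mmHg
    ecg: np.ndarray             # arbitrary units
    site: str | None = None     # lateral_ventricle (dorsal) | third_ventricle (ventral)
    interpolated: np.ndarray | None = None   # flags for gap-filled samples
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        for name in ("csf_pressure", "abp", "ecg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.time.shape:
                raise ValueError(f"{name} length does not match time")
            setattr(self, name, arr)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.time.shape, dtype=bool)
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time column must be strictly increasing")
        med = np.median(dt)
        if np.max(np.abs(dt - med)) > 0.01 * med:
            raise ValueError("sampling jitter exceeds 1% of the sample interval")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def channel(self, name: str) -> np.ndarray:
        try:
            return {"csf": self.csf_pressure, "abp": self.abp, "ecg": self.ecg}[name]
        except KeyError:
            raise ValueError(f"unknown channel {name!r} (csf | abp | ecg)") from None

    def to_csv(self, path) -> None:
        pd.DataFrame({
            DEFAULT_COLUMNS["time"]: self.time,
            DEFAULT_COLUMNS["csf"]: self.csf_pressure,
            DEFAULT_COLUMNS["abp"]: self.abp,
            DEFAULT_COLUMNS["ecg"]: self.ecg,
        }).to_csv(path, index=False)


def load_physio(path, column_map: dict | None = None, scale: dict | None = None,
                site: str | None = None, max_gap_fraction: float = 0.05) -> PhysiologyRecord:
    """Load a physiology CSV into a validated, uniformly sampled record.

    ``column_map`` overrides the default column names for other dialects;
    ``scale`` rescales integer-encoded channels (e.g. 32-bit counts to
    mmHg).  Dropped samples are detected from the time column, re-inserted
    on the uniform grid by linear interpolation and flagged; more than
    ``max_gap_fraction`` missing raises.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")
    t = df[cols["time"]].to_numpy(dtype=float)
    if t.size < 16:
        raise ValueError("record too short")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time column is not strictly increasing")

    dt = float(np.median(np.diff(t)))
    grid = t[0] + dt * np.arange(int(round((t[-1] - t[0]) / dt)) + 1)
    n_missing = grid.size - t.size
    if n_missing < 0:
        raise ValueError("time column inconsistent with its own median interval")
    if n_missing / grid.size > max_gap_fraction:
        raise ValueError(
            f"{n_missing}/{grid.size} samples missing (> {max_gap_fraction:.0%})"
        )
    # flag grid points with no original sample nearby
    idx = np.searchsorted(t, grid)
    idx_lo = np.clip(idx - 1, 0, t.size - 1)
    idx_hi = np.clip(idx, 0, t.size - 1)
    nearest = np.minimum(np.abs(grid - t[idx_lo]), np.abs(t[idx_hi] - grid))
    interpolated = nearest > 0.5 * dt

    scale = scale or {}
    chans = {}
    for key in ("csf", "abp", "ecg"):
        v = df[cols[key]].to_numpy(dtype=float) * float(scale.get(key, 1.0))
        good = np.isfinite(v)
        if good.sum() / v.size < 1.0 - max_gap_fraction:
            raise ValueError(f"channel {key}: too many non-finite samples")
        chans[key] = np.interp(grid, t[good], v[good])
        interpolated |= np.interp(grid, t, (~good).astype(float)) > 0.25

    return PhysiologyRecord(
        time=grid, csf_pressure=chans["csf"], abp=chans["abp"], ecg=chans["ecg"],
        site=site, interpolated=interpolated, meta={"source": str(path)},
    )


class TransientError(ValueError):
    """Zero or multiple candidate synchronization transients."""


@dataclass(frozen=True)
class ClockAlignment:
    offset: float           # seconds: pressure-clock time minus video-clock time
    uncertainty: float      # one video frame
    motion_onset: float     # on the video clock
    pressure_onset: float   # on the pressure clock


def _transient_onset(trace: Trace, k_mad: float, merge_gap_s: float = 0.5) -> float:
    """Onset time of the single above-threshold transient (half-peak crossing)."""
    x = trace.values
    dev = np.abs(x - np.median(x))
    mad = np.median(dev)
    above = np.flatnonzero(dev > k_mad * mad)
    if above.size == 0:
        raise TransientError(
            f"{trace.label or 'trace'}: no transient exceeds median + {k_mad:g} * MAD"
        )
    gap = max(1, int(round(merge_gap_s * trace.sampling_rate)))
    breaks = np.flatnonzero(np.diff(above) > gap)
    clusters = np.split(above, breaks + 1)
    if len(clusters) > 1:
        times = [trace.start_time + c[np.argmax(dev[c])] / trace.sampling_rate for c in clusters]
        raise TransientError(
            f"{trace.label or 'trace'}: {len(clusters)} candidate transients at "
            + ", ".join(f"{t:.2f}s" for t in times)
        )
    cluster = clusters[0]
    peak = cluster[np.argmax(dev[cluster])]
    half = dev[peak] / 2.0
    i = peak
    while i > 0 and dev[i - 1] >= half:
        i -= 1
    if i == 0:
        frac = 0.0
    else:
        d0, d1 = dev[i - 1], dev[i]
        frac = (half - d0) / (d1 - d0) if d1 > d0 else 0.0
        i -= 1
    return trace.start_time + (i + frac) / trace.sampling_rate


def align_clocks(motion_trace: Trace, pressure_trace: Trace, k_mad: float = 8.0) -> ClockAlignment:
    """Estimate the pressure-minus-video clock offset from the finger-flick pair.

    Each trace must contain exactly one transient exceeding its median +
    ``k_mad`` * MAD; the onset is the first crossing of half the peak
    deviation (linearly interpolated).  Uncertainty is one video frame.
    """
    t_m = _transient_onset(motion_trace, k_mad)
    t_p = _transient_onset(pressure_trace, k_mad)
    return ClockAlignment(
        offset=t_p - t_m,
        uncertainty=1.0 / motion_trace.sampling_rate,
        motion_onset=t_m,
        pressure_onset=t_p,
    )


def _record_band(rec: PhysiologyRecord, channel: str, f_hint: float | None) -> CardiacBand:
    coeffs = cwt(rec.channel(channel), rec.sampling_rate, HIGH_FREQ_RES)
    return select_cardiac_scale(coeffs, f_hint=f_hint)


def cardiac_reference_phase(rec: PhysiologyRecord, channel: str = "ecg",
                            band: CardiacBand | None = None,
                            f_hint: float | None = None) -> np.ndarray:
    """Complex CF analytic series of the cardiac reference channel.

    Raises when the channel has no prominent CF power (flat or broadband).
    """
    if band is None:
        band = _record_band(rec, channel, f_hint)
    return cf_filter(rec.channel(channel), rec.sampling_rate, band)


def _beat_bounds(rec: PhysiologyRecord, channel: str, f_center: float) -> np.ndarray:
    """Sample indices of detected cardiac cycle starts (reference-channel peaks)."""
    x = rec.channel(channel)
    fs = rec.sampling_rate
    x0 = x - np.median(x)
    peaks, _ = find_peaks(x0, height=0.5 * np.max(x0), distance=int(0.5 * fs / f_center))
    return peaks


@dataclass
class CsfPhaseResult:
    """Pooled dorsal-minus-ventral CSF CF phase differences."""

    samples: np.ndarray                 # all beat-pair differences, radians
    beat_phases_dorsal: np.ndarray
    beat_phases_ventral: np.ndarray
    summary: CircularSummary
    watson: WatsonOneSampleResult
    cardiac_freq: float
    subject: str | None = None

    def to_frame(self) -> pd.DataFrame:
        n_v = self.beat_phases_ventral.size
        k = np.arange(self.samples.size)
        return pd.DataFrame({
            "value_rad": self.samples,
            "beat_dorsal": k // n_v,
            "beat_ventral": k % n_v,
            "subject": self.subject,
        })


def _beat_phases(rec: PhysiologyRecord, reference: str, band: CardiacBand) -> np.ndarray:
    """One relative CSF-vs-reference phase per detected cardiac cycle."""
    ps: PhaseSeries = cross_wavelet_phase(
        rec.csf_pressure, rec.channel(reference), rec.sampling_rate, band
    )
    bounds = _beat_bounds(rec, reference, band.f_center)
    phases = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        sel = ps.valid[a:b]
        if np.count_nonzero(sel) == 0:
            continue
        phases.append(circ_summary(ps.values[a:b][sel]).mean)
    return np.asarray(phases)


def dorsoventral_csf_phase(rec_dorsal: PhysiologyRecord, rec_ventral: PhysiologyRecord,
                           reference: str = "ecg", f_hint: float | None = None,
                           subject: str | None = None) -> CsfPhaseResult:
    """Pooled dorsal-minus-ventral CF phase of CSF pressure, cardiac-synchronized.

    Per record the per-time cross-wavelet phase of CSF pressure against the
    cardiac reference is reduced to one circular mean per detected beat;
    the two epochs (which need not overlap in absolute time) are then
    combined by forming every dorsal-beat minus ventral-beat difference.
    Positive pooled mean: ventral (Third Ventricle) pressure leads, i.e.
    pressure waves travel ventral to dorsal.
    """
    if reference not in ("ecg", "abp"):
        raise ValueError("reference channel must be 'ecg' or 'abp'")
    out = []
    for rec in (rec_dorsal, rec_ventral):
        band = _record_band(rec, reference, f_hint)
        bp = _beat_phases(rec, reference, band)
        if bp.size < 3:
            raise ValueError(
                f"record {rec.site or '?'}: only {bp.size} beats with valid CF phase (< 3)"
            )
        out.append((bp, band))
    (bp_d, band_d), (bp_v, _) = out
    diffs = wrap_angle(bp_d[:, None] - bp_v[None, :]).ravel()
    summary = circ_summary(diffs)
    watson = watson_one_sample(diffs, mu0=0.0)
    return CsfPhaseResult(
        samples=diffs,
        beat_phases_dorsal=bp_d,
        beat_phases_ventral=bp_v,
        summary=summary,
        watson=watson,
        cardiac_freq=band_d.f_center,
        subject=subject,
    )
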