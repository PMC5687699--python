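"""Synthetic cine and physiology with known cardiac-frequency phase structure.

Every downstream stage of the pipeline is validated by recovering phase
parameters this module injects:

* :func:`generate_cine` builds a contrast-bolus cine of a synthetic
  peri-ventricular scene: a ring of vascular pixels around an open
  ventricular contour, split pixel-wise into arterial and venous
  compartments whose gamma-variate envelopes are separated by a transit
  time, each modulated at cardiac frequency with configurable phase
  offsets relative to a trackable oscillating blob (the pulse-motion
  reference); an unmodulated parenchymal blush (capillary transit damps
  pulsatility) anchors a unimodal time-intensity peak between the two
  compartment envelopes.  A ventral-to-dorsal phase gradient can be laid
  along the contour.
* :func:`generate_physio` builds two-site CSF pressure epochs (recorded at
  different start times on a continuous cardiac clock) with a known
  inter-site CF phase lag, plus shared ECG and ABP references.
* :func:`generate_flick_pair` builds the video-motion / pressure transient
  pair used to align unsynchronized instrument clocks.

Same seed, same configuration => bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cine import CineSequence
from .circular import wrap_angle
from .physio import PhysiologyRecord, Trace, DORSAL_SITE, VENTRAL_SITE

__all__ = [
    "BolusConfig",
    "MotionConfig",
    "SceneConfig",
    "CineGroundTruth",
    "generate_cine",
    "PhysioGroundTruth",
    "generate_physio",
    "generate_flick_pair",
]


def gamma_variate(t, t0: float, alpha: float, beta: float) -> np.ndarray:
    """Unit-peak gamma-variate bolus envelope, peaking at ``t0 + alpha*beta``."""
    tau = np.maximum(np.asarray(t, dtype=float) - t0, 0.0)
    tp = alpha * beta
    out = np.zeros_like(tau)
    m = tau > 0
    out[m] = (tau[m] / tp) ** alpha * np.exp(alpha - tau[m] / beta)
    return out


@dataclass
class BolusConfig:
    """Indicator-dilution model of the contrast bolus.

    The venous envelope is the arterial one delayed by ``transit_periods``
    cardiac periods.  The parenchymal blush peaks ``blush_delay`` seconds
    after the arterial peak with no CF modulation, so the band
    time-intensity curve has a single peak at the arteriovenous crossover
    while the CF signal stays compartment-dominated on either side of it.
    """

    t0: float | None = None        # bolus arrival (s); None -> peak mid-recording
    alpha: float = 8.0
    beta: float = 0.18             # => envelope peak 1.44 s after arrival
    amplitude: float = 60.0        # intensity units per compartment pixel
    transit_periods: float = 7.0   # arteriovenous delay in cardiac periods
    blush_amplitude: float = 150.0
    blush_sd: float = 1.2          # s
    blush_delay: float = 1.7       # s after the arterial envelope peak

    @property
    def peak_delay(self) -> float:
        return self.alpha * self.beta


@dataclass
class MotionConfig:
    """Trackable oscillating bright blob (the pulse-motion chronometer)."""

    amplitude_px: float = 0.4
    phase: float = 0.0             # radians of the blob's cos(2 pi f t + phase)
    axis: tuple[float, float] = (1.0, 0.0)
    center: tuple[float, float] = (20.0, 20.0)   # (x, y) pixels
    sigma_px: float = 2.5
    brightness: float = 80.0


@dataclass
class SceneConfig:
    """Geometry of the synthetic peri-ventricular scene (pixels, origin top-left)."""

    center: tuple[float, float] | None = None   # ellipse center; None -> frame center
    semi_axes: tuple[float, float] | None = None
    ring_inner: float = 0.85       # normalized ellipse radii bounding the vascular ring
    ring_outer: float = 1.15
    arc_start_deg: float = 210.0   # contour start (ventral tail, math angle, y up)
    arc_end_deg: float = -30.0     # contour end (other ventral tail)
    n_contour_vertices: int = 61
    transition_width: float = 1.0 / 30.0   # gradient ramp width in contour fraction


@dataclass
class CineGroundTruth:
    """Injected phase structure of a synthetic cine, for recovery tests.

    All phase fields are radians in (-pi, pi].  ``arterial_phase_offset``
    and ``venous_phase_offset`` are CF phases relative to the pulse-motion
    signal; ``ventral_dorsal_gradient`` is the dorsal-minus-ventral CF
    angle laid along the contour (positive values reproduce the reported
    ventral-to-dorsal travel of pulse waves).
    """

    cardiac_freq: float
    arterial_phase_offset: float
    venous_phase_offset: float
    ventral_dorsal_gradient: float
    bolus_peak_time: float
    compartment_masks: dict                  # {"arterial","venous","background"} -> bool (H,W)
    contour: np.ndarray                      # (n, 2) x,y vertices (ventral->dorsal->ventral)
    motion_roi: np.ndarray                   # (4, 2) polygon around the blob
    pulse_motion: np.ndarray                 # reference 1-D displacement signal (px)
    motion_axis: np.ndarray
    band_mask: np.ndarray                    # vascular ring pixels
    sampling_rate: float
    duration: float

    def __post_init__(self):
        for name in ("arterial_phase_offset", "venous_phase_offset", "ventral_dorsal_gradient"):
            v = float(getattr(self, name))
            if not (-np.pi < v <= np.pi):
                raise ValueError(f"{name}={v} outside (-pi, pi]")
        if not (0.0 < self.bolus_peak_time < self.duration):
            raise ValueError("bolus peak time outside the recording interval")


def _ellipse_geometry(shape, scene: SceneConfig):
    h, w = shape
    cx, cy = scene.center if scene.center is not None else (w / 2.0, h / 2.0 + 8.0)
    rx, ry = scene.semi_axes if scene.semi_axes is not None else (0.30 * w, 0.24 * h)
    return cx, cy, rx, ry


def _contour_param(x, y, cx, cy, scene: SceneConfig):
    """Fractional position q in [0,1] along the contour arc for pixel coords.

    q is the normalized sweep from arc_start to arc_end; pixels outside the
    swept sector get q = nan.
    """
    psi = np.degrees(np.arctan2(cy - y, x - cx))        # math angle, y up
    a0, a1 = scene.arc_start_deg, scene.arc_end_deg     # 210 .. -30 (descending)
    # unwrap so the swept sector [a1, a0] is contiguous (arctan2 cuts at 180)
    mid_gap = (a0 + a1) / 2.0 - 180.0                   # center of the unswept sector
    psi = np.where(psi < mid_gap, psi + 360.0, psi)
    q = (a0 - psi) / (a0 - a1)
    return q


def _gradient_ramp(q, width: float) -> np.ndarray:
    """0 on ventral thirds, 1 on the dorsal middle third, linear ramps between."""
    ramp_up = np.clip((q - (1.0 / 3.0 - width / 2)) / width, 0.0, 1.0)
    ramp_down = np.clip(((2.0 / 3.0 + width / 2) - q) / width, 0.0, 1.0)
    return np.minimum(ramp_up, ramp_down)


def generate_cine(shape=(128, 128), sampling_rate: float = 30.0, duration: float = 20.0,
                  cardiac_freq: float = 2.5, arterial_phase_offset: float = 0.5,
                  venous_phase_offset: float = -0.5, ventral_dorsal_gradient: float = 0.0,
                  bolus: BolusConfig | None = None, motion: MotionConfig | None = None,
                  scene: SceneConfig | None = None, modulation_depth: float = 0.25,
                  baseline: float = 20.0, noise_sd: float = 2.0,
                  masks: dict | None = None, seed: int = 0):
    """Generate a contrast-bolus cine with known CF phase structure.

    Returns ``(CineSequence, CineGroundTruth)``.  Compartment pixel signals
    are ``envelope(t) * (1 + m cos(2 pi f t + theta(x, y)))`` plus baseline,
    blush and Gaussian noise, where ``theta`` combines the compartment
    offset (relative to the blob's oscillation phase) and the
    ventral-to-dorsal gradient ramp along the contour.  ``masks`` may
    supply explicit boolean ``{"arterial", "venous"}`` masks (must not
    overlap); by default the vascular ring is split checkerboard-wise so
    both compartments are present everywhere along the band.
    """
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("frame dimensions must be positive")
    if cardiac_freq >= sampling_rate / 2.0:
        raise ValueError("cardiac frequency must be below Nyquist")
    if duration * cardiac_freq < 10.0:
        raise ValueError("need at least 10 cardiac periods of recording")
    for v in (arterial_phase_offset, venous_phase_offset, ventral_dorsal_gradient):
        if not (-np.pi < v <= np.pi):
            raise ValueError("phase parameters must lie in (-pi, pi]")

    bolus = bolus or BolusConfig()
    motion = motion or MotionConfig()
    scene = scene or SceneConfig()
    rng = np.random.default_rng(seed)

    n_t = int(round(duration * sampling_rate))
    t = np.arange(n_t) / sampling_rate
    omega = 2.0 * np.pi * cardiac_freq
    transit = bolus.transit_periods / cardiac_freq

    if bolus.t0 is None:
        # place the blush (and hence the TIC peak) mid-recording
        t0 = duration / 2.0 - (bolus.peak_delay + bolus.blush_delay)
    else:
        t0 = bolus.t0

    cx, cy, rx, ry = _ellipse_geometry((h, w), scene)
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
    q = _contour_param(xx, yy, cx, cy, scene)
    ring = (r >= scene.ring_inner) & (r <= scene.ring_outer) & (q >= 0.0) & (q <= 1.0)

    if masks is None:
        checker = (xx + yy) % 2 == 0
        mask_art = ring & checker
        mask_ven = ring & ~checker
    else:
        mask_art = np.asarray(masks["arterial"], dtype=bool)
        mask_ven = np.asarray(masks["venous"], dtype=bool)
        if np.any(mask_art & mask_ven):
            raise ValueError("arterial and venous masks overlap")

    # CF phase per pixel: compartment offset (vs motion) + gradient ramp
    theta_m = motion.phase
    ramp = _gradient_ramp(q, scene.transition_width)
    theta_grad = ventral_dorsal_gradient * np.where(np.isfinite(ramp), ramp, 0.0)
    theta_art = wrap_angle(arterial_phase_offset + theta_m + theta_grad)
    theta_ven = wrap_angle(venous_phase_offset + theta_m + theta_grad)

    env_art = bolus.amplitude * gamma_variate(t, t0, bolus.alpha, bolus.beta)
    env_ven = bolus.amplitude * gamma_variate(t, t0 + transit, bolus.alpha, bolus.beta)
    t_blush = t0 + bolus.peak_delay + bolus.blush_delay
    blush = bolus.blush_amplitude * np.exp(-((t - t_blush) ** 2) / (2.0 * bolus.blush_sd**2))

    frames = np.empty((h, w, n_t), dtype=float)
    frames[:] = baseline
    blush_region = r <= 1.4
    frames[blush_region] += blush[None, :]

    carrier = omega * t
    for mask, theta, env in ((mask_art, theta_art, env_art), (mask_ven, theta_ven, env_ven)):
        mod = 1.0 + modulation_depth * np.cos(carrier[None, :] + theta[mask][:, None])
        frames[mask] += env[None, :] * mod

    # trackable blob, oscillating in phase with the returned pulse-motion reference
    ax = np.asarray(motion.axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    disp = motion.amplitude_px * np.cos(omega * t + motion.phase)
    bx, by = motion.center
    half = int(np.ceil(4 * motion.sigma_px + motion.amplitude_px)) + 1
    x0, x1 = int(bx) - half, int(bx) + half + 1
    y0, y1 = int(by) - half, int(by) + half + 1
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError("motion blob does not fit inside the frame")
    patch_y, patch_x = np.mgrid[y0:y1, x0:x1]
    for k in range(n_t):
        px = bx + disp[k] * ax[0]
        py = by + disp[k] * ax[1]
        frames[y0:y1, x0:x1, k] += motion.brightness * np.exp(
            -((patch_x - px) ** 2 + (patch_y - py) ** 2) / (2.0 * motion.sigma_px**2)
        )

    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    np.clip(frames, 0.0, None, out=frames)

    # ground-truth bolus peak: band-mean of the noiseless intensity model
    n_art = mask_art.sum()
    n_ven = mask_ven.sum()
    tic_model = blush + (n_art * env_art + n_ven * env_ven) / max(n_art + n_ven, 1)
    bolus_peak_time = float(t[np.argmax(tic_model)])

    # open contour tracing ventral tail -> dorsal crown -> ventral tail
    psis = np.radians(np.linspace(scene.arc_start_deg, scene.arc_end_deg,
                                  scene.n_contour_vertices))
    contour = np.column_stack([
        cx + scene.ring_inner * rx * np.cos(psis),
        cy - scene.ring_inner * ry * np.sin(psis),
    ])
    roi_half = 3.5 * motion.sigma_px + motion.amplitude_px + 1
    motion_roi = np.array([
        [bx - roi_half, by - roi_half], [bx + roi_half, by - roi_half],
        [bx + roi_half, by + roi_half], [bx - roi_half, by + roi_half],
    ])

    truth = CineGroundTruth(
        cardiac_freq=cardiac_freq,
        arterial_phase_offset=arterial_phase_offset,
        venous_phase_offset=venous_phase_offset,
        ventral_dorsal_gradient=ventral_dorsal_gradient,
        bolus_peak_time=bolus_peak_time,
        compartment_masks={
            "arterial": mask_art, "venous": mask_ven,
            "background": ~(mask_art | mask_ven),
        },
        contour=contour,
        motion_roi=motion_roi,
        pulse_motion=disp,
        motion_axis=ax,
        band_mask=ring,
        sampling_rate=sampling_rate,
        duration=duration,
    )
    return CineSequence(frames, sampling_rate), truth


@dataclass
class PhysioGroundTruth:
    """Injected parameters of synthetic physiology, for recovery tests."""

    cardiac_freq: float
    site_phase_lag: float = 0.0   # dorsal-minus-ventral CSF CF angle (+: ventral leads)
    clock_offset: float = 0.0     # video clock minus pressure clock, seconds
    flick_time: float = 0.0

    def __post_init__(self):
        if not (-np.pi < self.site_phase_lag <= np.pi):
            raise ValueError("site_phase_lag outside (-pi, pi]")


def _ecg_train(t, cardiac_freq: float, phase0: float, width_s: float = 0.025) -> np.ndarray:
    """Impulse-like pulse train with R peaks where cos(w t + phase0) = 1."""
    omega = 2.0 * np.pi * cardiac_freq
    # nearest-peak distance in cardiac phase, converted to time
    dphi = wrap_angle(omega * t + phase0)
    dt = dphi / omega
    return np.exp(-(dt**2) / (2.0 * width_s**2))


def generate_physio(sampling_rate: float = 100.0, duration: float = 20.0,
                    cardiac_freq: float = 1.2, respiratory_freq: float = 0.25,
                    site_phase_lag: float = 0.8, csf_baseline: float = 10.0,
                    csf_cf_amplitude: float = 1.2, resp_amplitude: float = 1.5,
                    noise_sd: float = 0.1, epoch_gap: float = 120.0,
                    seed: int = 0):
    """Two-site CSF pressure epochs with a known CF phase lag, plus ECG/ABP.

    The ventral (Third Ventricle) and dorsal (Lateral Ventricle) records
    are separate epochs on one continuous cardiac clock, ``epoch_gap``
    seconds apart, so cardiac synchronization across epochs is actually
    exercised.  Returns ``(rec_ventral, rec_dorsal, PhysioGroundTruth)``.
    Positive ``site_phase_lag`` is the dorsal-minus-ventral CF angle the
    pipeline should recover (ventral pressure leading).
    """
    nyq = sampling_rate / 2.0
    if not (0 < cardiac_freq < nyq and 0 < respiratory_freq < nyq):
        raise ValueError("cardiac and respiratory frequencies must be below Nyquist")
    if abs(cardiac_freq - respiratory_freq) < 1e-9:
        raise ValueError("cardiac and respiratory frequencies must differ")
    if not (-np.pi < site_phase_lag <= np.pi):
        raise ValueError("site_phase_lag outside (-pi, pi]")

    rng = np.random.default_rng(seed)
    omega = 2.0 * np.pi * cardiac_freq
    phase0 = float(rng.uniform(-np.pi, np.pi))   # cardiac clock phase at t = 0
    delta_csf = -0.9                             # CSF pressure lag behind the R peak
    delta_abp = -0.6

    n = int(round(duration * sampling_rate))
    starts = {"ventral": 10.0, "dorsal": 10.0 + duration + epoch_gap}
    site_offsets = {"ventral": 0.0, "dorsal": site_phase_lag}
    site_names = {"ventral": VENTRAL_SITE, "dorsal": DORSAL_SITE}

    records = {}
    for key in ("ventral", "dorsal"):
        tt = starts[key] + np.arange(n) / sampling_rate
        csf = (
            csf_baseline
            + resp_amplitude * np.sin(2.0 * np.pi * respiratory_freq * tt)
            + csf_cf_amplitude * np.cos(omega * tt + phase0 + delta_csf + site_offsets[key])
            + rng.normal(0.0, noise_sd, size=n)
        )
        abp = (
            80.0
            + 20.0 * np.cos(omega * tt + phase0 + delta_abp)
            + 5.0 * np.cos(2.0 * (omega * tt + phase0 + delta_abp))
            + rng.normal(0.0, noise_sd, size=n)
        )
        ecg = _ecg_train(tt, cardiac_freq, phase0) + rng.normal(0.0, 0.02, size=n)
        records[key] = PhysiologyRecord(
            time=tt, csf_pressure=csf, abp=abp, ecg=ecg, site=site_names[key],
            meta={"epoch_start": starts[key], "seed": seed},
        )
    truth = PhysioGroundTruth(cardiac_freq=cardiac_freq, site_phase_lag=site_phase_lag)
    return records["ventral"], records["dorsal"], truth


def generate_flick_pair(frame_rate: float = 30.0, pressure_rate: float = 100.0,
                        duration: float = 30.0, clock_offset: float = 0.0,
                        flick_time: float | None = None, cardiac_freq: float = 1.2,
                        flick_amplitude: float = 5.0, spike_amplitude: float = 30.0,
                        noise_sd: float = 0.02, seed: int = 0):
    """Motion / pressure trace pair with a synchronization transient.

    The motion trace (video clock) carries a step-plus-decay transient at
    ``flick_time``; the pressure trace (pressure clock) carries a sharp
    spike whose pressure-clock reading is ``flick_time + clock_offset``,
    so :func:`~pulsewave.physio.align_clocks` recovers ``clock_offset``.
    Both traces carry background CF oscillation and noise.  Set
    ``flick_amplitude=0`` to produce a degenerate pair without a transient.
    """
    if flick_time is None:
        flick_time = duration / 2.0
    t_flick_pressure = flick_time + clock_offset
    if not (1.0 < flick_time < duration - 1.0):
        raise ValueError("flick time outside the video recording")
    if not (1.0 < t_flick_pressure < duration - 1.0):
        raise ValueError("clock offset pushes the flick outside the pressure recording")

    rng = np.random.default_rng(seed)
    omega = 2.0 * np.pi * cardiac_freq

    t_m = np.arange(int(round(duration * frame_rate))) / frame_rate
    mo = 0.15 * np.cos(omega * t_m) + rng.normal(0.0, noise_sd, size=t_m.size)
    step = t_m >= flick_time
    mo[step] += flick_amplitude * np.exp(-(t_m[step] - flick_time) / 0.3)

    t_p = np.arange(int(round(duration * pressure_rate))) / pressure_rate
    pr = 10.0 + 1.0 * np.cos(omega * t_p) + rng.normal(0.0, 5 * noise_sd, size=t_p.size)
    stepp = t_p >= t_flick_pressure
    pr[stepp] += spike_amplitude * np.exp(-(t_p[stepp] - t_flick_pressure) / 0.05)

    truth = PhysioGroundTruth(cardiac_freq=cardiac_freq, clock_offset=clock_offset,
                              flick_time=flick_time)
    return (
        Trace(mo, frame_rate, label="video motion"),
        Trace(pr, pressure_rate, label="csf pressure"),
        truth,
    )
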