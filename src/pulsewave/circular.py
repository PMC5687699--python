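"""Circular statistics for cardiac-frequency phase data.

Phase differences at cardiac frequency live on the circle, so means,
spreads and location tests must respect angular topology.  This module
provides the resultant-vector summary (mean direction, circular SD
``sqrt(-2 ln Rbar)``), Watson's large-sample test of a mean direction,
Watson's two-sample U^2 test with a seeded permutation null, rose-plot
histograms, and angular Q-Q quantile matching.

All angles are radians; results are wrapped to ``(-pi, pi]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

__all__ = [
    "wrap_angle",
    "CircularSummary",
    "circ_summary",
    "WatsonOneSampleResult",
    "watson_one_sample",
    "WatsonTwoSampleResult",
    "watson_two_sample",
    "circ_hist",
    "AngularQQ",
    "angular_qq",
]

_R_FLOOR = 1e-12
_P_FLOOR = 1e-16


class UndefinedMeanError(ValueError):
    """Raised when the resultant length is ~0 and the mean direction is undefined."""


def wrap_angle(theta):
    """Wrap angles (radians) to the interval ``(-pi, pi]``."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.remainder(theta + np.pi, 2.0 * np.pi) - np.pi
    # remainder maps pi -> -pi; restore the half-open convention (-pi, pi]
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def _clean(angles) -> np.ndarray:
    a = np.asarray(angles, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty circular sample")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite angles in circular sample")
    return wrap_angle(a)


@dataclass(frozen=True)
class CircularSummary:
    """Resultant-vector summary of a circular sample.

    ``sd = sqrt(-2 ln Rbar)`` is the circular standard deviation; ``Rbar``
    is the mean resultant length in ``[0, 1]``.
    """

    mean: float
    sd: float
    rbar: float
    n: int


def circ_summary(angles, weights=None) -> CircularSummary:
    """Circular mean, SD and mean resultant length of a sample of angles.

    Raises :class:`UndefinedMeanError` when the resultant length is below
    1e-12 (e.g. antipodal samples), where no mean direction exists.
    """
    a = _clean(angles)
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != a.shape or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative, match angles, and not sum to 0")
    z = np.sum(w * np.exp(1j * a)) / w.sum()
    rbar = float(np.abs(z))
    if rbar < _R_FLOOR:
        raise UndefinedMeanError(
            f"mean direction undefined: resultant length {rbar:.3e} < {_R_FLOOR:g}"
        )
    mean = float(wrap_angle(np.angle(z)))
    sd = float(np.sqrt(-2.0 * np.log(min(rbar, 1.0))))
    return CircularSummary(mean=mean, sd=sd, rbar=rbar, n=int(a.size))


@dataclass(frozen=True)
class WatsonOneSampleResult:
    statistic: float        # standard-normal deviate of the mean direction
    p: float                # two-sided, floored at 1e-16
    mu0: float
    summary: CircularSummary


def watson_one_sample(angles, mu0: float = 0.0) -> WatsonOneSampleResult:
    """Watson's large-sample nonparametric test of a specified mean direction.

    Tests H0: the population mean direction equals ``mu0``, using the
    circular dispersion ``delta = (1 - rho2) / (2 Rbar^2)`` (Fisher 1993),
    where ``rho2`` is the mean second-order cosine moment about the sample
    mean.  The deviate ``z = wrap(mean - mu0) / sqrt(delta / n)`` is
    referred to a standard normal, two-sided.

    Requires n >= 25 (large-sample regime); smaller samples raise, with
    the advice to bootstrap instead.
    """
    a = _clean(angles)
    n = a.size
    if n < 25:
        raise ValueError(
            f"n={n} < 25: large-sample test invalid; use a bootstrap test of the "
            "mean direction for small circular samples"
        )
    summ = circ_summary(a)
    rho2 = float(np.mean(np.cos(2.0 * (a - summ.mean))))
    delta = (1.0 - rho2) / (2.0 * summ.rbar**2)
    if delta <= 0:  # perfectly concentrated sample
        delta = np.finfo(float).tiny
    z = wrap_angle(summ.mean - mu0) / np.sqrt(delta / n)
    p = max(2.0 * (1.0 - ndtr(abs(z))), _P_FLOOR)
    return WatsonOneSampleResult(statistic=float(z), p=float(p), mu0=float(mu0), summary=summ)


@dataclass(frozen=True)
class WatsonTwoSampleResult:
    u2: float
    p: float                # permutation p-value (primary)
    p_asymptotic: float
    n_a: int
    n_b: int
    n_perm: int
    tie_warning: bool = field(default=False)


def _u2_from_mask(order_is_a: np.ndarray, n_a: int, n_b: int,
                  group_ends: np.ndarray, group_sizes: np.ndarray) -> np.ndarray:
    """Watson U^2 from boolean membership of the sorted pooled sample.

    ``order_is_a``: (..., N) boolean, True where the k-th smallest pooled
    value belongs to sample a.  The ECDF difference is evaluated once per
    tie group (``group_ends`` indexes the last sorted position of each
    unique value, ``group_sizes`` its multiplicity), so identical samples
    give exactly 0.  Vectorized over leading axes (permutations).
    """
    n = n_a + n_b
    ca = np.cumsum(order_is_a, axis=-1)[..., group_ends]
    cb = np.cumsum(~order_is_a, axis=-1)[..., group_ends]
    d = ca / n_a - cb / n_b
    w = group_sizes
    return (n_a * n_b / n**2) * (
        np.sum(w * d**2, axis=-1) - np.sum(w * d, axis=-1) ** 2 / n
    )


def _u2_asymptotic_p(u2: float, terms: int = 30) -> float:
    m = np.arange(1, terms + 1)
    p = 2.0 * np.sum((-1.0) ** (m - 1) * np.exp(-2.0 * m**2 * np.pi**2 * u2))
    return float(min(max(p, _P_FLOOR), 1.0))


def watson_two_sample(a, b, n_perm: int = 10_000, seed: int | None = 0) -> WatsonTwoSampleResult:
    """Watson's two-sample U^2 test that two circular samples share a distribution.

    The U^2 statistic is computed from the empirical CDF difference over the
    pooled sorted sample (rank-based, origin-invariant).  The p-value is
    obtained by seeded random permutation of the pooled labels (default
    10^4), with the asymptotic series value reported alongside.  A tie
    fraction above 25% of the pooled sample sets ``tie_warning`` (the
    rank-based statistic degrades under heavy ties).
    """
    a = _clean(a)
    b = _clean(b)
    n_a, n_b = a.size, b.size
    if n_a < 8 or n_b < 8:
        raise ValueError(f"need n_a, n_b >= 8 (got {n_a}, {n_b})")
    pooled = np.concatenate([a, b])
    n = n_a + n_b
    order = np.argsort(pooled, kind="stable")
    sorted_vals = pooled[order]
    is_last = np.r_[sorted_vals[1:] != sorted_vals[:-1], True]
    group_ends = np.flatnonzero(is_last)
    group_sizes = np.diff(np.r_[-1, group_ends]).astype(float)
    tie_frac = 1.0 - group_ends.size / n
    is_a_sorted = order < n_a
    u2_obs = float(_u2_from_mask(is_a_sorted, n_a, n_b, group_ends, group_sizes))

    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=bool)
    base = np.arange(n)
    for i in range(n_perm):  # row-wise permutation of labels over sorted positions
        masks[i, rng.permutation(base)[:n_a]] = True
    u2_perm = _u2_from_mask(masks, n_a, n_b, group_ends, group_sizes)
    p_perm = (1.0 + np.count_nonzero(u2_perm >= u2_obs - 1e-15)) / (n_perm + 1.0)
    return WatsonTwoSampleResult(
        u2=u2_obs,
        p=float(p_perm),
        p_asymptotic=_u2_asymptotic_p(u2_obs),
        n_a=n_a,
        n_b=n_b,
        n_perm=n_perm,
        tie_warning=bool(tie_frac > 0.25),
    )


def circ_hist(angles, n_bins: int = 36):
    """Equal-width bin counts partitioning ``(-pi, pi]``.

    Returns ``(counts, edges)`` with ``counts.sum() == n``.  Values exactly
    at ``-pi`` are wrapped to ``pi`` before binning.
    """
    a = _clean(angles)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    # shift pi into the last bin's half-open range
    a = np.where(a == np.pi, np.nextafter(np.pi, -np.pi), a)
    counts, _ = np.histogram(a, bins=edges)
    return counts, edges


def plot_circ_hist(angles, n_bins: int = 36, ax=None, **bar_kw):
    """Rose plot of a circular sample; returns the polar axes."""
    import matplotlib.pyplot as plt

    counts, edges = circ_hist(angles, n_bins)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = (edges[:-1] + edges[1:]) / 2
    ax.bar(centers, counts, width=np.diff(edges), bottom=0.0, **bar_kw)
    return ax


@dataclass(frozen=True)
class AngularQQ:
    quantiles_a: np.ndarray
    quantiles_b: np.ndarray
    max_abs_deviation: float
    mean_a: float
    mean_b: float
    centering: str = "own circular mean"


def angular_qq(a, b) -> AngularQQ:
    """Quantile-match two circular samples after centering each on its mean.

    Each sample is rotated so its circular mean sits at 0, wrapped to
    ``(-pi, pi]`` and sorted; quantiles at ``k/(m+1)``, ``k = 1..m`` with
    ``m = min(n_a, n_b)``, are obtained by linear interpolation of the
    empirical quantile function (plotting positions ``i/(n+1)``).  Two
    samples differing only by rotation fall exactly on the identity line.
    """
    a = _clean(a)
    b = _clean(b)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 angles per sample")
    mean_a = circ_summary(a).mean
    mean_b = circ_summary(b).mean
    ca = np.sort(wrap_angle(a - mean_a))
    cb = np.sort(wrap_angle(b - mean_b))
    m = min(a.size, b.size)
    probs = np.arange(1, m + 1) / (m + 1.0)
    qa = np.interp(probs, np.arange(1, a.size + 1) / (a.size + 1.0), ca)
    qb = np.interp(probs, np.arange(1, b.size + 1) / (b.size + 1.0), cb)
    return AngularQQ(
        quantiles_a=qa,
        quantiles_b=qb,
        max_abs_deviation=float(np.max(np.abs(qa - qb))),
        mean_a=mean_a,
        mean_b=mean_b,
    )


def plot_angular_qq(qq: AngularQQ, ax=None):
    """Q-Q scatter with the identity line; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(qq.quantiles_a, qq.quantiles_b, "o", ms=3)
    lim = max(np.max(np.abs(qq.quantiles_a)), np.max(np.abs(qq.quantiles_b)), 0.1)
    ax.plot([-lim, lim], [-lim, lim], "k--", lw=0.8)
    ax.set_xlabel("sample A quantiles (rad, centered)")
    ax.set_ylabel("sample B quantiles (rad, centered)")
    ax.set_aspect("equal")
    return ax
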