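"""Trajectory analysis: intervals, switch times, bias, Hill fits, spectra.

Because the simulation records the fundamental protomer states, locked states
are identified exactly — no filtering or thresholding is needed.  A *locked
state interval* runs from the sample at which the ring first reaches a fully
locked level (0 or N active protomers) to the sample at which it first
reaches the opposite level; consecutive intervals therefore tile the record
exactly.  The *switch time* of a transition is the span between the last
sample at the departing locked level and the first sample at the opposite
level.  Both resolutions are limited only by the sampling interval.

The Hill coefficient of the concentration response is estimated, as in
standard practice for ultrasensitive switches, as the slope of
``log[Y / (1 - Y)]`` against ``log(c / c_0.5)``, with the CW bias ``Y``
restricted to the most sensitive part of the response (default
``0.15 <= Y <= 0.85``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, signal, stats

from .kmc_engine import SimConfig, Trajectory, simulate
from .ring_model import ModelParams

__all__ = [
    "IntervalSet",
    "HillCurve",
    "SpectrumFit",
    "ExponentialFit",
    "GammaFit",
    "extract_intervals",
    "cw_bias",
    "hill_fit",
    "fit_exponential",
    "fit_gamma",
    "domain_occupancy",
    "power_spectrum",
    "sensitivity_curve",
    "default_c_grid",
]

CCW = "CCW"
CW = "CW"


@dataclass
class IntervalSet:
    """Locked-state intervals and switch times extracted from one trajectory.

    ``locked_intervals`` holds (duration_s, side) with side the locked state
    being occupied (CW = fully active); sides alternate along the record.
    ``switch_times`` holds (duration_s, direction) with direction e.g.
    ``"CCW->CW"``.  ``complete`` is False when fewer than two locked-state
    entries were found.
    """

    locked_intervals: List[Tuple[float, str]] = field(default_factory=list)
    switch_times: List[Tuple[float, str]] = field(default_factory=list)
    complete: bool = True

    @property
    def n_switches(self) -> int:
        return len(self.switch_times)

    def durations(self, side: Optional[str] = None) -> np.ndarray:
        """Locked-interval durations, optionally restricted to one side."""
        return np.array(
            [d for d, s in self.locked_intervals if side is None or s == side]
        )

    def switch_durations(self, direction: Optional[str] = None) -> np.ndarray:
        return np.array(
            [d for d, s in self.switch_times if direction is None or s == direction]
        )

    @property
    def mean_locked(self) -> float:
        return float(self.durations().mean()) if self.locked_intervals else math.nan

    @property
    def mean_switch(self) -> float:
        return float(self.switch_durations().mean()) if self.switch_times else math.nan


@dataclass
class HillCurve:
    """Concentration-response points and the fitted Hill slope."""

    points: List[Tuple[float, float]]  #: (c_rel, CW bias)
    h: float  #: fitted Hill coefficient
    intercept: float
    fit_window: Tuple[float, float] = (0.15, 0.85)
    n_used: int = 0  #: points inside the fit window


@dataclass
class SpectrumFit:
    """Segment-averaged power spectrum with a Lorentzian fit.

    ``s0`` is the zero-frequency plateau, ``fc`` the corner frequency of
    ``S(f) = s0 / (1 + (f / fc)^2)``.  ``has_interior_peak`` flags a smoothed
    interior bin that exceeds both neighbours and the fitted curve by more
    than three local spectral standard errors — the signature of a
    non-Lorentzian (multi-step) process.
    """

    frequencies: np.ndarray
    power: np.ndarray
    s0: float
    fc: float
    has_interior_peak: bool
    n_segments: int = 0


def extract_intervals(traj: Trajectory) -> IntervalSet:
    """Locked-state intervals and switch times from a sampled trajectory.

    Full-lock levels are ``n_active == 0`` and ``n_active == N``.  An *entry*
    into a side is the first sample at its level after the most recent entry
    into the opposite side.  Incomplete leading/trailing segments are
    discarded.  Returns an empty set with ``complete=False`` when fewer than
    two alternating entries exist.
    """
    na = np.asarray(traj.n_active)
    n = traj.n_protomers
    dt = traj.dt_sample
    level = np.where(na == n, 1, np.where(na == 0, -1, 0)).astype(np.int8)
    nz = np.flatnonzero(level)
    out = IntervalSet()
    if nz.size == 0:
        out.complete = False
        return out
    s = level[nz]
    change_pos = np.flatnonzero(np.diff(s) != 0) + 1  # positions in nz
    if change_pos.size == 0:
        out.complete = False
        return out
    entry_pos = np.concatenate(([0], change_pos))
    entry_idx = nz[entry_pos]
    entry_side = s[entry_pos]
    for j in range(entry_pos.size - 1):
        dur = (entry_idx[j + 1] - entry_idx[j]) * dt
        out.locked_intervals.append((dur, CW if entry_side[j] == 1 else CCW))
    for p in change_pos:
        # nz[p-1] is the last sample at the departing side's level
        dur = (nz[p] - nz[p - 1]) * dt
        direction = f"{CCW}->{CW}" if s[p] == 1 else f"{CW}->{CCW}"
        out.switch_times.append((dur, direction))
    return out


def cw_bias(traj: Trajectory) -> float:
    """Fraction of samples with a majority-active ring.

    Samples exactly at N/2 (even N) count one half, which is unbiased under
    the model's symmetry.
    """
    na = np.asarray(traj.n_active, dtype=float)
    if na.size == 0:
        raise ValueError("empty trajectory")
    half = traj.n_protomers / 2.0
    return float(np.mean(na > half) + 0.5 * np.mean(na == half))


def hill_fit(
    points: Sequence[Tuple[float, float]],
    fit_window: Tuple[float, float] = (0.15, 0.85),
    c_ref: float = 1.0,
) -> HillCurve:
    """Hill coefficient from (c_rel, bias) points by the logit-log slope.

    Ordinary least squares of ``logit(Y)`` on ``ln(c / c_ref)``, restricted
    to points with ``Y`` inside ``fit_window`` (saturated points carry no
    slope information and points at exactly 0 or 1 are undefined on the logit
    scale).
    """
    lo, hi = fit_window
    pts = [(c, y) for c, y in points if lo <= y <= hi and 0.0 < y < 1.0]
    if len(pts) < 3:
        raise ValueError(
            f"need >= 3 points with bias in [{lo}, {hi}] for a Hill fit, got {len(pts)}"
        )
    x = np.log([c / c_ref for c, _ in pts])
    z = np.array([math.log(y / (1.0 - y)) for _, y in pts])
    if np.ptp(x) <= 0:
        raise ValueError("degenerate concentration spread")
    res = stats.linregress(x, z)
    return HillCurve(
        points=list(points),
        h=float(res.slope),
        intercept=float(res.intercept),
        fit_window=fit_window,
        n_used=len(pts),
    )


@dataclass
class ExponentialFit:
    mean: float  #: maximum-likelihood mean (sample mean), s
    rate: float  #: 1 / mean, 1/s
    ks_pvalue: float  #: KS test against Exp(mean)
    hist_rate: float  #: secondary estimate: -slope of log-linear histogram


@dataclass
class GammaFit:
    shape: float
    scale: float  #: s
    mean: float  #: shape * scale, s
    sd: float  #: scale * sqrt(shape), s


def fit_exponential(durations: Sequence[float], min_n: int = 30) -> ExponentialFit:
    """Exponential fit of dwell-time durations.

    The ML estimate of the mean is the sample mean.  The KS p-value measures
    goodness of fit against the exponential with that mean.  A secondary
    estimate fits a line to the log-linear histogram (the graphical method of
    dwell-time analysis); its negated slope estimates the rate.
    """
    d = np.asarray(durations, dtype=float)
    if d.size < min_n:
        raise ValueError(f"need at least {min_n} durations, got {d.size}")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    mean = float(d.mean())
    ks = stats.kstest(d, "expon", args=(0.0, mean))
    counts, edges = np.histogram(d, bins=max(10, min(40, d.size // 20)))
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    with warnings.catch_warnings():
        # degenerate histograms (e.g. all mass in one bin) are fine here;
        # the ML estimate above is the primary result
        warnings.simplefilter("ignore")
        slope = np.polyfit(centers[keep], np.log(counts[keep]), 1)[0]
    return ExponentialFit(
        mean=mean, rate=1.0 / mean, ks_pvalue=float(ks.pvalue), hist_rate=float(-slope)
    )


def fit_gamma(durations: Sequence[float], min_n: int = 30) -> GammaFit:
    """Maximum-likelihood gamma fit of switch-time durations."""
    d = np.asarray(durations, dtype=float)
    if d.size < min_n:
        raise ValueError(f"need at least {min_n} durations, got {d.size}")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    shape, _, scale = stats.gamma.fit(d, floc=0.0)
    return GammaFit(
        shape=float(shape),
        scale=float(scale),
        mean=float(shape * scale),
        sd=float(scale * math.sqrt(shape)),
    )


def domain_occupancy(traj: Trajectory, opposite_state_convention: bool = False) -> Dict[int, float]:
    """Empirical distribution of the per-sample domain count.

    Default convention counts all maximal circular runs of equal conformation
    (coherent ring = 1 domain; otherwise an even count), which yields the
    categories {1, 2, 4, ...}.  With ``opposite_state_convention`` a coherent
    ring has 0 domains and a mixed ring counts only domains of the minority
    state (half the run count).
    """
    nd = np.asarray(traj.n_domains)
    if opposite_state_convention:
        nd = np.where(nd == 1, 0, nd // 2)
    counts = np.bincount(nd)
    total = nd.size
    return {int(k): counts[k] / total for k in np.flatnonzero(counts)}


def _lorentzian_log10(f: np.ndarray, log_s0: float, log_fc: float) -> np.ndarray:
    return log_s0 - np.log10(1.0 + (f / 10.0**log_fc) ** 2)


def power_spectrum(traj: Trajectory, n_segments: int = 8, n_log_bins: int = 30) -> SpectrumFit:
    """Segment-averaged power spectrum of the mean-removed activity trace.

    Bartlett averaging of ``n_segments`` non-overlapping Hann-windowed
    segments, then averaging into logarithmically spaced frequency bins (so
    the dense high-frequency tail does not dominate), and a least-squares
    Lorentzian fit of the binned spectrum in log-log space.

    Interior-peak detection runs on the log-binned spectrum.  The standard
    error of bin ``i`` is ``sqrt(2) * S_i / sqrt(m_i * n_segments)`` with
    ``m_i`` raw bins averaged (the sqrt(2) allows for the correlation of
    adjacent Hann-windowed periodogram bins); a peak is an interior bin
    exceeding both neighbours by two standard errors and the fitted
    Lorentzian by five.  A Lorentzian (single-nucleation-step) spectrum is
    monotone and never triggers this, while the order-unity spectral bump of
    a multi-step process does.
    """
    x = np.asarray(traj.n_active, dtype=float)
    nperseg = x.size // n_segments
    if nperseg < 16:
        raise ValueError("trajectory too short for the requested segmentation")
    x = x - x.mean()
    fs = 1.0 / traj.dt_sample
    freqs, power = signal.welch(x, fs=fs, nperseg=nperseg, noverlap=0)
    freqs, power = freqs[1:], power[1:]  # drop the f = 0 bin

    if np.all(power <= 0):
        return SpectrumFit(freqs, power, 0.0, math.nan, False, n_segments)

    edges = np.geomspace(freqs[0] * 0.999, freqs[-1], n_log_bins + 1)
    which = np.digitize(freqs, edges) - 1
    fb, pb, mb = [], [], []
    for b in range(n_log_bins):
        sel = which == b
        m = int(np.count_nonzero(sel))
        if m == 0:
            continue
        fb.append(float(np.exp(np.mean(np.log(freqs[sel])))))
        pb.append(float(power[sel].mean()))
        mb.append(m)
    fb = np.array(fb)
    pb = np.array(pb)
    mb = np.array(mb)

    s0_guess = float(pb[0])
    below = np.flatnonzero(pb < s0_guess / 2)
    fc_guess = float(fb[below[0]]) if below.size else float(fb[fb.size // 2])
    try:
        popt, _ = optimize.curve_fit(
            _lorentzian_log10,
            fb,
            np.log10(np.maximum(pb, 1e-300)),
            p0=[math.log10(max(s0_guess, 1e-300)), math.log10(fc_guess)],
            maxfev=10000,
        )
        s0, fc = 10.0 ** popt[0], 10.0 ** popt[1]
    except RuntimeError:  # pragma: no cover - fit failure fallback
        s0, fc = s0_guess, fc_guess

    fit_b = s0 / (1.0 + (fb / fc) ** 2)
    se = math.sqrt(2.0) * fit_b / np.sqrt(mb * n_segments)
    peak = False
    for i in range(1, fb.size - 1):
        if mb[i] * n_segments < 50:
            # too few periodogram samples for a stable bin average
            continue
        if (
            pb[i] > pb[i - 1] + 2.0 * se[i]
            and pb[i] > pb[i + 1] + 2.0 * se[i]
            and pb[i] - fit_b[i] > 5.0 * se[i]
        ):
            peak = True
            break
    return SpectrumFit(freqs, power, float(s0), float(fc), peak, n_segments)


def default_c_grid(
    h_expected: float, n_points: int = 9, logit_span: float = 1.7
) -> np.ndarray:
    """Log-spaced relative concentrations covering the sensitive response region.

    The response crosses bias ``logistic(+-logit_span)`` (0.15..0.85 for the
    default span) over a log-concentration half-width of
    ``logit_span / h``, so the grid half-width adapts to the expected
    steepness; it is clipped to [0.05, 1.0] in log units.
    """
    hw = min(1.0, max(0.05, logit_span / max(h_expected, 1e-6)))
    return np.exp(np.linspace(-hw, hw, n_points))


def sensitivity_curve(
    params: ModelParams,
    c_grid: Sequence[float],
    duration: float,
    seed: int,
    dt_sample: float = 1.0e-4,
    fit_window: Tuple[float, float] = (0.15, 0.85),
    c_ref: float = 1.0,
) -> HillCurve:
    """Simulate the ring across concentrations and fit the Hill slope.

    ``c_grid`` holds absolute relative concentrations (for asymmetric
    energies, centre it on the solved neutral-bias concentration and pass
    that as ``c_ref``).  Each concentration gets an independent seeded run.
    """
    points = []
    for i, c in enumerate(c_grid):
        run_seed = (seed + 7919 * i) % (2**31)
        traj = simulate(
            params.replace(c_rel=float(c)),
            SimConfig(duration=duration, dt_sample=dt_sample, seed=run_seed),
        )
        points.append((float(c), cw_bias(traj)))
    return hill_fit(points, fit_window=fit_window, c_ref=c_ref)
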