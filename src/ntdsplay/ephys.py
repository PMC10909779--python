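"""Desensitization kinetics from patch-clamp current traces.

Entry into desensitization is quantified by fitting the current decay
after the peak with a first- or second-order exponential,
y = sum_i A_i exp(-t/tau_i); second-order fits are summarized by the
amplitude-weighted time constant sum(A_i tau_i)/sum(A_i). Recovery from
desensitization comes from a two-pulse protocol: the test-pulse peak as
a fraction of the initial-pulse peak, fitted with a first-order
exponential time course over the interpulse interval. The peak ratio
between low-pH and reference applications quantifies proton block of
the peak response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import medfilt

__all__ = [
    "CurrentTrace",
    "DecayFit",
    "RecoverySeries",
    "detect_peak",
    "fit_decay",
    "recovery_ratios",
    "fit_recovery",
    "peak_ratio_ph",
]


@dataclass
class CurrentTrace:
    """Uniformly sampled current recording (t in ms, i in pA)."""

    t: np.ndarray
    i: np.ndarray
    stimulus_onset: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.t.shape != self.i.shape or self.t.ndim != 1:
            raise ValueError("t and i must be 1-D arrays of equal length")
        dt = np.diff(self.t)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("trace must be uniformly sampled")
        if not np.all(np.isfinite(self.i)):
            raise ValueError("trace contains non-finite samples")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else 0.0


@dataclass
class DecayFit:
    """Exponential decay fit of desensitization entry."""

    order: int
    amplitudes: np.ndarray  # pA, pre-normalization scale
    taus: np.ndarray  # ms, ascending for order 2
    tau_weighted: float  # ms, sum(A*tau)/sum(A)
    baseline: float  # pA, fixed to the pre-stimulus mean
    rss: float
    aic: float = np.nan


@dataclass
class RecoverySeries:
    """Two-pulse recovery: test/initial peak ratio per interpulse interval."""

    interpulse_intervals: np.ndarray  # ms, ascending
    peak_ratios: np.ndarray  # fraction of the initial peak
    tau_recov: float | None = None  # ms, set by fit_recovery

    def __post_init__(self) -> None:
        self.interpulse_intervals = np.asarray(self.interpulse_intervals, dtype=float)
        self.peak_ratios = np.asarray(self.peak_ratios, dtype=float)
        if self.interpulse_intervals.shape != self.peak_ratios.shape:
            raise ValueError("intervals and ratios must have equal length")
        if np.any(np.diff(self.interpulse_intervals) <= 0):
            raise ValueError("intervals must be ascending")


def _baseline(trace: CurrentTrace) -> float:
    pre = trace.t < trace.stimulus_onset
    return float(trace.i[pre].mean()) if pre.any() else 0.0


def detect_peak(trace: CurrentTrace, window_after_onset: float):
    """Locate the current extremum within a window after stimulus onset.

    The trace is smoothed with a 3-point median filter before taking
    the extremum (largest excursion from the pre-stimulus baseline), so
    a single noise spike cannot masquerade as the peak. Returns
    ``(t_peak, i_peak)`` with the signed peak current.
    """
    t0 = trace.stimulus_onset
    if t0 < trace.t[0] or t0 > trace.t[-1]:
        raise ValueError("stimulus onset lies outside the trace")
    hi = t0 + window_after_onset
    mask = (trace.t >= t0) & (trace.t <= hi)
    if not mask.any():
        raise ValueError("search window lies outside the trace")
    base = _baseline(trace)
    smooth = medfilt(trace.i, kernel_size=3) if trace.i.size >= 3 else trace.i
    seg = smooth[mask]
    k = int(np.argmax(np.abs(seg - base)))
    idx = np.flatnonzero(mask)[k]
    return float(trace.t[idx]), float(trace.i[idx])


def _multi_exp(t, *params):
    # params = (A1, tau1, A2, tau2, ...)
    y = np.zeros_like(t)
    for j in range(0, len(params), 2):
        y = y + params[j] * np.exp(-t / params[j + 1])
    return y


def _fit_order(t, y, order, tau0):
    """NLS fit of sum of `order` exponentials to (t, y), y normalized."""
    p0 = []
    lo, hi = [], []
    for j in range(order):
        p0 += [1.0 / order, tau0 * (3.0**j)]
        lo += [-np.inf, 1e-3]
        hi += [np.inf, 1e4]
    popt, _ = curve_fit(
        _multi_exp, t, y, p0=p0, bounds=(lo, hi), maxfev=20000
    )
    resid = y - _multi_exp(t, *popt)
    rss = float(resid @ resid)
    n = t.size
    k = 2 * order
    aic = n * np.log(max(rss / n, 1e-300)) + 2 * k
    return popt, rss, aic


def fit_decay(
    trace: CurrentTrace,
    order: int | None = None,
    peak_window: float = 20.0,
    stimulus_end: float | None = None,
) -> DecayFit:
    """Fit the post-peak current decay with 1 or 2 exponentials.

    The decay segment runs from the detected peak to ``stimulus_end``
    (trace end by default); the baseline is fixed to the pre-stimulus
    mean, and the segment is normalized to peak = 1 before fitting
    (amplitudes are reported back on the original scale). When ``order``
    is None, first vs second order is chosen by AIC. The weighted time
    constant is the amplitude-weighted mean sum(A_i tau_i)/sum(A_i).
    """
    t_peak, i_peak = detect_peak(trace, peak_window)
    base = _baseline(trace)
    t_end = trace.t[-1] if stimulus_end is None else stimulus_end
    mask = (trace.t >= t_peak) & (trace.t <= t_end)
    t = trace.t[mask] - t_peak
    y = trace.i[mask] - base
    if t.size < 10:
        raise ValueError("decay segment holds fewer than 10 samples")
    peak_amp = i_peak - base
    if peak_amp == 0:
        raise ValueError("zero peak amplitude")
    y = y / peak_amp  # normalized, decays from ~1

    # log-linear initial guess for the dominant time constant
    pos = y > 0.05
    if pos.sum() >= 2:
        slope, _ = np.polyfit(t[pos], np.log(y[pos]), 1)
        tau0 = float(np.clip(-1.0 / slope if slope < 0 else t[-1] / 3.0, 1e-2, 1e4))
    else:
        tau0 = max(t[-1] / 5.0, 1e-2)

    fits = {}
    orders = [order] if order in (1, 2) else [1, 2]
    for m in orders:
        try:
            fits[m] = _fit_order(t, y, m, tau0)
        except RuntimeError:
            continue
    if not fits:
        raise RuntimeError("exponential decay fit did not converge")
    # AIC selection with a strong-evidence margin: the biexponential must
    # beat the monoexponential by >10 AIC units, else the extra component
    # is fitting noise (exponential components are heavily nested)
    m = min(fits)
    if len(fits) == 2 and fits[2][2] < fits[1][2] - 10.0:
        m = 2
    popt, rss, aic = fits[m]
    A = popt[0::2] * peak_amp  # back to original scale
    tau = popt[1::2]
    idx = np.argsort(tau)
    A, tau = A[idx], tau[idx]
    if np.any(np.isclose(tau, 1e-3, rtol=1e-3)) or np.any(
        np.isclose(tau, 1e4, rtol=1e-3)
    ):
        warnings.warn("fitted time constant at its bound (1e-3 or 1e4 ms)")
    tau_w = float(np.sum(A * tau) / np.sum(A))
    return DecayFit(
        order=m,
        amplitudes=A,
        taus=tau,
        tau_weighted=tau_w,
        baseline=base,
        rss=rss * peak_amp**2,
        aic=aic,
    )


def recovery_ratios(intervals, initial_traces, test_traces, peak_window: float = 20.0):
    """Peak-ratio series from paired two-pulse traces.

    For each interpulse interval, the test-pulse peak amplitude is
    expressed as a fraction of the initial-pulse peak amplitude (both
    measured from their own baselines). The series is returned sorted
    by interval.
    """
    intervals = np.asarray(intervals, dtype=float)
    if not (len(intervals) == len(initial_traces) == len(test_traces)):
        raise ValueError("need one trace pair per interval")
    ratios = []
    for init, test in zip(initial_traces, test_traces):
        _, p1 = detect_peak(init, peak_window)
        _, p2 = detect_peak(test, peak_window)
        a1 = p1 - _baseline(init)
        if a1 == 0:
            raise ValueError("zero initial-pulse peak amplitude")
        ratios.append((p2 - _baseline(test)) / a1)
    order = np.argsort(intervals)
    return RecoverySeries(intervals[order], np.asarray(ratios)[order])


def fit_recovery(series: RecoverySeries, r0_free: bool = True) -> float:
    """Fit r(dt) = 1 - (1 - r0) exp(-dt/tau) and return tau (ms).

    ``r0`` is the zero-interval ratio (default free, bounded below by
    0); fix it to 0 with ``r0_free=False``. The fitted tau is also
    stored on the series.
    """
    if series.interpulse_intervals.size < 4:
        raise ValueError("need at least 4 interpulse intervals")
    if np.all(np.abs(series.peak_ratios - 1.0) < 0.02):
        warnings.warn("all ratios ~ 1: no measurable desensitization to recover from")
    dt = series.interpulse_intervals
    r = series.peak_ratios
    tau0 = dt[np.argmin(np.abs(r - (1 - np.exp(-1.0))))] if r.size else dt.mean()
    tau0 = float(np.clip(tau0, dt[0] / 10, dt[-1] * 10))
    if r0_free:
        fun = lambda x, tau, r0: 1.0 - (1.0 - r0) * np.exp(-x / tau)
        popt, _ = curve_fit(
            fun, dt, r, p0=[tau0, 0.0], bounds=([1e-6, 0.0], [np.inf, 1.0]),
            maxfev=20000,
        )
    else:
        fun = lambda x, tau: 1.0 - np.exp(-x / tau)
        popt, _ = curve_fit(fun, dt, r, p0=[tau0], bounds=(1e-6, np.inf), maxfev=20000)
    series.tau_recov = float(popt[0])
    return series.tau_recov


def peak_ratio_ph(
    trace_low_ph: CurrentTrace, trace_ref: CurrentTrace, peak_window: float = 20.0
) -> float:
    """|peak at low pH| / |peak at reference pH| (fraction)."""
    _, p_low = detect_peak(trace_low_ph, peak_window)
    _, p_ref = detect_peak(trace_ref, peak_window)
    a_low = p_low - _baseline(trace_low_ph)
    a_ref = p_ref - _baseline(trace_ref)
    if a_ref == 0:
        raise ValueError("zero reference peak amplitude")
    return float(abs(a_low) / abs(a_ref))
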