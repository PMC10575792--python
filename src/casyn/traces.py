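"""Calcium-indicator fluorescence traces: normalization, bursts, metrics.

A recording samples a cell's indicator fluorescence at 1 Hz: a spontaneous
period with activity bursts, two field-stimulation windows (3 s and 30 s at
20 Hz), and a terminal ionomycin treatment whose plateau defines the
maximal fluorescence F_max.  Traces are normalized as a percentage between
the initial intensity F0 and F_max; burst/peak statistics are computed on
the spontaneous (non-stimulus) part of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = ["Trace", "Burst", "TraceMetrics", "normalize_trace",
           "detect_bursts", "compute_metrics", "analyze_trace"]


@dataclass
class Trace:
    """Raw fluorescence series with its normalization anchors.

    ``f0_window``/``fmax_window`` are (start, end) times in seconds whose
    sample means define F0 and F_max; ``stim_windows`` lists stimulation
    intervals excluded from spontaneous burst analysis.
    """

    t: np.ndarray
    F: np.ndarray
    f0_window: tuple[float, float] = (0.0, 5.0)
    fmax_window: tuple[float, float] | None = None
    stim_windows: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.shape != self.F.shape or self.t.ndim != 1:
            raise ValueError("t and F must be matching 1-D arrays")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time vector must be strictly increasing")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("fluorescence series must be finite")
        if self.fmax_window is None:
            # default: terminal 15 s (post-ionomycin imaging period)
            self.fmax_window = (float(self.t[-1]) - 15.0, float(self.t[-1]))
        for a, b in [self.f0_window, self.fmax_window, *self.stim_windows]:
            if not (self.t[0] <= a < b <= self.t[-1] + 1e-9):
                raise ValueError(f"window ({a}, {b}) outside trace range")

    def _window_mean(self, window: tuple[float, float]) -> float:
        sel = (self.t >= window[0]) & (self.t <= window[1])
        return float(self.F[sel].mean())

    @property
    def F0(self) -> float:
        return self._window_mean(self.f0_window)

    @property
    def Fmax(self) -> float:
        return self._window_mean(self.fmax_window)


@dataclass(frozen=True)
class Burst:
    start: float       # seconds
    end: float         # seconds (inclusive of the last supra-threshold sample)
    n_samples: int
    peak_indices: tuple[int, ...]   # indices into the trace arrays

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class TraceMetrics:
    """Summary parameters of one cell's recording.

    Units follow the conventions of the assay: peak amplitudes in %F_max,
    total (per-burst summed) intensity in F/F0 - 1 units, burst length in
    seconds, burst/peak intervals as events per second of spontaneous
    recording.  Burst-dependent fields are ``None`` when no burst was
    detected (absent, not zero).
    """

    peak_intensity: float | None
    total_intensity: float | None
    burst_length: float | None
    burst_interval: float
    peak_interval: float
    fmax_over_f0: float
    stim_peaks: tuple[float, ...]
    n_bursts: int
    n_peaks: int
    spontaneous_duration: float


def normalize_trace(trace: Trace) -> np.ndarray:
    """Percent-of-range series p(t) = 100*(F - F0)/(Fmax - F0)."""
    f0, fmax = trace.F0, trace.Fmax
    if not fmax > f0:
        raise ValueError("Fmax must exceed F0 (ionomycin plateau below baseline?)")
    return 100.0 * (trace.F - f0) / (fmax - f0)


def _spontaneous_mask(trace: Trace) -> np.ndarray:
    """Samples outside stimulation windows and the Fmax plateau window."""
    mask = np.ones_like(trace.t, dtype=bool)
    for a, b in [*trace.stim_windows, trace.fmax_window]:
        mask &= ~((trace.t >= a) & (trace.t <= b))
    return mask


def detect_bursts(
    trace: Trace,
    p: np.ndarray | None = None,
    theta_burst: float = 5.0,
    theta_prom: float = 10.0,
) -> list[Burst]:
    """Spontaneous activity bursts in a normalized trace.

    A burst is a maximal contiguous run of spontaneous samples with
    p(t) > ``theta_burst`` (%F_max) that contains at least one local
    maximum of prominence >= ``theta_prom``; those maxima are the burst's
    peaks.  Deterministic given the thresholds.  Stimulus windows and the
    ionomycin plateau are excluded.
    """
    if p is None:
        p = normalize_trace(trace)
    p = np.asarray(p, dtype=float)
    spont = _spontaneous_mask(trace)
    peak_idx, _ = find_peaks(p, prominence=theta_prom, plateau_size=(1, None))
    peak_set = set(int(i) for i in peak_idx if spont[i])

    bursts: list[Burst] = []
    above = (p > theta_burst) & spont
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for a, b in zip(edges[::2], edges[1::2]):   # [a, b) runs of True
        peaks = tuple(sorted(i for i in peak_set if a <= i < b))
        if not peaks:
            continue
        bursts.append(Burst(
            start=float(trace.t[a]), end=float(trace.t[b - 1]),
            n_samples=int(b - a), peak_indices=peaks))
    return bursts


def compute_metrics(trace: Trace, bursts: list[Burst] | None = None,
                    p: np.ndarray | None = None) -> TraceMetrics:
    """Summary metrics from a trace and its detected bursts.

    * peak_intensity — mean peak amplitude, %F_max;
    * total_intensity — mean over bursts of the summed peak amplitudes of
      that burst, in F/F0 - 1 units;
    * burst_length — mean burst width in seconds (n_samples * sampling dt);
    * burst_interval / peak_interval — event counts divided by the
      spontaneous recording duration (stimulus and plateau windows
      excluded);
    * stim_peaks — max %F_max within each stimulation window.
    """
    if p is None:
        p = normalize_trace(trace)
    if bursts is None:
        bursts = detect_bursts(trace, p)
    dt = float(np.median(np.diff(trace.t)))
    spont = _spontaneous_mask(trace)
    duration = float(spont.sum()) * dt
    if duration <= 0:
        raise ValueError("no spontaneous samples to analyze")
    f0 = trace.F0
    n_peaks = sum(len(b.peak_indices) for b in bursts)

    if bursts:
        all_peaks = [i for b in bursts for i in b.peak_indices]
        peak_intensity = float(np.mean(p[all_peaks]))
        total_intensity = float(np.mean(
            [sum(trace.F[i] / f0 - 1.0 for i in b.peak_indices)
             for b in bursts]))
        burst_length = float(np.mean([b.n_samples * dt for b in bursts]))
    else:
        peak_intensity = total_intensity = burst_length = None

    stim_peaks = []
    for a, b in trace.stim_windows:
        sel = (trace.t >= a) & (trace.t <= b)
        stim_peaks.append(float(p[sel].max()) if sel.any() else float("nan"))

    return TraceMetrics(
        peak_intensity=peak_intensity,
        total_intensity=total_intensity,
        burst_length=burst_length,
        burst_interval=len(bursts) / duration,
        peak_interval=n_peaks / duration,
        fmax_over_f0=trace.Fmax / trace.F0,
        stim_peaks=tuple(stim_peaks),
        n_bursts=len(bursts),
        n_peaks=n_peaks,
        spontaneous_duration=duration,
    )


def analyze_trace(trace: Trace, theta_burst: float = 5.0,
                  theta_prom: float = 10.0) -> TraceMetrics:
    """Normalization + burst detection + metrics in one call."""
    p = normalize_trace(trace)
    bursts = detect_bursts(trace, p, theta_burst, theta_prom)
    return compute_metrics(trace, bursts, p)
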