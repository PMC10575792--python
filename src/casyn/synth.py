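"""Synthetic data generators with recorded ground truth.

Every pipeline input has a generator here: 3-layer Poisson ion-count stacks
with planted integer inter-layer shifts, ROI tables with planted linear
channel relationships (negative slopes allowed) and a two-population
calcium-binding mixture, isotope-turnover group tables bounded by the
labeled-source enrichment ceiling, indicator traces with planted bursts and
stimulus windows, and Poisson spike trains.  All generators are pure
functions of their arguments and a seed, and return the planted truth
alongside the data so tests can assert recovery.

Noise models: Poisson for ion counts (secondary-ion counting statistics),
Gaussian for fluorescence.  Default image size is 64x64 rather than the
instrument's 256x256 so suites run in seconds; pass ``shape`` for
full-size stacks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ionimage import (IonImage, enrichment_ceiling_permil,
                       natural_abundance_permil, shift_int)
from .model import DriveSpec
from .traces import Trace

__all__ = ["gen_ion_stack", "gen_roi_dataset", "gen_traces", "gen_trace",
           "gen_spike_train", "gen_turnover"]


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  background: float, n_sources: int,
                  amplitude: float, sigma_px: float) -> np.ndarray:
    """Flat background plus a few Gaussian sources, as a mean-count field."""
    h, w = shape
    ii, jj = np.mgrid[0:h, 0:w]
    field_ = np.full(shape, float(background))
    margin = int(3 * sigma_px) + 1
    for _ in range(n_sources):
        r0 = rng.integers(margin, h - margin)
        c0 = rng.integers(margin, w - margin)
        field_ += amplitude * np.exp(-((ii - r0) ** 2 + (jj - c0) ** 2)
                                     / (2.0 * sigma_px ** 2))
    return field_


def gen_ion_stack(
    seed: int,
    shape: tuple[int, int] = (64, 64),
    n_layers: int = 3,
    planted_shifts: Sequence[tuple[int, int]] | None = None,
    max_shift: int = 3,
    background: float = 20.0,
    n_sources: int = 4,
    amplitude: float = 150.0,
    sigma_px: float = 3.0,
    enrichment_permil: float = 10.0,
    raster_um: float = 40.0,
) -> tuple[dict[str, IonImage], dict]:
    """Poisson ion-count stacks for species 14N, 40Ca and 46Ca.

    Each species has one smooth mean-count truth field; layer k is a
    Poisson sample of that field displaced by the planted shift of layer k
    (the second layer is the reference and is never displaced).  The 46Ca
    mean field is the 40Ca field scaled by ``enrichment_permil/1000``.
    Returns the images and a truth dict with the fields and shifts.
    """
    rng = np.random.default_rng(seed)
    if planted_shifts is None:
        planted_shifts = [
            (0, 0) if k == 1 else (int(rng.integers(-max_shift, max_shift + 1)),
                                   int(rng.integers(-max_shift, max_shift + 1)))
            for k in range(n_layers)]
    planted_shifts = [tuple(int(v) for v in s) for s in planted_shifts]
    if len(planted_shifts) != n_layers:
        raise ValueError("one planted shift per layer required")
    if any(abs(s[0]) >= shape[0] or abs(s[1]) >= shape[1]
           for s in planted_shifts):
        raise ValueError("planted shift exceeds image shape")

    fields = {
        "14N": _smooth_field(rng, shape, 5 * background, n_sources,
                             5 * amplitude, sigma_px),
        "40Ca": _smooth_field(rng, shape, background, n_sources,
                              amplitude, sigma_px),
    }
    fields["46Ca"] = fields["40Ca"] * (enrichment_permil / 1000.0)

    images: dict[str, IonImage] = {}
    for species, mean_field in fields.items():
        layers = []
        for s in planted_shifts:
            shifted = shift_int(mean_field, s[0], s[1])
            layers.append(rng.poisson(shifted))
        images[species] = IonImage(species=species,
                                   layers=np.stack(layers),
                                   raster_um=raster_um)
    truth = {"fields": fields, "planted_shifts": planted_shifts,
             "enrichment_permil": enrichment_permil}
    return images, truth


@dataclass(frozen=True)
class ChannelRelation:
    """Planted linear relation channel = intercept + slope*Ca40 + noise."""

    intercept: float
    slope: float
    noise_sd: float


def gen_roi_dataset(
    seed: int,
    n: int = 200,
    mixture_fraction: float = 0.183,
    binding_ca_range: tuple[float, float] = (2.0, 12.0),
    nonbinding_ca_range: tuple[float, float] = (0.0, 2.0),
    channels: Mapping[str, ChannelRelation | tuple] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """ROI table with a two-population 40Ca mixture and linear channels.

    A fraction ``mixture_fraction`` of ROIs belongs to the calcium-binding
    population (mean 40Ca counts above 2); each named channel is generated
    as intercept + slope*Ca40 + Gaussian noise, slopes may be negative
    (activity-marker style).  Truth records group membership and the
    planted relations.
    """
    if n < 10:
        raise ValueError("need at least 10 ROIs")
    if not 0 <= mixture_fraction <= 1:
        raise ValueError("mixture_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if channels is None:
        channels = {"VGAT": ChannelRelation(5.0, 1.5, 1.0),
                    "Syt1": ChannelRelation(20.0, -0.8, 1.0)}
    channels = {k: (v if isinstance(v, ChannelRelation)
                    else ChannelRelation(*v)) for k, v in channels.items()}

    binding = rng.random(n) < mixture_fraction
    ca = np.where(
        binding,
        rng.uniform(*binding_ca_range, size=n),
        rng.uniform(*nonbinding_ca_range, size=n),
    )
    table = pd.DataFrame({"roi_id": np.arange(n), "Ca40": ca,
                          "group_truth": np.where(binding, "binding",
                                                  "non_binding")})
    for name, rel in channels.items():
        table[name] = (rel.intercept + rel.slope * ca
                       + rng.normal(0.0, rel.noise_sd, size=n))
    truth = {"mixture_fraction": mixture_fraction,
             "n_binding": int(binding.sum()),
             "channels": {k: v for k, v in channels.items()}}
    return table, truth


def _burst_profile(width: int, n_peaks: int, amplitude: float) -> np.ndarray:
    """Burst waveform in %F_max: triangular peaks on a pedestal.

    The pedestal (60% of amplitude) keeps the whole burst above the burst
    threshold while the triangles give each peak a prominence of 40% of
    the amplitude.
    """
    prof = np.full(width, 0.6 * amplitude)
    seg = width / n_peaks
    for k in range(n_peaks):
        center = (k + 0.5) * seg
        for i in range(width):
            tri = max(0.0, 1.0 - abs(i - center) / (seg / 2.0 + 1e-12))
            prof[i] = max(prof[i], 0.6 * amplitude + 0.4 * amplitude * tri)
    return prof


def gen_trace(
    seed: int,
    duration: float = 300.0,
    dt: float = 1.0,
    f0: float = 100.0,
    fmax: float = 400.0,
    noise_sd: float = 0.5,
    burst_starts: Sequence[float] | None = None,
    burst_widths: Sequence[float] | None = None,
    burst_amplitudes: Sequence[float] | None = None,
    peaks_per_burst: Sequence[int] | None = None,
    n_bursts: int = 5,
    stim_windows: Sequence[tuple[float, float]] = ((120.0, 123.0),
                                                   (180.0, 210.0)),
    stim_amplitude: float = 80.0,
    plateau_start: float | None = None,
) -> tuple[Trace, dict]:
    """One indicator trace: baseline + planted bursts + stimuli + plateau.

    Sampling at 1 Hz by default; the terminal 15 s hold the ionomycin
    plateau at ``fmax``.  Planted bursts (given explicitly or drawn at
    random in the spontaneous segments) must not overlap each other, a
    stimulation window or the plateau.  Truth records every planted event.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / dt)) + 1
    t = dt * np.arange(n)
    if plateau_start is None:
        plateau_start = duration - 15.0
    rng = np.random.default_rng(seed)

    blocked = list(stim_windows) + [(plateau_start, duration)]
    if burst_starts is None:
        widths = (list(burst_widths) if burst_widths is not None
                  else list(rng.integers(4, 9, size=n_bursts)))
        starts = []
        tries = 0
        while len(starts) < len(widths) and tries < 2000:
            tries += 1
            w = widths[len(starts)]
            s = float(rng.uniform(5.0, plateau_start - w - 5.0))
            cand = (s, s + w)
            if all(cand[1] + 2 < a or cand[0] - 2 > b
                   for a, b in blocked + [(x, x + y) for x, y in starts]):
                starts.append((s, w))
        burst_starts = [s for s, _ in starts]
        burst_widths = [w for _, w in starts]
    else:
        burst_starts = list(burst_starts)
        burst_widths = list(burst_widths if burst_widths is not None
                            else [5.0] * len(burst_starts))
    if burst_amplitudes is None:
        burst_amplitudes = [50.0] * len(burst_starts)
    if peaks_per_burst is None:
        peaks_per_burst = [1] * len(burst_starts)
    intervals = sorted(zip(burst_starts, burst_widths))
    for (s1, w1), (s2, _) in zip(intervals, intervals[1:]):
        if s1 + w1 > s2:
            raise ValueError("planted bursts overlap")

    p = np.zeros(n)
    for s, w, a, k in zip(burst_starts, burst_widths, burst_amplitudes,
                          peaks_per_burst):
        i0 = int(round(s / dt))
        width = max(int(round(w / dt)), 1)
        prof = _burst_profile(width, int(k), a)
        p[i0:i0 + width] = np.maximum(p[i0:i0 + width], prof[:n - i0])
    for (a, b) in stim_windows:
        sel = (t >= a) & (t <= b)
        p[sel] = np.maximum(p[sel], stim_amplitude)
    p[t >= plateau_start] = 100.0

    F = f0 + (fmax - f0) * p / 100.0 + rng.normal(0.0, noise_sd, size=n)
    # anchor windows: keep baseline and plateau clean of planted events
    F[t <= 5.0] = f0 + rng.normal(0.0, noise_sd, size=int((t <= 5.0).sum()))
    F[t >= plateau_start] = fmax + rng.normal(
        0.0, noise_sd, size=int((t >= plateau_start).sum()))

    trace = Trace(t=t, F=F, f0_window=(0.0, 5.0),
                  fmax_window=(plateau_start, duration),
                  stim_windows=list(stim_windows))
    truth = {"burst_starts": list(burst_starts),
             "burst_widths": list(burst_widths),
             "burst_amplitudes": list(burst_amplitudes),
             "peaks_per_burst": [int(k) for k in peaks_per_burst],
             "f0": f0, "fmax": fmax,
             "stim_amplitude": stim_amplitude}
    return trace, truth


def gen_traces(seed: int, n_cells: int = 10, **kw) -> tuple[list[Trace], list[dict]]:
    """A set of independent cell traces (one derived seed per cell)."""
    rng = np.random.default_rng(seed)
    traces, truths = [], []
    for _ in range(n_cells):
        tr, truth = gen_trace(int(rng.integers(0, 2**31 - 1)), **kw)
        traces.append(tr)
        truths.append(truth)
    return traces, truths


def gen_spike_train(rate: float, duration: float, seed: int) -> DriveSpec:
    """Homogeneous Poisson spike train on [0, duration)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    if rate == 0:
        return DriveSpec.from_spikes(())
    n_expect = rate * duration
    n = rng.poisson(n_expect)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    # enforce strictly increasing times (ties have probability ~0)
    times = np.unique(times)
    return DriveSpec.from_spikes(times)


def gen_turnover(
    groups: Sequence[tuple[str, float, int]],
    seed: int,
    mean_ca40_counts: float = 2.0e5,
    source_ca46_fraction: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell 46Ca/40Ca ratio table for labeled-uptake group comparisons.

    Each group is (label, enrichment_permil, n_cells); enrichments must lie
    between the natural abundance (~0.0413 per mil) and the ceiling set by
    the labeled source (50 per mil for a 5% 46Ca carbonate).  Per cell the
    40Ca and 46Ca totals are Poisson counts, so ratio noise follows
    counting statistics — single 46Ca counts visibly inflate low ratios.
    """
    floor = natural_abundance_permil()
    ceiling = enrichment_ceiling_permil(source_ca46_fraction)
    rng = np.random.default_rng(seed)
    rows = []
    for label, enrich, n_cells in groups:
        if enrich > ceiling + 1e-12:
            raise ValueError(
                f"group {label!r}: enrichment {enrich} per mil exceeds the "
                f"{ceiling} per mil ceiling of the labeled source")
        if enrich < floor - 1e-12:
            raise ValueError(
                f"group {label!r}: enrichment {enrich} below natural "
                f"abundance {floor:.4f}")
        for _ in range(int(n_cells)):
            n40 = max(int(rng.poisson(mean_ca40_counts)), 1)
            n46 = rng.poisson(n40 * enrich / 1000.0)
            rows.append((label, 1000.0 * n46 / n40, n46, n40))
    table = pd.DataFrame(rows, columns=["group", "ratio_permil",
                                        "counts_46", "counts_40"])
    truth = {"groups": {label: {"enrichment_permil": e, "n_cells": n}
                        for label, e, n in groups},
             "ceiling_permil": ceiling}
    return table, truth
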