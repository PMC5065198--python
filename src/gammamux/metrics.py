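"""Analysis suite: PSTHs, gamma spectra, phase histograms, coincidence
statistics, and the S/A/B state indices with their RGB conversion.

The state of a parameter point is summarised by three numbers in [0, 1]:

* ``S`` — failure of temporal segregation.  For the quadrant network it is
  the shared area between the 3 ms-smoothed higher-area cell traces,
  normalised to a reference poorly segregated state (no global inhibition
  anywhere); for the conjunction network it is the false-conjunction spike
  count per slow cycle, normalised to 3 and clipped at 1.
* ``A`` — representation of the selected (highest contrast/gain) item:
  selected-cell spikes per slow cycle / 3, clipped at 1.
* ``B`` — representation of the other items: mean spikes per slow cycle of
  the other cells / 2, clipped at 1.

These map to a colour: Green = S, Blue = (1-S) B, Red = (1-S)(A-B); the map
tends to black when the higher area is nearly silent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sp_signal

from .engine import SpikeRecord

__all__ = [
    "RateSeries",
    "StateIndices",
    "psth",
    "gamma_frequency",
    "phase_histogram",
    "near_coincidence_fraction",
    "spike_separation_S",
    "false_conjunction_S",
    "item_indices",
    "rgb_state",
    "classify_state",
    "slow_cycle_count",
]


@dataclass
class RateSeries:
    """A smoothed rate / firing-probability time series on a regular grid."""

    time: np.ndarray        # ms, bin centres
    values: np.ndarray      # (n_series, n_bins)
    smoothing_sd: float     # ms


def _binned_counts(times: np.ndarray, duration: float, dt: float) -> np.ndarray:
    edges = np.arange(0.0, duration + dt / 2, dt)
    counts, _ = np.histogram(times, bins=edges)
    return counts


def psth(
    record: SpikeRecord,
    pop: str = "higher_e",
    cells: list | None = None,
    smoothing_sd: float = 2.0,
    mode: str = "probability",
) -> RateSeries:
    """Per-cell PSTH averaged over repeats, Gaussian-smoothed.

    ``mode="probability"`` gives the per-repeat probability of a spike in
    each dt bin (the higher-area convention); ``mode="rate"`` gives the mean
    firing rate in spikes/s averaged over the listed cells (the lower-area
    convention; ``cells`` then defines the participating set, defaulting to
    all cells with at least one spike).
    """
    if record.repeats < 1:
        raise ValueError("record has no repeats")
    ev = record.events[pop]
    dt = record.dt
    nbins = int(round(record.duration / dt))
    tgrid = (np.arange(nbins) + 0.5) * dt
    if mode == "probability":
        if cells is None:
            cells = sorted(np.unique(ev["cell"]))
        if len(cells) == 0:
            raise ValueError("empty population")
        rows = []
        for c in cells:
            mask = ev["cell"] == c
            counts = _binned_counts(ev["time"][mask], record.duration, dt)
            rows.append(counts / record.repeats)
        vals = np.asarray(rows, dtype=float)
    elif mode == "rate":
        if cells is None:
            cells = np.unique(ev["cell"])
        n_cells = max(len(np.atleast_1d(cells)), 1)
        mask = np.isin(ev["cell"], np.atleast_1d(cells))
        counts = _binned_counts(ev["time"][mask], record.duration, dt)
        vals = (counts / (record.repeats * n_cells * dt * 1e-3))[None, :]
    else:
        raise ValueError(f"unknown psth mode {mode!r}")
    if smoothing_sd > 0:
        vals = ndimage.gaussian_filter1d(vals, smoothing_sd / dt, axis=1, mode="constant")
    return RateSeries(time=tgrid, values=vals, smoothing_sd=smoothing_sd)


def gamma_frequency(
    record: SpikeRecord,
    pop: str = "lower_e",
    band: tuple[float, float] = (20.0, 100.0),
    window: tuple[float, float] | None = None,
    resolution_hz: float = 1.0,
    smoothing_sd: float = 2.0,
):
    """Spectral peak of the pooled population PSTH within the gamma band.

    The pooled spike histogram of all activated cells is smoothed with the
    2 ms Gaussian PSTH kernel, mean-subtracted, Hann-windowed and zero-padded
    to the requested spectral resolution; the per-repeat power spectra are
    averaged and the peak located within ``band``.  Returns
    ``(peak_hz, freqs, power)``; ``peak_hz`` is ``nan`` when the record
    contains no spikes.
    """
    ev = record.events[pop]
    dt = record.dt
    t0, t1 = window if window is not None else (0.0, record.duration)
    nbins = int(round((t1 - t0) / dt))
    nfft = max(nbins, int(round(1000.0 / (resolution_hz * dt))))
    freqs = np.fft.rfftfreq(nfft, d=dt * 1e-3)
    if len(ev["time"]) == 0:
        return float("nan"), freqs, np.zeros_like(freqs)
    taper = sp_signal.windows.hann(nbins)
    power = np.zeros(len(freqs))
    for rep in range(record.repeats):
        mask = (ev["repeat"] == rep) & (ev["time"] >= t0) & (ev["time"] < t1)
        counts = _binned_counts(ev["time"][mask] - t0, t1 - t0, dt)[:nbins].astype(float)
        if smoothing_sd > 0:
            counts = ndimage.gaussian_filter1d(counts, smoothing_sd / dt, mode="constant")
        x = (counts - counts.mean()) * taper
        power += np.abs(np.fft.rfft(x, n=nfft)) ** 2
    power /= record.repeats
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if power[sel].max() <= 0:
        return float("nan"), freqs, power
    peak = freqs[sel][np.argmax(power[sel])]
    return float(peak), freqs, power


def phase_histogram(
    record: SpikeRecord,
    pop: str = "higher_e",
    cells: list | None = None,
    n_bins: int = 111,
    smoothing_sd_ms: float = 2.0,
    window: tuple[float, float] | None = None,
):
    """Firing probability versus slow-oscillation phase (polar profile).

    Phase 0 is the inhibition peak.  Smoothing is circular, with the 2 ms
    temporal SD converted to phase bins via the slow period.  Returns
    ``(phase_centres_rad, values)`` with one row per cell.
    """
    if record.slow is None or not record.slow.enabled:
        raise ValueError("record was simulated without a slow oscillation")
    period = record.slow.period_ms
    ev = record.events[pop]
    if cells is None:
        cells = sorted(np.unique(ev["cell"]))
    t0, t1 = window if window is not None else (0.0, record.duration)
    edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    n_cycles = max((t1 - t0) / period, 1e-9)
    sd_bins = smoothing_sd_ms / period * n_bins
    rows = []
    for c in cells:
        mask = (ev["cell"] == c) & (ev["time"] >= t0) & (ev["time"] < t1)
        phases = (ev["time"][mask] % period) / period * 2 * np.pi
        counts, _ = np.histogram(phases, bins=edges)
        vals = counts / (record.repeats * n_cycles)
        if sd_bins > 0:
            vals = ndimage.gaussian_filter1d(vals, sd_bins, mode="wrap")
        rows.append(vals)
    return centres, np.asarray(rows)


def near_coincidence_fraction(
    record: SpikeRecord,
    pop: str = "higher_e",
    cells: list | None = None,
    window_ms: float = 3.0,
    t_min: float = 0.0,
) -> float:
    """Fraction of spikes followed by a different cell's spike within the window.

    Pooled over repeats; within a repeat, a spike at time t counts as
    "coincident" if any other listed cell spikes in [t, t + window_ms]
    (cross-cell simultaneity at the same step counts; a cell's own later
    spikes never do).  Returns 0 when at most one cell is active.
    """
    ev = record.events[pop]
    if cells is None:
        cells = sorted(np.unique(ev["cell"]))
    if len(cells) < 2:
        return 0.0
    total = 0
    followed = 0
    for rep in range(record.repeats):
        sel = (ev["repeat"] == rep) & np.isin(ev["cell"], cells) & (ev["time"] >= t_min)
        t = ev["time"][sel]
        c = ev["cell"][sel]
        order = np.argsort(t, kind="stable")
        t, c = t[order], c[order]
        for i in range(len(t)):
            total += 1
            j = i + 1
            while j < len(t) and t[j] - t[i] <= window_ms:
                if c[j] != c[i]:
                    followed += 1
                    break
                j += 1
            else:
                # same-step spikes of other cells may sort before i
                k = i - 1
                while k >= 0 and t[k] == t[i]:
                    if c[k] != c[i]:
                        followed += 1
                        break
                    k -= 1
    return followed / total if total else 0.0


def slow_cycle_count(record: SpikeRecord, window: tuple[float, float] | None = None) -> int:
    """Number of complete slow cycles inside the analysis window."""
    if record.slow is None or not record.slow.enabled:
        raise ValueError("record was simulated without a slow oscillation")
    t0, t1 = window if window is not None else (0.0, record.duration)
    return int(np.floor((t1 - t0) / record.slow.period_ms))


def _smoothed_traces(record: SpikeRecord, pop: str, cells, rep: int, sd_ms: float,
                     window: tuple[float, float]):
    ev = record.events[pop]
    dt = record.dt
    t0, t1 = window
    nbins = int(round((t1 - t0) / dt))
    traces = np.zeros((len(cells), nbins))
    for i, c in enumerate(cells):
        mask = (ev["repeat"] == rep) & (ev["cell"] == c) & (ev["time"] >= t0) & (ev["time"] < t1)
        traces[i] = _binned_counts(ev["time"][mask] - t0, t1 - t0, dt)[:nbins]
    if sd_ms > 0:
        traces = ndimage.gaussian_filter1d(traces, sd_ms / dt, axis=1, mode="constant")
    return traces


def shared_area(record: SpikeRecord, pop: str = "higher_e", cells: list | None = None,
                sd_ms: float = 3.0, window: tuple[float, float] | None = None) -> float:
    """Mean pairwise overlap (integral of the pointwise minimum) of the
    3 ms-smoothed per-cell spike traces, averaged over repeats (raw,
    un-normalised)."""
    ev = record.events[pop]
    if cells is None:
        cells = sorted(np.unique(ev["cell"]))
    if len(cells) < 2:
        return 0.0
    w = window if window is not None else (0.0, record.duration)
    out = 0.0
    n_pairs = len(cells) * (len(cells) - 1) // 2
    for rep in range(record.repeats):
        traces = _smoothed_traces(record, pop, cells, rep, sd_ms, w)
        acc = 0.0
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                acc += np.minimum(traces[i], traces[j]).sum() * record.dt
        out += acc / n_pairs
    return out / record.repeats


def spike_separation_S(
    record: SpikeRecord,
    reference_value: float,
    pop: str = "higher_e",
    cells: list | None = None,
    sd_ms: float = 3.0,
    window: tuple[float, float] | None = None,
) -> float:
    """Quadrant-network temporal-segregation failure index.

    The raw shared area is normalised by ``reference_value`` — the same
    quantity measured in the stored poorly segregated reference state (no
    global inhibition in either area) — and clipped to [0, 1].  A silent
    record yields S = 0.
    """
    if reference_value < 0:
        raise ValueError("reference value must be non-negative")
    raw = shared_area(record, pop, cells, sd_ms, window)
    if raw == 0.0:
        return 0.0
    if reference_value == 0.0:
        return 1.0
    return float(np.clip(raw / reference_value, 0.0, 1.0))


def false_conjunction_S(
    record: SpikeRecord,
    false_cells: list,
    window: tuple[float, float] | None = None,
    per_cycle_norm: float = 3.0,
) -> float:
    """Conjunction-network segregation index: false-conjunction spikes per
    slow cycle, averaged over repeats, divided by 3 and clipped at 1."""
    n_cycles = slow_cycle_count(record, window)
    if n_cycles == 0:
        return 0.0
    ev = record.events["higher_e"]
    t0, t1 = window if window is not None else (0.0, record.duration)
    mask = np.isin(ev["cell"], false_cells) & (ev["time"] >= t0) & (ev["time"] < t1)
    per_rep = np.sum(mask) / record.repeats
    return float(np.clip(per_rep / n_cycles / per_cycle_norm, 0.0, 1.0))


def item_indices(
    record: SpikeRecord,
    selected_cell: int,
    other_cells: list,
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """(A, B): selected-item and other-item representation indices.

    A = selected-cell spikes per slow cycle / 3; B = mean over the other
    cells of spikes per slow cycle / 2; both averaged over repeats and
    clipped to [0, 1].  Only complete slow cycles in the window count.
    """
    n_cycles = slow_cycle_count(record, window)
    if n_cycles == 0:
        return 0.0, 0.0
    ev = record.events["higher_e"]
    t0, t1 = window if window is not None else (0.0, record.duration)
    inwin = (ev["time"] >= t0) & (ev["time"] < t1)

    def per_cycle(cell) -> float:
        n = np.sum(inwin & (ev["cell"] == cell))
        return n / record.repeats / n_cycles

    A = np.clip(per_cycle(selected_cell) / 3.0, 0.0, 1.0)
    B = 0.0
    if other_cells:
        B = np.clip(np.mean([per_cycle(c) for c in other_cells]) / 2.0, 0.0, 1.0)
    return float(A), float(B)


@dataclass
class StateIndices:
    """S/A/B state indices of one parameter point."""

    S: float
    A: float
    B: float

    def __post_init__(self) -> None:
        for name in ("S", "A", "B"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def rgb_state(indices: StateIndices) -> tuple[float, float, float]:
    """Convert (S, A, B) to the (Red, Green, Blue) classification colour.

    Green = S; Blue = (1-S) B; Red = (1-S)(A-B), clipped at 0 defensively
    (B exceeding A would otherwise yield a negative red channel).
    """
    S, A, B = indices.S, indices.A, indices.B
    red = float(np.clip((1 - S) * (A - B), 0.0, 1.0))
    green = float(np.clip(S, 0.0, 1.0))
    blue = float(np.clip((1 - S) * B, 0.0, 1.0))
    return red, green, blue


def classify_state(indices: StateIndices, black_threshold: float = 0.15) -> str:
    """Label a parameter point: 'poor-separation', 'F', 'LJ' or 'silent'."""
    r, g, b = rgb_state(indices)
    if max(r, g, b) < black_threshold:
        return "silent"
    label = ("F", "poor-separation", "LJ")[int(np.argmax([r, g, b]))]
    return label
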