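"""Fixed-step integration of the conductance-based LIF network.

Dynamics
--------
Every cell obeys  C dV/dt = g_leak (E_leak - V) + g_exc (E_exc - V)
+ g_inh (E_inh - V), integrated with forward Euler (default step 1 ms).
A spike is registered when the updated V reaches threshold, and V is reset.
Synaptic conductances are step increases that decay analytically: each
accumulator is multiplied by exp(-dt/tau) per step, so no integration error
accumulates in the synaptic dynamics.  A spike at step t increments its
targets' conductances at step t+1 (one-step propagation latency).

Lower-area excitatory cells additionally receive a constant stimulus drive,
per-step Gaussian conductance noise, and (optionally) the slow-oscillation
inhibition: an inhomogeneous-Poisson barrage of unitary inhibitory events
whose rate follows a raised cosine at the slow frequency (9 Hz by default),
peaking at t = 0 mod the slow period.  Its peak rate is set by
:func:`calibrate_slow_amplitude` so that, at full amplitude, firing in the
lower area is completely suppressed around the oscillation peak.

All randomness flows from a master seed through per-repeat and per-stream
``numpy`` SeedSequences, so a (network, drive, config) triple maps to a
bit-reproducible SpikeRecord.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .network import (
    E_INH,
    CellParams,
    NetworkSpec,
    RealizedNetwork,
    realize,
)
from .stimulus import DriveField

POPULATIONS = ("lower_e", "lower_i", "lower_g", "higher_e", "higher_g")

__all__ = [
    "POPULATIONS",
    "SlowOscConfig",
    "SimConfig",
    "SpikeRecord",
    "membrane_step",
    "decay_conductances",
    "slow_osc_rate",
    "run",
    "calibrate_slow_amplitude",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class SlowOscConfig:
    """Slow (theta/alpha-band) inhibitory modulation of lower-area cells.

    ``rate_max`` is the peak event rate per cell (events/ms) at amplitude
    scale 1; it is the quantity fixed by calibration.  ``scale`` rescales the
    rate (0.5 implements the halved-amplitude protocols; 0 disables the
    contribution while keeping phase bookkeeping).
    """

    enabled: bool = False
    freq_hz: float = 9.0
    scale: float = 1.0
    rate_max: float | None = None  # events/ms/cell at peak, amplitude scale 1
    # small unitary events at a high rate approximate the smooth conductance
    # envelope of a barrage from a large presynaptic pool (relative
    # fluctuation ~ 1/sqrt(rate * tau))
    g_unit: float = 0.05           # nS per unitary inhibitory event
    tau: float = 3.0               # ms decay of the unitary events

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.freq_hz


@dataclass
class SimConfig:
    duration: float            # ms
    repeats: int = 1
    seed: int = 0
    dt: float = 1.0            # ms
    noise_sd: float = 1.0      # nS, lower-area excitatory cells only
    slow: SlowOscConfig = field(default_factory=SlowOscConfig)
    record: tuple[str, ...] = POPULATIONS

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("dt must divide duration")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class SpikeRecord:
    """(population, cell, time, repeat) spike events plus run metadata."""

    events: dict                  # pop -> {"repeat","cell","time"} arrays
    duration: float
    dt: float
    repeats: int
    seed: int
    slow: SlowOscConfig | None = None

    def times(self, pop: str, repeat: int | None = None,
              cell: int | Sequence[int] | None = None) -> np.ndarray:
        ev = self.events[pop]
        mask = np.ones(len(ev["time"]), dtype=bool)
        if repeat is not None:
            mask &= ev["repeat"] == repeat
        if cell is not None:
            mask &= np.isin(ev["cell"], np.atleast_1d(cell))
        return ev["time"][mask]

    def counts(self, pop: str) -> np.ndarray:
        """Total spike count per repeat."""
        ev = self.events[pop]
        return np.bincount(ev["repeat"], minlength=self.repeats)

    def n_spikes(self, pop: str) -> int:
        return len(self.events[pop]["time"])


# --------------------------------------------------------------------------
# elementary operations (exposed for direct testing)
# --------------------------------------------------------------------------

def membrane_step(V, g_leak, g_exc, g_inh, params: CellParams, dt: float):
    """One forward-Euler update; returns (V', spiked)."""
    V = np.asarray(V, dtype=float)
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(np.asarray(g_exc)))
            and np.all(np.isfinite(np.asarray(g_inh)))):
        raise ValueError("non-finite membrane state or conductance")
    dV = (dt / params.C) * (
        g_leak * (params.E_leak - V) + np.asarray(g_exc) * (0.0 - V)
        + np.asarray(g_inh) * (E_INH - V)
    )
    Vn = V + dV
    spiked = Vn >= params.V_th
    return np.where(spiked, params.V_reset, Vn), spiked


def decay_conductances(g, tau: float, dt: float):
    """Analytic exponential decay of a conductance accumulator."""
    if np.isinf(tau):
        return np.asarray(g, dtype=float)
    return np.asarray(g, dtype=float) * np.exp(-dt / tau)


def slow_osc_rate(t_ms, cfg: SlowOscConfig):
    """Instantaneous event rate (events/ms/cell), peaking at t = 0 mod period."""
    if not cfg.enabled or cfg.scale == 0.0 or not cfg.rate_max:
        return np.zeros_like(np.asarray(t_ms, dtype=float))
    t = np.asarray(t_ms, dtype=float)
    return cfg.scale * cfg.rate_max * 0.5 * (1.0 + np.cos(2 * np.pi * cfg.freq_hz * t / 1000.0))


# --------------------------------------------------------------------------
# the simulation loop
# --------------------------------------------------------------------------

def _blur_sheet(counts: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = ndimage.correlate1d(counts, kernel, axis=0, mode="constant")
    return ndimage.correlate1d(out, kernel, axis=1, mode="constant")


class _Wiring:
    """Per-network index arrays shared across repeats."""

    def __init__(self, real: RealizedNetwork):
        spec = real.spec
        lay = spec.layout
        self.real = real
        self.grid = lay.grid
        self.n_lower = lay.n_units
        self.n_higher = spec.n_higher
        self.sheet_flat = lay.sheet_flat
        # per-unit (scale, orientation) group and in-grid position
        n_or = len(lay.orientations)
        self.so_id = np.where(lay.orientation_channel >= 0,
                              lay.scale * n_or + lay.orientation_channel, -1)
        self.pos_in_grid = lay.row * np.asarray(lay.sides)[lay.scale] + lay.col
        # contiguous slice covering all phases of one (scale, orientation)
        self.so_slice = {}
        for s in range(lay.n_scales):
            for o in range(n_or):
                a = lay.block(s, o, 0).start
                b = lay.block(s, o, lay.n_phases - 1).stop
                self.so_slice[s * n_or + o] = slice(a, b)
        # global per-scale position ids for the same-position (d=0) coupling
        offsets = np.cumsum([0] + [side * side for side in lay.sides[:-1]])
        self.scale_pos_id = offsets[lay.scale] + self.pos_in_grid
        self.n_scale_pos = offsets[-1] + lay.sides[-1] ** 2
        self.n_phases = lay.n_phases
        if spec.variant == "conjunction":
            self.n_colours = len(lay.colours)
            cells = np.arange(self.n_higher)
            self.cell_orient, self.cell_colour = np.divmod(cells, self.n_colours)


def _resolve_drive(drive, n_lower: int) -> np.ndarray:
    if drive is None:
        return np.zeros(n_lower)
    if isinstance(drive, DriveField):
        v = drive.values
    else:
        v = np.asarray(drive, dtype=float)
        if v.ndim == 0:
            v = np.full(n_lower, float(v))
    if v.shape != (n_lower,):
        raise ValueError("drive length does not match the lower-area population")
    return v


def run(
    network: RealizedNetwork | NetworkSpec,
    drive,
    config: SimConfig,
    schedule: Sequence[tuple[float, dict]] | None = None,
    schedule_fn: Callable[[int, np.random.Generator], Sequence[tuple[float, dict]]] | None = None,
) -> SpikeRecord:
    """Simulate ``config.repeats`` independent repeats and collect spikes.

    ``schedule`` is a list of ``(time_ms, changes)`` applied at exact step
    boundaries in every repeat; ``schedule_fn(repeat, rng)`` may generate a
    per-repeat schedule (e.g. jittered stimulus onset).  Supported change
    keys: ``drive`` (DriveField/array/scalar), ``ge_lower_amp``,
    ``ge_higher_amp``, ``slow_scale``, ``noise_sd``.
    """
    real = network if isinstance(network, RealizedNetwork) else realize(network)
    spec = real.spec
    wiring = _Wiring(real)
    n_lower, n_higher, grid = wiring.n_lower, wiring.n_higher, wiring.grid
    syn = spec.syn
    dt = config.dt
    n_steps = config.n_steps
    if config.slow.enabled and config.slow.scale > 0 and not config.slow.rate_max:
        raise ValueError("slow oscillation enabled but rate_max is not set "
                         "(run calibrate_slow_amplitude first)")

    base_drive = _resolve_drive(drive, n_lower)
    decay = {
        "ee": np.exp(-dt / syn.ee_tau), "ei": np.exp(-dt / syn.ei_tau),
        "ie": np.exp(-dt / syn.ie_tau), "eg": np.exp(-dt / syn.eg_tau),
        "ge_l": np.exp(-dt / syn.ge_lower_tau), "ff": np.exp(-dt / syn.ff_tau),
        "eg_h": np.exp(-dt / syn.eg_hi_tau), "ge_h": np.exp(-dt / syn.ge_higher_tau),
        "slow": np.exp(-dt / config.slow.tau),
    }
    exc, inh, hexc = spec.exc, spec.inh, spec.higher_exc
    kernel = real.gauss_kernel_1d
    noise_ref_sd = config.noise_sd * np.sqrt(dt / 1.0)  # per-step SD, 1 ms reference

    events = {p: {"repeat": [], "cell": [], "time": []} for p in config.record}
    master = np.random.SeedSequence(config.seed)
    rep_seqs = master.spawn(config.repeats)

    for rep in range(config.repeats):
        noise_seq, slow_seq, proto_seq = rep_seqs[rep].spawn(3)
        rng_noise = np.random.default_rng(noise_seq)
        rng_slow = np.random.default_rng(slow_seq)
        rng_proto = np.random.default_rng(proto_seq)

        # per-repeat mutable protocol state
        drive_now = base_drive
        ge_lower_amp = syn.ge_lower_amp
        ge_higher_amp = syn.ge_higher_amp
        slow_scale = config.slow.scale
        noise_sd = noise_ref_sd

        sched: list[tuple[float, dict]] = list(schedule or [])
        if schedule_fn is not None:
            sched += list(schedule_fn(rep, rng_proto))
        step_changes: dict[int, dict] = {}
        for t_ev, changes in sched:
            if not 0.0 <= t_ev <= config.duration:
                raise ValueError(f"schedule time {t_ev} outside [0, duration]")
            step_changes.setdefault(int(round(t_ev / dt)), {}).update(changes)

        # state
        V_e = np.full(n_lower, exc.E_leak)
        V_i = np.full(grid * grid, inh.E_leak)
        V_gl = np.array([inh.E_leak])
        V_he = np.full(n_higher, hexc.E_leak)
        V_gh = np.array([inh.E_leak])
        g_ee = np.zeros(n_lower)
        g_ie = np.zeros(n_lower)
        g_slow = np.zeros(n_lower)
        g_ge_l = 0.0
        g_ei = np.zeros(grid * grid)
        g_eg_l = 0.0
        g_ff = np.zeros(n_higher)
        g_ge_h = 0.0
        g_eg_h = 0.0

        # pending synaptic increments from the previous step's spikes
        pend_ee = None
        pend_ie = None
        pend_ei = None
        pend_ff = None
        prev_e_count = 0
        prev_he_count = 0
        prev_gl = 0
        prev_gh = 0

        rec: dict[str, tuple[list, list]] = {p: ([], []) for p in config.record}

        for step in range(n_steps):
            t = step * dt
            if step in step_changes:
                ch = step_changes[step]
                if "drive" in ch:
                    drive_now = _resolve_drive(ch["drive"], n_lower)
                ge_lower_amp = ch.get("ge_lower_amp", ge_lower_amp)
                ge_higher_amp = ch.get("ge_higher_amp", ge_higher_amp)
                slow_scale = ch.get("slow_scale", slow_scale)
                if "noise_sd" in ch:
                    noise_sd = ch["noise_sd"] * np.sqrt(dt / 1.0)

            # 1. analytic decay
            g_ee *= decay["ee"]; g_ie *= decay["ie"]; g_slow *= decay["slow"]
            g_ei *= decay["ei"]
            g_ge_l *= decay["ge_l"]; g_eg_l *= decay["eg"]
            g_ff *= decay["ff"]; g_ge_h *= decay["ge_h"]; g_eg_h *= decay["eg_h"]

            # 2. deliver spikes from the previous step
            if pend_ee is not None:
                g_ee += syn.ee_amp * pend_ee
            if pend_ie is not None:
                g_ie += syn.ie_amp * pend_ie
            if pend_ei is not None:
                g_ei += syn.ei_amp * pend_ei
            if pend_ff is not None:
                g_ff += pend_ff  # amplitudes applied at queueing time
            if prev_e_count:
                g_eg_l += syn.eg_amp * prev_e_count
            if prev_gl:
                g_ge_l += ge_lower_amp
            if prev_he_count:
                g_eg_h += syn.eg_hi_amp * prev_he_count
            if prev_gh:
                g_ge_h += ge_higher_amp

            # 3. external inputs to lower excitatory cells
            if config.slow.enabled and slow_scale > 0 and config.slow.rate_max:
                lam = slow_scale * config.slow.rate_max * 0.5 * (
                    1.0 + np.cos(2 * np.pi * config.slow.freq_hz * t / 1000.0))
                if lam * dt > 0:
                    g_slow += config.slow.g_unit * rng_slow.poisson(lam * dt, n_lower)
            if noise_sd > 0:
                eps = rng_noise.normal(0.0, noise_sd, n_lower)
            else:
                eps = 0.0

            gE_exc = np.clip(drive_now + g_ee + eps, 0.0, None)
            gE_inh = g_ie + g_ge_l + g_slow

            # 4. Euler updates + threshold
            V_e, sp_e = membrane_step(V_e, exc.g_leak, gE_exc, gE_inh, exc, dt)
            V_i, sp_i = membrane_step(V_i, inh.g_leak, g_ei + inh.tonic_exc, 0.0, inh, dt)
            V_gl, sp_gl = membrane_step(V_gl, inh.g_leak, g_eg_l + inh.tonic_exc, 0.0, inh, dt)
            V_he, sp_he = membrane_step(V_he, hexc.g_leak, g_ff + hexc.tonic_exc, g_ge_h,
                                        hexc, dt)
            V_gh, sp_gh = membrane_step(V_gh, inh.g_leak, g_eg_h + inh.tonic_exc, 0.0, inh, dt)

            idx_e = np.flatnonzero(sp_e)
            idx_i = np.flatnonzero(sp_i)
            idx_he = np.flatnonzero(sp_he)

            for pop, idx in (("lower_e", idx_e), ("lower_i", idx_i),
                             ("higher_e", idx_he),
                             ("lower_g", np.flatnonzero(sp_gl)),
                             ("higher_g", np.flatnonzero(sp_gh))):
                if pop in rec and len(idx):
                    cells, ts = rec[pop]
                    cells.append(idx)
                    ts.append(np.full(len(idx), t))

            # 5. queue this step's spikes for delivery at the next step
            if len(idx_e):
                sheet = np.zeros(grid * grid)
                np.add.at(sheet, wiring.sheet_flat[idx_e], 1.0)
                pend_ei = _blur_sheet(sheet.reshape(grid, grid), kernel).ravel()
                # lateral excitation: same-position coupling across all layers...
                pos_tot = np.bincount(wiring.scale_pos_id[idx_e],
                                      minlength=wiring.n_scale_pos)
                pend_ee = pos_tot[wiring.scale_pos_id].astype(float)
                pend_ee[idx_e] -= 1.0  # ...excluding self-connections
                # plus the collinearity-weighted same-orientation surround
                so = wiring.so_id[idx_e]
                for so_key in np.unique(so[so >= 0]):
                    sl = wiring.so_slice[so_key]
                    sel = idx_e[so == so_key]
                    n_pos = (sl.stop - sl.start) // wiring.n_phases
                    cnt = np.bincount(wiring.pos_in_grid[sel], minlength=n_pos)
                    s_key, o_key = divmod(int(so_key), len(spec.layout.orientations))
                    lat = real.lateral[(s_key, o_key)] @ cnt
                    pend_ee[sl] += np.tile(lat, wiring.n_phases)
                # feedforward pooling
                if spec.variant == "quadrant":
                    pend_ff = syn.ff_amp * np.bincount(
                        real.ff_labels[idx_e], minlength=4).astype(float)
                else:
                    oc = real.orient_channel[idx_e]
                    cc = real.colour_channel[idx_e]
                    ocnt = np.bincount(oc[oc >= 0], minlength=4)
                    ccnt = np.bincount(cc[cc >= 0], minlength=wiring.n_colours)
                    ff_col = syn.ff_colour_amp if syn.ff_colour_amp is not None else syn.ff_amp
                    pend_ff = (syn.ff_amp * ocnt[wiring.cell_orient]
                               + ff_col * ccnt[wiring.cell_colour]).astype(float)
            else:
                pend_ei = None
                pend_ee = None
                pend_ff = None
            if len(idx_i):
                sheetI = np.zeros(grid * grid)
                np.add.at(sheetI, idx_i, 1.0)
                blurI = _blur_sheet(sheetI.reshape(grid, grid), kernel).ravel()
                pend_ie = blurI[wiring.sheet_flat]
            else:
                pend_ie = None
            prev_e_count = len(idx_e)
            prev_he_count = len(idx_he)
            prev_gl = int(sp_gl[0])
            prev_gh = int(sp_gh[0])

        for pop in config.record:
            cells, ts = rec[pop]
            if cells:
                c = np.concatenate(cells)
                tt = np.concatenate(ts)
            else:
                c = np.empty(0, dtype=int)
                tt = np.empty(0)
            events[pop]["repeat"].append(np.full(len(c), rep, dtype=np.int32))
            events[pop]["cell"].append(c.astype(np.int32))
            events[pop]["time"].append(tt)

    out = {}
    for pop in config.record:
        out[pop] = {
            "repeat": np.concatenate(events[pop]["repeat"]) if events[pop]["repeat"]
            else np.empty(0, dtype=np.int32),
            "cell": np.concatenate(events[pop]["cell"]) if events[pop]["cell"]
            else np.empty(0, dtype=np.int32),
            "time": np.concatenate(events[pop]["time"]) if events[pop]["time"]
            else np.empty(0),
        }
    return SpikeRecord(events=out, duration=config.duration, dt=config.dt,
                       repeats=config.repeats, seed=config.seed,
                       slow=replace(config.slow))


# --------------------------------------------------------------------------
# slow-oscillation calibration
# --------------------------------------------------------------------------

def _peak_window_spikes(record: SpikeRecord, freq_hz: float, window_ms: float = 10.0,
                        t_min: float = 100.0) -> int:
    """Lower-area spikes within +/- window of slow-oscillation peaks after t_min."""
    t = record.times("lower_e")
    period = 1000.0 / freq_hz
    if len(t) == 0:
        return 0
    phase_t = (t + window_ms) % period  # distance past the previous peak, shifted
    near_peak = phase_t <= 2 * window_ms
    return int(np.sum(near_peak & (t >= t_min)))


def calibrate_slow_amplitude(
    network: RealizedNetwork | NetworkSpec,
    drive,
    dt: float = 1.0,
    seed: int = 0,
    freq_hz: float = 9.0,
    g_unit: float = 0.05,
    tau: float = 3.0,
    duration: float = 400.0,
    rel_tol: float = 0.05,
    start_rate: float = 2.0,
    max_rate: float = 4096.0,
    noise_sd: float = 1.0,
) -> float:
    """Find the smallest peak event rate that fully silences the lower area
    around the slow-oscillation peak under the given (maximal) drive.

    Doubles the candidate rate until the +/-10 ms peak windows contain no
    lower-area spikes, then bisects to the stated relative tolerance.
    Raises RuntimeError if no rate within bounds suppresses firing.
    """
    real = network if isinstance(network, RealizedNetwork) else realize(network)

    def silent(rate: float) -> bool:
        cfg = SimConfig(
            duration=duration, repeats=1, seed=seed, dt=dt, noise_sd=noise_sd,
            slow=SlowOscConfig(enabled=True, freq_hz=freq_hz, scale=1.0,
                               rate_max=rate, g_unit=g_unit, tau=tau),
            record=("lower_e",),
        )
        rec = run(real, drive, cfg)
        return _peak_window_spikes(rec, freq_hz) == 0

    lo, hi = 0.0, start_rate
    while not silent(hi):
        lo = hi
        hi *= 2.0
        if hi > max_rate:
            raise RuntimeError("slow-oscillation calibration failed within bounds")
    abs_tol = 0.05 * start_rate  # floor for the zero-drive corner (lo stays 0)
    while hi - lo > max(rel_tol * hi, abs_tol):
        mid = 0.5 * (lo + hi)
        if silent(mid):
            hi = mid
        else:
            lo = mid
    return hi
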