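"""Scripted, seeded scenario runners for each experiment protocol.

Every runner is a pure function of its arguments plus a master seed, and
returns a dict of results together with a manifest sufficient to re-run it
bit-identically.  Two geometry presets are provided:

* ``full``  — 128 x 128 base grid, 4 spatial scales (348,160 orientation
  units), the geometry of the original study;
* ``desk``  — 48 x 48 base grid, 2 scales, proportionally scaled objects.

The desk preset compensates for the smaller per-volley ensembles so that the
full geometry's dynamics are preserved: local E<->I, lower E->global and
feedforward amplitudes and the per-cell noise SD carry calibrated factors
(see :class:`ScalePreset`); time constants and the 7.5 nS drive ceiling are
unchanged.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as mt
from .engine import (
    SimConfig,
    SlowOscConfig,
    SpikeRecord,
    calibrate_slow_amplitude,
    membrane_step,
    run,
)
from .network import (
    NetworkSpec,
    RealizedNetwork,
    SynapseParams,
    build_conjunction_network,
    build_quadrant_network,
    realize,
)
from .stimulus import (
    DriveField,
    ObjectSpec,
    PatchSpec,
    build_gabor_bank,
    compute_drive,
    make_conjunction_stimulus,
    make_noise_stimulus,
    make_quadrant_stimulus,
)

__all__ = [
    "ScalePreset",
    "FULL",
    "DESK",
    "Protocol",
    "default_objects",
    "default_patches",
    "setup",
    "calibrate_feedforward",
    "conjunction_cells",
    "run_contrast_sweep",
    "run_state_map",
    "run_staged_switch",
    "run_slow_osc_series",
    "run_multi_item",
    "run_conjunction",
    "run_robustness_sweeps",
    "cycle_counts",
]


# --------------------------------------------------------------------------
# geometry presets and canonical operating points
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalePreset:
    name: str
    grid: int
    n_scales: int
    # local E<->I amplitude compensation: ensembles along the (smaller)
    # object contours recruit fewer local interneurons, so the per-cell
    # inhibitory volleys shrink; the factor is calibrated once so that the
    # scaled preset reproduces the full geometry's gamma dynamics (peak
    # frequency across contrasts), then frozen
    local_factor: float = 1.0
    # feedforward amplitude factor, on top of the convergence compensation:
    # calibrated once per preset so that in the default state (no global
    # inhibition) the higher-area cells operate at the scale the state
    # indices assume (selected cell ~ 3 spikes per slow cycle), then frozen
    ff_factor: float = 1.0
    # per-cell conductance-noise factor: the scaled geometry's volleys are
    # ~4x smaller, so per-cell noise is scaled by 1/sqrt(volley ratio) to
    # preserve the ensemble-level signal-to-noise of burst timing
    noise_factor: float = 1.0

    @property
    def convergence_factor(self) -> float:
        """Amplitude compensation for the many-to-one projections (lower-to-
        higher feedforward and lower E-to-global).  Their per-volley input
        scales with the ensemble volley size, which follows the object
        contour length (linear in grid side); the same calibrated residual
        as for the local loop applies on top."""
        return (128.0 / self.grid) * self.local_factor


FULL = ScalePreset("full", 128, 4, local_factor=1.0, ff_factor=2.0, noise_factor=1.0)
DESK = ScalePreset("desk", 48, 2, local_factor=1.5, ff_factor=3.0, noise_factor=0.5)
_PRESETS = {"full": FULL, "desk": DESK}

# Canonical "strong" global-inhibition amplitudes (nS) for the F- and
# LJ-multiplexing operating points, frozen after mapping the 0-30 nS plane
# (the F-multiplexing red region peaks at strong higher-area inhibition, the
# LJ blue region at moderate-to-strong lower-area inhibition).
F_POINT = {"ge_lower_amp": 0.0, "ge_higher_amp": 30.0}
LJ_POINT = {"ge_lower_amp": 20.0, "ge_higher_amp": 0.0}

# Operating amplitude of the slow oscillation relative to the calibrated
# minimal full-suppression amplitude.  The halved-amplitude protocols must
# leave the most strongly driven cells unsuppressed (margin < 2) while the
# full amplitude suppresses everything with headroom (margin > 1); 1.5 also
# places the per-ensemble release times on the steep limb of the cosine,
# which orders them by drive.
SLOW_MARGIN = 1.5

SLOW_FREQ_HZ = 9.0
DEFAULT_CONTRASTS = (1.0, 0.95, 0.9)
DEFAULT_QUADRANTS = ("top-left", "bottom-right", "top-right")


def default_objects(contrasts: Sequence[float] = DEFAULT_CONTRASTS) -> list[ObjectSpec]:
    """The canonical three-object stimulus: rectangles of decreasing contrast
    in the top-left, bottom-right and top-right quadrants."""
    return [ObjectSpec(q, c) for q, c in zip(DEFAULT_QUADRANTS, contrasts)]


def default_patches() -> list[PatchSpec]:
    """The canonical conjunction stimulus: red-vertical at full contrast plus
    a slightly lower-contrast blue-horizontal patch."""
    return [
        PatchSpec("red", 0.0, 1.0, "top-left"),
        PatchSpec("blue", 90.0, 0.95, "bottom-right"),
    ]


def _preset(scale) -> ScalePreset:
    if isinstance(scale, ScalePreset):
        return scale
    return _PRESETS[scale]


def _scaled_network(preset: ScalePreset, variant: str, **syn_overrides) -> NetworkSpec:
    f = preset.convergence_factor
    syn = SynapseParams(**syn_overrides)
    syn.ff_amp *= f * preset.ff_factor
    syn.eg_amp *= f
    syn.ei_amp *= preset.local_factor
    syn.ie_amp *= preset.local_factor
    build = build_quadrant_network if variant == "quadrant" else build_conjunction_network
    return build(grid=preset.grid, n_scales=preset.n_scales, syn=syn)


# --------------------------------------------------------------------------
# cached heavyweight setup (bank, realisation, slow-oscillation calibration)
# --------------------------------------------------------------------------

_CACHE: dict = {}


@dataclass
class Setup:
    preset: ScalePreset
    variant: str
    bank: object
    spec: NetworkSpec
    real: RealizedNetwork
    noise_sd: float = 1.0
    slow_rate_max: float | None = None
    ff_amp: float | None = None  # calibrated conjunction feedforward amplitude


def setup(scale="desk", variant: str = "quadrant", calibrate_slow: bool = False,
          calibration_seed: int = 12345, **syn_overrides) -> Setup:
    """Build (and cache) the bank, network and calibrations for one preset.

    The slow-oscillation amplitude is calibrated against the canonical
    maximal-drive stimulus of the variant; the conjunction feedforward
    amplitude is calibrated by :func:`calibrate_feedforward`.
    """
    preset = _preset(scale)
    key = (preset.name, variant, tuple(sorted(syn_overrides.items())), calibrate_slow)
    if key in _CACHE:
        return _CACHE[key]
    bank_key = ("bank", preset.name, variant)
    if bank_key not in _CACHE:
        _CACHE[bank_key] = build_gabor_bank(
            grid=preset.grid, n_scales=preset.n_scales,
            colour=(variant == "conjunction"))
    bank = _CACHE[bank_key]
    spec = _scaled_network(preset, variant, **syn_overrides)
    real = realize(spec)
    st = Setup(preset=preset, variant=variant, bank=bank, spec=spec, real=real,
               noise_sd=1.0 * preset.noise_factor)
    if variant == "conjunction":
        st.ff_amp, ff_colour = calibrate_feedforward(st, seed=calibration_seed)
        spec.syn.ff_amp = st.ff_amp
        spec.syn.ff_colour_amp = ff_colour
    if calibrate_slow:
        if variant == "quadrant":
            img = make_quadrant_stimulus(default_objects(), preset.grid)
        else:
            img = make_conjunction_stimulus(default_patches(), preset.grid)
        drive = compute_drive(img, bank)
        minimal = calibrate_slow_amplitude(real, drive, seed=calibration_seed,
                                           noise_sd=st.noise_sd)
        st.slow_rate_max = SLOW_MARGIN * minimal
    _CACHE[key] = st
    return st


def _slow(st: Setup, enabled: bool = True, scale: float = 1.0) -> SlowOscConfig:
    return SlowOscConfig(enabled=enabled, freq_hz=SLOW_FREQ_HZ, scale=scale,
                         rate_max=st.slow_rate_max)


def _manifest(name: str, seed: int, st: Setup, **params) -> dict:
    m = {
        "protocol": name,
        "seed": int(seed),
        "preset": st.preset.name,
        "grid": st.preset.grid,
        "n_scales": st.preset.n_scales,
        "variant": st.variant,
        "slow_rate_max": st.slow_rate_max,
        "ff_amp": st.ff_amp,
        "params": params,
    }
    m["hash"] = hashlib.sha256(repr(sorted(m.items())).encode()).hexdigest()[:16]
    return m


# --------------------------------------------------------------------------
# conjunction feedforward calibration
# --------------------------------------------------------------------------

def calibrate_feedforward(st: Setup, seed: int = 12345,
                          duration: float = 350.0, dt: float = 1.0) -> tuple[float, float]:
    """Tune the lower-to-higher synaptic amplitude of the conjunction network
    so that activity in both input channels (one orientation plus one colour)
    is required to drive a conjunction cell to threshold.

    A short lower-area-only run on the canonical stimulus yields the
    per-gamma-burst afferent spike counts a conjunction cell would see from
    each channel class.  Orientation channels carry larger volleys than
    colour channels, so the colour-synapse amplitude is first set to the
    median-burst ratio (both channels then contribute equally), after which
    bisections on a template volley locate the amplitudes at which a median
    single-channel volley versus a median dual-channel volley reach
    threshold; the geometric midpoint is returned as ``(ff_amp,
    ff_colour_amp)``.
    """
    preset = st.preset
    img = make_conjunction_stimulus(default_patches(), preset.grid)
    drive = compute_drive(img, st.bank)
    spec = st.spec
    probe = replace(spec, syn=replace(spec.syn, ff_amp=0.0))
    rec = run(realize(probe), drive,
              SimConfig(duration=duration, repeats=2, seed=seed, dt=dt,
                        noise_sd=1.0 * st.preset.noise_factor, record=("lower_e",)))
    lay = spec.layout
    hexc = spec.higher_exc
    tau_ff = spec.syn.ff_tau
    n = int(round(duration / dt))
    lag = max(1, int(round(1.0 / dt)))  # 1 ms pairing window

    period = 1000.0 / SLOW_FREQ_HZ

    def burst_size(series: np.ndarray) -> float:
        """Median over slow cycles of the dominant 2-step volley count.

        Each slow cycle carries one dominant entrained volley per channel
        (the small staggered release bursts are not what the higher area
        must discriminate), so the statistic is the per-cycle maximum,
        aggregated by the median across cycles.
        """
        kernel = np.ones(2 * lag)
        pair = np.convolve(series, kernel, mode="same")  # 2 ms volley count
        if pair.max() <= 0:
            return 0.0
        steps_per_cycle = int(round(period / dt))
        maxima = [pair[a:a + steps_per_cycle].max()
                  for a in range(0, n - steps_per_cycle + 1, steps_per_cycle)]
        maxima = [m for m in maxima if m > 0]
        return float(np.median(maxima)) if maxima else 0.0

    ev = rec.events["lower_e"]
    orient_meds, colour_meds = [], []
    for rep in range(rec.repeats):
        sel = ev["repeat"] == rep
        steps = np.round(ev["time"][sel] / dt).astype(int)
        oc = lay.orientation_channel[ev["cell"][sel]]
        cc = lay.colour_channel[ev["cell"][sel]]
        # channels stimulated by the canonical patches: vertical+horizontal
        # orientations, red+blue colours
        for o in (0, 2):
            orient_meds.append(burst_size(
                np.bincount(steps[oc == o], minlength=n).astype(float)))
        for c in (0, 2):
            colour_meds.append(burst_size(
                np.bincount(steps[cc == c], minlength=n).astype(float)))
    n_or = float(np.mean(orient_meds))
    n_col = float(np.mean(colour_meds))
    if n_or <= 0 or n_col <= 0:
        raise RuntimeError("conjunction feedforward calibration saw no bursts")
    ratio = n_or / n_col

    def fires(amp: float, series: np.ndarray) -> bool:
        V = np.array([hexc.E_leak])
        g = 0.0
        width = len(series)
        for k in range(int(round(40 / dt))):
            g = g * np.exp(-dt / tau_ff)
            if 1 <= k <= width:
                g += amp * series[k - 1]
            V, sp = membrane_step(V, hexc.g_leak, g + hexc.tonic_exc, 0.0, hexc, dt)
            if sp[0]:
                return True
        return False

    def threshold_amp(series: np.ndarray) -> float:
        lo, hi = 1e-4, 50.0
        for _ in range(40):
            mid = np.sqrt(lo * hi)
            if fires(mid, series):
                hi = mid
            else:
                lo = mid
        return hi

    width = 2 * lag
    spread = np.full(width, 2.0 * n_or / width)       # typical dual volley, 2 ms
    tail = np.zeros(max(lag, 1))
    tail[:lag] = 1.4 * n_or / lag                      # tail single volley, 1 ms
    # largest amplitude at which even a concentrated tail-sized single-channel
    # volley stays subthreshold, and the smallest at which a typical spread
    # dual-channel volley fires
    a_single = threshold_amp(tail)
    a_dual = threshold_amp(spread)
    if a_dual >= a_single:
        raise RuntimeError("conjunction feedforward calibration found no "
                           "amplitude separating single- from dual-channel drive")
    ff = float(np.sqrt(a_dual * a_single))
    return ff, ff * ratio


# --------------------------------------------------------------------------
# protocol container
# --------------------------------------------------------------------------

@dataclass
class Protocol:
    """Declarative description of one scenario (for configs/manifests)."""

    name: str
    scale: str = "desk"
    repeats: int = 10
    duration: float = 1000.0
    seed: int = 0
    params: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# runners
# --------------------------------------------------------------------------

def run_contrast_sweep(
    contrasts: Sequence[float] = (0.8, 0.85, 0.9, 0.95, 1.0),
    seed: int = 0,
    repeats: int = 10,
    duration: float = 1000.0,
    scale="desk",
    settle: float = 100.0,
) -> dict:
    """Gamma peak frequency of the lower area versus single-object contrast.

    One rectangle in the top-left quadrant; local inhibition only (no global
    inhibition, no slow oscillation).  The spectrum is estimated from the
    pooled PSTH of all activated cells over ``repeats`` x ``duration`` after
    a settling period.
    """
    st = setup(scale, "quadrant")
    rows = []
    spectra = {}
    for c in contrasts:
        img = make_quadrant_stimulus([ObjectSpec("top-left", float(c))], st.preset.grid)
        drive = compute_drive(img, st.bank)
        cfg = SimConfig(duration=duration + settle, repeats=repeats, seed=seed,
                        noise_sd=st.noise_sd, record=("lower_e",))
        rec = run(st.real, drive, cfg)
        peak, freqs, power = mt.gamma_frequency(rec, window=(settle, settle + duration))
        rows.append({"contrast": float(c), "gamma_peak_hz": peak,
                     "n_spikes": rec.n_spikes("lower_e")})
        spectra[float(c)] = (freqs, power)
    table = pd.DataFrame(rows)
    return {"table": table, "spectra": spectra,
            "manifest": _manifest("contrast_sweep", seed, st,
                                  contrasts=list(map(float, contrasts)),
                                  repeats=repeats, duration=duration)}


def _state_cells() -> tuple[int, list[int]]:
    """Higher-area cell indices for the canonical three-object stimulus:
    selected (highest contrast, top-left) and the others in contrast order."""
    # QUADRANTS order: TL=0, TR=1, BL=2, BR=3; contrasts 1/0.95/0.9 at TL/BR/TR
    return 0, [3, 1]


def run_state_map(
    lower_vals: Sequence[float] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
    higher_vals: Sequence[float] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
    seed: int = 0,
    repeats: int = 5,
    duration: float = 2000.0,
    scale="desk",
) -> dict:
    """S/A/B indices and RGB classification over the plane of global
    inhibition amplitudes (lower vs higher area), three-object stimulus.

    The spike-separation reference is the (0, 0) point of the same sweep
    (the known poorly segregated state)."""
    st = setup(scale, "quadrant", calibrate_slow=True)
    img = make_quadrant_stimulus(default_objects(), st.preset.grid)
    drive = compute_drive(img, st.bank)
    period = 1000.0 / SLOW_FREQ_HZ
    window = (period, float(duration))
    selected, others = _state_cells()
    cells = [selected] + others

    def run_point(gl: float, gh: float) -> SpikeRecord:
        cfg = SimConfig(duration=duration, repeats=repeats, seed=seed,
                        noise_sd=st.noise_sd, slow=_slow(st), record=("higher_e",))
        sched = [(0.0, {"ge_lower_amp": gl, "ge_higher_amp": gh})]
        return run(st.real, drive, cfg, schedule=sched)

    ref_rec = run_point(0.0, 0.0)
    reference = mt.shared_area(ref_rec, cells=cells, window=window)
    rows = []
    for gl in lower_vals:
        for gh in higher_vals:
            rec = ref_rec if (gl == 0.0 and gh == 0.0) else run_point(float(gl), float(gh))
            S = mt.spike_separation_S(rec, reference, cells=cells, window=window)
            A, B = mt.item_indices(rec, selected, others, window=window)
            idx = mt.StateIndices(S=S, A=A, B=B)
            r, g, b = mt.rgb_state(idx)
            rows.append({"ge_lower": float(gl), "ge_higher": float(gh),
                         "S": idx.S, "A": idx.A, "B": idx.B,
                         "R": r, "G": g, "Bch": b,
                         "state": mt.classify_state(idx)})
    table = pd.DataFrame(rows)
    return {"table": table, "reference": reference,
            "manifest": _manifest("state_map", seed, st,
                                  lower_vals=list(map(float, lower_vals)),
                                  higher_vals=list(map(float, higher_vals)),
                                  repeats=repeats, duration=duration)}


def run_staged_switch(
    seed: int = 0,
    repeats: int = 100,
    stage_ms: float = 333.0,
    scale="desk",
) -> dict:
    """Three regimes in one run: both global inhibitions off, then higher-area
    global inhibition on, then lower-area global inhibition on as well."""
    st = setup(scale, "quadrant", calibrate_slow=True)
    img = make_quadrant_stimulus(default_objects(), st.preset.grid)
    drive = compute_drive(img, st.bank)
    duration = 3 * stage_ms
    sched = [
        (0.0, {"ge_lower_amp": 0.0, "ge_higher_amp": 0.0}),
        (stage_ms, {"ge_higher_amp": F_POINT["ge_higher_amp"]}),
        (2 * stage_ms, {"ge_lower_amp": LJ_POINT["ge_lower_amp"]}),
    ]
    cfg = SimConfig(duration=duration, repeats=repeats, seed=seed, slow=_slow(st),
                    noise_sd=st.noise_sd, record=("lower_e", "higher_e"))
    rec = run(st.real, drive, cfg, schedule=sched)
    selected, others = _state_cells()
    hist = mt.psth(rec, "higher_e", cells=[selected] + others)
    stages = [(i * stage_ms, (i + 1) * stage_ms) for i in range(3)]
    return {"record": rec, "psth": hist, "stages": stages,
            "manifest": _manifest("staged_switch", seed, st,
                                  repeats=repeats, stage_ms=stage_ms)}


def _noise_drive(st: Setup, rng: np.random.Generator) -> DriveField:
    img = make_noise_stimulus(int(rng.integers(2**31)), st.preset.grid)
    return compute_drive(img, st.bank)


def run_slow_osc_series(
    variant: str,
    seed: int = 0,
    repeats: int = 100,
    scale="desk",
    duration: float = 1200.0,
    switch_ms: float = 645.0,
) -> dict:
    """The slow-oscillation protocols at the F-multiplexing point.

    A — no slow oscillation, 200 ms blank pre-stimulus; B — as A with a
    pixelated-noise pre-stimulus; C — slow oscillation restored, noise
    pre-stimulus, onset jittered uniformly over 150-250 ms; D — as C at half
    slow-oscillation amplitude; E — equal-contrast objects with the
    quadrant gains swapped at ``switch_ms`` to re-prioritise the second
    object.
    """
    if variant not in ("A", "B", "C", "D", "E"):
        raise ValueError(f"unknown slow-oscillation protocol variant {variant!r}")
    st = setup(scale, "quadrant", calibrate_slow=(variant in "CDE"))
    grid = st.preset.grid
    if variant == "E":
        img = make_quadrant_stimulus(default_objects((1.0, 1.0, 1.0)), grid)
        gains0 = {"top-left": 1.0, "bottom-right": 0.95, "top-right": 0.9}
        gains1 = {"top-left": 0.95, "bottom-right": 1.0, "top-right": 0.9}
        drive_on = compute_drive(img, st.bank, gains0)
        drive_sw = compute_drive(img, st.bank, gains1)
    else:
        img = make_quadrant_stimulus(default_objects(), grid)
        drive_on = compute_drive(img, st.bank)
        drive_sw = None

    slow_cfg = {"A": _slow(st, enabled=False), "B": _slow(st, enabled=False),
                "C": _slow(st), "D": _slow(st, scale=0.5), "E": _slow(st)}[variant]
    noise_pre = variant in "BCDE"
    jitter = variant in "CDE"

    def schedule(rep: int, rng: np.random.Generator):
        onset = float(rng.integers(150, 251)) if jitter else 200.0
        sched = [(onset, {"drive": drive_on})]
        if noise_pre:
            sched.insert(0, (0.0, {"drive": _noise_drive(st, rng)}))
        if variant == "E":
            sched.append((switch_ms, {"drive": drive_sw}))
        return sched

    base_drive = np.zeros(st.spec.layout.n_units)
    sched0 = [(0.0, dict(F_POINT))]
    cfg = SimConfig(duration=duration, repeats=repeats, seed=seed, slow=slow_cfg,
                    noise_sd=st.noise_sd, record=("lower_e", "higher_e"))
    rec = run(st.real, base_drive, cfg, schedule=sched0, schedule_fn=schedule)

    selected, others = _state_cells()
    cells = [selected] + others
    out = {"record": rec,
           "manifest": _manifest(f"slow_osc_{variant}", seed, st, repeats=repeats,
                                 duration=duration, variant=variant)}
    if variant in "AB":
        # analysed from stimulus onset: the noise pre-stimulus protocol
        # compromises selection most strongly in the early display period
        out["coincidence_fraction"] = mt.near_coincidence_fraction(
            rec, cells=cells, t_min=200.0)
    if variant in "CD":
        out["coincidence_fraction"] = mt.near_coincidence_fraction(
            rec, cells=cells, t_min=250.0 + 1000.0 / SLOW_FREQ_HZ)
        out["phase"] = mt.phase_histogram(rec, cells=cells, window=(360.0, duration))
    if variant == "E":
        out["cycles"] = cycle_counts(rec, cells, 1000.0 / SLOW_FREQ_HZ)
        out["switch_ms"] = switch_ms
    return out


def cycle_counts(rec: SpikeRecord, cells: Sequence[int], period: float) -> pd.DataFrame:
    """Higher-area spike counts per slow cycle per cell (pooled over repeats)."""
    ev = rec.events["higher_e"]
    n_cycles = int(np.floor(rec.duration / period))
    rows = []
    for k in range(n_cycles):
        t0, t1 = k * period, (k + 1) * period
        inwin = (ev["time"] >= t0) & (ev["time"] < t1)
        row = {"cycle": k, "t0": t0, "t1": t1}
        for c in cells:
            row[f"cell{c}"] = int(np.sum(inwin & (ev["cell"] == c)))
        rows.append(row)
    return pd.DataFrame(rows)


def run_multi_item(
    local_inh_tau: float = 20.0,
    seed: int = 0,
    repeats: int = 100,
    scale="desk",
    duration: float = 1200.0,
    slow_scale: float = 1.0,
) -> dict:
    """LJ-multiplexing with prolonged local inhibition in the lower area.

    With the local-inhibition decay raised from 3 ms to ~20 ms, each ensemble
    fires once per slow cycle and the network cycles through all three
    objects in contrast order; at the default 3 ms it alternates between the
    two strongest (ABA).  Onset is jittered 200 +/- 50 ms of blank screen.
    """
    st = setup(scale, "quadrant", calibrate_slow=True, ie_tau=float(local_inh_tau),
               **LJ_POINT)
    img = make_quadrant_stimulus(default_objects(), st.preset.grid)
    drive_on = compute_drive(img, st.bank)

    def schedule(rep: int, rng: np.random.Generator):
        onset = float(rng.integers(150, 251))
        return [(onset, {"drive": drive_on})]

    cfg = SimConfig(duration=duration, repeats=repeats, seed=seed,
                    noise_sd=st.noise_sd,
                    slow=_slow(st, scale=slow_scale), record=("lower_e", "higher_e"))
    rec = run(st.real, np.zeros(st.spec.layout.n_units), cfg, schedule_fn=schedule)
    selected, others = _state_cells()
    cells = [selected] + others
    phase = mt.phase_histogram(rec, cells=cells, window=(360.0, duration))
    counts = {c: len(rec.times("higher_e", cell=c)) for c in cells}
    return {"record": rec, "phase": phase, "counts": counts,
            "manifest": _manifest("multi_item", seed, st, repeats=repeats,
                                  local_inh_tau=local_inh_tau, slow_scale=slow_scale)}


CONJ_CORRECT = ("red-vertical", "blue-horizontal")


def conjunction_cells(spec: NetworkSpec) -> dict:
    """Higher-cell indices of the correct and false conjunctions for the
    canonical red-vertical + blue-horizontal stimulus."""
    lay = spec.layout
    vert = lay.orientations.index(0.0)
    horiz = lay.orientations.index(90.0)
    red = lay.colours.index("red")
    blue = lay.colours.index("blue")
    n_col = len(lay.colours)
    return {
        "red-vertical": vert * n_col + red,
        "blue-horizontal": horiz * n_col + blue,
        "blue-vertical": vert * n_col + blue,
        "red-horizontal": horiz * n_col + red,
    }


def run_conjunction(
    mode: str = "default",
    seed: int = 0,
    repeats: int = 100,
    scale="desk",
    duration: float = 1000.0,
    syn_overrides: dict | None = None,
) -> dict:
    """Feature-binding test on the conjunction network.

    ``mode`` selects the operating point: ``default`` (no global inhibition;
    false conjunctions expected), ``F`` (higher-area global inhibition) or
    ``LJ`` (lower-area global inhibition).  Reports false-conjunction spike
    counts per slow cycle and per-cell activity.
    """
    if mode not in ("default", "F", "LJ"):
        raise ValueError(f"unknown conjunction mode {mode!r}")
    st = setup(scale, "conjunction", calibrate_slow=True, **(syn_overrides or {}))
    img = make_conjunction_stimulus(default_patches(), st.preset.grid)
    drive = compute_drive(img, st.bank)
    point = {"default": {"ge_lower_amp": 0.0, "ge_higher_amp": 0.0},
             "F": dict(F_POINT), "LJ": dict(LJ_POINT)}[mode]
    cfg = SimConfig(duration=duration, repeats=repeats, seed=seed, slow=_slow(st),
                    noise_sd=st.noise_sd, record=("lower_e", "higher_e"))
    rec = run(st.real, drive, cfg, schedule=[(0.0, point)])
    cells = conjunction_cells(st.spec)
    period = 1000.0 / SLOW_FREQ_HZ
    window = (period, float(duration))
    n_cycles = mt.slow_cycle_count(rec, window)
    ev = rec.events["higher_e"]
    inwin = (ev["time"] >= window[0]) & (ev["time"] < window[1])

    def per_cycle(idx_list) -> float:
        n = np.sum(inwin & np.isin(ev["cell"], idx_list))
        return float(n) / rec.repeats / max(n_cycles, 1)

    false_cells = [cells["blue-vertical"], cells["red-horizontal"]]
    out = {
        "record": rec,
        "cells": cells,
        "false_per_cycle": per_cycle(false_cells),
        "correct_per_cycle": {name: per_cycle([cells[name]]) for name in CONJ_CORRECT},
        "S": mt.false_conjunction_S(rec, false_cells, window),
        "manifest": _manifest("conjunction", seed, st, mode=mode, repeats=repeats,
                              duration=duration),
    }
    return out


def run_robustness_sweeps(
    panel: str,
    seed: int = 0,
    repeats: int = 5,
    duration: float = 2000.0,
    scale="desk",
    amp_grid: Sequence[float] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
    tau_grid: Sequence[float] = (1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0),
) -> dict:
    """Parameter-plane sweeps on the conjunction network.

    Panels: ``A`` — lower vs higher global-inhibition amplitude at default
    parameters; ``B`` — as A with feedforward excitation reduced by the
    factor 120/135; ``C`` — as B with the global-inhibition decay constants
    reduced to 3.0 ms (lower) and 2.4 ms (higher); ``D`` — amplitude vs decay
    of higher-area global inhibition (no lower-area global inhibition,
    panel-C parameters); ``E`` — amplitude vs decay of lower-area global
    inhibition (no higher-area global inhibition, panel-C parameters).
    """
    if panel not in ("A", "B", "C", "D", "E"):
        raise ValueError(f"unknown robustness panel {panel!r}")
    overrides: dict = {}
    ff_reduction = 1.0
    if panel in "BCDE":
        ff_reduction = 120.0 / 135.0
    if panel in "CDE":
        overrides.update(ge_lower_tau=3.0, ge_higher_tau=2.4)
    st = setup(scale, "conjunction", calibrate_slow=True, **overrides)
    img = make_conjunction_stimulus(default_patches(), st.preset.grid)
    drive = compute_drive(img, st.bank)
    cells = conjunction_cells(st.spec)
    false_cells = [cells["blue-vertical"], cells["red-horizontal"]]
    selected = cells["red-vertical"]
    others = [cells["blue-horizontal"]]
    period = 1000.0 / SLOW_FREQ_HZ
    window = (period, float(duration))
    ff_amp = st.spec.syn.ff_amp * ff_reduction
    ff_colour = (st.spec.syn.ff_colour_amp or st.spec.syn.ff_amp) * ff_reduction

    if panel in ("A", "B", "C"):
        axes = [("ge_lower_amp", amp_grid), ("ge_higher_amp", amp_grid)]
    elif panel == "D":
        axes = [("ge_higher_amp", amp_grid), ("ge_higher_tau", tau_grid)]
    else:
        axes = [("ge_lower_amp", amp_grid), ("ge_lower_tau", tau_grid)]

    rows = []
    for x in axes[0][1]:
        for y in axes[1][1]:
            point = {axes[0][0]: float(x), axes[1][0]: float(y)}
            syn = replace(st.spec.syn, ff_amp=ff_amp, ff_colour_amp=ff_colour, **point)
            syn.validate()
            spec = replace(st.spec, syn=syn)
            rec = run(realize(spec), drive,
                      SimConfig(duration=duration, repeats=repeats, seed=seed,
                                noise_sd=st.noise_sd,
                                slow=_slow(st), record=("higher_e",)))
            S = mt.false_conjunction_S(rec, false_cells, window)
            A, B = mt.item_indices(rec, selected, others, window=window)
            idx = mt.StateIndices(S=S, A=A, B=B)
            r, g, b = mt.rgb_state(idx)
            rows.append({axes[0][0]: float(x), axes[1][0]: float(y),
                         "S": S, "A": A, "B": B, "R": r, "G": g, "Bch": b,
                         "state": mt.classify_state(idx)})
    table = pd.DataFrame(rows)
    return {"table": table,
            "manifest": _manifest(f"robustness_{panel}", seed, st, panel=panel,
                                  repeats=repeats, duration=duration)}
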