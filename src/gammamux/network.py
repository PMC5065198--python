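"""Network construction: cell parameters, synapse classes and wiring.

Two variants are supported.  The *quadrant* network has a higher area of 4
excitatory cells, each pooling every lower-area unit whose receptive-field
centre falls in one retinotopic quadrant.  The *conjunction* network has a
4 x 3 grid of higher cells (orientation x colour), each pooling the matching
orientation layers and the matching colour layers across the whole field.

Within the lower area: recurrent lateral excitation between same-scale
excitatory units follows a proximity x collinearity rule; a 128 x 128 sheet
of local interneurons couples to all excitatory layers with a 2-D Gaussian
profile (sigma 4 cells, identical for orientation- and colour-selective
layers); and a single "global" interneuron per area provides all-to-one /
one-to-all feedback whose amplitude is the key swept parameter.

All wiring is deterministic: a NetworkSpec fully determines the realised
connection structure without any RNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import sparse

from .stimulus import UnitLayout, COLOURS

E_EXC = 0.0    # mV, reversal of all excitatory synapses
E_INH = -75.0  # mV, reversal of all inhibitory synapses

__all__ = [
    "E_EXC",
    "E_INH",
    "CellParams",
    "EXC_CELL",
    "INH_CELL",
    "HIGHER_EXC_CELL",
    "GLOBAL_CELL",
    "SynapseParams",
    "LateralWeightParams",
    "NetworkSpec",
    "RealizedNetwork",
    "lateral_weight",
    "local_inhibition_weight",
    "build_quadrant_network",
    "build_conjunction_network",
    "realize",
]


@dataclass(frozen=True)
class CellParams:
    """Leaky integrate-and-fire parameters; tau_m = C / g_leak."""

    C: float        # pF
    g_leak: float   # nS
    E_leak: float   # mV (resting potential)
    V_th: float     # mV
    V_reset: float  # mV
    tonic_exc: float = 0.0  # nS, constant depolarising conductance

    @property
    def tau_m(self) -> float:
        return self.C / self.g_leak


EXC_CELL = CellParams(C=280.0, g_leak=17.5, E_leak=-66.0, V_th=-55.0, V_reset=-60.0)
INH_CELL = CellParams(C=50.0, g_leak=12.5, E_leak=-70.0, V_th=-40.0, V_reset=-70.0,
                      tonic_exc=7.0)
HIGHER_EXC_CELL = replace(EXC_CELL, tonic_exc=1.75)
GLOBAL_CELL = INH_CELL  # the global interneurons share the inhibitory cell parameters


@dataclass
class SynapseParams:
    """Peak per-connection amplitudes (nS) and decay time constants (ms).

    Amplitudes are the nearest-neighbour maxima, before any spatial Gaussian
    weighting.  ``ge_lower_amp`` / ``ge_higher_amp`` (global-to-excitatory)
    are the swept parameters, valid on [0, 30].
    """

    ee_amp: float = 1.2
    ee_tau: float = 2.0
    ei_amp: float = 0.68
    ei_tau: float = 2.0
    ie_amp: float = 0.62
    ie_tau: float = 3.0
    eg_amp: float = 0.1
    eg_tau: float = 2.0
    ge_lower_amp: float = 0.0
    ge_lower_tau: float = 4.0
    ff_amp: float = 0.11
    ff_tau: float = 1.0
    # conjunction variant only: amplitude of colour-channel feedforward
    # synapses (None = same as ff_amp); tuned so both input channels
    # contribute equally per burst despite unequal channel sizes
    ff_colour_amp: float | None = None
    eg_hi_amp: float = 6.0
    eg_hi_tau: float = 2.0
    ge_higher_amp: float = 0.0
    ge_higher_tau: float = 3.0

    def validate(self) -> None:
        for name in ("ge_lower_amp", "ge_higher_amp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 30.0:
                raise ValueError(f"{name}={v} outside the valid range [0, 30] nS")
        for f_ in self.__dataclass_fields__:
            v = getattr(self, f_)
            if v is None:
                continue
            if f_.endswith("_tau") and v <= 0:
                raise ValueError(f"{f_} must be positive")
            if f_.endswith("_amp") and v < 0:
                raise ValueError(f"{f_} must be non-negative")


@dataclass
class LateralWeightParams:
    """Parameters of the proximity x collinearity lateral-excitation rule.

    ``sigma_i``/``sigma_j`` (degrees) set the tolerance for the alignment of
    the connecting line with the pre-/post-synaptic orientation preference;
    ``sigma_d`` (pixels) sets the distance decay.  With
    ``formula="distance-sharpened"`` the presynaptic alignment tolerance
    tightens with distance, exp(-d (phi_i - phi_l)^2 / (2 sigma_i^2)); the
    ``"literal"`` alternative divides by distance instead,
    exp(-(phi_i - phi_l)^2 / (2 d sigma_i^2)).
    """

    sigma_i: float = 2.0
    sigma_j: float = 2.0
    sigma_d: float = 4.0
    cutoff_factor: float = 3.0  # connections beyond cutoff_factor * sigma_d dropped
    formula: Literal["distance-sharpened", "literal"] = "distance-sharpened"


def _ang_diff(a, b):
    """Orientation difference on the circular 180-degree domain."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


def lateral_weight(phi_i, phi_j, phi_l, d, params: LateralWeightParams | None = None):
    """Unnormalised lateral excitatory weight in [0, 1].

    At d = 0 the connecting-line orientation is undefined; both orientation
    factors are taken as 1 there (self-connections are excluded separately
    by the wiring code).
    """
    p = params or LateralWeightParams()
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    di = _ang_diff(phi_i, phi_l)
    dj = _ang_diff(phi_j, phi_l)
    if p.formula == "distance-sharpened":
        fi = np.exp(-d * di**2 / (2 * p.sigma_i**2))
    else:
        safe_d = np.where(d > 0, d, 1.0)
        fi = np.where(d > 0, np.exp(-(di**2) / (2 * safe_d * p.sigma_i**2)), 1.0)
    fj = np.exp(-(dj**2) / (2 * p.sigma_j**2))
    fd = np.exp(-(d**2) / (2 * p.sigma_d**2))
    return np.where(d == 0, 1.0, fi * fj * fd)


LOCAL_INH_SIGMA = 4.0  # grid cells, Gaussian spread of E<->I coupling
LOCAL_INH_CUTOFF = 12  # cells; weights beyond 3 sigma are dropped


def local_inhibition_weight(r) -> np.ndarray:
    """Spatial profile (peak 1) of local E->I and I->E coupling at grid distance r."""
    r = np.asarray(r, dtype=float)
    return np.exp(-(r**2) / (2 * LOCAL_INH_SIGMA**2))


@dataclass
class NetworkSpec:
    """Complete description of one network instance (no RNG involved)."""

    layout: UnitLayout
    variant: Literal["quadrant", "conjunction"]
    syn: SynapseParams = field(default_factory=SynapseParams)
    lateral: LateralWeightParams = field(default_factory=LateralWeightParams)
    exc: CellParams = EXC_CELL
    inh: CellParams = INH_CELL
    higher_exc: CellParams = HIGHER_EXC_CELL

    def __post_init__(self) -> None:
        self.syn.validate()
        if self.variant == "conjunction" and not self.layout.colours:
            raise ValueError("conjunction variant requires colour layers in the layout")

    @property
    def n_lower(self) -> int:
        return self.layout.n_units

    @property
    def n_higher(self) -> int:
        if self.variant == "quadrant":
            return 4
        return len(self.layout.orientations) * len(self.layout.colours)

    def higher_cell_index(self, orient: int | None = None, colour: int | None = None,
                          quadrant: int | None = None) -> int:
        if self.variant == "quadrant":
            if quadrant is None:
                raise ValueError("quadrant variant indexes higher cells by quadrant")
            return int(quadrant)
        if orient is None or colour is None:
            raise ValueError("conjunction variant indexes higher cells by (orient, colour)")
        return int(orient) * len(self.layout.colours) + int(colour)


def build_quadrant_network(grid: int = 128, n_scales: int = 4, **overrides) -> NetworkSpec:
    """Quadrant-selective two-area network (4 higher cells)."""
    layout = UnitLayout(grid, n_scales)
    syn = overrides.pop("syn", SynapseParams(**{k: overrides.pop(k) for k in list(overrides)
                                                if k in SynapseParams.__dataclass_fields__}))
    return NetworkSpec(layout=layout, variant="quadrant", syn=syn, **overrides)


def build_conjunction_network(grid: int = 128, n_scales: int = 4, **overrides) -> NetworkSpec:
    """Feature-conjunction two-area network (4 orientations x 3 colours = 12 higher cells)."""
    layout = UnitLayout(grid, n_scales, colours=COLOURS)
    syn = overrides.pop("syn", SynapseParams(**{k: overrides.pop(k) for k in list(overrides)
                                                if k in SynapseParams.__dataclass_fields__}))
    return NetworkSpec(layout=layout, variant="conjunction", syn=syn, **overrides)


# --------------------------------------------------------------------------
# realisation: the structures the simulation engine consumes
# --------------------------------------------------------------------------

def _lateral_matrix(layout: UnitLayout, scale: int, orient: int,
                    params: LateralWeightParams) -> sparse.csr_matrix:
    """Same-orientation lateral weights over one scale's position grid.

    Entries are in [0, 1] (amplitude applied by the engine); the diagonal is
    zero (d = 0 coupling is handled by the same-position term, cross-layer).
    Distances are measured in base-sheet pixels (unit spacing 2**scale px);
    the connecting-line orientation phi_l = atan2(dc, dr) so that a purely
    vertical displacement is 0 degrees, matching the stimulus convention.
    """
    side = layout.sides[scale]
    step = 1 << scale
    reach = int(np.floor(params.cutoff_factor * params.sigma_d / step))
    offs = []
    for dr in range(-reach, reach + 1):
        for dc in range(-reach, reach + 1):
            if dr == 0 and dc == 0:
                continue
            d = np.hypot(dr, dc) * step
            if d > params.cutoff_factor * params.sigma_d:
                continue
            phi_l = np.degrees(np.arctan2(dc, dr)) % 180.0
            phi = layout.orientations[orient]
            w = float(lateral_weight(phi, phi, phi_l, d, params))
            if w > 1e-7:
                offs.append((dr, dc, w))
    n = side * side
    if not offs:
        return sparse.csr_matrix((n, n))
    rows, cols, vals = [], [], []
    r, c = np.mgrid[0:side, 0:side]
    r, c = r.ravel(), c.ravel()
    for dr, dc, w in offs:
        rr, cc = r + dr, c + dc
        ok = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < side)
        rows.append((r * side + c)[ok])
        cols.append((rr * side + cc)[ok])
        vals.append(np.full(ok.sum(), w))
    m = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(cols), np.concatenate(rows))),
        shape=(n, n),
    )
    return m.tocsr()


@dataclass
class RealizedNetwork:
    """Deterministic connection structures derived from a NetworkSpec."""

    spec: NetworkSpec
    lateral: dict            # (scale, orient) -> csr over positions, weights in [0,1]
    gauss_kernel_1d: np.ndarray  # separable local-inhibition profile, peak 1
    ff_labels: np.ndarray    # quadrant variant: quadrant per lower unit
    orient_channel: np.ndarray
    colour_channel: np.ndarray

    def higher_afferent_mask(self, cell: int) -> np.ndarray:
        """Boolean mask of the lower units feeding one higher cell."""
        spec = self.spec
        lay = spec.layout
        if spec.variant == "quadrant":
            return lay.quadrant == cell
        orient, colour = divmod(cell, len(lay.colours))
        return (self.orient_channel == orient) | (self.colour_channel == colour)


def realize(spec: NetworkSpec) -> RealizedNetwork:
    lay = spec.layout
    lateral = {
        (s, o): _lateral_matrix(lay, s, o, spec.lateral)
        for s in range(lay.n_scales)
        for o in range(len(lay.orientations))
    }
    x = np.arange(-LOCAL_INH_CUTOFF, LOCAL_INH_CUTOFF + 1, dtype=float)
    gauss = np.exp(-(x**2) / (2 * LOCAL_INH_SIGMA**2))
    return RealizedNetwork(
        spec=spec,
        lateral=lateral,
        gauss_kernel_1d=gauss,
        ff_labels=lay.quadrant.copy(),
        orient_channel=lay.orientation_channel.copy(),
        colour_channel=lay.colour_channel.copy(),
    )
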