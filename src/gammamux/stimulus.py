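"""Synthetic visual stimuli and the retinotopic Gabor/colour filter frontend.

The lower network area is a bank of "simple cell" layers: 4 orientation
preferences x 4 spatial phases x several spatial scales, each layer a
retinotopic grid whose side halves (and receptive-field size doubles) at
every scale step.  A stimulus image is converted to a per-cell constant
excitatory conductance (the *drive*) by correlating it with each cell's
Gabor receptive field, half-wave rectifying, and scaling so that the
optimally driven cell for a full-contrast reference object receives
exactly ``DRIVE_CEILING_NS`` (7.5 nS) at gain 1.

For the feature-conjunction network the bank additionally carries
colour-selective layers (red/green/blue), duplicated across scales but
without orientation selectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

QUADRANTS = ("top-left", "top-right", "bottom-left", "bottom-right")
COLOURS = ("red", "green", "blue")
BACKGROUND = 0.5
DRIVE_CEILING_NS = 7.5

__all__ = [
    "QUADRANTS",
    "COLOURS",
    "BACKGROUND",
    "DRIVE_CEILING_NS",
    "StimulusImage",
    "ObjectSpec",
    "PatchSpec",
    "UnitLayout",
    "GaborBank",
    "DriveField",
    "default_object_shape",
    "make_quadrant_stimulus",
    "make_noise_stimulus",
    "make_conjunction_stimulus",
    "build_gabor_bank",
    "compute_drive",
    "save_image_png",
    "load_image_png",
]


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------

@dataclass
class StimulusImage:
    """A square luminance image in [0, 1], optionally with RGB colour planes.

    ``luminance`` drives the orientation-selective layers; ``planes`` (shape
    ``(3, side, side)``, one per colour channel) drives the colour-selective
    layers of the conjunction network.  A blank screen is uniformly 0.5.
    """

    luminance: np.ndarray
    planes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.luminance = np.asarray(self.luminance, dtype=float)
        if self.luminance.ndim != 2 or self.luminance.shape[0] != self.luminance.shape[1]:
            raise ValueError("luminance must be a square 2-D array")
        if self.luminance.min() < -1e-12 or self.luminance.max() > 1 + 1e-12:
            raise ValueError("luminance values must lie in [0, 1]")
        if self.planes is not None:
            self.planes = np.asarray(self.planes, dtype=float)
            if self.planes.shape != (3,) + self.luminance.shape:
                raise ValueError("planes must have shape (3, side, side)")
            if self.planes.min() < -1e-12 or self.planes.max() > 1 + 1e-12:
                raise ValueError("colour plane values must lie in [0, 1]")

    @property
    def side(self) -> int:
        return self.luminance.shape[0]


def _nearest_odd(x: float) -> int:
    # round to the nearest odd integer, never below 3
    return max(3, 2 * int(round((x - 1) / 2)) + 1)


def default_object_shape(grid: int) -> tuple[int, int]:
    """(height, width) of the rectangle object, scaled from 39 x 9 px at grid 128."""
    return _nearest_odd(39 * grid / 128), _nearest_odd(9 * grid / 128)


@dataclass(frozen=True)
class ObjectSpec:
    """A light rectangle with a single-pixel dark outline, confined to a quadrant.

    Contrast ``c`` maps interior luminance to ``0.5 + 0.5 c`` and the outline
    to ``0.5 - 0.5 c`` (symmetric deviation from the mid-gray background).
    """

    quadrant: str
    contrast: float
    shape: tuple[int, int] | None = None  # (height, width); default scales with grid

    def __post_init__(self) -> None:
        if self.quadrant not in QUADRANTS:
            raise ValueError(f"unknown quadrant {self.quadrant!r}")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")


def _quadrant_origin(quadrant: str, grid: int) -> tuple[int, int]:
    half = grid // 2
    return {
        "top-left": (0, 0),
        "top-right": (0, half),
        "bottom-left": (half, 0),
        "bottom-right": (half, half),
    }[quadrant]


def make_quadrant_stimulus(objects: Sequence[ObjectSpec], grid: int = 128) -> StimulusImage:
    """Render rectangle objects (at most one per quadrant) on a mid-gray field."""
    seen: set[str] = set()
    img = np.full((grid, grid), BACKGROUND)
    half = grid // 2
    for obj in objects:
        if obj.quadrant in seen:
            raise ValueError(f"more than one object in quadrant {obj.quadrant!r}")
        seen.add(obj.quadrant)
        h, w = obj.shape if obj.shape is not None else default_object_shape(grid)
        if h > half or w > half:
            raise ValueError(f"object of shape {(h, w)} overflows its {half}x{half} quadrant")
        qr, qc = _quadrant_origin(obj.quadrant, grid)
        r0 = qr + (half - h) // 2
        c0 = qc + (half - w) // 2
        c = obj.contrast
        img[r0 : r0 + h, c0 : c0 + w] = BACKGROUND - 0.5 * c  # outline
        img[r0 + 1 : r0 + h - 1, c0 + 1 : c0 + w - 1] = BACKGROUND + 0.5 * c
    return StimulusImage(img)


def make_noise_stimulus(seed: int, grid: int = 128) -> StimulusImage:
    """Pixelated white noise: independent per-pixel uniform values on [0, 1]."""
    rng = np.random.default_rng(seed)
    return StimulusImage(rng.uniform(0.0, 1.0, size=(grid, grid)))


@dataclass(frozen=True)
class PatchSpec:
    """A striped colour/orientation patch for the conjunction network."""

    colour: str
    orientation: float  # degrees; 0 = vertical stripes, 90 = horizontal
    contrast: float
    quadrant: str

    def __post_init__(self) -> None:
        if self.colour not in COLOURS:
            raise ValueError(f"unknown colour tag {self.colour!r}")
        if self.quadrant not in QUADRANTS:
            raise ValueError(f"unknown quadrant {self.quadrant!r}")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")


def make_conjunction_stimulus(
    patches: Sequence[PatchSpec], grid: int = 128, stripe_period: int = 4
) -> StimulusImage:
    """Render oriented colour-grating patches into luminance and colour planes.

    Within a square patch, "on" stripes take luminance ``0.5 + 0.5 c`` and the
    tagged colour plane follows; "off" stripes take luminance ``0.5 - 0.5 c``.
    Both orientation- and colour-selective layers are thereby driven.
    """
    lum = np.full((grid, grid), BACKGROUND)
    planes = np.full((3, grid, grid), BACKGROUND)
    side = _nearest_odd(39 * grid / 128)
    half = grid // 2
    if side > half:
        side = half if half % 2 == 1 else half - 1
    for patch in patches:
        qr, qc = _quadrant_origin(patch.quadrant, grid)
        r0 = qr + (half - side) // 2
        c0 = qc + (half - side) // 2
        rows, cols = np.mgrid[0:side, 0:side]
        theta = np.deg2rad(patch.orientation)
        u = cols * np.cos(theta) + rows * np.sin(theta)
        on = (np.floor(u) % stripe_period) < stripe_period / 2
        c = patch.contrast
        block = np.where(on, BACKGROUND + 0.5 * c, BACKGROUND - 0.5 * c)
        lum[r0 : r0 + side, c0 : c0 + side] = block
        k = COLOURS.index(patch.colour)
        plane = planes[k, r0 : r0 + side, c0 : c0 + side]
        planes[k, r0 : r0 + side, c0 : c0 + side] = np.where(on, BACKGROUND + 0.5 * c, plane)
    return StimulusImage(lum, planes)


# --------------------------------------------------------------------------
# unit layout
# --------------------------------------------------------------------------

class UnitLayout:
    """Flat indexing of all lower-area excitatory units.

    Orientation-selective units come first, ordered by
    ``(scale, orientation, phase, row, col)``; colour-selective units (if any)
    follow, ordered by ``(scale, colour, row, col)``.  Each unit's receptive
    field centre is mapped onto the base sheet (the ``grid x grid`` inhibitory
    lattice) by centre-aligned upsampling: a unit at coarse position ``r`` of
    scale ``s`` sits at base coordinate ``(r + 1/2) * 2**s - 1/2``.
    """

    def __init__(
        self,
        grid: int = 128,
        n_scales: int = 4,
        orientations: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
        n_phases: int = 4,
        colours: Sequence[str] = (),
    ):
        if grid % (1 << (n_scales - 1)) != 0:
            raise ValueError("grid side must be divisible by 2**(n_scales-1)")
        self.grid = grid
        self.n_scales = n_scales
        self.orientations = tuple(float(o) for o in orientations)
        self.n_phases = n_phases
        self.colours = tuple(colours)
        self.sides = tuple(grid >> s for s in range(n_scales))

        scale_l, orient_l, colour_l, row_l, col_l = [], [], [], [], []
        for s, side in enumerate(self.sides):
            r, c = np.mgrid[0:side, 0:side]
            n = side * side
            for oi in range(len(self.orientations)):
                for _p in range(n_phases):
                    scale_l.append(np.full(n, s))
                    orient_l.append(np.full(n, oi))
                    colour_l.append(np.full(n, -1))
                    row_l.append(r.ravel())
                    col_l.append(c.ravel())
        for s, side in enumerate(self.sides):
            r, c = np.mgrid[0:side, 0:side]
            n = side * side
            for k in range(len(self.colours)):
                scale_l.append(np.full(n, s))
                orient_l.append(np.full(n, -1))
                colour_l.append(np.full(n, k))
                row_l.append(r.ravel())
                col_l.append(c.ravel())

        self.scale = np.concatenate(scale_l)
        self.orientation_channel = np.concatenate(orient_l)
        self.colour_channel = np.concatenate(colour_l)
        self.row = np.concatenate(row_l)
        self.col = np.concatenate(col_l)

        step = (1 << self.scale).astype(float)
        self.base_row = (self.row + 0.5) * step - 0.5
        self.base_col = (self.col + 0.5) * step - 0.5
        self.sheet_row = np.clip(np.round(self.base_row).astype(int), 0, grid - 1)
        self.sheet_col = np.clip(np.round(self.base_col).astype(int), 0, grid - 1)
        self.sheet_flat = self.sheet_row * grid + self.sheet_col

        top = self.base_row < grid / 2
        left = self.base_col < grid / 2
        # quadrant index follows the QUADRANTS tuple ordering
        self.quadrant = np.where(top, np.where(left, 0, 1), np.where(left, 2, 3))

    @property
    def n_orient_units(self) -> int:
        return len(self.orientations) * self.n_phases * sum(s * s for s in self.sides)

    @property
    def n_colour_units(self) -> int:
        return len(self.colours) * sum(s * s for s in self.sides)

    @property
    def n_units(self) -> int:
        return self.n_orient_units + self.n_colour_units

    def block(self, scale: int, orient: int, phase: int) -> slice:
        """Flat slice of one orientation layer (one scale/orientation/phase grid)."""
        start = 0
        for s in range(scale):
            start += self.sides[s] ** 2 * len(self.orientations) * self.n_phases
        n = self.sides[scale] ** 2
        start += (orient * self.n_phases + phase) * n
        return slice(start, start + n)

    def colour_block(self, scale: int, colour: int) -> slice:
        start = self.n_orient_units
        for s in range(scale):
            start += self.sides[s] ** 2 * len(self.colours)
        n = self.sides[scale] ** 2
        start += colour * n
        return slice(start, start + n)


# --------------------------------------------------------------------------
# Gabor bank
# --------------------------------------------------------------------------

def _gabor_kernel(side: int, theta_deg: float, phase_deg: float,
                  sigma_factor: float = 0.25, wavelength_factor: float = 0.5) -> np.ndarray:
    """One zero-mean Gabor kernel; sigma/wavelength are fractions of the side.

    Orientation 0 means a carrier varying along the column axis (the cell
    prefers vertical stripes/edges); the DC component is removed with an
    envelope-weighted correction so uniform images yield exactly zero drive.
    """
    c = (side - 1) / 2
    rows, cols = np.mgrid[0:side, 0:side] - c
    theta = np.deg2rad(theta_deg)
    u = cols * np.cos(theta) + rows * np.sin(theta)
    env = np.exp(-(rows**2 + cols**2) / (2 * (side * sigma_factor) ** 2))
    g = env * np.cos(2 * np.pi * u / (side * wavelength_factor) + np.deg2rad(phase_deg))
    g -= env * (g.sum() / env.sum())
    # unit L1 norm: equal contrast sensitivity at every scale, so the
    # response to an optimal full-contrast pattern is scale-invariant
    return g / np.abs(g).sum()


@dataclass
class GaborBank:
    """Receptive-field kernels for every (scale, orientation, phase) layer.

    ``norm`` (and ``colour_norm``) convert raw rectified filter responses to
    conductances in nS; they are fixed once per bank so the optimal unit for
    the bank's full-contrast reference stimulus reaches 7.5 nS at gain 1.
    """

    layout: UnitLayout
    base_kernel_side: int = 9
    sigma_factor: float = 0.25
    wavelength_factor: float = 0.5
    response_exponent: float = 1.0
    phases: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    kernels: dict = field(default_factory=dict, repr=False)
    colour_sigmas: tuple[float, ...] = ()
    ref_max: float = 1.0         # raw response of the optimally driven unit
    colour_ref_max: float = 1.0  # ... for the colour channel

    def kernel(self, scale: int, orient: int, phase: int) -> np.ndarray:
        return self.kernels[(scale, orient, phase)]


def _raw_drive(image: StimulusImage, bank: GaborBank) -> np.ndarray:
    """Rectified filter responses for every unit, before normalisation/gain."""
    lay = bank.layout
    if image.side != lay.grid:
        raise ValueError(f"image side {image.side} does not match bank grid {lay.grid}")
    lum = image.luminance - BACKGROUND
    out = np.zeros(lay.n_units)
    for s in range(lay.n_scales):
        side = lay.sides[s]
        idx = np.clip(np.round((np.arange(side) + 0.5) * (1 << s) - 0.5).astype(int), 0, lay.grid - 1)
        for oi in range(len(lay.orientations)):
            for pi in range(lay.n_phases):
                resp = ndimage.correlate(lum, bank.kernel(s, oi, pi), mode="constant")
                out[lay.block(s, oi, pi)] = np.maximum(resp[np.ix_(idx, idx)], 0.0).ravel()
    if lay.colours:
        if image.planes is None:
            planes = np.zeros((3, lay.grid, lay.grid))
        else:
            planes = np.clip(image.planes - BACKGROUND, 0.0, None)
        for s in range(lay.n_scales):
            side = lay.sides[s]
            idx = np.clip(np.round((np.arange(side) + 0.5) * (1 << s) - 0.5).astype(int), 0, lay.grid - 1)
            sigma = bank.colour_sigmas[s]
            for k, name in enumerate(lay.colours):
                blurred = ndimage.gaussian_filter(planes[COLOURS.index(name)], sigma, mode="constant")
                out[lay.colour_block(s, k)] = blurred[np.ix_(idx, idx)].ravel()
    return out


def _reference_stimulus(layout: UnitLayout) -> StimulusImage:
    if layout.colours:
        return make_conjunction_stimulus([PatchSpec("red", 0.0, 1.0, "top-left")], layout.grid)
    return make_quadrant_stimulus([ObjectSpec("top-left", 1.0)], layout.grid)


def build_gabor_bank(
    grid: int = 128,
    n_scales: int = 4,
    colour: bool = False,
    base_kernel_side: int = 9,
    sigma_factor: float = 0.25,
    wavelength_factor: float = 0.5,
    response_exponent: float = 1.0,
) -> GaborBank:
    """Construct (and normalise) the filter bank for the given geometry."""
    layout = UnitLayout(grid, n_scales, colours=COLOURS if colour else ())
    bank = GaborBank(layout=layout, base_kernel_side=base_kernel_side,
                     sigma_factor=sigma_factor, wavelength_factor=wavelength_factor,
                     response_exponent=response_exponent)
    for s in range(n_scales):
        side = base_kernel_side * (1 << s)
        if side % 2 == 0:
            side += 1  # odd support keeps the kernel centred
        for oi, theta in enumerate(layout.orientations):
            for pi, ph in enumerate(bank.phases):
                bank.kernels[(s, oi, pi)] = _gabor_kernel(side, theta, ph,
                                                          sigma_factor, wavelength_factor)
    if colour:
        bank.colour_sigmas = tuple(
            (base_kernel_side * (1 << s)) / 4 for s in range(n_scales)
        )
    # fix the nS normalisation against the full-contrast reference stimulus
    raw = _raw_drive(_reference_stimulus(layout), bank)
    bank.ref_max = raw[: layout.n_orient_units].max()
    if colour:
        bank.colour_ref_max = raw[layout.n_orient_units :].max()
    return bank


# --------------------------------------------------------------------------
# drive
# --------------------------------------------------------------------------

@dataclass
class DriveField:
    """Per-unit constant stimulus-driven excitatory conductance (nS)."""

    values: np.ndarray
    layout: UnitLayout

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.layout.n_units,):
            raise ValueError("drive length does not match layout")
        if self.values.min() < 0:
            raise ValueError("drive must be non-negative")


def compute_drive(
    image: StimulusImage,
    bank: GaborBank,
    gains: Sequence[float] | dict | None = None,
) -> DriveField:
    """Filter an image through the bank and scale by per-quadrant gains.

    ``gains`` may be a mapping from quadrant name to gain or a sequence in
    ``QUADRANTS`` order; default is gain 1 everywhere.
    """
    lay = bank.layout
    if gains is None:
        gain_arr = np.ones(4)
    elif isinstance(gains, dict):
        gain_arr = np.array([gains.get(q, 1.0) for q in QUADRANTS], dtype=float)
    else:
        gain_arr = np.asarray(gains, dtype=float)
        if gain_arr.shape != (4,):
            raise ValueError("gains sequence must have length 4 (QUADRANTS order)")
    raw = _raw_drive(image, bank)
    gamma = bank.response_exponent
    out = np.empty_like(raw)
    o = slice(0, lay.n_orient_units)
    out[o] = DRIVE_CEILING_NS * (raw[o] / bank.ref_max) ** gamma
    if lay.colours:
        c = slice(lay.n_orient_units, lay.n_units)
        out[c] = DRIVE_CEILING_NS * (raw[c] / bank.colour_ref_max) ** gamma
    return DriveField(out * gain_arr[lay.quadrant], lay)


# --------------------------------------------------------------------------
# image serialisation
# --------------------------------------------------------------------------

def save_image_png(image: StimulusImage, path) -> None:
    """Write a stimulus as an 8-bit PNG (grayscale, or RGB if colour planes)."""
    import imageio.v3 as iio

    if image.planes is not None:
        arr = np.moveaxis(image.planes, 0, -1)
    else:
        arr = image.luminance
    iio.imwrite(path, np.round(arr * 255).astype(np.uint8))


def load_image_png(path) -> StimulusImage:
    """Read a stimulus image written by :func:`save_image_png`."""
    import imageio.v3 as iio

    arr = iio.imread(path).astype(float) / 255.0
    if arr.ndim == 3:
        planes = np.moveaxis(arr[..., :3], -1, 0)
        return StimulusImage(planes.mean(axis=0), planes)
    return StimulusImage(arr)
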