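"""2D simplified head geometry and focused-transducer source construction.

The model is a brain disc surrounded by a concentric skull annulus,
immersed in a water background.  The beam propagates along +x; the
transducer axis is the horizontal line through the head centre.  Pixel
centres sit at ``(i + 0.5) * dx`` from the grid corner.

All masks are built from *half-pixel integer offsets* relative to the
head centre / transducer axis so that mirror symmetry about the axis is
bit-exact, and circle radii are quantised to whole pixels so that the
skull annulus is exactly ``round(skull_thickness / dx)`` pixels wide
along the axis transect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np

from tfusim.errors import BoundsError, GeometryError

#: integer labels of the three media
WATER, SKULL, BRAIN = 0, 1, 2

LABEL_NAMES = {WATER: "water", SKULL: "skull", BRAIN: "brain"}


@dataclass(frozen=True)
class MediumProperties:
    """Acoustic properties of one medium."""

    sound_speed: float  # m/s
    density: float  # kg/m^3
    alpha0: float  # absorption constant, dB/(MHz.cm)

    def __post_init__(self):
        if self.sound_speed <= 0 or self.density <= 0:
            raise GeometryError("sound_speed and density must be strictly positive")
        if self.alpha0 < 0:
            raise GeometryError("alpha0 must be non-negative")


#: default media property table (water / skull / brain)
DEFAULT_MEDIA: Dict[str, MediumProperties] = {
    "water": MediumProperties(sound_speed=1481.0, density=998.0, alpha0=0.002),
    "skull": MediumProperties(sound_speed=2820.0, density=1732.0, alpha0=7.75),
    "brain": MediumProperties(sound_speed=1500.0, density=1000.0, alpha0=0.8),
}


@dataclass(frozen=True)
class HeadGeometryConfig:
    """Grid, head and transducer geometry (SI units throughout)."""

    grid_nx: int = 561
    grid_ny: int = 561
    dx: float = 0.5e-3
    brain_outer_radius: float = 85.0e-3  # outer skull radius
    skull_thickness: float = 5.4e-3
    standoff: float = 40.0e-3  # arc apex -> outer skull boundary, on axis
    transducer_aperture: float = 64.0e-3
    transducer_roc: float = 63.2e-3  # radius of curvature (focal distance)
    source_frequency: float = 250.0e3
    source_amplitude: float = 100.0e3
    points_per_wavelength: float = 4.0
    head_center: Optional[Tuple[float, float]] = None  # derived when None
    apex_margin: float = 15.0e-3  # water gap left of the arc apex

    def __post_init__(self):
        if self.skull_thickness < 0:
            raise GeometryError("skull_thickness must be >= 0")
        if self.skull_thickness > self.brain_outer_radius:
            raise GeometryError("skull_thickness exceeds brain_outer_radius")
        if self.standoff <= 0:
            raise GeometryError("standoff must be > 0")
        if self.dx <= 0 or self.grid_nx < 4 or self.grid_ny < 4:
            raise GeometryError("invalid grid discretisation")

    # -- derived coordinates -------------------------------------------------

    @property
    def axis_y(self) -> float:
        """Lateral coordinate of the transducer axis (grid mid-height)."""
        return 0.5 * self.grid_ny * self.dx

    @property
    def apex_x(self) -> float:
        """Axial coordinate of the transducer arc apex."""
        return self.apex_margin

    @property
    def focus_x(self) -> float:
        """Geometric focus of the curved transducer."""
        return self.apex_x + self.transducer_roc

    def resolved_head_center(self) -> Tuple[float, float]:
        if self.head_center is not None:
            return self.head_center
        xc = self.apex_x + self.standoff + self.brain_outer_radius
        return (xc, self.axis_y)

    def max_wavelength_dx(self, min_sound_speed: float) -> float:
        """Largest dx resolving the configured points-per-wavelength."""
        return min_sound_speed / (self.source_frequency * self.points_per_wavelength)

    def with_skull(self, skull_thickness: float) -> "HeadGeometryConfig":
        return replace(self, skull_thickness=skull_thickness)


@dataclass
class MediumMap:
    """Per-pixel labels and acoustic property rasters on the 2D grid.

    Arrays are indexed ``[i, j]`` with axis 0 = x (beam direction) and
    axis 1 = y (lateral).
    """

    labels: np.ndarray  # int, (nx, ny)
    sound_speed: np.ndarray  # m/s
    density: np.ndarray  # kg/m^3
    alpha0: np.ndarray  # dB/(MHz.cm)
    dx: float
    origin: Tuple[float, float] = (0.0, 0.0)
    head_center: Optional[Tuple[float, float]] = None
    brain_radius: Optional[float] = None  # quantised inner (brain) radius
    outer_radius: Optional[float] = None  # quantised outer (skull) radius

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["dx"] = self.dx
            f.attrs["origin"] = self.origin
            if self.head_center is not None:
                f.attrs["head_center"] = self.head_center
            for name in ("labels", "sound_speed", "density", "alpha0"):
                f.create_dataset(name, data=getattr(self, name))

    @classmethod
    def from_hdf5(cls, path) -> "MediumMap":
        import h5py

        with h5py.File(path, "r") as f:
            hc = f.attrs.get("head_center")
            return cls(
                labels=f["labels"][...],
                sound_speed=f["sound_speed"][...],
                density=f["density"][...],
                alpha0=f["alpha0"][...],
                dx=float(f.attrs["dx"]),
                origin=tuple(f.attrs["origin"]),
                head_center=tuple(hc) if hc is not None else None,
            )


@dataclass
class SourceDefinition:
    """Pixel mask and drive of the transducer.

    ``amplitude`` is the per-pixel surface-pressure amplitude in Pa; for
    the curved source it is the nominal drive amplitude weighted by the
    arc length crossing each pixel (in units of dx), which makes the
    radiated field converge under grid refinement.  ``mode`` selects a
    soft (additive, default) or hard (Dirichlet) injection.
    """

    mask: np.ndarray  # bool, (nx, ny)
    amplitude: np.ndarray  # Pa per pixel (zero off-mask)
    frequency: float  # Hz
    on_time: float  # s
    total_time: float  # s
    mode: str = "soft"
    normal_x2: Optional[np.ndarray] = None  # squared x-component of the
    normal_y2: Optional[np.ndarray] = None  # local propagation normal
    ramp_cycles: float = 5.0  # raised-cosine startup ramp (suppresses
    # the broadband switch-on transient that would pollute max|p| maps)

    def __post_init__(self):
        if self.on_time > self.total_time + 1e-15:
            raise GeometryError("on_time exceeds total_time")
        if self.mode not in ("soft", "hard"):
            raise GeometryError(f"unknown source mode {self.mode!r}")


# ---------------------------------------------------------------------------
# helpers


def _lateral_offsets(ny: int, dx: float) -> np.ndarray:
    """Signed lateral offsets of pixel centres from the grid mid-height.

    Half-pixel integers make the offsets of rows j and ny-1-j exact
    negatives of each other, so every derived mask is bit-mirror-
    symmetric about the transducer axis.
    """
    return (2 * np.arange(ny) + 1 - ny).astype(np.float64) * (0.5 * dx)


def _axial_offsets(nx: int, x0: float, dx: float) -> np.ndarray:
    """Axial offsets of pixel centres from continuous coordinate x0."""
    return (np.arange(nx) + 0.5) * dx - x0


# ---------------------------------------------------------------------------
# operations


def build_head_map(
    geometry: HeadGeometryConfig,
    media: Optional[Dict[str, MediumProperties]] = None,
) -> MediumMap:
    """Label the grid as water / skull / brain and fill property rasters.

    The head centre is snapped to the nearest pixel centre and both
    circle radii are quantised to whole-pixel multiples, so the skull
    annulus is exactly ``round(skull_thickness/dx)`` pixels wide along
    the axis transect.
    """
    media = dict(DEFAULT_MEDIA if media is None else media)
    for key in ("water", "skull", "brain"):
        if key not in media:
            raise GeometryError(f"media table is missing an entry for {key!r}")

    nx, ny, dx = geometry.grid_nx, geometry.grid_ny, geometry.dx
    xc, yc = geometry.resolved_head_center()

    # snap the centre to a pixel centre (x) / the grid mid-height (y)
    ci = int(round(xc / dx - 0.5))
    xc_snap = (ci + 0.5) * dx

    r_outer_px = int(round(geometry.brain_outer_radius / dx))
    t_px = int(round(geometry.skull_thickness / dx))
    r_brain_px = r_outer_px - t_px
    r_outer = r_outer_px * dx
    r_brain = r_brain_px * dx

    if xc_snap - r_outer < 0 or xc_snap + r_outer > nx * dx:
        raise BoundsError("head extends beyond the grid in x")
    if r_outer > 0.5 * ny * dx:
        raise BoundsError("head extends beyond the grid in y")

    ax = _axial_offsets(nx, xc_snap, dx)[:, None]
    lat = _lateral_offsets(ny, dx)[None, :]
    r2 = ax * ax + lat * lat

    labels = np.full((nx, ny), WATER, dtype=np.int8)
    labels[r2 <= r_outer * r_outer + 1e-18] = SKULL
    labels[r2 <= r_brain * r_brain + 1e-18] = BRAIN

    prop = {name: np.empty((nx, ny)) for name in ("sound_speed", "density", "alpha0")}
    for lbl, name in LABEL_NAMES.items():
        m = labels == lbl
        for p in prop:
            prop[p][m] = getattr(media[name], p)

    return MediumMap(
        labels=labels,
        dx=dx,
        head_center=(xc_snap, geometry.axis_y),
        brain_radius=r_brain,
        outer_radius=r_outer,
        **prop,
    )


def build_water_map(
    geometry: HeadGeometryConfig,
    media: Optional[Dict[str, MediumProperties]] = None,
) -> MediumMap:
    """All-water map on the same grid (free-field calibration runs)."""
    media = dict(DEFAULT_MEDIA if media is None else media)
    w = media["water"]
    nx, ny = geometry.grid_nx, geometry.grid_ny
    return MediumMap(
        labels=np.full((nx, ny), WATER, dtype=np.int8),
        sound_speed=np.full((nx, ny), w.sound_speed),
        density=np.full((nx, ny), w.density),
        alpha0=np.full((nx, ny), w.alpha0),
        dx=geometry.dx,
    )


def build_transducer_source(
    geometry: HeadGeometryConfig,
    duty_cycle: float,
    window: float,
) -> SourceDefinition:
    """Curved-arc source mask with a gated sinusoidal drive.

    The arc is the set of pixels within half a pixel of the circle of
    radius ``transducer_roc`` centred on the geometric focus, restricted
    to the transducer side (x < focus) and to the configured aperture.
    ``on_time = duty_cycle * window``.
    """
    if not 0.0 < duty_cycle <= 1.0:
        raise GeometryError("duty_cycle must be in (0, 1]")
    if window <= 0:
        raise GeometryError("window must be > 0")

    nx, ny, dx = geometry.grid_nx, geometry.grid_ny, geometry.dx
    roc = geometry.transducer_roc
    half_ap = 0.5 * geometry.transducer_aperture

    # accumulate the arc length crossing each pixel; one lateral side is
    # rasterised and mirrored so the weights are bit-mirror-symmetric
    theta_max = math.asin(min(half_ap / roc, 1.0))
    ds = dx / 32.0
    n_half = max(int(math.ceil(theta_max * roc / ds)), 2)
    theta = (np.arange(n_half) + 0.5) * (theta_max / n_half)
    seg = theta_max * roc / n_half  # arc length per sample
    xs = geometry.focus_x - roc * np.cos(theta)
    ys_off = roc * np.sin(theta)  # lateral offset from the axis, one side

    ii = np.floor(xs / dx).astype(np.int64)
    jj_hi = np.floor(0.5 * ny + ys_off / dx).astype(np.int64)  # upper side
    jj_lo = ny - 1 - jj_hi  # mirrored side

    weights = np.zeros((nx, ny))
    wx2 = np.zeros((nx, ny))
    wy2 = np.zeros((nx, ny))
    ok = (ii >= 0) & (ii < nx) & (jj_hi >= 0) & (jj_hi < ny)
    if not ok.all():
        raise BoundsError("transducer arc does not fit in the grid")
    w = seg / dx
    cos2 = np.cos(theta) ** 2
    sin2 = 1.0 - cos2
    for jj in (jj_hi, jj_lo):
        np.add.at(weights, (ii, jj), w)
        np.add.at(wx2, (ii, jj), w * cos2)
        np.add.at(wy2, (ii, jj), w * sin2)

    mask = weights > 0.0
    with np.errstate(invalid="ignore"):
        normal_x2 = np.where(mask, wx2 / np.where(mask, weights, 1.0), 0.5)
        normal_y2 = np.where(mask, wy2 / np.where(mask, weights, 1.0), 0.5)

    if not mask.any():
        raise BoundsError("transducer arc does not intersect the grid")
    ii = np.where(mask.any(axis=1))[0]
    if ii[0] == 0 or ii[-1] == nx - 1:
        raise BoundsError("transducer arc touches the grid boundary in x")
    jj = np.where(mask.any(axis=0))[0]
    if jj[0] == 0 or jj[-1] == ny - 1:
        raise BoundsError("transducer arc touches the grid boundary in y")

    amplitude = geometry.source_amplitude * weights
    return SourceDefinition(
        mask=mask,
        amplitude=amplitude,
        frequency=geometry.source_frequency,
        on_time=duty_cycle * window,
        total_time=window,
        mode="soft",
        normal_x2=normal_x2,
        normal_y2=normal_y2,
    )


def build_line_source(
    geometry: HeadGeometryConfig,
    x_position: float,
    duty_cycle: float = 1.0,
    window: float = 500e-6,
    amplitude: Optional[float] = None,
    mode: str = "soft",
) -> SourceDefinition:
    """Straight line source spanning the full grid height (validation)."""
    nx, ny, dx = geometry.grid_nx, geometry.grid_ny, geometry.dx
    i = int(round(x_position / dx - 0.5))
    if not 0 <= i < nx:
        raise BoundsError("line source outside the grid")
    mask = np.zeros((nx, ny), dtype=bool)
    mask[i, :] = True
    amp = geometry.source_amplitude if amplitude is None else amplitude
    return SourceDefinition(
        mask=mask,
        amplitude=np.where(mask, amp, 0.0),
        frequency=geometry.source_frequency,
        on_time=duty_cycle * window,
        total_time=window,
        mode=mode,
        normal_x2=np.where(mask, 1.0, 0.5),
        normal_y2=np.where(mask, 0.0, 0.5),
    )
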