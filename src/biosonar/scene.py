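"""Geometry of the imaging problem.

The scan region is a regular 2-D lattice of voxels at a fixed depth plane
inside the sample box; hydrophones sit on a planar frame just behind the
acoustically transparent screen, and the transmitters (or the echolocating
dolphin) sit in front of the screen.  Coordinates are metres, with the
origin at the centre of the box's back wall and z increasing towards the
screen.

Shape targets are built from PVC pipe, so target masks are rasterized from
stroke skeletons with a capsule (stadium) footprint of the pipe diameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

# Scene constants (metres / metres-per-second unless noted).
SOUND_SPEED = 1530.0          # nominal pool sound speed
SCREEN_Z = 0.23               # Plexiglas screen, from the back wall
OBJECT_Z = 0.03               # object plane: 0.20 m behind the screen
SENSOR_Z = 0.20               # sensor plane: 0.03 m behind the screen
PIPE_DIAMETER = 0.032         # schedule-40 PVC pipe used for the targets
ARRAY_FRAME = (0.87, 0.78)    # hydrophone frame width x height
DEVICE_DIAMETER = 0.36        # transmitter cluster fits in this disc
BEAMWIDTH_10DB_DEG = 20.0     # full 10-dB transmit beamwidth at 120 kHz


class EmptyGridError(ValueError):
    """Requested voxel spacing exceeds the extent of the scan region."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 2-D voxel lattice at a fixed z plane.

    Voxel centres lie on the lattice ``x_min + i*spacing`` (inclusive of
    both bounds when they are commensurate).  Linear indexing is row-major
    with x fastest: ``n = iy * nx + ix``.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    spacing: float = 0.005
    z_plane: float = OBJECT_Z

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("degenerate bounds")
        if (self.spacing > self.x_max - self.x_min
                or self.spacing > self.y_max - self.y_min):
            raise EmptyGridError(
                "spacing exceeds the scan-region extent; grid would be empty")

    @property
    def nx(self) -> int:
        return int(np.floor((self.x_max - self.x_min) / self.spacing + 1e-9)) + 1

    @property
    def ny(self) -> int:
        return int(np.floor((self.y_max - self.y_min) / self.spacing + 1e-9)) + 1

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny

    def x_coords(self) -> np.ndarray:
        return self.x_min + self.spacing * np.arange(self.nx)

    def y_coords(self) -> np.ndarray:
        return self.y_min + self.spacing * np.arange(self.ny)

    def centers(self) -> np.ndarray:
        """(N, 3) voxel-centre coordinates in linear-index order."""
        xx, yy = np.meshgrid(self.x_coords(), self.y_coords())
        z = np.full(self.n_voxels, self.z_plane)
        return np.column_stack([xx.ravel(), yy.ravel(), z])

    def index_to_xy(self, n: int | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = np.asarray(n)
        iy, ix = np.divmod(n, self.nx)
        return (self.x_min + ix * self.spacing, self.y_min + iy * self.spacing)

    def xy_to_index(self, x, y) -> np.ndarray:
        ix = np.rint((np.asarray(x) - self.x_min) / self.spacing).astype(int)
        iy = np.rint((np.asarray(y) - self.y_min) / self.spacing).astype(int)
        if np.any((ix < 0) | (ix >= self.nx) | (iy < 0) | (iy >= self.ny)):
            raise ValueError("coordinate outside the grid")
        return iy * self.nx + ix

    def image_shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)


def make_grid(bounds: tuple[float, float, float, float],
              spacing: float = 0.005,
              z_plane: float = OBJECT_Z) -> VoxelGrid:
    """Build a :class:`VoxelGrid` from ``(x_min, x_max, y_min, y_max)``."""
    x_min, x_max, y_min, y_max = bounds
    return VoxelGrid(x_min, x_max, y_min, y_max, spacing, z_plane)


def desk_grid(spacing: float = 0.01, half_extent: float = 0.20) -> VoxelGrid:
    """Reduced scan grid (default 41 x 41 = 1681 voxels) used for fast runs."""
    return make_grid((-half_extent, half_extent, -half_extent, half_extent),
                     spacing)


def paper_grid(half_extent: float = 0.25) -> VoxelGrid:
    """Full-resolution scan grid at 0.5 cm spacing."""
    return make_grid((-half_extent, half_extent, -half_extent, half_extent),
                     spacing=0.005)


@dataclass
class SensorArray:
    """Planar hydrophone array with a faulty-sensor exclusion mask."""

    positions: np.ndarray                 # (M_total, 3)
    active: np.ndarray | None = None      # boolean mask, (M_total,)
    min_spacing: float | None = None      # asserted at construction if set

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        if self.positions.shape[1] != 3:
            raise ValueError("positions must be (M, 3)")
        if self.active is None:
            self.active = np.ones(len(self.positions), bool)
        self.active = np.asarray(self.active, bool)
        if self.active.shape != (len(self.positions),):
            raise ValueError("active mask shape mismatch")
        if self.n_active < 1:
            raise ValueError("need at least one active sensor")
        if self.min_spacing is not None and len(self.positions) > 1:
            d = self.pairwise_min_spacing()
            if d < self.min_spacing - 1e-12:
                raise ValueError(
                    f"sensor spacing {d:.4f} m below required "
                    f"{self.min_spacing:.4f} m")

    def pairwise_min_spacing(self) -> float:
        p = self.positions
        d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)
        d[np.diag_indices(len(p))] = np.inf
        return float(d.min())

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def active_positions(self) -> np.ndarray:
        return self.positions[self.active]


def default_sensor_array(faulty: int | None = 0) -> SensorArray:
    """16-element 4x4 lattice filling the 87 x 78 cm frame, one sensor faulty.

    The physical array excludes one faulty hydrophone, leaving 15 active
    channels; pairwise spacing is >= 12.5 cm, far beyond half a wavelength
    at the click frequencies, so the array is heavily spatially aliased.
    """
    w, h = ARRAY_FRAME
    xs = np.linspace(-w / 2, w / 2, 4)
    ys = np.linspace(-h / 2, h / 2, 4)
    xx, yy = np.meshgrid(xs, ys)
    pos = np.column_stack([xx.ravel(), yy.ravel(),
                           np.full(16, SENSOR_Z)])
    active = np.ones(16, bool)
    if faulty is not None:
        active[faulty] = False
    return SensorArray(pos, active, min_spacing=0.125)


@dataclass
class TransmitterSet:
    """Transmitter cluster: positions, beam axes and a click schedule."""

    positions: np.ndarray                  # (T, 3)
    beam_axes: np.ndarray                  # (T, 3) unit vectors
    beamwidth_deg: float = BEAMWIDTH_10DB_DEG
    click_to_tx: np.ndarray = field(default_factory=lambda: np.arange(3))

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.beam_axes = np.atleast_2d(np.asarray(self.beam_axes, float))
        norms = np.linalg.norm(self.beam_axes, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero beam axis")
        self.beam_axes = self.beam_axes / norms
        self.click_to_tx = np.asarray(self.click_to_tx, int)
        if np.any((self.click_to_tx < 0)
                  | (self.click_to_tx >= len(self.positions))):
            raise ValueError("click schedule refers to unknown transmitter")

    @property
    def n_clicks(self) -> int:
        return len(self.click_to_tx)

    def click_positions(self) -> np.ndarray:
        return self.positions[self.click_to_tx]

    def directivity(self, grid: VoxelGrid) -> np.ndarray:
        """(K, N) Gaussian-beam amplitude attenuation towards each voxel.

        The beam is Gaussian in off-axis angle with a 10-dB (two-sided)
        width of ``beamwidth_deg``, i.e. the amplitude is 10**(-0.5) at
        ``beamwidth_deg / 2`` off axis.
        """
        centers = grid.centers()
        half = self.beamwidth_deg / 2.0
        out = np.empty((self.n_clicks, grid.n_voxels))
        for k, tx in enumerate(self.click_to_tx):
            d = centers - self.positions[tx]
            d = d / np.linalg.norm(d, axis=1, keepdims=True)
            cosang = np.clip(d @ self.beam_axes[tx], -1.0, 1.0)
            theta = np.degrees(np.arccos(cosang))
            out[k] = 10.0 ** (-0.5 * (theta / half) ** 2)
        return out


def default_transmitters(n_clicks_per_tx: int = 1,
                         stand_off: float = 1.0,
                         lateral_offset: float = -0.30,
                         aim_at: tuple[float, float, float] = (0.0, 0.0, OBJECT_Z),
                         ) -> TransmitterSet:
    """Three transmitters in a 36 cm disc, 1 m in front of the screen.

    The cluster sits below the object axis (the dolphin mostly echolocates
    from below), with the three elements on a small circle inside the
    device footprint, each beam aimed at the scan-region centre.
    """
    z = SCREEN_Z + stand_off
    r = DEVICE_DIAMETER / 3.0
    angles = np.deg2rad([90.0, 210.0, 330.0])
    pos = np.column_stack([r * np.cos(angles),
                           lateral_offset + r * np.sin(angles),
                           np.full(3, z)])
    target = np.asarray(aim_at, float)
    axes = target[None, :] - pos
    schedule = np.repeat(np.arange(3), n_clicks_per_tx)
    return TransmitterSet(pos, axes, click_to_tx=schedule)


# ---------------------------------------------------------------------------
# Shape masks

@dataclass
class ShapeMask:
    """Binary occupancy mask of a target shape on a voxel grid."""

    grid: VoxelGrid
    values: np.ndarray          # (N,) in {0, 1}
    label: str = "custom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.grid.n_voxels,):
            raise ValueError("mask length must equal the voxel count")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        self.values = self.values.astype(np.uint8)

    @property
    def n_set(self) -> int:
        return int(self.values.sum())

    @property
    def area(self) -> float:
        """Rasterized area in m^2 (voxel count times cell area)."""
        return self.n_set * self.grid.spacing ** 2

    def as_image(self) -> np.ndarray:
        return self.values.reshape(self.grid.image_shape())


def _point_segment_distance(points: np.ndarray, p0, p1) -> np.ndarray:
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0.0:
        return np.linalg.norm(points - p0, axis=1)
    t = np.clip((points - p0) @ d / denom, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.linalg.norm(points - proj, axis=1)


def rasterize_shape(strokes, grid: VoxelGrid,
                    width: float = PIPE_DIAMETER,
                    label: str = "custom") -> ShapeMask:
    """Rasterize line-segment strokes of a given pipe width into a mask.

    A voxel is set iff its centre lies within ``width / 2`` of any stroke
    segment (capsule footprint).  An empty stroke list yields an all-zero
    mask and a warning.
    """
    if width <= 0:
        raise ValueError("stroke width must be positive")
    centers = grid.centers()[:, :2]
    mask = np.zeros(grid.n_voxels, bool)
    if not strokes:
        warnings.warn("empty stroke list: all-zero shape mask")
        return ShapeMask(grid, mask.astype(np.uint8), label)
    for (p0, p1) in strokes:
        mask |= _point_segment_distance(centers, p0, p1) <= width / 2.0
    return ShapeMask(grid, mask.astype(np.uint8), label)


def _square_strokes(size: float, center):
    cx, cy = center
    s = size / 2.0
    c = [(cx - s, cy - s), (cx + s, cy - s), (cx + s, cy + s), (cx - s, cy + s)]
    return [(c[0], c[1]), (c[1], c[2]), (c[2], c[3]), (c[3], c[0])]


def _f_glyph(size: float, x0: float, cy: float, sign: float):
    # One "F": vertical spine plus top and middle arms pointing along `sign`.
    h = size
    top = cy + h / 2
    mid = cy + 0.05 * h
    arm1 = 0.62 * size * sign
    arm2 = 0.42 * size * sign
    return [((x0, cy - h / 2), (x0, top)),
            ((x0, top), (x0 + arm1, top)),
            ((x0, mid), (x0 + arm2, mid))]


def _double_f_strokes(size: float, center):
    # Two mirrored F glyphs, arms pointing outwards; arm lengths chosen so
    # the rasterized area matches the square outline of the same `size`
    # within 2% (the physical targets are equated for reflective area).
    cx, cy = center
    off = 0.27 * size
    return (_f_glyph(size, cx - off, cy, -1.0)
            + _f_glyph(size, cx + off, cy, +1.0))


def _octagon_loop_strokes(size: float, center):
    # "OC" preset: stylized octopus — a polygonal head loop with four legs.
    cx, cy = center
    r = 0.30 * size
    ang = np.deg2rad(np.arange(0, 360, 45))
    head = [(cx + r * np.cos(a), cy + 0.35 * size + r * np.sin(a)) for a in ang]
    strokes = [(head[i], head[(i + 1) % 8]) for i in range(8)]
    for xleg in np.linspace(-0.35, 0.35, 4) * size:
        strokes.append(((cx + xleg * 0.6, cy + 0.1 * size),
                        (cx + xleg, cy - 0.5 * size)))
    return strokes


def _elephant_strokes(size: float, center):
    # "EL" preset: stylized elephant — body bar, head, trunk and two legs.
    cx, cy = center
    s = size
    return [((cx - 0.5 * s, cy + 0.2 * s), (cx + 0.3 * s, cy + 0.2 * s)),
            ((cx + 0.3 * s, cy + 0.2 * s), (cx + 0.45 * s, cy + 0.05 * s)),
            ((cx + 0.45 * s, cy + 0.05 * s), (cx + 0.35 * s, cy - 0.45 * s)),
            ((cx - 0.4 * s, cy + 0.2 * s), (cx - 0.4 * s, cy - 0.45 * s)),
            ((cx, cy + 0.2 * s), (cx, cy - 0.45 * s))]


_PRESETS = {
    "SQ": _square_strokes,
    "FF": _double_f_strokes,
    "OC": _octagon_loop_strokes,
    "EL": _elephant_strokes,
}


def shape_strokes(label: str, size: float = 0.28,
                  center: tuple[float, float] = (0.0, 0.0)):
    """Stroke skeleton of a preset target shape (SQ | FF | OC | EL)."""
    try:
        fn = _PRESETS[label.upper()]
    except KeyError:
        raise KeyError(f"unknown shape preset {label!r}; "
                       f"choose from {sorted(_PRESETS)}") from None
    return fn(size, center)


def preset_mask(label: str, grid: VoxelGrid, size: float = 0.28,
                center: tuple[float, float] = (0.0, 0.0),
                width: float = PIPE_DIAMETER) -> ShapeMask:
    """Rasterized preset shape mask on the given grid."""
    return rasterize_shape(shape_strokes(label, size, center), grid,
                           width=width, label=label.upper())


# ---------------------------------------------------------------------------
# Array-design helper formulas

def nyquist_sensor_count(aperture_m: float, wavelength_m: float) -> float:
    """Sensors needed to fully populate a circular aperture at lambda/2.

    ``pi D^2 / (4 (lambda/2)^2)`` — the count below which a 2-D array of
    diameter D is spatially aliased at wavelength lambda.
    """
    if aperture_m <= 0 or wavelength_m <= 0:
        raise ValueError("aperture and wavelength must be positive")
    return np.pi * aperture_m ** 2 / (4.0 * (wavelength_m / 2.0) ** 2)


def diffraction_limit_deg(wavelength_m: float, aperture_m: float) -> float:
    """Narrowband angular resolution ~ lambda / D, in degrees."""
    if aperture_m <= 0 or wavelength_m <= 0:
        raise ValueError("aperture and wavelength must be positive")
    return np.degrees(wavelength_m / aperture_m)
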