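"""Cubic voxel grids and the three real-space density maps.

The grid covers three times the particle's maximum dimension (ample for
the Shannon minimum of twice Dmax) at 1 A voxels by default, capped at
256 voxels per side (the voxel size grows to compensate).  Three maps are
synthesized on it:

* in vacuo solute density -- per-atom sums of the real-space Gaussian
  form factor, with a small uniform B-factor smear (default 7 A^2,
  ~0.3 A rms displacement) so the sharp atomic peaks are sampled by the
  lattice; the smear is undone later by reciprocal-space sharpening.
  Each atom's deposited density is rescaled so it carries exactly
  Z * occupancy electrons.
* excluded volume -- unit-amplitude Gaussian dummy atoms
  exp(-pi r^2 / V_j^(2/3)) whose analytic integral is the adjusted volume
  V_j; the map stores shape only, multiplication by the bulk density
  rho0 happens in reciprocal space.  A flat "cube method" alternative
  paints the union of vdW spheres instead.
* hydration shell -- the shell center lies one water radius (1.4 A) off
  the vdW surface; each voxel within reach is assigned the real-space
  water form factor evaluated at its distance from that locus (via a
  Euclidean distance transform), then the map is rescaled so the mean
  over shell voxels equals the target contrast (default 0.019 e-/A^3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from voxsaxs.model_io import (
    AtomRecord,
    get_coeffs,
    positions_of,
    real_space_coeffs,
    water_real_space_coeffs,
)
from voxsaxs.volumes import AdjustedVolume

logger = logging.getLogger(__name__)


class MapRole(str, Enum):
    IN_VACUO = "in_vacuo"
    EXCLUDED_VOLUME = "excluded_volume"
    SHELL = "shell"
    TOTAL = "total"


@dataclass(frozen=True)
class GridSpec:
    """Cubic voxel grid: physical side length (A), voxel count, size, corner origin."""

    side_length: float
    n_voxels_per_side: int
    voxel_size: float
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if abs(self.side_length - self.n_voxels_per_side * self.voxel_size) > 1e-9 * self.side_length:
            raise ValueError("side_length must equal n_voxels_per_side * voxel_size")

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Grid-point coordinates along each axis (first point at the origin)."""
        return tuple(
            self.origin[k] + np.arange(self.n_voxels_per_side) * self.voxel_size
            for k in range(3)
        )

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size**3

    @property
    def qmax(self) -> float:
        """Nominal reciprocal-space extent 2*pi / voxel_size."""
        return 2.0 * np.pi / self.voxel_size

    @property
    def dq(self) -> float:
        """Reciprocal lattice spacing 2*pi / side_length."""
        return 2.0 * np.pi / self.side_length


@dataclass
class DensityGrid:
    """Scalar field (e-/A^3) on a GridSpec, tagged with its physical role."""

    spec: GridSpec
    values: np.ndarray
    role: MapRole

    def __post_init__(self) -> None:
        n = self.spec.n_voxels_per_side
        if self.values.shape != (n, n, n):
            raise ValueError("values shape inconsistent with grid spec")

    @property
    def integral(self) -> float:
        """Map integral (electrons for in vacuo, A^3 for unit-amplitude maps)."""
        return float(self.values.sum()) * self.spec.voxel_volume


def max_dimension(positions: np.ndarray) -> float:
    """Maximum pairwise distance (Dmax) of a point set."""
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 2:
        return 0.0
    pts = positions
    if len(positions) > 30:
        try:
            pts = positions[ConvexHull(positions).vertices]
        except QhullError:
            pass  # degenerate (planar/collinear) sets: fall back to all pairs
    return float(pdist(pts).max())


def make_grid(
    atoms: list[AtomRecord] | np.ndarray,
    voxel_size: float = 1.0,
    box_factor: float = 3.0,
    max_n: int = 256,
    min_side: float = 20.0,
) -> GridSpec:
    """Build the cubic grid: side = box_factor * Dmax, even voxel count.

    If the voxel count would exceed ``max_n``, the count is capped and the
    voxel size grows to keep the physical side.  Point-like models get a
    ``min_side`` box.  The particle is centered in the box.
    """
    positions = atoms if isinstance(atoms, np.ndarray) else positions_of(atoms)
    if len(positions) == 0:
        raise ValueError("need at least one atom")
    dmax = max_dimension(positions)
    side = max(box_factor * dmax, min_side)
    n = int(np.ceil(side / voxel_size))
    n += n % 2
    if n > max_n:
        n = max_n - (max_n % 2)
    else:
        side = n * voxel_size
    voxel = side / n
    center = 0.5 * (positions.min(axis=0) + positions.max(axis=0))
    origin = tuple(center - side / 2.0)
    return GridSpec(side_length=side, n_voxels_per_side=n, voxel_size=voxel, origin=origin)


def _atom_window(spec: GridSpec, position: np.ndarray, radius: float):
    """Index slices and squared distances of the cubic window around one atom."""
    n = spec.n_voxels_per_side
    dx = spec.voxel_size
    lo = np.floor((position - radius - np.array(spec.origin)) / dx).astype(int)
    hi = np.ceil((position + radius - np.array(spec.origin)) / dx).astype(int) + 1
    if np.any(hi <= 0) or np.any(lo >= n):
        raise ValueError("atom lies outside the grid; rebuild the grid from the same atoms")
    lo = np.clip(lo, 0, n)
    hi = np.clip(hi, 0, n)
    slices = tuple(slice(l, h) for l, h in zip(lo, hi))
    axes = spec.axes
    local = [axes[k][lo[k]:hi[k]] - position[k] for k in range(3)]
    r2 = (
        local[0][:, None, None] ** 2
        + local[1][None, :, None] ** 2
        + local[2][None, None, :] ** 2
    )
    return slices, r2


def in_vacuo_map(
    atoms: list[AtomRecord],
    spec: GridSpec,
    use_model_b: bool = False,
    b_smear: float = 7.0,
    window: float = 3.0,
) -> DensityGrid:
    """Solute electron density from the real-space Gaussian form factors.

    Per atom j the density added at distance r is

        rho_j(r) = sum_i a_i (4 pi / (b_i + B_j))^(3/2)
                   exp(-4 pi^2 r^2 / (b_i + B_j))

    with B_j = b_smear (+ the model B-factor when enabled), evaluated
    within ``window`` A of the center (enlarged for large B), and rescaled
    so each atom deposits exactly Z * occupancy electrons.
    """
    values = np.zeros((spec.n_voxels_per_side,) * 3)
    vv = spec.voxel_volume
    for atom in atoms:
        a, b = real_space_coeffs(atom.element)
        B = b_smear + (atom.b_factor if use_model_b else 0.0)
        rad = window + (0.3 * np.sqrt(max(B - b_smear, 0.0) / 7.0) if use_model_b else 0.0)
        slices, r2 = _atom_window(spec, atom.position, rad)
        mask = r2 <= rad * rad
        rho = np.zeros_like(r2)
        w = b + B
        rho_flat = np.zeros(int(mask.sum()))
        rm = r2[mask]
        for ai, wi in zip(a, w):
            rho_flat += ai * (4.0 * np.pi / wi) ** 1.5 * np.exp(-4.0 * np.pi**2 * rm / wi)
        total = rho_flat.sum() * vv
        z = get_coeffs(atom.element).n_electrons * atom.occupancy
        if total > 0:
            rho_flat *= z / total
        rho[mask] = rho_flat
        values[slices] += rho
    return DensityGrid(spec=spec, values=values, role=MapRole.IN_VACUO)


def excluded_volume_map(
    atoms: list[AtomRecord],
    volumes: list[AdjustedVolume],
    spec: GridSpec,
) -> DensityGrid:
    """Gaussian dummy-atom excluded-volume shape map.

    Each atom contributes exp(-pi r^2 / V_j^(2/3)), whose analytic
    integral is V_j.  The map is dimensionless shape only; the bulk
    solvent density multiplies it in reciprocal space.
    """
    if len(volumes) != len(atoms):
        raise ValueError("need one adjusted volume per atom")
    if any(v.volume <= 0 for v in volumes):
        raise ValueError("all adjusted volumes must be positive")
    values = np.zeros((spec.n_voxels_per_side,) * 3)
    for atom, av in zip(atoms, volumes):
        s = av.volume ** (2.0 / 3.0)
        # window where the Gaussian falls below 1e-4 of its peak
        rad = max(3.0, float(np.sqrt(s * np.log(1e4) / np.pi)))
        slices, r2 = _atom_window(spec, atom.position, rad)
        values[slices] += np.exp(-np.pi * r2 / s)
    return DensityGrid(spec=spec, values=values, role=MapRole.EXCLUDED_VOLUME)


def _vdw_support(atoms: list[AtomRecord], radii: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Boolean union of vdW spheres by voxel-center membership."""
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")
    support = np.zeros((spec.n_voxels_per_side,) * 3, dtype=bool)
    for atom, r in zip(atoms, radii):
        slices, r2 = _atom_window(spec, atom.position, float(r))
        support[slices] |= r2 <= r * r
    return support


def excluded_volume_map_cube(
    atoms: list[AtomRecord],
    radii: np.ndarray,
    spec: GridSpec,
) -> DensityGrid:
    """Flat (cube-method) excluded volume: 1 inside any vdW sphere, else 0."""
    support = _vdw_support(atoms, radii, spec)
    return DensityGrid(spec=spec, values=support.astype(float), role=MapRole.EXCLUDED_VOLUME)


def shell_map(
    atoms: list[AtomRecord],
    radii: np.ndarray,
    spec: GridSpec,
    water_radius: float = 1.4,
    mean_contrast: float = 0.019,
    shell_pad: float = 3.0,
    b_smear: float = 7.0,
) -> DensityGrid:
    """Implicit hydration-shell contrast map.

    Voxels outside the vdW support are assigned the real-space water form
    factor evaluated at |d - water_radius|, where d is the Euclidean
    distance to the support, out to d = water_radius + shell_pad; the
    shell follows cavities and channels reachable by the distance
    transform.  The same small B-factor smear used for the solute keeps
    the water profile resolvable on the lattice; the final map is
    rescaled so the mean over shell voxels equals ``mean_contrast``
    (which may legitimately be negative during fitting).
    """
    support = _vdw_support(atoms, radii, spec)
    dist = distance_transform_edt(~support, sampling=spec.voxel_size)
    shell_mask = (dist > 0) & (dist <= water_radius + shell_pad)
    if not shell_mask.any():
        raise ValueError("grid too small to hold a hydration shell")
    a, b = water_real_space_coeffs()
    w = b + b_smear
    r = np.abs(dist[shell_mask] - water_radius)
    rho = np.zeros_like(r)
    for ai, wi in zip(a, w):
        rho += ai * (4.0 * np.pi / wi) ** 1.5 * np.exp(-4.0 * np.pi**2 * r**2 / wi)
    mean = rho.mean()
    if mean_contrast < 0:
        logger.info("shell mean contrast is negative (%g e-/A^3)", mean_contrast)
    rho *= mean_contrast / mean
    values = np.zeros_like(dist)
    values[shell_mask] = rho
    return DensityGrid(spec=spec, values=values, role=MapRole.SHELL)


def write_mrc(grid: DensityGrid, path) -> None:
    """Write a map in CCP4/MRC mode-2 (float32) with the physical origin."""
    import gemmi

    g = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    s = grid.spec.side_length
    g.unit_cell = gemmi.UnitCell(s, s, s, 90.0, 90.0, 90.0)
    g.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), grid.spec.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))
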