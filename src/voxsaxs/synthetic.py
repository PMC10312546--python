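"""Synthetic models, analytic oracles, and simulated SWAXS data.

Everything here has a known closed-form answer, so every stage of the
pipeline can be validated without external downloads: single atoms
(oracle: the squared atomic form factor), uniform spheres (oracle: the
closed-form sphere intensity with its first minimum at qR = 4.493),
sphere pairs (oracle: the two-body Debye formula), clipped spheres
(oracle: sphere-minus-spherical-caps volumes), and a small hand-built
glycine dipeptide with explicit hydrogens for end-to-end runs.

Simulated data use multiplicative Gaussian noise -- a simple stand-in
for counting statistics -- with a mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from voxsaxs.density import DensityGrid, GridSpec, MapRole
from voxsaxs.model_io import AtomRecord, ScatteringProfile, get_coeffs


@dataclass
class SyntheticModel:
    """A fixture model plus the analytic ground truth it was built from."""

    atoms: list[AtomRecord]
    ground_truth: dict = field(default_factory=dict)


def make_single_atom(element: str, b_factor: float = 0.0) -> SyntheticModel:
    """One atom at the origin; oracle is |f(q)|^2."""
    coeffs = get_coeffs(element)  # fatal for unknown elements
    atom = AtomRecord(
        position=np.zeros(3),
        element=element,
        atom_name=element,
        residue_name="UNK",
        b_factor=b_factor,
    )
    return SyntheticModel(
        atoms=[atom],
        ground_truth={"element": element, "n_electrons": coeffs.n_electrons},
    )


# Hand-built glycylglycine with explicit hydrogens; idealized bond lengths
# (N-H ~1.0 A, C-H ~1.1 A, C-N ~1.35 A, C-C ~1.5 A, C=O ~1.2 A).
_GLYGLY = [
    # (atom_name, residue_name, element, x, y, z)
    ("N",   "GLY", "N", 0.000, 0.000, 0.000),
    ("H",   "GLY", "H", -0.950, 0.300, 0.000),
    ("H2",  "GLY", "H", 0.300, -0.950, 0.000),
    ("CA",  "GLY", "C", 1.450, 0.000, 0.000),
    ("HA2", "GLY", "H", 1.800, -0.700, 0.750),
    ("HA3", "GLY", "H", 1.800, -0.350, -0.950),
    ("C",   "GLY", "C", 2.000, 1.380, 0.000),
    ("O",   "GLY", "O", 1.400, 2.400, 0.300),
    ("N",   "GLY", "N", 3.300, 1.450, -0.250),
    ("H",   "GLY", "H", 3.800, 0.620, -0.450),
    ("CA",  "GLY", "C", 4.050, 2.700, -0.300),
    ("HA2", "GLY", "H", 3.700, 3.350, -1.080),
    ("HA3", "GLY", "H", 4.000, 3.220, 0.640),
    ("C",   "GLY", "C", 5.500, 2.450, -0.600),
    ("O",   "GLY", "O", 6.000, 1.350, -0.550),
    ("OXT", "GLY", "O", 6.200, 3.450, -0.900),
]


def make_peptide() -> SyntheticModel:
    """Glycylglycine dipeptide (16 atoms incl. hydrogens), Dmax ~ 7.5 A."""
    atoms = [
        AtomRecord(np.array([x, y, z]), el, name, res)
        for name, res, el, x, y, z in _GLYGLY
    ]
    return SyntheticModel(
        atoms=atoms,
        ground_truth={"n_residues": 2, "res_ids": [1] * 8 + [2] * 8},
    )


# --- analytic oracles --------------------------------------------------------


def sphere_volume(radius: float) -> float:
    return 4.0 / 3.0 * np.pi * radius**3


def spherical_cap_volume(radius: float, height: float) -> float:
    """Volume of a spherical cap of the given height cut from a sphere."""
    h = np.clip(height, 0.0, 2.0 * radius)
    return np.pi * h * h * (3.0 * radius - h) / 3.0


def clipped_sphere_volume(r1: float, r2: float, d: float) -> float:
    """Sphere 1's volume after removing everything beyond the radical plane
    of its intersection with sphere 2 at center distance d."""
    full = sphere_volume(r1)
    if d >= r1 + r2:
        return full
    if d <= 0:
        raise ValueError("coincident centers are degenerate")
    t = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    if t >= r1:
        return full
    if t <= -r1:
        return 0.0
    return full - spherical_cap_volume(r1, r1 - t)


def sphere_amplitude(q, radius: float, contrast: float = 1.0) -> np.ndarray:
    """Scattering amplitude of a uniform ball (contrast * volume at q = 0)."""
    q = np.asarray(q, dtype=float)
    x = q * radius
    vol = sphere_volume(radius)
    with np.errstate(invalid="ignore", divide="ignore"):
        shape = np.where(x > 1e-8, 3.0 * (np.sin(x) - x * np.cos(x)) / np.maximum(x, 1e-300) ** 3, 1.0)
    return contrast * vol * shape


def sphere_intensity(q, radius: float, contrast: float = 1.0) -> np.ndarray:
    """Closed-form intensity of a uniform ball; first minimum at qR ~ 4.493."""
    return sphere_amplitude(q, radius, contrast) ** 2


SPHERE_FIRST_MIN_QR = 4.493409457909064  # first positive root of tan(x) = x


def two_sphere_debye_intensity(q, radius: float, separation: float, contrast: float = 1.0) -> np.ndarray:
    """Two identical uniform balls at fixed center separation (Debye formula)."""
    q = np.asarray(q, dtype=float)
    A = sphere_amplitude(q, radius, contrast)
    x = q * separation
    sinc = np.where(x > 1e-8, np.sin(x) / np.maximum(x, 1e-300), 1.0)
    return 2.0 * A * A * (1.0 + sinc)


def make_uniform_sphere(
    radius: float,
    density: float,
    spec: GridSpec,
    center: np.ndarray | None = None,
) -> DensityGrid:
    """Paint a uniform ball onto the grid (voxel-center membership)."""
    if center is None:
        center = np.array(spec.origin) + spec.side_length / 2.0
    center = np.asarray(center, dtype=float)
    lo = np.array(spec.origin)
    hi = lo + spec.side_length - spec.voxel_size
    if np.any(center - radius < lo) or np.any(center + radius > hi):
        raise ValueError("sphere clipped by the box")
    ax, ay, az = spec.axes
    r2 = (
        (ax - center[0])[:, None, None] ** 2
        + (ay - center[1])[None, :, None] ** 2
        + (az - center[2])[None, None, :] ** 2
    )
    values = np.where(r2 <= radius * radius, density, 0.0)
    return DensityGrid(spec=spec, values=values, role=MapRole.IN_VACUO)


# --- simulated experimental data ---------------------------------------------


def make_synthetic_data(
    model: SyntheticModel,
    rho0: float,
    drho: float,
    noise_fraction: float,
    seed: int,
    voxel_size: float = 1.0,
    n_points: int = 201,
    q_max: float | None = None,
    **pipeline_kwargs,
) -> ScatteringProfile:
    """Forward-simulate an oversampled experimental profile at known parameters.

    The full pipeline is run at (rho0, drho), the calculated profile is
    spline-interpolated to a fine q grid (mimicking experimental
    oversampling), and multiplicative Gaussian noise of the given
    fractional level is added with a fixed seed.  The sigma column
    records the noise level actually used (a nominal 1% of I when
    ``noise_fraction`` is zero, so weighted fitting remains defined).
    """
    from voxsaxs.fitting import interpolate_profile
    from voxsaxs.pipeline import build_components

    if noise_fraction < 0:
        raise ValueError("noise_fraction must be non-negative")
    comp = build_components(model.atoms, voxel_size=voxel_size, **pipeline_kwargs)
    calc = comp.cross_terms.profile(rho0, drho / comp.shell_ref_contrast)
    lo = calc.q[1]  # first non-zero bin center
    hi = min(q_max, calc.q[-1]) if q_max is not None else calc.q[-1]
    q = np.linspace(lo, hi, n_points)
    truth = interpolate_profile(calc, q).intensity
    sigma = (noise_fraction if noise_fraction > 0 else 0.01) * np.abs(truth)
    intensity = truth.copy()
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        intensity = truth + rng.normal(0.0, 1.0, size=truth.shape) * sigma
    return ScatteringProfile(q, intensity, sigma)
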