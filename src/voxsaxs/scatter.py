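"""Structure factors, sharpening, and spherical averaging to a 1D profile.

The map's discrete Fourier transform is scaled by the voxel volume so the
q = 0 term equals the map integral (total electrons for the solute map).
The three amplitude grids combine per voxel as

    I(q) = | F_vac - rho0 * F_exvol + s * F_shell |^2

and the 1D profile is the arithmetic mean of I over reciprocal voxels
binned by |q| with bin width dq = 2 pi / side; the q = 0 voxel forms its
own first bin.  B-factor sharpening (a Debye-Waller factor with negative
B) undoes the uniform real-space smear applied to the solute map.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from voxsaxs.density import DensityGrid, GridSpec, MapRole
from voxsaxs.model_io import ScatteringProfile


@dataclass
class StructureFactorGrid:
    """Complex amplitudes on the reciprocal lattice of a cubic map."""

    spec: GridSpec
    values: np.ndarray
    role: MapRole

    def __post_init__(self) -> None:
        n = self.spec.n_voxels_per_side
        if self.values.shape != (n, n, n):
            raise ValueError("values shape inconsistent with grid spec")

    @property
    def q_magnitudes(self) -> np.ndarray:
        return q_magnitudes(self.spec)


def q_magnitudes(spec: GridSpec) -> np.ndarray:
    """|q| (1/A) at every voxel of the FFT reciprocal lattice."""
    qax = 2.0 * np.pi * np.fft.fftfreq(spec.n_voxels_per_side, d=spec.voxel_size)
    qx, qy, qz = np.meshgrid(qax, qax, qax, indexing="ij")
    return np.sqrt(qx * qx + qy * qy + qz * qz)


def map_to_structure_factors(grid: DensityGrid) -> StructureFactorGrid:
    """FFT of the map scaled by voxel volume (F(0) = map integral)."""
    F = np.fft.fftn(grid.values) * grid.spec.voxel_volume
    return StructureFactorGrid(spec=grid.spec, values=F, role=grid.role)


def sharpen(F: StructureFactorGrid, b: float = -7.0) -> StructureFactorGrid:
    """Apply the Debye-Waller factor exp(-b q^2 / 16 pi^2) to the amplitudes.

    With b = -7 A^2 this exactly undoes a +7 A^2 real-space smear in the
    continuum limit; b = 0 is the identity.
    """
    q2 = q_magnitudes(F.spec) ** 2
    return StructureFactorGrid(
        spec=F.spec,
        values=F.values * np.exp(-b * q2 / (16.0 * np.pi**2)),
        role=F.role,
    )


class RadialBinner:
    """Shell binning of the reciprocal lattice: bin k = floor(|q| / dq).

    The q = 0 voxel is alone in the first bin (reported at q = 0); bin
    k >= 1 covers [k dq, (k+1) dq) and is reported at its center
    (k + 1/2) dq.  Empty bins are dropped.
    """

    def __init__(self, spec: GridSpec):
        self.spec = spec
        dq = spec.dq
        qmag = q_magnitudes(spec)
        # nudge exact-lattice magnitudes across the bin edge they sit on
        idx = np.floor(qmag / dq + 1e-6).astype(np.intp).ravel()
        nbins = int(idx.max()) + 1
        counts = np.bincount(idx, minlength=nbins)
        keep = counts > 0
        self._idx = idx
        self._nbins = nbins
        self._counts = counts
        self._keep = keep
        q_centers = (np.arange(nbins) + 0.5) * dq
        q_centers[0] = 0.0
        self.q = q_centers[keep]

    def bin(self, voxel_values: np.ndarray) -> np.ndarray:
        """Mean of a real-valued reciprocal field over each |q| shell."""
        sums = np.bincount(self._idx, weights=voxel_values.ravel(), minlength=self._nbins)
        return sums[self._keep] / self._counts[self._keep]


class BinnedCrossTerms:
    """Precomputed shell-binned quadratic cross terms of the three amplitudes.

    Expanding |Fv - rho0 Fx + s Fs|^2 gives six real fields that do not
    depend on (rho0, s); binning them once makes every intensity
    evaluation during fitting a six-term combination of 1D arrays,
    identical to (but much faster than) recombining the 3D grids.
    """

    def __init__(
        self,
        Fv: StructureFactorGrid,
        Fx: StructureFactorGrid | None = None,
        Fs: StructureFactorGrid | None = None,
        binner: RadialBinner | None = None,
    ):
        for other in (Fx, Fs):
            if other is not None and other.spec != Fv.spec:
                raise ValueError("structure-factor grids live on different lattices")
        self.binner = binner or RadialBinner(Fv.spec)
        self.q = self.binner.q
        b = self.binner.bin
        v, x, s = Fv.values, None, None
        self.vv = b(np.abs(v) ** 2)
        zeros = np.zeros_like(self.vv)
        if Fx is not None:
            x = Fx.values
            self.xx = b(np.abs(x) ** 2)
            self.vx = b((v * np.conj(x)).real)
        else:
            self.xx = self.vx = zeros
        if Fs is not None:
            s = Fs.values
            self.ss = b(np.abs(s) ** 2)
            self.vs = b((v * np.conj(s)).real)
        else:
            self.ss = self.vs = zeros
        if Fx is not None and Fs is not None:
            self.xs = b((x * np.conj(s)).real)
        else:
            self.xs = zeros

    def intensity(self, rho0: float, shell_scale: float) -> np.ndarray:
        r, s = rho0, shell_scale
        out = (
            self.vv
            + r * r * self.xx
            + s * s * self.ss
            - 2.0 * r * self.vx
            + 2.0 * s * self.vs
            - 2.0 * r * s * self.xs
        )
        # round-off in the expansion can leave tiny negatives where the
        # amplitudes cancel almost exactly
        return np.maximum(out, 0.0)

    def profile(self, rho0: float, shell_scale: float) -> ScatteringProfile:
        return ScatteringProfile(self.q, self.intensity(rho0, shell_scale))


def combine_and_average(
    Fv: StructureFactorGrid,
    Fx: StructureFactorGrid | None = None,
    Fs: StructureFactorGrid | None = None,
    rho0: float = 0.334,
    drho_scale: float = 1.0,
) -> ScatteringProfile:
    """Combine the three amplitude grids and spherically average.

    ``drho_scale`` multiplies the shell term relative to the contrast the
    shell map was built with (1.0 keeps the built-in mean contrast).
    Absent terms are treated as zero.
    """
    return BinnedCrossTerms(Fv, Fx, Fs).profile(rho0, drho_scale)
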