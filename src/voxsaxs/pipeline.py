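"""Forward pipeline: atoms -> maps -> structure factors, ready for fitting."""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from voxsaxs import density, scatter
from voxsaxs.fitting import DEFAULT_DRHO
from voxsaxs.model_io import AtomRecord, radii_of
from voxsaxs.scatter import BinnedCrossTerms, StructureFactorGrid
from voxsaxs.volumes import (
    AdjustedVolume,
    VolumeDictionary,
    apply_volume_scale_factors,
    atom_volumes,
)


def default_scale_factors() -> dict[str, float]:
    """Per-element excluded-volume scale factors shipped with the package."""
    with resources.files("voxsaxs.data").joinpath("scale_factors.json").open() as fh:
        payload = json.load(fh)
    return {k: float(v) for k, v in payload["factors"].items()}


@dataclass
class Components:
    """Everything the fit needs, plus the maps for inspection/output."""

    spec: density.GridSpec
    in_vacuo: density.DensityGrid
    exvol: density.DensityGrid
    shell: density.DensityGrid
    Fv: StructureFactorGrid  # sharpened
    Fx: StructureFactorGrid
    Fs: StructureFactorGrid
    volumes: list[AdjustedVolume]
    shell_ref_contrast: float
    cross_terms: BinnedCrossTerms

    def total_map(self, rho0: float, drho: float) -> density.DensityGrid:
        values = (
            self.in_vacuo.values
            - rho0 * self.exvol.values
            + (drho / self.shell_ref_contrast) * self.shell.values
        )
        return density.DensityGrid(self.spec, values, density.MapRole.TOTAL)


def build_components(
    atoms: list[AtomRecord],
    voxel_size: float = 1.0,
    box_factor: float = 3.0,
    max_n: int = 256,
    exvol_method: str = "gaussian",
    use_b_factors: bool = False,
    b_smear: float = 7.0,
    vdict: VolumeDictionary | None = None,
    scale_factors: dict[str, float] | None = None,
    shell_contrast: float = DEFAULT_DRHO,
    water_radius: float = 1.4,
) -> Components:
    """Run the forward model up to binned structure factors."""
    spec = density.make_grid(atoms, voxel_size=voxel_size, box_factor=box_factor, max_n=max_n)
    radii = radii_of(atoms)

    vac = density.in_vacuo_map(atoms, spec, use_model_b=use_b_factors, b_smear=b_smear)
    Fv = scatter.sharpen(scatter.map_to_structure_factors(vac), b=-b_smear)

    if scale_factors is None:
        scale_factors = default_scale_factors()
    vols = atom_volumes(atoms, dictionary=vdict)
    vols = apply_volume_scale_factors(vols, [a.element for a in atoms], scale_factors)
    if exvol_method == "gaussian":
        exvol = density.excluded_volume_map(atoms, vols, spec)
    elif exvol_method == "cube":
        exvol = density.excluded_volume_map_cube(atoms, radii, spec)
    else:
        raise ValueError(f"unknown excluded-volume method {exvol_method!r}")
    Fx = scatter.map_to_structure_factors(exvol)

    shell = density.shell_map(
        atoms, radii, spec, water_radius=water_radius, mean_contrast=shell_contrast
    )
    Fs = scatter.map_to_structure_factors(shell)

    return Components(
        spec=spec,
        in_vacuo=vac,
        exvol=exvol,
        shell=shell,
        Fv=Fv,
        Fx=Fx,
        Fs=Fs,
        volumes=vols,
        shell_ref_contrast=shell_contrast,
        cross_terms=BinnedCrossTerms(Fv, Fx, Fs),
    )
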