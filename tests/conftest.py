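import numpy as np
import pytest

from voxsaxs import density, fitting, model_io, pipeline, scatter, synthetic


@pytest.fixture(scope="session")
def peptide():
    return synthetic.make_peptide()


@pytest.fixture(scope="session")
def peptide_components(peptide):
    """Forward model of the dipeptide at default settings (1 A voxels)."""
    return pipeline.build_components(peptide.atoms)


@pytest.fixture(scope="session")
def sphere_bundle():
    """Uniform ball R = 20 A in a 3*Dmax box: numeric profile + binned oracle."""
    R = 20.0
    spec = density.GridSpec(120.0, 120, 1.0, (-60.0, -60.0, -60.0))
    ball = synthetic.make_uniform_sphere(R, 1.0, spec)
    F = scatter.map_to_structure_factors(ball)
    prof = scatter.combine_and_average(F, rho0=0.0)
    binner = scatter.RadialBinner(spec)
    oracle = binner.bin(synthetic.sphere_intensity(scatter.q_magnitudes(spec), R))
    return {"radius": R, "spec": spec, "profile": prof, "oracle_binned": oracle}


def synthetic_profile_from(components, rho0, drho, noise_fraction=0.0, seed=0, n_points=201):
    """Oversampled data from already-built components (fast per-seed variant)."""
    calc = components.cross_terms.profile(rho0, drho / components.shell_ref_contrast)
    q = np.linspace(calc.q[1], calc.q[-1], n_points)
    truth = fitting.interpolate_profile(calc, q).intensity
    sigma = (noise_fraction if noise_fraction > 0 else 0.01) * np.abs(truth)
    intensity = truth.copy()
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        intensity = truth + rng.normal(size=truth.shape) * sigma
    return model_io.ScatteringProfile(q, intensity, sigma)


@pytest.fixture(scope="session")
def noiseless_peptide_data(peptide_components):
    """Data generated from the peptide itself at (rho0, drho) = (0.340, 0.025)."""
    return synthetic_profile_from(peptide_components, 0.340, 0.025)
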