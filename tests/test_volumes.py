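import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxsaxs import synthetic
from voxsaxs.model_io import AtomRecord
from voxsaxs.synthetic import clipped_sphere_volume, sphere_volume
from voxsaxs.volumes import (
    AdjustedVolume,
    VolumeDictionary,
    VolumeSource,
    apply_volume_scale_factors,
    atom_volumes,
    build_volume_dictionary,
    unique_volume,
    unique_volumes,
)

R_C = 1.70  # Bondi carbon


class TestUniqueVolume:
    def test_isolated_atom_matches_sphere_volume(self):
        av = unique_volume(np.zeros((1, 3)), np.array([R_C]), 0)
        assert av.volume == pytest.approx(sphere_volume(R_C), rel=0.02)

    def test_fine_grid_converges(self):
        av = unique_volume(np.zeros((1, 3)), np.array([R_C]), 0, fine_grid_n=48)
        assert av.volume == pytest.approx(sphere_volume(R_C), rel=0.005)

    def test_oracle_equivalence_tightens_at_fine_grid(self):
        """One- and two-neighbor voxel volumes track the analytic
        sphere-minus-cap values to 0.5% at n = 48, including a clipping
        plane tilted against the voxel lattice."""
        cases = [
            (np.array([[0.0, 0, 0], [1.5, 0, 0]]), np.array([R_C, R_C])),
            (np.array([[0.0, 0, 0], [0.9, 0.9, 0.6]]), np.array([R_C, R_C])),
        ]
        for pos, radii in cases:
            d = np.linalg.norm(pos[1])
            v = unique_volume(pos, radii, 0, fine_grid_n=48).volume
            assert v == pytest.approx(clipped_sphere_volume(R_C, radii[1], d), rel=0.005)

    def test_two_carbons_match_cap_oracle(self):
        # equal radii 1.5 A apart: the radical plane is the perpendicular
        # bisector; analytic volume = sphere minus cap of height R - d/2
        pos = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        radii = np.array([R_C, R_C])
        av = unique_volume(pos, radii, 0)
        expected = clipped_sphere_volume(R_C, R_C, 1.5)
        assert expected == pytest.approx(16.66, abs=0.01)  # hand value
        assert av.volume == pytest.approx(expected, rel=0.02)

    def test_unequal_radii_match_radical_plane_oracle(self):
        pos = np.array([[0.0, 0, 0], [1.2, 0, 0]])
        radii = np.array([R_C, 1.52])  # C-O pair
        for idx in (0, 1):
            av = unique_volume(pos, radii, idx)
            expected = clipped_sphere_volume(radii[idx], radii[1 - idx], 1.2)
            assert av.volume == pytest.approx(expected, rel=0.02)

    def test_non_overlapping_neighbor_leaves_volume_unchanged(self):
        lone = unique_volume(np.zeros((1, 3)), np.array([R_C]), 0)
        pos = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        paired = unique_volume(pos, np.array([R_C, R_C]), 0)
        assert paired.volume == lone.volume

    def test_symmetric_pair_gets_equal_volumes(self):
        pos = np.array([[0.0, 0, 0], [1.4, 0.3, -0.2]])
        radii = np.array([R_C, R_C])
        v0 = unique_volume(pos, radii, 0).volume
        v1 = unique_volume(pos, radii, 1).volume
        assert v0 == pytest.approx(v1, rel=0.02)

    def test_coincident_atoms_warn_and_skip(self):
        pos = np.zeros((2, 3))
        with pytest.warns(UserWarning, match="identical coordinates"):
            av = unique_volume(pos, np.array([R_C, R_C]), 0)
        assert av.volume == pytest.approx(sphere_volume(R_C), rel=0.02)

    def test_engulfed_atom_clipped_to_zero(self):
        pos = np.array([[0.0, 0, 0], [0.5, 0, 0]])
        radii = np.array([1.2, 3.0])
        with pytest.warns(UserWarning, match="engulfed"):
            av = unique_volume(pos, radii, 0)
        assert av.volume == 0.0

    def test_nonpositive_radius_fatal(self):
        with pytest.raises(ValueError):
            unique_volume(np.zeros((1, 3)), np.array([-1.0]), 0)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.floats(1.0, 4.0), st.floats(0.0, 2 * np.pi),
                              st.floats(-1.0, 1.0)), min_size=1, max_size=5))
    def test_adding_neighbors_never_increases_volume(self, polar):
        """Clipping monotonicity: every added neighbor can only remove voxels."""
        centers = [np.zeros(3)]
        for d, phi, z in polar:
            s = np.sqrt(max(1 - z * z, 0.0))
            centers.append(d * np.array([s * np.cos(phi), s * np.sin(phi), z]))
        prev = np.inf
        for k in range(1, len(centers) + 1):
            pos = np.array(centers[:k])
            radii = np.full(k, R_C)
            if k > 1 and np.min(np.linalg.norm(pos[1:] - pos[0], axis=1)) < 1e-6:
                return  # degenerate coincidence; covered elsewhere
            v = unique_volume(pos, radii, 0).volume
            assert v <= prev + 1e-12
            prev = v

    def test_cluster_total_below_vdw_sum(self, peptide):
        """Overlapping bonded atoms displace less solvent than free spheres."""
        vols = unique_volumes(peptide.atoms)
        total = sum(v.volume for v in vols)
        from voxsaxs.model_io import radii_of

        free = sum(sphere_volume(r) for r in radii_of(peptide.atoms))
        assert total < free


class TestVolumeDictionary:
    def test_build_from_single_model_equals_explicit(self, peptide):
        vd = build_volume_dictionary([peptide.atoms])
        explicit = unique_volumes(peptide.atoms)
        # GLY N appears twice (one per residue); dictionary holds their mean
        n_values = [
            v.volume for a, v in zip(peptide.atoms, explicit)
            if (a.residue_name, a.atom_name) == ("GLY", "N")
        ]
        assert vd.lookup("GLY", "N") == pytest.approx(np.mean(n_values))
        assert vd.counts[("GLY", "N")] == 2

    def test_same_atom_name_in_two_residues_kept_distinct(self, peptide):
        renamed = [
            AtomRecord(a.position, a.element, a.atom_name, "ALA", a.b_factor, a.occupancy)
            for a in peptide.atoms
        ]
        vd = build_volume_dictionary([peptide.atoms, renamed])
        assert ("GLY", "CA") in vd.volumes and ("ALA", "CA") in vd.volumes

    def test_lookup_miss_falls_back_to_explicit(self, peptide):
        vd = build_volume_dictionary([peptide.atoms])
        del vd.volumes[("GLY", "OXT")]
        vols = atom_volumes(peptide.atoms, dictionary=vd)
        oxt = [v for a, v in zip(peptide.atoms, vols) if a.atom_name == "OXT"]
        assert oxt[0].source is VolumeSource.EXPLICIT
        others = [v for a, v in zip(peptide.atoms, vols) if a.atom_name != "OXT"]
        assert all(v.source is VolumeSource.DICTIONARY for v in others)

    def test_empty_corpus_fatal(self):
        with pytest.raises(ValueError):
            build_volume_dictionary([])

    def test_json_roundtrip(self, peptide, tmp_path):
        vd = build_volume_dictionary([peptide.atoms], provenance="test corpus")
        p = tmp_path / "vd.json"
        vd.to_json(p)
        back = VolumeDictionary.from_json(p)
        assert back.volumes == vd.volumes
        assert back.provenance == "test corpus"


class TestScaleFactors:
    def _vols(self):
        return [AdjustedVolume(0, 10.0), AdjustedVolume(1, 20.0), AdjustedVolume(2, 5.0)]

    def test_identity_factors_leave_volumes_unchanged(self):
        out = apply_volume_scale_factors(self._vols(), ["C", "N", "H"], {"C": 1.0, "N": 1.0, "H": 1.0})
        assert [v.volume for v in out] == [10.0, 20.0, 5.0]

    def test_selective_scaling(self):
        out = apply_volume_scale_factors(self._vols(), ["C", "N", "C"], {"C": 1.1})
        assert [v.volume for v in out] == pytest.approx([11.0, 20.0, 5.5])

    def test_nonpositive_factor_fatal(self):
        with pytest.raises(ValueError):
            apply_volume_scale_factors(self._vols(), ["C", "N", "H"], {"C": 0.0})


class TestCalibration:
    def _synthetic_data(self, peptide, factors):
        from voxsaxs import fitting, pipeline
        from voxsaxs.model_io import ScatteringProfile

        comp = pipeline.build_components(peptide.atoms, scale_factors=factors)
        calc = comp.cross_terms.profile(0.334, 1.0)
        q = np.linspace(calc.q[1], calc.q[-1], 201)
        truth = fitting.interpolate_profile(calc, q).intensity
        return ScatteringProfile(q, truth, 0.01 * np.abs(truth))

    def test_recovers_known_factors(self, peptide):
        from voxsaxs.volumes import calibrate_scale_factors

        true = {"H": 1.05, "C": 1.10, "N": 1.08, "O": 1.12}
        data = self._synthetic_data(peptide, true)
        rec = calibrate_scale_factors(peptide.atoms, data)
        for el, f in true.items():
            assert rec[el] == pytest.approx(f, rel=0.02)

    def test_identity_factors_recovered_and_objective_not_worsened(self, peptide):
        from voxsaxs import fitting, pipeline
        from voxsaxs.volumes import calibrate_scale_factors

        data = self._synthetic_data(peptide, {"H": 1.0, "C": 1.0, "N": 1.0, "O": 1.0})
        rec = calibrate_scale_factors(peptide.atoms, data, maxiter=600)
        for el in ("H", "C", "N", "O"):
            assert rec[el] == pytest.approx(1.0, rel=0.02)
        # chi2 with calibrated factors cannot exceed the identity-factor chi2
        comp_id = pipeline.build_components(peptide.atoms, scale_factors={})
        comp_cal = pipeline.build_components(peptide.atoms, scale_factors=rec)
        kw = dict(fit_rho0=False, fit_drho=True, rho0_start=0.334)
        chi_id = fitting.fit_parameters(data, comp_id.Fv, comp_id.Fx, comp_id.Fs, **kw).chi2
        chi_cal = fitting.fit_parameters(data, comp_cal.Fv, comp_cal.Fx, comp_cal.Fs, **kw).chi2
        assert chi_cal <= chi_id + 1e-9
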