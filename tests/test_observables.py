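"""Membrane observables against analytic and hand-computed oracles."""

import numpy as np
import pytest

from lipidbank import observables as obs
from lipidbank import synthetic as syn
from lipidbank.errors import InputError, ThicknessUndefinedError


def single_frame_system(atom_z, electrons, names, molecules, box=(10.0, 10.0, 10.0)):
    n = len(atom_z)
    coords = np.zeros((1, n, 3))
    coords[0, :, 2] = atom_z
    return obs.FrameEnsemble(
        coords=coords,
        box=np.array([box]),
        times=np.array([0.0]),
        electron_counts=np.array(electrons, dtype=float),
        molecule_ids=np.arange(n),
        molecule_names=np.array(molecules, dtype=object),
        atom_names=np.array(names, dtype=object),
    )


class TestOrderParameters:
    def bond_system(self, direction, n_lipids=5, n_frames=3):
        """Lipids with one C-H bond along a fixed direction."""
        coords = np.zeros((n_frames, 2 * n_lipids, 3))
        for li in range(n_lipids):
            coords[:, 2 * li + 1, :] = 0.109 * np.asarray(direction)
        return obs.FrameEnsemble(
            coords=coords,
            box=np.tile([5.0, 5.0, 10.0], (n_frames, 1)),
            times=np.arange(n_frames, dtype=float),
            electron_counts=np.tile([6.0, 1.0], n_lipids),
            molecule_ids=np.repeat(np.arange(n_lipids), 2),
            molecule_names=np.full(2 * n_lipids, "POPC", dtype=object),
            atom_names=np.array(["C1", "H1"] * n_lipids, dtype=object),
        )

    @pytest.mark.parametrize(
        "direction,expected",
        [((0, 0, 1), 1.0), ((1, 0, 0), -0.5), ((0, 1, 0), -0.5)],
    )
    def test_axis_aligned_bonds(self, direction, expected):
        traj = self.bond_system(direction)
        ops = obs.order_parameters(traj, [("C1", "H1")], "POPC")
        stat = ops.bonds["C1 H1"]
        assert stat.s_mean == pytest.approx(expected, abs=1e-12)
        assert stat.sem == pytest.approx(0.0, abs=1e-12)

    def test_uniform_sphere_is_disordered(self, rng):
        # Monte-Carlo oracle: <(3 cos^2 - 1)/2> over the sphere is zero
        n_lipids, n_frames = 100, 100
        u = rng.standard_normal((n_frames, n_lipids, 3))
        u /= np.linalg.norm(u, axis=2, keepdims=True)
        coords = np.zeros((n_frames, 2 * n_lipids, 3))
        coords[:, 1::2, :] = 0.109 * u
        traj = obs.FrameEnsemble(
            coords=coords,
            box=np.tile([5.0, 5.0, 10.0], (n_frames, 1)),
            times=np.arange(n_frames, dtype=float),
            electron_counts=np.tile([6.0, 1.0], n_lipids),
            molecule_ids=np.repeat(np.arange(n_lipids), 2),
            molecule_names=np.full(2 * n_lipids, "POPC", dtype=object),
            atom_names=np.array(["C1", "H1"] * n_lipids, dtype=object),
        )
        stat = obs.order_parameters(traj, [("C1", "H1")], "POPC").bonds["C1 H1"]
        assert abs(stat.s_mean) < 3 * stat.sem

    def test_bounds_for_arbitrary_geometry(self, rng):
        traj, bonds = syn.make_oriented_bond_trajectory(
            0.3, n_lipids=5, n_frames=10, seed=3, tilt_noise=0.5
        )
        for stat in obs.order_parameters(traj, bonds, "POPC").bonds.values():
            assert -0.5 <= stat.s_mean <= 1.0

    def test_per_lipid_first_equals_pooled_average(self, rng):
        traj, bonds = syn.make_oriented_bond_trajectory(
            0.2, n_lipids=8, n_frames=12, seed=5, tilt_noise=0.2
        )
        stat = obs.order_parameters(traj, bonds[:1], "POPC").bonds[
            f"{bonds[0][0]} {bonds[0][1]}"
        ]
        c = traj.coords[:, traj.atom_names == bonds[0][0], :]
        h = traj.coords[:, traj.atom_names == bonds[0][1], :]
        v = h - c
        cos2 = (v[..., 2] / np.linalg.norm(v, axis=-1)) ** 2
        pooled = np.mean(1.5 * cos2 - 0.5)
        assert stat.s_mean == pytest.approx(pooled, rel=1e-12)


class TestElectronDensity:
    def test_single_atom_histogram_arithmetic(self):
        traj = single_frame_system(
            [0.0, 4.0], [8.0, 0.0], ["O", "OW"], ["POPC", "SOL"]
        )
        prof = obs.electron_density_profile(traj, ["POPC"], ["SOL"])
        # bin volume = (100 A)^2 * (1/3 A); all 8 electrons land in one bin
        expected = 8.0 / (100.0 * 100.0 * (1.0 / 3.0))
        assert prof.rho_total.max() == pytest.approx(expected, rel=1e-12)
        assert prof.rho_total.sum() == pytest.approx(expected, rel=1e-12)

    def test_translation_invariance_from_com_centering(self):
        traj = single_frame_system(
            [0.3, -0.8, 4.0], [8.0, 4.0, 0.0], ["O", "C", "OW"], ["POPC", "POPC", "SOL"]
        )
        prof1 = obs.electron_density_profile(traj, ["POPC"], ["SOL"])
        shifted = obs.FrameEnsemble(
            coords=traj.coords + 1.0,
            box=traj.box,
            times=traj.times,
            electron_counts=traj.electron_counts,
            molecule_ids=traj.molecule_ids,
            molecule_names=traj.molecule_names,
            atom_names=traj.atom_names,
        )
        prof2 = obs.electron_density_profile(shifted, ["POPC"], ["SOL"])
        np.testing.assert_allclose(prof1.rho_total, prof2.rho_total, atol=1e-12)

    def test_uniform_solvent_gives_zero_contrast(self, rng):
        n_water = 3000
        z = rng.uniform(-5.0, 5.0, n_water)
        traj = single_frame_system(
            np.concatenate([[0.0], z]),
            [1e-9] + [10.0] * n_water,
            ["C"] + ["OW"] * n_water,
            ["POPC"] + ["SOL"] * n_water,
        )
        prof = obs.electron_density_profile(traj, ["POPC"], ["SOL"])
        # contrast vanishes wherever solvent reaches its own plateau
        assert np.abs(prof.delta_rho).max() <= np.abs(
            prof.rho_solvent - prof.rho_solvent.mean()
        ).max() + 1e-9

    def test_empty_selection_rejected(self):
        traj = single_frame_system([0.0, 1.0], [8, 8], ["O", "OW"], ["POPC", "SOL"])
        with pytest.raises(InputError):
            obs.electron_density_profile(traj, ["CHOL"], ["SOL"])


class TestFormFactor:
    def test_slab_matches_closed_form(self):
        prof = syn.make_slab_profile(d=40.0, contrast=0.1)
        ff = obs.form_factor(prof)
        exact = syn.slab_form_factor(ff.q, 40.0, 0.1)
        rel_rms = np.sqrt(np.mean((ff.F_abs - exact) ** 2)) / np.sqrt(np.mean(exact**2))
        assert rel_rms < 0.005

    def test_zero_profile_gives_zero(self):
        prof = syn.make_slab_profile(d=40.0, contrast=0.0)
        ff = obs.form_factor(prof)
        assert np.allclose(ff.F_abs, 0.0)

    def test_mirror_invariance(self):
        prof = syn.make_slab_profile(d=40.0, contrast=0.1)
        asym = obs.ElectronDensityProfile(
            prof.bin_centers,
            prof.rho_total,
            prof.rho_solvent,
            prof.delta_rho * (1.0 + 0.3 * np.sign(prof.bin_centers)),
        )
        mirrored = obs.ElectronDensityProfile(
            asym.bin_centers, asym.rho_total, asym.rho_solvent, asym.delta_rho[::-1]
        )
        np.testing.assert_allclose(
            obs.form_factor(asym).F_abs, obs.form_factor(mirrored).F_abs, atol=1e-9
        )

    def test_f_at_zero_equals_integral(self):
        prof = syn.make_slab_profile(d=35.0, contrast=0.07)
        ff = obs.form_factor(prof)
        assert ff.F_abs[0] == pytest.approx(
            abs(np.sum(prof.delta_rho) * prof.bin_width), rel=1e-12
        )

    def test_first_minimum_invariant_under_padding(self):
        from lipidbank.quality import first_form_factor_minimum

        small = obs.form_factor(syn.make_slab_profile(40.0, 0.1, box=100.0))
        padded = obs.form_factor(syn.make_slab_profile(40.0, 0.1, box=200.0))
        m1 = first_form_factor_minimum(small.q, small.F_abs)
        m2 = first_form_factor_minimum(padded.q, padded.F_abs)
        assert abs(m1 - m2) < 0.001


class TestAreaPerLipid:
    def test_worked_example(self):
        traj = single_frame_system([0.0], [8.0], ["O"], ["POPC"], box=(6.4, 6.4, 10.0))
        assert obs.area_per_lipid(traj, 128) == pytest.approx(64.0)

    def test_linearity_in_box_area(self):
        t1 = single_frame_system([0.0], [8.0], ["O"], ["POPC"], box=(6.4, 6.4, 10.0))
        t2 = single_frame_system([0.0], [8.0], ["O"], ["POPC"], box=(6.4, 12.8, 10.0))
        assert obs.area_per_lipid(t2, 128) == pytest.approx(
            2 * obs.area_per_lipid(t1, 128)
        )

    def test_fluctuating_box_uses_time_average(self):
        traj = single_frame_system([0.0], [8.0], ["O"], ["POPC"])
        traj.coords = np.repeat(traj.coords, 2, axis=0)
        traj.times = np.array([0.0, 1.0])
        traj.box = np.array([[6.0, 6.0, 10.0], [7.0, 7.0, 10.0]])
        expected = 2 * 100.0 * np.mean([36.0, 49.0]) / 128
        assert obs.area_per_lipid(traj, 128) == pytest.approx(expected)

    def test_zero_molecules_rejected(self):
        traj = single_frame_system([0.0], [8.0], ["O"], ["POPC"])
        with pytest.raises(InputError):
            obs.area_per_lipid(traj, 0)


class TestThickness:
    z = np.linspace(-50.0, 50.0, 301)

    def test_step_profiles(self):
        lipid = np.where(np.abs(self.z) < 20.0, 1.0, 0.0)
        water = 1.0 - lipid
        assert obs.bilayer_thickness(lipid, water, self.z) == pytest.approx(4.0, abs=0.05)

    def test_triangular_profiles_analytic_crossing(self):
        lipid = np.clip(1.0 - np.abs(self.z) / 30.0, 0.0, None)
        water = np.full_like(self.z, 0.5)
        # 1 - |z|/30 = 0.5 at z = +-15 A -> 3.0 nm
        assert obs.bilayer_thickness(lipid, water, self.z) == pytest.approx(3.0, abs=1e-6)

    def test_translation_invariance(self):
        lipid = np.clip(1.0 - np.abs(self.z - 5.0) / 30.0, 0.0, None)
        water = np.full_like(self.z, 0.5)
        assert obs.bilayer_thickness(lipid, water, self.z) == pytest.approx(3.0, abs=1e-6)

    def test_no_crossing_rejected(self):
        lipid = np.full_like(self.z, 1.0)
        water = np.full_like(self.z, 0.2)
        with pytest.raises(ThicknessUndefinedError):
            obs.bilayer_thickness(lipid, water, self.z)
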