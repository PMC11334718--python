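"""Structural statistics: RDF normalisation and shell detection,
coordination decomposition, hydration and orientation histograms, and
axial/radial/planar densities."""

import numpy as np
import pytest

from cntchan.atoms import AtomSet, Trajectory
from cntchan.solvation import (ShellSpec, coordination_profile, density,
                               hydration_histogram, locate_profile_peaks,
                               orientation_histogram, rdf)
from cntchan.synthetic import (generate_solvation_snapshot,
                               generate_uniform_gas)

from conftest import gas_trajectory


class TestRDF:
    def test_ideal_gas_is_unity(self):
        traj = gas_trajectory(n=5000, seed=1)
        res = rdf(traj, "water_O", ("water_O",), r_max=10.0, dr=0.25)
        window = (res.r >= 3.0) & (res.r <= 10.0)
        assert np.all(np.abs(res.g["total"][window] - 1.0) < 0.05)

    def test_error_shrinks_with_sample_size(self):
        def rms_dev(n, seed):
            traj = gas_trajectory(n=n, seed=seed)
            res = rdf(traj, "water_O", ("water_O",), r_max=10.0, dr=0.25)
            w = (res.r >= 3.0) & (res.r <= 10.0)
            return np.sqrt(np.mean((res.g["total"][w] - 1.0) ** 2))

        assert rms_dev(5000, 2) < rms_dev(600, 2)

    def test_single_pair_mass_in_one_bin(self):
        atoms = AtomSet.from_tags(["ion_K", "water_O"],
                                  [[0, 0, 0], [0, 0, 3.0]])
        traj = Trajectory.from_atomset(atoms)
        res = rdf(traj, "ion_K", ("water_O",), r_max=5.0, dr=0.2,
                  bulk_density=0.01)
        hit = np.nonzero(res.g["water_O"])[0]
        assert len(hit) == 1
        assert res.r[hit[0]] == pytest.approx(3.1, abs=0.100001)

    def test_constructed_first_minimum_detected(self):
        # bimodal partner distances: equal gaussians at 2.8 and 4.4 Å put
        # the density minimum midway, at the 3.6 Å shell radius
        rng = np.random.default_rng(0)
        n = 20_000
        d = np.where(rng.random(n) < 0.5,
                     rng.normal(2.8, 0.35, n), rng.normal(4.4, 0.35, n))
        d = np.clip(d, 0.5, 6.5)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pos = np.vstack([[0.0, 0.0, 0.0], d[:, None] * v])
        atoms = AtomSet.from_tags(["ion_K"] + ["water_O"] * n, pos)
        traj = Trajectory.from_atomset(atoms)
        res = rdf(traj, "ion_K", ("water_O",), r_max=7.0, dr=0.1,
                  bulk_density=0.0334)
        assert res.first_min == pytest.approx(3.6, abs=0.1)
        assert res.first_peak == pytest.approx(2.8, abs=0.15)

    def test_empty_partner_set_rejected(self):
        traj = gas_trajectory(n=10)
        with pytest.raises(ValueError):
            rdf(traj, "water_O", ())


def snapshot_traj(**kwargs):
    return Trajectory.from_atomset(generate_solvation_snapshot(**kwargs))


class TestCoordination:
    def test_mixed_shell_decomposition(self):
        traj = snapshot_traj(ion="Na", n_water=2, n_carbonyl=4,
                             radii={"water_O": 2.9, "carbonyl_O": 2.4},
                             seed=0)
        prof = coordination_profile(traj, species=("ion_Na",))
        b = np.nanargmax(prof.counts["ion_Na"])
        assert prof.total["ion_Na"][b] == 6.0
        assert prof.carbonyl["ion_Na"][b] == 4.0
        assert prof.water["ion_Na"][b] == 2.0

    def test_empty_neighbourhood_is_zero(self):
        traj = snapshot_traj(ion="K", n_water=0, n_carbonyl=0)
        prof = coordination_profile(traj, species=("ion_K",))
        b = np.nanargmax(prof.counts["ion_K"])
        assert prof.total["ion_K"][b] == 0.0

    def test_additivity_and_bruteforce_oracle(self):
        # random fixture: ion in a uniform gas, counts checked by pair scan
        gas = generate_uniform_gas(400, (20, 20, 20), seed=4)
        pos = np.vstack([[10.0, 10.0, 10.0], gas.positions])
        atoms = AtomSet.from_tags(["ion_K"] + ["water_O"] * 400, pos)
        traj = Trajectory.from_atomset(atoms)
        shells = ShellSpec()
        prof = coordination_profile(traj, shells, species=("ion_K",))
        b = np.nanargmax(prof.counts["ion_K"])
        brute = int(np.sum(np.linalg.norm(gas.positions
                                          - [10, 10, 10], axis=1) <= 3.6))
        assert prof.total["ion_K"][b] == brute
        np.testing.assert_allclose(
            np.nan_to_num(prof.total["ion_K"]),
            np.nan_to_num(prof.carbonyl["ion_K"] + prof.water["ion_K"]))


class TestHydration:
    def test_point_mass_at_six(self):
        traj = snapshot_traj(ion="K", n_water=6, seed=1)
        assert hydration_histogram(traj, species="ion_K") == {6: 1.0}

    def test_constructed_mixture_is_half_half(self):
        a = generate_solvation_snapshot("K", n_water=6, seed=2)
        b = a.copy()
        # push one water (O and its H's) far outside the shell
        o_idx = np.nonzero(b.mask("water_O"))[0][0]
        b.positions[o_idx:o_idx + 3] += 20.0
        pos = np.stack([a.positions, b.positions])
        traj = Trajectory(pos, a.tags, a.elements, np.array([0.0, 0.01]))
        hist = hydration_histogram(traj, species="ion_K")
        assert hist == {5: 0.5, 6: 0.5}

    def test_histogram_normalised(self):
        traj = snapshot_traj(ion="Na", n_water=4, n_carbonyl=2, seed=3)
        assert sum(hydration_histogram(traj, species="ion_Na").values()) == \
            pytest.approx(1.0)

    def test_no_water_rejected(self):
        traj = snapshot_traj(ion="K", n_water=0, n_carbonyl=2)
        with pytest.raises(ValueError, match="water"):
            hydration_histogram(traj, species="ion_K")


class TestOrientation:
    def test_aligned_dipoles_first_bin(self):
        traj = snapshot_traj(ion="K", n_water=10, seed=0,
                             dipole_axis=(0, 0, 1))
        res = orientation_histogram(traj, species="ion_K")
        assert res["p"][0] == pytest.approx(1.0)

    def test_antialigned_dipoles_last_bin(self):
        traj = snapshot_traj(ion="K", n_water=10, seed=0,
                             dipole_axis=(0, 0, -1))
        res = orientation_histogram(traj, species="ion_K")
        assert res["p"][-1] == pytest.approx(1.0)

    def test_isotropic_matches_sin_theta_baseline(self):
        # radially-pointing dipoles on an isotropic shell are isotropic
        frames = [generate_solvation_snapshot("K", n_water=40, seed=s)
                  for s in range(50)]
        pos = np.stack([f.positions for f in frames])
        traj = Trajectory(pos, frames[0].tags, frames[0].elements,
                          0.01 * np.arange(len(frames)))
        res = orientation_histogram(traj, species="ion_K")
        n = res["n_samples"]
        q = res["isotropic"]
        bound = 3 * np.sqrt(q * (1 - q) / n)
        assert np.all(np.abs(res["p"] - q) <= bound + 1e-12)

    def test_missing_hydrogens_rejected(self):
        gas = generate_uniform_gas(10, (10, 10, 10), seed=1)
        traj = Trajectory.from_atomset(gas)
        with pytest.raises(ValueError, match="hydrogen"):
            orientation_histogram(traj, species="ion_K")


class TestDensity:
    def test_uniform_gas_axial_flat(self):
        traj = gas_trajectory(n=20_000, n_frames=5, seed=3, centered=True)
        res = density(traj, "water_O", "axial",
                      bins=np.arange(-20, 20.01, 2.0))
        assert np.all(np.abs(res.density / res.density.mean() - 1.0) < 0.05)

    def test_uniform_gas_radial_flat(self):
        traj = gas_trajectory(n=20_000, n_frames=20, seed=5, centered=True)
        res = density(traj, "water_O", "radial", dr=0.5, r_max=8.0,
                      z_range=(-15, 15))
        rel = res.density / res.density.mean() - 1.0
        # well-populated annuli flat within 5%; sparse innermost within 5 sigma
        counts = res.density * res.bin_measure * traj.n_frames
        good = counts > 2000
        assert np.all(np.abs(rel[good]) < 0.05)
        assert np.all(np.abs(rel) < 5.0 / np.sqrt(counts) + 0.05)

    def test_single_static_particle_delta(self):
        atoms = AtomSet.from_tags(["ion_K"], [[0.3, 0.0, 2.2]])
        traj = Trajectory.from_atomset(atoms)
        res = density(traj, "ion_K", "axial", bins=np.arange(-5, 5.01, 0.5))
        hit = np.nonzero(res.density)[0]
        assert len(hit) == 1 and res.grid[0][hit[0]] == pytest.approx(2.25)

    def test_density_integrates_to_mean_count(self, gen_traj):
        traj, _ = gen_traj
        res = density(traj, "ion_K", "axial")
        total = float((res.density * res.bin_measure).sum())
        assert total == pytest.approx(res.mean_count, rel=1e-9)
        # and mean_count is the brute-force in-domain average
        z = traj.positions[:, traj.atom_indices("ion_K"), 2]
        manual = np.mean(np.sum((z >= -12.0) & (z <= 12.0), axis=1))
        assert res.mean_count == pytest.approx(manual)

    def test_generator_k_axial_has_six_peaks(self, gen_traj):
        traj, _ = gen_traj
        res = density(traj, "ion_K", "axial")
        peaks = locate_profile_peaks(res)
        assert len(peaks) == 6
        expected = [-6.3, -4.05, -1.35, 1.35, 4.05, 6.3]
        assert np.allclose(sorted(peaks), expected, atol=0.5)

    def test_generator_radial_separation_k_on_axis_na_off_axis(self, gen_traj):
        traj, _ = gen_traj
        rad_k = density(traj, "ion_K", "radial", dr=0.25)
        rad_na = density(traj, "ion_Na", "radial", dr=0.25)
        peak_k = rad_k.grid[0][np.argmax(rad_k.density)]
        peak_na = rad_na.grid[0][np.argmax(rad_na.density)]
        assert peak_k < 1.0
        assert peak_na == pytest.approx(2.0, abs=0.5)

    def test_planar_map_mass_near_axis(self, gen_traj):
        traj, _ = gen_traj
        res = density(traj, "ion_K", "planar", dxy=0.5)
        x, y = res.grid
        ix, iy = np.unravel_index(np.argmax(res.density), res.density.shape)
        assert abs(x[ix]) < 1.0 and abs(y[iy]) < 1.0

    def test_unknown_mode_rejected(self, gen_traj):
        traj, _ = gen_traj
        with pytest.raises(ValueError):
            density(traj, "ion_K", "spherical")
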