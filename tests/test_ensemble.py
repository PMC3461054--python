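"""Ensemble metrics: superposition, fluctuations, SASA, interactions, helicity."""

import math

import numpy as np
import pandas as pd
import pytest

from coilmelt import ensemble as ens
from coilmelt import simulate as sim
from coilmelt.ensemble import (AtomSelection, EnsembleFormatError,
                               StructureEnsemble, atom_sasa, helicity,
                               hydrophobic_contacts, kabsch_superpose,
                               radius_of_gyration, read_ensemble, rmsd_series,
                               rmsf, salt_bridges, sasa_partition,
                               write_ensemble)


def ca_atoms(n, chain="A"):
    return pd.DataFrame({"chain": chain, "resid": np.arange(1, n + 1),
                         "resname": "ALA", "name": "CA", "element": "C"})


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


class TestKabsch:
    def test_identical_frames_have_zero_rmsd(self, rng):
        P = rng.normal(size=(8, 3))
        _, _, r = kabsch_superpose(P, P)
        assert r < 1e-12

    def test_rigid_motion_is_removed(self, rng):
        P = rng.normal(size=(10, 3))
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        Q = P @ R.T + np.array([5.0, -3.0, 2.0])
        _, _, r = kabsch_superpose(P, Q)
        assert r < 1e-8

    def test_rotation_is_proper(self, rng):
        P = rng.normal(size=(6, 3))
        # mirror image: an improper transform must not be "solved" by a flip
        Q = P * np.array([-1.0, 1.0, 1.0])
        R, _, _ = kabsch_superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0)

    @staticmethod
    def _quat_rotations(quats):
        q = quats / np.linalg.norm(quats, axis=1, keepdims=True)
        w, x, y, z = q.T
        return np.stack([
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z),
                      2 * (x * z + w * y)], axis=-1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z),
                      2 * (y * z - w * x)], axis=-1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x),
                      1 - 2 * (x * x + y * y)], axis=-1)], axis=1)

    def test_matches_brute_force_quaternion_search(self):
        # oracle: dense random quaternion sampling plus local refinement,
        # entirely independent of the SVD solution
        rng = np.random.default_rng(77)
        for _ in range(3):
            P = rng.normal(size=(6, 3))
            Q = rng.normal(size=(6, 3))
            _, _, r_kabsch = kabsch_superpose(Q, P)
            P0 = P - P.mean(axis=0)
            Q0 = Q - Q.mean(axis=0)

            def rmsd_batch(quats):
                R = self._quat_rotations(quats)
                moved = np.einsum("kij,nj->kni", R, P0)
                return np.sqrt(((moved - Q0) ** 2).sum(axis=2).mean(axis=1))

            quats = rng.normal(size=(200_000, 4))
            r = rmsd_batch(quats)
            best_q = quats[np.argmin(r)]
            for scale in (0.05, 0.01, 0.002):
                local = best_q + rng.normal(scale=scale, size=(20_000, 4))
                r = rmsd_batch(local)
                best_q = local[np.argmin(r)]
            best = float(r.min())
            assert r_kabsch <= best + 1e-9
            assert abs(r_kabsch - best) < 1e-3

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def test_static_ensemble_is_zero(self, ideal_helix30):
        xyz = np.repeat(ideal_helix30.coords, 4, axis=0)
        e = StructureEnsemble(ideal_helix30.atoms, xyz)
        assert np.allclose(rmsd_series(e, selection="calpha"), 0.0)

    def test_rigid_motion_frames_are_zero(self, ideal_helix30, rng):
        base = ideal_helix30.coords[0]
        moved = base @ random_rotation(rng).T + np.array([3.0, 1.0, -2.0])
        e = StructureEnsemble(ideal_helix30.atoms, np.stack([base, moved]))
        assert np.allclose(rmsd_series(e, selection="calpha"), 0.0, atol=1e-8)

    def test_mean_rmsd_matches_displacement_expectation(self, ideal_helix30):
        # isotropic per-atom sigma: E[RMSD^2] ~ 3 sigma^2 (minus the 6 rigid
        # degrees of freedom absorbed by superposition)
        sigma = 0.5
        means = []
        for seed in range(50):
            e = sim.perturb_ensemble(sim.EnsembleGenerator(
                base=ideal_helix30, sigma_A=sigma, n_frames=10, seed=seed))
            means.append(rmsd_series(e, selection="calpha",
                                     reference=ideal_helix30.coords[0]).mean())
        n_atoms = ideal_helix30.n_atoms
        expect = sigma * math.sqrt(3.0) * math.sqrt(1 - 6.0 / (3 * n_atoms))
        assert np.mean(means) == pytest.approx(expect, rel=0.10)

    def test_nm_flag_scales_by_ten(self, ideal_helix30):
        e = sim.perturb_ensemble(sim.EnsembleGenerator(
            base=ideal_helix30, sigma_A=0.3, n_frames=5, seed=0))
        a = rmsd_series(e, selection="calpha")
        b = rmsd_series(e, selection="calpha", nm=True)
        assert np.allclose(a, b * 10)


class TestRmsf:
    def test_static_ensemble_is_zero(self, ideal_helix30):
        xyz = np.repeat(ideal_helix30.coords, 3, axis=0)
        e = StructureEnsemble(ideal_helix30.atoms, xyz)
        assert np.allclose(rmsf(e)["rmsf_A"], 0.0)

    def test_single_frame_rejected(self, ideal_helix30):
        with pytest.raises(ValueError):
            rmsf(ideal_helix30)

    def test_planted_sigma_profile_recovered(self):
        base = sim.gen_ideal_helix(40)
        profile = np.linspace(0.2, 0.6, 40)
        e = sim.perturb_ensemble(sim.EnsembleGenerator(
            base=base, sigma_A=profile, n_frames=500, seed=11))
        out = rmsf(e)["rmsf_A"].to_numpy()
        assert np.all(np.abs(out - profile * math.sqrt(3)) /
                      (profile * math.sqrt(3)) < 0.10)

    def test_global_rigid_motion_does_not_inflate_rmsf(self):
        base = sim.gen_ideal_helix(24)
        still = sim.perturb_ensemble(sim.EnsembleGenerator(
            base=base, sigma_A=0.4, n_frames=200, seed=5))
        moving = sim.perturb_ensemble(sim.EnsembleGenerator(
            base=base, sigma_A=0.4, n_frames=200, seed=5, rigid_motion=True))
        a = rmsf(still)["rmsf_A"].to_numpy()
        b = rmsf(moving)["rmsf_A"].to_numpy()
        assert np.allclose(a, b, rtol=0.15)


class TestRadiusOfGyration:
    def test_two_point_symmetry(self):
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        atoms = pd.DataFrame({"chain": "A", "resid": [1, 1], "resname": "ALA",
                              "name": ["C1", "C2"], "element": ["C", "C"]})
        assert radius_of_gyration(frame, atoms) == pytest.approx(0.1)

    def test_translation_invariance(self, ideal_helix30):
        xyz = ideal_helix30.coords[0]
        a = radius_of_gyration(xyz, ideal_helix30.atoms)
        b = radius_of_gyration(xyz + np.array([10.0, -4.0, 7.0]),
                               ideal_helix30.atoms)
        assert a == pytest.approx(b)

    def test_matches_direct_summation(self, rng):
        xyz = rng.normal(scale=5.0, size=(100, 3))
        elements = rng.choice(["C", "N", "O", "S"], size=100)
        atoms = pd.DataFrame({"chain": "A", "resid": np.arange(100),
                              "resname": "ALA", "name": "X",
                              "element": elements})
        masses = np.array([ens.ATOMIC_MASSES[e] for e in elements])
        com = (masses[:, None] * xyz).sum(axis=0) / masses.sum()
        expect = math.sqrt((masses * ((xyz - com) ** 2).sum(axis=1)).sum()
                           / masses.sum()) / 10.0
        assert radius_of_gyration(xyz, atoms) == pytest.approx(expect, abs=1e-10)


class TestSasa:
    def test_isolated_sphere_analytic_area(self):
        area = atom_sasa(np.array([[0.0, 0, 0]]), ["C"])[0]
        assert area == pytest.approx(4 * math.pi * (1.7 + 1.4) ** 2, rel=1e-12)

    def test_two_sphere_analytic_overlap(self):
        # two identical expanded spheres of radius R at separation d lose a
        # cap of height h = R - d/2 each: A = 2*(4 pi R^2 - 2 pi R h)
        R = 1.7 + 1.4
        d = 3.0
        frame = np.array([[0.0, 0, 0], [d, 0, 0]])
        total = atom_sasa(frame, ["C", "C"], n_sphere_points=2000).sum()
        h = R - d / 2
        analytic = 2 * (4 * math.pi * R ** 2 - 2 * math.pi * R * h)
        assert total == pytest.approx(analytic, rel=0.01)

    def test_partition_conserves_total(self, rng):
        frame, atoms = sim.build_salt_bridge_frame(3.5)
        part = sasa_partition(frame, atoms, n_sphere_points=240)
        assert part.total_nm2 == pytest.approx(
            part.hydrophobic_nm2 + part.hydrophilic_nm2, abs=1e-9)
        assert part.hydrophilic_nm2 > 0  # GLU and LYS are both hydrophilic

    def test_rotation_invariance(self, rng):
        frame, atoms = sim.build_salt_bridge_frame(3.5)
        moved = frame @ random_rotation(rng).T + np.array([4.0, 4.0, -1.0])
        a = sasa_partition(frame, atoms, n_sphere_points=480)
        b = sasa_partition(moved, atoms, n_sphere_points=480)
        assert a.total_nm2 == pytest.approx(b.total_nm2, rel=0.01)

    def test_unknown_element_gets_default_radius(self):
        area = atom_sasa(np.array([[0.0, 0, 0]]), ["ZZ"])[0]
        assert area == pytest.approx(4 * math.pi * (1.5 + 1.4) ** 2, rel=1e-12)

    def test_matches_independent_implementation(self):
        mdtraj = pytest.importorskip("mdtraj")
        frame, atoms = sim.build_salt_bridge_frame(4.0)
        mine = atom_sasa(frame, atoms["element"], n_sphere_points=960)
        top = mdtraj.Topology()
        ch = top.add_chain()
        res = top.add_residue("GLU", ch)
        radii = {"C": 1.7, "N": 1.55, "O": 1.52}
        for i, el in enumerate(atoms["element"]):
            top.add_atom(f"X{i}", mdtraj.element.carbon, res)
        traj = mdtraj.Trajectory(frame[None] / 10.0, top)
        ref = mdtraj.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960,
                                   change_radii={"C": 0.17}).sum() * 100.0
        mine_c = atom_sasa(frame, ["C"] * len(atoms), n_sphere_points=960).sum()
        assert mine_c == pytest.approx(ref, rel=0.02)


class TestInteractions:
    def test_constructed_bridge_found_interchain(self):
        frame, atoms = sim.build_salt_bridge_frame(3.5)
        found = salt_bridges(frame, atoms, cutoff=4.0)
        assert len(found) == 1
        assert found[0].interchain
        assert found[0].distance_A == pytest.approx(3.5, abs=1e-6)

    def test_bridge_beyond_cutoff_ignored(self):
        frame, atoms = sim.build_salt_bridge_frame(4.5)
        assert salt_bridges(frame, atoms, cutoff=4.0) == []

    def test_bridge_persistence_over_frames(self):
        near, atoms = sim.build_salt_bridge_frame(3.5)
        far, _ = sim.build_salt_bridge_frame(5.5)
        counts = [len(salt_bridges(f, atoms, cutoff=4.0))
                  for f in [near, far, near, far]]
        assert np.mean(counts) == pytest.approx(0.5)

    def test_hydrophobic_pair_across_chains(self):
        frame, atoms = sim.build_salt_bridge_frame(4.0, pair=("LEU", "LEU"))
        n, pairs = hydrophobic_contacts(frame, atoms, cutoff=5.0)
        assert n == 1
        assert pairs[0][0][0] != pairs[0][1][0]

    def test_same_chain_excluded_by_default(self):
        frame, atoms = sim.build_salt_bridge_frame(
            4.0, pair=("LEU", "LEU"), chains=("A", "A"))
        assert hydrophobic_contacts(frame, atoms, cutoff=5.0)[0] == 0
        assert hydrophobic_contacts(frame, atoms, cutoff=5.0,
                                    interchain_only=False)[0] == 1

    def test_contacts_match_brute_force(self, rng):
        frames, tables = [], []
        for k, chain in enumerate("AB"):
            for j in range(3):
                f, a = sim.build_salt_bridge_frame(4.0, pair=("LEU", "LEU"))
                offset = rng.normal(scale=6.0, size=3)
                frames.append(f[:8] + offset)
                a = a.iloc[:8].copy()
                a["chain"] = chain
                a["resid"] = 10 * k + j
                tables.append(a)
        frame = np.concatenate(frames)
        atoms = pd.concat(tables, ignore_index=True)
        n, pairs = hydrophobic_contacts(frame, atoms, cutoff=5.0)
        # brute force over residue pairs
        expected = set()
        groups = {key: sub for key, sub in
                  atoms[~atoms["name"].isin(ens.BACKBONE_ATOMS)]
                  .groupby(["chain", "resid", "resname"], sort=False)}
        keys = list(groups)
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                if keys[i][0] == keys[j][0]:
                    continue
                d = np.linalg.norm(
                    frame[groups[keys[i]].index][:, None]
                    - frame[groups[keys[j]].index][None], axis=2).min()
                if d <= 5.0:
                    expected.add((keys[i], keys[j]))
        assert {(p[0], p[1]) for p in pairs} == expected


class TestHelicity:
    def test_ideal_helix_fully_helical(self, ideal_helix30):
        pct, codes = helicity(ideal_helix30.coords[0], ideal_helix30.atoms)
        assert pct >= 95.0

    def test_extended_chain_scores_zero(self):
        n = 30
        xyz = np.column_stack([np.arange(n) * 3.5, np.zeros(n), np.zeros(n)])
        assert helicity(xyz, ca_atoms(n))[0] == 0.0

    def test_helix_coil_helix_fraction(self):
        h1 = sim.gen_ideal_helix(20).coords[0]
        h2 = sim.gen_ideal_helix(20).coords[0]
        coil = np.column_stack([np.zeros(10), np.zeros(10),
                                np.arange(1, 11) * 3.5]) + h1[-1]
        seg3 = h2 + (coil[-1] - h2[0]) + np.array([0, 0, 3.5])
        xyz = np.concatenate([h1, coil, seg3])
        pct, _ = helicity(xyz, ca_atoms(50))
        assert 60.0 <= pct <= 90.0

    def test_short_chains_excluded(self):
        xyz = np.zeros((4, 3)) + np.arange(4)[:, None]
        with pytest.raises(ValueError):
            helicity(xyz, ca_atoms(4))

    def test_rotation_invariance(self, ideal_helix30, rng):
        xyz = ideal_helix30.coords[0]
        moved = xyz @ random_rotation(rng).T + 5.0
        assert helicity(xyz, ideal_helix30.atoms)[0] == \
            helicity(moved, ideal_helix30.atoms)[0]


class TestIOAndReport:
    def test_multimodel_round_trip(self, tmp_path, ideal_helix30):
        e = sim.perturb_ensemble(sim.EnsembleGenerator(
            base=ideal_helix30, sigma_A=0.3, n_frames=3, seed=1))
        path = tmp_path / "ens.pdb"
        write_ensemble(e, path)
        back = read_ensemble(path)
        assert back.n_frames == 3
        assert back.atoms[["chain", "resid", "name"]].equals(
            e.atoms[["chain", "resid", "name"]])
        assert np.abs(back.coords - e.coords).max() < 1e-3

    def test_water_excluded_by_default(self, tmp_path):
        pdb = tmp_path / "w.pdb"
        pdb.write_text(
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "HETATM    3  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O\n"
            "ENDMDL\nEND\n")
        e = read_ensemble(pdb)
        assert e.n_atoms == 2

    def test_inconsistent_models_rejected(self, tmp_path):
        pdb = tmp_path / "bad.pdb"
        pdb.write_text(
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nMODEL        2\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n")
        with pytest.raises(EnsembleFormatError, match="model 2"):
            read_ensemble(pdb)

    def test_distance_timeline_static_and_missing(self, ideal_helix30):
        xyz = np.repeat(ideal_helix30.coords, 3, axis=0)
        e = StructureEnsemble(ideal_helix30.atoms, xyz)
        df = ens.distance_timeline(e, [(("A", 1), ("A", 10))])
        assert df.shape == (3, 1)
        assert df.nunique().iloc[0] == 1
        with pytest.raises(KeyError):
            ens.distance_timeline(e, [(("A", 1), ("B", 99))])

    def test_report_composition_identity(self):
        cc = sim.gen_coiled_coil(20)
        e = sim.perturb_ensemble(sim.EnsembleGenerator(
            base=cc, sigma_A=0.1, n_frames=3, seed=2))
        df = ens.ensemble_report(e, selection="calpha", trailing=3,
                                 sasa_points=120)
        assert len(df) == 4  # 3 frames + mean row
        frame0 = e.coords[0]
        assert df.iloc[0]["rg_nm"] == pytest.approx(
            radius_of_gyration(frame0, e.atoms))
        assert df.iloc[0]["helicity_pct"] == pytest.approx(
            helicity(frame0, e.atoms)[0])
        # trailing window equal to length -> mean row equals column means
        assert df.loc["mean", "rg_nm"] == pytest.approx(
            df.iloc[:3]["rg_nm"].mean())


class TestSelections:
    def test_presets(self, ideal_helix30):
        assert AtomSelection.preset("calpha").mask(ideal_helix30.atoms).sum() == 30
        with pytest.raises(KeyError):
            AtomSelection.preset("sidechain")

    def test_empty_selection_rejected(self, ideal_helix30):
        sel = AtomSelection(chains=frozenset({"Z"}))
        with pytest.raises(ValueError):
            sel.mask(ideal_helix30.atoms)
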