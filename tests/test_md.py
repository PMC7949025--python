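import numpy as np
import pytest
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial.transform import Rotation

from pntkit import datasets, synth
from pntkit.hx import DecayFit, ProtectionRecord, protection
from pntkit.md import (
    Trajectory,
    compare_hbond_pf,
    delta_rmsf,
    hbond_persistence,
    pca,
    rmsd_series,
    rmsf,
    superpose,
)
from pntkit.structures import Atom, Residue, Structure


def static_traj(structure: Structure, n_frames: int = 1) -> Trajectory:
    coords = structure.coordinates()
    return Trajectory(structure, np.repeat(coords[None, :, :], n_frames, axis=0))


def brute_force_min_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent oracle: minimize RMSD over unit quaternions numerically."""
    m0 = mobile - mobile.mean(axis=0)
    r0 = reference - reference.mean(axis=0)

    def cost(q):
        q = q / np.linalg.norm(q)
        R = Rotation.from_quat(q).as_matrix()
        return np.sqrt(np.mean(np.sum((m0 @ R.T - r0) ** 2, axis=1)))

    best = np.inf
    rng = np.random.default_rng(0)
    for _ in range(40):
        res = scipy_minimize(cost, rng.normal(size=4), method="Nelder-Mead",
                             options={"xatol": 1e-6, "fatol": 1e-9})
        best = min(best, res.fun)
    return best


class TestSuperpose:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(1).normal(size=(10, 3))
        R, t, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_rigid_transform_removed(self):
        pts = np.random.default_rng(2).normal(size=(12, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([5.0, -3.0, 2.0])
        _, _, rmsd = superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_search_oracle(self):
        ref = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                        [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
        mobile = ref.copy()
        mobile[0] += [1.0, 0.0, 0.0]
        _, _, rmsd = superpose(mobile, ref)
        assert rmsd == pytest.approx(brute_force_min_rmsd(mobile, ref), abs=1e-3)

    def test_degenerate_geometry_rejected(self):
        line = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="degenerate"):
            superpose(line, line)


class TestRmsd:
    def test_static_trajectory_all_zero(self, helix_bundle):
        df = rmsd_series(static_traj(helix_bundle, 5), (47, 123))
        assert np.allclose(df["rmsd_A"], 0.0, atol=1e-6)

    def test_pure_rotations_all_zero(self, helix_bundle):
        coords = helix_bundle.coordinates()
        rng = np.random.default_rng(3)
        frames = np.stack([
            coords @ Rotation.random(random_state=rng).as_matrix().T + rng.normal(size=3)
            for _ in range(6)
        ])
        df = rmsd_series(Trajectory(helix_bundle, frames), (47, 123))
        assert np.allclose(df["rmsd_A"], 0.0, atol=1e-5)

    def test_gaussian_fluctuations_match_analytic_mean(self, helix_bundle):
        # frame-vs-frame0 displacements are N(0, 2 sigma^2) per component,
        # so the expected RMSD is sqrt(6)*sigma (alignment shrinkage is
        # negligible for ~344 fitted atoms)
        sigma = 0.5
        traj = synth.gen_trajectory(helix_bundle, sigma, n_frames=200, seed=3)
        df = rmsd_series(traj, (40, 125))
        assert df["rmsd_A"][1:].mean() == pytest.approx(np.sqrt(6) * sigma, rel=0.10)

    def test_core_selection_excludes_termini(self, helix_bundle):
        traj = synth.gen_trajectory(helix_bundle, 0.2, n_frames=5, seed=1)
        df = rmsd_series(traj, (57, 120))
        assert "57-120" in df["selection"].iloc[0]

    def test_empty_selection_rejected(self, helix_bundle):
        with pytest.raises(ValueError, match="empty selection"):
            rmsd_series(static_traj(helix_bundle, 3), (300, 310))


class TestRmsf:
    def test_static_trajectory_zero(self, helix_bundle):
        df = rmsf(static_traj(helix_bundle, 4))
        assert np.allclose(df["rmsf_A"], 0.0, atol=1e-9)

    def test_single_frame_rejected(self, helix_bundle):
        with pytest.raises(ValueError, match="2 frames"):
            rmsf(static_traj(helix_bundle, 1))

    def test_isotropic_gaussian_closed_form(self, helix_bundle):
        # per-component sigma 0.3 A -> RMSF = sqrt(3)*0.3 = 0.52 A
        traj = synth.gen_trajectory(helix_bundle, 0.3, n_frames=500, seed=3)
        df = rmsf(traj)
        assert df["rmsf_A"].mean() == pytest.approx(0.3 * np.sqrt(3), rel=0.05)

    def test_elevated_termini_reproduced(self, helix_bundle):
        profile = {r.number: 0.9 if r.number < 50 or r.number > 120 else 0.3
                   for r in helix_bundle.residues}
        traj = synth.gen_trajectory(helix_bundle, profile, n_frames=300, seed=9)
        df = rmsf(traj).set_index("residue")
        termini = df.loc[[r for r in df.index if r < 50 or r > 120], "rmsf_A"].mean()
        core = df.loc[[r for r in df.index if 60 <= r <= 110], "rmsf_A"].mean()
        assert termini > 2.0 * core

    def test_concatenated_trajectory_same_rmsf(self, helix_bundle):
        traj = synth.gen_trajectory(helix_bundle, 0.3, n_frames=100, seed=5)
        doubled = Trajectory(helix_bundle, np.concatenate([traj.frames, traj.frames]))
        a = rmsf(traj)["rmsf_A"].to_numpy()
        b = rmsf(doubled)["rmsf_A"].to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_global_rotation_invariance(self, helix_bundle):
        traj = synth.gen_trajectory(helix_bundle, 0.3, n_frames=50, seed=6)
        rot = Rotation.from_euler("xyz", [30, -40, 110], degrees=True).as_matrix()
        rotated = Trajectory(helix_bundle, traj.frames @ rot.T + np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(
            rmsf(traj)["rmsf_A"], rmsf(rotated)["rmsf_A"], atol=1e-6
        )


class TestDeltaRmsf:
    def test_identical_profiles_all_neutral(self, helix_bundle):
        prof = rmsf(synth.gen_trajectory(helix_bundle, 0.3, 50, seed=2))
        out = delta_rmsf(prof, prof)
        assert (out["classification"] == "neutral").all()

    def test_uniform_offset_classified(self, helix_bundle):
        prof = rmsf(synth.gen_trajectory(helix_bundle, 0.3, 50, seed=2))
        shifted = prof.copy()
        shifted["rmsf_A"] = shifted["rmsf_A"] + 0.5
        out = delta_rmsf(prof, shifted)  # a - b = -0.5 everywhere
        assert (out["classification"] == "reduced_in_a").all()

    def test_damped_interface_recovered(self, heterodimer):
        damped = set(datasets.EH_SURFACE.residues)
        sigma = {}
        for res in heterodimer.residues:
            base = 0.45
            if res.chain_id == "A" and res.number in damped:
                sigma[(res.chain_id, res.number)] = 0.05  # rigidified interface
            else:
                sigma[(res.chain_id, res.number)] = base
        traj = synth.gen_trajectory(heterodimer, sigma, n_frames=300, seed=7)
        prof_b = rmsf(traj, chain_id="B")
        prof_a = rmsf(traj, chain_id="A")
        out = delta_rmsf(prof_b, prof_a)  # positive where chain A is damped
        flagged = set(out.loc[out["classification"] == "reduced_in_b", "residue"])
        assert flagged == damped

    def test_mismatched_residues_rejected(self, helix_bundle):
        prof = rmsf(synth.gen_trajectory(helix_bundle, 0.3, 20, seed=2))
        with pytest.raises(ValueError, match="different residues"):
            delta_rmsf(prof, prof[prof["residue"] > 50])


class TestPca:
    def two_mode_traj(self, structure, amp1=2.0, amp2=1.0, n=200):
        coords = structure.coordinates()
        frames = np.repeat(coords[None, :, :], n, axis=0)
        t = np.arange(n)
        frames[:, 0, 0] += amp1 * np.sqrt(2) * np.sin(2 * np.pi * t / 40)
        frames[:, 7, 1] += amp2 * np.sqrt(2) * np.sin(2 * np.pi * t / 28)
        return Trajectory(structure, frames)

    def test_fractions_sum_to_one(self, helix_bundle):
        traj = synth.gen_trajectory(helix_bundle, 0.3, 60, seed=4)
        out = pca(traj)
        assert out["variance_fractions"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (out["eigenvalues"] >= 0).all()

    def test_single_mode_captures_everything(self, helix_bundle):
        coords = helix_bundle.coordinates()
        frames = np.repeat(coords[None, :, :], 50, axis=0)
        frames[:, 3, 0] += np.sin(np.linspace(0, 6 * np.pi, 50))
        out = pca(Trajectory(helix_bundle, frames), residue_range=(40, 125),
                  atom_class="all", align=False)
        assert out["variance_fractions"][0] == pytest.approx(1.0, abs=1e-9)

    def test_two_modes_split_4_to_1(self, helix_bundle):
        out = pca(self.two_mode_traj(helix_bundle), residue_range=(40, 125),
                  atom_class="all", align=False)
        assert out["variance_fractions"][0] == pytest.approx(0.8, abs=0.02)
        assert out["variance_fractions"][1] == pytest.approx(0.2, abs=0.02)

    def test_reconstruction_from_all_components(self, helix_bundle):
        traj = synth.gen_trajectory(helix_bundle, 0.2, 30, seed=8)
        idx = traj.atom_index((57, 120), "backbone")
        X = traj.frames[:, idx, :].reshape(traj.n_frames, -1)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (traj.n_frames - 1)
        evals, evecs = np.linalg.eigh(cov)
        np.testing.assert_allclose(Xc @ evecs @ evecs.T, Xc, atol=1e-9)

    def test_static_trajectory_rejected(self, helix_bundle):
        with pytest.raises(ValueError, match="variance"):
            pca(static_traj(helix_bundle, 12))


class TestHbonds:
    def test_ideal_helix_bonds_i_minus_4(self, helix_bundle):
        hb = hbond_persistence(static_traj(helix_bundle)).set_index("residue")
        # mid-helix amides of H1 (well inside 63-76)
        for resnum in range(68, 76):
            assert hb.loc[resnum, "bonded"]
            assert hb.loc[resnum, "partner_1"] == f"A{resnum - 4}"
            assert hb.loc[resnum, "mean_dist_1_A"] == pytest.approx(3.09, abs=0.1)

    def test_extended_chain_has_no_bonds(self, extended_chain):
        hb = hbond_persistence(static_traj(extended_chain))
        assert not hb["bonded"].any()

    def test_cutoff_is_inclusive_at_3p5(self):
        # two residues far apart in sequence, N...O exactly 3.50 A
        def res(num, atoms):
            r = Residue(number=num, code="A", chain_id="A")
            for name, xyz in atoms:
                r.atoms.append(Atom(name, name[0], np.array(xyz)))
            return r

        s = Structure(chains={"A": [
            res(1, [("N", [0.0, 0.0, 0.0]), ("CA", [1.5, 0.0, 0.0]),
                    ("C", [2.2, 1.3, 0.0]), ("O", [3.5, 0.0, 0.0])]),
            res(5, [("N", [7.0, 0.0, 0.0]), ("CA", [8.5, 0.0, 0.0]),
                    ("C", [9.2, 1.3, 0.0]), ("O", [20.0, 0.0, 0.0])]),
        ]})
        hb = hbond_persistence(static_traj(s)).set_index("residue")
        assert hb.loc[5, "mean_dist_1_A"] == pytest.approx(3.5)
        assert bool(hb.loc[5, "bonded"])

    def test_static_equals_multi_frame_static(self, helix_bundle):
        one = hbond_persistence(static_traj(helix_bundle, 1))
        five = hbond_persistence(static_traj(helix_bundle, 5))
        assert (one["bonded"] == five["bonded"]).all()
        assert (one["partner_1"] == five["partner_1"]).all()
        np.testing.assert_allclose(one["mean_dist_1_A"], five["mean_dist_1_A"], rtol=1e-12)

    def test_prolines_excluded_as_donors(self, helix_bundle):
        hb = hbond_persistence(static_traj(helix_bundle))
        prolines = {r.number for r in helix_bundle.residues if r.code == "P"}
        assert prolines.isdisjoint(set(hb["residue"]))


class TestHbondPfComparison:
    def _protection_records(self, residues, log_pf):
        recs = []
        for r in residues:
            fit = DecayFit(10.0 ** (-log_pf), None, 100.0, None, "measured")
            recs.append(protection(fit, k_pred=1.0, residue=r))
        return recs

    def test_perfect_association(self, helix_bundle):
        hb = hbond_persistence(static_traj(helix_bundle))
        bonded = hb.loc[hb["bonded"], "residue"].tolist()
        loose = hb.loc[~hb["bonded"], "residue"].tolist()
        recs = self._protection_records(bonded, 6.0) + self._protection_records(loose, 1.0)
        counts = compare_hbond_pf(hb, recs)
        assert counts["bonded_unprotected"] == 0
        assert counts["unbonded_protected"] == 0
        assert counts["bonded_protected"] == len(bonded)

    def test_slow_limit_counts_as_protected(self, helix_bundle):
        hb = hbond_persistence(static_traj(helix_bundle))
        resnum = int(hb.loc[hb["bonded"], "residue"].iloc[0])
        rec = ProtectionRecord(residue=resnum, k_pred=1.0, status="slow_limit",
                               bound_direction="lower")
        counts = compare_hbond_pf(hb, [rec])
        assert counts["bonded_protected"] == 1

    def test_empty_protection_rejected(self, helix_bundle):
        hb = hbond_persistence(static_traj(helix_bundle))
        with pytest.raises(ValueError, match="empty"):
            compare_hbond_pf(hb, [])

    def test_disjoint_residues_rejected(self, helix_bundle):
        hb = hbond_persistence(static_traj(helix_bundle))
        recs = self._protection_records([999], 5.0)
        with pytest.raises(ValueError, match="shared"):
            compare_hbond_pf(hb, recs)
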