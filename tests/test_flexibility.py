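import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hemekin.flexibility import (
    Ensemble,
    RMSFProfile,
    read_multimodel_pdb,
    region_report,
    rmsf,
    superpose,
    write_multimodel_pdb,
)
from hemekin.synthetic import gen_ensemble


def toy_ensemble(coords):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    return Ensemble(
        coords=coords,
        atom_names=np.full(n, "CA"),
        residue_ids=np.arange(1, n + 1),
        ca_mask=np.ones(n, dtype=bool),
    )


def naive_rmsf(coords):
    """Independent double-loop reference implementation."""
    n_frames, n_atoms, _ = coords.shape
    out = np.zeros(n_atoms)
    for i in range(n_atoms):
        mean = coords[:, i, :].mean(axis=0)
        acc = 0.0
        for f in range(n_frames):
            d = coords[f, i, :] - mean
            acc += float(d @ d)
        out[i] = np.sqrt(acc / n_frames)
    return out


class TestRMSF:
    def test_identical_frames_zero(self):
        base = np.random.default_rng(0).normal(size=(1, 8, 3))
        ens = toy_ensemble(np.repeat(base, 4, axis=0))
        assert np.allclose(rmsf(ens).rmsf, 0.0)

    def test_two_point_displacement(self):
        # one atom at x = +/- d/2 across two frames: RMSF = d/2
        d = 1.2
        coords = np.zeros((2, 3, 3))
        coords[:, 1:, :] = np.arange(6).reshape(1, 2, 3)  # spectators fixed
        coords[0, 0, 0] = -d / 2
        coords[1, 0, 0] = d / 2
        profile = rmsf(toy_ensemble(coords))
        assert profile.rmsf[0] == pytest.approx(d / 2)
        assert np.allclose(profile.rmsf[1:], 0.0)

    def test_matches_naive_oracle_on_small_ensembles(self, rng):
        coords = rng.normal(size=(5, 12, 3))
        ens = toy_ensemble(coords)
        assert np.allclose(rmsf(ens).rmsf, naive_rmsf(coords), atol=1e-12)

    def test_sqrt3_sigma_law(self, gaussian_ensemble):
        ens, truth = gaussian_ensemble
        profile = rmsf(ens)
        # 500 frames: Monte-Carlo scatter ~ sigma*sqrt(3)/sqrt(2*500) per residue
        assert profile.rmsf.mean() == pytest.approx(
            truth.true_rmsf_A.mean(), rel=0.05
        )

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            rmsf(toy_ensemble(np.zeros((1, 3, 3))))

    def test_negative_rmsf_rejected(self):
        with pytest.raises(ValueError):
            RMSFProfile(np.array([1]), np.array([-0.1]))


class TestSuperpose:
    def test_rigid_motions_removed(self, rng):
        base = rng.normal(size=(10, 3)) * 3.0
        frames = [base]
        for _ in range(4):
            rot = Rotation.random(random_state=rng)
            frames.append(rot.apply(base) + rng.normal(size=3) * 5.0)
        ens = superpose(toy_ensemble(np.array(frames)))
        assert np.allclose(rmsf(ens).rmsf, 0.0, atol=1e-8)

    def test_already_aligned_unchanged(self, rng):
        coords = rng.normal(size=(4, 10, 3))
        ens = toy_ensemble(coords)
        aligned = superpose(ens, tol=1e-10)
        twice = superpose(aligned, tol=1e-10)
        assert np.allclose(twice.coords, aligned.coords, atol=1e-8)

    def test_rmsf_invariant_under_global_rigid_motion(self, rng):
        coords = rng.normal(size=(6, 15, 3)) + np.arange(15)[None, :, None]
        rot = Rotation.random(random_state=rng)
        moved = np.array([rot.apply(f) + [10.0, -4.0, 2.0] for f in coords])
        r1 = rmsf(superpose(toy_ensemble(coords))).rmsf
        r2 = rmsf(superpose(toy_ensemble(moved))).rmsf
        assert np.allclose(r1, r2, atol=1e-8)

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            superpose(toy_ensemble(np.zeros((1, 5, 3))))


class TestPDBRoundtrip:
    def test_write_read_roundtrip(self, tmp_path, gaussian_ensemble):
        ens, _ = gen_ensemble(n_residues=10, n_frames=3, sigma_A=0.2, seed=9)
        path = str(tmp_path / "ens.pdb")
        write_multimodel_pdb(ens, path)
        back = read_multimodel_pdb(path)
        assert back.n_frames == 3
        assert int(back.ca_mask.sum()) == 10
        # PDB coordinates carry 3 decimals
        assert np.allclose(back.coords, ens.coords, atol=2e-3)

    def test_single_model_rejected(self, tmp_path):
        ens, _ = gen_ensemble(n_residues=4, n_frames=2, sigma_A=0.1, seed=1)
        path = str(tmp_path / "single.pdb")
        write_multimodel_pdb(ens, path)
        text = open(path).read()
        head = text.split("MODEL", 2)
        single = head[0] + "MODEL" + head[1].replace("ENDMDL", "ENDMDL\nEND")
        single_path = str(tmp_path / "one.pdb")
        open(single_path, "w").write(single)
        with pytest.raises(ValueError, match=">= 2"):
            read_multimodel_pdb(single_path)

    def test_inconsistent_models_rejected(self, tmp_path):
        ens, _ = gen_ensemble(n_residues=4, n_frames=3, sigma_A=0.1, seed=1)
        path = str(tmp_path / "ens.pdb")
        write_multimodel_pdb(ens, path)
        lines = open(path).read().splitlines()
        # drop one ATOM line from the second model
        out, dropped, in_model2, model_count = [], False, False, 0
        for ln in lines:
            if ln.startswith("MODEL"):
                model_count += 1
                in_model2 = model_count == 2
            if in_model2 and ln.startswith("ATOM") and not dropped:
                dropped = True
                continue
            out.append(ln)
        bad_path = str(tmp_path / "bad.pdb")
        open(bad_path, "w").write("\n".join(out) + "\n")
        with pytest.raises(ValueError, match="inconsistent"):
            read_multimodel_pdb(bad_path)


class TestRegionReport:
    def test_flat_profile_equal_means(self):
        profile = RMSFProfile(np.arange(1, 101), np.full(100, 0.7))
        report = region_report(
            profile, {"omega_loop": (70, 85), "hinge": (42, 56)}
        )
        assert np.allclose(report["mean_rmsf_A"], 0.7)

    def test_elevated_region_has_max_mean(self):
        ids = np.arange(1, 101)
        vals = np.where((ids >= 70) & (ids <= 85), 1.5, 0.5)
        report = region_report(
            RMSFProfile(ids, vals),
            {"20-28": (20, 28), "42-56": (42, 56), "70-85": (70, 85)},
        )
        best = report.loc[report["mean_rmsf_A"].idxmax(), "region"]
        assert best == "70-85"

    def test_empty_region_list(self):
        profile = RMSFProfile(np.arange(1, 11), np.full(10, 0.3))
        report = region_report(profile, {})
        assert len(report) == 0

    def test_missing_residues_warn(self):
        profile = RMSFProfile(np.arange(1, 11), np.full(10, 0.3))
        with pytest.warns(UserWarning, match="missing"):
            report = region_report(profile, {"edge": (8, 15)})
        assert report.loc[0, "n_residues"] == 3
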