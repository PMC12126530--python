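"""Alignment-tensor SVD fitting, R-factor, PDB-derived geometry."""

import numpy as np
import pytest

from nmrbind.io import read_structure
from nmrbind.rdc import (
    AlignmentTensor,
    IllConditionedError,
    RdcObservation,
    dmax,
    fit_saupe,
    parse_selection,
    r_factor,
    saupe_matrix_from_components,
    svd_fit_tensor,
)
from nmrbind.synth import gen_rdc


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _write_pdb(path, n_res=8, seed=5):
    """Synthetic miniature coordinate file with N/H/C backbone atoms."""
    rng = np.random.default_rng(seed)
    lines = []
    serial = 1
    for i in range(1, n_res + 1):
        n_pos = np.array([3.8 * i, 0.3 * i**2 % 5, np.sin(i) * 4])
        # N-H bond ~1.02 A in a varying direction
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        h_pos = n_pos + 1.02 * u
        c_pos = n_pos + np.array([1.2, 0.8, -0.5])
        for name, pos in (("N", n_pos), ("H", h_pos), ("C", c_pos)):
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}ALA A{i:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


class TestSaupeFit:
    def test_exact_recovery_and_zero_r_factor(self):
        df, manifest = gen_rdc(3, noise_hz=0.0)
        v = df[["vx", "vy", "vz"]].to_numpy()
        tensor, d_calc = fit_saupe(v, df["D_Hz"], df["dmax_Hz"])
        assert np.allclose(tensor.components, manifest["saupe"], atol=1e-12)
        assert r_factor(df["D_Hz"], d_calc) < 1e-8

    def test_zero_tensor_back_calculates_zero(self):
        df, _ = gen_rdc(4, saupe=(0.0, 0.0, 0.0, 0.0, 0.0))
        v = df[["vx", "vy", "vz"]].to_numpy()
        tensor, d_calc = fit_saupe(v, df["D_Hz"], df["dmax_Hz"])
        assert np.allclose(d_calc, 0.0, atol=1e-10)
        assert abs(tensor.axial) < 1e-12

    def test_noisy_axial_component_within_monte_carlo_ci(self):
        truth_axial = AlignmentTensor(
            components=(4e-4, -2e-4, 1.5e-4, -1e-4, 2.5e-4)).axial
        estimates = []
        for rep in range(100):
            df, _ = gen_rdc(1000 + rep, noise_hz=1.0)
            v = df[["vx", "vy", "vz"]].to_numpy()
            tensor, _ = fit_saupe(v, df["D_Hz"], df["dmax_Hz"])
            estimates.append(tensor.axial)
        mean = np.mean(estimates)
        sem = np.std(estimates) / np.sqrt(len(estimates))
        assert abs(mean - truth_axial) < 4 * sem

    def test_physical_magnitude_for_experimental_range(self):
        # couplings in the measured -7..12 Hz window imply |Szz| < 1e-2
        df, _ = gen_rdc(6, saupe=(2e-4, -1e-4, 8e-5, -6e-5, 1.2e-4))
        assert df["D_Hz"].between(-25, 25).all()
        v = df[["vx", "vy", "vz"]].to_numpy()
        tensor, _ = fit_saupe(v, df["D_Hz"], df["dmax_Hz"])
        assert abs(tensor.axial) < 1e-2

    def test_rotation_covariance(self, rng):
        df, manifest = gen_rdc(8)
        v = df[["vx", "vy", "vz"]].to_numpy()
        R = _random_rotation(rng)
        t1, d1 = fit_saupe(v, df["D_Hz"], df["dmax_Hz"])
        t2, d2 = fit_saupe(v @ R.T, df["D_Hz"], df["dmax_Hz"])
        # back-calculated couplings and R-factor are frame independent
        assert np.allclose(d1, d2, atol=1e-9)
        assert r_factor(df["D_Hz"], d1) == pytest.approx(
            r_factor(df["D_Hz"], d2), abs=1e-9)
        # and the tensor transforms as R S R^T
        assert np.allclose(R @ t1.matrix @ R.T, t2.matrix, atol=1e-12)

    def test_collinear_vectors_ill_conditioned(self):
        v = np.tile(np.array([1.0, 0.0, 0.0]), (8, 1))
        v += 1e-12 * np.arange(24).reshape(8, 3)
        with pytest.raises(IllConditionedError, match="cond"):
            fit_saupe(v, np.ones(8), np.full(8, 21700.0))

    def test_needs_five_observations(self):
        with pytest.raises(ValueError):
            fit_saupe(np.eye(3), np.ones(3), np.full(3, 1.0))


class TestRFactor:
    def test_perfect_agreement(self):
        assert r_factor([1.0, -2.0, 3.0], [1.0, -2.0, 3.0]) == 0.0

    def test_null_prediction(self):
        d = [1.0, -2.0, 3.0]
        assert r_factor(d, [0.0, 0.0, 0.0]) == pytest.approx(100 / np.sqrt(2))

    def test_scale_invariance(self, rng):
        obs = rng.standard_normal(20)
        calc = obs + 0.3 * rng.standard_normal(20)
        assert r_factor(obs, calc) == pytest.approx(
            r_factor(5.0 * obs, 5.0 * calc))

    def test_all_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            r_factor([0.0, 0.0], [1.0, 2.0])


class TestSelectionAndStructure:
    def test_selection_parser(self):
        sel = parse_selection("1-75,100-105!48,57,58,68,69")
        assert 1 in sel and 75 in sel and 100 in sel and 105 in sel
        assert 48 not in sel and 69 not in sel and 76 not in sel
        assert len(sel) == 75 + 6 - 5

    def test_structure_round_trip_fit(self, tmp_path, rng):
        pdb = _write_pdb(tmp_path / "mini.pdb")
        model = read_structure(pdb)
        truth = np.array([3e-4, -1.5e-4, 1e-4, -8e-5, 2e-4])
        S = saupe_matrix_from_components(truth)
        obs = []
        for rid in sorted(model.residues):
            vec, r = model.internuclear_vector(rid, "NH")
            d = dmax("N", "H", 1.041) * float(vec @ S @ vec)
            obs.append(RdcObservation(rid, "NH", d))
        tensor, table = svd_fit_tensor(obs, model)
        assert np.allclose(tensor.components, truth, rtol=1e-8)
        assert r_factor(table["d_obs"], table["d_calc"]) < 1e-6

    def test_two_bond_geometry_uses_preceding_carbonyl(self, tmp_path):
        pdb = _write_pdb(tmp_path / "mini.pdb")
        model = read_structure(pdb)
        vec, r = model.internuclear_vector(3, "CH")
        c = model.position(2, "C")
        h = model.position(3, "H")
        want = (h - c) / np.linalg.norm(h - c)
        assert np.allclose(vec, want)
        assert r == pytest.approx(float(np.linalg.norm(h - c)))

    def test_missing_atoms_reported(self, tmp_path):
        pdb = _write_pdb(tmp_path / "mini.pdb", n_res=6)
        model = read_structure(pdb)
        obs = [RdcObservation(r, "NH", 1.0) for r in (1, 2, 3, 4, 5, 99)]
        with pytest.raises(KeyError, match="99"):
            svd_fit_tensor(obs, model)

    def test_selection_filters_fit(self, tmp_path):
        pdb = _write_pdb(tmp_path / "mini.pdb")
        model = read_structure(pdb)
        obs = [RdcObservation(r, "NH", float(r)) for r in range(1, 9)]
        _, table = svd_fit_tensor(obs, model, selection="1-8!3")
        assert 3 not in set(table["residue_id"])

    def test_dmax_magnitude_nh(self):
        # static N-H dipolar scale at the effective 1.041 A bond length
        assert dmax("N", "H", 1.041) == pytest.approx(10.8e3, rel=0.02)
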