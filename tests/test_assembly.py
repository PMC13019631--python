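import json
import subprocess
import sys

import numpy as np
import pytest

from f12quad.assembly import (RunConfig, assemble_energy, f12_energy,
                              flop_probe)
from f12quad.fixtures import generate_fixture, linear_hn_chain, \
    pseudo_glycine_chain
from f12quad.molecule import Molecule, Atom
from f12quad.quadrature import ConfigurationError


class TestEnergyAssembly:
    def test_report_self_consistency(self, he_report):
        he_report.validate()
        total = sum(he_report.contributions.values())
        assert he_report.e_f12 == pytest.approx(total, abs=1e-12)

    def test_single_pair_collapse(self, he_report):
        """For He the assembly reduces to
        (5/4 - 1/4) V + (7/32 + 1/32) B - 2 eps (7/32 + 1/32) X."""
        inter = he_report.intermediates
        eps1 = he_report.intermediates.xw_exchange / (
            2.0 * he_report.intermediates.x_exchange)  # = eps_1 by symmetry
        expected = (1.0 * inter.v_exchange + 0.25 * inter.b_exchange
                    - 2.0 * eps1 * 0.25 * inter.x_exchange)
        assert he_report.e_f12 == pytest.approx(expected, abs=1e-12)

    def test_correction_is_negative(self, he_report):
        """A basis-set incompleteness correction lowers the energy."""
        assert he_report.e_f12 < 0.0
        assert he_report.e_mp2 is None or he_report.e_mp2 < 0.0

    def test_b_direct_fix_changes_only_b_slot(self, he_report):
        e_a, _ = assemble_energy(he_report.intermediates, True)
        e_b, _ = assemble_energy(he_report.intermediates, False)
        # single-pair system: both readings coincide exactly
        assert e_a == pytest.approx(e_b, abs=1e-12)

    def test_gamma_continuity(self, he_bundle, he_spaces):
        """Halving gamma changes the correction smoothly and preserves the
        V-term sign pattern."""
        reps = {}
        for g in (0.65, 1.3):
            reps[g] = f12_energy(he_bundle.molecule, he_bundle.obs,
                                 he_bundle.cabs_aux, he_bundle.df_aux,
                                 RunConfig(grid_level="g1", gamma=g),
                                 spaces=he_spaces)
        for g, rep in reps.items():
            assert rep.intermediates.v_direct < 0.0
            assert rep.contributions["V_direct"] < 0.0
        assert abs(reps[0.65].e_f12 - reps[1.3].e_f12) < 0.05

    def test_end_to_end_determinism(self, he_bundle, he_spaces):
        a = f12_energy(he_bundle.molecule, he_bundle.obs, he_bundle.cabs_aux,
                       he_bundle.df_aux, RunConfig(grid_level="g0"),
                       spaces=he_spaces)
        b = f12_energy(he_bundle.molecule, he_bundle.obs, he_bundle.cabs_aux,
                       he_bundle.df_aux, RunConfig(grid_level="g0"),
                       spaces=he_spaces)
        assert a.e_f12 == b.e_f12
        assert a.to_dict()["terms"] == b.to_dict()["terms"]

    def test_weight_threshold_soundness(self, h2_bundle, h2_spaces):
        """Halving the grid-point retention threshold changes the energy by
        less than the level's grid error (~0.5 uEh at g1 for this system)."""
        es = {}
        for wt in (0.0, 5e-6, 1e-5):
            cfg = RunConfig(grid_level="g1", theta_nq=0.0,
                            weight_threshold=wt)
            es[wt] = f12_energy(h2_bundle.molecule, h2_bundle.obs,
                                h2_bundle.cabs_aux, h2_bundle.df_aux, cfg,
                                spaces=h2_spaces).e_f12
        assert abs(es[1e-5] - es[0.0]) < 0.5e-6
        assert abs(es[5e-6] - es[0.0]) < 0.5e-6

    def test_rotational_invariance(self):
        """A rigidly rotated molecule gives the same correction."""
        from f12quad.basis import fixture_basis
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("zyx", [31.0, -57.0, 12.0],
                                  degrees=True).as_matrix()
        base = generate_fixture("h2o")
        mol0 = base.molecule
        atoms = [Atom(a.symbol, a.charge, rot @ a.position)
                 for a in mol0.atoms]
        mol1 = Molecule(atoms, name="h2o_rot")
        # weight pruning off: a sharp retention threshold lets borderline
        # points flip between frames at the level of the pruning error itself
        cfg = RunConfig(grid_level="g0", theta_nq=0.0, weight_threshold=0.0)
        e0 = f12_energy(mol0, base.obs, base.cabs_aux, base.df_aux, cfg).e_f12
        obs1 = fixture_basis(mol1, "fix.h2o.obs", "orbital")
        cabs1 = fixture_basis(mol1, "fix.h2o.cabs", "cabs_aux")
        df1 = fixture_basis(mol1, "fix.h2o.df", "df_aux")
        e1 = f12_energy(mol1, obs1, cabs1, df1, cfg).e_f12
        assert e1 == pytest.approx(e0, abs=1e-8)


class TestFixtures:
    def test_chain_is_collinear_and_spaced(self):
        fx = linear_hn_chain(4, 1.4)
        pos = fx.molecule.positions
        assert np.abs(pos[:, :2]).max() == 0.0
        assert np.allclose(np.diff(pos[:, 2]), 1.4)

    def test_pseudo_glycine_atom_count_affine(self):
        n1 = len(pseudo_glycine_chain(1).molecule.atoms)
        n2 = len(pseudo_glycine_chain(2).molecule.atoms)
        n3 = len(pseudo_glycine_chain(3).molecule.atoms)
        assert n2 - n1 == n3 - n2 == n1

    def test_h2_standard_dimer(self):
        fx = generate_fixture("h2", distance_angstrom=0.74)
        d = np.linalg.norm(fx.molecule.positions[1]
                           - fx.molecule.positions[0])
        assert d == pytest.approx(1.3984, abs=1e-3)

    def test_invalid_chain_length_rejected(self):
        with pytest.raises(ConfigurationError):
            linear_hn_chain(3)
        with pytest.raises(ConfigurationError):
            pseudo_glycine_chain(0)


class TestScalingProbe:
    def test_exponent_separation(self):
        """Hybrid path grows ~N^4 in its dominant counter, the DF-only
        comparator ~N^5."""
        out = flop_probe([4, 8], grid_level="g0")
        e = out["exponents"][0]
        assert e["hybrid_exponent"] <= 4.2
        assert e["df_only_exponent"] >= 4.6

    def test_single_size_gives_no_exponents(self):
        out = flop_probe([4], grid_level="g0")
        assert out["exponents"] == []


class TestCli:
    def test_compute_happy_path(self, tmp_path):
        out = tmp_path / "report.json"
        r = subprocess.run(
            [sys.executable, "-m", "f12quad.cli", "compute", "--fixture",
             "he", "--grid", "g0", "--report", str(out)],
            capture_output=True, text=True)
        assert r.returncode == 0, r.stderr
        data = json.loads(out.read_text())
        assert data["e_f12"] < 0.0
        assert data["config"]["grid_level"] == "g0"

    def test_oracle_size_guard_nonzero_exit(self, tmp_path):
        xyz = tmp_path / "chain.xyz"
        lines = ["22", ""] + [f"H 0 0 {i * 0.9}" for i in range(22)]
        xyz.write_text("\n".join(lines))
        r = subprocess.run(
            [sys.executable, "-m", "f12quad.cli", "oracle",
             "--xyz", str(xyz), "--obs", "fixture:fix.hchain.obs",
             "--cabs", "fixture:fix.hchain.cabs",
             "--df", "fixture:fix.hchain.df"],
            capture_output=True, text=True)
        assert r.returncode != 0

    def test_bad_flags_usage_error(self):
        r = subprocess.run(
            [sys.executable, "-m", "f12quad.cli", "compute", "--grid", "g9"],
            capture_output=True, text=True)
        assert r.returncode != 0

    def test_fixtures_subcommand(self, tmp_path):
        r = subprocess.run(
            [sys.executable, "-m", "f12quad.cli", "fixtures", "h2",
             "--out-prefix", str(tmp_path / "fx")],
            capture_output=True, text=True)
        assert r.returncode == 0
        assert (tmp_path / "fx.xyz").exists()
        assert (tmp_path / "fx.obs.g94").exists()
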