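"""Production V/X/B pipeline against the brute-force dense oracle, and the
structural invariants of the B term list."""

import numpy as np
import pytest

from f12quad.intermediates import IntermediateBuilder
from f12quad.quadrature import ConfigurationError, build_grid, make_batches
from f12quad.dense import dense_intermediates

UEH = 1e-6

TERM_MAP = [
    # production term      oracle term   tolerance (hartree)
    ("term_fg", "fg", 1e-7),          # FG, pure NQ vs exact 4c2e
    ("term_oo_FG", "oo_FG", 5e-6),       # hybrid NQ+DF vs exact
    ("term_vv_FG", "vv_FG", 5e-6),
    ("term_six_FG", "sixFG", 1e-7),       # both quadrature; g4 vs g7
    ("term_f2", "ff", 1e-7),
    ("term_oo_FF", "oo_FF", 5e-6),
    ("term_vv_FF", "vv_FF", 5e-6),
    ("term_six_FF", "sixFF", 1e-7),
    ("term_fk_ri", "e61", 1e-7),
    ("term_k_ri", "e62", 1e-7),
    ("term_fo_ri", "e63", 1e-7),
    ("term_ofo", "e64", 1e-7),
    ("term_U", "U", 5e-6),
    ("term_T", "T", 5e-6),
]


class TestDenseOracleEquivalence:
    @pytest.mark.parametrize("prod_name,dense_name,tol", TERM_MAP)
    @pytest.mark.parametrize("pattern", ["x", "d"])
    def test_he_per_term(self, he_production_g4, he_dense, prod_name,
                         dense_name, tol, pattern):
        a = he_production_g4.terms[f"{prod_name}_{pattern}"]
        b = he_dense.intermediates.terms[f"{dense_name}_{pattern}"]
        assert a == pytest.approx(b, abs=tol)

    @pytest.mark.parametrize("name", ["v", "x", "xw", "b"])
    def test_h2_pair_sums(self, h2_production_g4, h2_dense, name):
        for pat in ("exchange", "direct"):
            a = getattr(h2_production_g4, f"{name}_{pat}")
            b = getattr(h2_dense.intermediates, f"{name}_{pat}")
            assert abs(a - b) <= 5 * UEH


class TestSinglePairDegeneracy:
    def test_direct_equals_exchange_for_he(self, he_production_g4):
        r = he_production_g4
        assert r.v_direct == pytest.approx(r.v_exchange, abs=1e-12)
        assert r.x_direct == pytest.approx(r.x_exchange, abs=1e-12)
        assert r.b_direct == pytest.approx(r.b_exchange, abs=1e-12)


class TestStructure:
    def test_empty_virtual_space_zeroes_vv_terms(self):
        """Minimal He basis: occupied == basis, so the virtual-virtual
        products vanish identically."""
        from f12quad.basis import fixture_basis
        from f12quad.fixtures import he
        from f12quad.spaces import make_spaces
        fx = he()
        obs_min = fixture_basis(fx.molecule, "fix.he.min", "orbital")
        sp = make_spaces(fx.molecule, obs_min, fx.cabs_aux)
        assert sp.n_virt == 0
        grid = build_grid(fx.molecule, "g1", 0.0, obs_min)
        make_batches(grid, 64)
        r = IntermediateBuilder(sp, grid, fx.df_aux, theta_nq=0.0).run()
        assert r.terms["term_vv_FG_x"] == 0.0
        assert r.terms["term_vv_FF_x"] == 0.0
        assert r.terms["term_T_x"] == 0.0

    def test_b_terms_homogeneous_in_fock_data(self, he_bundle, he_spaces):
        """Every Fock/exchange-carrying B term is linear in (f, k)."""
        import copy
        fx = he_bundle
        grid = build_grid(fx.molecule, "g1", 0.0, fx.obs)
        make_batches(grid, 64)
        base = IntermediateBuilder(he_spaces, grid, fx.df_aux,
                                   theta_nq=0.0).run()
        sp2 = copy.copy(he_spaces)
        sp2.f_mo = 2.0 * he_spaces.f_mo
        sp2.k_mo = 2.0 * he_spaces.k_mo
        doubled = IntermediateBuilder(sp2, grid, fx.df_aux,
                                      theta_nq=0.0).run()
        for t in ("term_fk_ri_x", "term_k_ri_x", "term_fo_ri_x", "term_ofo_x",
                  "term_U_x", "term_T_x"):
            assert doubled.terms[t] == pytest.approx(2.0 * base.terms[t],
                                                     rel=1e-12, abs=1e-15)

    def test_commutator_level_none_bookkeeping(self, he_bundle, he_spaces):
        """Omitting the commutator add-ons changes B by exactly twice the
        (1/2 gamma^2 F2 + single-RI) pieces."""
        fx = he_bundle
        grid = build_grid(fx.molecule, "g1", 0.0, fx.obs)
        make_batches(grid, 64)
        full = IntermediateBuilder(he_spaces, grid, fx.df_aux,
                                   theta_nq=0.0).run()
        none = IntermediateBuilder(he_spaces, grid, fx.df_aux, theta_nq=0.0,
                                   commutator_level="none").run()
        gsq = 1.3 ** 2
        addon = 2.0 * (0.5 * gsq * full.terms["term_f2_x"]
                       + full.terms["term_fk_ri_x"])
        assert full.b_exchange - none.b_exchange == pytest.approx(addon,
                                                                  abs=1e-13)
        assert none.commutator_level == "none"

    def test_shared_subspace_pass_matches_standalone(self, he_spaces):
        """The merged scaled-MO map equals the sum of the three standalone
        subspace contributions (U) and the two standalone ones (T)."""
        sp = he_spaces
        f = sp.f_mo
        nU, nocc, np_ = sp.n_union, sp.n_occ, sp.n_p
        occ_ind = np.zeros(nU)
        occ_ind[:nocc] = 1.0
        virt_ind = np.zeros(nU)
        virt_ind[nocc:np_] = 1.0
        merged_U = (-1.0 + 2.0 * occ_ind[None, :]
                    - occ_ind[:, None] * occ_ind[None, :]) * f
        standalone = (-1.0 * f
                      + 2.0 * f * occ_ind[None, :]
                      - (occ_ind[:, None] * occ_ind[None, :]) * f)
        assert np.abs(merged_U - standalone).max() == 0.0
        merged_T = ((-2.0 + virt_ind[:, None]) * f)[:, nocc:np_]
        standalone_T = (-2.0 * f + virt_ind[:, None] * f)[:, nocc:np_]
        assert np.abs(merged_T - standalone_T).max() == 0.0

    def test_fock_carrier_swap_symmetry(self, h2_dense):
        """Whether electron 1 or 2 carries the Fock operator only transposes
        the pair matrix; pair sums are unchanged."""
        for pat in ("x", "d"):
            b = h2_dense.b_pairs[pat]
            assert np.abs(b - b.T).max() < 1e-11

    def test_invalid_configuration_rejected(self, he_bundle, he_spaces):
        grid = build_grid(he_bundle.molecule, "g0", 0.0)
        make_batches(grid, 64)
        with pytest.raises(ConfigurationError):
            IntermediateBuilder(he_spaces, grid, he_bundle.df_aux,
                                mode="bogus")
        with pytest.raises(ConfigurationError):
            IntermediateBuilder(he_spaces, grid, he_bundle.df_aux,
                                commutator_level="half")


class TestThetaMonotonicity:
    def test_screening_deviation_shrinks_with_threshold(self, h2o_bundle,
                                                        h2o_spaces):
        """|E(theta) - E(0)| non-increasing through 1e-8, 1e-9, 1e-10, and
        at most 1 uEh at 1e-10."""
        from f12quad.assembly import RunConfig, f12_energy
        fx = h2o_bundle
        grid = build_grid(fx.molecule, "g1", 1e-5, fx.obs)
        make_batches(grid, 64)
        energies = {}
        for th in (0.0, 1e-8, 1e-9, 1e-10):
            rep = f12_energy(fx.molecule, fx.obs, fx.cabs_aux, fx.df_aux,
                             RunConfig(grid_level="g1", theta_nq=th),
                             spaces=h2o_spaces, grid=grid)
            energies[th] = rep.e_f12
        devs = [abs(energies[th] - energies[0.0])
                for th in (1e-8, 1e-9, 1e-10)]
        assert devs[0] >= devs[1] - 1e-13
        assert devs[1] >= devs[2] - 1e-13
        assert devs[2] <= 1 * UEH
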