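import numpy as np
import pytest

from f12quad.basis import BasisSet, Shell
from f12quad.integrals import ao_values, eri_2c2e, eri_3c2e, eri_4c2e, overlap
from f12quad.kernels import KernelSpec
from f12quad.nq_engine import (DfFitBlock, OpCounters, contract_6c3e_ao,
                               contract_6c3e_mo, df_fit_pairs,
                               mo_transform_3c1e, product_4c2e_df,
                               product_4c2e_nq_df)
from f12quad.quadrature import build_grid, make_batches
from f12quad.spaces import make_spaces


@pytest.fixture(scope="module")
def he_setup(he_bundle=None):
    from f12quad import fixtures
    fx = fixtures.he()
    sp = make_spaces(fx.molecule, fx.obs, fx.cabs_aux)
    grid = build_grid(fx.molecule, "g3", 0.0, fx.obs)
    make_batches(grid, 10 ** 9)
    return fx, sp, grid


def _mo_3c1e(op, basis, pts, Cl, Cr):
    from f12quad.integrals import grid_3c1e
    t = grid_3c1e(op, basis, basis, pts)
    return np.einsum("gmn,mi,nk->gik", t, Cl, Cr, optimize=True)


class TestContract6c3eMo:
    def test_constant_kernel_collapse(self, he_setup):
        """Y == c collapses to c * sum_ij <ij|W|ji> by MO orthonormality."""
        fx, sp, grid = he_setup
        b = grid.batches[0]
        C = sp.reference.C
        occ = sp.mo_slice("occ")
        nocc = sp.n_occ
        kF = KernelSpec("F")
        W = _mo_3c1e(kF, fx.obs, b.points, C[:, occ], C[:, occ])
        c = 0.7
        Y = np.broadcast_to(c * np.eye(nocc), (b.n_points, nocc, nocc))
        phi = (ao_values(fx.obs, b.points).T @ C[:, occ])
        e = contract_6c3e_mo(W, Y, phi, phi, b.weights)
        mul = eri_4c2e(kF, fx.obs, fx.obs, fx.obs, fx.obs)
        mo = np.einsum("mnls,mi,nj,lk,st->ijkt", mul, C[:, occ], C[:, occ],
                       C[:, occ], C[:, occ], optimize=True)
        # sum_ij <ij|W|ji> = sum_ij (ij|W|ji) Mulliken (ik|..|jl) ordering
        ref = c * float(np.einsum("ijji->", mo))
        assert e == pytest.approx(ref, abs=5e-7)

    def test_zero_weights(self, he_setup):
        fx, sp, grid = he_setup
        b = grid.batches[0]
        n = sp.n_occ
        W = np.ones((b.n_points, n, n))
        phi = np.ones((b.n_points, n))
        assert contract_6c3e_mo(W, W, phi, phi,
                                np.zeros(b.n_points)) == 0.0

    def test_batch_mismatch_rejected(self):
        with pytest.raises(ValueError):
            contract_6c3e_mo(np.ones((3, 1, 1)), np.ones((4, 1, 1)),
                             np.ones((3, 1)), np.ones((4, 1)), np.ones(3))


class TestContract6c3eAo:
    def test_ao_mo_equivalence(self, he_setup):
        """A = B = C = P reproduces the MO path (change of representation)."""
        from f12quad.integrals import grid_3c1e
        fx, sp, grid = he_setup
        b = grid.batches[0]
        C = sp.reference.C
        occ = sp.mo_slice("occ")
        P = C[:, occ] @ C[:, occ].T
        chi = ao_values(fx.obs, b.points)
        kF, kG = KernelSpec("F"), KernelSpec("G")
        Wao = grid_3c1e(kF, fx.obs, fx.obs, b.points)
        Yao = grid_3c1e(kG, fx.obs, fx.obs, b.points)
        e_ao = contract_6c3e_ao(P, P, P, Wao, Yao, chi, b.weights)
        Wmo = np.einsum("gmn,mi,nk->gik", Wao, C[:, occ], C[:, occ])
        Ymo = np.einsum("gmn,mk,nj->gkj", Yao, C[:, occ], C[:, occ])
        phi = chi.T @ C[:, occ]
        e_mo = contract_6c3e_mo(Wmo, Ymo, phi, phi, b.weights)
        assert e_ao == pytest.approx(e_mo, abs=1e-11)

    def test_annihilating_middle_dressing(self, he_setup):
        from f12quad.integrals import grid_3c1e
        fx, sp, grid = he_setup
        b = grid.batches[0]
        nao = fx.obs.n_ao
        chi = ao_values(fx.obs, b.points)
        W = grid_3c1e(KernelSpec("F"), fx.obs, fx.obs, b.points)
        P = sp.reference.P
        assert contract_6c3e_ao(P, P, np.zeros((nao, nao)), W, W, chi,
                                b.weights) == 0.0


class TestDensityDressing:
    def test_symmetric_tags_validated(self):
        from f12quad.nq_engine import DensityDressing
        m = np.array([[1.0, 0.2], [0.2, 0.5]])
        DensityDressing(m, "occupied")  # fine
        with pytest.raises(ValueError):
            DensityDressing(np.array([[1.0, 0.3], [0.2, 0.5]]), "occupied")
        DensityDressing(np.array([[1.0, 0.3], [0.2, 0.5]]), "custom")  # free


class TestDensityFitting:
    def test_single_aux_scalar_fit(self):
        b = BasisSet([Shell(0, np.zeros(3), 0, [1.0], [1.0])])
        aux = BasisSet([Shell(0, np.zeros(3), 0, [2.0], [1.0])],
                       role="df_aux")
        kG = KernelSpec("G")
        raw = np.transpose(eri_3c2e(kG, b, b, aux), (2, 0, 1))
        metric = eri_2c2e(kG, aux)
        blk = df_fit_pairs(raw, np.linalg.inv(metric))
        assert blk.fit[0, 0, 0] == pytest.approx(
            raw[0, 0, 0] / metric[0, 0], rel=1e-12)

    def test_zero_block_gives_zero_coefficients(self):
        blk = df_fit_pairs(np.zeros((3, 2, 2)), np.eye(3))
        assert np.abs(blk.fit).max() == 0.0

    @pytest.mark.parametrize("tag", ["F", "G", "FG", "F2"])
    def test_completeness_on_exact_product_space(self, tag):
        """Two s functions whose products are exactly spanned by the aux
        basis: fitted 4c2e equals exact 4c2e."""
        A = np.zeros(3)
        B = np.array([0.0, 0.0, 1.2])
        a1, a2 = 1.1, 0.5
        obs = BasisSet([Shell(0, A, 0, [a1], [1.0]), Shell(0, B, 0, [a2], [1.0])])
        mid = (a1 * A + a2 * B) / (a1 + a2)
        aux = BasisSet([Shell(0, A, 0, [2 * a1], [1.0]),
                        Shell(0, B, 0, [2 * a2], [1.0]),
                        Shell(0, mid, 0, [a1 + a2], [1.0])], role="df_aux")
        kern = KernelSpec(tag, 1.3)
        exact = eri_4c2e(kern, obs, obs, obs, obs)
        metric = eri_2c2e(kern, aux)
        raw = np.transpose(eri_3c2e(kern, obs, obs, aux), (2, 0, 1))
        w, V = np.linalg.eigh(metric)
        inv = (V / w) @ V.T
        fit = np.einsum("QP,Qab->Pab", inv, raw)
        fitted = np.einsum("Pab,Pcd->abcd", fit, raw)
        assert np.abs(fitted - exact).max() <= 1e-8


class TestProductPaths:
    def test_df_only_matches_exact_product_on_he(self, he_setup):
        fx, sp, grid = he_setup
        C = sp.reference.C
        occ, virt = sp.mo_slice("occ"), sp.mo_slice("virt")
        kF = KernelSpec("F")
        kG = KernelSpec("G")
        mulF = np.einsum("mnls,mp,nq,lr,st->pqrt",
                         eri_4c2e(kF, fx.obs, fx.obs, fx.obs, fx.obs),
                         C, C, C, C, optimize=True)
        mulG = np.einsum("mnls,mp,nq,lr,st->pqrt",
                         eri_4c2e(kG, fx.obs, fx.obs, fx.obs, fx.obs),
                         C, C, C, C, optimize=True)
        exact = float(np.einsum("ikjl,kjli->", mulF[occ, occ, occ, occ],
                                mulG[occ, occ, occ, occ]))
        # DF route
        rawF = np.einsum("mnR,mp,nq->Rpq",
                         eri_3c2e(kF, fx.obs, fx.obs, fx.df_aux), C, C)
        rawG = np.einsum("mnR,mp,nq->Rpq",
                         eri_3c2e(kG, fx.obs, fx.obs, fx.df_aux), C, C)
        for raw, kern in ((rawF, kF), (rawG, kG)):
            pass
        mF = eri_2c2e(kF, fx.df_aux)
        mG = eri_2c2e(kG, fx.df_aux)

        def inv(m):
            w, V = np.linalg.eigh(m)
            keep = np.abs(w) > 1e-10 * np.abs(w).max()
            return (V[:, keep] / w[keep]) @ V[:, keep].T

        fitF = DfFitBlock(np.einsum("QP,Qab->Pab", inv(mF), rawF)[:, occ, occ])
        fitG = DfFitBlock(np.einsum("QP,Qab->Pab", inv(mG), rawG)[:, occ, occ])
        e = product_4c2e_df(fitF, rawF[:, occ, occ], fitG, rawG[:, occ, occ])
        assert e == pytest.approx(exact, abs=2e-6)

    def test_direct_equals_exchange_single_pair(self, he_setup):
        """He has one occupied orbital: both index patterns coincide."""
        fx, sp, grid = he_setup
        C = sp.reference.C
        occ = sp.mo_slice("occ")
        kF = KernelSpec("F")
        rawF = np.einsum("mnR,mp,nq->Rpq",
                         eri_3c2e(kF, fx.obs, fx.obs, fx.df_aux),
                         C[:, occ], C[:, occ])
        m = eri_2c2e(kF, fx.df_aux)
        w, V = np.linalg.eigh(m)
        keep = np.abs(w) > 1e-10 * np.abs(w).max()
        fit = DfFitBlock(np.einsum(
            "QP,Qab->Pab", (V[:, keep] / w[keep]) @ V[:, keep].T, rawF))
        ex = product_4c2e_df(fit, rawF, fit, rawF, "exchange")
        di = product_4c2e_df(fit, rawF, fit, rawF, "direct")
        assert ex == pytest.approx(di, abs=1e-12)

    def test_zero_kernel_gives_zero(self, he_setup):
        fx, sp, grid = he_setup
        b = grid.batches[0]
        nocc = sp.n_occ
        fit = DfFitBlock(np.zeros((3, nocc, nocc)))
        raw = np.zeros((3, nocc, nocc))
        phi = np.ones((b.n_points, nocc))
        gw = np.ones((b.n_points, nocc, nocc))
        assert product_4c2e_nq_df(gw, fit, raw, phi, phi, b.weights) == 0.0


class TestMoTransform:
    def test_identity_transform(self):
        t = np.random.default_rng(0).standard_normal((40, 3, 3))
        out = mo_transform_3c1e(t, np.eye(3), np.eye(3))
        assert np.array_equal(out, t)

    def test_sub_batch_invariance(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal((40, 4, 5))
        Cl = rng.standard_normal((4, 2))
        Cr = rng.standard_normal((5, 3))
        a = mo_transform_3c1e(t, Cl, Cr, sub_batch=16)
        b = mo_transform_3c1e(t, Cl, Cr, sub_batch=40)
        assert np.abs(a - b).max() < 1e-13

    def test_explicit_loop_oracle(self, he_setup):
        from f12quad.integrals import grid_3c1e
        fx, sp, grid = he_setup
        pts = grid.batches[0].points[:5]
        t = grid_3c1e(KernelSpec("F"), fx.obs, fx.obs, pts)
        C1 = sp.reference.C[:, :1]
        out = mo_transform_3c1e(t, C1, C1)
        ref = np.zeros_like(out)
        for g in range(len(pts)):
            for m in range(fx.obs.n_ao):
                for n in range(fx.obs.n_ao):
                    ref[g, 0, 0] += C1[m, 0] * C1[n, 0] * t[g, m, n]
        assert np.abs(out - ref).max() < 1e-13

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mo_transform_3c1e(np.ones((2, 3, 3)), np.ones((4, 1)),
                              np.ones((3, 1)))
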