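"""Integral-engine validation against closed forms and independent quadrature."""

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss

from f12quad.basis import BasisSet, Shell
from f12quad.boys import boys
from f12quad.integrals import (ao_values, eri_2c2e, eri_3c2e, eri_4c2e,
                               grid_3c1e, kinetic, overlap)
from f12quad.kernels import KernelSpec


@pytest.fixture(scope="module")
def spd_basis():
    return BasisSet([Shell(0, np.zeros(3), 0, [1.0], [1.0]),
                     Shell(0, np.array([0.0, 0.5, 1.0]), 1, [0.9], [1.0]),
                     Shell(0, np.array([0.3, 0.0, 0.2]), 2, [0.7], [1.0])])


def spherical_grid(center, rmax=12.0, nr=100, nt=36, nphi=72):
    xr, wr = leggauss(nr)
    r = (xr + 1) * rmax / 2
    wr = wr * rmax / 2
    xt, wt = leggauss(nt)
    phi = 2 * np.pi * np.arange(nphi) / nphi
    st = np.sqrt(1 - xt ** 2)
    pts, wts = [], []
    for i in range(nr):
        for j in range(nt):
            x = r[i] * st[j] * np.cos(phi)
            y = r[i] * st[j] * np.sin(phi)
            z = r[i] * xt[j] * np.ones(nphi)
            pts.append(np.stack([x, y, z], 1) + center)
            wts.append(np.full(nphi, wr[i] * wt[j] * (2 * np.pi / nphi) * r[i] ** 2))
    return np.concatenate(pts), np.concatenate(wts)


class TestBoys:
    def test_against_quadrature(self):
        x, w = leggauss(200)
        t = (x + 1) / 2
        w = w / 2
        for n in (0, 3, 8):
            for arg in (0.0, 1e-14, 0.5, 7.0, 40.0, 150.0):
                ref = np.sum(w * t ** (2 * n) * np.exp(-arg * t * t))
                assert boys(n, arg)[n, 0] == pytest.approx(ref, abs=1e-13)

    def test_small_x_limit(self):
        assert boys(2, 0.0)[2, 0] == pytest.approx(1.0 / 5.0, abs=1e-15)


class TestClosedForms:
    def test_coulomb_ssss_self_repulsion(self):
        b = BasisSet([Shell(0, np.zeros(3), 0, [1.0], [1.0])])
        v = eri_4c2e(KernelSpec("G"), b, b, b, b)[0, 0, 0, 0]
        assert v == pytest.approx(2.0 / np.sqrt(np.pi), abs=1e-12)

    def test_grid_coulomb_at_center(self):
        alpha = 1.7
        b = BasisSet([Shell(0, np.zeros(3), 0, [alpha], [1.0])])
        v = grid_3c1e(KernelSpec("G"), b, b, np.zeros((1, 3)))[0, 0, 0]
        assert v == pytest.approx(2.0 * np.sqrt(2 * alpha / np.pi), abs=1e-12)

    def test_grid_geminal_far_point_vanishes(self):
        b = BasisSet([Shell(0, np.zeros(3), 0, [1.0], [1.0])])
        far = np.array([[0.0, 0.0, 50.0]])
        v = grid_3c1e(KernelSpec("F"), b, b, far)[0, 0, 0]
        assert abs(v) <= 1e-14

    def test_geminal_vanishes_for_large_gamma(self):
        b = BasisSet([Shell(0, np.zeros(3), 0, [1.0], [1.0])])
        v = eri_4c2e(KernelSpec("F", gamma=60.0), b, b, b, b)[0, 0, 0, 0]
        assert abs(v) < 1e-4

    def test_kinetic_normalized_s(self):
        b = BasisSet([Shell(0, np.zeros(3), 0, [1.0], [1.0])])
        assert kinetic(b)[0, 0] == pytest.approx(1.5, abs=1e-12)

    def test_ao_amplitude_closed_forms(self):
        alpha = 0.8
        bs = BasisSet([Shell(0, np.zeros(3), 0, [alpha], [1.0]),
                       Shell(0, np.zeros(3), 1, [alpha], [1.0])])
        at_center = ao_values(bs, np.zeros((1, 3)))
        assert at_center[0, 0] == pytest.approx((2 * alpha / np.pi) ** 0.75,
                                                abs=1e-12)
        assert np.abs(at_center[1:4, 0]).max() == 0.0
        far = ao_values(bs, np.array([[50.0, 0.0, 0.0]]))
        assert np.abs(far).max() <= 1e-14


class TestKernelIdentities:
    def test_del2f_equals_gamma_sq_f2(self, spd_basis):
        b = spd_basis
        f2 = eri_4c2e(KernelSpec("F2", gamma=1.3), b, b, b, b)
        d2 = eri_4c2e(KernelSpec("DEL2F", gamma=1.3), b, b, b, b)
        assert np.abs(d2 - 1.3 ** 2 * f2).max() < 1e-12

    def test_fg_coulomb_limit(self):
        """gamma * FG-kernel -> -1/r as gamma -> 0 (signed geminal)."""
        b = BasisSet([Shell(0, np.zeros(3), 0, [1.0], [1.0]),
                      Shell(0, np.array([0, 0, 1.2]), 0, [0.6], [1.0])])
        g = 1e-3
        # a single Gaussian suffices: exp(-g r) is nearly constant on the mesh
        fg = eri_3c2e(KernelSpec("FG", gamma=g, n_fit=1),
                      b, b, BasisSet([Shell(0, np.zeros(3), 0, [0.8], [1.0])],
                                     role="df_aux"))
        cc = eri_3c2e(KernelSpec("G"), b, b,
                      BasisSet([Shell(0, np.zeros(3), 0, [0.8], [1.0])],
                               role="df_aux"))
        # fit residual of the nearly-constant exponential bounds the deviation
        assert np.abs(g * fg + cc).max() < 0.02 * np.abs(cc).max()

    def test_signed_kernel_values(self):
        k = KernelSpec("F", gamma=1.3)
        assert k.kernel_value(0.0) == pytest.approx(-1.0 / 1.3)
        k2 = KernelSpec("F2", gamma=1.3)
        kd = KernelSpec("DEL2F", gamma=1.3)
        r = np.linspace(0.0, 5.0, 11)
        assert np.allclose(kd.kernel_value(r), 1.3 ** 2 * k2.kernel_value(r))


class TestPermutationalSymmetry:
    @pytest.mark.parametrize("tag", ["G", "F", "FG", "F2"])
    def test_real_integral_symmetry(self, spd_basis, tag):
        t = eri_4c2e(KernelSpec(tag), spd_basis, spd_basis, spd_basis,
                     spd_basis)
        assert np.abs(t - t.transpose(1, 0, 2, 3)).max() < 1e-10
        assert np.abs(t - t.transpose(0, 1, 3, 2)).max() < 1e-10
        assert np.abs(t - t.transpose(2, 3, 0, 1)).max() < 1e-10

    def test_grid_block_pair_symmetry(self, spd_basis):
        pts = np.array([[0.4, -0.3, 0.9], [1.0, 0.2, -0.5]])
        t = grid_3c1e(KernelSpec("F"), spd_basis, spd_basis, pts)
        assert np.abs(t - t.transpose(0, 2, 1)).max() < 1e-12


class TestQuadratureConsistency:
    @pytest.mark.parametrize("tag", ["G", "F", "FG"])
    def test_grid_contraction_reproduces_eri(self, spd_basis, tag):
        """sum_g w_g chi_a chi_b (g|O|cd) == (ab|O|cd)."""
        b = spd_basis
        pts, wts = spherical_grid(np.array([0.1, 0.1, 0.4]), rmax=11.0,
                                  nr=80, nt=30, nphi=60)
        ao = ao_values(b, pts)
        t3 = grid_3c1e(KernelSpec(tag), b, b, pts)
        t4 = eri_4c2e(KernelSpec(tag), b, b, b, b)
        for (a, bb, c, d) in [(0, 3, 4, 7), (4, 4, 7, 7), (9, 2, 3, 0)]:
            q = np.einsum("g,g,g->", ao[a] * ao[bb], wts, t3[:, c, d])
            assert q == pytest.approx(t4[a, bb, c, d], abs=1e-10)

    def test_empty_ao_block(self):
        b = BasisSet([Shell(0, np.zeros(3), 0, [1.0], [1.0])])
        empty = BasisSet([])
        t = eri_3c2e(KernelSpec("G"), empty, empty, b)
        assert t.shape == (0, 0, 1)


class TestDfMetric:
    def test_scalar_inverse(self):
        aux = BasisSet([Shell(0, np.zeros(3), 0, [0.8], [1.0])], role="df_aux")
        y = eri_2c2e(KernelSpec("G"), aux)
        assert y.shape == (1, 1) and y[0, 0] > 0

    def test_geminal_metric_definite(self):
        """(R|F|S) is the negative of a positive definite matrix."""
        aux = BasisSet([Shell(0, np.zeros(3), 0, [0.5], [1.0]),
                        Shell(0, np.zeros(3), 0, [1.5], [1.0]),
                        Shell(0, np.array([0, 0, 1.0]), 1, [0.9], [1.0])],
                       role="df_aux")
        y = eri_2c2e(KernelSpec("F", gamma=1.3), aux)
        w = np.linalg.eigvalsh(-y)
        assert w.min() > -1e-10

    def test_fit_order_convergence(self, spd_basis):
        """Doubling the STG fit order changes 3c1e tensors below fit tol."""
        pts = np.array([[0.4, -0.3, 0.9]])
        a = grid_3c1e(KernelSpec("F", n_fit=4), spd_basis, spd_basis, pts)
        b = grid_3c1e(KernelSpec("F", n_fit=8), spd_basis, spd_basis, pts)
        assert np.abs(a - b).max() < 5e-3
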