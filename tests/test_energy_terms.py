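"""Pairwise energy terms against independent plug-in oracles and limits."""

import numpy as np
import pytest

from hepcg.energy import (
    cavity_iso,
    cavity_tails,
    electrostatics,
    gay_berne,
    gb_function,
    gb_polarization,
    head_tail_polarization,
    lj_heads,
)
from hepcg.errors import ParameterError, SingularityError
from hepcg.fixtures import make_toy_dimer
from hepcg.params import C_ELEC, CGParameters


from oracles import lj


def random_pair_geometry(rng, rmin=3.5, rmax=12.0):
    u_i = rng.normal(size=3)
    u_i /= np.linalg.norm(u_i)
    u_j = rng.normal(size=3)
    u_j /= np.linalg.norm(u_j)
    sep = rng.normal(size=3)
    sep *= rng.uniform(rmin, rmax) / np.linalg.norm(sep)
    return np.zeros(3), sep, u_i, u_j


class TestGayBerne:
    def test_isotropic_limit_equals_lj(self, rng):
        p = CGParameters(chi_gb_sigma=0.0, chi_gb_eps=0.0)
        for _ in range(1000):
            ti, tj, ui, uj = random_pair_geometry(rng)
            r = np.linalg.norm(tj - ti)
            assert gay_berne(ti, tj, ui, uj, p) == pytest.approx(
                lj(r, p.sigma0_tail, p.eps_tail), abs=1e-10
            )

    def test_zero_at_side_to_side_contact(self, params):
        dimer = make_toy_dimer("side_to_side", separation=params.sigma0_tail, params=params)
        e = gay_berne(dimer.tails[0], dimer.tails[1], *dimer.orientations, params)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_zero_at_orientation_dependent_contact(self, rng, params):
        # for arbitrary orientations the zero sits at sigma_ij(omega):
        # solve for it by bisection on the energy itself is circular, so use
        # the independent sigma formula
        for _ in range(50):
            ti, tj, ui, uj = random_pair_geometry(rng)
            rhat = (tj - ti) / np.linalg.norm(tj - ti)
            a, bi, bj = ui @ uj, rhat @ ui, rhat @ uj
            chi = params.chi_gb_sigma
            S = (bi + bj) ** 2 / (1 + chi * a) + (bi - bj) ** 2 / (1 - chi * a)
            sig = params.sigma0_tail / np.sqrt(1 - chi * S / 2)
            e = gay_berne(ti, ti + sig * rhat, ui, uj, params)
            assert e == pytest.approx(0.0, abs=1e-10)

    def test_spherical_minimum_at_lj_location(self):
        p = CGParameters(chi_gb_sigma=0.0, chi_gb_eps=0.0)
        rmin = 2 ** (1 / 6) * p.sigma0_tail
        e = gay_berne([0, 0, 0], [rmin, 0, 0], [0, 0, 1], [0, 0, 1], p)
        assert e == pytest.approx(-p.eps_tail, rel=1e-12)

    def test_vanishes_at_large_separation(self, params):
        e = gay_berne([0, 0, 0], [500.0, 0, 0], [0, 0, 1], [0, 1, 0], params)
        assert abs(e) < 1e-10

    def test_singular_at_zero_distance(self, params):
        with pytest.raises(SingularityError):
            gay_berne([0, 0, 0], [0, 0, 0], [0, 0, 1], [0, 0, 1], params)


class TestGBFunction:
    def test_born_limit_at_zero(self):
        assert gb_function(0.0, 2.0, 2.0) == pytest.approx(2.0)
        assert gb_function(0.0, 1.5, 2.5) == pytest.approx(np.sqrt(1.5 * 2.5))

    def test_coulomb_limit_at_large_r(self):
        r = 20.0 * 2.5
        assert gb_function(r, 1.5, 2.5) / r == pytest.approx(1.0, rel=0.01)

    def test_plug_in_oracle(self):
        r, ai, aj = 3.0, 1.5, 2.5
        expected = np.sqrt(r**2 + ai * aj * np.exp(-(r**2) / (4 * ai * aj)))
        assert gb_function(r, ai, aj) == pytest.approx(expected, rel=1e-12)

    def test_monotone_increasing(self):
        rs = np.linspace(0, 30, 400)
        vals = [gb_function(r, 1.5, 2.5) for r in rs]
        assert np.all(np.diff(vals) > 0)

    def test_negative_radius_rejected(self):
        with pytest.raises(ParameterError):
            gb_function(1.0, -1.0, 2.0)


class TestGBPolarization:
    def test_zero_charge_gives_zero(self, params):
        assert gb_polarization([0, 0, 0], [8, 0, 0], 0.0, -2.0, params) == 0.0

    def test_no_contrast_limit(self):
        p = CGParameters(eps_in=80.0 * (1 - 1e-12), eps_out=80.0)
        e = gb_polarization([0, 0, 0], [8, 0, 0], -2.0, -2.0, p)
        assert abs(e) < 1e-9

    def test_like_charges_stabilizing(self, params):
        e = gb_polarization([0, 0, 0], [8, 0, 0], -2.0, -2.0, params)
        assert e < 0

    def test_plug_in_oracle(self):
        p = CGParameters(kappa=0.3)
        r, qi, qj = 7.0, -2.0, -2.0
        ai = aj = p.born_radii[0]
        f = np.sqrt(r**2 + ai * aj * np.exp(-(r**2) / (4 * ai * aj)))
        expected = C_ELEC * (1 / p.eps_out - 1 / p.eps_in) * qi * qj * np.exp(-p.kappa * r) / f
        got = gb_polarization([0, 0, 0], [r, 0, 0], qi, qj, p)
        assert got == pytest.approx(expected, rel=1e-12)


class TestHeadTailPolarization:
    def geometry(self, params, separation=6.0):
        d = make_toy_dimer("end_to_end", separation=separation, params=params)
        return d

    def test_zero_solvation_factors(self):
        p = CGParameters(alpha1=0.0, alpha2=0.0)
        d = self.geometry(p)
        e = head_tail_polarization(
            d.heads[0], d.tails[0], d.heads[1], d.tails[1], -2.0, -2.0, p
        )
        assert e == 0.0

    def test_exchange_symmetry(self, rng, params):
        for _ in range(20):
            h_i, h_j = rng.normal(size=3) * 3, rng.normal(size=3) * 3 + 8
            t_i, t_j = h_i + rng.normal(size=3), h_j + rng.normal(size=3)
            e_ij = head_tail_polarization(h_i, t_i, h_j, t_j, -2.0, -2.0, params)
            e_ji = head_tail_polarization(h_j, t_j, h_i, t_i, -2.0, -2.0, params)
            assert e_ij == pytest.approx(e_ji, rel=1e-12)

    def test_screening_reduces_magnitude(self):
        p0 = CGParameters(kappa=0.0)
        p1 = CGParameters(kappa=1.0)
        d = self.geometry(p0)
        e0 = head_tail_polarization(d.heads[0], d.tails[0], d.heads[1], d.tails[1], -2, -2, p0)
        e1 = head_tail_polarization(d.heads[0], d.tails[0], d.heads[1], d.tails[1], -2, -2, p1)
        assert abs(e1) < abs(e0)

    def test_collinear_dimer_plug_in_oracle(self):
        p = CGParameters(kappa=0.2, head_offset=1.0, tail_offset=-1.0)
        d = make_toy_dimer("end_to_end", separation=7.0, params=p)
        # hand geometry: centers at x=0 and 7, heads at +1 offset, tails at -1
        r_ht = 7.0 - 1.0 - 1.0   # head_i (x=1) to tail_j (x=6)
        r_th = 7.0 + 1.0 + 1.0   # tail_i (x=-1) to head_j (x=8)
        contrast = 1 / p.eps_in - 1 / p.eps_out
        expected = -C_ELEC * contrast * (
            p.alpha2 * 4.0 * np.exp(-2 * p.kappa * r_ht) / r_ht**4
            + p.alpha1 * 4.0 * np.exp(-2 * p.kappa * r_th) / r_th**4
        )
        got = head_tail_polarization(
            d.heads[0], d.tails[0], d.heads[1], d.tails[1], -2.0, -2.0, p
        )
        assert got == pytest.approx(expected, rel=1e-12)


class TestCavityTerms:
    def test_iso_decays(self, params):
        assert cavity_iso([0, 0, 0], [300.0, 0, 0], params) == pytest.approx(0.0, abs=1e-12)

    def test_iso_exchange_symmetric(self, params, rng):
        a, b = rng.normal(size=3), rng.normal(size=3) + 5
        assert cavity_iso(a, b, params) == cavity_iso(b, a, params)

    def test_iso_plug_in_at_contact(self, params):
        r = 2 * params.sigma_iso  # x = 1: shape x² exp(1-x²) peaks at eps_cav
        e = cavity_iso([0, 0, 0], [r, 0, 0], params)
        assert e == pytest.approx(params.eps_cav_iso, rel=1e-12)

    def test_tails_isotropic_limit_matches_iso_form(self, rng):
        p = CGParameters(chi_cav_1=0.0, chi_cav_2=0.0)
        for _ in range(200):
            ti, tj, ui, uj = random_pair_geometry(rng)
            r = np.linalg.norm(tj - ti)
            x = r / (2 * p.sigma_cav_tail)
            expected = p.eps_cav_tail * x**2 * np.exp(1 - x**2)
            assert cavity_tails(ti, tj, ui, uj, p) == pytest.approx(expected, abs=1e-12)

    def test_tails_exchange_symmetry(self, rng, params):
        ti, tj, ui, uj = random_pair_geometry(rng)
        e_ij = cavity_tails(ti, tj, ui, uj, params)
        e_ji = cavity_tails(tj, ti, uj, ui, params)
        assert e_ij == pytest.approx(e_ji, rel=1e-12)

    def test_side_vs_end_orientation_dependence(self, params):
        side = make_toy_dimer("side_to_side", separation=5.0, params=params)
        end = make_toy_dimer("end_to_end", separation=5.0, params=params)
        e_side = cavity_tails(side.tails[0], side.tails[1], *side.orientations, params)
        e_end = cavity_tails(end.tails[0], end.tails[1], *end.orientations, params)
        # independent evaluation of the documented contact-distance formula
        def oracle(a, bi, bj, r):
            S = (bi + bj) ** 2 / (1 + params.chi_cav_2 * a) + (bi - bj) ** 2 / (
                1 - params.chi_cav_2 * a
            )
            sig = 2 * params.sigma_cav_tail / np.sqrt(1 - params.chi_cav_1 * S / 2)
            x = r / sig
            return params.eps_cav_tail * x**2 * np.exp(1 - x**2)

        assert e_side == pytest.approx(oracle(1.0, 0.0, 0.0, 5.0), rel=1e-12)
        assert e_end == pytest.approx(oracle(1.0, 1.0, 1.0, 5.0), rel=1e-12)
        assert e_side != pytest.approx(e_end)


class TestLJHeads:
    def test_zero_at_sigma(self, params):
        assert lj_heads([0, 0, 0], [params.sigma_head, 0, 0], params) == pytest.approx(0.0)

    def test_minimum_depth(self, params):
        r = 2 ** (1 / 6) * params.sigma_head
        assert lj_heads([0, 0, 0], [r, 0, 0], params) == pytest.approx(-params.eps_head)

    def test_vanishes_at_infinity(self, params):
        assert lj_heads([0, 0, 0], [400.0, 0, 0], params) == pytest.approx(0.0, abs=1e-12)


class TestElectrostatics:
    def test_zero_charge(self, params):
        assert electrostatics([0, 0, 0], [10, 0, 0], 0.0, -2.0, params) == 0.0

    def test_unscreened_coulomb_oracle(self):
        p = CGParameters(kappa=0.0)
        got = electrostatics([0, 0, 0], [10.0, 0, 0], -2.0, -2.0, p)
        assert got == pytest.approx(C_ELEC * 4.0 / (p.eel_eps * 10.0), rel=1e-12)

    def test_like_charges_repulsive(self, params):
        assert electrostatics([0, 0, 0], [10, 0, 0], -2.0, -2.0, params) > 0

    def test_screening_monotone(self):
        e0 = electrostatics([0, 0, 0], [10, 0, 0], -2, -2, CGParameters(kappa=0.0))
        e5 = electrostatics([0, 0, 0], [10, 0, 0], -2, -2, CGParameters(kappa=0.5))
        assert 0 < e5 < e0

    def test_configured_dielectric(self):
        p = CGParameters(eel_dielectric=10.0)
        got = electrostatics([0, 0, 0], [10.0, 0, 0], -2.0, -2.0, p.replace(kappa=0.0))
        assert got == pytest.approx(C_ELEC * 4.0 / (10.0 * 10.0), rel=1e-12)
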