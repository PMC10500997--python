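"""Numba-compiled energy, force and Langevin-integration kernels.

Single source of truth for the effective energy function used by dynamics:
:func:`hepcg.energy.total_energy` and :func:`hepcg.dynamics.run_simulation`
both call :func:`energy_forces` / :func:`integrate`.  The readable closed-form
term functions in :mod:`hepcg.energy` are cross-checked against this kernel in
the test suite.

Parameter vector layout (see ``CGParameters.kernel_vector``)::

    0 bond_k        1 bond_d0      2 angle_k       3 cos(theta0)
    4..6 torsion c1..c3
    7 sigma0_tail   8 eps_tail     9 chi_gb_sigma 10 chi_gb_eps
    11 sigma_head  12 eps_head    13 eps_in       14 eps_out
    15 alpha1      16 alpha2      17 eps_cav_iso  18 sigma_iso
    19 eps_cav_tail 20 sigma_cav_tail 21 chi_cav_1 22 chi_cav_2
    23 eel_eps     24 kappa       25 head_offset  26 tail_offset
    27..29 screening flags (polGB, pol, eel)

Energy-term index order matches ``params.TERM_NAMES``:
bond 0, angle 1, torsion 2, gberne 3, polGB 4, pol 5, caviso 6, cavtail 7,
vdw 8, eel 9.
"""

import math

import numpy as np
from numba import njit

#: kcal·Å/(mol·e²)
C_ELEC = 332.063713
#: acceleration unit conversion, Å/fs² per (kcal/mol/Å)/amu
FCONV = 4.184e-4
#: first included nonbonded neighbour offset: pairs (i, i+1), (i, i+2) are
#: excluded (their geometry is governed by the bonded terms)
NB_EXCLUSION = 3

N_TERMS = 10


@njit(cache=True)
def _aniso_contact(sig0, chi_x, chi_d, a, bi, bj):
    """Anisotropic contact distance sigma(ω) and its partials w.r.t. (a, bi, bj).

    sigma = sig0 * [1 - (chi_x/2) * S]^(-1/2) with
    S = (bi+bj)²/(1+chi_d*a) + (bi-bj)²/(1-chi_d*a).
    """
    p = 1.0 + chi_d * a
    q = 1.0 - chi_d * a
    sp = bi + bj
    sm = bi - bj
    S = sp * sp / p + sm * sm / q
    X = 1.0 - 0.5 * chi_x * S
    sig = sig0 / math.sqrt(X)
    dsig_dS = 0.25 * chi_x * sig / X
    dS_da = chi_d * (sm * sm / (q * q) - sp * sp / (p * p))
    dS_dbi = 2.0 * sp / p + 2.0 * sm / q
    dS_dbj = 2.0 * sp / p - 2.0 * sm / q
    return sig, dsig_dS * dS_da, dsig_dS * dS_dbi, dsig_dS * dS_dbj


@njit(cache=True)
def _gay_berne(r, a, bi, bj, sig0, eps0, chi, chip):
    """Shifted Gay–Berne energy and partials (dE/dr, dE/da, dE/dbi, dE/dbj)."""
    sig, dsda, dsdbi, dsdbj = _aniso_contact(sig0, chi, chi, a, bi, bj)
    # orientation-dependent well depth eps = eps0 * eps1 * eps2²
    one_m = 1.0 - chi * chi * a * a
    eps1 = 1.0 / math.sqrt(one_m)
    deps1_da = chi * chi * a * eps1 * eps1 * eps1
    pp = 1.0 + chip * a
    qq = 1.0 - chip * a
    sp = bi + bj
    sm = bi - bj
    Sp = sp * sp / pp + sm * sm / qq
    eps2 = 1.0 - 0.5 * chip * Sp
    dSp_da = chip * (sm * sm / (qq * qq) - sp * sp / (pp * pp))
    dSp_dbi = 2.0 * sp / pp + 2.0 * sm / qq
    dSp_dbj = 2.0 * sp / pp - 2.0 * sm / qq
    eps = eps0 * eps1 * eps2 * eps2
    deps_da = eps0 * (deps1_da * eps2 * eps2 + eps1 * 2.0 * eps2 * (-0.5 * chip) * dSp_da)
    deps_dbi = eps0 * eps1 * 2.0 * eps2 * (-0.5 * chip) * dSp_dbi
    deps_dbj = eps0 * eps1 * 2.0 * eps2 * (-0.5 * chip) * dSp_dbj

    h = r - sig + sig0
    rho = sig0 / h
    r6 = rho ** 6
    r12 = r6 * r6
    core = r12 - r6
    E = 4.0 * eps * core
    dE_drho = 4.0 * eps * (12.0 * r12 - 6.0 * r6) / rho
    drho_dr = -rho * rho / sig0
    dE_dr = dE_drho * drho_dr
    dE_dsig = -dE_dr  # rho depends on (r - sig)
    dE_da = dE_dsig * dsda + 4.0 * core * deps_da
    dE_dbi = dE_dsig * dsdbi + 4.0 * core * deps_dbi
    dE_dbj = dE_dsig * dsdbj + 4.0 * core * deps_dbj
    return E, dE_dr, dE_da, dE_dbi, dE_dbj


@njit(cache=True)
def _cavity(r, sig, eps_cav):
    """Cavity shape eps * x² exp(1-x²), x = r/sig; returns (E, dE/dr, dE/dsig)."""
    x = r / sig
    g = x * x * math.exp(1.0 - x * x)
    dg_dx = (2.0 * x - 2.0 * x * x * x) * math.exp(1.0 - x * x)
    E = eps_cav * g
    dE_dx = eps_cav * dg_dx
    return E, dE_dx / sig, -dE_dx * r / (sig * sig)


@njit(cache=True)
def _f_gb(r, ab):
    """Still interpolation function f_GB and df/dr; ab = a_i * a_j."""
    e = math.exp(-r * r / (4.0 * ab))
    f = math.sqrt(r * r + ab * e)
    df = r * (4.0 - e) / (4.0 * f)
    return f, df


@njit(cache=True)
def energy_forces(anchors, charges, born, P, wf, eterms, grad):
    """Per-term energies (raw, unweighted) and the weighted-total gradient.

    Parameters
    ----------
    anchors : (n+1, 3) float64
    charges, born : (n,) per-site charge (e) and Born radius (Å)
    P : kernel parameter vector
    wf : (10,) per-term weight × temperature factor, multiplies gradients
    eterms : (10,) output, raw per-term energies
    grad : (n+1, 3) output, gradient of Σ wf·E w.r.t. anchors
    """
    n_anchor = anchors.shape[0]
    n_bond = n_anchor - 1
    n_site = n_bond

    eterms[:] = 0.0
    grad[:, :] = 0.0

    bond_k = P[0]
    bond_d0 = P[1]
    angle_k = P[2]
    cos_th0 = P[3]
    tc1 = P[4]
    tc2 = P[5]
    tc3 = P[6]
    sig0_t = P[7]
    eps_t = P[8]
    chi_gb = P[9]
    chip_gb = P[10]
    sig_h = P[11]
    eps_h = P[12]
    eps_in = P[13]
    eps_out = P[14]
    alpha1 = P[15]
    alpha2 = P[16]
    eps_ci = P[17]
    sig_iso = P[18]
    eps_ct = P[19]
    sig_ctail = P[20]
    chi_c1 = P[21]
    chi_c2 = P[22]
    eel_eps = P[23]
    kappa = P[24]
    h_off = P[25]
    t_off = P[26]
    kap_polgb = kappa if P[27] != 0.0 else 0.0
    kap_pol = kappa if P[28] != 0.0 else 0.0
    kap_eel = kappa if P[29] != 0.0 else 0.0

    # ------------------------------------------------------------------
    # derived geometry
    # ------------------------------------------------------------------
    dlen = np.empty(n_bond)
    u = np.empty((n_bond, 3))
    head = np.empty((n_site, 3))
    tail = np.empty((n_site, 3))
    for k in range(n_bond):
        bx = anchors[k + 1, 0] - anchors[k, 0]
        by = anchors[k + 1, 1] - anchors[k, 1]
        bz = anchors[k + 1, 2] - anchors[k, 2]
        d = math.sqrt(bx * bx + by * by + bz * bz)
        dlen[k] = d
        u[k, 0] = bx / d
        u[k, 1] = by / d
        u[k, 2] = bz / d
        mx = 0.5 * (anchors[k, 0] + anchors[k + 1, 0])
        my = 0.5 * (anchors[k, 1] + anchors[k + 1, 1])
        mz = 0.5 * (anchors[k, 2] + anchors[k + 1, 2])
        head[k, 0] = mx + h_off * u[k, 0]
        head[k, 1] = my + h_off * u[k, 1]
        head[k, 2] = mz + h_off * u[k, 2]
        tail[k, 0] = mx + t_off * u[k, 0]
        tail[k, 1] = my + t_off * u[k, 1]
        tail[k, 2] = mz + t_off * u[k, 2]

    g_head = np.zeros((n_site, 3))
    g_tail = np.zeros((n_site, 3))
    g_u = np.zeros((n_site, 3))

    # ------------------------------------------------------------------
    # bonded: virtual-bond stretching
    # ------------------------------------------------------------------
    w = wf[0]
    for k in range(n_bond):
        dd = dlen[k] - bond_d0
        eterms[0] += bond_k * dd * dd
        gmag = w * 2.0 * bond_k * dd
        for c in range(3):
            grad[k + 1, c] += gmag * u[k, c]
            grad[k, c] -= gmag * u[k, c]

    # ------------------------------------------------------------------
    # bonded: virtual-bond-angle bending, U = k/2 (cosθ - cosθ0)²
    # θ_k at anchor k+1 between bonds k and k+1
    # ------------------------------------------------------------------
    n_ang = n_bond - 1
    cth = np.empty(max(n_ang, 0))
    sth = np.empty(max(n_ang, 0))
    w = wf[1]
    for k in range(n_ang):
        c = 0.0
        for cc in range(3):
            c += (-u[k, cc]) * u[k + 1, cc]
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        cth[k] = c
        s2 = 1.0 - c * c
        sth[k] = math.sqrt(s2) if s2 > 0.0 else 0.0
        dev = c - cos_th0
        eterms[1] += 0.5 * angle_k * dev * dev
        dEdc = w * angle_k * dev
        # e1 = -u[k] (vertex -> previous anchor), e2 = u[k+1]
        for cc in range(3):
            e1 = -u[k, cc]
            e2 = u[k + 1, cc]
            gA = (e2 - c * e1) / dlen[k]        # d c / d anchors[k]
            gC = (e1 - c * e2) / dlen[k + 1]    # d c / d anchors[k+2]
            grad[k, cc] += dEdc * gA
            grad[k + 2, cc] += dEdc * gC
            grad[k + 1, cc] -= dEdc * (gA + gC)

    # ------------------------------------------------------------------
    # bonded: torsion U = sinθ_{i-1} sinθ_i · F(γ)
    # ------------------------------------------------------------------
    w = wf[2]
    for k in range(n_bond - 2):
        # dihedral over anchors k..k+3, bonds k, k+1, k+2
        n1 = np.empty(3)
        n2 = np.empty(3)
        n1[0] = u[k, 1] * u[k + 1, 2] - u[k, 2] * u[k + 1, 1]
        n1[1] = u[k, 2] * u[k + 1, 0] - u[k, 0] * u[k + 1, 2]
        n1[2] = u[k, 0] * u[k + 1, 1] - u[k, 1] * u[k + 1, 0]
        n2[0] = u[k + 1, 1] * u[k + 2, 2] - u[k + 1, 2] * u[k + 2, 1]
        n2[1] = u[k + 1, 2] * u[k + 2, 0] - u[k + 1, 0] * u[k + 2, 2]
        n2[2] = u[k + 1, 0] * u[k + 2, 1] - u[k + 1, 1] * u[k + 2, 0]
        cx = n1[1] * n2[2] - n1[2] * n2[1]
        cy = n1[2] * n2[0] - n1[0] * n2[2]
        cz = n1[0] * n2[1] - n1[1] * n2[0]
        sin_part = cx * u[k + 1, 0] + cy * u[k + 1, 1] + cz * u[k + 1, 2]
        cos_part = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
        gam = math.atan2(sin_part, cos_part)

        F = (
            tc1 * (1.0 + math.cos(gam))
            + tc2 * (1.0 - math.cos(2.0 * gam))
            + tc3 * (1.0 + math.cos(3.0 * gam))
        )
        dF = (
            -tc1 * math.sin(gam)
            + 2.0 * tc2 * math.sin(2.0 * gam)
            - 3.0 * tc3 * math.sin(3.0 * gam)
        )
        s1 = sth[k]
        s2 = sth[k + 1]
        eterms[2] += s1 * s2 * F

        # --- dγ/danchors (standard four-point formulas, bond vectors b=d*u) ---
        n1sq = n1[0] * n1[0] + n1[1] * n1[1] + n1[2] * n1[2]
        n2sq = n2[0] * n2[0] + n2[1] * n2[1] + n2[2] * n2[2]
        a12 = u[k, 0] * u[k + 1, 0] + u[k, 1] * u[k + 1, 1] + u[k, 2] * u[k + 1, 2]
        a32 = (
            u[k + 2, 0] * u[k + 1, 0]
            + u[k + 2, 1] * u[k + 1, 1]
            + u[k + 2, 2] * u[k + 1, 2]
        )
        if n1sq > 1e-18 and n2sq > 1e-18:
            dEdg = w * s1 * s2 * dF
            d1 = dlen[k]
            d2 = dlen[k + 1]
            d3 = dlen[k + 2]
            # n1, n2 are unit-bond crosses; with unnormalized bonds the
            # classic formulas reduce to F1 = -n1/(d1 |n1|²), F4 = n2/(d3 |n2|²)
            t1 = d1 * a12 / d2
            t2 = d3 * a32 / d2
            for cc in range(3):
                g0 = -n1[cc] / (d1 * n1sq)            # dγ/dA[k]
                g3 = n2[cc] / (d3 * n2sq)             # dγ/dA[k+3]
                g1 = -(1.0 + t1) * g0 + t2 * g3
                g2 = t1 * g0 - (1.0 + t2) * g3
                grad[k, cc] += dEdg * g0
                grad[k + 1, cc] += dEdg * g1
                grad[k + 2, cc] += dEdg * g2
                grad[k + 3, cc] += dEdg * g3

        # --- d(sinθ)/danchors contributions ---
        for which in range(2):
            idx = k + which            # angle index
            s_this = sth[idx]
            if s_this < 1e-8:
                continue
            pref = w * F * (s2 if which == 0 else s1)
            dEdc = -pref * cth[idx] / s_this
            for cc in range(3):
                e1 = -u[idx, cc]
                e2 = u[idx + 1, cc]
                gA = (e2 - cth[idx] * e1) / dlen[idx]
                gC = (e1 - cth[idx] * e2) / dlen[idx + 1]
                grad[idx, cc] += dEdc * gA
                grad[idx + 2, cc] += dEdc * gC
                grad[idx + 1, cc] -= dEdc * (gA + gC)

    # ------------------------------------------------------------------
    # nonbonded pair terms
    # ------------------------------------------------------------------
    d_polgb = 1.0 / eps_out - 1.0 / eps_in     # < 0: stabilizing for like charges
    d_pol = 1.0 / eps_in - 1.0 / eps_out       # > 0
    sig_ci = 2.0 * sig_iso
    sig_ct0 = 2.0 * sig_ctail

    for i in range(n_site):
        for j in range(i + NB_EXCLUSION, n_site):
            qi = charges[i]
            qj = charges[j]

            # ---- tail-tail geometry (anisotropic frame) ----
            rtx = tail[j, 0] - tail[i, 0]
            rty = tail[j, 1] - tail[i, 1]
            rtz = tail[j, 2] - tail[i, 2]
            r_tt = math.sqrt(rtx * rtx + rty * rty + rtz * rtz)
            rhx = rtx / r_tt
            rhy = rty / r_tt
            rhz = rtz / r_tt
            a = u[i, 0] * u[j, 0] + u[i, 1] * u[j, 1] + u[i, 2] * u[j, 2]
            bi = rhx * u[i, 0] + rhy * u[i, 1] + rhz * u[i, 2]
            bj = rhx * u[j, 0] + rhy * u[j, 1] + rhz * u[j, 2]

            # ---- Gay-Berne tails ----
            E, dEdr, dEda, dEdbi, dEdbj = _gay_berne(
                r_tt, a, bi, bj, sig0_t, eps_t, chi_gb, chip_gb
            )
            eterms[3] += E
            w = wf[3]
            for cc in range(3):
                rh = rhx if cc == 0 else (rhy if cc == 1 else rhz)
                gv = (
                    dEdr * rh
                    + dEdbi * (u[i, cc] - bi * rh) / r_tt
                    + dEdbj * (u[j, cc] - bj * rh) / r_tt
                )
                g_tail[j, cc] += w * gv
                g_tail[i, cc] -= w * gv
                g_u[i, cc] += w * (dEda * u[j, cc] + dEdbi * rh)
                g_u[j, cc] += w * (dEda * u[i, cc] + dEdbj * rh)

            # ---- anisotropic tail cavity ----
            sigc, dsda, dsdbi, dsdbj = _aniso_contact(sig_ct0, chi_c1, chi_c2, a, bi, bj)
            E, dEdr, dEdsig = _cavity(r_tt, sigc, eps_ct)
            eterms[7] += E
            w = wf[7]
            for cc in range(3):
                rh = rhx if cc == 0 else (rhy if cc == 1 else rhz)
                gv = (
                    dEdr * rh
                    + dEdsig * dsdbi * (u[i, cc] - bi * rh) / r_tt
                    + dEdsig * dsdbj * (u[j, cc] - bj * rh) / r_tt
                )
                g_tail[j, cc] += w * gv
                g_tail[i, cc] -= w * gv
                g_u[i, cc] += w * dEdsig * (dsda * u[j, cc] + dsdbi * rh)
                g_u[j, cc] += w * dEdsig * (dsda * u[i, cc] + dsdbj * rh)

            # ---- head-head geometry ----
            rhhx = head[j, 0] - head[i, 0]
            rhhy = head[j, 1] - head[i, 1]
            rhhz = head[j, 2] - head[i, 2]
            r_hh = math.sqrt(rhhx * rhhx + rhhy * rhhy + rhhz * rhhz)

            # ---- GB polarization (heads) ----
            ab = born[i] * born[j]
            f, dfdr = _f_gb(r_hh, ab)
            scr = math.exp(-kap_polgb * r_hh)
            E = C_ELEC * d_polgb * qi * qj * scr / f
            dEdr = C_ELEC * d_polgb * qi * qj * scr * (-kap_polgb / f - dfdr / (f * f))
            eterms[4] += E
            gfac = wf[4] * dEdr / r_hh
            g_head[j, 0] += gfac * rhhx
            g_head[j, 1] += gfac * rhhy
            g_head[j, 2] += gfac * rhhz
            g_head[i, 0] -= gfac * rhhx
            g_head[i, 1] -= gfac * rhhy
            g_head[i, 2] -= gfac * rhhz

            # ---- isotropic head cavity ----
            E, dEdr, _ = _cavity(r_hh, sig_ci, eps_ci)
            eterms[6] += E
            gfac = wf[6] * dEdr / r_hh
            g_head[j, 0] += gfac * rhhx
            g_head[j, 1] += gfac * rhhy
            g_head[j, 2] += gfac * rhhz
            g_head[i, 0] -= gfac * rhhx
            g_head[i, 1] -= gfac * rhhy
            g_head[i, 2] -= gfac * rhhz

            # ---- LJ heads ----
            sr6 = (sig_h / r_hh) ** 6
            E = 4.0 * eps_h * (sr6 * sr6 - sr6)
            dEdr = 4.0 * eps_h * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r_hh
            eterms[8] += E
            gfac = wf[8] * dEdr / r_hh
            g_head[j, 0] += gfac * rhhx
            g_head[j, 1] += gfac * rhhy
            g_head[j, 2] += gfac * rhhz
            g_head[i, 0] -= gfac * rhhx
            g_head[i, 1] -= gfac * rhhy
            g_head[i, 2] -= gfac * rhhz

            # ---- screened Coulomb (heads) ----
            scr = math.exp(-kap_eel * r_hh)
            E = C_ELEC * qi * qj * scr / (eel_eps * r_hh)
            dEdr = -E * (kap_eel + 1.0 / r_hh)
            eterms[9] += E
            gfac = wf[9] * dEdr / r_hh
            g_head[j, 0] += gfac * rhhx
            g_head[j, 1] += gfac * rhhy
            g_head[j, 2] += gfac * rhhz
            g_head[i, 0] -= gfac * rhhx
            g_head[i, 1] -= gfac * rhhy
            g_head[i, 2] -= gfac * rhhz

            # ---- head-tail polarization (two screened charge/induced-dipole
            #      cross terms: head_i->tail_j and head_j->tail_i) ----
            w = wf[5]
            # head i - tail j  (r''_ij), tail j has solvation factor alpha2
            r1x = tail[j, 0] - head[i, 0]
            r1y = tail[j, 1] - head[i, 1]
            r1z = tail[j, 2] - head[i, 2]
            r1 = math.sqrt(r1x * r1x + r1y * r1y + r1z * r1z)
            scr = math.exp(-2.0 * kap_pol * r1)
            r1_4 = r1 ** 4
            E = -C_ELEC * d_pol * alpha2 * qi * qi * scr / r1_4
            dEdr = -E * (2.0 * kap_pol + 4.0 / r1)
            eterms[5] += E
            gfac = w * dEdr / r1
            g_tail[j, 0] += gfac * r1x
            g_tail[j, 1] += gfac * r1y
            g_tail[j, 2] += gfac * r1z
            g_head[i, 0] -= gfac * r1x
            g_head[i, 1] -= gfac * r1y
            g_head[i, 2] -= gfac * r1z
            # tail i - head j  (r''_ji), tail i has solvation factor alpha1
            r2x = head[j, 0] - tail[i, 0]
            r2y = head[j, 1] - tail[i, 1]
            r2z = head[j, 2] - tail[i, 2]
            r2 = math.sqrt(r2x * r2x + r2y * r2y + r2z * r2z)
            scr = math.exp(-2.0 * kap_pol * r2)
            r2_4 = r2 ** 4
            E = -C_ELEC * d_pol * alpha1 * qj * qj * scr / r2_4
            dEdr = -E * (2.0 * kap_pol + 4.0 / r2)
            eterms[5] += E
            gfac = w * dEdr / r2
            g_head[j, 0] += gfac * r2x
            g_head[j, 1] += gfac * r2y
            g_head[j, 2] += gfac * r2z
            g_tail[i, 0] -= gfac * r2x
            g_tail[i, 1] -= gfac * r2y
            g_tail[i, 2] -= gfac * r2z

    # ------------------------------------------------------------------
    # propagate head/tail/orientation gradients to the anchors
    # ------------------------------------------------------------------
    for k in range(n_site):
        d = dlen[k]
        for src in range(2):
            off = h_off if src == 0 else t_off
            gp = g_head if src == 0 else g_tail
            gu_dot = gp[k, 0] * u[k, 0] + gp[k, 1] * u[k, 1] + gp[k, 2] * u[k, 2]
            for cc in range(3):
                perp = gp[k, cc] - gu_dot * u[k, cc]
                grad[k, cc] += 0.5 * gp[k, cc] - (off / d) * perp
                grad[k + 1, cc] += 0.5 * gp[k, cc] + (off / d) * perp
        gu_dot = g_u[k, 0] * u[k, 0] + g_u[k, 1] * u[k, 1] + g_u[k, 2] * u[k, 2]
        for cc in range(3):
            perp = (g_u[k, cc] - gu_dot * u[k, cc]) / d
            grad[k + 1, cc] += perp
            grad[k, cc] -= perp


@njit(cache=True)
def weighted_total(eterms, wf):
    tot = 0.0
    for k in range(N_TERMS):
        tot += wf[k] * eterms[k]
    return tot


@njit(cache=True)
def integrate(
    anchors,
    vel,
    masses,
    charges,
    born,
    P,
    wf,
    dt,
    gamma_fs,
    kT,
    n_steps,
    stride,
    seed,
    remove_com,
):
    """BAOAB Langevin integration of the anchor chain.

    Returns ``(frames, epot, ekin, fail_step)``; ``fail_step`` is -1 on
    success, otherwise the step at which coordinates/energies turned
    non-finite (frames up to the previous snapshot stay valid).

    With ``gamma_fs == 0`` the O-step is the identity and the scheme reduces
    to symplectic velocity-Verlet (no noise).
    """
    np.random.seed(seed)
    n = anchors.shape[0]
    x = anchors.copy()
    v = vel.copy()
    n_frames = n_steps // stride + 1
    frames = np.empty((n_frames, n, 3))
    epot = np.empty(n_frames)
    ekin = np.empty(n_frames)

    eterms = np.empty(N_TERMS)
    grad = np.empty((n, 3))

    if gamma_fs > 0.0:
        c1 = math.exp(-gamma_fs * dt)
        c2 = math.sqrt(1.0 - c1 * c1)
    else:
        c1 = 1.0
        c2 = 0.0

    energy_forces(x, charges, born, P, wf, eterms, grad)
    frames[0] = x
    epot[0] = weighted_total(eterms, wf)
    ke = 0.0
    for p in range(n):
        for cc in range(3):
            ke += masses[p] * v[p, cc] * v[p, cc]
    ekin[0] = 0.5 * ke / FCONV

    fail_step = -1
    idx = 1
    for step in range(1, n_steps + 1):
        # B (half kick)
        for p in range(n):
            fac = 0.5 * dt * FCONV / masses[p]
            for cc in range(3):
                v[p, cc] -= fac * grad[p, cc]
        # A (half drift)
        for p in range(n):
            for cc in range(3):
                x[p, cc] += 0.5 * dt * v[p, cc]
        # O (thermostat)
        if gamma_fs > 0.0:
            for p in range(n):
                vs = math.sqrt(kT * FCONV / masses[p])
                for cc in range(3):
                    v[p, cc] = c1 * v[p, cc] + c2 * vs * np.random.standard_normal()
        # A (half drift)
        for p in range(n):
            for cc in range(3):
                x[p, cc] += 0.5 * dt * v[p, cc]
        # force update + B (half kick)
        energy_forces(x, charges, born, P, wf, eterms, grad)
        ok = True
        for p in range(n):
            for cc in range(3):
                if not math.isfinite(grad[p, cc]) or not math.isfinite(x[p, cc]):
                    ok = False
        if not ok:
            fail_step = step
            break
        for p in range(n):
            fac = 0.5 * dt * FCONV / masses[p]
            for cc in range(3):
                v[p, cc] -= fac * grad[p, cc]

        if step % stride == 0:
            if remove_com:
                mtot = 0.0
                vcx = 0.0
                vcy = 0.0
                vcz = 0.0
                for p in range(n):
                    mtot += masses[p]
                    vcx += masses[p] * v[p, 0]
                    vcy += masses[p] * v[p, 1]
                    vcz += masses[p] * v[p, 2]
                vcx /= mtot
                vcy /= mtot
                vcz /= mtot
                for p in range(n):
                    v[p, 0] -= vcx
                    v[p, 1] -= vcy
                    v[p, 2] -= vcz
            frames[idx] = x
            epot[idx] = weighted_total(eterms, wf)
            ke = 0.0
            for p in range(n):
                for cc in range(3):
                    ke += masses[p] * v[p, cc] * v[p, cc]
            ekin[idx] = 0.5 * ke / FCONV
            idx += 1

    if fail_step >= 0:
        # truncate outputs to completed snapshots
        frames = frames[:idx]
        epot = epot[:idx]
        ekin = ekin[:idx]
    return frames, epot, ekin, fail_step
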