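"""Numba-compiled numerical core.

Everything here operates on packed plain arrays; the public modules
(:mod:`mmnathist.cohort`, :mod:`mmnathist.likelihood`,
:mod:`mmnathist.inference`, :mod:`mmnathist.montecarlo`) own the
user-facing types and build these arrays.

Grid conventions
----------------
The age grid runs from ``age_start`` to ``age_end`` with step ``dt``
where ``1/dt`` is an integer (``spy`` steps per year), so every step
lies inside a single integer-age year. Smooth hazards (the two
transition rates) are sampled on the *half grid* (spacing ``dt/2``,
``2*n_steps + 1`` points) so RK4 stages have exact midpoint values.
Background mortality is piecewise constant on integer-age years and is
passed *per step* (length ``n_steps``), which keeps each RK4 step inside
a region where the right-hand side is smooth.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Reject parameter vectors whose hazard exponent exceeds this anywhere
#: on the grid: rates above e^3 ~ 20 /yr are epidemiologically absurd
#: and would destabilize the fixed-step integrator.
HAZ_EXP_CAP = 3.0

NEG_INF = -np.inf


@njit(cache=True, inline="always")
def _deriv(ph, pg, pm, pd, l1, l2, mh, mg, mum):
    dh = -(l1 + mh) * ph
    dg = l1 * ph - (l2 + mg) * pg
    dm = l2 * pg - mum * pm
    dd = mh * ph + mg * pg + mum * pm
    return dh, dg, dm, dd


@njit(cache=True)
def rk4_cohort(lam1_half, s1, lam2_half, s2, mu_h_step, mu_g_step, mu_mm,
               n_steps, dt, init, out):
    """Fixed-step RK4 of the four-state cohort ODE.

    lam1_half/lam2_half: hazards on the half grid (2*n_steps+1), each
    multiplied by the scalar stratum factor s1/s2. mu_h_step/mu_g_step:
    per-step (piecewise-constant) mortality. out: (n_steps+1, 4).
    """
    ph = init[0]
    pg = init[1]
    pm = init[2]
    pd = init[3]
    out[0, 0] = ph
    out[0, 1] = pg
    out[0, 2] = pm
    out[0, 3] = pd
    for i in range(n_steps):
        j = 2 * i
        l1a = lam1_half[j] * s1
        l2a = lam2_half[j] * s2
        l1b = lam1_half[j + 1] * s1
        l2b = lam2_half[j + 1] * s2
        l1c = lam1_half[j + 2] * s1
        l2c = lam2_half[j + 2] * s2
        mh = mu_h_step[i]
        mg = mu_g_step[i]

        k1h, k1g, k1m, k1d = _deriv(ph, pg, pm, pd, l1a, l2a, mh, mg, mu_mm)
        h2 = 0.5 * dt
        k2h, k2g, k2m, k2d = _deriv(ph + h2 * k1h, pg + h2 * k1g, pm + h2 * k1m,
                                    pd + h2 * k1d, l1b, l2b, mh, mg, mu_mm)
        k3h, k3g, k3m, k3d = _deriv(ph + h2 * k2h, pg + h2 * k2g, pm + h2 * k2m,
                                    pd + h2 * k2d, l1b, l2b, mh, mg, mu_mm)
        k4h, k4g, k4m, k4d = _deriv(ph + dt * k3h, pg + dt * k3g, pm + dt * k3m,
                                    pd + dt * k3d, l1c, l2c, mh, mg, mu_mm)
        w = dt / 6.0
        ph += w * (k1h + 2.0 * k2h + 2.0 * k3h + k4h)
        pg += w * (k1g + 2.0 * k2g + 2.0 * k3g + k4g)
        pm += w * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
        pd += w * (k1d + 2.0 * k2d + 2.0 * k3d + k4d)
        out[i + 1, 0] = ph
        out[i + 1, 1] = pg
        out[i + 1, 2] = pm
        out[i + 1, 3] = pd


@njit(cache=True)
def model_eval(theta, lo, hi, logprior_const,
               ages_half, ages2_half,
               mu_h_step, mu_g_step, mu_mm,
               fem, nhb, spy, n_years, dt,
               pv_str, pv_y, pv_n, Wp,
               iv_str, iv_logx, Wi,
               pbar_out, ibar_out):
    """Log-posterior and log-likelihood of one parameter vector.

    Also fills pbar_out (per prevalence row, weighted model prevalence)
    and ibar_out (per incidence row, weighted model incidence per
    person-year). Returns (log_posterior, log_likelihood); out-of-prior
    or numerically inadmissible parameters give (-inf, -inf).
    """
    npar = theta.shape[0]
    for p in range(npar):
        if theta[p] < lo[p] or theta[p] > hi[p]:
            return NEG_INF, NEG_INF
    tau2 = theta[9]
    if tau2 <= 0.0:
        return NEG_INF, NEG_INF
    g1 = theta[0]
    b1a = theta[1]
    b1s = theta[2]
    b1r = theta[3]
    g2 = theta[4]
    b2a = theta[5]
    b2a2 = theta[6]
    b2s = theta[7]
    b2r = theta[8]

    n_steps = n_years * spy
    a_lo = ages_half[0]
    a_hi = ages_half[2 * n_steps]

    # hazard-exponent cap (see HAZ_EXP_CAP)
    m1 = max(g1 + b1a * a_lo, g1 + b1a * a_hi) + max(0.0, b1s) + max(0.0, b1r)
    m2 = max(g2 + b2a * a_lo + b2a2 * a_lo * a_lo,
             g2 + b2a * a_hi + b2a2 * a_hi * a_hi)
    if b2a2 < 0.0:
        av = -b2a / (2.0 * b2a2)
        if a_lo < av < a_hi:
            m2 = max(m2, g2 + b2a * av + b2a2 * av * av)
    m2 += max(0.0, b2s) + max(0.0, b2r)
    if m1 > HAZ_EXP_CAP or m2 > HAZ_EXP_CAP:
        return NEG_INF, NEG_INF

    lam1_base = np.exp(g1 + b1a * ages_half)
    lam2_base = np.exp(g2 + b2a * ages_half + b2a2 * ages2_half)

    n_int = n_years + 1
    pG = np.empty((4, n_int))
    iM = np.empty((4, n_int))
    traj = np.empty((n_steps + 1, 4))
    init = np.zeros(4)
    init[0] = 1.0
    for st in range(4):
        s1 = np.exp(b1s * fem[st] + b1r * nhb[st])
        s2 = np.exp(b2s * fem[st] + b2r * nhb[st])
        rk4_cohort(lam1_base, s1, lam2_base, s2,
                   mu_h_step[st], mu_g_step[st], mu_mm[st],
                   n_steps, dt, init, traj)
        for a in range(n_int):
            row = a * spy
            alive = 1.0 - traj[row, 3]
            if alive <= 1e-12:
                return NEG_INF, NEG_INF
            pg = traj[row, 1] / alive
            pG[st, a] = pg
            iM[st, a] = lam2_base[2 * row] * s2 * pg

    ll_prev = 0.0
    for r in range(pv_str.shape[0]):
        st = pv_str[r]
        pbar = 0.0
        for a in range(n_int):
            w = Wp[r, a]
            if w > 0.0:
                pbar += w * pG[st, a]
        pbar_out[r] = pbar
        y = pv_y[r]
        n = pv_n[r]
        if pbar <= 0.0:
            if y > 0.0:
                return NEG_INF, NEG_INF
        elif pbar >= 1.0:
            if y < n:
                return NEG_INF, NEG_INF
        else:
            ll_prev += y * np.log(pbar) + (n - y) * np.log1p(-pbar)

    ll_inc = 0.0
    c = -0.5 * np.log(2.0 * np.pi * tau2)
    for r in range(iv_str.shape[0]):
        st = iv_str[r]
        ibar = 0.0
        for a in range(n_int):
            w = Wi[r, a]
            if w > 0.0:
                ibar += w * iM[st, a]
        ibar_out[r] = ibar
        if ibar <= 0.0:
            return NEG_INF, NEG_INF
        z = iv_logx[r] - np.log(ibar)
        ll_inc += c - z * z / (2.0 * tau2)

    ll = ll_prev + ll_inc
    return logprior_const + ll, ll


@njit(cache=True)
def metropolis_block(theta, lp_in, active, Lchol, z, logu,
                     chain_out, lp_out,
                     lo, hi, logprior_const,
                     ages_half, ages2_half,
                     mu_h_step, mu_g_step, mu_mm,
                     fem, nhb, spy, n_years, dt,
                     pv_str, pv_y, pv_n, Wp,
                     iv_str, iv_logx, Wi,
                     pbar_out, ibar_out):
    """Run one block of random-walk Metropolis steps with a fixed
    (lower-triangular Cholesky) proposal. Mutates theta in place;
    returns (final log-posterior, acceptance count)."""
    B = z.shape[0]
    d = active.shape[0]
    npar = theta.shape[0]
    prop = np.empty(npar)
    lp = lp_in
    acc = 0
    for t in range(B):
        for q in range(npar):
            prop[q] = theta[q]
        for ai in range(d):
            s = 0.0
            for bi in range(ai + 1):
                s += Lchol[ai, bi] * z[t, bi]
            prop[active[ai]] += s
        lpp, _ll = model_eval(prop, lo, hi, logprior_const,
                              ages_half, ages2_half,
                              mu_h_step, mu_g_step, mu_mm,
                              fem, nhb, spy, n_years, dt,
                              pv_str, pv_y, pv_n, Wp,
                              iv_str, iv_logx, Wi,
                              pbar_out, ibar_out)
        if lpp - lp > logu[t]:
            for q in range(npar):
                theta[q] = prop[q]
            lp = lpp
            acc += 1
        for q in range(npar):
            chain_out[t, q] = theta[q]
        lp_out[t] = lp
    return lp, acc


# ---------------------------------------------------------------------------
# Individual-based event simulator (independent Monte-Carlo oracle)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _invert_cum(cum, tgrid, target):
    """Invert a piecewise-linear non-decreasing cumulative hazard."""
    idx = np.searchsorted(cum, target)
    if idx == 0:
        return tgrid[0]
    if idx >= cum.shape[0]:
        return tgrid[-1]
    c0 = cum[idx - 1]
    c1 = cum[idx]
    t0 = tgrid[idx - 1]
    t1 = tgrid[idx]
    if c1 <= c0:
        return t0
    return t0 + (target - c0) / (c1 - c0) * (t1 - t0)


@njit(cache=True)
def simulate_individuals(seed, n_ind, tgrid, cum_h, lam1, mu_h_pt,
                         cum_g, lam2, mu_g_pt, mu_mm,
                         record_t, out_counts):
    """Simulate individual life courses by cumulative-hazard inversion.

    All individuals start healthy at tgrid[0]. cum_h / cum_g are the
    cumulative exit hazards from the healthy / MGUS states on tgrid;
    lam1, lam2, mu_h_pt, mu_g_pt are the per-point hazards used for
    destination choice. out_counts: (len(record_t), 4) occupancy counts
    (H, MGUS, MM, D) at each recorded age.
    """
    np.random.seed(seed)
    big = 1.0e30
    for _ in range(n_ind):
        t_mgus = big
        t_mm = big
        t_death = big
        e1 = -np.log(np.random.random())
        if e1 < cum_h[-1]:
            t1 = _invert_cum(cum_h, tgrid, e1)
            l1 = np.interp(t1, tgrid, lam1)
            m1 = np.interp(t1, tgrid, mu_h_pt)
            if np.random.random() < l1 / (l1 + m1):
                t_mgus = t1
            else:
                t_death = t1
        if t_mgus < big:
            base = np.interp(t_mgus, tgrid, cum_g)
            e2 = -np.log(np.random.random())
            if base + e2 < cum_g[-1]:
                t2 = _invert_cum(cum_g, tgrid, base + e2)
                l2 = np.interp(t2, tgrid, lam2)
                m2 = np.interp(t2, tgrid, mu_g_pt)
                if np.random.random() < l2 / (l2 + m2):
                    t_mm = t2
                else:
                    t_death = t2
            if t_mm < big and mu_mm > 0.0:
                t_death = t_mm - np.log(np.random.random()) / mu_mm
        for j in range(record_t.shape[0]):
            rt = record_t[j]
            if t_death <= rt:
                out_counts[j, 3] += 1
            elif t_mm <= rt:
                out_counts[j, 2] += 1
            elif t_mgus <= rt:
                out_counts[j, 1] += 1
            else:
                out_counts[j, 0] += 1


@njit(cache=True)
def simulate_dwell(seed, n_ind, tgrid, cum_g, lam2, mu_g_pt):
    """Simulate MGUS sub-cohorts entering at tgrid[0].

    Returns (n_mm, sum_dwell, sum_dwell_sq) over individuals who
    progress to MM before dying or reaching the end of the grid; dwell
    is measured from tgrid[0].
    """
    np.random.seed(seed)
    n_mm = 0
    s = 0.0
    s2 = 0.0
    for _ in range(n_ind):
        e = -np.log(np.random.random())
        if e >= cum_g[-1]:
            continue
        t = _invert_cum(cum_g, tgrid, e)
        l2 = np.interp(t, tgrid, lam2)
        m2 = np.interp(t, tgrid, mu_g_pt)
        if np.random.random() < l2 / (l2 + m2):
            n_mm += 1
            dw = t - tgrid[0]
            s += dw
            s2 += dw * dw
    return n_mm, s, s2
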