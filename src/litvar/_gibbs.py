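"""Numba kernels for the single-site Gibbs samplers of the animal models.

All location effects (fixed levels, permanent environmental effects,
breeding values) are updated one at a time from their normal full
conditionals, maintaining a running residual vector; variance components are
drawn from their scaled inverse-chi-square (or, for the bivariate genetic
covariance matrix, inverse-Wishart) full conditionals under unbounded flat
priors. Residual variances are floored at 1e-8.

Record-to-effect incidences are passed as CSR-style (indptr, indices)
arrays prepared by :mod:`litvar.animal`.
"""

import numpy as np
from numba import njit

SIGMA2_FLOOR = 1e-8


@njit(cache=True)
def _draw_invchi2(scale_sum, df):
    # flat prior on the variance: p(s2 | data) ~ scaled-inv-chi2(df, scale)
    if df < 1:
        df = 1
    return max(scale_sum / np.random.chisquare(df), SIGMA2_FLOOR)


@njit(cache=True)
def _quad_form_ainv(indptr, indices, data, u):
    s = 0.0
    n = indptr.size - 1
    for i in range(n):
        row = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            row += data[k] * u[indices[k]]
        s += u[i] * row
    return s


@njit(cache=True)
def _scale_move(e, w, s2e, u, effect_of_rec, jac_power, tau):
    """Joint Metropolis scaling of a random-effect vector and its variance.

    Proposes u' = c u together with the matching rescaling of the effect's
    (co)variance (performed by the caller with the returned c); the prior
    quadratic form is then invariant, so the acceptance ratio is the
    residual-likelihood ratio times c^jac_power (determinant and Jacobian
    terms: 2 for a scalar variance, 3 for one column of a 2x2 covariance).
    Cures the slow random walk of (u, sigma_u^2) at low heritability.
    Returns the accepted scale c, or 1.0 on rejection.
    """
    c = np.exp(tau * np.random.normal())
    d_old = 0.0
    d_new = 0.0
    for r in range(e.size):
        a = effect_of_rec[r]
        if a < 0:
            continue
        en = e[r] + (1.0 - c) * u[a]
        d_old += w[r] * e[r] * e[r]
        d_new += w[r] * en * en
    log_acc = -0.5 * (d_new - d_old) / s2e + jac_power * np.log(c)
    if np.log(np.random.random()) < log_acc:
        for r in range(e.size):
            a = effect_of_rec[r]
            if a >= 0:
                e[r] += (1.0 - c) * u[a]
        for a in range(u.size):
            u[a] *= c
        return c
    return 1.0


@njit(cache=True)
def univariate_chain(
    y, w,
    lev_indptr, lev_recs, n_fix,
    perm_indptr, perm_recs, n_perm, use_perm, perm_of_rec,
    arec_indptr, arec_recs, anim_of_rec,
    ai_indptr, ai_indices, ai_data, ai_diag, q, use_additive,
    group_idx, n_groups,
    iterations, burn_in, thin, seed,
    s2u0, s2p0, s2e0,
):
    np.random.seed(seed)
    n = y.size
    beta = np.zeros(n_fix)
    perm = np.zeros(n_perm)
    u = np.zeros(q)
    s2u, s2p, s2e = s2u0, s2p0, s2e0
    e = y.copy()

    keep = (iterations - burn_in) // thin
    beta_out = np.zeros((keep, n_fix))
    var_out = np.zeros((keep, 3))  # s2u, s2p, s2e
    grp_out = np.zeros((keep, n_groups))
    grp_size = np.zeros(n_groups)
    for a in range(q):
        if group_idx[a] >= 0:
            grp_size[group_idx[a]] += 1.0

    k_out = 0
    for it in range(iterations):
        # fixed levels
        for l in range(n_fix):
            sw = 0.0
            swr = 0.0
            for kk in range(lev_indptr[l], lev_indptr[l + 1]):
                r = lev_recs[kk]
                sw += w[r]
                swr += w[r] * (e[r] + beta[l])
            prec = sw / s2e
            mean = (swr / s2e) / prec
            new = mean + np.random.normal() / np.sqrt(prec)
            delta = new - beta[l]
            for kk in range(lev_indptr[l], lev_indptr[l + 1]):
                e[lev_recs[kk]] -= delta
            beta[l] = new

        # permanent environmental effects
        if use_perm:
            for d in range(n_perm):
                sw = 0.0
                swr = 0.0
                for kk in range(perm_indptr[d], perm_indptr[d + 1]):
                    r = perm_recs[kk]
                    sw += w[r]
                    swr += w[r] * (e[r] + perm[d])
                prec = sw / s2e + 1.0 / s2p
                mean = (swr / s2e) / prec
                new = mean + np.random.normal() / np.sqrt(prec)
                delta = new - perm[d]
                for kk in range(perm_indptr[d], perm_indptr[d + 1]):
                    e[perm_recs[kk]] -= delta
                perm[d] = new
            c = _scale_move(e, w, s2e, perm, perm_of_rec, 2.0, 0.3)
            s2p *= c * c
            sp = 0.0
            for d in range(n_perm):
                sp += perm[d] * perm[d]
            s2p = _draw_invchi2(sp, n_perm - 2)

        # breeding values
        if use_additive:
            for a in range(q):
                dot = 0.0
                for kk in range(ai_indptr[a], ai_indptr[a + 1]):
                    j = ai_indices[kk]
                    if j != a:
                        dot += ai_data[kk] * u[j]
                sw = 0.0
                swr = 0.0
                for kk in range(arec_indptr[a], arec_indptr[a + 1]):
                    r = arec_recs[kk]
                    sw += w[r]
                    swr += w[r] * (e[r] + u[a])
                prec = sw / s2e + ai_diag[a] / s2u
                mean = (swr / s2e - dot / s2u) / prec
                new = mean + np.random.normal() / np.sqrt(prec)
                delta = new - u[a]
                for kk in range(arec_indptr[a], arec_indptr[a + 1]):
                    e[arec_recs[kk]] -= delta
                u[a] = new
            c = _scale_move(e, w, s2e, u, anim_of_rec, 2.0, 0.3)
            s2u *= c * c
            squ = _quad_form_ainv(ai_indptr, ai_indices, ai_data, u)
            s2u = _draw_invchi2(squ, q - 2)

        # residual variance
        se = 0.0
        for r in range(n):
            se += w[r] * e[r] * e[r]
        s2e = _draw_invchi2(se, n - 2)

        if it >= burn_in and (it - burn_in) % thin == 0 and k_out < keep:
            for l in range(n_fix):
                beta_out[k_out, l] = beta[l]
            var_out[k_out, 0] = s2u
            var_out[k_out, 1] = s2p
            var_out[k_out, 2] = s2e
            for a in range(q):
                gidx = group_idx[a]
                if gidx >= 0:
                    grp_out[k_out, gidx] += u[a]
            for gdx in range(n_groups):
                if grp_size[gdx] > 0:
                    grp_out[k_out, gdx] /= grp_size[gdx]
            k_out += 1

    return beta_out, var_out, grp_out


@njit(cache=True)
def _chol2(a11, a12, a22):
    l11 = np.sqrt(a11)
    l21 = a12 / l11
    l22 = np.sqrt(max(a22 - l21 * l21, 1e-12))
    return l11, l21, l22


@njit(cache=True)
def _inv2(a11, a12, a22):
    det = a11 * a22 - a12 * a12
    if det < 1e-12:
        det = 1e-12
    return a22 / det, -a12 / det, a11 / det


@njit(cache=True)
def _draw_invwishart2(s11, s12, s22, df):
    """G ~ IW(df, S) for a 2x2 scale matrix via Bartlett on W = G^-1."""
    p11, p12, p22 = _inv2(s11, s12, s22)
    l11, l21, l22 = _chol2(p11, p12, p22)
    c11 = np.sqrt(np.random.chisquare(df))
    c21 = np.random.normal()
    c22 = np.sqrt(np.random.chisquare(df - 1))
    # B = L @ C ; W = B @ B.T
    b11 = l11 * c11
    b21 = l21 * c11 + l22 * c21
    b22 = l22 * c22
    w11 = b11 * b11
    w12 = b11 * b21
    w22 = b21 * b21 + b22 * b22
    g11, g12, g22 = _inv2(w11, w12, w22)
    return g11, g12, g22


@njit(cache=True)
def bivariate_chain(
    # trait 1: one variance record per doe, heteroscedastic weights
    y1, w1, lev1_indptr, lev1_recs, n_fix1, a1rec_indptr, a1rec_recs, a1_of_rec,
    # trait 2: repeated litter-size records, permanent effect
    y2, lev2_indptr, lev2_recs, n_fix2,
    perm_indptr, perm_recs, n_perm, perm_of_rec,
    a2rec_indptr, a2rec_recs, a2_of_rec,
    # pedigree
    ai_indptr, ai_indices, ai_data, ai_diag, q,
    iterations, burn_in, thin, seed,
    g11_0, g22_0, s2e1_0, s2e2_0, s2p0,
):
    np.random.seed(seed)
    n1 = y1.size
    n2 = y2.size
    w2 = np.ones(n2)
    beta1 = np.zeros(n_fix1)
    beta2 = np.zeros(n_fix2)
    perm = np.zeros(n_perm)
    u1 = np.zeros(q)
    u2 = np.zeros(q)
    g11, g12, g22 = g11_0, 0.0, g22_0
    s2e1, s2e2, s2p = s2e1_0, s2e2_0, s2p0
    e1 = y1.copy()
    e2 = y2.copy()

    keep = (iterations - burn_in) // thin
    out = np.zeros((keep, 6))  # g11, g12, g22, s2e1, s2e2, s2p
    k_out = 0

    for it in range(iterations):
        # fixed effects, trait 1
        for l in range(n_fix1):
            sw = 0.0
            swr = 0.0
            for kk in range(lev1_indptr[l], lev1_indptr[l + 1]):
                r = lev1_recs[kk]
                sw += w1[r]
                swr += w1[r] * (e1[r] + beta1[l])
            prec = sw / s2e1
            new = (swr / s2e1) / prec + np.random.normal() / np.sqrt(prec)
            delta = new - beta1[l]
            for kk in range(lev1_indptr[l], lev1_indptr[l + 1]):
                e1[lev1_recs[kk]] -= delta
            beta1[l] = new
        # fixed effects, trait 2
        for l in range(n_fix2):
            sw = 0.0
            swr = 0.0
            for kk in range(lev2_indptr[l], lev2_indptr[l + 1]):
                r = lev2_recs[kk]
                sw += 1.0
                swr += e2[r] + beta2[l]
            prec = sw / s2e2
            new = (swr / s2e2) / prec + np.random.normal() / np.sqrt(prec)
            delta = new - beta2[l]
            for kk in range(lev2_indptr[l], lev2_indptr[l + 1]):
                e2[lev2_recs[kk]] -= delta
            beta2[l] = new
        # permanent effects, trait 2
        for d in range(n_perm):
            sw = 0.0
            swr = 0.0
            for kk in range(perm_indptr[d], perm_indptr[d + 1]):
                r = perm_recs[kk]
                sw += 1.0
                swr += e2[r] + perm[d]
            prec = sw / s2e2 + 1.0 / s2p
            new = (swr / s2e2) / prec + np.random.normal() / np.sqrt(prec)
            delta = new - perm[d]
            for kk in range(perm_indptr[d], perm_indptr[d + 1]):
                e2[perm_recs[kk]] -= delta
            perm[d] = new
        c = _scale_move(e2, w2, s2e2, perm, perm_of_rec, 2.0, 0.3)
        s2p *= c * c
        sp = 0.0
        for d in range(n_perm):
            sp += perm[d] * perm[d]
        s2p = _draw_invchi2(sp, n_perm - 2)

        # bivariate breeding values
        q11, q12, q22 = _inv2(g11, g12, g22)  # G^-1
        for a in range(q):
            dot1 = 0.0
            dot2 = 0.0
            for kk in range(ai_indptr[a], ai_indptr[a + 1]):
                j = ai_indices[kk]
                if j != a:
                    dot1 += ai_data[kk] * u1[j]
                    dot2 += ai_data[kk] * u2[j]
            sw1 = 0.0
            swr1 = 0.0
            for kk in range(a1rec_indptr[a], a1rec_indptr[a + 1]):
                r = a1rec_recs[kk]
                sw1 += w1[r]
                swr1 += w1[r] * (e1[r] + u1[a])
            sw2 = 0.0
            swr2 = 0.0
            for kk in range(a2rec_indptr[a], a2rec_indptr[a + 1]):
                r = a2rec_recs[kk]
                sw2 += 1.0
                swr2 += e2[r] + u2[a]
            aii = ai_diag[a]
            p11 = sw1 / s2e1 + aii * q11
            p12 = aii * q12
            p22 = sw2 / s2e2 + aii * q22
            r1 = swr1 / s2e1 - (q11 * dot1 + q12 * dot2)
            r2 = swr2 / s2e2 - (q12 * dot1 + q22 * dot2)
            # mean = P^-1 rhs ; draw via chol of P
            i11, i12, i22 = _inv2(p11, p12, p22)
            m1 = i11 * r1 + i12 * r2
            m2 = i12 * r1 + i22 * r2
            l11, l21, l22 = _chol2(p11, p12, p22)
            z1 = np.random.normal()
            z2 = np.random.normal()
            # solve L^T x = z
            x2 = z2 / l22
            x1 = (z1 - l21 * x2) / l11
            new1 = m1 + x1
            new2 = m2 + x2
            d1 = new1 - u1[a]
            d2 = new2 - u2[a]
            for kk in range(a1rec_indptr[a], a1rec_indptr[a + 1]):
                e1[a1rec_recs[kk]] -= d1
            for kk in range(a2rec_indptr[a], a2rec_indptr[a + 1]):
                e2[a2rec_recs[kk]] -= d2
            u1[a] = new1
            u2[a] = new2

        # scaling moves on each trait's breeding-value column
        c = _scale_move(e1, w1, s2e1, u1, a1_of_rec, 3.0, 0.3)
        g11 *= c * c
        g12 *= c
        c = _scale_move(e2, w2, s2e2, u2, a2_of_rec, 3.0, 0.3)
        g22 *= c * c
        g12 *= c

        # genetic covariance matrix
        s11 = _quad_form_ainv(ai_indptr, ai_indices, ai_data, u1)
        s22 = _quad_form_ainv(ai_indptr, ai_indices, ai_data, u2)
        s12 = 0.0
        for i in range(q):
            row = 0.0
            for kk in range(ai_indptr[i], ai_indptr[i + 1]):
                row += ai_data[kk] * u2[ai_indices[kk]]
            s12 += u1[i] * row
        df = q - 3
        if df < 3:
            df = 3
        g11, g12, g22 = _draw_invwishart2(s11, s12, s22, df)
        if g11 < SIGMA2_FLOOR:
            g11 = SIGMA2_FLOOR
        if g22 < SIGMA2_FLOOR:
            g22 = SIGMA2_FLOOR

        # residual variances
        se1 = 0.0
        for r in range(n1):
            se1 += w1[r] * e1[r] * e1[r]
        s2e1 = _draw_invchi2(se1, n1 - 2)
        se2 = 0.0
        for r in range(n2):
            se2 += e2[r] * e2[r]
        s2e2 = _draw_invchi2(se2, n2 - 2)

        if it >= burn_in and (it - burn_in) % thin == 0 and k_out < keep:
            out[k_out, 0] = g11
            out[k_out, 1] = g12
            out[k_out, 2] = g22
            out[k_out, 3] = s2e1
            out[k_out, 4] = s2e2
            out[k_out, 5] = s2p
            k_out += 1

    return out
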