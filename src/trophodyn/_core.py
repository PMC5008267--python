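"""Numerical core: jitted right-hand side and adaptive Runge-Kutta stepper.

The model is packed into flat arrays (CSR-style link lists) so the hot loop is
free of Python objects.  The stepper is a Dormand-Prince 5(4) pair with
standard proportional step control, a step-size cap (default one day) so that
extinction thresholds are monitored at least daily, and first-same-as-last
reuse of the final stage.  Living nodes whose stock falls below the extinction
threshold are zeroed and masked out of every interaction term in place;
detrital stocks are floored at zero but never go extinct.
"""

import numpy as np
from numba import njit

# Dormand-Prince 5(4) tableau
_C2, _C3, _C4, _C5 = 1 / 5, 3 / 10, 4 / 5, 8 / 9
_A21 = 1 / 5
_A31, _A32 = 3 / 40, 9 / 40
_A41, _A42, _A43 = 44 / 45, -56 / 15, 32 / 9
_A51, _A52, _A53, _A54 = 19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729
_A61, _A62, _A63, _A64, _A65 = 9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656
_A71, _A73, _A74, _A75, _A76 = 35 / 384, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84
# error coefficients: 5th-order minus 4th-order weights
_E1, _E3, _E4, _E5, _E6, _E7 = (35 / 384 - 5179 / 57600, 500 / 1113 - 7571 / 16695,
                                125 / 192 - 393 / 640, -2187 / 6784 + 92097 / 339200,
                                11 / 84 - 187 / 2100, -1 / 40)

STATUS_OK = 0
STATUS_STEP_UNDERFLOW = 1
STATUS_NONFINITE = 2
STATUS_STEP_BUDGET = 3

_MAX_STEPS = 2_000_000  # failsafe per window; far above any physical step count


@njit(cache=True)
def rhs(B, alive, cat, r, d, x, a, K,
        pptr, pidx, pval, cptr, cidx, cval,
        form, resptr, residx, linkval, y, Hh, q, h,
        bp, bh, loss, intake, dB):
    """Biomass derivatives of the four-category bioenergetic model.

    Work arrays ``bp``, ``bh``, ``loss``, ``intake`` and the output ``dB`` are
    caller allocated (length S).  ``form`` is 0 for the saturating response, 1
    for the linear one; ``linkval`` holds omega_ij or f_ij per feeding link.
    """
    S = B.shape[0]
    sumpro = 0.0
    for i in range(S):
        bi = B[i]
        if bi < 0.0 or not alive[i]:
            bi = 0.0
        bp[i] = bi
        loss[i] = 0.0
        intake[i] = 0.0
        dB[i] = 0.0
        if cat[i] == 0:
            sumpro += bi
    if form == 0:  # resource stocks enter as B^h; cache the powers per node
        for i in range(S):
            bh[i] = bp[i] ** h

    # trophic flows Phi_ij * B_j accumulated into per-node loss and intake
    for j in range(S):
        if not alive[j]:
            continue
        n0 = resptr[j]
        n1 = resptr[j + 1]
        if n1 == n0:
            continue
        bj = bp[j]
        if bj <= 0.0:
            continue
        if form == 0:
            s = 0.0
            for lk in range(n0, n1):
                i = residx[lk]
                if alive[i]:
                    s += linkval[lk] * bh[i]
            denom = Hh[j] * (1.0 + q[j] * bj) + s
            if denom <= 0.0:
                continue
            coef = y[j] * bj / denom
            for lk in range(n0, n1):
                i = residx[lk]
                if alive[i]:
                    fb = coef * linkval[lk] * bh[i]
                    loss[i] += fb
                    intake[j] += fb
        else:
            for lk in range(n0, n1):
                i = residx[lk]
                if alive[i]:
                    fb = linkval[lk] * bp[i] * bj
                    loss[i] += fb
                    intake[j] += fb

    for i in range(S):
        if not alive[i]:
            continue
        ci = cat[i]
        m = 0.0  # carbon routed into detritus from node i
        if ci == 0:
            dB[i] += r[i] * bp[i] * (1.0 - sumpro / K) - loss[i] - d[i] * bp[i]
            m = d[i] * bp[i]
        elif ci <= 2:
            dB[i] += a[i] * intake[i] - loss[i] - x[i] * bp[i]
            m = (1.0 - a[i]) * intake[i]
        else:
            dB[i] -= loss[i]
            for lk in range(cptr[i], cptr[i + 1]):
                k2 = cidx[lk]
                fb = cval[lk] * bp[i]
                dB[k2] += fb
                dB[i] -= fb
        if m > 0.0:
            for lk in range(pptr[i], pptr[i + 1]):
                dB[pidx[lk]] += pval[lk] * m


@njit(cache=True)
def integrate_window(B, alive, days, cat, r, d, x, a, K,
                     pptr, pidx, pval, cptr, cidx, cval,
                     form, resptr, residx, linkval, y, Hh, q, h,
                     threshold, rtol, atol, max_step,
                     ext_idx, ext_time):
    """Integrate one window of ``days`` days, handling extinctions in place.

    Modifies ``B`` and ``alive``; extinction events (node index, day within
    the window) are written to ``ext_idx`` / ``ext_time``.  Returns
    (status, n_extinctions, t_reached, n_steps).
    """
    S = B.shape[0]
    bp = np.empty(S)
    bh = np.empty(S)
    loss = np.empty(S)
    intake = np.empty(S)
    k1 = np.empty(S)
    k2 = np.empty(S)
    k3 = np.empty(S)
    k4 = np.empty(S)
    k5 = np.empty(S)
    k6 = np.empty(S)
    k7 = np.empty(S)
    yt = np.empty(S)
    y5 = np.empty(S)

    t = 0.0
    hs = min(0.01, max_step, days)
    n_ext = 0
    n_steps = 0

    rhs(B, alive, cat, r, d, x, a, K, pptr, pidx, pval, cptr, cidx, cval,
        form, resptr, residx, linkval, y, Hh, q, h, bp, bh, loss, intake, k1)

    while t < days * (1.0 - 1e-14):
        if hs > days - t:
            hs = days - t
        if hs > max_step:
            hs = max_step

        for i in range(S):
            yt[i] = B[i] + hs * _A21 * k1[i]
        rhs(yt, alive, cat, r, d, x, a, K, pptr, pidx, pval, cptr, cidx, cval,
            form, resptr, residx, linkval, y, Hh, q, h, bp, bh, loss, intake, k2)
        for i in range(S):
            yt[i] = B[i] + hs * (_A31 * k1[i] + _A32 * k2[i])
        rhs(yt, alive, cat, r, d, x, a, K, pptr, pidx, pval, cptr, cidx, cval,
            form, resptr, residx, linkval, y, Hh, q, h, bp, bh, loss, intake, k3)
        for i in range(S):
            yt[i] = B[i] + hs * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
        rhs(yt, alive, cat, r, d, x, a, K, pptr, pidx, pval, cptr, cidx, cval,
            form, resptr, residx, linkval, y, Hh, q, h, bp, bh, loss, intake, k4)
        for i in range(S):
            yt[i] = B[i] + hs * (_A51 * k1[i] + _A52 * k2[i] + _A53 * k3[i] + _A54 * k4[i])
        rhs(yt, alive, cat, r, d, x, a, K, pptr, pidx, pval, cptr, cidx, cval,
            form, resptr, residx, linkval, y, Hh, q, h, bp, bh, loss, intake, k5)
        for i in range(S):
            yt[i] = B[i] + hs * (_A61 * k1[i] + _A62 * k2[i] + _A63 * k3[i]
                                 + _A64 * k4[i] + _A65 * k5[i])
        rhs(yt, alive, cat, r, d, x, a, K, pptr, pidx, pval, cptr, cidx, cval,
            form, resptr, residx, linkval, y, Hh, q, h, bp, bh, loss, intake, k6)
        for i in range(S):
            y5[i] = B[i] + hs * (_A71 * k1[i] + _A73 * k3[i] + _A74 * k4[i]
                                 + _A75 * k5[i] + _A76 * k6[i])
        rhs(y5, alive, cat, r, d, x, a, K, pptr, pidx, pval, cptr, cidx, cval,
            form, resptr, residx, linkval, y, Hh, q, h, bp, bh, loss, intake, k7)

        n_steps += 1
        if n_steps > _MAX_STEPS:
            return STATUS_STEP_BUDGET, n_ext, t, n_steps
        # scaled error norm
        err2 = 0.0
        finite = True
        for i in range(S):
            e = hs * (_E1 * k1[i] + _E3 * k3[i] + _E4 * k4[i] + _E5 * k5[i]
                      + _E6 * k6[i] + _E7 * k7[i])
            ay = abs(B[i])
            ay5 = abs(y5[i])
            sc = atol + rtol * (ay if ay > ay5 else ay5)
            v = e / sc
            err2 += v * v
            if not np.isfinite(y5[i]):
                finite = False
        if not finite or not np.isfinite(err2):
            hs *= 0.25
            if hs < 1e-13:
                return STATUS_NONFINITE, n_ext, t, n_steps
            continue
        enorm = (err2 / S) ** 0.5

        if enorm <= 1.0:
            t += hs
            changed = False
            for i in range(S):
                B[i] = y5[i]
                k1[i] = k7[i]
            for i in range(S):
                if cat[i] == 3:
                    if B[i] < 0.0:
                        B[i] = 0.0
                        changed = True
                elif alive[i] and B[i] < threshold:
                    B[i] = 0.0
                    alive[i] = False
                    ext_idx[n_ext] = i
                    ext_time[n_ext] = t
                    n_ext += 1
                    changed = True
            if changed:
                rhs(B, alive, cat, r, d, x, a, K, pptr, pidx, pval, cptr, cidx, cval,
                    form, resptr, residx, linkval, y, Hh, q, h, bp, bh, loss, intake, k1)
            if enorm > 1e-30:
                fac = 0.9 * enorm ** -0.2
            else:
                fac = 5.0
        else:
            fac = 0.9 * enorm ** -0.2

        if fac < 0.2:
            fac = 0.2
        elif fac > 5.0:
            fac = 5.0
        hs *= fac
        if hs < 1e-13:
            return STATUS_STEP_UNDERFLOW, n_ext, t, n_steps

    return STATUS_OK, n_ext, t, n_steps
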