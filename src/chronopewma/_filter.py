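"""Compiled kernels for the PEWMA filter likelihood and its maximisation.

The filter recursion is inherently sequential, so the hot loop is jit-compiled.
The likelihood is maximised by a Nelder–Mead simplex over transformed
parameters (logit-scaled discount factor, raw regression coefficients);
the public fitting surface lives in :mod:`chronopewma.pewma`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# discount factor search range: omega in (OMEGA_LO, OMEGA_LO + OMEGA_SCALE)
OMEGA_LO = 0.01
OMEGA_SCALE = 0.99


@njit(cache=True)
def omega_from_u(u: float) -> float:
    return OMEGA_LO + OMEGA_SCALE / (1.0 + math.exp(-u))


def u_from_omega(omega: float) -> float:
    w = (omega - OMEGA_LO) / OMEGA_SCALE
    w = min(max(w, 1e-12), 1.0 - 1e-12)
    return math.log(w / (1.0 - w))


@njit(cache=True)
def filter_loglik(y, X, delta, omega, base_rate, a0, b0, skip):
    """One pass of the PEWMA filter; returns the predictive log-likelihood.

    Per step: discount the Gamma belief (a ← ωa, b ← ωb), form the exposure
    m_t = exp(r + x_t·δ), score y_t under the Gamma-mixed Poisson (negative
    binomial with size a and success probability b/(b+m)), then update the
    belief conjugately (a ← a + y_t, b ← b + m_t).  The first ``skip``
    predictive terms are excluded from the sum.
    """
    n = y.shape[0]
    k = X.shape[1]
    a = a0
    b = b0
    ll = 0.0
    for t in range(n):
        a *= omega
        b *= omega
        eta = base_rate
        for j in range(k):
            eta += X[t, j] * delta[j]
        m = math.exp(eta)
        p = b / (b + m)
        yt = y[t]
        if t >= skip:
            ll += (
                math.lgamma(a + yt)
                - math.lgamma(a)
                - math.lgamma(yt + 1.0)
                + a * math.log(p)
                + yt * math.log(1.0 - p)
            )
        a += yt
        b += m
    return ll


@njit(cache=True)
def filter_states(y, X, delta, omega, base_rate, a0, b0):
    """Filter pass recording the posterior Gamma belief (a_t, b_t) per step."""
    n = y.shape[0]
    k = X.shape[1]
    a_out = np.empty(n)
    b_out = np.empty(n)
    a = a0
    b = b0
    for t in range(n):
        a *= omega
        b *= omega
        eta = base_rate
        for j in range(k):
            eta += X[t, j] * delta[j]
        m = math.exp(eta)
        a += y[t]
        b += m
        a_out[t] = a
        b_out[t] = b
    return a_out, b_out


@njit(cache=True)
def _neg_ll(theta, y, X, base_rate, a0, b0, skip):
    omega = omega_from_u(theta[0])
    delta = theta[1:]
    ll = filter_loglik(y, X, delta, omega, base_rate, a0, b0, skip)
    if math.isnan(ll) or math.isinf(ll):
        return 1.0e300
    return -ll


@njit(cache=True)
def nelder_mead(y, X, base_rate, a0, b0, skip, x0, step, ftol, xtol, max_iter):
    """Nelder–Mead simplex minimisation of the negative log-likelihood.

    Standard reflection/expansion/contraction/shrink with coefficients
    (1, 2, 0.5, 0.5).  Returns (theta_best, f_best, converged).
    """
    d = x0.shape[0]
    npt = d + 1
    simplex = np.empty((npt, d))
    fvals = np.empty(npt)
    for i in range(npt):
        for j in range(d):
            simplex[i, j] = x0[j]
        if i > 0:
            simplex[i, i - 1] += step
        fvals[i] = _neg_ll(simplex[i], y, X, base_rate, a0, b0, skip)

    converged = False
    for _ in range(max_iter):
        order = np.argsort(fvals)
        simplex = simplex[order]
        fvals = fvals[order]
        # convergence: function spread and simplex size
        fspread = abs(fvals[npt - 1] - fvals[0])
        xspread = 0.0
        for i in range(1, npt):
            for j in range(d):
                s = abs(simplex[i, j] - simplex[0, j])
                if s > xspread:
                    xspread = s
        if fspread <= ftol * (abs(fvals[0]) + ftol) and xspread <= xtol:
            converged = True
            break

        centroid = np.zeros(d)
        for i in range(npt - 1):
            for j in range(d):
                centroid[j] += simplex[i, j]
        centroid /= npt - 1

        xr = centroid + 1.0 * (centroid - simplex[npt - 1])
        fr = _neg_ll(xr, y, X, base_rate, a0, b0, skip)
        if fr < fvals[0]:
            xe = centroid + 2.0 * (centroid - simplex[npt - 1])
            fe = _neg_ll(xe, y, X, base_rate, a0, b0, skip)
            if fe < fr:
                simplex[npt - 1] = xe
                fvals[npt - 1] = fe
            else:
                simplex[npt - 1] = xr
                fvals[npt - 1] = fr
        elif fr < fvals[npt - 2]:
            simplex[npt - 1] = xr
            fvals[npt - 1] = fr
        else:
            if fr < fvals[npt - 1]:
                xc = centroid + 0.5 * (xr - centroid)
            else:
                xc = centroid + 0.5 * (simplex[npt - 1] - centroid)
            fc = _neg_ll(xc, y, X, base_rate, a0, b0, skip)
            if fc < min(fr, fvals[npt - 1]):
                simplex[npt - 1] = xc
                fvals[npt - 1] = fc
            else:
                for i in range(1, npt):
                    simplex[i] = simplex[0] + 0.5 * (simplex[i] - simplex[0])
                    fvals[i] = _neg_ll(simplex[i], y, X, base_rate, a0, b0, skip)

    order = np.argsort(fvals)
    return simplex[order[0]], fvals[order[0]], converged


@njit(cache=True)
def multistart_fit(y, X, base_rate, a0, b0, skip, omega_starts_u, ftol, xtol, max_iter):
    """Run Nelder–Mead from each discount-factor start (delta = 0); keep the best."""
    d = 1 + X.shape[1]
    best_theta = np.zeros(d)
    best_f = 1.0e301
    best_conv = False
    for s in range(omega_starts_u.shape[0]):
        x0 = np.zeros(d)
        x0[0] = omega_starts_u[s]
        theta, f, conv = nelder_mead(
            y, X, base_rate, a0, b0, skip, x0, 0.5, ftol, xtol, max_iter
        )
        if f < best_f:
            best_f = f
            best_theta = theta
            best_conv = conv
    return best_theta, best_f, best_conv
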