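"""Independent dense oracles for the moment structure and BLUP algebra.

Everything here is assembled entrywise from scalar formulas with explicit
loops and `np.linalg.inv`, deliberately avoiding the package's block-matrix
and Cholesky code paths so the two can cross-check each other.
"""

from __future__ import annotations

import numpy as np


def dense_mu(alpha, beta, Z, X):
    Z = np.atleast_2d(Z)
    X = np.atleast_2d(X)
    T = Z.shape[0]
    mu = np.empty(2 * T)
    for t in range(T):
        mu[t] = np.exp(Z[t] @ alpha + X[t] @ beta)
        mu[T + t] = np.exp(Z[t] @ alpha)
    return mu


def dense_cov_v(sigma2, tau2, rho, T):
    """Cov(V_jt, V_j't') entry by entry: sigma2 + [j==j'] tau2_j rho_j^|t-t'|."""
    C = np.empty((2 * T, 2 * T))
    for a in range(2 * T):
        for b in range(2 * T):
            ja, ta = divmod(a, T)
            jb, tb = divmod(b, T)
            C[a, b] = sigma2
            if ja == jb:
                C[a, b] += tau2[ja] * rho[ja] ** abs(ta - tb)
    return C


def dense_var_y(mu, CovV):
    n = len(mu)
    V = np.empty((n, n))
    for a in range(n):
        for b in range(n):
            V[a, b] = mu[a] * mu[b] * CovV[a, b] + (mu[a] if a == b else 0.0)
    return V


def dense_blups(alpha, beta, sigma2, tau2, rho, Z, X, y):
    """(u_hat, v_hat) by brute-force dense linear algebra."""
    T = np.atleast_2d(Z).shape[0]
    mu = dense_mu(alpha, beta, Z, X)
    CovV = dense_cov_v(sigma2, tau2, rho, T)
    VarY = dense_var_y(mu, CovV)
    Vinv = np.linalg.inv(VarY)
    resid = np.asarray(y, dtype=float) - mu
    cov_uy = sigma2 * mu
    u_hat = 1.0 + cov_uy @ Vinv @ resid
    cov_vy = CovV @ np.diag(mu)
    v_hat = 1.0 + cov_vy @ Vinv @ resid
    return u_hat, v_hat


def dense_corrections(alpha, beta, sigma2, tau2, rho, Z, X):
    """c, d[j][t], b[j][(t, t')] from the moment identities, via np.linalg.inv.

    c      = E(U - 1)^2 - E(Uhat - 1)^2
    d_jt   = E(V_jt - U)^2 - E(Vhat_jt - Uhat)^2
    b_j,tt' = E(V_jt - U)(V_jt' - U) - E(Vhat_jt - Uhat)(Vhat_jt' - Uhat)

    with the BLUP second moments expanded through Cov(., Y) Var^-1(Y)
    Cov(Y, .).
    """
    T = np.atleast_2d(Z).shape[0]
    mu = dense_mu(alpha, beta, Z, X)
    CovV = dense_cov_v(sigma2, tau2, rho, T)
    VarY = dense_var_y(mu, CovV)
    Vinv = np.linalg.inv(VarY)
    cov_uy = sigma2 * mu
    cov_vy = CovV @ np.diag(mu)  # row k = Cov(V_k, Y)

    c = sigma2 - cov_uy @ Vinv @ cov_uy
    d = np.empty((2, T))
    b = {0: {}, 1: {}}
    for j in range(2):
        for t in range(T):
            k = j * T + t
            row = cov_vy[k]
            e_vu = tau2[j]  # E(V_jt - U)^2
            e_hat = (row - cov_uy) @ Vinv @ (row - cov_uy)
            d[j, t] = e_vu - e_hat
        for t in range(T):
            for t2 in range(T):
                if t2 <= t:
                    continue
                k1, k2 = j * T + t, j * T + t2
                e_vu = tau2[j] * rho[j] ** abs(t - t2)
                e_hat = (cov_vy[k1] - cov_uy) @ Vinv @ (cov_vy[k2] - cov_uy)
                b[j][(t, t2)] = e_vu - e_hat
    return c, d, b
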