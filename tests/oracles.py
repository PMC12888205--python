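"""Independent oracles used by the tests.

Everything here is deliberately written against the raw long-format data with
dense linear algebra or quadrature, sharing no code path with the package's
collapsed-cell implementations.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, roots_hermite
from scipy.stats import multivariate_normal


def dense_design(frame, include_interaction=True):
    trt = frame["trt"].to_numpy(dtype=float)
    gr = frame["gr"].to_numpy(dtype=np.int64)
    p = int(gr.max()) + 1
    cols = [np.ones(len(frame)), trt]
    cols += [(gr == k).astype(float) for k in range(1, p)]
    if include_interaction:
        cols += [trt * (gr == k) for k in range(1, p)]
    return np.column_stack(cols)


def dense_Z(frame, q):
    gr = frame["gr"].to_numpy(dtype=np.int64)
    if q == 1:
        return np.ones((len(frame), 1))
    return np.column_stack([np.ones(len(frame))]
                           + [(gr == k).astype(float) for k in range(1, q)])


def cluster_blocks(frame):
    ids = np.unique(frame["cluster_id"].to_numpy())
    for cid in ids:
        yield frame[frame["cluster_id"] == cid]


def gls_beta(frame, Sigma_u, sigma2):
    """Closed-form GLS estimate with known covariance (dense, per cluster)."""
    q = Sigma_u.shape[0]
    XtViX = 0.0
    XtViy = 0.0
    for sub in cluster_blocks(frame):
        X = dense_design(sub)
        Z = dense_Z(sub, q)
        y = sub["y"].to_numpy(dtype=float)
        V = sigma2 * np.eye(len(sub)) + Z @ Sigma_u @ Z.T
        Vi = np.linalg.inv(V)
        XtViX = XtViX + X.T @ Vi @ X
        XtViy = XtViy + X.T @ Vi @ y
    return np.linalg.solve(XtViX, XtViy)


def lmm_loglik_dense(frame, gamma, q, method="REML"):
    """Gaussian mixed-model (restricted) loglik, dense V, beta profiled.

    gamma = (lower-triangle entries of chol(Sigma_u), log sigma2), on the
    absolute covariance scale (a different parametrization from the package's
    relative factor; Satterthwaite df is invariant to this choice).
    """
    nt = q * (q + 1) // 2
    L = np.zeros((q, q))
    L[np.tril_indices(q)] = gamma[:nt]
    Sigma_u = L @ L.T
    sigma2 = float(np.exp(gamma[nt]))
    XtViX, XtViy, quad, logdet, n = 0.0, 0.0, 0.0, 0.0, 0
    blocks = []
    for sub in cluster_blocks(frame):
        X = dense_design(sub)
        Z = dense_Z(sub, q)
        y = sub["y"].to_numpy(dtype=float)
        V = sigma2 * np.eye(len(sub)) + Z @ Sigma_u @ Z.T
        Vi = np.linalg.inv(V)
        sign, ld = np.linalg.slogdet(V)
        logdet += ld
        XtViX = XtViX + X.T @ Vi @ X
        XtViy = XtViy + X.T @ Vi @ y
        n += len(sub)
        blocks.append((X, Vi, y))
    beta = np.linalg.solve(XtViX, XtViy)
    for X, Vi, y in blocks:
        r = y - X @ beta
        quad += r @ Vi @ r
    k = X.shape[1]
    ll = -0.5 * (logdet + quad + n * np.log(2 * np.pi))
    if method == "REML":
        sign, ldx = np.linalg.slogdet(XtViX)
        ll += 0.5 * k * np.log(2 * np.pi) - 0.5 * ldx
    return ll


def satterthwaite_dense(frame, fit, contrast, q, rel=1e-4):
    """Brute-force Satterthwaite df from the dense likelihood above."""
    Lhat = np.linalg.cholesky(fit.re_cov + 1e-12 * np.eye(q))
    gamma0 = np.concatenate([Lhat[np.tril_indices(q)], [np.log(fit.scale)]])
    d = len(gamma0)
    c = np.asarray(contrast, dtype=float)
    nt = q * (q + 1) // 2

    def covfun(gamma):
        L = np.zeros((q, q))
        L[np.tril_indices(q)] = gamma[:nt]
        Sigma_u = L @ L.T
        sigma2 = float(np.exp(gamma[nt]))
        XtViX = 0.0
        for sub in cluster_blocks(frame):
            X = dense_design(sub)
            Z = dense_Z(sub, q)
            V = sigma2 * np.eye(len(sub)) + Z @ Sigma_u @ Z.T
            XtViX = XtViX + X.T @ np.linalg.inv(V) @ X
        return np.linalg.inv(XtViX)

    def g(gamma):
        return float(c @ covfun(gamma) @ c)

    def ll(gamma):
        return lmm_loglik_dense(frame, gamma, q, fit.method)

    h = rel * np.maximum(np.abs(gamma0), 1.0)
    grad = np.zeros(d)
    for i in range(d):
        e = np.zeros(d); e[i] = h[i]
        grad[i] = (g(gamma0 + e) - g(gamma0 - e)) / (2 * h[i])
    H = np.zeros((d, d))
    f0 = ll(gamma0)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        H[i, i] = (ll(gamma0 + ei) - 2 * f0 + ll(gamma0 - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = h[j]
            H[i, j] = H[j, i] = (ll(gamma0 + ei + ej) - ll(gamma0 + ei - ej)
                                 - ll(gamma0 - ei + ej) + ll(gamma0 - ei - ej)) \
                / (4 * h[i] * h[j])
    A = np.linalg.inv(-H)
    g0 = g(gamma0)
    return 2 * g0 ** 2 / float(grad @ A @ grad)


def _cond_logpost(u, X, Z, y, beta, Sigma, family):
    eta = X @ beta + Z @ u
    if family == "poisson":
        ll = np.sum(y * eta - np.exp(eta) - gammaln(y + 1))
    elif family == "bernoulli":
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    else:
        raise ValueError(family)
    q = len(u)
    Si = np.linalg.inv(Sigma)
    sign, ld = np.linalg.slogdet(Sigma)
    return ll - 0.5 * u @ Si @ u - 0.5 * ld - 0.5 * q * np.log(2 * np.pi)


def agh_cluster_loglik(frame_block, beta, Sigma, family, n_nodes=61):
    """Adaptive Gauss-Hermite marginal loglik for one cluster (q <= 2)."""
    X = dense_design(frame_block)
    Z = dense_Z(frame_block, Sigma.shape[0])
    y = frame_block["y"].to_numpy(dtype=float)
    q = Sigma.shape[0]
    h = lambda u: _cond_logpost(np.atleast_1d(u), X, Z, y, beta, Sigma, family)
    res = minimize(lambda u: -h(u), np.zeros(q), method="BFGS")
    uh = res.x
    # numerical Hessian of -h at the mode
    e = 1e-5
    H = np.zeros((q, q))
    for i in range(q):
        for j in range(q):
            ei = np.zeros(q); ei[i] = e
            ej = np.zeros(q); ej[j] = e
            H[i, j] = -(h(uh + ei + ej) - h(uh + ei - ej)
                        - h(uh - ei + ej) + h(uh - ei - ej)) / (4 * e * e)
    C = np.linalg.cholesky(np.linalg.inv(H))
    nodes, wts = roots_hermite(n_nodes)
    if q == 1:
        pts = nodes[:, None]
        ws = wts
        t2 = nodes ** 2
    else:
        a, b = np.meshgrid(nodes, nodes, indexing="ij")
        pts = np.column_stack([a.ravel(), b.ravel()])
        ws = np.outer(wts, wts).ravel()
        t2 = (pts ** 2).sum(axis=1)
    vals = np.array([h(uh + np.sqrt(2.0) * C @ t) for t in pts]) + t2
    mx = vals.max()
    integral = np.log(np.sum(ws * np.exp(vals - mx))) + mx
    sign, ldC = np.linalg.slogdet(C)
    return integral + ldC + 0.5 * q * np.log(2.0)


def agh_loglik(frame, beta, Sigma, family, n_nodes=61):
    return sum(agh_cluster_loglik(b, beta, Sigma, family, n_nodes)
               for b in cluster_blocks(frame))


def sandwich_double_loop(frame, beta, family):
    """Cluster-robust sandwich by an explicit observation-level double loop."""
    X = dense_design(frame)
    y = frame["y"].to_numpy(dtype=float)
    eta = X @ beta
    if family == "gaussian":
        mu, w = eta, np.ones_like(eta)
    elif family == "poisson":
        mu = np.exp(eta); w = mu
    else:
        mu = expit(eta); w = mu * (1 - mu)
    k = X.shape[1]
    A = np.zeros((k, k))
    for i in range(len(y)):
        A += w[i] * np.outer(X[i], X[i])
    Ainv = np.linalg.inv(A)
    meat = np.zeros((k, k))
    for cid in np.unique(frame["cluster_id"]):
        idx = np.flatnonzero(frame["cluster_id"].to_numpy() == cid)
        Ui = np.zeros(k)
        for i in idx:
            Ui += (y[i] - mu[i]) * X[i]
        meat += np.outer(Ui, Ui)
    return Ainv @ meat @ Ainv
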