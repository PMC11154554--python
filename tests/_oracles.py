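"""Independent oracles used by the test suite.

These deliberately avoid the package's closed forms: the Bayes-factor
oracle integrates the two marginal likelihoods numerically (tensor-product
Gauss-Legendre in peak-stabilised coordinates), and the Benjamini-Hochberg
oracle tries every cutoff by brute force.
"""

import numpy as np
from scipy.special import logsumexp


def quadrature_log_bf(x, y, n_uv=200, n_z=240, half_width=9.0):
    """Numerical-integration log unscaled BF for the common-variance
    two-sample normal problem.

    Priors: flat on the common location mu, flat on the standardized shift
    delta/sigma (density 1/sigma on delta), d(sigma)/sigma on the scale.
    Substitutions mu = xbar + sigma*u, delta = (ybar - xbar) + sigma*v,
    sigma = e^z keep the integrand's peak near the origin for every sigma,
    so a fixed Gauss-Legendre grid converges to ~1e-9 relative error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    n_tot = nx + ny
    s = np.concatenate([x, y]).std(ddof=1)
    xu, wu = np.polynomial.legendre.leggauss(n_uv)
    u = xu * half_width
    logwu = np.log(wu * half_width)
    xz, wz = np.polynomial.legendre.leggauss(n_z)
    zlo, zhi = np.log(s) - 9.0, np.log(s) + 13.0
    z = (xz + 1) / 2 * (zhi - zlo) + zlo
    lwz = np.log(wz * (zhi - zlo) / 2)
    sig = np.exp(z)

    xc = x - x.mean()
    yc = y - y.mean()
    allc = np.concatenate([x, y]) - np.concatenate([x, y]).mean()
    uu = u[:, None]
    vv = u[None, :]
    log_m1 = np.empty(len(z))
    log_m0 = np.empty(len(z))
    for k, (sg, lw) in enumerate(zip(sig, lwz)):
        a = xc / sg
        b = yc / sg
        e1 = -0.5 * ((a[:, None, None] - uu[None]) ** 2).sum(0) \
             - 0.5 * ((b[:, None, None] - (uu + vv)[None]) ** 2).sum(0)
        li1 = logsumexp(e1 + logwu[:, None] + logwu[None, :])
        log_m1[k] = -n_tot / 2 * np.log(2 * np.pi * sg * sg) + li1 + np.log(sg) + lw
        e0 = -0.5 * ((allc[:, None] / sg - u[None, :]) ** 2).sum(0)
        log_m0[k] = -n_tot / 2 * np.log(2 * np.pi * sg * sg) + \
            logsumexp(e0 + logwu) + np.log(sg) + lw
    return logsumexp(log_m1) - logsumexp(log_m0)


def bh_bruteforce(pvalues, q):
    """Step-up by exhaustive search: largest k with p_(k) <= k q / m."""
    pvalues = np.asarray(pvalues, float)
    m = len(pvalues)
    order = np.argsort(pvalues, kind="stable")
    ps = pvalues[order]
    k_best = 0
    for k in range(1, m + 1):
        if ps[k - 1] <= k * q / m:
            k_best = k
    return np.sort(order[:k_best])
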