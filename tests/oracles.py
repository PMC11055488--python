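"""Independent oracles for the mixed-model tests.

These re-derive quantities by routes unrelated to the package's Laplace
implementation: adaptive Gauss-Hermite integration of the single-random-
intercept binomial likelihood, and (in the tests) plain GLM fits from
statsmodels and glmer fits from R's lme4.
"""

import numpy as np
from scipy import optimize


def agq_binomial_loglik(beta, sigma, df, nodes=50):
    """Adaptive GH quadrature log-likelihood for ``y ~ x + (1 | g)`` Bernoulli.

    Each group's integral over its random intercept is centered at the
    conditional mode with curvature-matched scaling, then integrated on a
    ``nodes``-point Gauss-Hermite grid.
    """
    xg, wg = np.polynomial.hermite.hermgauss(nodes)
    X = np.column_stack([np.ones(len(df)), df["x"].to_numpy()])
    eta0 = X @ np.asarray(beta)
    ll = 0.0
    for _, sub in df.groupby("g"):
        e0 = eta0[sub.index.to_numpy()]
        y = sub["y"].to_numpy()

        def neg_joint(u):
            eta = e0 + u
            return -(np.sum(y * eta - np.logaddexp(0.0, eta))
                     - 0.5 * u * u / sigma ** 2)

        res = optimize.minimize_scalar(neg_joint, bounds=(-12, 12),
                                       method="bounded")
        uhat = res.x
        h = 1e-4
        hess = (neg_joint(uhat + h) - 2 * neg_joint(uhat)
                + neg_joint(uhat - h)) / h ** 2
        s = 1.0 / np.sqrt(max(hess, 1e-10))
        u = uhat + np.sqrt(2.0) * s * xg
        eta = e0[:, None] + u[None, :]
        log_joint = (np.sum(y[:, None] * eta - np.logaddexp(0.0, eta), axis=0)
                     - 0.5 * u ** 2 / sigma ** 2
                     - 0.5 * np.log(2 * np.pi * sigma ** 2))
        t = log_joint + xg ** 2
        m = np.max(t)
        ll += m + np.log(np.sum(wg * np.exp(t - m)) * np.sqrt(2.0) * s)
    return float(ll)
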