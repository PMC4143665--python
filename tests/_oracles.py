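"""Independent oracles used to validate the sampler.

These deliberately avoid the package's Gibbs code paths: posterior inclusion
probabilities by exhaustive model enumeration with Gaussian marginal
likelihoods, and a 1-D quadrature for the collapsed spike-and-slab Bayes
factor.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy import integrate, stats
from scipy.special import betaln


def enumeration_pips(y, C, S, fam, subj, sigmas, a, b, tau2, v0):
    """Exact per-trait PIPs by enumerating all 2^(2G) joint models.

    Coefficients (prior N(0, v0) for the fixed columns, N(0, tau2) for active
    SNV columns) and all random effects are integrated analytically, so each
    model's marginal likelihood is a single 2n-dimensional Gaussian density.
    """
    Sp, Ss, Se = sigmas
    n, G = S.shape
    Zf = np.zeros((n, fam.max() + 1)); Zf[np.arange(n), fam] = 1
    Zs = np.zeros((n, subj.max() + 1)); Zs[np.arange(n), subj] = 1
    V0 = (
        np.kron(Zf @ Zf.T, Sp)
        + np.kron(Zs @ Zs.T, Ss)
        + np.kron(np.eye(n), Se)
    )
    yflat = y.reshape(-1)  # observation-major, trait-minor

    def embed(col, k):
        w = np.zeros(2 * n)
        w[np.arange(n) * 2 + k] = col
        return w

    def log_model_prior(nk):
        # Beta-Bernoulli marginal over gamma_k with q integrated out
        return betaln(a + nk, b + G - nk) - betaln(a, b)

    log_post = {}
    for g1 in itertools.product((0, 1), repeat=G):
        for g2 in itertools.product((0, 1), repeat=G):
            cols, var = [], []
            for k, gk in enumerate((g1, g2)):
                for j in range(C.shape[1]):
                    cols.append(embed(C[:, j], k)); var.append(v0)
                for j in range(G):
                    if gk[j]:
                        cols.append(embed(S[:, j], k)); var.append(tau2)
            W = np.column_stack(cols)
            V = W @ np.diag(var) @ W.T + V0
            ll = stats.multivariate_normal.logpdf(yflat, mean=np.zeros(2 * n), cov=V)
            log_post[(g1, g2)] = ll + log_model_prior(sum(g1)) + log_model_prior(sum(g2))

    mx = max(log_post.values())
    Z = sum(np.exp(v - mx) for v in log_post.values())
    pips = np.zeros((2, G))
    for (g1, g2), v in log_post.items():
        w = np.exp(v - mx) / Z
        pips[0] += w * np.array(g1)
        pips[1] += w * np.array(g2)
    return pips


def quadrature_inclusion_probability(x, u, v, tau2, q):
    """P(gamma=1 | u) by numerically integrating the slab marginal likelihood.

    u = x*beta + eps with eps ~ N(0, v) iid; beta ~ N(0, tau2) under the slab.
    """
    def integrand(beta):
        resid = u - beta * x
        loglik = -0.5 * np.sum(resid**2) / v
        return np.exp(loglik) * stats.norm.pdf(beta, 0.0, np.sqrt(tau2))

    m1, _ = integrate.quad(integrand, -50 * np.sqrt(tau2), 50 * np.sqrt(tau2),
                           limit=200)
    m0 = np.exp(-0.5 * np.sum(u**2) / v)
    return q * m1 / (q * m1 + (1 - q) * m0)
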