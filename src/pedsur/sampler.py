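"""Gibbs sampler for the Bayesian bivariate longitudinal pedigree model.

Model, for trait k in {1,2} of subject j in family i at visit t:

    y_ijtk = b0k + X_ij' bxk + Z_ijt' bzk + sum_g gamma_gk beta_gk SNV_ijg
             + p_ik + s_ijk + e_ijtk

with p_i ~ N2(0, Sigma_p) shared by a family, s_ij ~ N2(0, Sigma_s) shared by
a subject's visits, and e_ijt ~ N2(0, Sigma_e) correlating the two traits'
residuals at a visit (seemingly-unrelated-regression structure). SNV
inclusion uses a spike-and-slab prior with Beta-Bernoulli multiplicity
control: gamma_gk ~ Bernoulli(q_k), q_k ~ Beta(a, b) with a=1, b=G by
default, so the marginal prior odds of any one association are 1/G whatever
G is.

Sampling scheme: indicators are updated with the slab coefficient analytically
marginalized (collapsed update), which mixes well without pseudo-prior tuning;
all active coefficients are then redrawn jointly from the exact multivariate
normal full conditional of the whitened stacked bivariate regression. Random
effects and covariance matrices have conjugate bivariate-normal and
inverse-Wishart full conditionals.

``mode="univariate"`` constrains every covariance matrix to be diagonal, so
the two traits are modeled independently; each trait then consumes its own
RNG stream and its results are bit-for-bit independent of the other trait's
data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .types import ModelDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PriorSpec:
    """Hyperparameters.

    a, b: Beta prior on the per-trait inclusion probability q (b=None means
    b=G, the sceptical default). tau2: slab variance of SNV coefficients on
    the working (standardized-trait) scale. v0: prior variance of intercept
    and covariate coefficients. nu0, s0: inverse-Wishart degrees of freedom
    and scale (s0*I if scalar) shared by Sigma_p, Sigma_s, Sigma_e.
    """

    a: float = 1.0
    b: float | None = None
    tau2: float = 100.0
    v0: float = 1e4
    nu0: float = 3.0
    s0: float | np.ndarray = 0.01

    def resolve(self, n_snvs: int) -> "PriorSpec":
        b = float(n_snvs) if self.b is None else float(self.b)
        s0 = self.s0
        S0 = np.asarray(s0, dtype=float)
        if S0.ndim == 0:
            S0 = float(S0) * np.eye(2)
        if self.a <= 0 or b <= 0:
            raise ValueError("Beta hyperparameters a, b must be positive")
        if self.tau2 <= 0:
            raise ValueError("slab variance tau2 must be positive")
        if self.nu0 < 3:
            raise ValueError("inverse-Wishart df nu0 must be >= 3 for a finite mean")
        w = np.linalg.eigvalsh((S0 + S0.T) / 2)
        if np.any(w <= 0):
            raise ValueError("inverse-Wishart scale must be symmetric positive definite")
        out = PriorSpec(a=self.a, b=b, tau2=self.tau2, v0=self.v0, nu0=self.nu0, s0=S0)
        return out

    @property
    def S0(self) -> np.ndarray:
        S0 = np.asarray(self.s0, dtype=float)
        return float(S0) * np.eye(2) if S0.ndim == 0 else S0


@dataclass
class ChainConfig:
    n_iterations: int = 20000
    burn_in: int = 5000
    thinning: int = 10
    seed: int = 0
    mode: str = "bivariate"          # "bivariate" | "univariate"
    shared_q: bool = False
    standardize: bool = True
    fixed_sigmas: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.mode not in ("bivariate", "univariate"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_draws(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thinning


# ---------------------------------------------------------------------------
# prepared data


class FitData:
    """Design arrays on the working scale.

    Traits are standardized (mean 0, SD 1) unless ``standardize=False``;
    SNV dosage columns are always centered (keeping coefficients per-allele
    while decorrelating them from the intercept); covariate columns are
    centered when standardizing.
    """

    def __init__(self, y, C, S, fam, subj, subj_fam, *, y_mean=None, y_sd=None,
                 c_means=None, s_means=None, snv_ids=None, fixed_names=None,
                 trait_names=("trait1", "trait2")):
        self.y = np.asarray(y, dtype=float)
        self.C = np.asarray(C, dtype=float)
        self.S = np.asarray(S, dtype=float)
        self.fam = np.asarray(fam, dtype=int)
        self.subj = np.asarray(subj, dtype=int)
        self.subj_fam = np.asarray(subj_fam, dtype=int)
        self.n_obs = self.y.shape[0]
        self.n_fam = self.subj_fam.max() + 1 if self.subj_fam.size else 0
        self.n_subj = len(self.subj_fam)
        self.n_fixed = self.C.shape[1]
        self.n_snvs = self.S.shape[1]
        self.fam_counts = np.bincount(self.fam, minlength=self.n_fam)
        self.subj_counts = np.bincount(self.subj, minlength=self.n_subj)
        self.y_mean = np.zeros(2) if y_mean is None else np.asarray(y_mean)
        self.y_sd = np.ones(2) if y_sd is None else np.asarray(y_sd)
        self.c_means = np.zeros(self.n_fixed) if c_means is None else np.asarray(c_means)
        self.s_means = np.zeros(self.n_snvs) if s_means is None else np.asarray(s_means)
        self.snv_ids = tuple(snv_ids) if snv_ids is not None else tuple(
            f"snv{j}" for j in range(self.n_snvs)
        )
        self.fixed_names = tuple(fixed_names) if fixed_names is not None else tuple(
            f"c{j}" for j in range(self.n_fixed)
        )
        self.trait_names = tuple(trait_names)

    @classmethod
    def from_dataset(cls, data: ModelDataset, standardize: bool = True) -> "FitData":
        y = data.y.astype(float).copy()
        C = data.fixed.astype(float).copy()
        S = data.snv.astype(float).copy()
        s_means = S.mean(axis=0)
        S -= s_means
        if standardize:
            y_mean = y.mean(axis=0)
            y_sd = y.std(axis=0, ddof=0)
            if np.any(y_sd == 0):
                raise ValueError("a trait has zero variance; cannot standardize")
            y = (y - y_mean) / y_sd
            c_means = C.mean(axis=0)
            c_means[0] = 0.0  # keep the intercept column as-is
            C = C - c_means
        else:
            y_mean, y_sd = np.zeros(2), np.ones(2)
            c_means = np.zeros(C.shape[1])
        return cls(
            y, C, S, data.fam_idx, data.subj_idx, data.subj_fam,
            y_mean=y_mean, y_sd=y_sd, c_means=c_means, s_means=s_means,
            snv_ids=data.snv_ids, fixed_names=data.fixed_names,
            trait_names=data.trait_names,
        )


# ---------------------------------------------------------------------------
# state


@dataclass
class MCMCState:
    beta_fixed: np.ndarray   # (2, p)
    beta_snv: np.ndarray     # (2, G)
    gamma: np.ndarray        # (2, G) int8
    q: np.ndarray            # (2,)
    p_fam: np.ndarray        # (I, 2)
    s_subj: np.ndarray       # (N, 2)
    sigma_p: np.ndarray      # (2, 2)
    sigma_s: np.ndarray
    sigma_e: np.ndarray

    def copy(self) -> "MCMCState":
        return MCMCState(*(getattr(self, f).copy() for f in (
            "beta_fixed", "beta_snv", "gamma", "q", "p_fam", "s_subj",
            "sigma_p", "sigma_s", "sigma_e",
        )))

    def validate(self) -> None:
        assert np.all((self.q > 0) & (self.q < 1)), "q outside (0,1)"
        assert np.isin(self.gamma, (0, 1)).all(), "gamma not binary"
        for name in ("sigma_p", "sigma_s", "sigma_e"):
            m = getattr(self, name)
            assert np.allclose(m, m.T), f"{name} not symmetric"
            assert np.all(np.linalg.eigvalsh(m) > 0), f"{name} not positive definite"
            rho = m[0, 1] / np.sqrt(m[0, 0] * m[1, 1])
            assert -1.0 < rho < 1.0, f"{name} correlation outside (-1,1)"
        assert np.all(np.isfinite(self.beta_fixed) & ~np.isnan(self.beta_fixed))
        assert np.all((self.gamma == 1) | (self.beta_snv == 0.0)), \
            "inactive SNV coefficient stored nonzero"


# ---------------------------------------------------------------------------
# small linear-algebra helpers


def _inv2(m: np.ndarray) -> np.ndarray:
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if not det > 0 or not m[0, 0] > 0:
        raise np.linalg.LinAlgError("2x2 matrix not positive definite")
    return np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det


def _chol_spd(m: np.ndarray) -> np.ndarray:
    """Cholesky with one symmetrize-and-jitter retry."""
    try:
        return np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        m = (m + m.T) / 2 + 1e-10 * np.eye(m.shape[0])
        return np.linalg.cholesky(m)


def _draw_mvn_prec(prec: np.ndarray, b: np.ndarray, rng: np.random.Generator):
    """Draw from N(prec^-1 b, prec^-1); returns (draw, mean)."""
    L = _chol_spd(prec)
    mean = np.linalg.solve(L.T, np.linalg.solve(L, b))
    z = rng.standard_normal(b.shape[0])
    return mean + np.linalg.solve(L.T, z), mean


def invwishart_rvs(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-Wishart draw via the Bartlett decomposition.

    Draws X ~ Wishart(df, scale^-1) and returns X^-1 ~ IW(df, scale).
    """
    p = scale.shape[0]
    if df < p:
        raise ValueError("inverse-Wishart df must be >= dimension")
    Lv = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    F = Lv @ A                      # X = F F'
    Finv = np.linalg.inv(F)
    return Finv.T @ Finv


def _as_rng_pair(rng):
    if isinstance(rng, tuple):
        return rng
    return (rng, rng)


def _fitted(state: MCMCState, data: FitData) -> np.ndarray:
    """(n,2) fitted fixed + genetic part (no random effects)."""
    return data.C @ state.beta_fixed.T + data.S @ (state.gamma * state.beta_snv).T


# ---------------------------------------------------------------------------
# closed-form pieces (exposed for verification against hand-derived formulas)


def snv_inclusion_moments(x: np.ndarray, u: np.ndarray, v: float, tau2: float):
    """Collapsed spike-and-slab moments for one SNV column.

    With u = x*beta + eps, eps ~ N(0, v) iid and slab beta ~ N(0, tau2):
    returns (log Bayes factor for inclusion, posterior mean, posterior
    variance of beta given inclusion).
    """
    sxx = float(x @ x) / v
    sxu = float(x @ u) / v
    post_prec = 1.0 / tau2 + sxx
    m = sxu / post_prec
    log_bf = -0.5 * np.log1p(tau2 * sxx) + 0.5 * sxu * sxu / post_prec
    return log_bf, m, 1.0 / post_prec


def inclusion_beta_params(n_included: int, n_total: int, a: float, b: float):
    """Conjugate Beta posterior parameters for the inclusion probability."""
    return a + n_included, b + n_total - n_included


def iw_posterior_params(nu0: float, S0: np.ndarray, vectors: np.ndarray):
    """Conjugate inverse-Wishart posterior parameters given N(0, Sigma) rows."""
    vectors = np.atleast_2d(vectors)
    return nu0 + vectors.shape[0], S0 + vectors.T @ vectors


def random_effect_fullcond(prior_cov: np.ndarray, sigma_e: np.ndarray,
                           resid_sum: np.ndarray, n: int):
    """Posterior (mean, cov) of a bivariate random effect with n residual rows."""
    omega = _inv2(sigma_e)
    prec = _inv2(prior_cov) + n * omega
    cov = _inv2(prec)
    return cov @ (omega @ resid_sum), cov


# ---------------------------------------------------------------------------
# initialization


def init_state(data: FitData, priors: PriorSpec, seed: int = 0) -> MCMCState:
    """Deterministic starting point: least squares for the fixed effects,
    moment-based diagonal variance-component estimates, empty model."""
    priors = priors.resolve(data.n_snvs)
    C = data.C
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise np.linalg.LinAlgError("fixed-effect design is singular")
    beta_fixed = np.zeros((2, data.n_fixed))
    resid = np.empty_like(data.y)
    for k in (0, 1):
        coef, *_ = np.linalg.lstsq(C, data.y[:, k], rcond=None)
        beta_fixed[k] = coef
        resid[:, k] = data.y[:, k] - C @ coef
    vp, vs, ve = _moment_variance_components(resid, data)
    q0 = priors.a / (priors.a + priors.b)
    return MCMCState(
        beta_fixed=beta_fixed,
        beta_snv=np.zeros((2, data.n_snvs)),
        gamma=np.zeros((2, data.n_snvs), dtype=np.int8),
        q=np.array([q0, q0]),
        p_fam=np.zeros((data.n_fam, 2)),
        s_subj=np.zeros((data.n_subj, 2)),
        sigma_p=np.diag(vp),
        sigma_s=np.diag(vs),
        sigma_e=np.diag(ve),
    )


def _moment_variance_components(resid: np.ndarray, data: FitData):
    """Method-of-moments split of residual variance into family / subject /
    visit layers, using within-subject and within-family residual products."""
    vp = np.empty(2)
    vs = np.empty(2)
    ve = np.empty(2)
    for k in (0, 1):
        r = resid[:, k]
        total = float(np.var(r))
        subj_sum = np.bincount(data.subj, weights=r, minlength=data.n_subj)
        subj_sq = np.bincount(data.subj, weights=r * r, minlength=data.n_subj)
        m = data.subj_counts
        pairs_s = float(np.sum(m * (m - 1)))
        cov_subj = (
            float(np.sum(subj_sum**2 - subj_sq)) / pairs_s if pairs_s > 0 else 0.0
        )
        fam_sum = np.bincount(data.fam, weights=r, minlength=data.n_fam)
        subj_sum_by_fam = np.bincount(
            data.subj_fam, weights=subj_sum**2, minlength=data.n_fam
        )
        n_i = data.fam_counts
        m_by_fam = np.bincount(data.subj_fam, weights=m.astype(float)**2,
                               minlength=data.n_fam)
        pairs_f = float(np.sum(n_i**2 - m_by_fam))
        cov_fam = (
            float(np.sum(fam_sum**2 - subj_sum_by_fam)) / pairs_f if pairs_f > 0 else 0.0
        )
        floor = 0.05 * total
        vp[k] = max(cov_fam, floor)
        vs[k] = max(cov_subj - cov_fam, floor)
        ve[k] = max(total - max(cov_subj, 0.0), floor)
    return vp, vs, ve


# ---------------------------------------------------------------------------
# full-conditional updates


def update_regression_coefficients(state: MCMCState, data: FitData,
                                   priors: PriorSpec, rng,
                                   mode: str = "bivariate") -> MCMCState:
    """Joint draw of all active coefficients (intercept, covariates, and
    included SNVs, both traits) from the whitened SUR full conditional."""
    rngs = _as_rng_pair(rng)
    r = data.y - state.p_fam[data.fam] - state.s_subj[data.subj]
    act = [np.flatnonzero(state.gamma[k]) for k in (0, 1)]
    W = [
        np.hstack([data.C, data.S[:, act[k]]]) if act[k].size else data.C
        for k in (0, 1)
    ]
    pvar = [
        np.concatenate([np.full(data.n_fixed, priors.v0),
                        np.full(act[k].size, priors.tau2)])
        for k in (0, 1)
    ]
    if mode == "bivariate":
        omega = _inv2(state.sigma_e)
        p1, p2 = W[0].shape[1], W[1].shape[1]
        A = np.empty((p1 + p2, p1 + p2))
        A[:p1, :p1] = omega[0, 0] * (W[0].T @ W[0])
        A[:p1, p1:] = omega[0, 1] * (W[0].T @ W[1])
        A[p1:, :p1] = A[:p1, p1:].T
        A[p1:, p1:] = omega[1, 1] * (W[1].T @ W[1])
        A[np.diag_indices(p1 + p2)] += 1.0 / np.concatenate(pvar)
        b = np.concatenate([
            W[0].T @ (omega[0, 0] * r[:, 0] + omega[0, 1] * r[:, 1]),
            W[1].T @ (omega[0, 1] * r[:, 0] + omega[1, 1] * r[:, 1]),
        ])
        draw, _ = _draw_mvn_prec(A, b, rngs[0])
        parts = (draw[:p1], draw[p1:])
    else:
        parts = []
        for k in (0, 1):
            ve = state.sigma_e[k, k]
            A = W[k].T @ W[k] / ve
            A[np.diag_indices_from(A)] += 1.0 / pvar[k]
            b = W[k].T @ r[:, k] / ve
            d, _ = _draw_mvn_prec(A, b, rngs[k])
            parts.append(d)
    for k in (0, 1):
        state.beta_fixed[k] = parts[k][: data.n_fixed]
        state.beta_snv[k] = 0.0
        if act[k].size:
            state.beta_snv[k, act[k]] = parts[k][data.n_fixed:]
    return state


def update_snv_indicator(state: MCMCState, data: FitData, priors: PriorSpec,
                         g: int, k: int, rng, mode: str = "bivariate",
                         fitted: np.ndarray | None = None,
                         rand_eff: np.ndarray | None = None) -> MCMCState:
    """Collapsed spike-and-slab update of (gamma_gk, beta_gk).

    The slab coefficient is integrated out analytically against the trait-k
    residual likelihood, conditioning on the other trait's current residuals
    through Sigma_e; beta_gk is redrawn from its conditional normal when the
    indicator comes up active.
    """
    if priors.tau2 <= 0:
        raise ValueError("slab variance tau2 must be positive")
    rngs = _as_rng_pair(rng)
    F = _fitted(state, data) if fitted is None else fitted
    re = (state.p_fam[data.fam] + state.s_subj[data.subj]) if rand_eff is None else rand_eff
    ko = 1 - k
    x = data.S[:, g]
    old = state.gamma[k, g] * state.beta_snv[k, g]
    fk = F[:, k] - old * x
    r_k = data.y[:, k] - fk - re[:, k]
    if mode == "bivariate":
        c = state.sigma_e[k, ko] / state.sigma_e[ko, ko]
        v = state.sigma_e[k, k] - state.sigma_e[k, ko] ** 2 / state.sigma_e[ko, ko]
        e_other = data.y[:, ko] - F[:, ko] - re[:, ko]
        u = r_k - c * e_other
    else:
        v = state.sigma_e[k, k]
        u = r_k
    log_bf, m, var = snv_inclusion_moments(x, u, v, priors.tau2)
    q = state.q[k]
    log_odds = np.log(q) - np.log1p(-q) + log_bf
    include = rngs[k].random() < expit(log_odds)
    if include:
        beta = m + np.sqrt(var) * rngs[k].standard_normal()
        state.gamma[k, g] = 1
        state.beta_snv[k, g] = beta
    else:
        state.gamma[k, g] = 0
        state.beta_snv[k, g] = 0.0
        beta = 0.0
    if fitted is not None:
        fitted[:, k] = fk + beta * x
    return state


def update_inclusion_probability(state: MCMCState, priors: PriorSpec, rng,
                                 shared_q: bool = False) -> MCMCState:
    rngs = _as_rng_pair(rng)
    G = state.gamma.shape[1]
    if shared_q:
        a_post, b_post = inclusion_beta_params(
            int(state.gamma.sum()), 2 * G, priors.a, priors.b
        )
        q = rngs[0].beta(a_post, b_post)
        state.q[:] = q
    else:
        for k in (0, 1):
            a_post, b_post = inclusion_beta_params(
                int(state.gamma[k].sum()), G, priors.a, priors.b
            )
            state.q[k] = rngs[k].beta(a_post, b_post)
    return state


def _update_effects(levels: str, state: MCMCState, data: FitData, rng,
                    mode: str, fitted: np.ndarray | None) -> MCMCState:
    rngs = _as_rng_pair(rng)
    F = _fitted(state, data) if fitted is None else fitted
    if levels == "family":
        other = state.s_subj[data.subj]
        index, counts, prior = data.fam, data.fam_counts, state.sigma_p
        target, n_units = state.p_fam, data.n_fam
    else:
        other = state.p_fam[data.fam]
        index, counts, prior = data.subj, data.subj_counts, state.sigma_s
        target, n_units = state.s_subj, data.n_subj
    r = data.y - F - other
    sums = np.zeros((n_units, 2))
    np.add.at(sums, index, r)
    if mode == "bivariate":
        omega = _inv2(state.sigma_e)
        prior_prec = _inv2(prior)
        for c in np.unique(counts):
            sel = counts == c
            prec = prior_prec + c * omega
            cov = _inv2(prec)
            L = _chol_spd(cov)
            means = sums[sel] @ (cov @ omega).T
            target[sel] = means + rngs[0].standard_normal((sel.sum(), 2)) @ L.T
    else:
        for k in (0, 1):
            prec = 1.0 / prior[k, k] + counts / state.sigma_e[k, k]
            mean = (sums[:, k] / state.sigma_e[k, k]) / prec
            target[:, k] = mean + rngs[k].standard_normal(n_units) / np.sqrt(prec)
    return state


def update_family_effects(state, data, rng, mode="bivariate", fitted=None):
    """Exact bivariate-normal full-conditional draw of every family effect."""
    return _update_effects("family", state, data, rng, mode, fitted)


def update_subject_effects(state, data, rng, mode="bivariate", fitted=None):
    """Exact bivariate-normal full-conditional draw of every subject effect."""
    return _update_effects("subject", state, data, rng, mode, fitted)


def update_covariances(state: MCMCState, data: FitData, priors: PriorSpec, rng,
                       mode: str = "bivariate",
                       fitted: np.ndarray | None = None) -> MCMCState:
    """Conjugate inverse-Wishart draws of Sigma_p, Sigma_s, Sigma_e (bivariate
    mode) or per-trait inverse-gamma draws of the diagonals (univariate)."""
    rngs = _as_rng_pair(rng)
    F = _fitted(state, data) if fitted is None else fitted
    e = data.y - F - state.p_fam[data.fam] - state.s_subj[data.subj]
    groups = (
        ("sigma_p", state.p_fam),
        ("sigma_s", state.s_subj),
        ("sigma_e", e),
    )
    if mode == "bivariate":
        for name, vectors in groups:
            df, scale = iw_posterior_params(priors.nu0, priors.S0, vectors)
            setattr(state, name, invwishart_rvs(df, scale, rngs[0]))
    else:
        for name, vectors in groups:
            sig = np.zeros((2, 2))
            for k in (0, 1):
                shape = (priors.nu0 + vectors.shape[0]) / 2.0
                rate = (priors.S0[k, k] + float(vectors[:, k] @ vectors[:, k])) / 2.0
                sig[k, k] = rate / rngs[k].gamma(shape)
            setattr(state, name, sig)
    return state


# ---------------------------------------------------------------------------
# sweep and chain


def gibbs_sweep(state: MCMCState, data: FitData, priors: PriorSpec, rng,
                mode: str = "bivariate", shared_q: bool = False,
                update_covs: bool = True) -> MCMCState:
    """One fixed-scan sweep over all full conditionals."""
    update_regression_coefficients(state, data, priors, rng, mode=mode)
    fitted = _fitted(state, data)
    rand_eff = state.p_fam[data.fam] + state.s_subj[data.subj]
    for g in range(data.n_snvs):
        for k in (0, 1):
            update_snv_indicator(
                state, data, priors, g, k, rng, mode=mode,
                fitted=fitted, rand_eff=rand_eff,
            )
    update_inclusion_probability(state, priors, rng, shared_q=shared_q)
    update_family_effects(state, data, rng, mode=mode, fitted=fitted)
    update_subject_effects(state, data, rng, mode=mode, fitted=fitted)
    if update_covs:
        update_covariances(state, data, priors, rng, mode=mode, fitted=fitted)
    return state


@dataclass
class ChainSamples:
    """Thinned post-burn-in draws plus bookkeeping for PIP estimation."""

    gamma: np.ndarray        # (D, 2, G)
    beta_snv: np.ndarray     # (D, 2, G) working scale
    beta_fixed: np.ndarray   # (D, 2, p) working scale
    q: np.ndarray            # (D, 2)
    sigma_p: np.ndarray      # (D, 2, 2) working scale
    sigma_s: np.ndarray
    sigma_e: np.ndarray
    snv_ids: tuple[str, ...]
    fixed_names: tuple[str, ...]
    trait_names: tuple[str, str]
    y_mean: np.ndarray
    y_sd: np.ndarray
    mode: str
    seed: int
    n_iterations: int
    burn_in: int
    thinning: int

    @property
    def n_draws(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_snvs(self) -> int:
        return self.gamma.shape[2]

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            gamma=self.gamma, beta_snv=self.beta_snv, beta_fixed=self.beta_fixed,
            q=self.q, sigma_p=self.sigma_p, sigma_s=self.sigma_s,
            sigma_e=self.sigma_e, y_mean=self.y_mean, y_sd=self.y_sd,
            snv_ids=np.array(self.snv_ids), fixed_names=np.array(self.fixed_names),
            trait_names=np.array(self.trait_names),
            meta=np.array([self.seed, self.n_iterations, self.burn_in, self.thinning]),
            mode=np.array(self.mode),
        )

    @classmethod
    def load(cls, path) -> "ChainSamples":
        z = np.load(path, allow_pickle=False)
        seed, n_it, burn, thin = (int(v) for v in z["meta"])
        return cls(
            gamma=z["gamma"], beta_snv=z["beta_snv"], beta_fixed=z["beta_fixed"],
            q=z["q"], sigma_p=z["sigma_p"], sigma_s=z["sigma_s"],
            sigma_e=z["sigma_e"],
            snv_ids=tuple(str(s) for s in z["snv_ids"]),
            fixed_names=tuple(str(s) for s in z["fixed_names"]),
            trait_names=tuple(str(s) for s in z["trait_names"]),
            y_mean=z["y_mean"], y_sd=z["y_sd"], mode=str(z["mode"]),
            seed=seed, n_iterations=n_it, burn_in=burn, thinning=thin,
        )


def run_chain(data: ModelDataset | FitData, priors: PriorSpec,
              cfg: ChainConfig) -> ChainSamples:
    """Run the Gibbs sampler and collect thinned post-burn-in draws."""
    fit = data if isinstance(data, FitData) else FitData.from_dataset(
        data, standardize=cfg.standardize
    )
    priors = priors.resolve(fit.n_snvs)
    ss = np.random.SeedSequence(cfg.seed)
    if cfg.mode == "univariate":
        c1, c2 = ss.spawn(2)
        rng = (np.random.default_rng(c1), np.random.default_rng(c2))
    else:
        g = np.random.default_rng(ss)
        rng = (g, g)
    state = init_state(fit, priors, seed=cfg.seed)
    update_covs = cfg.fixed_sigmas is None
    if cfg.fixed_sigmas is not None:
        state.sigma_p = np.asarray(cfg.fixed_sigmas[0], dtype=float)
        state.sigma_s = np.asarray(cfg.fixed_sigmas[1], dtype=float)
        state.sigma_e = np.asarray(cfg.fixed_sigmas[2], dtype=float)

    D = cfg.n_draws
    G, p = fit.n_snvs, fit.n_fixed
    store = {
        "gamma": np.empty((D, 2, G), dtype=np.int8),
        "beta_snv": np.empty((D, 2, G)),
        "beta_fixed": np.empty((D, 2, p)),
        "q": np.empty((D, 2)),
        "sigma_p": np.empty((D, 2, 2)),
        "sigma_s": np.empty((D, 2, 2)),
        "sigma_e": np.empty((D, 2, 2)),
    }
    d = 0
    for it in range(1, cfg.n_iterations + 1):
        gibbs_sweep(state, fit, priors, rng, mode=cfg.mode,
                    shared_q=cfg.shared_q, update_covs=update_covs)
        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0:
            store["gamma"][d] = state.gamma
            store["beta_snv"][d] = state.beta_snv
            store["beta_fixed"][d] = state.beta_fixed
            store["q"][d] = state.q
            store["sigma_p"][d] = state.sigma_p
            store["sigma_s"][d] = state.sigma_s
            store["sigma_e"][d] = state.sigma_e
            d += 1
        if it % 5000 == 0:
            logger.info("sweep %d/%d (%d draws stored)", it, cfg.n_iterations, d)
    return ChainSamples(
        **store,
        snv_ids=fit.snv_ids, fixed_names=fit.fixed_names,
        trait_names=fit.trait_names, y_mean=fit.y_mean, y_sd=fit.y_sd,
        mode=cfg.mode, seed=cfg.seed, n_iterations=cfg.n_iterations,
        burn_in=cfg.burn_in, thinning=cfg.thinning,
    )


# ---------------------------------------------------------------------------
# log joint density (testing aid)


def log_joint(state: MCMCState, data: FitData, priors: PriorSpec,
              mode: str = "bivariate") -> float:
    """Unnormalized log posterior of the full hierarchy at ``state``."""
    priors = priors.resolve(data.n_snvs)
    total = 0.0
    e = data.y - _fitted(state, data) - state.p_fam[data.fam] - state.s_subj[data.subj]
    total += _mvn2_logpdf_rows(e, state.sigma_e)
    total += _mvn2_logpdf_rows(state.p_fam, state.sigma_p)
    total += _mvn2_logpdf_rows(state.s_subj, state.sigma_s)
    # coefficient priors
    total += _norm_logpdf(state.beta_fixed, priors.v0)
    active = state.gamma == 1
    total += _norm_logpdf(state.beta_snv[active], priors.tau2)
    # indicators and inclusion probability
    for k in (0, 1):
        n1 = int(state.gamma[k].sum())
        G = state.gamma.shape[1]
        total += n1 * np.log(state.q[k]) + (G - n1) * np.log1p(-state.q[k])
        total += _beta_logpdf(state.q[k], priors.a, priors.b)
    for m in (state.sigma_p, state.sigma_s, state.sigma_e):
        total += _invwishart_logpdf(m, priors.nu0, priors.S0, diag_only=(mode == "univariate"))
    return float(total)


def _mvn2_logpdf_rows(rows: np.ndarray, cov: np.ndarray) -> float:
    rows = np.atleast_2d(rows)
    omega = _inv2(cov)
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    quad = np.einsum("ni,ij,nj->", rows, omega, rows)
    n = rows.shape[0]
    return -0.5 * (quad + n * (np.log(det) + 2 * np.log(2 * np.pi)))


def _norm_logpdf(values: np.ndarray, var: float) -> float:
    v = np.ravel(values)
    return float(-0.5 * (v @ v / var + v.size * np.log(2 * np.pi * var)))


def _beta_logpdf(x: float, a: float, b: float) -> float:
    return float(
        (a - 1) * np.log(x) + (b - 1) * np.log1p(-x)
        + gammaln(a + b) - gammaln(a) - gammaln(b)
    )


def _invwishart_logpdf(m: np.ndarray, nu: float, S: np.ndarray,
                       diag_only: bool = False) -> float:
    if diag_only:
        # independent inverse-gamma priors on the diagonal
        total = 0.0
        for k in (0, 1):
            a, b = nu / 2.0, S[k, k] / 2.0
            x = m[k, k]
            total += a * np.log(b) - gammaln(a) - (a + 1) * np.log(x) - b / x
        return float(total)
    p = 2
    det_s = np.linalg.det(S)
    det_m = np.linalg.det(m)
    tr = np.trace(np.linalg.solve(m, S))
    lg2 = gammaln(nu / 2) + gammaln((nu - 1) / 2) + 0.5 * np.log(np.pi)
    return float(
        0.5 * nu * np.log(det_s) - 0.5 * nu * p * np.log(2) - lg2
        - 0.5 * (nu + p + 1) * np.log(det_m) - 0.5 * tr
    )
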