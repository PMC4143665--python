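"""Sampler self-validation utilities.

The joint-distribution (Geweke-style "getting it right") check compares two
ways of sampling from the same joint distribution p(parameters, data):

* marginal-conditional: draw parameters from the prior, then data given
  parameters — exact independent draws;
* successive-conditional: alternate one Gibbs sweep on the current data with
  re-simulation of the data given the current parameters — a Markov chain
  whose stationary distribution equals the same joint *only if every full
  conditional is correct*.

Matching means of many scalar functionals across the two arms is a sharp
detector of full-conditional bugs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampler import (
    FitData,
    MCMCState,
    PriorSpec,
    _fitted,
    gibbs_sweep,
    invwishart_rvs,
)


def draw_state_from_prior(data: FitData, priors: PriorSpec,
                          rng: np.random.Generator,
                          mode: str = "bivariate") -> MCMCState:
    """One exact draw of all latent quantities from the prior."""
    priors = priors.resolve(data.n_snvs)
    G, p = data.n_snvs, data.n_fixed
    if mode == "bivariate":
        sigma_p = invwishart_rvs(priors.nu0, priors.S0, rng)
        sigma_s = invwishart_rvs(priors.nu0, priors.S0, rng)
        sigma_e = invwishart_rvs(priors.nu0, priors.S0, rng)
    else:
        def diag_ig():
            m = np.zeros((2, 2))
            for k in (0, 1):
                m[k, k] = (priors.S0[k, k] / 2.0) / rng.gamma(priors.nu0 / 2.0)
            return m
        sigma_p, sigma_s, sigma_e = diag_ig(), diag_ig(), diag_ig()
    q = rng.beta(priors.a, priors.b, size=2)
    gamma = (rng.random((2, G)) < q[:, None]).astype(np.int8)
    beta_snv = gamma * rng.normal(0.0, np.sqrt(priors.tau2), size=(2, G))
    state = MCMCState(
        beta_fixed=rng.normal(0.0, np.sqrt(priors.v0), size=(2, p)),
        beta_snv=beta_snv,
        gamma=gamma,
        q=q,
        p_fam=rng.multivariate_normal(np.zeros(2), sigma_p, size=data.n_fam),
        s_subj=rng.multivariate_normal(np.zeros(2), sigma_s, size=data.n_subj),
        sigma_p=sigma_p,
        sigma_s=sigma_s,
        sigma_e=sigma_e,
    )
    return state


def simulate_response(state: MCMCState, data: FitData,
                      rng: np.random.Generator) -> None:
    """Re-draw data.y in place from the model given the current state."""
    e = rng.multivariate_normal(np.zeros(2), state.sigma_e, size=data.n_obs)
    data.y[:] = (
        _fitted(state, data)
        + state.p_fam[data.fam]
        + state.s_subj[data.subj]
        + e
    )


def default_functionals(data: FitData) -> dict:
    """Scalar summaries monitored by the joint-distribution test."""
    fns = {}
    for k in (0, 1):
        for j in range(data.n_fixed):
            fns[f"beta_fixed[{k},{j}]"] = (
                lambda s, k=k, j=j: s.beta_fixed[k, j]
            )
        fns[f"q[{k}]"] = lambda s, k=k: s.q[k]
    for name in ("sigma_p", "sigma_s", "sigma_e"):
        for (i, j) in ((0, 0), (1, 1), (0, 1)):
            fns[f"{name}[{i},{j}]"] = (
                lambda s, name=name, i=i, j=j: getattr(s, name)[i, j]
            )
    fns["p_fam[0,0]"] = lambda s: s.p_fam[0, 0]
    fns["s_subj[0,0]"] = lambda s: s.s_subj[0, 0]
    fns["mean_gamma"] = lambda s: float(s.gamma.mean())
    return fns


@dataclass
class GewekeResult:
    table: pd.DataFrame   # one row per functional: means, ses, z

    @property
    def max_abs_z(self) -> float:
        return float(self.table["z"].abs().max())


def geweke_joint_test(data: FitData, priors: PriorSpec, n_draws: int = 20000,
                      seed: int = 0, mode: str = "bivariate",
                      functionals: dict | None = None) -> GewekeResult:
    """Run both simulators and z-score each monitored functional."""
    priors = priors.resolve(data.n_snvs)
    fns = functionals or default_functionals(data)
    names = list(fns)
    ss = np.random.SeedSequence(seed)
    s1, s2 = ss.spawn(2)

    # marginal-conditional arm: iid prior draws (data plays no role)
    rng1 = np.random.default_rng(s1)
    mc = np.empty((n_draws, len(names)))
    for d in range(n_draws):
        st = draw_state_from_prior(data, priors, rng1, mode=mode)
        mc[d] = [fns[n](st) for n in names]

    # successive-conditional arm: Gibbs sweep + data re-simulation
    rng2 = np.random.default_rng(s2)
    gibbs_rng = (rng2, rng2) if mode == "bivariate" else tuple(
        np.random.default_rng(c) for c in s2.spawn(2)
    )
    state = draw_state_from_prior(data, priors, rng2, mode=mode)
    simulate_response(state, data, rng2)
    sc = np.empty((n_draws, len(names)))
    for d in range(n_draws):
        gibbs_sweep(state, data, priors, gibbs_rng, mode=mode)
        simulate_response(state, data, rng2)
        sc[d] = [fns[n](state) for n in names]

    rows = []
    for j, name in enumerate(names):
        m1, m2 = mc[:, j].mean(), sc[:, j].mean()
        se1 = mc[:, j].std(ddof=1) / np.sqrt(n_draws)
        se2 = _batch_se(sc[:, j])
        z = (m1 - m2) / np.hypot(se1, se2)
        rows.append((name, m1, m2, se1, se2, z))
    table = pd.DataFrame(
        rows, columns=["functional", "mean_mc", "mean_sc", "se_mc", "se_sc", "z"]
    )
    return GewekeResult(table=table)


def _batch_se(x: np.ndarray, n_batches: int = 50) -> float:
    """Batch-means standard error for an autocorrelated sequence."""
    n = x.size
    bs = n // n_batches
    means = x[: bs * n_batches].reshape(n_batches, bs).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))
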