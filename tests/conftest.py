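"""Shared fixtures and scenario builders."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pedsur.sampler import ChainSamples, FitData
from pedsur.simulate import FamilyTemplate, SimConfig


@pytest.fixture
def trio_fam_text():
    return "fam1 dad 0 0 1\nfam1 mom 0 0 2\nfam1 kid dad mom 1\n"


def micro_design(seed: int = 42, n_fam: int = 2, n_subj_per: int = 3,
                 n_vis: int = 2, G: int = 2) -> FitData:
    """Tiny balanced design with dosage-like SNV columns and zero response."""
    rng = np.random.default_rng(seed)
    subj_fam = np.repeat(np.arange(n_fam), n_subj_per)
    subj = np.repeat(np.arange(n_fam * n_subj_per), n_vis)
    fam = subj_fam[subj]
    n = subj.size
    C = np.column_stack([np.ones(n), rng.normal(size=n)])
    S = rng.binomial(2, 0.4, size=(n_fam * n_subj_per, G)).astype(float)[subj]
    S = S - S.mean(axis=0)
    return FitData(np.zeros((n, 2)), C, S, fam, subj, subj_fam)


def recovery_config(G: int = 10, causal: tuple[int, ...] = (0, 1),
                    betas: tuple = ((-9.0, -10.0), (8.0, 9.0)),
                    maf_causal: float = 0.04) -> SimConfig:
    """20 multigenerational families, 3 visits, a few strong rare causal SNVs.

    Variance components give a familial ICC of ~0.1 and within-subject
    repeatability ~0.45 on each trait, moderate for adjusted BP-like traits.
    """
    effects = np.zeros((2, G))
    for idx, (b1, b2) in zip(causal, betas):
        effects[0, idx] = b1
        effects[1, idx] = b2
    mafs = np.full(G, 0.2)
    mafs[list(causal)] = maf_causal
    return SimConfig(
        n_families=20,
        template=FamilyTemplate(offspring_range=(2, 4), generations=2),
        n_visits=3,
        mafs=mafs,
        effects=effects,
        sigma_p=(2.0, 2.5),
        sigma_s=(3.0, 3.5),
        sigma_e=(4.0, 4.5),
        rho_p=0.4, rho_s=0.4, rho_e=0.4,
    )


def null_config(G: int = 30, n_families: int = 20,
                rho: float = 0.4) -> SimConfig:
    """All-noise scenario: no genetic effects at all."""
    return SimConfig(
        n_families=n_families,
        template=FamilyTemplate(offspring_range=(2, 3), generations=2),
        n_visits=3,
        mafs=np.full(G, 0.2),
        effects=np.zeros((2, G)),
        sigma_p=(2.0, 2.5),
        sigma_s=(3.0, 3.5),
        sigma_e=(4.0, 4.5),
        rho_p=rho, rho_s=rho, rho_e=rho,
    )


def fake_samples(gamma: np.ndarray, beta_snv: np.ndarray | None = None,
                 y_sd=(1.0, 1.0)) -> ChainSamples:
    """ChainSamples with prescribed indicator/coefficient draws."""
    gamma = np.asarray(gamma, dtype=np.int8)
    D, _, G = gamma.shape
    if beta_snv is None:
        beta_snv = gamma.astype(float)
    return ChainSamples(
        gamma=gamma,
        beta_snv=np.asarray(beta_snv, dtype=float),
        beta_fixed=np.zeros((D, 2, 1)),
        q=np.full((D, 2), 0.1),
        sigma_p=np.tile(np.eye(2), (D, 1, 1)),
        sigma_s=np.tile(np.eye(2), (D, 1, 1)),
        sigma_e=np.tile(np.eye(2), (D, 1, 1)),
        snv_ids=tuple(f"snv{j + 1:03d}" for j in range(G)),
        fixed_names=("intercept",),
        trait_names=("trait1", "trait2"),
        y_mean=np.zeros(2),
        y_sd=np.asarray(y_sd, dtype=float),
        mode="bivariate",
        seed=0,
        n_iterations=D,
        burn_in=0,
        thinning=1,
    )
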