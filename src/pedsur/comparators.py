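"""Baseline analyses: the Bayesian univariate model and a measured-genotype
style single-SNV mixed-model scan.

``run_univariate`` refits the same hierarchy with all cross-trait covariances
constrained to zero, so the two traits are analyzed independently (still
longitudinal, still multi-SNV with multiplicity control).

``mga_scan`` is a behavioral stand-in for the classical family-based measured
genotype approach: one trait, one SNV at a time, first-visit measurements
only, a linear mixed model with a family random intercept fit by maximum
likelihood, and a 1-df likelihood-ratio test per SNV, followed by Bonferroni
correction. It uses a family random intercept (as does the Bayesian model
here) rather than a kinship-matrix polygenic term.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sampler import ChainConfig, ChainSamples, PriorSpec, run_chain
from .types import ModelDataset

logger = logging.getLogger(__name__)


def run_univariate(data: ModelDataset, priors: PriorSpec,
                   cfg: ChainConfig) -> ChainSamples:
    """The Bayesian univariate comparator (diagonal covariance matrices)."""
    cfg = ChainConfig(
        n_iterations=cfg.n_iterations, burn_in=cfg.burn_in, thinning=cfg.thinning,
        seed=cfg.seed, mode="univariate", shared_q=cfg.shared_q,
        standardize=cfg.standardize, fixed_sigmas=cfg.fixed_sigmas,
    )
    return run_chain(data, priors, cfg)


@dataclass
class ScanResult:
    table: pd.DataFrame            # snv_id, trait, beta, se, stat, p
    trait: str
    alpha: float | None = None
    n_tests: int | None = None
    threshold: float | None = None

    @property
    def selected(self) -> set[str]:
        if self.threshold is None:
            return set()
        t = self.table
        return set(t.loc[t["p"].notna() & (t["p"] <= self.threshold), "snv_id"])


def mga_scan(data: ModelDataset, visit: str = "first", trait: int = 0,
             snv_ids: tuple[str, ...] | None = None) -> ScanResult:
    """Single-SNV mixed-model scan with a family random intercept.

    Each SNV is tested by comparing maximum-likelihood fits of the trait on
    the fixed covariates with vs without the SNV dosage; the p-value is the
    1-df likelihood-ratio test. ``visit="first"`` keeps each subject's first
    measurement only (the classical single-measurement analysis);
    ``visit="all"`` uses every row (with the family intercept still the only
    random term).
    """
    import statsmodels.api as sm

    if visit == "first":
        first = np.zeros(data.n_obs, dtype=bool)
        seen: set[int] = set()
        order = np.lexsort((data.visit, data.subj_idx))
        for i in order:
            if data.subj_idx[i] not in seen:
                seen.add(int(data.subj_idx[i]))
                first[i] = True
        mask = first
    elif visit == "all":
        mask = np.ones(data.n_obs, dtype=bool)
    else:
        raise ValueError("visit must be 'first' or 'all'")

    y = data.y[mask, trait]
    X0 = data.fixed[mask]
    groups = data.fam_idx[mask]
    ids = snv_ids or data.snv_ids

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null_fit = sm.MixedLM(y, X0, groups=groups).fit(reml=False)
    rows = []
    for sid in ids:
        g = data.snv_ids.index(sid)
        x = data.snv[mask, g]
        if np.var(x) == 0.0:
            logger.warning("SNV %r has zero dosage variance; skipped", sid)
            rows.append((sid, data.trait_names[trait], np.nan, np.nan, np.nan, np.nan))
            continue
        X1 = np.column_stack([X0, x])
        if np.linalg.matrix_rank(X1) <= np.linalg.matrix_rank(X0):
            logger.warning("SNV %r is collinear with the covariates; skipped", sid)
            rows.append((sid, data.trait_names[trait], np.nan, np.nan, np.nan, np.nan))
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.MixedLM(y, X1, groups=groups).fit(reml=False)
            lrt = max(0.0, 2.0 * (fit.llf - null_fit.llf))
            p = float(stats.chi2.sf(lrt, df=1))
            beta = float(fit.fe_params[-1])
            se = float(fit.bse_fe[-1])
        except (np.linalg.LinAlgError, ValueError) as err:
            logger.warning("SNV %r: mixed-model fit failed (%s)", sid, err)
            beta = se = lrt = p = np.nan
        rows.append((sid, data.trait_names[trait], beta, se, lrt, p))
    table = pd.DataFrame(
        rows, columns=["snv_id", "trait", "beta", "se", "stat", "p"]
    )
    return ScanResult(table=table, trait=data.trait_names[trait])


def bonferroni_select(scan: ScanResult, alpha: float, n_tests: int) -> ScanResult:
    """Apply the Bonferroni threshold alpha / n_tests to a scan."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n_p = int(scan.table["p"].notna().sum())
    if n_tests < n_p:
        raise ValueError(f"n_tests={n_tests} smaller than the {n_p} computed p-values")
    return ScanResult(
        table=scan.table, trait=scan.trait, alpha=alpha, n_tests=n_tests,
        threshold=alpha / n_tests,
    )
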