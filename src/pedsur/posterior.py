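"""Posterior summaries: inclusion probabilities, model selection, error
accounting, coefficient summaries, and stability diagnostics.

The posterior inclusion probability (PIP) of SNV g for trait k is the
frequency of gamma_gk = 1 across the models visited by the chain; the median
probability model selects every (SNV, trait) pair with PIP >= 0.5. Monte
Carlo standard errors use non-overlapping batch means.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampler import ChainSamples
from .simulate import SimulationTruth


def _batch_se(x: np.ndarray, n_batches: int = 20) -> float:
    n = x.shape[0]
    if n < n_batches:
        n_batches = max(2, n)
    bs = n // n_batches
    means = x[: bs * n_batches].reshape(n_batches, bs, *x.shape[1:]).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def inclusion_probabilities(samples: ChainSamples, n_batches: int = 20) -> pd.DataFrame:
    """PIP table: one row per (SNV, trait) with PIP, MC-SE, and the posterior
    exclusion probability 1 - PIP."""
    if samples.n_draws < 1:
        raise ValueError("empty chain: no stored draws")
    rows = []
    for k, trait in enumerate(samples.trait_names):
        for g, sid in enumerate(samples.snv_ids):
            seq = samples.gamma[:, k, g].astype(float)
            pip = float(seq.mean())
            rows.append((sid, trait, pip, _batch_se(seq, n_batches), 1.0 - pip))
    return pd.DataFrame(
        rows, columns=["snv_id", "trait", "pip", "mcse", "exclusion_prob"]
    )


@dataclass
class SelectionResult:
    selected: dict              # trait -> set of snv ids
    threshold: float
    tp: dict | None = None      # trait -> count, filled by confusion_counts
    fp: dict | None = None
    fn: dict | None = None
    tp_ids: dict | None = None
    fp_ids: dict | None = None

    def n_selected(self) -> int:
        return sum(len(v) for v in self.selected.values())

    def to_dict(self) -> dict:
        out = {
            "threshold": self.threshold,
            "selected": {t: sorted(v) for t, v in self.selected.items()},
        }
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) is not None:
                out[name] = getattr(self, name)
        return out


def median_probability_model(pips: pd.DataFrame, threshold: float = 0.5) -> SelectionResult:
    """Select every (SNV, trait) with PIP >= threshold (ties included)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    selected = {
        trait: set(sub.loc[sub["pip"] >= threshold, "snv_id"])
        for trait, sub in pips.groupby("trait", sort=False)
    }
    return SelectionResult(selected=selected, threshold=threshold)


def confusion_counts(sel: SelectionResult, truth: SimulationTruth,
                     trait_names: tuple[str, str] | None = None) -> SelectionResult:
    """Fill TP/FP/FN counts against a simulation truth, per trait."""
    universe = set(truth.snv_ids)
    names = trait_names or tuple(sel.selected)
    sel.tp, sel.fp, sel.fn = {}, {}, {}
    sel.tp_ids, sel.fp_ids = {}, {}
    for k, trait in enumerate(names):
        chosen = sel.selected.get(trait, set())
        unknown = chosen - universe
        if unknown:
            raise ValueError(f"selected SNVs unknown to the truth set: {sorted(unknown)}")
        causal = set(truth.causal_sets[k])
        sel.tp_ids[trait] = chosen & causal
        sel.fp_ids[trait] = chosen - causal
        sel.tp[trait] = len(chosen & causal)
        sel.fp[trait] = len(chosen - causal)
        sel.fn[trait] = len(causal - chosen)
    return sel


def coefficient_summaries(samples: ChainSamples, raw_scale: bool = True) -> pd.DataFrame:
    """Per-(SNV, trait) coefficient summaries.

    Primary summaries condition on inclusion (draws with gamma=1 only): mean,
    SD, central 95% interval, and the number of conditioning draws. The
    model-averaged (unconditional) mean is also reported. With ``raw_scale``
    the working-scale coefficients are mapped back to the original trait
    units (multiplied by the trait SD used for standardization).
    """
    if samples.n_draws < 1:
        raise ValueError("empty chain: no stored draws")
    rows = []
    for k, trait in enumerate(samples.trait_names):
        scale = samples.y_sd[k] if raw_scale else 1.0
        for g, sid in enumerate(samples.snv_ids):
            inc = samples.gamma[:, k, g] == 1
            n_inc = int(inc.sum())
            pip = float(inc.mean())
            avg = float((samples.gamma[:, k, g] * samples.beta_snv[:, k, g]).mean()) * scale
            if n_inc == 0:
                rows.append((sid, trait, pip, 1.0 - pip, 0, None, None, None, None,
                             avg, "no-inclusion"))
                continue
            b = samples.beta_snv[inc, k, g] * scale
            lo, hi = np.percentile(b, [2.5, 97.5])
            sd = float(b.std(ddof=1)) if n_inc > 1 else 0.0
            rows.append((sid, trait, pip, 1.0 - pip, n_inc, float(b.mean()), sd,
                         float(lo), float(hi), avg, "ok"))
    return pd.DataFrame(
        rows,
        columns=["snv_id", "trait", "pip", "exclusion_prob", "n_included",
                 "cond_mean", "cond_sd", "ci_lower", "ci_upper",
                 "model_avg_mean", "flag"],
    )


@dataclass
class StabilityTrace:
    """Cumulative PIP after each chain segment, per (trait, SNV)."""

    cumulative: np.ndarray   # (n_segments, 2, G)
    snv_ids: tuple[str, ...]
    trait_names: tuple[str, str]

    def max_final_half_drift(self) -> float:
        """Largest absolute change of any cumulative PIP over the final half
        of the segment sequence."""
        half = self.cumulative[self.cumulative.shape[0] // 2:]
        return float(np.abs(np.diff(half, axis=0)).max()) if half.shape[0] > 1 else 0.0


def pip_stability(samples: ChainSamples, n_segments: int = 10) -> StabilityTrace:
    """Cumulative-PIP trace showing how early the estimates settle."""
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    D = samples.n_draws
    bounds = np.linspace(D / n_segments, D, n_segments).round().astype(int)
    csum = samples.gamma.astype(float).cumsum(axis=0)
    cum = np.stack([csum[b - 1] / b for b in bounds])
    return StabilityTrace(
        cumulative=cum, snv_ids=samples.snv_ids, trait_names=samples.trait_names
    )
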