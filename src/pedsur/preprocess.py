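"""Phenotype adjustment and genotype hygiene utilities.

Blood-pressure traits measured under antihypertensive treatment understate the
untreated value. The adjustment used here imputes the no-medication value by
adding back the observation-level mean treatment difference estimated among
hypertensive observations: delta = mean(BP | htn=1, med=1) - mean(BP | htn=1,
med=0), and adjusted = observed - delta for rows with htn=1 and med=1. Stratum
means pool all visits and subjects (observation-level means). Each trait is
adjusted independently with its own delta.

Also here: minor-allele-frequency and composite (genotype-correlation) LD
utilities used for false-positive accounting.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import GenotypeError, GenotypeMatrix, PhenotypeError, PhenotypeTable


@dataclass(frozen=True)
class MedAdjustmentReport:
    trait: str
    delta: float | None       # None when no rows needed adjustment
    n_htn_med1: int
    n_htn_med0: int
    n_adjusted: int
    pooling: str = "observation-level means pooled over visits and subjects"

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "delta": self.delta,
            "n_htn_med1": self.n_htn_med1,
            "n_htn_med0": self.n_htn_med0,
            "n_adjusted": self.n_adjusted,
            "pooling": self.pooling,
        }


def adjust_for_medication(
    pheno: PhenotypeTable, trait: int
) -> tuple[PhenotypeTable, MedAdjustmentReport]:
    """Impute untreated trait values for medicated hypertensive observations.

    Only rows with htn=1 and med=1 are modified. If no such rows exist the
    table is returned unchanged (delta is then undefined).
    """
    if pheno.htn_col is None or pheno.med_col is None:
        raise PhenotypeError("phenotype table has no htn/med flag columns")
    col = pheno.trait_cols[trait]
    df = pheno.data
    htn = df[pheno.htn_col].astype(float) == 1
    med = df[pheno.med_col].astype(float) == 1
    target = htn & med & ~df[col].isna()
    control = htn & ~med & ~df[col].isna()

    if int(target.sum()) == 0:
        report = MedAdjustmentReport(
            trait=col, delta=None, n_htn_med1=0, n_htn_med0=int(control.sum()),
            n_adjusted=0,
        )
        return pheno, report
    if int(control.sum()) == 0:
        raise PhenotypeError(
            f"cannot estimate medication effect for {col!r}: no htn=1, med=0 observations"
        )

    delta = float(df.loc[target, col].mean() - df.loc[control, col].mean())
    out = df.copy()
    out.loc[target, col] = out.loc[target, col] - delta
    adjusted = PhenotypeTable(
        data=out, trait_cols=pheno.trait_cols, x_cols=pheno.x_cols,
        z_cols=pheno.z_cols, htn_col=pheno.htn_col, med_col=pheno.med_col,
    )
    report = MedAdjustmentReport(
        trait=col, delta=delta, n_htn_med1=int(target.sum()),
        n_htn_med0=int(control.sum()), n_adjusted=int(target.sum()),
    )
    return adjusted, report


def adjust_both_traits(
    pheno: PhenotypeTable,
) -> tuple[PhenotypeTable, list[MedAdjustmentReport]]:
    reports = []
    for k in (0, 1):
        pheno, rep = adjust_for_medication(pheno, k)
        reports.append(rep)
    return pheno, reports


def maf(geno: GenotypeMatrix, snv: str) -> float:
    """Folded minor-allele frequency of one SNV, ignoring missing dosages."""
    col = geno.column(snv)
    col = col[~np.isnan(col)]
    if col.size == 0:
        raise GenotypeError(f"SNV {snv!r} has no non-missing dosages")
    f = float(col.sum()) / (2.0 * col.size)
    return min(f, 1.0 - f)


def ld_r2(geno: GenotypeMatrix, snv_a: str, snv_b: str) -> float:
    """Composite LD: squared Pearson correlation of dosage vectors.

    Phase-free; computed on the shared non-missing subject set.
    """
    a = geno.column(snv_a)
    b = geno.column(snv_b)
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    for name, v in ((snv_a, a), (snv_b, b)):
        if v.size == 0 or np.var(v) == 0.0:
            raise GenotypeError(f"SNV {name!r} has zero dosage variance")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def discount_ld_false_positives(
    selected_noise: set[str],
    selected_true: set[str],
    geno: GenotypeMatrix,
    threshold: float = 0.8,
) -> tuple[set[str], set[str]]:
    """Partition false positives into LD-explained vs unexplained.

    A selected noise SNV is LD-explained when its maximum r-squared with any
    selected true positive reaches ``threshold``; such selections are indirect
    effects of real signals rather than genuine errors.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("LD threshold must be in (0, 1]")
    explained, unexplained = set(), set()
    for fp in selected_noise:
        hit = any(ld_r2(geno, fp, tp) >= threshold for tp in selected_true)
        (explained if hit else unexplained).add(fp)
    return explained, unexplained
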