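"""File intake/output and dataset assembly.

Formats: PLINK-style FAM for pedigrees, plain VCF (GT field) or a dosage CSV
for genotypes, long CSV for phenotypes, YAML for analysis configuration.
All readers are strict: identifier problems are hard errors, and any row
dropped intentionally is logged and counted.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    AssemblyError,
    GenotypeError,
    GenotypeMatrix,
    ModelDataset,
    PedigreeError,
    PedigreeSet,
    PhenotypeError,
    PhenotypeTable,
)

logger = logging.getLogger(__name__)

DEFAULT_SCHEMA = {
    "family_id": "family_id",
    "individual_id": "individual_id",
    "visit": "visit",
}


# ---------------------------------------------------------------------------
# pedigree


def read_pedigree(path) -> PedigreeSet:
    """Read a whitespace-delimited FAM file (5 or 6 columns; 6th ignored)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) not in (5, 6):
                raise PedigreeError(
                    f"{path}:{ln}: expected 5 or 6 whitespace-delimited columns, "
                    f"got {len(parts)}"
                )
            rows.append(parts[:5])
    if not rows:
        raise PedigreeError(f"{path}: empty pedigree file")
    df = pd.DataFrame(
        rows, columns=["family_id", "individual_id", "father_id", "mother_id", "sex"]
    )
    return PedigreeSet.from_table(df)


def write_pedigree(ped: PedigreeSet, path) -> None:
    with open(path, "w") as fh:
        for r in ped.table.itertuples():
            fh.write(
                f"{r.family_id}\t{r.individual_id}\t{r.father_id or '0'}\t"
                f"{r.mother_id or '0'}\t{r.sex}\t-9\n"
            )


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes_long(
    path,
    trait_cols: tuple[str, str],
    x_cols: tuple[str, ...] = (),
    z_cols: tuple[str, ...] = (),
    htn_col: str | None = None,
    med_col: str | None = None,
    schema: dict | None = None,
) -> PhenotypeTable:
    """Read a long-format phenotype CSV.

    ``schema`` maps canonical id column names (family_id, individual_id,
    visit) to the file's column names when they differ.
    """
    df = pd.read_csv(path)
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    rename = {v: k for k, v in schema.items() if v != k}
    df = df.rename(columns=rename)
    return PhenotypeTable.from_frame(
        df, trait_cols=trait_cols, x_cols=x_cols, z_cols=z_cols,
        htn_col=htn_col, med_col=med_col,
    )


def write_phenotypes_long(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, fmt: str = "vcf") -> GenotypeMatrix:
    """Read dosages from a VCF (ALT-allele count from GT) or a dosage CSV."""
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "dosage_csv":
        return _read_dosage_csv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = tuple(vcf.samples)
    cols, ids, positions, alleles = [], [], [], []
    for var in vcf:
        dos = np.empty(len(subjects))
        for i, gt in enumerate(var.genotypes):
            a = [x for x in gt[:2] if x >= 0]
            dos[i] = np.nan if len(a) < 2 else float(sum(1 for x in a if x > 0))
        cols.append(dos)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)
        alleles.append((var.REF, var.ALT[0] if var.ALT else "."))
    vcf.close()
    if not cols:
        raise GenotypeError(f"{path}: no variant records")
    return GenotypeMatrix(
        dosages=np.column_stack(cols),
        subject_ids=subjects,
        snv_ids=tuple(ids),
        positions=tuple(positions),
        alleles=tuple(alleles),
    )


def write_vcf(geno: GenotypeMatrix, path, chrom: str = "3") -> None:
    """Write dosages as an unphased plain-text VCF (heterozygote coded 0/1)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.subject_ids) + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, sid in enumerate(geno.snv_ids):
            pos = geno.positions[j] if geno.positions else j + 1
            ref, alt = geno.alleles[j] if geno.alleles else ("A", "C")
            gts = "\t".join(
                "./." if np.isnan(d) else gt_map[d] for d in geno.dosages[:, j]
            )
            fh.write(f"{chrom}\t{pos}\t{sid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def _read_dosage_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path)
    subj_col = df.columns[0]
    subjects = tuple(str(s) for s in df[subj_col])
    snv_ids = tuple(df.columns[1:])
    d = df[list(snv_ids)].to_numpy(dtype=float)
    ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise GenotypeError(
            f"{path}: dosage {d[i, j]!r} for subject {subjects[i]!r}, "
            f"SNV {snv_ids[j]!r} outside {{0,1,2,missing}}"
        )
    return GenotypeMatrix(dosages=d, subject_ids=subjects, snv_ids=snv_ids)


def write_dosage_csv(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.dosages, columns=list(geno.snv_ids))
    df.insert(0, "individual_id", list(geno.subject_ids))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# assembly


def assemble_dataset(
    ped: PedigreeSet,
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    snv_subset: tuple[str, ...] | None = None,
    drop_ungenotyped: bool = False,
    missing_dosage: str = "error",
) -> ModelDataset:
    """Cross-resolve ids and build the model's aligned arrays.

    Subjects are matched between the genotype matrix and the pedigree by
    individual id, which must therefore be globally unique. Monomorphic SNV
    columns are dropped with a warning. Individuals with genotypes but no
    phenotype rows remain in the pedigree but contribute no likelihood rows.
    """
    iid_counts = ped.table["individual_id"].value_counts()
    if (iid_counts > 1).any():
        bad = iid_counts[iid_counts > 1].index[0]
        raise AssemblyError(
            f"individual id {bad!r} occurs in more than one family; genotype "
            "matching requires globally unique individual ids"
        )
    ped_iids = set(ped.table["individual_id"])
    for sid in geno.subject_ids:
        if sid not in ped_iids:
            logger.warning("genotyped subject %r absent from pedigree", sid)

    t1, t2 = pheno.trait_cols
    obs = pheno.data[~pheno.data[t1].isna()].copy()
    covar_cols = list(pheno.x_cols) + list(pheno.z_cols)
    if covar_cols and obs[covar_cols].isna().any().any():
        bad = [c for c in covar_cols if obs[c].isna().any()]
        raise AssemblyError(
            f"missing values in covariates {bad}; covariate imputation is not performed"
        )

    geno_index = {sid: i for i, sid in enumerate(geno.subject_ids)}
    keep_rows, dropped_subjects = [], set()
    for r in obs.itertuples():
        iid = r.individual_id
        if iid not in ped_iids:
            raise AssemblyError(f"phenotyped individual {iid!r} not in pedigree")
        if iid not in geno_index:
            if drop_ungenotyped:
                dropped_subjects.add(iid)
                keep_rows.append(False)
                continue
            raise AssemblyError(
                f"individual {iid!r} has phenotypes but no genotypes "
                "(pass drop_ungenotyped=True to drop such subjects)"
            )
        keep_rows.append(True)
    if dropped_subjects:
        logger.warning(
            "dropped %d phenotyped-but-ungenotyped subjects (%d rows)",
            len(dropped_subjects), int(np.sum(~np.asarray(keep_rows))),
        )
    obs = obs[np.asarray(keep_rows, dtype=bool)]
    if obs.empty:
        raise AssemblyError("no usable observation rows after cross-resolution")

    snv_ids = list(snv_subset) if snv_subset is not None else list(geno.snv_ids)
    snv_pos = dict(zip(geno.snv_ids, geno.positions)) if geno.positions else None
    cols = np.column_stack([geno.column(s) for s in snv_ids])
    subj_rows = np.array([geno_index[iid] for iid in obs["individual_id"]])

    # monomorphism filter on the analysis subjects
    sub = cols[np.unique(subj_rows)]
    keep = []
    for j, sid in enumerate(snv_ids):
        col = sub[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0 or np.all(col == col[0]):
            logger.warning("SNV %r is monomorphic among analysis subjects; dropped", sid)
            continue
        keep.append(j)
    snv_ids = [snv_ids[j] for j in keep]
    cols = cols[:, keep]

    snv_obs = cols[subj_rows]
    if np.isnan(snv_obs).any():
        if missing_dosage == "mean":
            col_means = np.nanmean(cols[np.unique(subj_rows)], axis=0)
            nan_i, nan_j = np.where(np.isnan(snv_obs))
            snv_obs[nan_i, nan_j] = col_means[nan_j]
            logger.warning("mean-imputed %d missing dosages", len(nan_i))
        else:
            raise AssemblyError(
                "missing dosages among analysis subjects; set missing_dosage='mean' "
                "to mean-impute"
            )

    fam_ids = tuple(dict.fromkeys(obs["family_id"]))
    fam_index = {f: i for i, f in enumerate(fam_ids)}
    subj_keys = tuple(dict.fromkeys(zip(obs["family_id"], obs["individual_id"])))
    subj_index = {k: i for i, k in enumerate(subj_keys)}

    fixed = np.column_stack(
        [np.ones(len(obs))] + [obs[c].to_numpy(dtype=float) for c in covar_cols]
    )
    return ModelDataset(
        y=obs[[t1, t2]].to_numpy(dtype=float),
        fixed=fixed,
        fixed_names=("intercept", *covar_cols),
        snv=snv_obs,
        snv_ids=tuple(snv_ids),
        fam_idx=np.array([fam_index[f] for f in obs["family_id"]]),
        subj_idx=np.array(
            [subj_index[(f, i)] for f, i in zip(obs["family_id"], obs["individual_id"])]
        ),
        subj_fam=np.array([fam_index[f] for f, _ in subj_keys]),
        visit=obs["visit"].to_numpy(dtype=int),
        family_ids=fam_ids,
        subject_keys=subj_keys,
        trait_names=pheno.trait_cols,
        snv_positions=tuple(snv_pos[s] for s in snv_ids) if snv_pos else None,
    )


# ---------------------------------------------------------------------------
# configuration and manifests


@dataclass
class AnalysisConfig:
    """YAML-loadable analysis configuration."""

    trait_cols: tuple[str, str]
    x_cols: tuple[str, ...] = ()
    z_cols: tuple[str, ...] = ()
    htn_col: str | None = None
    med_col: str | None = None
    snv_subset: tuple[str, ...] | None = None
    priors: dict = field(default_factory=dict)
    chain: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["trait_cols"] = tuple(raw["trait_cols"])
        for key in ("x_cols", "z_cols"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if raw.get("snv_subset") is not None:
            raw["snv_subset"] = tuple(raw["snv_subset"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()},
                fh,
            )


def write_manifest(path, inputs: dict, seed: int | None = None) -> None:
    """Versioned run manifest: input paths with content hashes, config, seed."""
    from . import __version__

    entries = {}
    for name, p in inputs.items():
        p = Path(p)
        h = hashlib.sha256(p.read_bytes()).hexdigest()[:16] if p.is_file() else None
        entries[name] = {"path": str(p), "sha256_16": h}
    manifest = {
        "pedsur_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "inputs": entries,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
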