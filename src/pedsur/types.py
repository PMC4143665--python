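"""Core data containers.

The analysis joins three sources: a pedigree (family structure), a long-format
longitudinal phenotype table with two traits, and a dosage matrix of candidate
SNVs. Each container validates its own invariants on construction;
:func:`pedsur.io_core.assemble_dataset` cross-links them into a
:class:`ModelDataset` ready for model fitting.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_PARENT_CODES = {"0", "", "nan", "none", "na", "."}

PED_COLUMNS = ["family_id", "individual_id", "father_id", "mother_id", "sex"]


class PedigreeError(ValueError):
    """Invalid pedigree structure."""


class PhenotypeError(ValueError):
    """Invalid phenotype table."""


class GenotypeError(ValueError):
    """Invalid genotype data."""


class AssemblyError(ValueError):
    """Pedigree, phenotype and genotype sources do not cross-resolve."""


def _norm_parent(value) -> str | None:
    s = str(value).strip()
    return None if s.lower() in MISSING_PARENT_CODES else s


@dataclass(frozen=True)
class PedigreeSet:
    """A collection of families with parent links.

    ``table`` has columns family_id, individual_id, father_id, mother_id
    (``None`` for founders), sex (1 male, 2 female, 0 unknown) and the derived
    boolean ``is_founder``.
    """

    table: pd.DataFrame

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "PedigreeSet":
        df = df.copy()
        missing = [c for c in PED_COLUMNS if c not in df.columns]
        if missing:
            raise PedigreeError(f"pedigree table missing columns: {missing}")
        for col in ("family_id", "individual_id"):
            df[col] = df[col].astype(str)
        df["father_id"] = [_norm_parent(v) for v in df["father_id"]]
        df["mother_id"] = [_norm_parent(v) for v in df["mother_id"]]
        df["sex"] = [int(s) if str(s) in {"1", "2"} else 0 for s in df["sex"]]

        dup = df.duplicated(subset=["family_id", "individual_id"])
        if dup.any():
            bad = df.loc[dup, ["family_id", "individual_id"]].iloc[0]
            raise PedigreeError(
                f"duplicate individual id {bad.individual_id!r} in family {bad.family_id!r}"
            )

        for fid, fam in df.groupby("family_id", sort=False):
            members = set(fam["individual_id"])
            parents: dict[str, list[str]] = {}
            for row in fam.itertuples():
                pp = []
                for pid in (row.father_id, row.mother_id):
                    if pid is not None:
                        if pid not in members:
                            raise PedigreeError(
                                f"parent {pid!r} of {row.individual_id!r} not found "
                                f"in family {fid!r}"
                            )
                        pp.append(pid)
                parents[row.individual_id] = pp
            _toposort_family(fid, parents)

        df["is_founder"] = [
            (f is None and m is None) for f, m in zip(df["father_id"], df["mother_id"])
        ]
        df = df.reset_index(drop=True)
        return cls(table=df)

    @property
    def n_individuals(self) -> int:
        return len(self.table)

    @property
    def n_families(self) -> int:
        return self.table["family_id"].nunique()

    @property
    def family_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["family_id"]))

    @property
    def n_founders(self) -> int:
        return int(self.table["is_founder"].sum())

    def family_sizes(self) -> pd.Series:
        return self.table.groupby("family_id", sort=False).size()

    def topological_order(self) -> pd.DataFrame:
        """Rows reordered so that every parent precedes its children."""
        frames = []
        for fid, fam in self.table.groupby("family_id", sort=False):
            parents = {
                r.individual_id: [p for p in (r.father_id, r.mother_id) if p is not None]
                for r in fam.itertuples()
            }
            order = _toposort_family(fid, parents)
            fam = fam.set_index("individual_id").loc[order].reset_index()
            frames.append(fam[["family_id"] + [c for c in fam.columns if c != "family_id"]])
        return pd.concat(frames, ignore_index=True)

    def equals(self, other: "PedigreeSet") -> bool:
        key = ["family_id", "individual_id"]
        a = self.table.sort_values(key).reset_index(drop=True)
        b = other.table.sort_values(key).reset_index(drop=True)
        return a.equals(b)

    def __eq__(self, other) -> bool:  # type: ignore[override]
        return isinstance(other, PedigreeSet) and self.equals(other)


def _toposort_family(fid: str, parents: dict[str, list[str]]) -> list[str]:
    """Kahn's algorithm over parent->child edges; raises on cycles."""
    children: dict[str, list[str]] = {iid: [] for iid in parents}
    indeg = {iid: 0 for iid in parents}
    for iid, pp in parents.items():
        for p in pp:
            if p == iid:
                raise PedigreeError(f"individual {iid!r} in family {fid!r} is its own parent")
            children[p].append(iid)
            indeg[iid] += 1
    queue = sorted(iid for iid, d in indeg.items() if d == 0)
    if not queue and parents:
        raise PedigreeError(f"family {fid!r} has no founder (pedigree cycle)")
    order: list[str] = []
    while queue:
        iid = queue.pop(0)
        order.append(iid)
        for c in children[iid]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != len(parents):
        cyc = sorted(set(parents) - set(order))
        raise PedigreeError(f"pedigree cycle in family {fid!r} involving {cyc}")
    return order


@dataclass(frozen=True)
class PhenotypeTable:
    """Long-format bivariate longitudinal phenotypes.

    One row per (individual, visit). Both traits must be observed or missing
    together at a visit — the model assumes the two outcomes are measured at
    the same time points.
    """

    data: pd.DataFrame
    trait_cols: tuple[str, str]
    x_cols: tuple[str, ...] = ()
    z_cols: tuple[str, ...] = ()
    htn_col: str | None = None
    med_col: str | None = None

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        trait_cols: tuple[str, str],
        x_cols: tuple[str, ...] = (),
        z_cols: tuple[str, ...] = (),
        htn_col: str | None = None,
        med_col: str | None = None,
    ) -> "PhenotypeTable":
        df = df.copy()
        needed = ["family_id", "individual_id", "visit", *trait_cols, *x_cols, *z_cols]
        for c in (htn_col, med_col):
            if c is not None:
                needed.append(c)
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise PhenotypeError(f"phenotype table missing columns: {missing}")
        df["family_id"] = df["family_id"].astype(str)
        df["individual_id"] = df["individual_id"].astype(str)
        df["visit"] = df["visit"].astype(int)

        dup = df.duplicated(subset=["family_id", "individual_id", "visit"])
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise PhenotypeError(
                f"duplicate visit {bad['visit']} for individual "
                f"{bad['individual_id']!r} (family {bad['family_id']!r})"
            )
        t1, t2 = trait_cols
        half = df[t1].isna() != df[t2].isna()
        if half.any():
            bad = df.loc[half].iloc[0]
            raise PhenotypeError(
                f"individual {bad['individual_id']!r} visit {bad['visit']} has one trait "
                "observed and the other missing; the model assumes both outcomes are "
                "measured at the same set of time points"
            )
        df = df.sort_values(["family_id", "individual_id", "visit"]).reset_index(drop=True)
        return cls(
            data=df,
            trait_cols=tuple(trait_cols),
            x_cols=tuple(x_cols),
            z_cols=tuple(z_cols),
            htn_col=htn_col,
            med_col=med_col,
        )

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def visit_counts(self) -> pd.Series:
        """m_ij: number of visits with observed traits per subject."""
        obs = self.data[~self.data[self.trait_cols[0]].isna()]
        return obs.groupby(["family_id", "individual_id"], sort=False).size()

    def equals(self, other: "PhenotypeTable") -> bool:
        if self.trait_cols != other.trait_cols:
            return False
        a = self.data.reset_index(drop=True)
        b = other.data[a.columns].reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False, atol=1e-12, rtol=0)
        except AssertionError:
            return False
        return True


@dataclass(frozen=True)
class GenotypeMatrix:
    """Subjects x SNVs minor-allele dosage matrix; entries 0/1/2 or NaN."""

    dosages: np.ndarray
    subject_ids: tuple[str, ...]
    snv_ids: tuple[str, ...]
    positions: tuple[int, ...] | None = None
    alleles: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self):
        d = np.asarray(self.dosages, dtype=float)
        object.__setattr__(self, "dosages", d)
        if d.ndim != 2:
            raise GenotypeError("dosage matrix must be 2-D (subjects x SNVs)")
        if d.shape != (len(self.subject_ids), len(self.snv_ids)):
            raise GenotypeError("dosage matrix shape does not match id lists")
        vals = d[~np.isnan(d)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise GenotypeError(f"dosage {bad!r} outside {{0,1,2,missing}}")
        if len(set(self.snv_ids)) != len(self.snv_ids):
            raise GenotypeError("SNV ids are not unique")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise GenotypeError("subject ids are not unique in the genotype matrix")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snvs(self) -> int:
        return len(self.snv_ids)

    def column(self, snv_id: str) -> np.ndarray:
        try:
            j = self.snv_ids.index(snv_id)
        except ValueError:
            raise GenotypeError(f"unknown SNV id {snv_id!r}") from None
        return self.dosages[:, j]


@dataclass(frozen=True)
class ModelDataset:
    """Index-aligned arrays for model fitting.

    Observation rows are (family i, subject j, visit t) triples with both
    traits observed. ``fixed`` carries the intercept and covariate columns
    (shared between the two traits' equations); ``snv`` the raw dosage columns.
    """

    y: np.ndarray                     # (n_obs, 2) raw trait values
    fixed: np.ndarray                 # (n_obs, p) intercept + X + Z columns
    fixed_names: tuple[str, ...]
    snv: np.ndarray                   # (n_obs, G) dosages
    snv_ids: tuple[str, ...]
    fam_idx: np.ndarray               # (n_obs,) int, family index 0..I-1
    subj_idx: np.ndarray              # (n_obs,) int, subject index 0..N-1
    subj_fam: np.ndarray              # (N,) family index of each subject
    visit: np.ndarray                 # (n_obs,) visit indices
    family_ids: tuple[str, ...]
    subject_keys: tuple[tuple[str, str], ...]
    trait_names: tuple[str, str]
    snv_positions: tuple[int, ...] | None = None

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_keys)

    @property
    def n_snvs(self) -> int:
        return len(self.snv_ids)

    def obs_per_family(self) -> np.ndarray:
        return np.bincount(self.fam_idx, minlength=self.n_families)

    def obs_per_subject(self) -> np.ndarray:
        return np.bincount(self.subj_idx, minlength=self.n_subjects)
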