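"""Synthetic pedigree, genotype and phenotype generation.

The generator realizes the same model the sampler fits: multigenerational
pedigrees, Mendelian gene-dropped dosages, and bivariate longitudinal traits

    y_ijtk = b0k + X'bxk + Z'bzk + sum_g beta_gk SNV_ijg + p_ik + s_ijk + e_ijtk

with bivariate normal family (Sigma_p), subject (Sigma_s) and residual
(Sigma_e) layers. The benchmark scenario emulates the GAW18 MAP4 setting:
20 multigenerational pedigrees of ~42 members on average, three visits per
subject, a panel of 15 causal variants with known MAFs and additive effects
per minor allele, and a configurable number of independently drawn noise
variants. Truth (causal sets, effects, covariance parameters) is recorded for
recovery and false-positive accounting tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_core import assemble_dataset
from .types import GenotypeMatrix, ModelDataset, PedigreeSet, PhenotypeTable


def _cov2(s1: float, s2: float, rho: float) -> np.ndarray:
    return np.array([[s1 * s1, rho * s1 * s2], [rho * s1 * s2, s2 * s2]])


@dataclass(frozen=True)
class FamilyTemplate:
    """Branching-process family template.

    A founder couple has a uniform number of children per couple; each
    non-final-generation child marries (a new founder spouse) with probability
    ``marry_prob`` and the couple reproduces in the next generation. Defaults
    give a mean family size near 42 (the multigenerational-pedigree scale the
    benchmark emulates).
    """

    offspring_range: tuple[int, int] = (2, 6)
    generations: int = 3
    marry_prob: float = 0.55


@dataclass(frozen=True)
class MedicationModel:
    """Optional observed-trait medication layer.

    Subjects whose latent second trait (systolic BP in the benchmark) exceeds
    ``htn_threshold`` at any visit are hypertensive; each such subject is
    medicated with probability ``med_prob``, and medication shifts both
    observed traits additively at every visit.
    """

    htn_threshold: float = 140.0
    med_prob: float = 0.7
    med_effect: tuple[float, float] = (-6.0, -12.0)


@dataclass(frozen=True)
class SimConfig:
    n_families: int = 20
    template: FamilyTemplate = field(default_factory=FamilyTemplate)
    n_visits: int = 3
    mafs: np.ndarray = field(default_factory=lambda: np.full(4, 0.3))
    effects: np.ndarray = field(default_factory=lambda: np.zeros((2, 4)))  # (2, G)
    ld_pairs: tuple[tuple[int, int, float], ...] = ()  # (source, target, flip_prob)
    beta0: tuple[float, float] = (75.0, 120.0)
    beta_sex: tuple[float, float] = (-2.0, -3.0)
    beta_smoke: tuple[float, float] = (1.5, 2.5)
    beta_age: tuple[float, float] = (0.35, 0.6)
    age_range: tuple[float, float] = (20.0, 70.0)
    age_increment: float = 5.0
    smoking_prevalence: float = 0.25
    sigma_p: tuple[float, float] = (4.0, 6.0)
    sigma_s: tuple[float, float] = (5.0, 8.0)
    sigma_e: tuple[float, float] = (5.0, 7.0)
    rho_p: float = 0.55
    rho_s: float = 0.55
    rho_e: float = 0.55
    medication: MedicationModel | None = None
    trait_names: tuple[str, str] = ("dbp", "sbp")
    snv_ids: tuple[str, ...] | None = None
    snv_positions: tuple[int, ...] | None = None

    def __post_init__(self):
        mafs = np.asarray(self.mafs, dtype=float)
        effects = np.asarray(self.effects, dtype=float)
        object.__setattr__(self, "mafs", mafs)
        object.__setattr__(self, "effects", effects)
        if effects.shape != (2, mafs.size):
            raise ValueError("effects must have shape (2, G) matching mafs")
        if np.any((mafs <= 0) | (mafs > 0.5)):
            raise ValueError("MAFs must lie in (0, 0.5]")
        for s in (*self.sigma_p, *self.sigma_s, *self.sigma_e):
            if s < 0:
                raise ValueError("sigmas must be non-negative")
        for r in (self.rho_p, self.rho_s, self.rho_e):
            if not -1.0 < r < 1.0:
                raise ValueError("correlations must lie in (-1, 1)")

    @property
    def n_snvs(self) -> int:
        return self.mafs.size

    def sigma_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            _cov2(*self.sigma_p, self.rho_p),
            _cov2(*self.sigma_s, self.rho_s),
            _cov2(*self.sigma_e, self.rho_e),
        )


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth retained for recovery and error accounting."""

    snv_ids: tuple[str, ...]
    effects: np.ndarray                 # (2, G)
    causal_sets: tuple[frozenset, frozenset]
    sigma_p: np.ndarray
    sigma_s: np.ndarray
    sigma_e: np.ndarray
    beta0: tuple[float, float]
    config: SimConfig

    @classmethod
    def from_config(cls, cfg: SimConfig, snv_ids: tuple[str, ...]) -> "SimulationTruth":
        sp, ss, se = cfg.sigma_matrices()
        causal = tuple(
            frozenset(snv_ids[g] for g in np.nonzero(cfg.effects[k])[0]) for k in (0, 1)
        )
        return cls(
            snv_ids=snv_ids, effects=cfg.effects.copy(), causal_sets=causal,
            sigma_p=sp, sigma_s=ss, sigma_e=se, beta0=cfg.beta0, config=cfg,
        )


# ---------------------------------------------------------------------------
# pedigree structure


def simulate_pedigree_structure(cfg: SimConfig, seed: int) -> PedigreeSet:
    """Grow ``n_families`` independent families from the branching template."""
    rng = np.random.default_rng(seed)
    tpl = cfg.template
    lo, hi = tpl.offspring_range
    if cfg.n_families < 1 or hi < 1:
        raise ValueError("template implies zero individuals")
    rows = []
    for fi in range(cfg.n_families):
        fid = f"fam{fi + 1:02d}"
        counter = 0

        def new_iid():
            nonlocal counter
            counter += 1
            return f"{fid}_{counter:03d}"

        father, mother = new_iid(), new_iid()
        rows.append((fid, father, None, None, 1))
        rows.append((fid, mother, None, None, 2))
        couples = [(father, mother)]
        for gen in range(1, tpl.generations + 1):
            next_couples = []
            for f, m in couples:
                for _ in range(int(rng.integers(lo, hi + 1))):
                    child = new_iid()
                    sex = 1 if rng.random() < 0.5 else 2
                    rows.append((fid, child, f, m, sex))
                    if gen < tpl.generations and rng.random() < tpl.marry_prob:
                        spouse = new_iid()
                        rows.append((fid, spouse, None, None, 2 if sex == 1 else 1))
                        next_couples.append(
                            (child, spouse) if sex == 1 else (spouse, child)
                        )
            couples = next_couples
    df = pd.DataFrame(
        rows, columns=["family_id", "individual_id", "father_id", "mother_id", "sex"]
    )
    return PedigreeSet.from_table(df)


# ---------------------------------------------------------------------------
# gene dropping


def drop_genes(
    ped: PedigreeSet,
    mafs: np.ndarray,
    seed: int,
    ld_pairs: tuple[tuple[int, int, float], ...] = (),
    snv_ids: tuple[str, ...] | None = None,
    positions: tuple[int, ...] | None = None,
    ensure_polymorphic: bool = False,
) -> GenotypeMatrix:
    """Realize dosages by gene dropping.

    Founder alleles are Bernoulli(maf) per chromosome; each child inherits one
    uniformly chosen allele from each parent, independently across SNVs. An
    optional LD pair (source, target, flip_prob) makes the target column a
    copy of the source at the founder-allele level with per-allele flip noise,
    transmitted with the source's meioses — LD decays only through the flips,
    and Mendelian consistency holds exactly for every column.

    With ``ensure_polymorphic``, founder columns that drew zero minor alleles
    are redrawn (variants are ascertained as segregating in the sample); this
    conditions rare-variant frequencies upward slightly.
    """
    mafs = np.asarray(mafs, dtype=float)
    G = mafs.size
    rng = np.random.default_rng(seed)
    ordered = ped.topological_order()

    founder_iids = [r.individual_id for r in ordered.itertuples() if r.father_id is None]
    nf = len(founder_iids)
    fa = (rng.random((nf, 2, G)) < mafs).astype(np.int8)
    if ensure_polymorphic:
        for _ in range(1000):
            mono = np.where(fa.sum(axis=(0, 1)) == 0)[0]
            if mono.size == 0:
                break
            fa[:, :, mono] = (
                rng.random((nf, 2, mono.size)) < mafs[mono]
            ).astype(np.int8)
    for src, tgt, eps in ld_pairs:
        flips = (rng.random((nf, 2)) < eps).astype(np.int8)
        fa[:, :, tgt] = fa[:, :, src] ^ flips

    alleles: dict[str, np.ndarray] = {
        iid: fa[i] for i, iid in enumerate(founder_iids)
    }
    for r in ordered.itertuples():
        iid = r.individual_id
        if r.father_id is None:
            continue
        a = np.empty((2, G), dtype=np.int8)
        for pi, parent in enumerate((r.father_id, r.mother_id)):
            choice = rng.integers(0, 2, G)
            for src, tgt, _ in ld_pairs:
                choice[tgt] = choice[src]
            a[pi] = alleles[parent][choice, np.arange(G)]
        alleles[iid] = a
    iids = tuple(ped.table["individual_id"])
    dosage = np.array([alleles[i].sum(axis=0) for i in iids], dtype=float)
    return GenotypeMatrix(
        dosages=dosage,
        subject_ids=iids,
        snv_ids=snv_ids or tuple(f"snv{j + 1:03d}" for j in range(G)),
        positions=positions,
    )


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    ped: PedigreeSet,
    geno: GenotypeMatrix,
    cfg: SimConfig,
    seed: int,
) -> tuple[PhenotypeTable, SimulationTruth]:
    """Generate the bivariate longitudinal traits from the model."""
    for name, sig in zip(("Sigma_p", "Sigma_s", "Sigma_e"), cfg.sigma_matrices()):
        w = np.linalg.eigvalsh(sig)
        if np.any(w < -1e-12):
            raise ValueError(f"{name} is not positive semi-definite")
    rng = np.random.default_rng(seed)
    sp, ss, se = cfg.sigma_matrices()
    ped_tab = ped.table
    geno_index = {s: i for i, s in enumerate(geno.subject_ids)}

    fam_ids = list(dict.fromkeys(ped_tab["family_id"]))
    p_fam = {f: _mvn2(rng, sp) for f in fam_ids}

    effects = cfg.effects  # (2, G)
    rows = []
    latent2 = []
    subj_meta = []
    for r in ped_tab.itertuples():
        dos = geno.dosages[geno_index[r.individual_id]]
        genetic = effects @ np.nan_to_num(dos)
        sex = float(r.sex == 2)  # female indicator
        smoke = float(rng.random() < cfg.smoking_prevalence)
        base_age = rng.uniform(*cfg.age_range)
        s_ij = _mvn2(rng, ss)
        subj_meta.append((r.family_id, r.individual_id))
        for t in range(1, cfg.n_visits + 1):
            age = base_age + (t - 1) * cfg.age_increment
            e = _mvn2(rng, se)
            mean = (
                np.asarray(cfg.beta0)
                + sex * np.asarray(cfg.beta_sex)
                + smoke * np.asarray(cfg.beta_smoke)
                + age * np.asarray(cfg.beta_age)
                + genetic
            )
            y = mean + p_fam[r.family_id] + s_ij + e
            rows.append(
                [r.family_id, r.individual_id, t, y[0], y[1], sex, smoke, age, 0, 0]
            )
            latent2.append(y[1])

    t1, t2 = cfg.trait_names
    df = pd.DataFrame(
        rows,
        columns=["family_id", "individual_id", "visit", t1, t2, "sex", "smoke", "age",
                 "htn", "med"],
    )
    if cfg.medication is not None:
        mm = cfg.medication
        latent2 = np.asarray(latent2)
        df["htn"] = (latent2 >= mm.htn_threshold).astype(int)
        by_subj = df.groupby(["family_id", "individual_id"], sort=False)["htn"].transform("max")
        med_draw = {
            key: int(rng.random() < mm.med_prob) for key in subj_meta
        }
        subj_keys = list(zip(df["family_id"], df["individual_id"]))
        df["med"] = [
            med_draw[k] if any_h else 0 for k, any_h in zip(subj_keys, by_subj)
        ]
        medicated = df["med"] == 1
        df.loc[medicated, t1] += mm.med_effect[0]
        df.loc[medicated, t2] += mm.med_effect[1]

    pheno = PhenotypeTable.from_frame(
        df, trait_cols=(t1, t2), x_cols=("sex", "smoke"), z_cols=("age",),
        htn_col="htn", med_col="med",
    )
    truth = SimulationTruth.from_config(cfg, geno.snv_ids)
    return pheno, truth


def _mvn2(rng: np.random.Generator, cov: np.ndarray) -> np.ndarray:
    # cov is 2x2 PSD; explicit Cholesky-with-fallback keeps sigma->0 limits exact
    if cov[0, 0] == 0.0 and cov[1, 1] == 0.0:
        return np.zeros(2)
    w, v = np.linalg.eigh(cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return root @ rng.standard_normal(2)


def simulate_dataset(cfg: SimConfig, seed: int) -> tuple[ModelDataset, SimulationTruth]:
    """Pedigree -> genotypes -> phenotypes -> assembled ModelDataset."""
    ss = np.random.SeedSequence(seed)
    s_ped, s_gene, s_pheno = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    ped = simulate_pedigree_structure(cfg, s_ped)
    geno = drop_genes(
        ped, cfg.mafs, s_gene, ld_pairs=cfg.ld_pairs, snv_ids=cfg.snv_ids,
        positions=cfg.snv_positions,
    )
    pheno, truth = simulate_phenotypes(ped, geno, cfg, s_pheno)
    data = assemble_dataset(ped, pheno, geno)
    return data, truth


# ---------------------------------------------------------------------------
# benchmark scenario

# Causal-variant panel of the GAW18 MAP4 benchmark: position on chromosome 3,
# minor allele frequency, and additive effect per minor allele on diastolic
# and systolic blood pressure (mm Hg). One variant has a null effect on both
# traits and is excluded from the causal truth sets.
MAP4_PANEL: tuple[tuple[int, float, float, float], ...] = (
    (47912898, 0.0049, 1.71, 2.34),
    (47913455, 0.0049, -5.46, -8.70),
    (47924216, 0.0066, 1.35, 1.84),
    (47955326, 0.0066, -1.93, -2.63),
    (47956424, 0.3777, -1.50, -2.38),
    (47957741, 0.0016, -5.08, -8.10),
    (47957996, 0.0301, -4.64, -7.39),
    (48058037, 0.3420, 0.00, -0.00),
    (47973345, 0.0082, 2.14, 2.92),
    (48040283, 0.0318, -6.22, -9.91),
    (48040284, 0.0131, -6.95, -11.1),
    (48054461, 0.1187, 0.46, 0.63),
    (48061725, 0.0050, 1.79, 2.44),
    (48069438, 0.0065, -1.78, -2.43),
    (48091219, 0.0065, 2.54, 3.46),
)


def gaw_config(
    noise_count: int,
    seed: int,
    n_families: int = 20,
    template: FamilyTemplate | None = None,
    medication: MedicationModel | None = None,
) -> SimConfig:
    """Benchmark configuration: the causal panel plus ``noise_count`` null
    SNVs with MAFs drawn log-uniformly on [0.005, 0.5] (the source region is
    dominated by rare variation)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)).generate_state(1)[0])
    panel = np.array(MAP4_PANEL)
    noise_mafs = np.exp(rng.uniform(np.log(0.005), np.log(0.5), noise_count))
    mafs = np.concatenate([panel[:, 1], noise_mafs])
    effects = np.zeros((2, 15 + noise_count))
    effects[0, :15] = panel[:, 2]
    effects[1, :15] = panel[:, 3]
    snv_ids = tuple(f"map4_{int(p)}" for p in panel[:, 0]) + tuple(
        f"noise_{j + 1:03d}" for j in range(noise_count)
    )
    positions = tuple(int(p) for p in panel[:, 0]) + tuple(
        48100000 + 1000 * (j + 1) for j in range(noise_count)
    )
    return SimConfig(
        n_families=n_families,
        template=template or FamilyTemplate(),
        mafs=mafs,
        effects=effects,
        medication=MedicationModel() if medication is None else medication,
        snv_ids=snv_ids,
        snv_positions=positions,
    )


def gaw_like_scenario(
    noise_count: int,
    seed: int,
    n_families: int = 20,
    template: FamilyTemplate | None = None,
    medication: MedicationModel | None = None,
    adjust_medication: bool = True,
) -> tuple[ModelDataset, SimulationTruth]:
    """Benchmark scenario: the causal panel plus ``noise_count`` null SNVs.

    When a medication layer is active (the default), observed traits are
    medication-adjusted before assembly, as in the benchmark's analysis
    pipeline.
    """
    cfg = gaw_config(noise_count, seed, n_families=n_families,
                     template=template, medication=medication)
    snv_ids, positions = cfg.snv_ids, cfg.snv_positions

    ss = np.random.SeedSequence(seed)
    s_ped, s_gene, s_pheno = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    ped = simulate_pedigree_structure(cfg, s_ped)
    geno = drop_genes(
        ped, cfg.mafs, s_gene, snv_ids=snv_ids, positions=positions,
        ensure_polymorphic=True,
    )
    pheno, truth = simulate_phenotypes(ped, geno, cfg, s_pheno)
    if adjust_medication and cfg.medication is not None:
        from .preprocess import adjust_both_traits

        pheno, _ = adjust_both_traits(pheno)
    data = assemble_dataset(ped, pheno, geno)
    return data, truth
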