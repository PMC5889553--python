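"""Synthetic breeding-population generator.

Emulates the data structure of a closed purebred pig nucleus line: a
multi-generation pedigree with a study cohort of intensively phenotyped boars
(default 1363 offspring of 63 sires and 439 dams, mean pairwise additive
relationship near 0.12), pedigree-structured linkage disequilibrium from
gene-dropping over that pedigree, nested marker panels (80K-like subset of a
650K-like subset of "sequence" variants) with common-variant ascertainment,
oligogenic and polygenic trait architectures, fixed effects (contemporary
group, ultrasound machine, age covariate), genotype-error corruption standing
in for imputation error, and functional annotation terms with configurable
QTL enrichment.

Founder haplotypes draw allele frequencies from a U-shaped Beta(0.5, 0.5);
LD is built purely by drift through several burn-in generations with a small
number of parents (effective size of the order reported for pig nucleus
lines, roughly 55-115). Meiosis uses Haldane's model: Poisson crossover
counts with mean equal to the map length in Morgans, no interference.

All randomness flows through one ``numpy.random.Generator`` threaded
explicitly through every operation; identical config + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, check_panel_nesting, new_variant_table
from .pedigree import Pedigree

__all__ = [
    "SimConfig",
    "TraitArchitecture",
    "TrueValues",
    "simulate_pedigree",
    "sample_founder_haplotypes",
    "drop_haplotypes",
    "assign_qtl_effects",
    "simulate_phenotypes",
    "define_panels",
    "corrupt_genotypes",
    "annotate_variants",
    "simulate_dataset",
    "SimData",
]

# raw functional terms and their background frequencies (renormalised);
# loosely genome-like: mostly intergenic/intronic, few coding changes
BACKGROUND_TERMS: dict[str, float] = {
    "intergenic": 0.52,
    "intronic": 0.30,
    "synonymous": 0.030,
    "missense": 0.020,
    "splice_site": 0.003,
    "frameshift": 0.002,
    "inframe_indel": 0.002,
    "stop_gained": 0.001,
    "utr": 0.022,
    "near_gene": 0.050,
    "noncoding_exon": 0.050,
}

#: terms mapped to the NSC (non-synonymous coding) and REG (regulatory) classes
NSC_TERMS = ("missense", "splice_site", "frameshift", "inframe_indel", "stop_gained")
REG_TERMS = ("utr", "near_gene", "noncoding_exon")


@dataclass(frozen=True)
class TraitArchitecture:
    """Genetic architecture of one simulated trait.

    ``oligogenic`` draws few large gamma-distributed effects restricted to
    designated chromosomes (big-QTL traits such as feed intake and backfat);
    ``polygenic`` spreads many small normal effects genome-wide (growth-rate
    like traits).
    """

    trait_name: str
    n_qtl: int
    effect_distribution: str  # "oligogenic" | "polygenic"
    qtl_maf_range: tuple[float, float] = (0.01, 0.5)
    target_genetic_variance: float = 1.0
    designated_chromosomes: tuple = ()  # oligogenic only; empty = first two
    has_machine_effect: bool = False

    def __post_init__(self) -> None:
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be >= 1")
        if self.effect_distribution not in ("oligogenic", "polygenic"):
            raise ValueError(f"unknown effect_distribution {self.effect_distribution!r}")
        lo, hi = self.qtl_maf_range
        if not (0 <= lo < hi <= 0.5):
            raise ValueError("qtl_maf_range must satisfy 0 <= lo < hi <= 0.5")


def _default_traits() -> tuple[TraitArchitecture, ...]:
    return (
        TraitArchitecture("ADFI", 10, "oligogenic"),
        TraitArchitecture("FAT", 10, "oligogenic", has_machine_effect=True),
        TraitArchitecture("ADG", 300, "polygenic"),
        TraitArchitecture("LMD", 300, "polygenic", has_machine_effect=True),
    )


def _default_h2() -> dict[str, float]:
    return {"ADFI": 0.45, "FAT": 0.55, "ADG": 0.35, "LMD": 0.40}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic population.

    Per-generation parent/offspring counts may be scalars (every generation)
    or sequences of length ``n_generations``; the last generation is the
    study cohort. The defaults reproduce the cohort shape the package is
    benchmarked on: 7 burn-in generations of 20 sires x 60 dams (small
    effective size builds background relatedness and LD) followed by a final
    cohort of 1363 boars from 63 sires and 439 dams.
    """

    n_founders: int = 160
    n_generations: int = 8
    n_sires: int | tuple = (24, 24, 24, 24, 24, 24, 24, 63)
    n_dams: int | tuple = (72, 72, 72, 72, 72, 72, 72, 439)
    n_offspring: int | tuple = (160, 160, 160, 160, 160, 160, 560, 1363)
    n_chromosomes: int = 18
    chrom_length_cM: float = 100.0
    n_seq_variants: int = 20000
    n_panel650_variants: int = 5000
    n_panel80_variants: int = 1000
    trait_architectures: tuple = field(default_factory=_default_traits)
    h2_targets: dict = field(default_factory=_default_h2)
    n_contemporary_groups: int | None = None  # None: one per ~17.5 cohort animals
    cg_sd: float = 0.7          # contemporary-group effect SD (genetic-SD units)
    machine_effect: float = 0.4  # level-2 minus level-1 machine contrast
    age_slope: float = 0.02      # trait units per day of age at end of test
    age_range: tuple = (140, 170)
    genotype_error_rate: float = 0.0
    rng_seed: int = 2024

    def per_generation(self, attr: str) -> list[int]:
        if self.n_generations == 0:
            return []
        v = getattr(self, attr)
        if np.isscalar(v):
            return [int(v)] * self.n_generations
        v = list(v)
        if len(v) != self.n_generations:
            raise ValueError(f"{attr} must be scalar or length n_generations")
        return [int(x) for x in v]

    def __post_init__(self) -> None:
        if not (
            self.n_panel80_variants <= self.n_panel650_variants <= self.n_seq_variants
        ):
            raise ValueError("panel sizes must nest: 80K <= 650K <= SEQ")
        for t, h2 in self.h2_targets.items():
            if not (0 < h2 <= 1):
                raise ValueError(f"h2 target for {t} must be in (0, 1], got {h2}")
        if self.chrom_length_cM < 0:
            raise ValueError("chromosome length must be >= 0")
        if self.n_generations:
            avail = self.n_founders
            for g, (ns, nd, no) in enumerate(
                zip(
                    self.per_generation("n_sires"),
                    self.per_generation("n_dams"),
                    self.per_generation("n_offspring"),
                )
            ):
                if ns + nd > avail:
                    raise ValueError(
                        f"generation {g + 1} requests {ns} sires + {nd} dams but only "
                        f"{avail} candidates exist in the previous generation"
                    )
                avail = no

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Multi-generation random-mating pedigree with birthdates.

    Founders get birthdate 0; generation g is born around day 365*g, with the
    final cohort spread over weekly batches (the batches later become
    contemporary groups).
    """
    rng = config.rng() if rng is None else rng
    animals: list[str] = [f"F{i:04d}" for i in range(config.n_founders)]
    sires: list[str] = ["0"] * config.n_founders
    dams: list[str] = ["0"] * config.n_founders
    birth: list[int] = [0] * config.n_founders
    prev = list(animals)
    ns_l = config.per_generation("n_sires")
    nd_l = config.per_generation("n_dams")
    no_l = config.per_generation("n_offspring")
    for g in range(config.n_generations):
        ns, nd, no = ns_l[g], nd_l[g], no_l[g]
        parents = rng.choice(len(prev), size=ns + nd, replace=False)
        gen_sires = [prev[i] for i in parents[:ns]]
        gen_dams = [prev[i] for i in parents[ns:]]
        # each dam produces a litter; every selected dam and sire is used
        dam_of = np.concatenate([np.arange(nd), rng.integers(0, nd, size=max(no - nd, 0))])[:no]
        rng.shuffle(dam_of)
        sire_of_dam = np.concatenate([np.arange(ns), rng.integers(0, ns, size=max(nd - ns, 0))])[:nd]
        rng.shuffle(sire_of_dam)
        base = 365 * (g + 1)
        is_final = g == config.n_generations - 1
        order = np.argsort(dam_of, kind="stable") if is_final else np.arange(no)
        new: list[str] = []
        for k in range(no):
            i = order[k]
            a = f"G{g + 1:02d}_{i:05d}"
            animals.append(a)
            sires.append(gen_sires[sire_of_dam[dam_of[i]]])
            dams.append(gen_dams[dam_of[i]])
            # weekly batches of ~24 animals in the final cohort
            birth.append(base + 7 * (k // 24) if is_final else base)
            new.append(a)
        prev = new
    return Pedigree(
        np.array(animals, dtype=object),
        np.array(sires, dtype=object),
        np.array(dams, dtype=object),
        np.array(birth),
    )


def make_variant_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Variant table with positions uniform over equal-length chromosomes (1 cM/Mb)."""
    n = config.n_seq_variants
    per = np.full(config.n_chromosomes, n // config.n_chromosomes)
    per[: n % config.n_chromosomes] += 1
    L_bp = max(int(config.chrom_length_cM * 1e6), int(per.max()) * 2)
    ids, chroms, pos = [], [], []
    for c in range(config.n_chromosomes):
        p = np.sort(rng.choice(L_bp, size=per[c], replace=False)) + 1
        pos.append(p)
        chroms += [str(c + 1)] * per[c]
        ids += [f"v{c + 1}_{k}" for k in range(per[c])]
    ref, alt = rng.choice(list("ACGT"), size=(2, n))
    same = ref == alt
    alt[same] = np.where(ref[same] == "A", "G", "A")
    return new_variant_table(ids, chroms, np.concatenate(pos), ref=ref, alt=alt)


def sample_founder_haplotypes(
    config: SimConfig, variants: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Phased founder haplotypes, shape (n_founders, 2, n_variants), uint8.

    Allele frequencies are drawn per variant from Beta(0.5, 0.5) clipped to
    [0.01, 0.99]; founder haplotypes are independent Bernoulli draws, i.e.
    founders start in Hardy-Weinberg and linkage equilibrium.
    """
    p = np.clip(rng.beta(0.5, 0.5, size=len(variants)), 0.01, 0.99)
    return (
        rng.random((config.n_founders, 2, len(variants))) < p
    ).astype(np.uint8)


def _meiosis(
    parent_haps: np.ndarray,
    chrom_slices: list[slice],
    cM: np.ndarray,
    lengths_cM: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete: per chromosome, Haldane crossovers over the parent's two haplotypes."""
    gamete = np.empty(parent_haps.shape[1], dtype=np.uint8)
    for sl, L in zip(chrom_slices, lengths_cM):
        n_x = rng.poisson(L / 100.0)
        phase = rng.integers(0, 2)
        if n_x == 0:
            gamete[sl] = parent_haps[phase, sl]
            continue
        xpos = np.sort(rng.random(n_x) * L)
        # phase flips at each crossover: phase(pos) = start + #crossovers before pos
        flips = np.searchsorted(xpos, cM[sl])
        take = (phase + flips) % 2
        seg = parent_haps[:, sl]
        gamete[sl] = seg[take, np.arange(sl.stop - sl.start)]
    return gamete


def drop_haplotypes(
    pedigree: Pedigree,
    founder_haps: np.ndarray,
    variants: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    return_haplotypes: bool = False,
):
    """Gene-drop founder haplotypes through the pedigree.

    Each transmitted haplotype is a recombinant mosaic of the parent's two
    haplotypes (Poisson crossover count, Haldane model). Unknown parents of
    non-founders receive a fresh founder-like haplotype drawn from the founder
    pool. Returns a :class:`GenotypeMatrix` over all pedigree animals.
    """
    n_var = len(variants)
    if founder_haps.shape[2] != n_var:
        raise ValueError("founder haplotypes do not match the variant table")
    chrom_order = list(dict.fromkeys(variants["chrom"]))
    chrom_slices, lengths = [], []
    start = 0
    pos_cM = np.empty(n_var)
    for c in chrom_order:
        m = np.flatnonzero((variants["chrom"] == c).to_numpy())
        if not np.array_equal(m, np.arange(m[0], m[-1] + 1)):
            raise ValueError("variant table must be sorted by chromosome")
        sl = slice(m[0], m[-1] + 1)
        cm = variants["pos"].to_numpy()[sl] / 1e6
        if cm.max() > config.chrom_length_cM and config.chrom_length_cM > 0:
            raise ValueError("variant position outside the genetic map")
        pos_cM[sl] = cm
        chrom_slices.append(sl)
        lengths.append(config.chrom_length_cM)
        start = sl.stop
    lengths = np.asarray(lengths)
    si, di = pedigree.parent_indices()
    n = len(pedigree)
    pool = founder_haps.reshape(-1, n_var)  # one row per founder haplotype
    haps = np.empty((n, 2, n_var), dtype=np.uint8)
    n_founder_used = 0
    for i in range(n):
        for slot, p in enumerate((si[i], di[i])):
            if p < 0:
                if n_founder_used >= pool.shape[0]:
                    raise ValueError(
                        "founder haplotype pool exhausted: pedigree has more "
                        "unknown-parent slots than supplied founder haplotypes"
                    )
                haps[i, slot] = pool[n_founder_used]
                n_founder_used += 1
            else:
                haps[i, slot] = _meiosis(haps[p], chrom_slices, pos_cM, lengths, rng)
    geno = GenotypeMatrix(
        haps.sum(axis=1).astype(np.int8), pedigree.animal, variants["id"].to_numpy()
    )
    return (geno, haps) if return_haplotypes else geno


@dataclass
class TrueValues:
    """Simulation ground truth for parameter-recovery tests.

    ``qtl_effects`` maps trait -> Series(variant id -> allele substitution
    effect on the 0/1/2 dosage scale); ``tbv`` is animals x traits.
    """

    qtl_effects: dict[str, pd.Series]
    tbv: pd.DataFrame
    fixed_truth: dict = field(default_factory=dict)

    def qtl_ids(self, trait: str) -> np.ndarray:
        return self.qtl_effects[trait].index.to_numpy()


def assign_qtl_effects(
    variants: pd.DataFrame,
    arch: TraitArchitecture,
    geno: GenotypeMatrix,
    rng: np.random.Generator,
    cohort_ids: np.ndarray | None = None,
) -> pd.Series:
    """Sample QTL and allele-substitution effects for one trait.

    QTL are drawn from segregating sequence variants inside the architecture's
    MAF window (oligogenic: restricted to the designated chromosomes, spaced
    apart to limit mutual LD; effect magnitudes Gamma(0.4) with random sign.
    Polygenic: genome-wide normal effects). Effects are rescaled so
    sum(2 p (1-p) alpha^2) over QTL equals ``target_genetic_variance``.
    """
    sub = geno if cohort_ids is None else geno.subset(animal_ids=cohort_ids)
    maf = pd.Series(sub.maf(), index=[str(v) for v in geno.variant_ids])
    maf = maf.reindex(variants["id"]).to_numpy()
    lo, hi = arch.qtl_maf_range
    ok = (maf >= lo) & (maf <= hi) & variants["in_seq"].to_numpy()
    if arch.effect_distribution == "oligogenic":
        chroms = arch.designated_chromosomes or tuple(
            dict.fromkeys(variants["chrom"])
        )[:2]
        ok &= variants["chrom"].isin([str(c) for c in chroms]).to_numpy()
    cand = np.flatnonzero(ok)
    if len(cand) < arch.n_qtl:
        raise ValueError(
            f"only {len(cand)} segregating variants in MAF range "
            f"{arch.qtl_maf_range} for trait {arch.trait_name!r}; need {arch.n_qtl}"
        )
    if arch.effect_distribution == "oligogenic":
        # spread picks along the candidate list to keep QTL apart on the map
        stride = len(cand) / arch.n_qtl
        jitter = rng.integers(0, max(int(stride * 0.5), 1), size=arch.n_qtl)
        pick = cand[(np.arange(arch.n_qtl) * stride).astype(int) + jitter]
        mags = rng.gamma(0.4, 1.0, size=arch.n_qtl) + 0.05
        eff = mags * rng.choice([-1.0, 1.0], size=arch.n_qtl)
    else:
        pick = rng.choice(cand, size=arch.n_qtl, replace=False)
        eff = rng.normal(0.0, 1.0, size=arch.n_qtl)
    p = sub.allele_freq()[pick]
    denom = float(np.sum(2 * p * (1 - p) * eff**2))
    if denom <= 0:
        raise ValueError("degenerate QTL draw: zero expected genetic variance")
    eff *= np.sqrt(arch.target_genetic_variance / denom)
    return pd.Series(eff, index=variants["id"].to_numpy()[pick], name=arch.trait_name)


def true_breeding_values(geno: GenotypeMatrix, qtl_effects: dict[str, pd.Series]) -> pd.DataFrame:
    """TBV = dosage x effect summed over QTL, per trait."""
    out = {}
    for trait, eff in qtl_effects.items():
        cols = geno.variant_index(eff.index.to_numpy())
        out[trait] = geno.dosages[:, cols].astype(float) @ eff.to_numpy()
    return pd.DataFrame(out, index=geno.animal_ids)


def simulate_phenotypes(
    geno: GenotypeMatrix,
    truth: TrueValues,
    pedigree: Pedigree,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Phenotypes for the final cohort: y = mu + CG + machine + age + TBV + e.

    The residual variance per trait is sigma_g2 (1 - h2) / h2 with sigma_g2
    the realized TBV variance of the cohort, so the realized heritability
    matches the target. Contemporary groups follow the weekly birth batches;
    the machine effect attaches only to the ultrasound-type traits. True fixed
    effects are stored in ``truth.fixed_truth`` for recovery tests.
    """
    cohort = _final_cohort(pedigree, config)
    idx = pedigree.index_of(cohort)
    bd = np.asarray(pedigree.birthdate)[idx]
    n = len(cohort)
    batches = pd.factorize(bd)[0]
    if config.n_contemporary_groups is not None:
        batches = batches % config.n_contemporary_groups
    n_cg = batches.max() + 1
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    machine = rng.integers(0, 2, size=n)
    df = pd.DataFrame(
        {
            "animal": cohort,
            "birthdate": bd,
            "cg": [f"cg{b:03d}" for b in batches],
            "machine": [f"m{m}" for m in machine],
            "age": age,
        }
    )
    tbv = truth.tbv.loc[cohort]
    fixed_truth: dict[str, dict] = {}
    arch_by_name = {a.trait_name: a for a in config.trait_architectures}
    for trait in tbv.columns:
        h2 = config.h2_targets[trait]
        g = tbv[trait].to_numpy()
        sg2 = float(np.var(g))
        sg = np.sqrt(sg2) if sg2 > 0 else 1.0
        cg_eff = rng.normal(0.0, config.cg_sd * sg, size=n_cg)
        has_machine = arch_by_name[trait].has_machine_effect
        mach_eff = np.array([0.0, config.machine_effect * sg]) if has_machine else np.zeros(2)
        slope = config.age_slope * sg
        se2 = sg2 * (1 - h2) / h2
        e = rng.normal(0.0, np.sqrt(se2), size=n) if se2 > 0 else np.zeros(n)
        y = 10.0 * sg + cg_eff[batches] + mach_eff[machine] + slope * (age - age.mean()) + g + e
        df[trait] = y
        fixed_truth[trait] = {
            "cg_effects": cg_eff,
            "machine_effects": mach_eff,
            "age_slope": slope,
            "sigma_g2": sg2,
            "sigma_e2": se2,
        }
    truth.fixed_truth.update(fixed_truth)
    return df


def _final_cohort(pedigree: Pedigree, config: SimConfig) -> np.ndarray:
    if config.n_generations == 0:
        return pedigree.animal
    tag = f"G{config.n_generations:02d}_"
    return pedigree.animal[np.char.startswith(pedigree.animal.astype(str), tag)]


def define_panels(
    variants: pd.DataFrame,
    geno: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator,
    cohort_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Nested panel membership with common-variant ascertainment.

    Array panels are sampled with probability proportional to MAF (among the
    genotyped cohort), mirroring the high-MAF bias of commercial SNP chips;
    the 80K-like panel is drawn from inside the 650K-like panel, which keeps
    the strict 80K < 650K < SEQ chain.
    """
    out = variants.copy()
    sub = geno if cohort_ids is None else geno.subset(animal_ids=cohort_ids)
    maf = pd.Series(sub.maf(), index=geno.variant_ids).reindex(out["id"]).to_numpy()
    out["maf"] = maf
    out["in_seq"] = True
    w = np.maximum(maf, 1e-6)
    k650 = config.n_panel650_variants
    k80 = config.n_panel80_variants
    pick650 = rng.choice(len(out), size=k650, replace=False, p=w / w.sum())
    out["in_650k"] = False
    out.iloc[pick650, out.columns.get_loc("in_650k")] = True
    w80 = w[pick650]
    pick80 = pick650[rng.choice(k650, size=k80, replace=False, p=w80 / w80.sum())]
    out["in_80k"] = False
    out.iloc[pick80, out.columns.get_loc("in_80k")] = True
    check_panel_nesting(out)
    return out


def corrupt_genotypes(
    geno: GenotypeMatrix,
    error_rate: float,
    rng: np.random.Generator,
    maf_dependence: bool = False,
    maf: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Random genotype substitution emulating imputation error.

    Each genotype is independently replaced by one of the two other legal
    dosages with per-variant probability ``error_rate`` or, with
    ``maf_dependence``, ``error_rate`` scaled by a logistic weight that grows
    as MAF shrinks (rare variants impute worse). The input is untouched.
    """
    if error_rate < 0 or error_rate > 1:
        raise ValueError("error_rate must be in [0, 1]")
    out = geno.copy()
    if error_rate == 0:
        return out
    if maf_dependence:
        m = geno.maf() if maf is None else np.asarray(maf, float)
        weight = 0.5 + 1.5 / (1.0 + np.exp(20.0 * (m - 0.1)))
        e = np.clip(error_rate * weight, 0.0, 1.0)
    else:
        e = np.full(geno.n_variants, float(error_rate))
    hit = rng.random(out.dosages.shape) < e
    hit &= out.dosages != -1
    shift = rng.integers(1, 3, size=int(hit.sum()))
    out.dosages[hit] = ((out.dosages[hit] + shift) % 3).astype(np.int8)
    return out


def annotate_variants(
    variants: pd.DataFrame,
    qtl_ids: np.ndarray,
    rng: np.random.Generator,
    enrichment: float = 1.0,
) -> pd.DataFrame:
    """Assign one raw functional term per variant, enriching QTL.

    Background terms follow :data:`BACKGROUND_TERMS`; for true QTL the
    probabilities of NSC- and REG-mapped terms are multiplied by
    ``enrichment`` and renormalised, emulating causal variants clustering in
    functional sequence.
    """
    terms = list(BACKGROUND_TERMS)
    pb = np.array([BACKGROUND_TERMS[t] for t in terms])
    pb = pb / pb.sum()
    pq = pb * np.array([enrichment if t in NSC_TERMS + REG_TERMS else 1.0 for t in terms])
    pq = pq / pq.sum()
    out = variants.copy()
    is_qtl = out["id"].isin(np.asarray(qtl_ids, dtype=object)).to_numpy()
    n = len(out)
    draw_b = rng.choice(len(terms), size=n, p=pb)
    draw_q = rng.choice(len(terms), size=n, p=pq)
    chosen = np.where(is_qtl, draw_q, draw_b)
    out["annotation_term"] = [terms[k] for k in chosen]
    out["is_qtl"] = is_qtl
    return out


@dataclass
class SimData:
    """A complete simulated dataset (one seed, one config)."""

    config: SimConfig
    pedigree: Pedigree
    variants: pd.DataFrame
    geno_true: GenotypeMatrix   # error-free cohort genotypes
    geno: GenotypeMatrix        # cohort genotypes after the error model
    phenotypes: pd.DataFrame
    truth: TrueValues
    cohort: np.ndarray

    def cohort_geno(self, panel: str = "seq", true_genotypes: bool = False) -> GenotypeMatrix:
        """Cohort genotypes restricted to a panel ('80k', '650k', 'seq')."""
        col = {"80k": "in_80k", "650k": "in_650k", "seq": "in_seq"}[panel.lower()]
        vids = self.variants.loc[self.variants[col], "id"].to_numpy()
        src = self.geno_true if true_genotypes else self.geno
        return src.subset(variant_ids=vids)


def simulate_dataset(
    config: SimConfig, rng: np.random.Generator | None = None, annotation_enrichment: float = 1.0
) -> SimData:
    """Run the full generator: pedigree, genotypes, panels, traits, phenotypes.

    The error model is applied only to variants outside the 80K-like panel
    (array genotypes are observed directly; denser panels are 'imputed').
    """
    rng = config.rng() if rng is None else rng
    ped = simulate_pedigree(config, rng)
    variants = make_variant_map(config, rng)
    founders = sample_founder_haplotypes(config, variants, rng)
    geno_all = drop_haplotypes(ped, founders, variants, config, rng)
    cohort = _final_cohort(ped, config)
    geno_cohort = geno_all.subset(animal_ids=cohort)
    variants = define_panels(variants, geno_cohort, config, rng)
    qtl_effects: dict[str, pd.Series] = {}
    for arch in config.trait_architectures:
        qtl_effects[arch.trait_name] = assign_qtl_effects(variants, arch, geno_cohort, rng)
    truth = TrueValues(qtl_effects, true_breeding_values(geno_all, qtl_effects))
    all_qtl = np.unique(np.concatenate([e.index.to_numpy() for e in qtl_effects.values()]))
    variants = annotate_variants(variants, all_qtl, rng, enrichment=annotation_enrichment)
    pheno = simulate_phenotypes(geno_all, truth, ped, config, rng)
    geno_err = geno_cohort
    if config.genotype_error_rate > 0:
        imputed = ~pd.Series(variants["in_80k"].to_numpy(), index=variants["id"]).reindex(
            geno_cohort.variant_ids
        ).to_numpy()
        geno_err = geno_cohort.copy()
        sub = geno_cohort.subset(variant_ids=geno_cohort.variant_ids[imputed])
        corr = corrupt_genotypes(
            sub, config.genotype_error_rate, rng, maf_dependence=True
        )
        geno_err.dosages[:, imputed] = corr.dosages
    return SimData(config, ped, variants, geno_cohort, geno_err, pheno, truth, cohort)
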