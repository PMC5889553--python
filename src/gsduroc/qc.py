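"""Variant and phenotype quality control, plus imputation-accuracy statistics.

Filters follow the standard array-genotyping pipeline for a purebred pig
cohort: variant call rate > 0.95, autosomes only, Hardy-Weinberg chi-square
below a (deliberately permissive) threshold of 600, MAF > 0.05 among the
genotyped animals, and — where an imputed panel is being screened —
per-variant imputation accuracy > 0.95. Phenotypes are trimmed at three
standard deviations from the trait mean.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

__all__ = [
    "QCThresholds",
    "hwe_chisq",
    "filter_variants",
    "FilterLog",
    "trim_outlier_phenotypes",
    "imputation_accuracy",
    "ACCURACY_BINS",
]


@dataclass(frozen=True)
class QCThresholds:
    """Variant-retention thresholds (defaults match the package benchmarks).

    Any criterion can be disabled by setting it to None.
    """

    min_call_rate: float | None = 0.95
    max_hwe_chisq: float | None = 600.0
    min_maf: float | None = 0.05
    min_imputation_accuracy: float | None = 0.95
    autosomes_only: bool = True


def hwe_chisq(n_homref: int, n_het: int, n_homalt: int) -> float:
    """1-df Pearson chi-square against Hardy-Weinberg expected counts.

    Expected counts come from the observed allele frequency; no continuity
    correction. A monomorphic variant returns 0 by convention.
    """
    counts = np.array([n_homref, n_het, n_homalt], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    return float(np.sum((counts - expected) ** 2 / expected))


def hwe_chisq_per_variant(geno: GenotypeMatrix) -> np.ndarray:
    d = geno.dosages
    obs = d != MISSING
    n0 = ((d == 0) & obs).sum(axis=0)
    n1 = (d == 1).sum(axis=0)
    n2 = (d == 2).sum(axis=0)
    return np.array([hwe_chisq(a, b, c) if a + b + c else 0.0 for a, b, c in zip(n0, n1, n2)])


@dataclass
class FilterLog:
    """Per-criterion removal counts, in order of application."""

    order: list
    removed: dict
    n_in: int
    n_out: int

    def to_dict(self) -> dict:
        return asdict(self)


def filter_variants(
    geno: GenotypeMatrix,
    variants: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
    accuracy: np.ndarray | pd.Series | None = None,
    autosomes: set | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, FilterLog]:
    """Apply the variant filters; survivors satisfy every enabled threshold.

    Order of application (recorded in the log): call rate, autosome, HWE,
    MAF, imputation accuracy. Retention is strict in the keep direction:
    call rate > min, chi-square < max, MAF > min, accuracy > min.

    ``accuracy`` is an optional per-variant fraction aligned with
    ``geno.variant_ids`` (or indexed by variant id).
    """
    variants = variants.set_index("id", drop=False).loc[list(geno.variant_ids)].reset_index(drop=True)
    keep = np.ones(geno.n_variants, dtype=bool)
    removed: dict[str, int] = {}
    order: list[str] = []
    t = thresholds

    def apply(name: str, ok: np.ndarray) -> None:
        order.append(name)
        newly = keep & ~ok
        removed[name] = int(newly.sum())
        keep[newly] = False

    if t.min_call_rate is not None:
        apply("call_rate", geno.call_rate() > t.min_call_rate)
    if t.autosomes_only:
        if autosomes is None:
            autos = np.array([str(c).isdigit() for c in variants["chrom"]])
        else:
            autos = variants["chrom"].astype(str).isin({str(c) for c in autosomes}).to_numpy()
        apply("autosome", autos)
    if t.max_hwe_chisq is not None:
        apply("hwe", hwe_chisq_per_variant(geno) < t.max_hwe_chisq)
    if t.min_maf is not None:
        apply("maf", geno.maf() > t.min_maf)
    if t.min_imputation_accuracy is not None and accuracy is not None:
        acc = (
            accuracy.reindex(geno.variant_ids).to_numpy()
            if isinstance(accuracy, pd.Series)
            else np.asarray(accuracy, float)
        )
        apply("imputation_accuracy", acc > t.min_imputation_accuracy)
    log = FilterLog(order, removed, geno.n_variants, int(keep.sum()))
    kept_ids = geno.variant_ids[keep]
    return geno.subset(variant_ids=kept_ids), variants.loc[keep].reset_index(drop=True), log


def trim_outlier_phenotypes(
    pheno: pd.DataFrame, traits: list[str], k_sd: float = 3.0
) -> pd.DataFrame:
    """Blank trait records more than ``k_sd`` SD from the trait mean.

    Mean and SD are computed on the input values of each trait; offending
    records are set to NaN for that trait only (other traits and covariates
    are untouched). A zero-SD trait removes nothing.
    """
    out = pheno.copy()
    for t in traits:
        y = out[t].to_numpy(dtype=float)
        mu, sd = np.nanmean(y), np.nanstd(y)
        if sd == 0:
            continue
        out.loc[np.abs(y - mu) > k_sd * sd, t] = np.nan
    return out


#: imputation-accuracy summary bins (percent); ">95" is strict, 95.0 falls in "90-95"
ACCURACY_BINS = ["<80", "80-85", "85-90", "90-95", ">95"]


def _bin_accuracy(acc_pct: np.ndarray) -> pd.Series:
    counts = {}
    counts["<80"] = np.sum(acc_pct < 80.0)
    counts["80-85"] = np.sum((acc_pct >= 80.0) & (acc_pct < 85.0))
    counts["85-90"] = np.sum((acc_pct >= 85.0) & (acc_pct < 90.0))
    counts["90-95"] = np.sum((acc_pct >= 90.0) & (acc_pct <= 95.0))
    counts[">95"] = np.sum(acc_pct > 95.0)
    total = max(len(acc_pct), 1)
    return pd.Series({k: 100.0 * v / total for k, v in counts.items()})


def imputation_accuracy(
    true_geno: GenotypeMatrix, imputed_geno: GenotypeMatrix
) -> tuple[pd.Series, pd.Series, float]:
    """Per-variant genotype concordance plus a binned summary.

    Concordance is the percentage of matching genotypes among pairs where
    both calls are non-missing; it is symmetric in the two arguments.

    Returns
    -------
    per_variant : Series (variant id -> accuracy in percent)
    binned : Series of the percentage of variants per accuracy bin
        (<80, 80-85, 85-90, 90-95, >95; upper bins half-open, ">95" strict)
    mean : overall mean accuracy in percent
    """
    if true_geno.dosages.shape != imputed_geno.dosages.shape:
        raise ValueError("genotype matrices have different shapes")
    if not np.array_equal(true_geno.variant_ids, imputed_geno.variant_ids):
        raise ValueError("variant id lists differ")
    a, b = true_geno.dosages, imputed_geno.dosages
    both = (a != MISSING) & (b != MISSING)
    match = (a == b) & both
    with np.errstate(invalid="ignore"):
        acc = 100.0 * match.sum(axis=0) / both.sum(axis=0)
    per_variant = pd.Series(acc, index=true_geno.variant_ids)
    valid = per_variant.dropna().to_numpy()
    return per_variant, _bin_accuracy(valid), float(np.mean(valid))
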