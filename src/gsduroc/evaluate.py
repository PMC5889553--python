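"""Prediction accuracy, bias, improvement metrics and benchmark orchestration.

Accuracy of a prediction set is the Pearson correlation between (G)EBV and
the corrected phenotypes (y_c1, from the full-data pedigree model) of the
validation animals, divided by the square root of the trait heritability.
Bias is the ordinary least-squares slope of predictions regressed on
corrected phenotypes (1 = unbiased). Method/density comparisons use the
signed percentage improvement 100 * (acc_a - acc_b) / acc_b.

``run_benchmark`` wires the whole pipeline on one synthetic dataset:
simulate -> QC -> pedigree BLUP (full + reduced) -> GBLUP / BayesB per panel
-> (optionally) pre-selection, classification, LD pruning and BayesRC on the
sequence set -> one tidy report table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import BayesB
from .bayesrc import BayesRC, MixtureSpec
from .gblup import GBLUP
from .pedigree import PedigreeBLUP, split_train_validation
from .qc import QCThresholds, filter_variants, trim_outlier_phenotypes
from .select import classify_variants, ld_prune, make_subdatasets, preselect_top
from .simulate import SimConfig, simulate_dataset

__all__ = ["accuracy", "bias_slope", "improvement_pct", "BenchmarkConfig", "run_benchmark"]


def accuracy(predictions: np.ndarray, yc1: np.ndarray, h2: float) -> float:
    """cor(GEBV, corrected phenotype) / sqrt(h2) over validation animals."""
    predictions = np.asarray(predictions, float)
    yc1 = np.asarray(yc1, float)
    if len(predictions) < 3:
        raise ValueError("need at least 3 validation animals")
    if not (0 < h2 <= 1):
        raise ValueError("h2 must be in (0, 1]")
    if np.std(predictions) == 0 or np.std(yc1) == 0:
        raise ValueError("zero variance in predictions or corrected phenotypes")
    return float(np.corrcoef(predictions, yc1)[0, 1] / np.sqrt(h2))


def bias_slope(predictions: np.ndarray, yc1: np.ndarray) -> float:
    """OLS slope of predictions on corrected phenotypes (1 = no bias)."""
    predictions = np.asarray(predictions, float)
    yc1 = np.asarray(yc1, float)
    vx = np.var(yc1)
    if vx == 0:
        raise ValueError("zero variance in corrected phenotypes")
    return float(np.cov(predictions, yc1, ddof=0)[0, 1] / vx)


def improvement_pct(acc_a: float, acc_b: float) -> float:
    """Signed percentage improvement of a over b: 100 (a - b) / b."""
    if acc_b == 0:
        raise ValueError("reference accuracy is zero")
    return 100.0 * (acc_a - acc_b) / acc_b


@dataclass
class BenchmarkConfig:
    """Controls for one end-to-end benchmark run."""

    sim: SimConfig = field(default_factory=SimConfig)
    traits: tuple | None = None            # None: all simulated traits
    panels: tuple = ("80k", "650k")
    methods: tuple = ("pedigree", "gblup", "bayesb")
    run_bayesrc: bool = False              # adds the SEQ pre-selection + BayesRC branch
    validation_fraction: float = 0.144     # youngest animals held out
    pi_by_panel: dict = field(default_factory=lambda: {"80k": 0.99, "650k": 0.999, "seq": 0.9995})
    n_iter: int = 2000
    burn_in: int = 400
    scan_n_iter: int = 1000                # per-chromosome pre-selection scans
    scan_burn_in: int = 200
    bayesrc_chains: int = 2
    preselect_fraction: float = 0.0005
    annotation_enrichment: float = 1.0
    qc: QCThresholds = field(default_factory=lambda: QCThresholds(min_imputation_accuracy=None))
    seed: int = 1


def _fixed_design(pheno: pd.DataFrame, trait: str, with_machine: bool) -> np.ndarray:
    """Intercept + contemporary-group dummies (first level dropped) + machine + age."""
    from .pedigree import FixedEffectsSpec

    spec = FixedEffectsSpec(
        factors=("cg", "machine") if with_machine else ("cg",), covariates=("age",)
    )
    X, _ = spec.build_design(pheno)
    return X


def run_benchmark(config: BenchmarkConfig) -> pd.DataFrame:
    """Run the full comparison grid on one synthetic dataset.

    Returns a tidy DataFrame with one row per (trait, panel, method) holding
    accuracy, bias, the truth-based accuracy cor(GEBV, TBV), and metadata.
    Reruns with the same config are identical.
    """
    rng = np.random.default_rng(config.seed)
    data = simulate_dataset(
        config.sim, rng, annotation_enrichment=config.annotation_enrichment
    )
    ped, pheno = data.pedigree, data.phenotypes
    traits = list(config.traits or data.truth.tbv.columns)
    pheno = trim_outlier_phenotypes(pheno, traits)
    arch = {a.trait_name: a for a in config.sim.trait_architectures}

    # birthdate split: youngest fraction for validation
    cut = np.quantile(
        pheno["birthdate"].to_numpy(), 1 - config.validation_fraction, method="higher"
    )
    train_ids, val_ids = split_train_validation(ped, cut)
    cohort = set(pheno["animal"])
    train_ids = np.array([a for a in train_ids if a in cohort], dtype=object)
    val_ids = np.array([a for a in val_ids if a in cohort], dtype=object)

    rows = []
    for trait in traits:
        sub = pheno.loc[pheno[trait].notna()].reset_index(drop=True)
        y = sub[trait].to_numpy(float)
        X = _fixed_design(sub, trait, arch[trait].has_machine_effect)
        ids = sub["animal"].to_numpy(dtype=object)
        is_val = np.isin(ids, val_ids)
        # full model: variance components + y_c1 for validation
        full = PedigreeBLUP().fit(X, y, pedigree=ped, pheno_ids=ids)
        h2 = full.h2_
        yc1 = full.solution_.corrected()
        # reduced model: EBV2 for validation, y_c2 for training
        red = PedigreeBLUP(full.vc_.sigma_a2, full.vc_.sigma_e2).fit(
            X, y, pedigree=ped, pheno_ids=ids, mask=is_val
        )
        yc2 = red.solution_.corrected()
        yv = yc1.loc[ids[is_val]].to_numpy()
        tbv_v = data.truth.tbv.loc[ids[is_val], trait].to_numpy()

        def add(panel, method, preds):
            rows.append(
                {
                    "trait": trait,
                    "panel": panel,
                    "method": method,
                    "accuracy": accuracy(preds, yv, h2),
                    "bias": bias_slope(preds, yv),
                    "accuracy_tbv": float(np.corrcoef(preds, tbv_v)[0, 1]),
                    "h2": h2,
                    "n_train": int((~is_val).sum()),
                    "n_val": int(is_val.sum()),
                    "seed": config.seed,
                }
            )

        if "pedigree" in config.methods:
            add("pedigree", "BLUP", red.predict(ids[is_val]))
        for panel in config.panels:
            geno_p = data.cohort_geno(panel).subset(animal_ids=ids)
            geno_p, _, _ = filter_variants(geno_p, data.variants, config.qc)
            Xtr = geno_p.subset(animal_ids=ids[~is_val])
            Xva = geno_p.subset(animal_ids=ids[is_val])
            sg2 = h2 * float(np.var(y))
            if "gblup" in config.methods:
                g = GBLUP(sigma_a2=full.vc_.sigma_a2, sigma_e2=full.vc_.sigma_e2)
                g.fit(Xtr, y[~is_val], fixed=X[~is_val])
                add(panel, "GBLUP", g.predict(Xva))
            if "bayesb" in config.methods:
                bb = BayesB(
                    pi=config.pi_by_panel.get(panel, 0.99),
                    n_iter=config.n_iter, burn_in=config.burn_in,
                    seed=int(rng.integers(2**31 - 1)),
                )
                bb.fit(
                    Xtr, y[~is_val], fixed=X[~is_val],
                    sigma_g2=sg2, sigma_e2=full.vc_.sigma_e2,
                )
                add(panel, "BayesB", bb.predict(Xva))
        if config.run_bayesrc:
            add_bayesrc_row(
                config, data, trait, ids, is_val, y, X, full, yc2, rng, add
            )
    return pd.DataFrame(rows)


def add_bayesrc_row(config, data, trait, ids, is_val, y, X, full, yc2, rng, add):
    """SEQ branch: split-and-merge scans, classification, prune, BayesRC."""
    variants = data.variants
    subsets = make_subdatasets(variants)
    geno = data.geno.subset(animal_ids=ids)
    eff_all = {}
    train = ids[~is_val]
    for sd in subsets:
        vids = sd.variant_ids
        g = geno.subset(animal_ids=train, variant_ids=vids)
        bb = BayesB(
            pi=config.pi_by_panel.get("seq", 0.9995),
            n_iter=config.scan_n_iter, burn_in=config.scan_burn_in,
            seed=int(rng.integers(2**31 - 1)),
        )
        bb.fit(g, y[~is_val], fixed=X[~is_val])
        for v, a in zip(vids[: len(sd.focal_ids)], bb.alpha_hat_[: len(sd.focal_ids)]):
            eff_all[v] = a
    eff = pd.Series(eff_all)
    _, merged = preselect_top({trait: eff}, config.preselect_fraction)
    classified = classify_variants(variants, merged["id"].to_numpy())
    poly = geno.subset(animal_ids=train).maf() > 0  # polymorphic in training
    kept, _ = ld_prune(
        geno.subset(variant_ids=geno.variant_ids[poly]),
        classified.loc[classified["id"].isin(geno.variant_ids[poly])],
    )
    gk = geno.subset(variant_ids=kept["id"].to_numpy())
    rc = BayesRC(
        MixtureSpec(sigma_g2=max(full.vc_.sigma_a2, 1e-8)),
        n_iter=config.n_iter, burn_in=config.burn_in,
        n_chains=config.bayesrc_chains, seed=int(rng.integers(2**31 - 1)),
    )
    rc.fit(
        gk.subset(animal_ids=train),
        yc2.loc[train].to_numpy(),
        classes=kept["class_label"].to_numpy(),
        pedigree=data.pedigree,
        pheno_ids=train,
    )
    add("seq", "BayesRC", rc.predict(gk.subset(animal_ids=ids[is_val])))
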