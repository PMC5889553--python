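"""In-memory containers shared across the pipeline.

Genotypes live in a :class:`GenotypeMatrix` (animals x variants dosage matrix,
int8, missing coded -1). Variant metadata is a plain pandas DataFrame with a
documented column set (see :data:`VARIANT_COLUMNS`); phenotypes likewise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: canonical variant-table columns
VARIANT_COLUMNS = [
    "id",            # variant label
    "chrom",         # chromosome label
    "pos",           # 1-based bp position
    "ref",           # reference allele (coded 0)
    "alt",           # alternate allele (coded 1)
    "maf",           # minor allele frequency among genotyped animals
    "call_rate",     # fraction of non-missing genotypes
    "in_80k",        # panel membership flags (nested 80K < 650K < SEQ)
    "in_650k",
    "in_seq",
    "annotation_term",  # raw functional term (missense, intergenic, ...)
    "class_label",      # NSC | REG | CHIP | unassigned
    "is_qtl",           # truth flag, synthetic data only
]


@dataclass
class GenotypeMatrix:
    """Dosage matrix (n_animals x n_variants) with entries {0,1,2,-1=missing}."""

    dosages: np.ndarray
    animal_ids: np.ndarray
    variant_ids: np.ndarray
    _vindex: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.dtype != np.int8:
            self.dosages = self.dosages.astype(np.int8)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        na, nv = self.dosages.shape
        if na != len(self.animal_ids) or nv != len(self.variant_ids):
            raise ValueError("dosage matrix shape does not match id lists")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 for missing")
        self._vindex = {v: j for j, v in enumerate(self.variant_ids)}

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self, ids) -> np.ndarray:
        return np.array([self._vindex[v] for v in np.asarray(ids, dtype=object)])

    def subset(self, animal_ids=None, variant_ids=None) -> "GenotypeMatrix":
        d = self.dosages
        aids, vids = self.animal_ids, self.variant_ids
        if animal_ids is not None:
            aidx = {a: i for i, a in enumerate(self.animal_ids)}
            rows = np.array([aidx[a] for a in np.asarray(animal_ids, dtype=object)])
            d = d[rows]
            aids = self.animal_ids[rows]
        if variant_ids is not None:
            cols = self.variant_index(variant_ids)
            d = d[:, cols]
            vids = self.variant_ids[cols]
        return GenotypeMatrix(d.copy(), aids.copy(), vids.copy())

    def allele_freq(self) -> np.ndarray:
        """Per-variant alternate-allele frequency over non-missing genotypes."""
        d = self.dosages
        obs = d != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(obs, d, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return (self.dosages != MISSING).mean(axis=0)

    def mean_impute(self) -> np.ndarray:
        """Float copy with missing dosages replaced by the variant mean."""
        d = self.dosages.astype(float)
        miss = self.dosages == MISSING
        if miss.any():
            obs = ~miss
            col_mean = np.where(obs, d, 0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
            d[miss] = np.broadcast_to(col_mean, d.shape)[miss]
        return d

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), self.animal_ids.copy(), self.variant_ids.copy())


def new_variant_table(ids, chrom, pos, ref="A", alt="G") -> pd.DataFrame:
    """Variant table with canonical columns and sensible defaults."""
    n = len(ids)
    df = pd.DataFrame(
        {
            "id": np.asarray(ids, dtype=object),
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": ref if np.isscalar(ref) else np.asarray(ref, dtype=object),
            "alt": alt if np.isscalar(alt) else np.asarray(alt, dtype=object),
            "maf": np.nan,
            "call_rate": 1.0,
            "in_80k": False,
            "in_650k": False,
            "in_seq": True,
            "annotation_term": "unannotated",
            "class_label": "unassigned",
            "is_qtl": False,
        }
    )
    if (df["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    if df["id"].duplicated().any():
        raise ValueError("duplicate variant ids")
    return df


def check_panel_nesting(variants: pd.DataFrame) -> None:
    """Assert the 80K < 650K < SEQ membership chain."""
    if (variants["in_80k"] & ~variants["in_650k"]).any():
        raise AssertionError("panel nesting violated: 80K variant missing from 650K")
    if (variants["in_650k"] & ~variants["in_seq"]).any():
        raise AssertionError("panel nesting violated: 650K variant missing from SEQ")
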