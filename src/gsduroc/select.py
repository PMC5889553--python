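"""Sequence-variant pre-selection, biological classes and ordered LD pruning.

The split-and-merge pre-selection runs one association scan per autosome on a
sub-dataset holding that chromosome's sequence variants plus the 80K-panel
SNPs of all other chromosomes (which absorb polygenic background). Effects
for focal variants from every scan are merged genome-wide and, per trait,
the top fraction by absolute effect is selected. Variants are then assigned
to three broad classes:

* NSC — predicted non-synonymous coding changes (missense, splice site,
  in-frame indels, frameshift, stop gained/lost) plus any variant
  pre-selected by the association scans regardless of its term;
* REG — putatively regulatory: near-gene (within 5 kb), UTR, non-coding exon;
* CHIP — the remainder (intergenic, intronic, synonymous, unannotated).

LD pruning (r^2 on genotype dosages) runs in three ordered stages: within
each class independently; then REG/CHIP variants in complete LD with an NSC
variant are removed; finally CHIP variants in complete LD with a REG variant
are removed. The survivors form the "SEQ" analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .simulate import NSC_TERMS, REG_TERMS

__all__ = [
    "SubDataset",
    "make_subdatasets",
    "preselect_top",
    "classify_variants",
    "ld_prune",
    "PruneLog",
]


@dataclass
class SubDataset:
    """One per-autosome association-scan input."""

    focal_chromosome: str
    focal_ids: np.ndarray      # sequence variants of the focal chromosome
    background_ids: np.ndarray  # 80K-panel variants from the other chromosomes

    @property
    def variant_ids(self) -> np.ndarray:
        return np.concatenate([self.focal_ids, self.background_ids])


def make_subdatasets(variants: pd.DataFrame, n_autosomes: int | None = None) -> list[SubDataset]:
    """Split-and-merge sub-datasets, one per autosome.

    Every sequence variant appears as focal exactly once; a sub-dataset never
    contains 80K variants from its own focal chromosome.
    """
    chroms = list(dict.fromkeys(variants["chrom"].astype(str)))
    if n_autosomes is not None:
        chroms = chroms[:n_autosomes]
    seq = variants.loc[variants["in_seq"]]
    chip = variants.loc[variants["in_80k"]]
    out = []
    for c in chroms:
        focal = seq.loc[seq["chrom"].astype(str) == c, "id"].to_numpy()
        bg = chip.loc[chip["chrom"].astype(str) != c, "id"].to_numpy()
        out.append(SubDataset(c, focal, bg))
    return out


def preselect_top(
    effects_per_trait: dict[str, pd.Series], fraction: float
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Per-trait top lists by |effect| and their merged union.

    ``effects_per_trait`` maps trait -> Series(variant id -> effect) covering
    all sequence variants (focal entries merged across the per-chromosome
    scans). Per trait, ceil(fraction * n) variants are chosen by descending
    absolute effect, ties broken by variant id for determinism. Returns the
    per-trait id arrays and a merged table with per-variant trait provenance.
    """
    import math
    import warnings

    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    top: dict[str, np.ndarray] = {}
    for trait, eff in effects_per_trait.items():
        k = math.ceil(fraction * len(eff))
        if (eff == 0).all():
            warnings.warn(f"all effects zero for {trait!r}; selection degenerates to id order")
        df = pd.DataFrame({"id": eff.index.astype(str), "a": eff.to_numpy()})
        df["absa"] = np.abs(df["a"])
        df = df.sort_values(["absa", "id"], ascending=[False, True], kind="stable")
        top[trait] = df["id"].to_numpy(dtype=object)[:k]
    prov: dict[str, list[str]] = {}
    for trait, ids in top.items():
        for v in ids:
            prov.setdefault(v, []).append(trait)
    merged = pd.DataFrame(
        {"id": list(prov), "traits": [",".join(t) for t in prov.values()]}
    ).sort_values("id").reset_index(drop=True)
    return top, merged


def classify_variants(variants: pd.DataFrame, preselected_ids=()) -> pd.DataFrame:
    """Assign NSC/REG/CHIP class labels from annotation terms.

    Pre-selected variants are forced into NSC whatever their term; the rest
    map through the term table (NSC terms, REG terms, everything else CHIP).
    Returns a copy of the variant table with ``class_label`` and
    ``class_provenance`` filled.
    """
    out = variants.copy()
    term = out["annotation_term"].astype(str)
    label = np.where(
        term.isin(NSC_TERMS), "NSC", np.where(term.isin(REG_TERMS), "REG", "CHIP")
    )
    prov = np.full(len(out), "annotation-rule", dtype=object)
    pre = out["id"].isin(np.asarray(list(preselected_ids), dtype=object)).to_numpy()
    label = np.where(pre, "NSC", label)
    prov = np.where(pre, "preselected-GWAS", prov)
    out["class_label"] = label
    out["class_provenance"] = prov
    return out


@dataclass
class PruneLog:
    """Removed variants with the stage and partner that triggered each removal."""

    removed: dict = field(default_factory=dict)  # id -> (stage, partner id)

    def record(self, vid, stage, partner) -> None:
        self.removed[vid] = (stage, partner)

    def to_dict(self) -> dict:
        return {v: {"stage": s, "partner": p} for v, (s, p) in self.removed.items()}


def _prune_within(
    order: np.ndarray,
    pos: np.ndarray,
    D: np.ndarray,
    maf: np.ndarray,
    r2_threshold: float,
    window_kb: float,
    window_count: int,
    alive: np.ndarray,
    log: PruneLog,
    ids: np.ndarray,
    stage: str,
) -> None:
    """Stage-1 style sliding-window prune among the variants in ``order``.

    Windows hold ``window_count`` variants bounded by ``window_kb`` and
    advance by half the count. Of a flagged pair the lower-MAF member is
    removed (ties by id), honouring the arbitrary-member rule
    deterministically.
    """
    step = max(window_count // 2, 1)
    start = 0
    m = len(order)
    while start < m:
        win = [j for j in order[start:start + window_count] if alive[j]]
        win = [j for j in win if pos[j] - pos[win[0]] <= window_kb * 1000] if win else []
        for x in range(len(win)):
            j = win[x]
            if not alive[j]:
                continue
            for ytx in range(x + 1, len(win)):
                k = win[ytx]
                if not alive[k]:
                    continue
                d1 = D[:, j] - D[:, j].mean()
                d2 = D[:, k] - D[:, k].mean()
                den = np.sqrt((d1 @ d1) * (d2 @ d2))
                r2 = (d1 @ d2) ** 2 / den**2 if den > 0 else 0.0
                if r2 > r2_threshold:
                    # drop the lower-MAF member, ties by id
                    if (maf[j], str(ids[j])) <= (maf[k], str(ids[k])):
                        drop, keep = j, k
                    else:
                        drop, keep = k, j
                    alive[drop] = False
                    log.record(ids[drop], stage, ids[keep])
                    if drop == j:
                        break
        start += step


def ld_prune(
    geno: GenotypeMatrix,
    variants: pd.DataFrame,
    r2_threshold: float = 0.99,
    window_kb: float = 5000.0,
    window_count: int = 50,
) -> tuple[pd.DataFrame, PruneLog]:
    """Three-stage ordered LD prune producing the SEQ analysis set.

    Stage 1 prunes within each class independently (sliding windows per
    chromosome); stage 2 removes any surviving REG or CHIP variant in
    complete LD with a surviving NSC variant; stage 3 removes CHIP variants
    in complete LD with a surviving REG variant. Cross-stage comparisons are
    restricted to the same chromosome within ``window_kb``.

    Returns the surviving rows of ``variants`` and the removal log.
    """
    if window_kb <= 0 or window_count <= 0:
        raise ValueError("window parameters must be positive")
    v = variants.set_index("id", drop=False).loc[list(geno.variant_ids)].reset_index(drop=True)
    if "class_label" not in v or (v["class_label"] == "unassigned").all():
        raise ValueError("variants must carry NSC/REG/CHIP class labels")
    D = geno.dosages.astype(float)
    maf = geno.maf()
    ids = v["id"].to_numpy(dtype=object)
    pos = v["pos"].to_numpy()
    chrom = v["chrom"].astype(str).to_numpy()
    cls = v["class_label"].to_numpy()
    alive = np.ones(len(v), dtype=bool)
    log = PruneLog()
    for c in dict.fromkeys(chrom):
        on_c = np.flatnonzero(chrom == c)
        on_c = on_c[np.argsort(pos[on_c], kind="stable")]
        for label in ("NSC", "REG", "CHIP"):
            order = on_c[cls[on_c] == label]
            _prune_within(
                order, pos, D, maf, r2_threshold, window_kb, window_count,
                alive, log, ids, f"within-{label}",
            )
        # stages 2 and 3: cross-class complete-LD removal, priority NSC > REG > CHIP
        for stage, high, low in (
            ("vs-NSC", "NSC", ("REG", "CHIP")),
            ("vs-REG", "REG", ("CHIP",)),
        ):
            hi = on_c[(cls[on_c] == high) & alive[on_c]]
            lo = on_c[np.isin(cls[on_c], low) & alive[on_c]]
            if len(hi) == 0 or len(lo) == 0:
                continue
            for j in lo:
                near = hi[np.abs(pos[hi] - pos[j]) <= window_kb * 1000]
                if len(near) == 0:
                    continue
                d1 = D[:, j] - D[:, j].mean()
                n1 = d1 @ d1
                for k in near:
                    if not alive[j]:
                        break
                    d2 = D[:, k] - D[:, k].mean()
                    den = n1 * (d2 @ d2)
                    r2 = (d1 @ d2) ** 2 / den if den > 0 else 0.0
                    if r2 > r2_threshold:
                        alive[j] = False
                        log.record(ids[j], stage, ids[k])
    return v.loc[alive].reset_index(drop=True), log
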