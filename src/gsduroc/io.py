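"""Reading and writing the standard on-disk formats.

Genotypes travel either as VCF 4.2 (GT field, 1-based positions, contig
headers; read back through cyvcf2) or as a plain dosage TSV (variants x
animals, 0/1/2, '.' for missing). Pedigree, phenotype, annotation and truth
tables are TSV with headers. Round trips are lossless for the dosage matrix
and id lists.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, new_variant_table
from .pedigree import Pedigree

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_pedigree",
    "read_pedigree",
    "write_phenotypes",
    "read_phenotypes",
    "write_annotation",
    "read_annotation",
    "load_dataset",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(path, geno: GenotypeMatrix, variants: pd.DataFrame) -> None:
    """Write genotypes as an uncompressed VCF 4.2 with GT fields."""
    v = variants.set_index("id", drop=False).loc[list(geno.variant_ids)]
    contigs = list(dict.fromkeys(v["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gsduroc\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(a) for a in geno.animal_ids)
            + "\n"
        )
        d = geno.dosages
        for j, (_, row) in enumerate(v.iterrows()):
            gts = "\t".join(_GT[int(x)] for x in d[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF (via cyvcf2) into a GenotypeMatrix and variant table."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    ids, chroms, pos, ref, alt, rows = [], [], [], [], [], []
    for rec in vcf:
        ids.append(rec.ID if rec.ID else f"{rec.CHROM}_{rec.POS}")
        chroms.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0] if rec.ALT else "N")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        row = np.where(gt == 3, 2, gt).astype(np.int8)
        row[gt == 2] = MISSING
        rows.append(row)
    vcf.close()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant IDs in VCF")
    dos = np.array(rows, dtype=np.int8).T if rows else np.empty((len(samples), 0), np.int8)
    vt = new_variant_table(ids, chroms, pos, ref=np.array(ref, object), alt=np.array(alt, object))
    return GenotypeMatrix(dos, samples, np.array(ids, dtype=object)), vt


def write_dosage_tsv(path, geno: GenotypeMatrix) -> None:
    """Variants x animals dosage TSV; '.' encodes a missing genotype."""
    df = pd.DataFrame(
        geno.dosages.T, index=pd.Index(geno.variant_ids, name="variant_id"),
        columns=geno.animal_ids,
    ).astype(object)
    df[df == MISSING] = "."
    df.to_csv(path, sep="\t")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    d = df.to_numpy()
    d = np.where(d == ".", MISSING, d).astype(np.int8)
    return GenotypeMatrix(d.T, df.columns.to_numpy(dtype=object), df.index.to_numpy(dtype=object))


def write_pedigree(path, ped: Pedigree) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    return Pedigree.from_frame(pd.read_csv(path, sep="\t", dtype={"animal": str, "sire": str, "dam": str}))


def write_phenotypes(path, pheno: pd.DataFrame) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"animal": str})


def write_annotation(path, variants: pd.DataFrame) -> None:
    variants[["id", "annotation_term"]].rename(columns={"id": "variant_id"}).to_csv(
        path, sep="\t", index=False
    )


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_filter_log(path, log) -> None:
    Path(path).write_text(json.dumps(log.to_dict(), indent=2))


def load_dataset(
    genotype_path,
    pedigree_path,
    phenotype_path,
    annotation_path=None,
    strict: bool = True,
):
    """Load and cross-reference a dataset from disk.

    ``genotype_path`` may be a VCF (suffix .vcf) or dosage TSV. Unknown
    parents in the pedigree are treated as founders. With ``strict`` on, a
    phenotype row whose animal has no genotype raises; otherwise it warns.

    Returns (GenotypeMatrix, variant table, Pedigree, phenotype table).
    """
    import warnings

    gp = str(genotype_path)
    if gp.endswith(".vcf") or gp.endswith(".vcf.gz"):
        geno, variants = read_vcf(genotype_path)
    else:
        geno = read_dosage_tsv(genotype_path)
        variants = new_variant_table(
            geno.variant_ids, ["1"] * geno.n_variants, np.arange(1, geno.n_variants + 1)
        )
    variants["maf"] = geno.maf()
    variants["call_rate"] = geno.call_rate()
    ped = read_pedigree(pedigree_path)
    pheno = read_phenotypes(phenotype_path)
    genotyped = set(geno.animal_ids)
    orphan = [a for a in pheno["animal"] if a not in genotyped]
    if orphan:
        msg = f"{len(orphan)} phenotype rows reference animals with no genotype (e.g. {orphan[0]!r})"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    if annotation_path is not None:
        ann = read_annotation(annotation_path).set_index("variant_id")["annotation_term"]
        variants["annotation_term"] = (
            ann.reindex(variants["id"]).fillna("unannotated").to_numpy()
        )
    return geno, variants, ped, pheno
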