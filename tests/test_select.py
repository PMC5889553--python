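"""Split-and-merge pre-selection, class assignment and ordered LD pruning."""

import numpy as np
import pandas as pd
import pytest

from gsduroc import (
    classify_variants,
    ld_prune,
    make_subdatasets,
    preselect_top,
)
from gsduroc.containers import GenotypeMatrix, new_variant_table


class TestMakeSubdatasets:
    def _variants(self, n_chrom=18, per_chrom=20, n_chip=5):
        ids, chrom = [], []
        for c in range(1, n_chrom + 1):
            ids += [f"v{c}_{k}" for k in range(per_chrom)]
            chrom += [str(c)] * per_chrom
        v = new_variant_table(ids, chrom, list(range(1, per_chrom + 1)) * n_chrom)
        v["in_seq"] = True
        chip = v.groupby("chrom").head(n_chip).index
        v.loc[chip, "in_80k"] = True
        v.loc[chip, "in_650k"] = True
        return v

    def test_one_subdataset_per_autosome(self):
        v = self._variants()
        subs = make_subdatasets(v)
        assert len(subs) == 18

    def test_focal_variants_partition_sequence_set(self):
        v = self._variants(n_chrom=5)
        subs = make_subdatasets(v)
        focal = np.concatenate([s.focal_ids for s in subs])
        assert sorted(focal) == sorted(v.loc[v["in_seq"], "id"])
        assert len(set(focal)) == len(focal)

    def test_no_own_chromosome_chip_variants(self):
        v = self._variants(n_chrom=5)
        for s in make_subdatasets(v):
            bg_chrom = v.set_index("id").loc[s.background_ids, "chrom"]
            assert s.focal_chromosome not in set(bg_chrom)
            assert v.set_index("id").loc[s.background_ids, "in_80k"].all()


class TestPreselectTop:
    def test_fraction_arithmetic(self):
        rng = np.random.default_rng(0)
        eff = pd.Series(rng.normal(0, 1, 10_000),
                        index=[f"v{i}" for i in range(10_000)])
        top, merged = preselect_top({"t": eff}, 0.0005)
        assert len(top["t"]) == 5
        # top 5 really are the largest |effect|
        assert set(top["t"]) == set(eff.abs().nlargest(5).index)

    def test_merged_count_with_pairwise_overlap(self):
        """Four lists of 2025 sharing 245 variants pairwise merge to 7855."""
        n_list, n_shared = 2025, 245
        ids = [f"v{i:05d}" for i in range(4 * n_list)]
        traits = {}
        shared = ids[: n_shared]  # appear in exactly two lists (t0 and t1)
        pool = iter(ids[n_shared:])
        lists = {
            "t0": shared + [next(pool) for _ in range(n_list - n_shared)],
            "t1": shared + [next(pool) for _ in range(n_list - n_shared)],
            "t2": [next(pool) for _ in range(n_list)],
            "t3": [next(pool) for _ in range(n_list)],
        }
        all_ids = sorted(set(i for l in lists.values() for i in l))
        for t, members in lists.items():
            eff = pd.Series(0.0, index=all_ids)
            eff.loc[members] = np.linspace(10, 1, n_list)
            traits[t] = eff
        top, merged = preselect_top(traits, n_list / len(all_ids))
        assert all(len(v) == n_list for v in top.values())
        assert len(merged) == 7855

    def test_ties_broken_deterministically_by_id(self):
        eff = pd.Series([1.0, 1.0, 1.0, 0.5], index=["vb", "va", "vc", "vd"])
        top, _ = preselect_top({"t": eff}, 0.5)  # ceil(0.5*4) = 2
        assert list(top["t"]) == ["va", "vb"]

    def test_all_zero_effects_warns(self):
        eff = pd.Series(0.0, index=["v1", "v2", "v3"])
        with pytest.warns(UserWarning, match="zero"):
            top, _ = preselect_top({"t": eff}, 0.4)
        assert list(top["t"]) == ["v1", "v2"]

    def test_invalid_fraction_rejected(self):
        eff = pd.Series([1.0], index=["v"])
        with pytest.raises(ValueError):
            preselect_top({"t": eff}, 0.0)


class TestClassifyVariants:
    def _variants(self):
        v = new_variant_table(
            ["a", "b", "c", "d", "e"], ["1"] * 5, [1, 2, 3, 4, 5]
        )
        v["annotation_term"] = [
            "missense", "intergenic", "intronic", "utr", "synonymous"
        ]
        return v

    def test_term_rules(self):
        out = classify_variants(self._variants())
        got = dict(zip(out["id"], out["class_label"]))
        assert got == {"a": "NSC", "b": "CHIP", "c": "CHIP", "d": "REG", "e": "CHIP"}

    def test_preselected_forced_into_nsc(self):
        out = classify_variants(self._variants(), preselected_ids=["b"])
        got = out.set_index("id")
        assert got.loc["b", "class_label"] == "NSC"
        assert got.loc["b", "class_provenance"] == "preselected-GWAS"
        assert got.loc["a", "class_provenance"] == "annotation-rule"

    def test_partition_complete(self):
        out = classify_variants(self._variants())
        assert set(out["class_label"]) <= {"NSC", "REG", "CHIP"}
        assert out["class_label"].notna().all()


def _geno_from(dos):
    dos = np.asarray(dos, dtype=np.int8)
    n, p = dos.shape
    return GenotypeMatrix(
        dos,
        np.array([f"a{i}" for i in range(n)], object),
        np.array([f"v{j}" for j in range(p)], object),
    )


def _vt(p, classes, pos=None, chrom=None):
    v = new_variant_table(
        [f"v{j}" for j in range(p)],
        ["1"] * p if chrom is None else chrom,
        list(range(1, p + 1)) if pos is None else pos,
    )
    v["class_label"] = classes
    return v


class TestLdPrune:
    def test_exact_duplicates_keep_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 30)
        dos = np.column_stack([col, col, rng.integers(0, 3, 30)])
        geno = _geno_from(dos)
        kept, log = ld_prune(geno, _vt(3, ["CHIP"] * 3))
        ids = set(kept["id"])
        assert len(ids & {"v0", "v1"}) == 1
        assert "v2" in ids
        removed = set(geno.variant_ids) - ids
        assert all(log.removed[r][0] == "within-CHIP" for r in removed)

    def test_class_priority_nsc_survives_chip(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, 40)
        dos = np.column_stack([col, col])
        geno = _geno_from(dos)
        kept, log = ld_prune(geno, _vt(2, ["NSC", "CHIP"]))
        assert list(kept["id"]) == ["v0"]
        assert log.removed["v1"][0] == "vs-NSC"
        assert log.removed["v1"][1] == "v0"

    def test_chip_removed_against_reg(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, 40)
        geno = _geno_from(np.column_stack([col, col]))
        kept, log = ld_prune(geno, _vt(2, ["REG", "CHIP"]))
        assert list(kept["id"]) == ["v0"]
        assert log.removed["v1"][0] == "vs-REG"

    def test_windowless_matches_brute_force_oracle(self):
        """Window spanning the chromosome reproduces an all-pairs greedy prune."""
        rng = np.random.default_rng(3)
        n, p = 60, 200
        base = rng.integers(0, 3, (n, 30))
        cols = []
        for j in range(p):
            src = base[:, rng.integers(0, 30)]
            if rng.random() < 0.5:
                cols.append(src.copy())  # duplicates -> complete LD
            else:
                cols.append(rng.integers(0, 3, n))
        dos = np.column_stack(cols)
        geno = _geno_from(dos)
        classes = ["CHIP"] * p
        variants = _vt(p, classes)
        kept, _ = ld_prune(
            geno, variants, r2_threshold=0.99, window_kb=10**6, window_count=p
        )

        # independent oracle: ordered all-pairs greedy removal, same drop rule
        D = dos.astype(float)
        maf = geno.maf()
        alive = np.ones(p, bool)
        for x in range(p):
            if not alive[x]:
                continue
            for ytx in range(x + 1, p):
                if not (alive[x] and alive[ytx]):
                    continue
                d1 = D[:, x] - D[:, x].mean()
                d2 = D[:, ytx] - D[:, ytx].mean()
                den = np.sqrt((d1 @ d1) * (d2 @ d2))
                r2 = (d1 @ d2) ** 2 / den**2 if den > 0 else 0.0
                if r2 > 0.99:
                    if (maf[x], f"v{x}") <= (maf[ytx], f"v{ytx}"):
                        alive[x] = False
                    else:
                        alive[ytx] = False
        expected = {f"v{j}" for j in np.flatnonzero(alive)}
        assert set(kept["id"]) == expected

    def test_no_remaining_complete_ld_within_class(self):
        rng = np.random.default_rng(4)
        n, p = 50, 80
        base = rng.integers(0, 3, (n, 10))
        dos = np.column_stack(
            [base[:, rng.integers(0, 10)] for _ in range(p)]
        )
        geno = _geno_from(dos)
        classes = rng.choice(["NSC", "REG", "CHIP"], p).tolist()
        kept, _ = ld_prune(
            geno, _vt(p, classes), window_kb=10**6, window_count=p
        )
        kd = geno.subset(variant_ids=kept["id"].to_numpy()).dosages.astype(float)
        C = np.corrcoef(kd.T) ** 2
        for lbl in ("NSC", "REG", "CHIP"):
            m = (kept["class_label"] == lbl).to_numpy()
            if m.sum() > 1:
                sub = C[np.ix_(m, m)]
                off = sub[~np.eye(m.sum(), dtype=bool)]
                assert np.nanmax(off) <= 0.99 + 1e-12

    def test_bad_window_parameters_rejected(self):
        geno = _geno_from(np.random.default_rng(0).integers(0, 3, (10, 3)))
        with pytest.raises(ValueError, match="window"):
            ld_prune(geno, _vt(3, ["CHIP"] * 3), window_kb=0)

    def test_unlabelled_variants_rejected(self):
        geno = _geno_from(np.random.default_rng(0).integers(0, 3, (10, 3)))
        v = _vt(3, ["unassigned"] * 3)
        with pytest.raises(ValueError, match="class"):
            ld_prune(geno, v)
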