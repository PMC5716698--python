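"""Category tables, permutation overlap enrichment, gene-set hypergeometrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from cpgdiff import category_distribution, geneset_enrichment, permutation_overlap
from cpgdiff.core import ValidationError
from cpgdiff.enrichment import category_percentages, read_gmt, write_gmt
from conftest import make_annotation, make_common


class TestCategoryDistribution:
    def test_percentages_from_printed_style_counts(self):
        """Column-percentage convention: 265 hypo intergenic of 801 hypo total -> 33%."""
        counts = pd.DataFrame(
            {"hypo": [265, 270, 266], "hyper": [116, 250, 192]},
            index=["Intergenic", "Body", "other"],
        )
        pct = category_percentages(counts)
        assert pct.loc["Intergenic", "hypo"] == 33
        assert pct.loc["Body", "hyper"] == 45

    def test_identical_proportions_give_zero_chi2(self):
        chi2, p, _, _ = stats.chi2_contingency([[10, 90], [10, 90]], correction=False)
        # same code path used internally; construct a table realizing it
        ann = make_annotation(
            [{"probe_id": f"i{k}", "island": "Island" if k % 10 == 0 else "OpenSea"} for k in range(200)]
        )
        records = {}
        for k in range(200):
            records[f"i{k}"] = (("hypo", -0.1) if k < 100 else ("hyper", 0.1))
        common = make_common(records)
        tables = category_distribution(common, ann)
        isl = tables["island"]
        assert isl.loc["Island", "chi2"] == pytest.approx(0.0, abs=1e-12)
        assert isl.loc["Island", "p"] == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)

    def test_manual_enumeration_toy(self):
        ann = make_annotation(
            [
                {"probe_id": "a", "genes": ("G1",), "relations": ("Body",), "island": "Island"},
                {"probe_id": "b", "genes": ("G1", "G2"), "relations": ("Body", "TSS200"), "island": "OpenSea"},
                {"probe_id": "c", "island": "N_Shore"},  # intergenic
                {"probe_id": "d", "genes": ("G3",), "relations": ("Body",), "island": "OpenSea"},
            ]
        )
        common = make_common(
            {"a": ("hypo", -0.1), "b": ("hypo", -0.2), "c": ("hyper", 0.1), "d": ("hyper", 0.2)}
        )
        tables = category_distribution(common, ann)
        gene = tables["gene"]
        # association counting: probe b contributes to Body AND TSS200
        assert gene.loc["Body", "hypo"] == 2
        assert gene.loc["TSS200", "hypo"] == 1
        assert gene.loc["Intergenic", "hyper"] == 1
        assert gene.attrs["totals"] == {"hypo": 3, "hyper": 2}
        isl = tables["island"]
        assert isl.loc["OpenSea", "hypo"] == 1 and isl.loc["OpenSea", "hyper"] == 1
        assert int(isl["hypo"].sum()) == 2 and int(isl["hyper"].sum()) == 2

    def test_multi_category_probe_counted_once_per_category(self):
        ann = make_annotation(
            [{"probe_id": "a", "genes": ("G1", "G2"), "relations": ("Body", "Body")}]
        )
        common = make_common({"a": ("hypo", -0.1)})
        gene = category_distribution(common, ann)["gene"]
        assert gene.loc["Body", "hypo"] == 1  # distinct categories, not gene associations


class TestPermutationOverlap:
    def test_reference_equals_background_boundary(self):
        bg = [f"p{i}" for i in range(300)]
        enr = permutation_overlap(bg[:50], bg, bg, B=200, seed=0)
        assert enr.observed_overlap == 50
        assert enr.empirical_p == 1.0

    def test_perfect_overlap_hits_floor(self):
        """Query identical to a 5-probe reference in a 1000-probe background:
        the empirical p sits at its 1/(B+1) floor; the hypergeometric tail
        (~8e-15) confirms enrichment far beyond the permutation resolution."""
        bg = [f"p{i}" for i in range(1000)]
        ref = bg[:5]
        B = 10_000
        enr = permutation_overlap(ref, ref, bg, B=B, seed=1)
        assert enr.empirical_p == pytest.approx(1 / (B + 1))
        tail = stats.hypergeom.sf(4, 1000, 5, 5)
        assert tail < 1e-12

    def test_null_mean_matches_hypergeometric_expectation(self):
        bg = [f"p{i}" for i in range(2000)]
        ref = bg[:400]
        rng = np.random.default_rng(2)
        query = list(rng.choice(bg, 200, replace=False))
        enr = permutation_overlap(query, ref, bg, B=2000, seed=3)
        expected = 200 * 400 / 2000
        sd = np.sqrt(200 * 0.2 * 0.8 * (1800 / 1999))
        assert abs(enr.null_mean - expected) < 3 * sd / np.sqrt(2000)

    def test_direction_concordance(self):
        bg = [f"p{i}" for i in range(200)]
        qdir = {p: "hypo" for p in bg[:10]}
        rdir = {p: ("hypo" if i < 8 else "hyper") for i, p in enumerate(bg[:10])}
        enr = permutation_overlap(bg[:10], bg[:10], bg, B=200, seed=4, query_directions=qdir, reference_directions=rdir)
        assert enr.concordant_fraction == pytest.approx(0.8)
        assert enr.hypo_overlap == 8

    def test_validation_errors(self):
        bg = [f"p{i}" for i in range(200)]
        with pytest.raises(ValidationError):
            permutation_overlap(["zz"], bg[:5], bg, B=200, seed=0)
        with pytest.raises(ValidationError):
            permutation_overlap(bg[:5], bg[:5], bg, B=10, seed=0)

    def test_fixed_seed_reproducible(self):
        bg = [f"p{i}" for i in range(500)]
        a = permutation_overlap(bg[:40], bg[20:80], bg, B=300, seed=9)
        b = permutation_overlap(bg[:40], bg[20:80], bg, B=300, seed=9)
        assert a.empirical_p == b.empirical_p and a.null_mean == b.null_mean


class TestGenesetEnrichment:
    def test_closed_form_worked_example(self):
        """Query of 5 from a 20-gene background equal to a 5-gene set: p = 1/C(20,5)."""
        bg = [f"g{i}" for i in range(20)]
        table = geneset_enrichment(bg[:5], {"S": bg[:5]}, bg, min_genes=5)
        assert table.loc[0, "p"] == pytest.approx(1 / comb(20, 5, exact=True), rel=1e-10)
        assert table.loc[0, "significant"]

    def test_min_gene_rule_blocks_small_overlaps(self):
        bg = [f"g{i}" for i in range(30)]
        table = geneset_enrichment(bg[:4], {"S": bg[:4]}, bg, min_genes=5)
        assert not table.loc[0, "eligible"]
        assert not table.loc[0, "significant"]
        assert table.loc[0, "p"] < 0.001  # p alone would have passed

    def test_disjoint_set_p_one(self):
        bg = [f"g{i}" for i in range(30)]
        table = geneset_enrichment(bg[:5], {"S": bg[20:25]}, bg, min_genes=5)
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_query_rejected(self):
        with pytest.raises(ValidationError):
            geneset_enrichment([], {"S": ["a"]}, ["a"])

    def test_gmt_round_trip(self, tmp_path):
        sets = {"A": ["g1", "g2"], "B": ["g3"]}
        write_gmt(sets, tmp_path / "s.gmt")
        assert read_gmt(tmp_path / "s.gmt") == sets
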