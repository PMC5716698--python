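"""Enrichment analyses.

* Genomic-category contingency tables: direction (hypo/hyper) vs
  category membership, one 2x2 chi-square per category, association
  counting (a probe contributes once per distinct category it carries).
* Permutation overlap enrichment of a query DMS set against an external
  reference catalog over a probe background, with an empirical one-sided
  p-value and direction concordance.
* Hypergeometric gene-set enrichment with BH adjustment and a minimum
  overlapping-gene eligibility rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import INTERGENIC, AnnotationTable, ValidationError
from .diffmeth import bh_adjust
from .integrate import CommonDMSSet


def category_percentages(counts: pd.DataFrame, ndigits: int = 0) -> pd.DataFrame:
    """Percent of each direction column falling in each category row.

    ``counts`` has categories as index and columns ``hypo`` / ``hyper``;
    percentages are taken against each column's total and rounded
    (integers by default, for report parity).
    """
    totals = counts.sum(axis=0)
    pct = 100.0 * counts / totals
    return pct.round(ndigits)


def _two_by_two_test(in_hypo: int, in_hyper: int, tot_hypo: int, tot_hyper: int, yates: bool) -> tuple[float, float]:
    table = np.array([[in_hypo, tot_hypo - in_hypo], [in_hyper, tot_hyper - in_hyper]], dtype=float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan, np.nan
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def category_distribution(
    common: CommonDMSSet,
    annotation: AnnotationTable,
    yates: bool = False,
) -> dict[str, pd.DataFrame]:
    """Direction-by-category tables for gene relation and island relation.

    For each category a 2x2 chi-square tests direction against
    (in-category vs rest of the class). Gene-relation counts are
    association counts: a probe annotated to several distinct categories
    contributes once to each; probes with no gene annotation count as
    Intergenic. Island relation is single-valued per probe.

    Returns ``{"gene": table, "island": table}``; each table has columns
    hypo, hypo_pct, hyper, hyper_pct, chi2, p (p is NA for empty
    categories).
    """
    missing = [p for p in common.probe_ids if p not in annotation.probe_ids]
    if missing:
        raise ValidationError(f"annotation does not cover common probes: {missing[:5]}")
    directions = common.records["direction"]

    # gene-relation class: association counting via expansion
    assoc = annotation.gene_associations(common.probe_ids)
    assoc["gene_relation"] = assoc["gene_relation"].fillna(INTERGENIC)
    assoc = assoc.drop_duplicates(["probe_id", "gene_relation"])
    assoc["direction"] = directions.loc[assoc["probe_id"]].to_numpy()
    gene_counts = (
        assoc.groupby(["gene_relation", "direction"]).size().unstack(fill_value=0).reindex(columns=["hypo", "hyper"], fill_value=0)
    )

    isl = pd.DataFrame(
        {
            "island_relation": annotation.table.loc[common.probe_ids, "island_relation"],
            "direction": directions,
        }
    )
    isl_counts = (
        isl.groupby(["island_relation", "direction"]).size().unstack(fill_value=0).reindex(columns=["hypo", "hyper"], fill_value=0)
    )

    out = {}
    for name, counts in (("gene", gene_counts), ("island", isl_counts)):
        tot_hypo, tot_hyper = int(counts["hypo"].sum()), int(counts["hyper"].sum())
        pct = category_percentages(counts)
        chi2s, ps = [], []
        for cat in counts.index:
            chi2, p = _two_by_two_test(int(counts.loc[cat, "hypo"]), int(counts.loc[cat, "hyper"]), tot_hypo, tot_hyper, yates)
            chi2s.append(chi2)
            ps.append(p)
        table = pd.DataFrame(
            {
                "hypo": counts["hypo"].astype(int),
                "hypo_pct": pct["hypo"],
                "hyper": counts["hyper"].astype(int),
                "hyper_pct": pct["hyper"],
                "chi2": chi2s,
                "p": ps,
            },
            index=counts.index,
        )
        table.attrs["totals"] = {"hypo": tot_hypo, "hyper": tot_hyper}
        out[name] = table
    return out


@dataclass
class OverlapEnrichment:
    """Permutation overlap enrichment result."""

    observed_overlap: int
    n_query: int
    n_reference: int
    n_background: int
    n_permutations: int
    null_mean: float
    null_sd: float
    empirical_p: float  # (#{null >= observed} + 1) / (B + 1)
    concordant_fraction: float | None  # among overlapping probes, same direction both sides
    hypo_overlap: int | None
    hyper_overlap: int | None
    seed: int

    def __post_init__(self) -> None:
        assert 0 < self.empirical_p <= 1
        assert self.observed_overlap <= min(self.n_query, self.n_reference)


def _null_overlap_counts(n_background: int, ref_mask: np.ndarray, n_query: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """B overlap counts of uniform |query|-subsets of the background with the reference.

    Vectorized: each draw takes the n_query smallest of n_background
    uniforms (a uniform random subset), chunked to bound memory.
    """
    counts = np.empty(B, dtype=np.int64)
    chunk = max(1, int(2e7) // max(n_background, 1))
    ref = ref_mask.astype(np.int64)
    done = 0
    while done < B:
        b = min(chunk, B - done)
        u = rng.random((b, n_background))
        idx = np.argpartition(u, n_query - 1, axis=1)[:, :n_query]
        counts[done : done + b] = ref[idx].sum(axis=1)
        done += b
    return counts


def permutation_overlap(
    query: list[str],
    reference: list[str],
    background: list[str],
    B: int = 10_000,
    seed: int = 0,
    query_directions: dict[str, str] | pd.Series | None = None,
    reference_directions: dict[str, str] | pd.Series | None = None,
) -> OverlapEnrichment:
    """Test whether the query overlaps the reference more than chance.

    The null is B draws of |query| probes uniformly without replacement
    from the background; the one-sided enrichment p-value is
    (#{null >= observed} + 1)/(B + 1), never zero. If directions are
    supplied for both sides the concordant fraction among overlapping
    probes is reported.
    """
    if B < 100:
        raise ValidationError("B must be >= 100")
    query_set, ref_set, bg = set(query), set(reference), list(dict.fromkeys(background))
    bg_set = set(bg)
    if not query_set <= bg_set:
        raise ValidationError(f"query not a subset of background ({len(query_set - bg_set)} probes outside)")
    if len(query_set) > len(bg):
        raise ValidationError("query larger than background")
    overlap = sorted(query_set & ref_set)
    observed = len(overlap)

    rng = np.random.default_rng(seed)
    ref_mask = np.fromiter((p in ref_set for p in bg), dtype=bool, count=len(bg))
    null = _null_overlap_counts(len(bg), ref_mask, len(query_set), B, rng)
    empirical_p = (int((null >= observed).sum()) + 1) / (B + 1)

    concordant_fraction = hypo = hyper = None
    if query_directions is not None and reference_directions is not None:
        qd = pd.Series(query_directions)
        rd = pd.Series(reference_directions)
        if overlap:
            same = [p for p in overlap if qd.get(p) == rd.get(p)]
            concordant_fraction = len(same) / len(overlap)
            hypo = sum(1 for p in same if qd[p] == "hypo")
            hyper = sum(1 for p in same if qd[p] == "hyper")
        else:
            concordant_fraction, hypo, hyper = float("nan"), 0, 0

    return OverlapEnrichment(
        observed_overlap=observed,
        n_query=len(query_set),
        n_reference=len(ref_set),
        n_background=len(bg),
        n_permutations=B,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        empirical_p=empirical_p,
        concordant_fraction=concordant_fraction,
        hypo_overlap=hypo,
        hyper_overlap=hyper,
        seed=seed,
    )


def geneset_enrichment(
    query_genes: list[str],
    gene_sets: dict[str, list[str]],
    background_genes: list[str],
    min_genes: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of query genes per set.

    For each set, P(X >= k) where k is the query/set overlap, drawing
    |query| genes from the background. Sets overlapping the query in
    fewer than ``min_genes`` genes are flagged ineligible (non-significant
    regardless of p). BH adjustment across all tested sets.
    """
    qset = set(query_genes)
    if not qset:
        raise ValidationError("empty query gene list")
    bg = set(background_genes)
    if not qset <= bg:
        raise ValidationError("query genes not a subset of the background")
    rows = []
    for name, genes in gene_sets.items():
        gs = set(genes) & bg
        k = len(qset & gs)
        # hypergeom: population M=|bg|, successes n=|set|, draws N=|query|
        p = float(stats.hypergeom.sf(k - 1, len(bg), len(gs), len(qset))) if gs else 1.0
        rows.append({"set": name, "set_size": len(gs), "overlap": k, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    table["eligible"] = table["overlap"] >= min_genes
    table["significant"] = table["eligible"] & (table["adj_p"] < alpha)
    return table.sort_values("p").reset_index(drop=True)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format (set name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
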