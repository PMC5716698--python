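"""Correlation-distance hierarchical clustering with bootstrap support,
notch-interval median comparison, and LINE-1 per-CpG group tests."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

from .core import ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    """Agglomerative clustering of samples on 1 - Pearson correlation.

    ``supports`` maps each internal node's sample bipartition (the
    frozenset of sample IDs under the node, complement-canonicalized) to
    the fraction of feature-bootstrap trees in which it recurs.
    """

    linkage_matrix: np.ndarray
    samples: list[str]
    assignments: pd.Series  # two-cluster cut, values 1/2
    misplaced_count: int | None
    supports: dict[frozenset, float]
    n_bootstrap: int
    seed: int

    @property
    def top_split_support(self) -> float:
        """Bootstrap support of the root bipartition (the two-cluster split)."""
        members = frozenset(self.assignments.index[self.assignments == 1])
        key = _canonical_side(members, frozenset(self.samples))
        return self.supports[key]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node) -> str:
            if node.is_leaf():
                return self.samples[node.id]
            d = node.dist
            left, right = node.get_left(), node.get_right()
            return f"({rec(left)}:{d - left.dist:.6g},{rec(right)}:{d - right.dist:.6g})"

        return rec(tree) + ";"


def _canonical_side(side: frozenset, universe: frozenset) -> frozenset:
    """Represent the bipartition {side, universe - side} by the half
    containing the lexicographically smallest sample."""
    anchor = min(universe)
    return side if anchor in side else universe - side


def _correlation_linkage(X: np.ndarray, samples: list[str], method: str) -> np.ndarray:
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = samples[int(np.argmax(sd == 0))]
        raise ValidationError(f"sample {bad!r} has zero variance; correlation distance undefined")
    corr = np.corrcoef(X.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)  # enforce symmetry against FP noise
    return hierarchy.linkage(squareform(dist, checks=False), method=method)


def _bipartitions(Z: np.ndarray, samples: list[str]) -> set[frozenset]:
    """All non-trivial sample bipartitions implied by a linkage tree."""
    n = len(samples)
    universe = frozenset(samples)
    members: dict[int, frozenset] = {i: frozenset([samples[i]]) for i in range(n)}
    out: set[frozenset] = set()
    for i, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        if 1 < len(merged) < n:
            out.add(_canonical_side(merged, universe))
    return out


def cluster_samples(
    matrix: pd.DataFrame,
    linkage: str = "complete",
    B: int = 100,
    seed: int = 0,
    labels: pd.Series | dict | None = None,
) -> ClusterResult:
    """Hierarchically cluster samples by 1 - Pearson correlation.

    Parameters
    ----------
    matrix
        features x samples values (e.g. beta-values of selected DMSs).
    linkage
        ``"complete"`` (methylation convention) or ``"average"``
        (expression convention).
    B
        Number of feature bootstraps (resampling features with
        replacement) used to score how often each original internal-node
        bipartition recurs.
    labels
        Optional true group label per sample; the two-cluster cut is then
        scored by majority labeling and ``misplaced_count`` reported
        (ties count against, i.e. as misplaced).
    """
    if linkage not in ("complete", "average"):
        raise ValidationError(f"linkage must be 'complete' or 'average', got {linkage!r}")
    if matrix.shape[1] < 3:
        raise ValidationError("need >=3 samples to cluster")
    if matrix.shape[0] < 2:
        raise ValidationError("need >=2 features to cluster")
    samples = list(matrix.columns)
    X = matrix.to_numpy(dtype=float)
    Z = _correlation_linkage(X, samples, linkage)

    original = _bipartitions(Z, samples)
    hits = {bp: 0 for bp in original}
    rng = np.random.default_rng(seed)
    n_feat = X.shape[0]
    for _ in range(B):
        idx = rng.integers(0, n_feat, size=n_feat)
        try:
            Zb = _correlation_linkage(X[idx], samples, linkage)
        except ValidationError:  # a bootstrap can zero a sample's variance; skip it
            continue
        boot = _bipartitions(Zb, samples)
        for bp in original:
            if bp in boot:
                hits[bp] += 1
    supports = {bp: (hits[bp] / B if B > 0 else float("nan")) for bp in original}
    # root bipartition key (two-cluster split) for top_split_support
    cut = hierarchy.fcluster(Z, 2, criterion="maxclust")
    assignments = pd.Series(cut, index=samples)
    universe = frozenset(samples)
    root_side = _canonical_side(frozenset(assignments.index[assignments == 1]), universe)
    supports.setdefault(root_side, supports.get(root_side, 0.0))

    misplaced = None
    if labels is not None:
        lab = pd.Series(labels).loc[samples]
        misplaced = 0
        for k in (1, 2):
            in_k = lab[assignments == k]
            if len(in_k) == 0:
                continue
            counts = in_k.value_counts()
            top = counts.iloc[0]
            if len(counts) > 1 and counts.iloc[1] == top:
                # tie: no majority; conservatively count all as misplaced
                misplaced += len(in_k)
            else:
                misplaced += len(in_k) - int(top)
    return ClusterResult(
        linkage_matrix=Z,
        samples=samples,
        assignments=assignments,
        misplaced_count=misplaced,
        supports=supports,
        n_bootstrap=B,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# notch boxplot intervals


@dataclass
class NotchSummary:
    """Boxplot notch: median +/- 1.57 * IQR / sqrt(n).

    Non-overlap of two notches is informal evidence (~95% confidence)
    that the medians differ. IQR uses linearly interpolated quartiles
    (type-7), the numpy default — the half-width depends on this choice.
    """

    median: float
    half_width: float
    n: int

    @property
    def interval(self) -> tuple[float, float]:
        return (self.median - self.half_width, self.median + self.half_width)


def notch_summary(values) -> NotchSummary:
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValidationError("cannot summarize an empty vector")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    half = 1.57 * (q3 - q1) / np.sqrt(x.size)
    return NotchSummary(median=float(med), half_width=float(half), n=int(x.size))


def notches_overlap(a: NotchSummary, b: NotchSummary) -> bool:
    """True if the two notch intervals overlap (medians NOT clearly different)."""
    lo_a, hi_a = a.interval
    lo_b, hi_b = b.interval
    return not (hi_a < lo_b or hi_b < lo_a)


# ---------------------------------------------------------------------------
# LINE-1 per-CpG comparisons


CPG_COLUMNS = ("cpg1", "cpg2", "cpg3", "cpg4")


@dataclass
class Line1Table:
    """Per-sample percent methylation at 4 LINE-1 CpG positions plus group label.

    ``data`` columns: sample, group, cpg1..cpg4 (values in [0, 100]).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "group", *CPG_COLUMNS}
        if not required <= set(self.data.columns):
            raise ValidationError(f"LINE-1 table missing columns: {sorted(required - set(self.data.columns))}")
        vals = self.data[list(CPG_COLUMNS)].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 100)).any():
            raise ValidationError("LINE-1 percent methylation outside [0, 100]")


def line1_compare(table: Line1Table | pd.DataFrame, groups: list[str], welch: bool = False) -> pd.DataFrame:
    """Compare LINE-1 methylation between groups at each of the 4 CpGs.

    Two groups: Student t-test (equal variances) by default, Welch behind
    the flag. Three or more groups: Kruskal-Wallis with tie correction.
    No multiplicity correction across positions (raw per-CpG p-values).
    Groups with fewer than 2 samples are dropped with a warning.
    """
    df = table.data if isinstance(table, Line1Table) else Line1Table(table).data
    usable = []
    for g in groups:
        n = int((df["group"] == g).sum())
        if n < 2:
            logger.warning("group %r has %d sample(s); omitted from comparison", g, n)
        else:
            usable.append(g)
    if len(usable) < 2:
        raise ValidationError("need at least two groups with >=2 samples")
    rows = []
    for cpg in CPG_COLUMNS:
        arrays = [df.loc[df["group"] == g, cpg].to_numpy(dtype=float) for g in usable]
        if len(usable) == 2:
            import warnings

            with warnings.catch_warnings():
                # constant data trip scipy's precision-loss warning; handled below
                warnings.simplefilter("ignore", RuntimeWarning)
                stat, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=not welch)
            test = "welch_t" if welch else "student_t"
        else:
            try:
                with np.errstate(invalid="ignore"):
                    stat, p = stats.kruskal(*arrays)
            except ValueError:  # all values identical across groups
                stat, p = 0.0, 1.0
            test = "kruskal_wallis"
        if np.isnan(p):  # constant data within both groups: no evidence of difference
            stat, p = 0.0, 1.0
        rows.append({"cpg": cpg, "test": test, "statistic": float(stat), "p": float(p)})
    return pd.DataFrame(rows)
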