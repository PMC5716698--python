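"""Discovery/validation integration: DMS intersection with direction
consistency, per-chromosome effect profiles, and the sex-stratified
X-chromosome comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnnotationTable, BetaMatrix, DMSSet, ValidationError

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


@dataclass
class CommonDMSSet:
    """DMSs shared by the discovery and validation arms.

    ``records`` is indexed by probe with columns direction,
    delta_beta_discovery, delta_beta_validation, direction_consistent.
    ``overlap_fraction`` is referenced to the discovery arm.
    """

    records: pd.DataFrame
    n_discovery: int
    n_validation: int
    n_discordant: int

    @property
    def n_common(self) -> int:
        return len(self.records)

    @property
    def overlap_fraction(self) -> float:
        return self.n_common / self.n_discovery if self.n_discovery else float("nan")

    @property
    def overlap_percent(self) -> int:
        """Overlap as a whole percent of the discovery arm (report convention)."""
        return int(round(100.0 * self.overlap_fraction))

    @property
    def probe_ids(self) -> pd.Index:
        return self.records.index

    def __len__(self) -> int:
        return len(self.records)


def intersect_dms(discovery: DMSSet, validation: DMSSet, require_same_direction: bool = True) -> CommonDMSSet:
    """Intersect two DMS sets, optionally dropping direction-discordant probes.

    The overlap fraction is computed against the discovery set, matching
    the convention of reporting the validated share of the paired arm.
    """
    common = discovery.records.index.intersection(validation.records.index)
    disc = discovery.records.loc[common]
    val = validation.records.loc[common]
    consistent = disc["direction"].to_numpy() == val["direction"].to_numpy()
    n_discordant = int((~consistent).sum())
    if require_same_direction:
        keep = common[consistent]
    else:
        keep = common
    records = pd.DataFrame(
        {
            "direction": discovery.records.loc[keep, "direction"],
            "delta_beta_discovery": discovery.records.loc[keep, "delta_beta"],
            "delta_beta_validation": validation.records.loc[keep, "delta_beta"],
            "direction_consistent": disc.loc[keep, "direction"].to_numpy()
            == val.loc[keep, "direction"].to_numpy(),
        }
    )
    return CommonDMSSet(
        records=records,
        n_discovery=len(discovery),
        n_validation=len(validation),
        n_discordant=n_discordant if require_same_direction else 0,
    )


def chromosome_profile(common: CommonDMSSet, annotation: AnnotationTable, arm: str = "discovery") -> pd.DataFrame:
    """Per-autosome mean / SD / median of delta_beta over the common DMSs.

    Chromosomes with no DMSs are absent from the result; chrX/chrY probes
    are excluded (logged) since the profile is autosome-only.
    """
    if arm not in ("discovery", "validation"):
        raise ValidationError(f"arm must be 'discovery' or 'validation', got {arm!r}")
    missing = [p for p in common.probe_ids if p not in annotation.probe_ids]
    if missing:
        raise ValidationError(f"annotation does not cover common probes: {missing[:5]}")
    col = f"delta_beta_{arm}"
    chrom = annotation.table.loc[common.probe_ids, "chromosome"]
    non_auto = ~chrom.isin(AUTOSOMES)
    if non_auto.any():
        logger.info("excluding %d sex-chromosome probes from the autosome profile", int(non_auto.sum()))
    df = pd.DataFrame({"chromosome": chrom[~non_auto], "delta_beta": common.records.loc[chrom.index[~non_auto], col]})
    prof = (
        df.groupby("chromosome", sort=False)["delta_beta"]
        .agg(n="size", mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, median="median")
        .reset_index()
    )
    order = {c: i for i, c in enumerate(AUTOSOMES)}
    return prof.sort_values("chromosome", key=lambda s: s.map(order)).reset_index(drop=True)


def sex_chromosome_profile(beta: BetaMatrix, annotation: AnnotationTable) -> pd.DataFrame:
    """Summaries of chrX beta per sex x group cell plus sex-matched contrasts.

    Returns one row per (sex, group) with n_samples, mean, q1, median, q3,
    and (on group='tumor' rows) the sex-matched tumor-minus-control median
    difference. Cells with no samples are omitted with a warning.
    """
    if "sex" not in beta.metadata.columns:
        raise ValidationError("metadata has no 'sex' column")
    chrx = [p for p in beta.probe_ids if annotation.table.loc[p, "chromosome"] == "chrX"]
    if not chrx:
        raise ValidationError("no chrX probes in the matrix (were sex chromosomes filtered?)")
    vals = beta.values.loc[chrx]
    rows = []
    medians: dict[tuple[str, str], float] = {}
    for sex in ("M", "F"):
        for group in ("tumor", "control"):
            samp = beta.metadata.index[(beta.metadata["sex"] == sex) & (beta.metadata["group"] == group)]
            if len(samp) == 0:
                logger.warning("no samples for sex=%s group=%s; contrast omitted", sex, group)
                continue
            flat = vals[list(samp)].to_numpy().ravel()
            flat = flat[~np.isnan(flat)]
            q1, med, q3 = np.percentile(flat, [25, 50, 75])
            medians[(sex, group)] = med
            rows.append(
                {
                    "sex": sex,
                    "group": group,
                    "n_samples": len(samp),
                    "mean": flat.mean(),
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                }
            )
    out = pd.DataFrame(rows)
    out["median_diff_vs_control"] = np.nan
    for sex in ("M", "F"):
        if (sex, "tumor") in medians and (sex, "control") in medians:
            mask = (out["sex"] == sex) & (out["group"] == "tumor")
            out.loc[mask, "median_diff_vs_control"] = medians[(sex, "tumor")] - medians[(sex, "control")]
    return out
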