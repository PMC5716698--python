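"""Core containers and text I/O.

Beta-value matrices (probe x sample methylation fractions with sample
metadata), Illumina-manifest-style probe annotation, and differential
methylation call sets, plus TSV/CSV readers, writers, and BED6 export.

Conventions
-----------
* Annotation positions are 1-based (manifest convention); BED export
  converts to 0-based half-open single-base intervals.
* Missing beta values are NA, excluded per probe from group means and
  model fits.
* Sample reconciliation between matrix and metadata is by ID,
  case-sensitive, never by column position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")
GENE_RELATIONS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")
INTERGENIC = "Intergenic"
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")


class ValidationError(ValueError):
    """Raised when an input file or container violates an invariant."""


@dataclass
class BetaMatrix:
    """Probe-by-sample methylation fractions with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame with probe IDs as index, sample IDs as columns; entries are
        beta-values in [0, 1] (fraction of methylated alleles) or NA.
    metadata
        DataFrame indexed by sample ID with at least a ``group`` column
        (``tumor`` / ``control``); optional ``pair_id`` (paired design),
        ``sex`` (``M`` / ``F`` / ``unknown``) and numeric covariate columns.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe IDs: {dups[:5]}")
        if not self.values.columns.is_unique:
            raise ValidationError("duplicate sample IDs in matrix")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        extra = [s for s in self.metadata.index if s not in self.values.columns]
        if missing or extra:
            raise ValidationError(
                f"sample mismatch between matrix and metadata: "
                f"matrix-only={missing[:5]} metadata-only={extra[:5]}"
            )
        # align metadata rows to matrix column order
        self.metadata = self.metadata.loc[list(self.values.columns)]
        arr = self.values.to_numpy()
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta out of [0,1]: probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}, value {arr[i, j]}"
            )
        if "group" not in self.metadata.columns:
            raise ValidationError("metadata must have a 'group' column")
        groups = set(self.metadata["group"].unique())
        if not groups <= {"tumor", "control"}:
            raise ValidationError(f"unknown group labels: {groups - {'tumor', 'control'}}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.metadata.index[self.metadata["group"] == group])

    def validate_pairing(self) -> pd.DataFrame:
        """Check the paired design: every pair_id on exactly one tumor and one control.

        Returns a DataFrame indexed by pair_id with columns ``tumor`` and
        ``control`` holding sample IDs, restricted to samples that carry a
        pair_id.
        """
        if "pair_id" not in self.metadata.columns:
            raise ValidationError("paired design declared but metadata has no 'pair_id' column")
        md = self.metadata[self.metadata["pair_id"].notna()]
        rows = {}
        for pid, sub in md.groupby("pair_id"):
            counts = sub["group"].value_counts()
            if counts.get("tumor", 0) != 1 or counts.get("control", 0) != 1:
                raise ValidationError(
                    f"pair {pid!r} must have exactly one tumor and one control "
                    f"(got {counts.to_dict()})"
                )
            rows[pid] = {
                "tumor": sub.index[sub["group"] == "tumor"][0],
                "control": sub.index[sub["group"] == "control"][0],
            }
        if not rows:
            raise ValidationError("no complete pairs found")
        return pd.DataFrame.from_dict(rows, orient="index")

    def subset_probes(self, probes: Iterable[str]) -> "BetaMatrix":
        probes = [p for p in probes if p in self.values.index]
        return BetaMatrix(self.values.loc[probes], self.metadata.copy())

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values[list(samples)], self.metadata.loc[list(samples)].copy())


@dataclass
class AnnotationTable:
    """Per-probe genomic annotation in the Illumina-manifest style.

    ``table`` is indexed by probe ID with columns: ``chromosome``,
    ``position`` (1-based), ``gene_symbols`` (tuple, may be empty),
    ``gene_relations`` (tuple aligned with gene_symbols; empty tuple means
    intergenic), ``island_relation``, ``snp_flag``, ``cpg_probe``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            raise ValidationError("duplicate probe IDs in annotation")
        bad_chr = set(self.table["chromosome"].unique()) - set(VALID_CHROMOSOMES)
        if bad_chr:
            raise ValidationError(f"unknown chromosomes: {sorted(bad_chr)}")
        if (self.table["position"] <= 0).any():
            bad = self.table.index[self.table["position"] <= 0][0]
            raise ValidationError(f"non-positive position for probe {bad!r}")
        bad_isl = set(self.table["island_relation"].unique()) - set(ISLAND_RELATIONS)
        if bad_isl:
            raise ValidationError(f"unknown island-relation tokens: {sorted(bad_isl)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def gene_associations(self, probes: Iterable[str] | None = None) -> pd.DataFrame:
        """Expand multi-gene probes to one row per (probe, gene, gene_relation).

        Probes with no gene annotation yield a single row with
        gene=NA and gene_relation="Intergenic".
        """
        sub = self.table if probes is None else self.table.loc[[p for p in probes]]
        rows = []
        for probe, genes, rels in zip(sub.index, sub["gene_symbols"], sub["gene_relations"]):
            if len(genes) == 0:
                rows.append((probe, None, INTERGENIC))
            else:
                seen = set()
                for g, r in zip(genes, rels):
                    if (g, r) not in seen:
                        seen.add((g, r))
                        rows.append((probe, g, r))
        return pd.DataFrame(rows, columns=["probe_id", "gene", "gene_relation"])

    def chromosomes(self, probes: Iterable[str]) -> pd.Series:
        return self.table.loc[list(probes), "chromosome"]

    def subset(self, probes: Iterable[str]) -> "AnnotationTable":
        return AnnotationTable(self.table.loc[list(probes)].copy())


@dataclass
class DMSRecord:
    """One differentially methylated CpG site."""

    probe_id: str
    delta_beta: float  # mean beta(tumor) - mean beta(control), in [-1, 1]
    t_mod: float
    p_value: float
    adj_p: float
    direction: str  # "hypo" if delta_beta < 0 else "hyper"


@dataclass
class DMSSet:
    """Differential methylation calls below an FDR threshold.

    ``records`` is a DataFrame indexed by probe with columns delta_beta,
    t_mod, p_value, adj_p, direction.
    """

    records: pd.DataFrame
    alpha: float
    design: str  # "paired" | "unpaired"
    n_tested: int

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if len(self.records) and (self.records["adj_p"] >= self.alpha).any():
            raise ValidationError("DMSSet contains records with adj_p >= alpha")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def probe_ids(self) -> pd.Index:
        return self.records.index

    def directions(self) -> pd.Series:
        return self.records["direction"]

    def direction_counts(self) -> dict[str, int]:
        c = self.records["direction"].value_counts()
        return {"hypo": int(c.get("hypo", 0)), "hyper": int(c.get("hyper", 0))}

    def hypo_fraction_percent(self, ndigits: int = 1) -> float:
        """Percentage of calls that are hypomethylated, rounded to `ndigits`."""
        if len(self.records) == 0:
            raise ValidationError("empty DMS set has no direction fractions")
        counts = self.direction_counts()
        return round(100.0 * counts["hypo"] / len(self.records), ndigits)

    def to_frame(self) -> pd.DataFrame:
        return self.records.copy()


# ---------------------------------------------------------------------------
# readers / writers


def read_beta_matrix(matrix_path: str | Path, metadata_path: str | Path, sep: str = "\t") -> BetaMatrix:
    """Read a probe x sample beta matrix and its sample metadata.

    The matrix file has probe IDs in the first column and one column per
    sample; the metadata file has one row per sample (ID in column
    ``sample``) with group / pair_id / sex / covariate columns. Samples are
    reconciled by ID; metadata row order need not match matrix column order.
    """
    values = pd.read_csv(matrix_path, sep=sep, index_col=0)
    metadata = pd.read_csv(metadata_path, sep=sep)
    if "sample" not in metadata.columns:
        raise ValidationError("metadata file must have a 'sample' column")
    if metadata["sample"].duplicated().any():
        raise ValidationError("duplicate sample IDs in metadata")
    metadata = metadata.set_index("sample")
    if "pair_id" in metadata.columns:
        metadata["pair_id"] = metadata["pair_id"].astype("object").where(metadata["pair_id"].notna(), None)
    return BetaMatrix(values, metadata)


def write_beta_matrix(beta: BetaMatrix, matrix_path: str | Path, metadata_path: str | Path, sep: str = "\t") -> None:
    beta.values.to_csv(matrix_path, sep=sep, index_label="probe_id")
    beta.metadata.to_csv(metadata_path, sep=sep, index_label="sample")


def read_annotation(path: str | Path, sep: str = "\t", multi_delim: str = ";") -> AnnotationTable:
    """Read an Illumina-manifest-like annotation TSV.

    Expected columns: probe_id, chromosome, position, gene_symbols,
    gene_relations, island_relation, snp_flag, cpg_probe. Multi-gene cells
    use ``multi_delim``; gene_symbols and gene_relations must align
    element-wise. Empty gene cells are classified Intergenic.
    """
    df = pd.read_csv(path, sep=sep, dtype={"gene_symbols": str, "gene_relations": str})
    required = {"probe_id", "chromosome", "position", "gene_symbols", "gene_relations", "island_relation", "snp_flag", "cpg_probe"}
    if not required <= set(df.columns):
        raise ValidationError(f"annotation missing columns: {sorted(required - set(df.columns))}")
    df = df.set_index("probe_id")

    def _split(cell: object) -> tuple[str, ...]:
        if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
            return ()
        return tuple(tok for tok in str(cell).split(multi_delim) if tok)

    genes = df["gene_symbols"].map(_split)
    rels = df["gene_relations"].map(_split)
    for probe, g, r in zip(df.index, genes, rels):
        if len(g) != len(r):
            raise ValidationError(
                f"probe {probe!r}: gene_symbols and gene_relations lengths differ ({len(g)} vs {len(r)})"
            )
        bad = set(r) - set(GENE_RELATIONS)
        if bad:
            raise ValidationError(f"probe {probe!r}: unknown gene-relation tokens {sorted(bad)}")
    out = pd.DataFrame(
        {
            "chromosome": df["chromosome"],
            "position": df["position"].astype(int),
            "gene_symbols": genes,
            "gene_relations": rels,
            "island_relation": df["island_relation"],
            "snp_flag": df["snp_flag"].astype(bool),
            "cpg_probe": df["cpg_probe"].astype(bool),
        }
    )
    return AnnotationTable(out)


def write_annotation(annotation: AnnotationTable, path: str | Path, sep: str = "\t", multi_delim: str = ";") -> None:
    df = annotation.table.copy()
    df["gene_symbols"] = df["gene_symbols"].map(multi_delim.join)
    df["gene_relations"] = df["gene_relations"].map(multi_delim.join)
    df.to_csv(path, sep=sep, index_label="probe_id")


def write_dms_bed(dms: DMSSet, annotation: AnnotationTable, path: str | Path) -> None:
    """Export DMS calls as BED6 single-base intervals.

    chrom / [position-1, position) / name=probe / score=round(1000*|delta_beta|)
    capped at 1000 / strand "." — sorted by (chrom, start).
    """
    missing = [p for p in dms.probe_ids if p not in annotation.probe_ids]
    if missing:
        raise ValidationError(f"probes missing from annotation: {missing[:10]}")
    rows = []
    for probe, rec in dms.records.iterrows():
        ann = annotation.table.loc[probe]
        start = int(ann["position"]) - 1
        score = min(1000, int(round(1000 * abs(rec["delta_beta"]))))
        rows.append((ann["chromosome"], start, start + 1, probe, score, "."))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def read_dms_bed(path: str | Path) -> pd.DataFrame:
    """Read back a BED6 file written by :func:`write_dms_bed`."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        return pd.read_csv(path, sep="\t", header=None, names=cols)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=cols)


def write_dms_table(dms: DMSSet, path: str | Path) -> None:
    dms.records.to_csv(path, sep="\t", index_label="probe_id")


def read_dms_table(path: str | Path, alpha: float, design: str, n_tested: int) -> DMSSet:
    records = pd.read_csv(path, sep="\t", index_col="probe_id")
    return DMSSet(records=records, alpha=alpha, design=design, n_tested=n_tested)
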