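"""Gene-level DMR calling.

A differentially methylated region is a gene harboring >= min_sites
significant CpG sites, all in the same direction, with at least one
site showing an absolute methylation difference >= min_effect (default
20 percentage points of beta). Direction partitioning happens before
counting, so a gene can yield at most one hypomethylated and one
hypermethylated region (promoter-hypo / body-hyper patterns appear as
two rows for the same gene). Intergenic sites do not participate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import AnnotationTable, ValidationError
from .integrate import CommonDMSSet


@dataclass
class DMRConfig:
    min_sites: int = 3
    min_effect: float = 0.20  # absolute delta_beta units
    per_category: bool = False  # strict mode: group by (gene, gene_relation) instead of gene

    def __post_init__(self) -> None:
        if self.min_sites < 2:
            raise ValidationError("min_sites must be >= 2")
        if not 0 < self.min_effect < 1:
            raise ValidationError("min_effect must be in (0, 1)")


@dataclass
class DMRRecord:
    gene: str
    direction: str
    probes: list[str]
    delta_betas: list[float]
    max_abs_delta: float
    gene_relations: list[str]  # distinct categories spanned, sorted
    island_relations: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.probes)


@dataclass
class DMRSet:
    records: list[DMRRecord] = field(default_factory=list)
    config: DMRConfig = field(default_factory=DMRConfig)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genes(self) -> list[str]:
        return sorted({r.gene for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": r.gene,
                "direction": r.direction,
                "n_sites": r.n_sites,
                "max_abs_delta": r.max_abs_delta,
                "gene_relations": ";".join(r.gene_relations),
                "island_relations": ";".join(r.island_relations),
                "probes": ";".join(r.probes),
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=["gene", "direction", "n_sites", "max_abs_delta", "gene_relations", "island_relations", "probes"])


def call_dmrs(common: CommonDMSSet, annotation: AnnotationTable, config: DMRConfig | None = None, arm: str = "discovery") -> DMRSet:
    """Apply the gene-level DMR rule to the common DMS set.

    Probes annotated to multiple genes are expanded to every
    (gene, category) association; a probe therefore can support a region
    in each of its genes. The effect size used is the chosen arm's
    delta_beta.
    """
    config = config or DMRConfig()
    if len(common) == 0:
        return DMRSet(records=[], config=config)
    col = f"delta_beta_{arm}"
    assoc = annotation.gene_associations(common.probe_ids)
    assoc = assoc[assoc["gene"].notna()]  # intergenic sites excluded
    if assoc.empty:
        return DMRSet(records=[], config=config)
    assoc = assoc.merge(
        common.records[[col, "direction"]].rename(columns={col: "delta_beta"}),
        left_on="probe_id",
        right_index=True,
    )
    assoc["island_relation"] = annotation.table.loc[assoc["probe_id"], "island_relation"].to_numpy()

    group_cols = ["gene", "gene_relation"] if config.per_category else ["gene"]
    records: list[DMRRecord] = []
    for key, sub in assoc.groupby(group_cols + ["direction"], sort=False):
        # one probe may map to a gene via several categories; count it once in gene mode
        sub = sub.drop_duplicates("probe_id") if not config.per_category else sub
        if len(sub) < config.min_sites:
            continue
        if sub["delta_beta"].abs().max() < config.min_effect:
            continue
        gene = key[0]
        direction = key[-1]
        records.append(
            DMRRecord(
                gene=gene,
                direction=direction,
                probes=sorted(sub["probe_id"]),
                delta_betas=[float(d) for _, d in sorted(zip(sub["probe_id"], sub["delta_beta"]))],
                max_abs_delta=float(sub["delta_beta"].abs().max()),
                gene_relations=sorted(assoc[(assoc["gene"] == gene) & (assoc["direction"] == direction) & assoc["probe_id"].isin(sub["probe_id"])]["gene_relation"].unique()),
                island_relations=sorted(sub["island_relation"].unique()),
            )
        )
    records.sort(key=lambda r: (r.gene, r.direction))
    return DMRSet(records=records, config=config)
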