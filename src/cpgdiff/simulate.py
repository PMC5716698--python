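"""Synthetic 450K-style cohorts with known spiked effects.

The generator emulates the structure of a paired tumor/normal
methylation study: a manifest-like annotation with gene runs and
island-relation zones; a cohort of matched tumor/control pairs plus an
unpaired validation arm; spiked differentially methylated sites and
gene-level DMR blocks with configurable direction balance and effect
size; a direction-concordant external reference catalog; and LINE-1
pyrosequencing tables. Effects are injected on the M scale and
transformed back so beta-values stay in range.

Default cohort sizes follow the emulated study design: 8 tumor/control
pairs (discovery) and 11 extra tumors with 3 extra controls
(validation, pooled with the 8 paired controls); ~58% of spikes
hypomethylated; mean spike effect 0.20 in beta units; a small tumor-wide
hypomethylation shift of 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    GENE_RELATIONS,
    ISLAND_RELATIONS,
    AnnotationTable,
    BetaMatrix,
    ValidationError,
)
from .preprocess import beta_to_m, m_to_beta

_CLIP_EPS = 1e-6

# island-relation sampling weights: open sea majority, islands/shores next
_ISLAND_WEIGHTS = {
    "Island": 0.15,
    "N_Shore": 0.11,
    "S_Shore": 0.11,
    "N_Shelf": 0.05,
    "S_Shelf": 0.05,
    "OpenSea": 0.53,
}
# baseline beta distribution (Beta(a, b)) per island relation: islands low,
# open sea high, shores/shelves intermediate — the bimodal 450K profile
_BASELINE_BETA = {
    "Island": (1.5, 8.5),
    "N_Shore": (5.0, 5.0),
    "S_Shore": (5.0, 5.0),
    "N_Shelf": (6.0, 4.0),
    "S_Shelf": (6.0, 4.0),
    "OpenSea": (8.0, 2.0),
}
_GENE_RELATION_WEIGHTS = {
    "TSS200": 0.10,
    "TSS1500": 0.14,
    "5'UTR": 0.12,
    "1stExon": 0.06,
    "Body": 0.48,
    "3'UTR": 0.10,
}


def _rng(seed: int, stream: int) -> np.random.Generator:
    # one global seed fans out to per-component substreams
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass
class SpikeConfig:
    """Conditions for a synthetic cohort with spiked effects.

    noise_sd is on the M scale; delta_beta_effect and global_hypo_shift
    are in beta units. global_hypo_shift is the signed tumor-wide shift
    (negative = hypomethylation).
    """

    n_probes: int = 10_000
    n_pairs: int = 8
    n_extra_tumors: int = 11
    n_extra_controls: int = 3
    n_spiked_dms: int = 200
    fraction_hypo: float = 0.58
    delta_beta_effect: float = 0.20
    n_dmr_blocks: int = 0
    dmr_block_size: int = 3
    within_pair_correlation: float = 0.5
    noise_sd: float = 0.10
    global_hypo_shift: float = -0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_hypo <= 1:
            raise ValidationError("fraction_hypo must be in [0, 1]")
        if self.dmr_block_size < 3:
            raise ValidationError("dmr_block_size must be >= 3")
        if self.n_spiked_dms + self.n_dmr_blocks * self.dmr_block_size > self.n_probes:
            raise ValidationError("spike counts exceed the number of probes")
        if not 0 <= self.within_pair_correlation < 1:
            raise ValidationError("within_pair_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")


@dataclass
class TruthTable:
    """Ground truth for a generated cohort.

    ``table`` is indexed by probe with columns is_spiked, true_direction
    (hypo/hyper or NA), spike_delta (signed beta-scale spike, 0 if not
    spiked), true_delta_beta (actual injected tumor-minus-control mean
    beta difference, including the global shift), dmr_block_id (NA for
    non-block probes).
    """

    table: pd.DataFrame

    @property
    def spiked_probes(self) -> list[str]:
        return list(self.table.index[self.table["is_spiked"]])

    @property
    def n_spiked(self) -> int:
        return int(self.table["is_spiked"].sum())

    def block_members(self) -> dict[str, list[str]]:
        blocks = self.table[self.table["dmr_block_id"].notna()]
        return {str(b): list(sub.index) for b, sub in blocks.groupby("dmr_block_id")}


def generate_annotation(n_probes: int, seed: int = 0, chrx_fraction: float = 0.0) -> AnnotationTable:
    """Generate a manifest-like annotation table.

    Probes are laid across chr1..chr22 (plus chrX when
    ``chrx_fraction`` > 0) with sorted positions. Genes cover runs of
    consecutive probes (1-8 probes per gene, most runs sharing one
    gene-relation category so DMR blocks exist by construction);
    between-gene runs are intergenic. Island relations are sampled with
    an open-sea majority. Deterministic given the seed.
    """
    if n_probes < 100:
        raise ValidationError("n_probes must be >= 100 for meaningful category tallies")
    rng = _rng(seed, 0)
    chroms = [f"chr{i}" for i in range(1, 23)]
    n_x = int(round(chrx_fraction * n_probes))
    chrom_assign = list(rng.choice(chroms, size=n_probes - n_x)) + ["chrX"] * n_x

    rows = []
    gene_counter = 0
    by_chrom: dict[str, int] = {}
    for c in chrom_assign:
        by_chrom[c] = by_chrom.get(c, 0) + 1
    probe_counter = 0
    for chrom in chroms + (["chrX"] if n_x else []):
        n_c = by_chrom.get(chrom, 0)
        if n_c == 0:
            continue
        positions = np.sort(rng.integers(1, 200_000_000, size=n_c))
        positions = positions + np.arange(n_c)  # break ties, keep sorted
        i = 0
        while i < n_c:
            intergenic_run = rng.random() < 0.25
            run = int(rng.integers(1, 9))
            run = min(run, n_c - i)
            if intergenic_run:
                gene, rels = None, None
            else:
                gene_counter += 1
                gene = f"GENE{gene_counter:05d}"
                if rng.random() < 0.6:  # homogeneous-category gene run
                    rel = rng.choice(list(_GENE_RELATION_WEIGHTS), p=list(_GENE_RELATION_WEIGHTS.values()))
                    rels = [rel] * run
                else:
                    rels = list(
                        rng.choice(list(_GENE_RELATION_WEIGHTS), size=run, p=list(_GENE_RELATION_WEIGHTS.values()))
                    )
            for k in range(run):
                probe_counter += 1
                island = rng.choice(list(_ISLAND_WEIGHTS), p=list(_ISLAND_WEIGHTS.values()))
                rows.append(
                    {
                        "probe_id": f"cg{probe_counter:08d}",
                        "chromosome": chrom,
                        "position": int(positions[i + k]),
                        "gene_symbols": () if gene is None else (gene,),
                        "gene_relations": () if gene is None else (rels[k],),
                        "island_relation": island,
                        "snp_flag": bool(rng.random() < 0.01),
                        "cpg_probe": bool(rng.random() >= 0.007),
                    }
                )
            i += run
    df = pd.DataFrame(rows).set_index("probe_id")
    return AnnotationTable(df)


def _pick_dmr_blocks(annotation: AnnotationTable, config: SpikeConfig, rng: np.random.Generator) -> list[list[str]]:
    """Choose n_dmr_blocks gene runs with >= block_size probes sharing
    (gene, gene_relation), avoiding SNP/non-CpG/sex-chromosome probes so
    blocks survive filtering."""
    tab = annotation.table
    usable = tab[(~tab["snp_flag"]) & tab["cpg_probe"] & ~tab["chromosome"].isin(["chrX", "chrY"])]
    assoc = annotation.gene_associations(usable.index)
    assoc = assoc[assoc["gene"].notna()]
    candidates = []
    for (gene, rel), sub in assoc.groupby(["gene", "gene_relation"]):
        if len(sub) >= config.dmr_block_size:
            candidates.append(list(sub["probe_id"].iloc[: config.dmr_block_size]))
    if len(candidates) < config.n_dmr_blocks:
        raise ValidationError(
            f"annotation supports only {len(candidates)} DMR blocks of size "
            f"{config.dmr_block_size}; {config.n_dmr_blocks} requested"
        )
    chosen = rng.choice(len(candidates), size=config.n_dmr_blocks, replace=False)
    return [candidates[i] for i in chosen]


def generate_cohort(annotation: AnnotationTable, config: SpikeConfig) -> tuple[BetaMatrix, TruthTable]:
    """Simulate a paired + unpaired cohort with spiked DMSs/DMR blocks.

    Baseline per-probe methylation is bimodal by island relation. Tumor
    mean beta = baseline + global shift + spike effect (clipped);
    differences are realized on the M scale, where each sample also gets
    a shared-intercept pair effect (within-pair correlation) and i.i.d.
    Gaussian noise. Spiked probes get mid-range baselines so the
    configured effect always fits inside [0, 1].
    """
    probes = list(annotation.probe_ids)
    if len(probes) != config.n_probes:
        raise ValidationError(f"annotation has {len(probes)} probes but config.n_probes={config.n_probes}")
    n = config.n_probes
    rng = _rng(config.seed, 1)

    island = annotation.table["island_relation"].to_numpy()
    baseline = np.empty(n)
    for rel, (a, b) in _BASELINE_BETA.items():
        mask = island == rel
        baseline[mask] = rng.beta(a, b, size=int(mask.sum()))
    baseline = np.clip(baseline, 0.02, 0.98)

    # --- choose spiked probes ------------------------------------------------
    blocks = _pick_dmr_blocks(annotation, config, rng) if config.n_dmr_blocks else []
    block_probe_set = [p for blk in blocks for p in blk]
    probe_pos = {p: i for i, p in enumerate(probes)}
    tab = annotation.table
    eligible = [
        p
        for p in probes
        if p not in set(block_probe_set)
        and not tab.loc[p, "snp_flag"]
        and tab.loc[p, "cpg_probe"]
        and tab.loc[p, "chromosome"] not in ("chrX", "chrY")
    ]
    if len(eligible) < config.n_spiked_dms:
        raise ValidationError("not enough eligible probes for the requested spike count")
    singles = list(rng.choice(eligible, size=config.n_spiked_dms, replace=False))

    spike_delta = np.zeros(n)
    dmr_block_id = np.full(n, None, dtype=object)
    for b, blk in enumerate(blocks):
        sign = -1.0 if rng.random() < config.fraction_hypo else 1.0
        for p in blk:
            i = probe_pos[p]
            baseline[i] = rng.uniform(0.35, 0.65)  # headroom for the effect
            spike_delta[i] = sign * (config.delta_beta_effect + rng.uniform(0.0, 0.05))
            dmr_block_id[i] = f"block{b:03d}"
    for p in singles:
        i = probe_pos[p]
        sign = -1.0 if rng.random() < config.fraction_hypo else 1.0
        baseline[i] = rng.uniform(0.35, 0.65)
        mag = config.delta_beta_effect + rng.uniform(-0.05, 0.05)
        spike_delta[i] = sign * max(mag, 0.05)

    control_mean = baseline
    tumor_mean = np.clip(baseline + config.global_hypo_shift + spike_delta, _CLIP_EPS, 1 - _CLIP_EPS)
    true_delta = tumor_mean - control_mean

    m_control = beta_to_m(control_mean, epsilon=_CLIP_EPS)
    m_tumor = beta_to_m(tumor_mean, epsilon=_CLIP_EPS)

    # --- samples -------------------------------------------------------------
    r = config.within_pair_correlation
    sd_pair = config.noise_sd * np.sqrt(r / (1 - r)) if r > 0 else 0.0

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    sexes = rng.choice(["M", "F"], size=config.n_pairs + config.n_extra_tumors + config.n_extra_controls)
    si = 0

    def _sample(mean_m: np.ndarray, intercept: np.ndarray) -> np.ndarray:
        noise = rng.normal(0.0, config.noise_sd, size=n)
        return m_to_beta(mean_m + intercept + noise)

    for k in range(config.n_pairs):
        b = rng.normal(0.0, sd_pair, size=n)
        sex = sexes[si]
        si += 1
        age = float(rng.uniform(0.3, 13.0))
        columns[f"T{k+1:02d}"] = _sample(m_tumor, b)
        columns[f"C{k+1:02d}"] = _sample(m_control, b)
        meta_rows.append({"sample": f"T{k+1:02d}", "group": "tumor", "pair_id": f"P{k+1:02d}", "sex": sex, "age": age})
        meta_rows.append({"sample": f"C{k+1:02d}", "group": "control", "pair_id": f"P{k+1:02d}", "sex": sex, "age": age})
    for k in range(config.n_extra_tumors):
        b = rng.normal(0.0, sd_pair, size=n)
        columns[f"VT{k+1:02d}"] = _sample(m_tumor, b)
        meta_rows.append(
            {"sample": f"VT{k+1:02d}", "group": "tumor", "pair_id": None, "sex": sexes[si], "age": float(rng.uniform(0.3, 13.0))}
        )
        si += 1
    for k in range(config.n_extra_controls):
        b = rng.normal(0.0, sd_pair, size=n)
        columns[f"VC{k+1:02d}"] = _sample(m_control, b)
        meta_rows.append(
            {"sample": f"VC{k+1:02d}", "group": "control", "pair_id": None, "sex": sexes[si], "age": float(rng.uniform(0.3, 13.0))}
        )
        si += 1

    values = pd.DataFrame(columns, index=probes).clip(_CLIP_EPS, 1 - _CLIP_EPS)
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    beta = BetaMatrix(values, metadata)

    truth = pd.DataFrame(
        {
            "is_spiked": spike_delta != 0.0,
            "true_direction": np.where(spike_delta < 0, "hypo", np.where(spike_delta > 0, "hyper", None)),
            "spike_delta": spike_delta,
            "true_delta_beta": true_delta,
            "dmr_block_id": dmr_block_id,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return beta, TruthTable(truth)


def generate_reference_set(
    truth: TruthTable,
    background: list[str],
    concordance: float = 0.8,
    extra_n: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """External reference DMS catalog overlapping the spiked truth.

    Contains round(concordance * n_spiked) spiked probes with their true
    directions plus ``extra_n`` random background probes (not among the
    chosen spikes) with random directions. Emulates an independent
    developmental methylation catalog sharing signal with the cohort.
    """
    if not 0 <= concordance <= 1:
        raise ValidationError("concordance must be in [0, 1]")
    rng = _rng(seed, 2)
    spiked = truth.spiked_probes
    k = int(round(concordance * len(spiked)))
    chosen = list(rng.choice(spiked, size=k, replace=False)) if k else []
    directions = [truth.table.loc[p, "true_direction"] for p in chosen]
    pool = [p for p in background if p not in set(chosen)]
    if extra_n > len(pool):
        raise ValidationError(f"extra_n={extra_n} exceeds available background ({len(pool)})")
    extras = list(rng.choice(pool, size=extra_n, replace=False)) if extra_n else []
    extra_dirs = list(rng.choice(["hypo", "hyper"], size=extra_n))
    return pd.DataFrame(
        {"probe_id": chosen + extras, "direction": directions + extra_dirs}
    ).set_index("probe_id")


def generate_line1_table(
    group_sizes: dict[str, int],
    seed: int = 0,
    base_means: tuple[float, float, float, float] = (72.0, 70.0, 71.0, 69.0),
    sd: float = 2.0,
    group_shifts: dict[str, tuple[float, float, float, float]] | None = None,
) -> pd.DataFrame:
    """Synthetic LINE-1 pyrosequencing table: 4 CpG percent-methylation
    columns per sample.

    By default the ``tumor`` group is shifted -2 percentage points at
    CpG1 only, mirroring a slight first-position hypomethylation;
    other positions are unshifted.
    """
    if group_shifts is None:
        group_shifts = {"tumor": (-2.0, 0.0, 0.0, 0.0)}
    rng = _rng(seed, 3)
    rows = []
    for group, size in group_sizes.items():
        shift = np.asarray(group_shifts.get(group, (0.0, 0.0, 0.0, 0.0)))
        for k in range(size):
            vals = np.clip(np.asarray(base_means) + shift + rng.normal(0.0, sd, size=4), 0.0, 100.0)
            rows.append(
                {
                    "sample": f"{group}_{k+1:02d}",
                    "group": group,
                    "cpg1": vals[0],
                    "cpg2": vals[1],
                    "cpg3": vals[2],
                    "cpg4": vals[3],
                }
            )
    return pd.DataFrame(rows)
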