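"""Shared fixtures and toy-object factories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cpgdiff import AnnotationTable, BetaMatrix, DMSSet, SpikeConfig, generate_annotation, generate_cohort
from cpgdiff.integrate import CommonDMSSet


def make_annotation(rows: list[dict]) -> AnnotationTable:
    """Build an AnnotationTable from sparse row dicts (sensible defaults)."""
    full = []
    for i, r in enumerate(rows):
        full.append(
            {
                "probe_id": r.get("probe_id", f"cg{i:06d}"),
                "chromosome": r.get("chromosome", "chr1"),
                "position": r.get("position", 1000 + i * 100),
                "gene_symbols": tuple(r.get("genes", ())),
                "gene_relations": tuple(r.get("relations", ())),
                "island_relation": r.get("island", "OpenSea"),
                "snp_flag": r.get("snp", False),
                "cpg_probe": r.get("cpg", True),
            }
        )
    return AnnotationTable(pd.DataFrame(full).set_index("probe_id"))


def make_dms_set(records: dict[str, tuple[str, float]], alpha: float = 0.05, design: str = "paired", n_tested: int = 1000) -> DMSSet:
    """DMSSet from {probe: (direction, delta_beta)} with filled-in stats."""
    df = pd.DataFrame(
        {
            "delta_beta": {p: d for p, (_, d) in records.items()},
            "t_mod": {p: (5.0 if d > 0 else -5.0) for p, (_, d) in records.items()},
            "p_value": {p: 1e-6 for p in records},
            "adj_p": {p: 1e-4 for p in records},
            "direction": {p: direc for p, (direc, _) in records.items()},
        }
    )
    return DMSSet(records=df, alpha=alpha, design=design, n_tested=n_tested)


def make_common(records: dict[str, tuple[str, float]], n_discovery: int | None = None) -> CommonDMSSet:
    """CommonDMSSet from {probe: (direction, delta_beta)} (same delta both arms)."""
    df = pd.DataFrame(
        {
            "direction": {p: d for p, (d, _) in records.items()},
            "delta_beta_discovery": {p: v for p, (_, v) in records.items()},
            "delta_beta_validation": {p: v for p, (_, v) in records.items()},
            "direction_consistent": {p: True for p in records},
        }
    )
    return CommonDMSSet(records=df, n_discovery=n_discovery or len(df), n_validation=len(df), n_discordant=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small spiked cohort shared by read-only tests (2000 probes, seed 11)."""
    ann = generate_annotation(2000, seed=11)
    cfg = SpikeConfig(
        n_probes=2000,
        n_spiked_dms=100,
        n_dmr_blocks=4,
        noise_sd=0.08,
        delta_beta_effect=0.25,
        global_hypo_shift=0.0,
        seed=11,
    )
    beta, truth = generate_cohort(ann, cfg)
    return ann, cfg, beta, truth


@pytest.fixture
def tiny_beta():
    """3 probes x 4 samples, one complete pair plus two unpaired samples."""
    values = pd.DataFrame(
        np.array([[0.1, 0.2, 0.3, 0.4], [0.5, 0.6, 0.7, 0.8], [0.9, 0.85, 0.15, 0.25]]),
        index=["cg1", "cg2", "cg3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    metadata = pd.DataFrame(
        {
            "group": ["tumor", "control", "tumor", "control"],
            "pair_id": ["P1", "P1", None, None],
            "sex": ["M", "M", "F", "F"],
            "age": [1.0, 1.0, 2.0, 3.0],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
    )
    return BetaMatrix(values, metadata)
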