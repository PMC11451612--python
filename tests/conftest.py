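"""Shared fixtures: tiny hand-built inputs and one shared synthetic dataset."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fclmr.simulate import SimConfig, simulate_expression, simulate_genomes
from fclmr.types import CODING, LNCRNA, ExpressionMatrix, GeneModel, PipelineConfig


def gene(gene_id, start, end, *, chrom="chr1", species="human", strand="+", biotype=CODING):
    return GeneModel(gene_id, species, chrom, start, end, strand, biotype)


def lnc(gene_id, start, end, **kw):
    return gene(gene_id, start, end, biotype=LNCRNA, **kw)


def make_expr(values: dict[str, list[float]], conditions: list[str] | None = None,
              compartment: str = "human") -> ExpressionMatrix:
    """Expression matrix from gene -> per-sample values.

    Sample ids are c<i>_r<j>; ``conditions`` assigns each sample a condition
    label (defaults to one condition per sample).
    """
    n = len(next(iter(values.values())))
    conditions = conditions if conditions is not None else [f"c{i}" for i in range(n)]
    assert len(conditions) == n
    counts: dict[str, int] = {}
    sample_ids = []
    replicates = []
    for c in conditions:
        counts[c] = counts.get(c, 0) + 1
        sample_ids.append(f"{c}_r{counts[c]}")
        replicates.append(counts[c])
    meta = pd.DataFrame(
        {"compartment": compartment, "condition": conditions, "replicate": replicates},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    df = pd.DataFrame(values, index=sample_ids).T
    return ExpressionMatrix(df, meta)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


#: compact generator settings for tests that re-simulate many times
SMALL_SIM = dict(
    n_chromosomes=2,
    coding_genes_per_chrom=60,
    n_true_fclmr_pairs=3,
    n_decoy_lnc_per_species=12,
    n_syntenic_decoy_pairs=3,
    n_coreg_decoy_pairs=3,
    n_pathways=6,
    pathway_size=8,
)


@pytest.fixture(scope="session")
def sim_bundle():
    """One default-config synthetic dataset shared by read-only tests."""
    cfg = SimConfig(seed=11)
    annot_h, annot_m, omap, truth = simulate_genomes(cfg)
    expr_h, expr_m = simulate_expression(truth, cfg)
    return cfg, annot_h, annot_m, omap, truth, expr_h, expr_m
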