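"""Knockdown/rescue transcriptome-reversal scoring.

The functional-equivalence assay: knock down the mouse lncRNA (KD vs
control), express the human lncRNA on top (rescue vs KD), and ask how much
of the KD-induced transcriptome change reverts. A pathway is *rescued*
when it is over-represented among differential genes in both comparisons
with opposite aggregate directions; a gene is *rescued* when it is
significant in both comparisons with opposite log2FC signs. The headline
number is the percentage of KD-perturbed pathways that were rescued.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coregulation import DEResult, differential_expression
from .matching import hypergeometric_enrichment
from .types import ExpressionMatrix, PathwayDB, PipelineConfig


@dataclass(frozen=True)
class PathwayRescueCall:
    pathway_id: str
    kd_enriched: bool
    kd_direction: str  # "up", "down" or "none"
    rescue_enriched: bool
    rescue_direction: str
    status: str  # "rescued" or "not_rescued"


@dataclass(frozen=True)
class GeneRescueCall:
    gene_id: str
    kd_log2fc: float
    rescue_log2fc: float
    status: str  # "rescued", "not_rescued" or "unaffected"


@dataclass
class RescueReport:
    """Pathway- and gene-level reversal calls for one KD/rescue experiment.

    ``percent_rescued`` is 100 × rescued / KD-enriched pathways; when no
    pathway is KD-enriched the percentage is undefined (None) and
    ``denominator_empty`` is set instead of silently reporting 0.
    """

    pathway_calls: list[PathwayRescueCall]
    gene_calls: list[GeneRescueCall]
    percent_rescued: float | None
    denominator_empty: bool = False

    @property
    def n_kd_enriched(self) -> int:
        return sum(1 for c in self.pathway_calls if c.kd_enriched)

    @property
    def n_rescued(self) -> int:
        return sum(1 for c in self.pathway_calls if c.status == "rescued")

    def gene_status_counts(self) -> dict[str, int]:
        counts = {"rescued": 0, "not_rescued": 0, "unaffected": 0}
        for c in self.gene_calls:
            counts[c.status] += 1
        return counts

    def summary(self) -> dict:
        return {
            "percent_rescued": self.percent_rescued,
            "denominator_empty": self.denominator_empty,
            "n_pathways_kd_enriched": self.n_kd_enriched,
            "n_pathways_rescued": self.n_rescued,
            "n_genes_by_status": self.gene_status_counts(),
        }


def _significant_genes(de: Sequence[DEResult], config: PipelineConfig) -> set[str]:
    return {
        r.gene_id
        for r in de
        if abs(r.log2fc) > config.lfc_threshold and r.p_value < config.p_threshold
    }


def _pathway_direction(
    members: frozenset[str], sig_genes: set[str], de_by_gene: Mapping[str, DEResult]
) -> str:
    """Sign of the mean log2FC over the pathway's significant member genes."""
    fcs = [de_by_gene[g].log2fc for g in members & sig_genes]
    if not fcs:
        return "none"
    mean_fc = float(np.mean(fcs))
    if mean_fc > 0:
        return "up"
    if mean_fc < 0:
        return "down"
    return "none"


def rescue_gene_classification(
    de_kd: Sequence[DEResult],
    de_rescue: Sequence[DEResult],
    config: PipelineConfig,
) -> list[GeneRescueCall]:
    """Per-gene reversal status from the two comparisons.

    unaffected: not significant in KD vs control. Otherwise rescued when
    also significant in rescue vs KD with the opposite log2FC sign, else
    not_rescued.
    """
    kd_by_gene = {r.gene_id: r for r in de_kd}
    rescue_by_gene = {r.gene_id: r for r in de_rescue}
    if set(kd_by_gene) != set(rescue_by_gene):
        only = set(kd_by_gene) ^ set(rescue_by_gene)
        raise ValueError(f"gene(s) present in only one DE list: {sorted(only)[:5]}")

    sig_kd = _significant_genes(de_kd, config)
    sig_rescue = _significant_genes(de_rescue, config)

    calls = []
    for gene_id in sorted(kd_by_gene):
        kd_fc = kd_by_gene[gene_id].log2fc
        re_fc = rescue_by_gene[gene_id].log2fc
        if gene_id not in sig_kd:
            status = "unaffected"
        elif gene_id in sig_rescue and kd_fc * re_fc < 0:
            status = "rescued"
        else:
            status = "not_rescued"
        calls.append(
            GeneRescueCall(gene_id=gene_id, kd_log2fc=kd_fc, rescue_log2fc=re_fc, status=status)
        )
    return calls


def rescue_pathway_report(
    expr: ExpressionMatrix,
    ctrl: Sequence[str],
    kd: Sequence[str],
    rescue: Sequence[str],
    db: PathwayDB,
    config: PipelineConfig,
) -> RescueReport:
    """Score the rescue experiment at pathway and gene level.

    Runs DE(KD vs control) and DE(rescue vs KD); per comparison the DE gene
    set (screen significance rule) is tested for pathway over-representation
    (hypergeometric, BH at ``fdr_alpha``) against the all-genes universe;
    a pathway's direction is the sign of the mean log2FC over its
    significant members. Rescued = enriched in both comparisons with
    opposite directions; the percentage is over KD-enriched pathways.
    """
    groups = [list(ctrl), list(kd), list(rescue)]
    for name, g in zip(("ctrl", "kd", "rescue"), groups):
        if len(g) < 2:
            raise ValueError(f"group {name!r} needs >= 2 samples")
    all_ids = [s for g in groups for s in g]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("ctrl/kd/rescue groups must be disjoint")

    de_kd = differential_expression(expr, groups[0], groups[1], config.pseudocount)
    de_rescue = differential_expression(expr, groups[1], groups[2], config.pseudocount)
    kd_by_gene = {r.gene_id: r for r in de_kd}
    rescue_by_gene = {r.gene_id: r for r in de_rescue}

    sig_kd = _significant_genes(de_kd, config)
    sig_rescue = _significant_genes(de_rescue, config)
    universe = set(expr.gene_ids)

    enriched_kd: dict[str, bool] = {}
    enriched_rescue: dict[str, bool] = {}
    for sig, out in ((sig_kd, enriched_kd), (sig_rescue, enriched_rescue)):
        results = hypergeometric_enrichment(sig & universe, db, universe) if sig else []
        flagged = {r.pathway_id: r.adjusted_p < config.fdr_alpha for r in results}
        for pid in db.pathway_ids():
            out[pid] = flagged.get(pid, False)

    pathway_calls = []
    for pid in db.pathway_ids():
        members = db.members(pid) & universe
        kd_dir = _pathway_direction(members, sig_kd, kd_by_gene)
        re_dir = _pathway_direction(members, sig_rescue, rescue_by_gene)
        rescued = (
            enriched_kd[pid]
            and enriched_rescue[pid]
            and kd_dir != "none"
            and re_dir != "none"
            and kd_dir != re_dir
        )
        pathway_calls.append(
            PathwayRescueCall(
                pathway_id=pid,
                kd_enriched=enriched_kd[pid],
                kd_direction=kd_dir,
                rescue_enriched=enriched_rescue[pid],
                rescue_direction=re_dir,
                status="rescued" if rescued else "not_rescued",
            )
        )

    n_kd = sum(1 for c in pathway_calls if c.kd_enriched)
    n_rescued = sum(1 for c in pathway_calls if c.status == "rescued")
    if n_kd == 0:
        percent, empty = None, True
    else:
        percent, empty = 100.0 * n_rescued / n_kd, False

    gene_calls = rescue_gene_classification(de_kd, de_rescue, config)
    return RescueReport(
        pathway_calls=pathway_calls,
        gene_calls=gene_calls,
        percent_rescued=percent,
        denominator_empty=empty,
    )


def report_to_frames(report: RescueReport) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(pathway table, gene table) for TSV output."""
    pw = pd.DataFrame(
        [
            {
                "pathway_id": c.pathway_id,
                "kd_enriched": c.kd_enriched,
                "kd_direction": c.kd_direction,
                "rescue_enriched": c.rescue_enriched,
                "rescue_direction": c.rescue_direction,
                "status": c.status,
            }
            for c in report.pathway_calls
        ]
    )
    genes = pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "kd_log2fc": c.kd_log2fc,
                "rescue_log2fc": c.rescue_log2fc,
                "status": c.status,
            }
            for c in report.gene_calls
        ]
    )
    return pw, genes
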