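"""Stage 3 of the screen: guilt-by-association functional matching.

Each surviving lncRNA is correlated against all expressed coding genes,
its top partners are tested for pathway over-representation
(hypergeometric, Benjamini–Hochberg adjusted), and a human/mouse pair is a
final candidate when the two species' enriched pathway sets agree. Also
houses the ortholog-recovery benchmark (how well cross-species expression
correlation re-identifies orthologous coding genes) and the discovery-rate
summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix, OrthologMap, PathwayDB, PipelineConfig
from .synteny import SyntenicPair


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one pathway in a query set."""

    pathway_id: str
    overlap_k: int
    query_n: int
    pathway_K: int
    universe_N: int
    p_value: float
    adjusted_p: float


@dataclass(frozen=True)
class SimilarityResult:
    """Cross-species agreement of two enriched-pathway sets."""

    shared_pathways: frozenset[str]
    significant_h: frozenset[str]
    significant_m: frozenset[str]
    jaccard: float
    passes: bool


@dataclass(frozen=True)
class FcLMRCandidate:
    """A syntenic pair that survived all three stages, with provenance."""

    pair: SyntenicPair
    matching_conditions: tuple[str, ...]
    similarity: SimilarityResult


def correlate_lnc_mrna(
    expr: ExpressionMatrix,
    lnc_id: str,
    coding_ids: Sequence[str],
    method: str = "spearman",
) -> pd.Series:
    """Correlation of one lncRNA's profile with each coding gene's.

    Returns one coefficient in [-1, 1] per coding gene; genes whose profile
    is constant across samples (correlation undefined) come back as NaN and
    are excluded by downstream ranking. Requires >= 3 samples.
    """
    if len(expr.sample_ids) < 3:
        raise ValueError("correlation needs >= 3 samples")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    missing = ({lnc_id} | set(coding_ids)) - set(expr.gene_ids)
    if missing:
        raise ValueError(f"gene(s) absent from matrix: {sorted(missing)[:5]}")

    x = expr.values.loc[lnc_id].to_numpy(float)
    mat = expr.values.loc[list(coding_ids)].to_numpy(float)
    if method == "spearman":
        x = stats.rankdata(x)
        mat = stats.rankdata(mat, axis=1)
    x_c = x - x.mean()
    mat_c = mat - mat.mean(axis=1, keepdims=True)
    x_sd = np.sqrt((x_c**2).sum())
    mat_sd = np.sqrt((mat_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mat_c @ x_c) / (mat_sd * x_sd)
    r[(mat_sd == 0) | (x_sd == 0)] = np.nan
    return pd.Series(np.clip(r, -1.0, 1.0), index=list(coding_ids), name=lnc_id)


def top_correlated_genes(correlations: pd.Series, top_n: int) -> list[str]:
    """First ``top_n`` genes by |coefficient| descending, ties by gene_id.

    NaN (undefined) coefficients are dropped; if every coefficient is
    undefined that is an error.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    defined = correlations.dropna()
    if defined.empty:
        raise ValueError("all correlations undefined (constant profiles?)")
    order = sorted(defined.index, key=lambda g: (-abs(defined[g]), g))
    return order[:top_n]


def hypergeometric_enrichment(
    query: set[str],
    db: PathwayDB,
    universe: set[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of each pathway against the query.

    Pathway member sets are intersected with the universe before testing;
    p = P(overlap >= k) under sampling query_n genes from universe_N with
    pathway_K marked; Benjamini–Hochberg adjustment across the tested
    pathway family. Sorted by (adjusted_p, p_value, pathway_id).
    """
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n = len(query)
    N = len(universe)
    rows: list[tuple[str, int, int, float]] = []
    for pid in db.pathway_ids():
        members = db.members(pid) & universe
        if not members:
            continue
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((pid, k, K, min(p, 1.0)))
    if not rows:
        return []
    raw_p = [r[3] for r in rows]
    _, adj, _, _ = multipletests(raw_p, method="fdr_bh")
    results = [
        EnrichmentResult(
            pathway_id=pid,
            overlap_k=k,
            query_n=n,
            pathway_K=K,
            universe_N=N,
            p_value=p,
            adjusted_p=float(a),
        )
        for (pid, k, K, p), a in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.pathway_id))
    return results


def pathway_similarity(
    enrich_h: Sequence[EnrichmentResult],
    enrich_m: Sequence[EnrichmentResult],
    config: PipelineConfig,
) -> SimilarityResult:
    """Agreement of the two species' significantly enriched pathway sets.

    Significance is adjusted_p < fdr_alpha within each species' own test
    family; the result records the shared set and Jaccard index, and passes
    when |shared| >= min_shared_pathways and jaccard >= jaccard_threshold.
    Symmetric in its two arguments.
    """
    sig_h = frozenset(r.pathway_id for r in enrich_h if r.adjusted_p < config.fdr_alpha)
    sig_m = frozenset(r.pathway_id for r in enrich_m if r.adjusted_p < config.fdr_alpha)
    shared = sig_h & sig_m
    union = sig_h | sig_m
    jaccard = len(shared) / len(union) if union else 0.0
    passes = len(shared) >= config.min_shared_pathways and jaccard >= config.jaccard_threshold
    return SimilarityResult(
        shared_pathways=shared,
        significant_h=sig_h,
        significant_m=sig_m,
        jaccard=jaccard,
        passes=passes,
    )


def select_fclmr(
    coreg_pairs: Sequence[tuple[SyntenicPair, list[str]]],
    similarity_by_pair: Mapping[tuple[str, str], SimilarityResult],
    config: PipelineConfig,
) -> list[FcLMRCandidate]:
    """Final candidates: co-regulated pairs whose pathway sets agree.

    Every surviving pair must have a similarity result; candidates carry
    full stage provenance and are ordered by (lnc_h, lnc_m).
    """
    candidates = []
    for pair, conditions in coreg_pairs:
        key = (pair.lnc_h, pair.lnc_m)
        if key not in similarity_by_pair:
            raise ValueError(f"pair {key} has no similarity result")
        sim = similarity_by_pair[key]
        if sim.passes:
            candidates.append(
                FcLMRCandidate(
                    pair=pair,
                    matching_conditions=tuple(sorted(conditions)),
                    similarity=sim,
                )
            )
    candidates.sort(key=lambda c: (c.pair.lnc_h, c.pair.lnc_m))
    return candidates


def expressed_universe(expr: ExpressionMatrix, gene_ids: Sequence[str], fraction: float = 0.5) -> set[str]:
    """Genes nonzero in at least ``fraction`` of samples — the enrichment universe."""
    sub = expr.values.loc[list(gene_ids)]
    frac_nonzero = (sub.to_numpy(float) > 0).mean(axis=1)
    return {g for g, f in zip(sub.index, frac_nonzero) if f >= fraction}


def ortholog_recovery_rate(
    expr_h: ExpressionMatrix,
    expr_m: ExpressionMatrix,
    orthologs: OrthologMap,
    k: int = 10,
    method: str = "spearman",
) -> float:
    """Fraction of human coding genes whose ortholog ranks in their top-k
    cross-species correlation partners.

    For each human gene with >= 1 ortholog present in the mouse matrix, all
    mouse genes are ranked by |correlation| over the shared sample set; the
    gene counts as recovered when any of its orthologs makes the top k.
    This is the benchmark for whether paired-compartment (humanized-liver)
    expression data carries cross-species co-expression signal.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    shared = [s for s in expr_h.sample_ids if s in set(expr_m.sample_ids)]
    if len(shared) < 3:
        raise ValueError("matrices must share >= 3 samples")

    genes_m = list(expr_m.gene_ids)
    idx_m = {g: i for i, g in enumerate(genes_m)}
    tested_genes = [
        g for g in expr_h.gene_ids if any(o in idx_m for o in orthologs.lookup(g))
    ]
    if not tested_genes:
        raise ValueError("no orthologous genes present in both matrices")

    h = expr_h.values.loc[tested_genes, shared].to_numpy(float)
    m = expr_m.values.loc[genes_m, shared].to_numpy(float)
    if method == "spearman":
        h = stats.rankdata(h, axis=1)
        m = stats.rankdata(m, axis=1)
    h_c = h - h.mean(axis=1, keepdims=True)
    m_c = m - m.mean(axis=1, keepdims=True)
    h_sd = np.sqrt((h_c**2).sum(axis=1))
    m_sd = np.sqrt((m_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (h_c @ m_c.T) / np.outer(h_sd, m_sd)
    corr = np.nan_to_num(np.abs(corr), nan=-1.0)

    k_eff = min(k, len(genes_m))
    recovered = 0
    # top-k by |corr|; kth largest threshold via partition
    for i, g in enumerate(tested_genes):
        row = corr[i]
        if k_eff >= len(genes_m):
            topk = set(range(len(genes_m)))
        else:
            part = np.argpartition(-row, k_eff - 1)[:k_eff]
            topk = set(part.tolist())
        orth_idx = {idx_m[o] for o in orthologs.lookup(g) if o in idx_m}
        if orth_idx & topk:
            recovered += 1
    return recovered / len(tested_genes)


def discovery_rate(n_selected: int, n_candidates: int) -> float:
    """Percentage of candidates selected, reported to one decimal.

    E.g. 59 selected out of 2419 candidates -> 2.4.
    """
    if n_candidates <= 0:
        raise ValueError("n_candidates must be > 0")
    if not 0 <= n_selected <= n_candidates:
        raise ValueError("need 0 <= n_selected <= n_candidates")
    return round(100.0 * n_selected / n_candidates, 1)
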