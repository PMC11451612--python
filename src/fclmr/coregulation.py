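"""Stage 2 of the screen: per-condition differential regulation and the
cross-species consistency filter.

Each lncRNA is tested per metabolic condition (treated vs control) for
differential expression; a syntenic pair survives when its two members are
significantly regulated in the same direction under at least one shared
condition, and (by default) never significantly regulated in opposite
directions under any condition. Significance is the screen's rule:
|log2 fold change| strictly greater than the threshold AND raw p below the
significance level — no multiple-testing correction at this stage (that is
deferred to pathway enrichment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, PipelineConfig
from .synteny import SyntenicPair


@dataclass(frozen=True)
class DEResult:
    """One gene's differential-expression call between two sample groups."""

    gene_id: str
    log2fc: float
    p_value: float
    mean_a: float
    mean_b: float


@dataclass(frozen=True)
class ConditionCall:
    log2fc: float
    p_value: float
    significant: bool
    direction: str  # "up", "down" or "none"


@dataclass(frozen=True)
class RegulationProfile:
    """Per-condition regulation calls for one lncRNA."""

    lnc_id: str
    calls: Mapping[str, ConditionCall]

    def conditions(self) -> list[str]:
        return list(self.calls)


def differential_expression(
    expr: ExpressionMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    pseudocount: float = 1.0,
    genes: Sequence[str] | None = None,
) -> list[DEResult]:
    """Welch two-sample test per gene between groups A (reference) and B.

    log2FC = log2((mean_b + pseudocount) / (mean_a + pseudocount)) on the
    raw abundance scale; the p-value comes from a two-sided unequal-variance
    t test on log2(value + pseudocount), which is the natural scale for
    TPM-like inputs at small group sizes. Genes with zero variance in both
    groups and equal means get p = 1 (no evidence of change). The test is a
    pluggable choice: any per-gene two-group test returning (log2FC, p)
    could stand behind this interface.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    overlap = set(samples_a) & set(samples_b)
    if overlap:
        raise ValueError(f"groups must be disjoint; shared samples {sorted(overlap)[:5]}")
    unknown = (set(samples_a) | set(samples_b)) - set(expr.sample_ids)
    if unknown:
        raise ValueError(f"unknown sample id(s): {sorted(unknown)[:5]}")

    values = expr.values if genes is None else expr.values.loc[list(genes)]
    a = values[samples_a].to_numpy(float)
    b = values[samples_b].to_numpy(float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(divide="ignore"):
        log2fc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)

    log_a = np.log2(a + pseudocount)
    log_b = np.log2(b + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant genes trigger a scipy precision warning; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_res = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    p = np.asarray(t_res.pvalue, float)
    # degenerate genes: no variance anywhere -> NaN from the test
    degenerate = np.isnan(p)
    if degenerate.any():
        same_mean = np.isclose(log_a.mean(axis=1), log_b.mean(axis=1))
        p = np.where(degenerate & same_mean, 1.0, p)
        p = np.where(degenerate & ~same_mean, 0.0, p)

    return [
        DEResult(gene_id=g, log2fc=float(fc), p_value=float(pv), mean_a=float(ma), mean_b=float(mb))
        for g, fc, pv, ma, mb in zip(values.index, log2fc, p, mean_a, mean_b)
    ]


def condition_de(
    expr: ExpressionMatrix,
    reference_condition: str,
    compartment: str | None = None,
    pseudocount: float = 1.0,
    genes: Sequence[str] | None = None,
) -> dict[str, list[DEResult]]:
    """DE of every non-reference condition against the reference condition."""
    out: dict[str, list[DEResult]] = {}
    ref_samples = expr.samples_for(reference_condition, compartment)
    for cond in expr.conditions:
        if cond == reference_condition:
            continue
        out[cond] = differential_expression(
            expr, ref_samples, expr.samples_for(cond, compartment), pseudocount, genes
        )
    return out


def _call(log2fc: float, p: float, config: PipelineConfig) -> ConditionCall:
    significant = abs(log2fc) > config.lfc_threshold and p < config.p_threshold
    if significant:
        direction = "up" if log2fc > 0 else "down"
    else:
        direction = "none"
    return ConditionCall(log2fc=log2fc, p_value=p, significant=significant, direction=direction)


def build_regulation_profile(
    lnc_ids: Iterable[str],
    de_by_condition: Mapping[str, list[DEResult]],
    config: PipelineConfig,
) -> list[RegulationProfile]:
    """One profile per lncRNA across all conditions.

    Significance follows the strict rule: |log2FC| > lfc_threshold (strict
    inequality, so a fold change sitting exactly on the threshold does not
    count) and p < p_threshold.
    """
    if not de_by_condition:
        raise ValueError("empty condition set")
    indexed = {
        cond: {r.gene_id: r for r in results} for cond, results in de_by_condition.items()
    }
    profiles = []
    for lnc in lnc_ids:
        calls: dict[str, ConditionCall] = {}
        for cond in sorted(indexed):
            if lnc not in indexed[cond]:
                raise ValueError(f"lncRNA {lnc!r} missing from condition {cond!r}")
            r = indexed[cond][lnc]
            calls[cond] = _call(r.log2fc, r.p_value, config)
        profiles.append(RegulationProfile(lnc_id=lnc, calls=calls))
    return profiles


def match_coregulated(
    pairs: Sequence[SyntenicPair],
    profiles_h: Sequence[RegulationProfile],
    profiles_m: Sequence[RegulationProfile],
    config: PipelineConfig,
) -> list[tuple[SyntenicPair, list[str]]]:
    """Cross-species consistency filter over syntenic pairs.

    A pair is retained iff >= 1 condition has both members significant with
    the same direction, and (when ``config.opposite_veto``) no condition has
    both significant with opposite directions. Returns retained pairs with
    their matching conditions.
    """
    ph = {p.lnc_id: p for p in profiles_h}
    pm = {p.lnc_id: p for p in profiles_m}
    retained: list[tuple[SyntenicPair, list[str]]] = []
    for pair in pairs:
        if pair.lnc_h not in ph or pair.lnc_m not in pm:
            raise ValueError(f"pair ({pair.lnc_h}, {pair.lnc_m}) lacks a regulation profile")
        prof_h, prof_m = ph[pair.lnc_h], pm[pair.lnc_m]
        shared = sorted(set(prof_h.calls) & set(prof_m.calls))
        if not shared:
            raise ValueError(f"pair ({pair.lnc_h}, {pair.lnc_m}): no shared conditions")
        matching, opposite = [], []
        for cond in shared:
            ch, cm = prof_h.calls[cond], prof_m.calls[cond]
            if ch.significant and cm.significant:
                if ch.direction == cm.direction:
                    matching.append(cond)
                else:
                    opposite.append(cond)
        if matching and not (config.opposite_veto and opposite):
            retained.append((pair, matching))
    return retained


def profiles_to_frame(profiles: Sequence[RegulationProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for cond, c in p.calls.items():
            rows.append(
                {
                    "lnc_id": p.lnc_id,
                    "condition": cond,
                    "log2fc": c.log2fc,
                    "p_value": c.p_value,
                    "significant": c.significant,
                    "direction": c.direction,
                }
            )
    return pd.DataFrame(rows, columns=["lnc_id", "condition", "log2fc", "p_value", "significant", "direction"])
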