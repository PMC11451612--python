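"""End-to-end screen orchestration: synteny → co-regulation → matching.

`run_screen_frames` is the in-memory API the examples and tests use;
`run_screen` is the file-driven entry point behind the CLI, reading one
YAML config and writing the candidate table, a per-candidate provenance
JSON and a run manifest from which the run is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from . import coregulation, io as fio, matching, synteny
from .matching import FcLMRCandidate
from .types import ExpressionMatrix, GeneModel, OrthologMap, PathwayDB, PipelineConfig

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Reproducibility record: config echo, input digests, stage funnel."""

    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    tool_version: str = __version__
    seed: int = 0
    started_at: str = ""
    finished_at: str = ""

    def validate(self) -> None:
        funnel = [
            self.stage_counts.get(k)
            for k in ("syntenic_pairs", "coregulated_pairs", "fclmr_candidates")
            if k in self.stage_counts
        ]
        for earlier, later in zip(funnel, funnel[1:]):
            if later > earlier:
                raise ValueError(f"stage counts must be non-increasing, got {funnel}")

    def to_json(self, path: str | Path) -> None:
        self.validate()
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ScreenResult:
    syntenic_pairs: list[synteny.SyntenicPair]
    coregulated_pairs: list[tuple[synteny.SyntenicPair, list[str]]]
    candidates: list[FcLMRCandidate]
    manifest: RunManifest

    def candidates_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            (h_up, m_up), (h_down, m_down) = c.pair.flank_orthologs
            rows.append(
                {
                    "lnc_h": c.pair.lnc_h,
                    "lnc_m": c.pair.lnc_m,
                    "flank_up_h": h_up,
                    "flank_up_m": m_up,
                    "flank_down_h": h_down,
                    "flank_down_m": m_down,
                    "orientation_preserved": c.pair.orientation_preserved,
                    "matching_conditions": ",".join(c.matching_conditions),
                    "shared_pathways": ",".join(sorted(c.similarity.shared_pathways)),
                    "jaccard": c.similarity.jaccard,
                }
            )
        cols = [
            "lnc_h", "lnc_m", "flank_up_h", "flank_up_m", "flank_down_h",
            "flank_down_m", "orientation_preserved", "matching_conditions",
            "shared_pathways", "jaccard",
        ]
        return pd.DataFrame(rows, columns=cols)

    def provenance(self) -> list[dict]:
        return [
            {
                "lnc_h": c.pair.lnc_h,
                "lnc_m": c.pair.lnc_m,
                "flank_orthologs": [list(p) for p in c.pair.flank_orthologs],
                "orientation_preserved": c.pair.orientation_preserved,
                "matching_conditions": list(c.matching_conditions),
                "significant_pathways_h": sorted(c.similarity.significant_h),
                "significant_pathways_m": sorted(c.similarity.significant_m),
                "shared_pathways": sorted(c.similarity.shared_pathways),
                "jaccard": c.similarity.jaccard,
            }
            for c in self.candidates
        ]


def _lnc_profiles(
    expr: ExpressionMatrix,
    lnc_ids: Sequence[str],
    reference_condition: str,
    config: PipelineConfig,
) -> list[coregulation.RegulationProfile]:
    missing = set(lnc_ids) - set(expr.gene_ids)
    if missing:
        raise ValueError(f"lncRNA(s) absent from expression matrix: {sorted(missing)[:5]}")
    de = coregulation.condition_de(
        expr, reference_condition, pseudocount=config.pseudocount, genes=sorted(set(lnc_ids))
    )
    return coregulation.build_regulation_profile(sorted(set(lnc_ids)), de, config)


def run_screen_frames(
    annot_h: list[GeneModel],
    annot_m: list[GeneModel],
    orthologs: OrthologMap,
    expr_h: ExpressionMatrix,
    expr_m: ExpressionMatrix,
    db: PathwayDB,
    config: PipelineConfig,
    reference_condition: str,
) -> ScreenResult:
    """Run stages 1–3 on in-memory inputs.

    Stage 2 compares every non-reference condition against
    ``reference_condition`` within each species' matrix; stage 3 correlates
    each surviving lncRNA against the expressed coding universe of its own
    species, tests the top partners for pathway over-representation and
    requires the two species' enriched pathway sets to agree.
    """
    started = datetime.now(timezone.utc).isoformat()

    pairs = synteny.enumerate_syntenic_pairs(annot_h, annot_m, orthologs, config.flank_mode)
    logger.info("stage 1 (synteny): %d pairs", len(pairs))

    lnc_h = sorted({p.lnc_h for p in pairs})
    lnc_m = sorted({p.lnc_m for p in pairs})
    profiles_h = _lnc_profiles(expr_h, lnc_h, reference_condition, config)
    profiles_m = _lnc_profiles(expr_m, lnc_m, reference_condition, config)
    coreg = coregulation.match_coregulated(pairs, profiles_h, profiles_m, config)
    logger.info("stage 2 (co-regulation): %d pairs", len(coreg))

    coding_h = [g.gene_id for g in annot_h if g.biotype == "coding" and g.gene_id in set(expr_h.gene_ids)]
    coding_m = [g.gene_id for g in annot_m if g.biotype == "coding" and g.gene_id in set(expr_m.gene_ids)]
    universe_h = matching.expressed_universe(expr_h, coding_h, config.expressed_fraction)
    universe_m = matching.expressed_universe(expr_m, coding_m, config.expressed_fraction)

    similarity: dict[tuple[str, str], matching.SimilarityResult] = {}
    enrich_cache_h: dict[str, list[matching.EnrichmentResult]] = {}
    enrich_cache_m: dict[str, list[matching.EnrichmentResult]] = {}

    def enrich(expr, lnc, universe, cache):
        if lnc not in cache:
            corr = matching.correlate_lnc_mrna(
                expr, lnc, sorted(universe), config.correlation_method
            )
            top = matching.top_correlated_genes(corr, config.top_n_correlated)
            cache[lnc] = matching.hypergeometric_enrichment(set(top), db, universe)
        return cache[lnc]

    for pair, _conds in coreg:
        e_h = enrich(expr_h, pair.lnc_h, universe_h, enrich_cache_h)
        e_m = enrich(expr_m, pair.lnc_m, universe_m, enrich_cache_m)
        similarity[(pair.lnc_h, pair.lnc_m)] = matching.pathway_similarity(e_h, e_m, config)

    candidates = matching.select_fclmr(coreg, similarity, config)
    logger.info("stage 3 (functional matching): %d candidates", len(candidates))

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        stage_counts={
            "syntenic_pairs": len(pairs),
            "coregulated_pairs": len(coreg),
            "fclmr_candidates": len(candidates),
        },
        seed=config.seed,
        started_at=started,
        finished_at=datetime.now(timezone.utc).isoformat(),
    )
    manifest.validate()
    return ScreenResult(
        syntenic_pairs=pairs, coregulated_pairs=coreg, candidates=candidates, manifest=manifest
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


_REQUIRED_KEYS = (
    "annotation_h",
    "annotation_m",
    "orthologs",
    "expression_h",
    "samples_h",
    "expression_m",
    "samples_m",
    "gene_sets",
    "out_dir",
)


def run_screen(config_path: str | Path) -> tuple[Path, RunManifest]:
    """File-driven screen from one YAML config.

    The config names every input path, the reference condition, and an
    optional ``pipeline:`` block of :class:`PipelineConfig` overrides.
    Writes ``candidates.tsv``, ``provenance.json`` and ``manifest.json``
    into ``out_dir``; on any stage error the partially written outputs are
    removed and the error is re-raised with the stage name.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    for key in _REQUIRED_KEYS:
        if key not in cfg:
            raise KeyError(f"screen config is missing required key {key!r}")

    pconfig = PipelineConfig(**cfg.get("pipeline", {}))
    reference = cfg.get("reference_condition", "chow")
    base = config_path.parent

    def resolve(key: str) -> Path:
        p = Path(cfg[key])
        return p if p.is_absolute() else base / p

    stage = "input"
    out_dir = resolve("out_dir")
    outputs = [out_dir / "candidates.tsv", out_dir / "provenance.json", out_dir / "manifest.json"]
    try:
        annot_h = fio.read_annotation(resolve("annotation_h"), cfg.get("annotation_format", "gtf"), species="human")
        annot_m = fio.read_annotation(resolve("annotation_m"), cfg.get("annotation_format", "gtf"), species="mouse")
        orthologs = fio.read_ortholog_table(resolve("orthologs"))
        expr_h = fio.read_expression(resolve("expression_h"), resolve("samples_h"))
        expr_m = fio.read_expression(resolve("expression_m"), resolve("samples_m"))
        db = fio.read_gene_sets(resolve("gene_sets"))

        stage = "screen"
        result = run_screen_frames(
            annot_h, annot_m, orthologs, expr_h, expr_m, db, pconfig, reference
        )

        stage = "output"
        out_dir.mkdir(parents=True, exist_ok=True)
        result.candidates_frame().to_csv(outputs[0], sep="\t", index=False)
        with open(outputs[1], "w") as fh:
            json.dump(result.provenance(), fh, indent=1, sort_keys=True)
        manifest = result.manifest
        for key in _REQUIRED_KEYS[:-1]:
            manifest.input_digests[key] = _sha256(resolve(key))
        manifest.config["reference_condition"] = reference
        manifest.to_json(outputs[2])
        return outputs[0], manifest
    except Exception as exc:
        for p in outputs:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"screen failed at stage {stage!r}: {exc}") from exc
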