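"""Domain types shared by every stage of the screen.

Coordinates are 0-based half-open everywhere inside the package; format
converters live only in :mod:`fclmr.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CODING = "coding"
LNCRNA = "lncRNA"
VALID_BIOTYPES = (CODING, LNCRNA)
VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, slots=True)
class GeneModel:
    """One gene locus, collapsed across transcripts to its union interval.

    Parameters
    ----------
    gene_id
        Unique identifier within one species' annotation.
    species
        Free-form species tag (e.g. ``"human"`` or ``"mouse"``).
    chrom
        Chromosome / scaffold name.
    start, end
        0-based half-open interval; ``start < end``.
    strand
        ``"+"``, ``"-"`` or ``"."`` (unknown).
    biotype
        Either ``"coding"`` or ``"lncRNA"``.
    """

    gene_id: str
    species: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if self.biotype not in VALID_BIOTYPES:
            raise ValueError(f"gene {self.gene_id}: invalid biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GeneModel") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


class OrthologMap:
    """Symmetric coding-gene ortholog lookup supporting one-to-many relations.

    Stores (species A id, species B id) pairs; ``lookup`` maps A→B and
    ``reverse_lookup`` maps B→A, always mutually consistent.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        self._forward: dict[str, set[str]] = {}
        self._reverse: dict[str, set[str]] = {}
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        self._forward.setdefault(a, set()).add(b)
        self._reverse.setdefault(b, set()).add(a)

    def lookup(self, a: str) -> frozenset[str]:
        return frozenset(self._forward.get(a, ()))

    def reverse_lookup(self, b: str) -> frozenset[str]:
        return frozenset(self._reverse.get(b, ()))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return b in self._forward.get(a, ())

    def __len__(self) -> int:
        return sum(len(v) for v in self._forward.values())

    def pairs(self) -> list[tuple[str, str]]:
        return sorted((a, b) for a, bs in self._forward.items() for b in bs)

    def reversed(self) -> "OrthologMap":
        """The B→A map (for species-symmetry operations)."""
        return OrthologMap((b, a) for a, b in self.pairs())

    def validate_against(self, annot_a: Iterable[GeneModel], annot_b: Iterable[GeneModel]) -> None:
        """Check every referenced id resolves to a coding gene."""
        coding_a = {g.gene_id for g in annot_a if g.biotype == CODING}
        coding_b = {g.gene_id for g in annot_b if g.biotype == CODING}
        for a, b in self.pairs():
            if a not in coding_a:
                raise ValueError(f"ortholog id {a!r} is not a coding gene in annotation A")
            if b not in coding_b:
                raise ValueError(f"ortholog id {b!r} is not a coding gene in annotation B")


class ExpressionMatrix:
    """Genes × samples abundance matrix (TPM-like, nonnegative) with metadata.

    ``values`` is a DataFrame indexed by gene_id with sample-id columns;
    ``sample_meta`` is indexed by sample_id with at least ``compartment``,
    ``condition`` and ``replicate`` columns.
    """

    REQUIRED_META = ("compartment", "condition", "replicate")

    def __init__(self, values: pd.DataFrame, sample_meta: pd.DataFrame) -> None:
        values = values.astype(float)
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if (values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        missing_meta = set(values.columns) - set(sample_meta.index)
        if missing_meta:
            raise ValueError(f"samples missing from metadata: {sorted(missing_meta)[:5]}")
        for col in self.REQUIRED_META:
            if col not in sample_meta.columns:
                raise ValueError(f"sample metadata lacks required column {col!r}")
        if sample_meta["condition"].isna().any():
            raise ValueError("every sample needs a condition label")
        self.values = values
        self.sample_meta = sample_meta.loc[list(values.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.sample_meta["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def samples_for(self, condition: str, compartment: str | None = None) -> list[str]:
        meta = self.sample_meta
        mask = meta["condition"] == condition
        if compartment is not None:
            mask &= meta["compartment"] == compartment
        return list(meta.index[mask])

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.sample_meta)

    def __repr__(self) -> str:
        return (
            f"ExpressionMatrix({len(self.gene_ids)} genes x "
            f"{len(self.sample_ids)} samples, {len(self.conditions)} conditions)"
        )


class PathwayDB:
    """pathway_id → (name, member gene-id set), as read from GMT."""

    def __init__(self, pathways: Mapping[str, tuple[str, frozenset[str]]] | None = None) -> None:
        self._pathways: dict[str, tuple[str, frozenset[str]]] = {}
        if pathways:
            for pid, (name, members) in pathways.items():
                self.add(pid, name, members)

    def add(self, pathway_id: str, name: str, members: Iterable[str]) -> None:
        if pathway_id in self._pathways:
            raise ValueError(f"duplicate pathway id {pathway_id!r}")
        member_set = frozenset(members)
        if not member_set:
            raise ValueError(f"pathway {pathway_id!r} has no members")
        self._pathways[pathway_id] = (name, member_set)

    def members(self, pathway_id: str) -> frozenset[str]:
        return self._pathways[pathway_id][1]

    def name(self, pathway_id: str) -> str:
        return self._pathways[pathway_id][0]

    def pathway_ids(self) -> list[str]:
        return sorted(self._pathways)

    def __len__(self) -> int:
        return len(self._pathways)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._pathways

    def items(self):
        return self._pathways.items()


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and knobs for the three-stage screen and rescue scorer.

    ``lfc_threshold``/``p_threshold`` implement the screen's significance
    rule (|log2FC| strictly greater than 0.5 and raw p < 0.05 by default);
    enrichment significance uses Benjamini–Hochberg ``fdr_alpha``.
    """

    lfc_threshold: float = 0.5
    p_threshold: float = 0.05
    fdr_alpha: float = 0.05
    top_n_correlated: int = 500
    min_shared_pathways: int = 1
    jaccard_threshold: float = 0.0
    pseudocount: float = 1.0
    correlation_method: str = "spearman"
    flank_mode: str = "unordered"
    opposite_veto: bool = True
    expressed_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or self.p_threshold <= 0 or self.fdr_alpha <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 <= self.jaccard_threshold <= 1.0:
            raise ValueError("jaccard_threshold must lie in [0, 1]")
        if self.top_n_correlated < 1:
            raise ValueError("top_n_correlated must be >= 1")
        if self.correlation_method not in ("spearman", "pearson"):
            raise ValueError(f"unknown correlation method {self.correlation_method!r}")
        if self.flank_mode not in ("unordered", "ordered"):
            raise ValueError(f"unknown flank mode {self.flank_mode!r}")

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def as_sorted_gene_list(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Genes sorted by (chrom, start, end, gene_id) for deterministic scans."""
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))


def check_unique_ids(genes: Iterable[GeneModel]) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in annotation")
        seen.add(g.gene_id)


def rng_from_seed(seed: int, *salt: int) -> np.random.Generator:
    """Deterministic substream: one global seed, per-module salted children."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=salt))
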