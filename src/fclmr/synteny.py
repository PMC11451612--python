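"""Stage 1 of the screen: syntenic lncRNA pairing.

A human lncRNA and a mouse lncRNA are candidate functional analogues when
the protein-coding genes immediately flanking them are orthologous — the
lncRNA sits in the same conserved gene neighbourhood in both genomes even
though its own sequence does not align. By default flank matching is
unordered (tolerant of local inversions); ``mode="ordered"`` additionally
requires upstream→upstream, downstream→downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .types import CODING, LNCRNA, GeneModel, OrthologMap, as_sorted_gene_list

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FlankPair:
    """The nearest coding genes on either side of an intergenic lncRNA."""

    lnc_id: str
    upstream_id: str  # lower-coordinate side
    downstream_id: str  # higher-coordinate side
    upstream_gap: int
    downstream_gap: int

    def __post_init__(self) -> None:
        if self.upstream_gap < 0 or self.downstream_gap < 0:
            raise ValueError(f"{self.lnc_id}: flank gaps must be >= 0")
        if self.upstream_id == self.downstream_id:
            raise ValueError(f"{self.lnc_id}: upstream and downstream flanks coincide")


@dataclass(frozen=True)
class SyntenicPair:
    """A (human lncRNA, mouse lncRNA) pair sharing an orthologous flank frame.

    ``flank_orthologs`` holds the two (species A coding, species B coding)
    pairs through which the frames matched; ``orientation_preserved`` is
    True when upstream mapped to upstream and downstream to downstream.
    """

    lnc_h: str
    lnc_m: str
    flank_orthologs: tuple[tuple[str, str], tuple[str, str]]
    orientation_preserved: bool


def flanking_coding_genes(lnc: GeneModel, coding: list[GeneModel]) -> FlankPair | None:
    """Nearest coding flanks of ``lnc`` among same-chromosome coding genes.

    Returns None when the lncRNA lacks a flank on either side (chromosome
    edge) or overlaps a coding gene (it is then not an intergenic locus;
    logged). Ties in boundary coordinate are broken by gene_id so results
    are deterministic.
    """
    if lnc.biotype != LNCRNA:
        raise ValueError(f"{lnc.gene_id}: not a lncRNA")
    for g in coding:
        if g.biotype != CODING:
            raise ValueError(f"{g.gene_id}: coding list contains biotype {g.biotype!r}")
        if g.chrom != lnc.chrom:
            raise ValueError(f"{g.gene_id}: not on lncRNA chromosome {lnc.chrom}")

    overlapping = [g for g in coding if g.overlaps(lnc)]
    if overlapping:
        logger.info(
            "lncRNA %s overlaps coding gene(s) %s; excluded from synteny",
            lnc.gene_id,
            [g.gene_id for g in overlapping],
        )
        return None

    # upstream: greatest end <= lnc.start; ties by gene_id
    up_candidates = [g for g in coding if g.end <= lnc.start]
    down_candidates = [g for g in coding if g.start >= lnc.end]
    if not up_candidates or not down_candidates:
        return None
    upstream = min(up_candidates, key=lambda g: (-g.end, g.gene_id))
    downstream = min(down_candidates, key=lambda g: (g.start, g.gene_id))
    return FlankPair(
        lnc_id=lnc.gene_id,
        upstream_id=upstream.gene_id,
        downstream_id=downstream.gene_id,
        upstream_gap=lnc.start - upstream.end,
        downstream_gap=downstream.start - lnc.end,
    )


def _flank_index(annot: list[GeneModel]) -> dict[str, FlankPair]:
    """lnc_id → FlankPair for every intergenic, flanked lncRNA."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in as_sorted_gene_list(annot):
        by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, FlankPair] = {}
    for chrom, genes in by_chrom.items():
        coding = [g for g in genes if g.biotype == CODING]
        for lnc in genes:
            if lnc.biotype != LNCRNA:
                continue
            fp = flanking_coding_genes(lnc, coding)
            if fp is not None:
                out[lnc.gene_id] = fp
    return out


def enumerate_syntenic_pairs(
    annot_h: list[GeneModel],
    annot_m: list[GeneModel],
    orthologs: OrthologMap,
    mode: str = "unordered",
) -> list[SyntenicPair]:
    """All (human lncRNA, mouse lncRNA) pairs whose flank frames map.

    A frame matches when the human upstream/downstream coding genes map
    through the ortholog table onto the mouse flanks — in either
    orientation for ``mode="unordered"``, or only upstream→upstream for
    ``mode="ordered"``. When several lncRNAs of each species share one
    frame, all cross pairs are emitted. One-to-many orthologs are
    accommodated by trying every combination; a pair is emitted if any
    combination matches. Output is sorted by (lnc_h, lnc_m).
    """
    if mode not in ("unordered", "ordered"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(orthologs) == 0:
        raise ValueError("empty ortholog map: no flank frame can match")

    flanks_h = _flank_index(annot_h)
    flanks_m = _flank_index(annot_m)

    # index mouse lncRNAs by their (upstream, downstream) coding frame
    by_frame_m: dict[tuple[str, str], list[str]] = {}
    for lnc_m, fp in flanks_m.items():
        by_frame_m.setdefault((fp.upstream_id, fp.downstream_id), []).append(lnc_m)

    pairs: dict[tuple[str, str], SyntenicPair] = {}
    for lnc_h in sorted(flanks_h):
        fp_h = flanks_h[lnc_h]
        up_orths = orthologs.lookup(fp_h.upstream_id)
        down_orths = orthologs.lookup(fp_h.downstream_id)
        # (mouse up, mouse down, orientation_preserved) candidate frames
        candidate_frames: list[tuple[str, str, bool]] = [
            (mu, md, True) for mu in sorted(up_orths) for md in sorted(down_orths) if mu != md
        ]
        if mode == "unordered":
            candidate_frames += [
                (md, mu, False) for mu in sorted(up_orths) for md in sorted(down_orths) if mu != md
            ]
        for mu, md, preserved in candidate_frames:
            for lnc_m in by_frame_m.get((mu, md), ()):
                key = (lnc_h, lnc_m)
                if key in pairs:
                    continue  # first (orientation-preserved first) match wins
                if preserved:
                    flank_orths = ((fp_h.upstream_id, mu), (fp_h.downstream_id, md))
                else:
                    flank_orths = ((fp_h.upstream_id, md), (fp_h.downstream_id, mu))
                pairs[key] = SyntenicPair(
                    lnc_h=lnc_h,
                    lnc_m=lnc_m,
                    flank_orthologs=flank_orths,
                    orientation_preserved=preserved,
                )
    return [pairs[k] for k in sorted(pairs)]


def pairs_to_frame(pairs: list[SyntenicPair]) -> pd.DataFrame:
    """Tabular view for TSV output."""
    rows = []
    for p in pairs:
        (h_up, m_up), (h_down, m_down) = p.flank_orthologs
        rows.append(
            {
                "lnc_h": p.lnc_h,
                "lnc_m": p.lnc_m,
                "flank_up_h": h_up,
                "flank_up_m": m_up,
                "flank_down_h": h_down,
                "flank_down_m": m_down,
                "orientation_preserved": p.orientation_preserved,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lnc_h",
            "lnc_m",
            "flank_up_h",
            "flank_up_m",
            "flank_down_h",
            "flank_down_m",
            "orientation_preserved",
        ],
    )
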