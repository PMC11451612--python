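"""Pathway over-representation and cross-species pathway-set agreement.

Small hand-built inputs: a 10-gene universe, one 5-gene pathway, and a
query that overlaps it completely — the textbook hypergeometric case —
followed by a Jaccard comparison of two species' enriched pathway sets.
"""

from fclmr import PipelineConfig
from fclmr.matching import hypergeometric_enrichment, pathway_similarity
from fclmr.types import PathwayDB

universe = {f"g{i}" for i in range(10)}
db = PathwayDB()
db.add("fatty_acid_metabolism", "demo", {f"g{i}" for i in range(5)})
query = {f"g{i}" for i in range(5)}

(res,) = hypergeometric_enrichment(query, db, universe)
print(f"overlap {res.overlap_k}/{res.pathway_K} in a query of {res.query_n} "
      f"from a universe of {res.universe_N}")
print(f"hypergeometric p = {res.p_value:.6f}  (= 1/C(10,5) = 1/252)")
print(f"BH-adjusted p    = {res.adjusted_p:.6f}  (single test: unchanged)")

config = PipelineConfig()


class Enriched:
    def __init__(self, pathway_id, adjusted_p):
        self.pathway_id, self.adjusted_p = pathway_id, adjusted_p


enrich_h = [Enriched(p, 0.01) for p in ("P1", "P2", "P3")]
enrich_m = [Enriched(p, 0.01) for p in ("P2", "P3", "P4")]
sim = pathway_similarity(enrich_h, enrich_m, config)
print(f"shared pathways: {sorted(sim.shared_pathways)}")
print(f"jaccard: {sim.jaccard}  passes: {sim.passes}")

# The screen calls a human/mouse lncRNA pair functionally matched when the
# pathway sets enriched among each lncRNA's top correlated coding genes
# overlap (here 2 shared of 4 total: Jaccard 0.5, passing the default
# >=1-shared-pathway rule).
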