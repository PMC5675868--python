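"""Gene-neighborhood context extraction and auxiliary-gene co-occurrence mining.

The core inference: for every relaxase homolog, find the gene(s) directly
upstream of it in its own transcription direction, then cross the upstream
gene products with the auxiliary-protein homolog hit lists.  A relaxase row
gets ``has_aux2 = True`` iff its adjacent upstream gene product is in the
aux2 hit set, and ``has_aux1 = True`` iff, additionally, the next gene
further upstream is in the aux1 hit set — the nested "preceded by ... and of
these ... contained an additional" pattern of relaxosome operons, where the
order along the DNA is aux1, aux2, relaxase.

"Upstream" requires co-orientation: genes on the opposite strand are
ignored, matching operon semantics.  Replicons are treated as linear by
default (plasmids are circular, but neighbor lookup in sequence databases is
effectively linear); pass ``circular=True`` to wrap around.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .homology import HomologHit
from .rhh import percent_positive
from .seqio import GeneFeature, RepliconAnnotation


@dataclass
class NeighborContext:
    """Upstream-gene relationships of one (relaxase) gene.

    Distances are in bp, 1-based-inclusive gap convention:
    distance = next gene start − previous gene end − 1, mapped through
    strand; negative values mean the CDSs overlap.  ``coupled`` flags a
    stop/start overlap (distance <= 0), i.e. translational coupling.
    """

    gene_id: str
    replicon_id: str
    strand: str
    upstream1: str | None = None
    upstream2: str | None = None
    distance1: int | None = None   # upstream1 -> gene
    distance2: int | None = None   # upstream2 -> upstream1
    co_oriented1: bool = False
    co_oriented2: bool = False
    coupled: bool = False


def _upstream_of(annotation: RepliconAnnotation, feat: GeneFeature,
                 max_distance: int, circular: bool) -> tuple[GeneFeature | None, int | None]:
    """Nearest co-oriented CDS on the 5' side of ``feat`` (gene orientation)."""
    L = len(annotation)
    best: tuple[int, GeneFeature] | None = None
    for f in annotation.features:
        if f.gene_id == feat.gene_id or f.strand != feat.strand:
            continue
        if feat.strand == "+":
            dist = feat.start - f.end - 1
        else:
            dist = f.start - feat.end - 1
        if circular and dist < -max(len(f), len(feat)):
            dist += L
        # allow small overlaps (coupling) but not containment
        if dist < -min(len(f), len(feat)) + 1:
            continue
        if dist > max_distance:
            continue
        if best is None or dist < best[0]:
            best = (dist, f)
    if best is None:
        return None, None
    return best[1], best[0]


def gene_context(annotation: RepliconAnnotation, gene_id: str,
                 max_distance: int = 1000, circular: bool = False) -> NeighborContext:
    """Extract the upstream-gene context of a gene.

    ``upstream1`` is the nearest co-oriented CDS 5' of the gene within
    ``max_distance`` bp; ``upstream2`` likewise relative to upstream1.
    A gene at the replicon edge simply has absent upstream fields.
    """
    feat = annotation.feature(gene_id)
    ctx = NeighborContext(gene_id=gene_id, replicon_id=annotation.replicon_id,
                          strand=feat.strand)
    up1, d1 = _upstream_of(annotation, feat, max_distance, circular)
    if up1 is None:
        return ctx
    ctx.upstream1, ctx.distance1 = up1.gene_id, d1
    ctx.co_oriented1 = True
    ctx.coupled = d1 <= 0
    up2, d2 = _upstream_of(annotation, up1, max_distance, circular)
    if up2 is not None:
        ctx.upstream2, ctx.distance2 = up2.gene_id, d2
        ctx.co_oriented2 = True
    return ctx


def cross_cooccurrence(relaxase_hits: list[HomologHit],
                       aux1_hits: list[HomologHit],
                       aux2_hits: list[HomologHit],
                       contexts: list[NeighborContext]) -> pd.DataFrame:
    """Cross relaxase neighborhoods with the auxiliary hit lists.

    One row per relaxase hit.  ``has_aux2`` requires the adjacent upstream
    gene to be an aux2 homolog; ``has_aux1`` additionally requires the next
    upstream gene to be an aux1 homolog (nested).  Relaxase hits without a
    resolvable context are kept and flagged, not dropped.
    """
    ctx_by_gene = {c.gene_id: c for c in contexts}
    aux1_ids = {h.subject_id for h in aux1_hits}
    aux2_ids = {h.subject_id for h in aux2_hits}
    rows = []
    for hit in relaxase_hits:
        ctx = ctx_by_gene.get(hit.subject_id)
        if ctx is None:
            rows.append({"relaxase_gene": hit.subject_id, "replicon": pd.NA,
                         "resolved": False, "upstream1": pd.NA, "upstream2": pd.NA,
                         "distance1": pd.NA, "distance2": pd.NA,
                         "coupled": False, "has_aux2": False, "has_aux1": False})
            continue
        has_aux2 = ctx.upstream1 is not None and ctx.upstream1 in aux2_ids
        has_aux1 = (has_aux2 and ctx.upstream2 is not None
                    and ctx.upstream2 in aux1_ids)
        rows.append({
            "relaxase_gene": ctx.gene_id, "replicon": ctx.replicon_id,
            "resolved": True,
            "upstream1": ctx.upstream1 if ctx.upstream1 is not None else pd.NA,
            "upstream2": ctx.upstream2 if ctx.upstream2 is not None else pd.NA,
            "distance1": ctx.distance1 if ctx.distance1 is not None else pd.NA,
            "distance2": ctx.distance2 if ctx.distance2 is not None else pd.NA,
            "coupled": ctx.coupled, "has_aux2": has_aux2, "has_aux1": has_aux1,
        })
    columns = ["relaxase_gene", "replicon", "resolved", "upstream1", "upstream2",
               "distance1", "distance2", "coupled", "has_aux2", "has_aux1"]
    return pd.DataFrame(rows, columns=columns)


def summarize(table: pd.DataFrame, rhh_table: pd.DataFrame | None = None) -> dict:
    """Count co-occurrences and RHH-positive percentages among the aux proteins.

    ``rhh_table`` is the per-protein output of :func:`relaxkit.rhh.screen_candidates`
    for the upstream gene products; percentages are over the unique aux gene
    ids referenced by the co-occurrence table, to one decimal.
    """
    n_relaxases = len(table)
    n_aux2 = int(table["has_aux2"].sum()) if n_relaxases else 0
    n_aux1 = int(table["has_aux1"].sum()) if n_relaxases else 0
    aux2_genes = (set(table.loc[table["has_aux2"], "upstream1"].dropna())
                  if n_relaxases else set())
    aux1_genes = (set(table.loc[table["has_aux1"], "upstream2"].dropna())
                  if n_relaxases else set())
    summary = {
        "n_relaxases": n_relaxases,
        "n_with_aux2": n_aux2,
        "n_with_aux1_and_aux2": n_aux1,
        "n_aux2_genes": len(aux2_genes),
        "n_aux1_genes": len(aux1_genes),
    }
    if rhh_table is not None and len(rhh_table):
        pos = set(rhh_table.loc[rhh_table["rhh_positive"], "protein_id"])
        summary["pct_aux2_rhh"] = percent_positive(len(aux2_genes & pos),
                                                   len(aux2_genes))
        summary["pct_aux1_rhh"] = percent_positive(len(aux1_genes & pos),
                                                   len(aux1_genes))
    else:
        summary["pct_aux2_rhh"] = 0.0
        summary["pct_aux1_rhh"] = 0.0
    return summary
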