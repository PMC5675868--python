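"""Upstream-gene contexts and co-occurrence crossing."""

import pandas as pd
import pytest

from relaxkit.homology import HomologHit
from relaxkit.neighborhood import (NeighborContext, cross_cooccurrence,
                                   gene_context, summarize)
from relaxkit.seqio import (GeneFeature, RepliconAnnotation,
                            reverse_complement_annotation)
from relaxkit.synth import SynthConfig, generate_replicons
from relaxkit._seed_proteins import SEED_QUERIES


def _hit(qid, sid):
    return HomologHit(qid, sid, 100.0, 1e-20)


@pytest.fixture(scope="module")
def triplet_annotations():
    """Replicons where every aux1-aux2 and aux2-relaxase gap is exactly 183 bp."""
    cfg = SynthConfig(seed=5, n_replicons=6, p_aux2_upstream=1.0,
                      p_aux1_upstream=1.0, p_coupled=0.0,
                      intergenic_bp_range=(183, 183), mutation_rate=0.0)
    return generate_replicons(cfg)


def _relaxase_contexts(annotations, manifest, **kw):
    rel = manifest.family_ids("relaxase")
    out = []
    for ann in annotations:
        for f in ann.features:
            if f.gene_id in rel:
                out.append((ann, gene_context(ann, f.gene_id, **kw)))
    return out


def test_intergenic_distance_183(triplet_annotations):
    """Small intergenic regions between auxiliary genes are measured exactly."""
    annotations, manifest = triplet_annotations
    aux1 = manifest.family_ids("aux1-like")
    aux2 = manifest.family_ids("aux2-like")
    for ann, ctx in _relaxase_contexts(annotations, manifest):
        assert ctx.upstream1 in aux2
        assert ctx.distance1 == 183
        assert ctx.upstream2 in aux1
        assert ctx.distance2 == 183
        assert not ctx.coupled


def test_translational_coupling_distance_minus_one():
    """A TAA/ATG stop-start overlap sharing one base gives distance -1."""
    cfg = SynthConfig(seed=6, n_replicons=6, p_aux2_upstream=1.0,
                      p_aux1_upstream=0.0, p_coupled=1.0, mutation_rate=0.0)
    annotations, manifest = generate_replicons(cfg)
    for ann, ctx in _relaxase_contexts(annotations, manifest):
        assert ctx.distance1 == -1
        assert ctx.coupled


def test_no_upstream_within_max_distance():
    seq = "A" * 3000
    feats = [GeneFeature("far", 1, 300, "+"),
             GeneFeature("rel", 2000, 2500, "+")]
    ann = RepliconAnnotation("r", seq, feats)
    ctx = gene_context(ann, "rel", max_distance=1000)
    assert ctx.upstream1 is None
    ctx2 = gene_context(ann, "rel", max_distance=2000)
    assert ctx2.upstream1 == "far"


def test_opposite_strand_gene_ignored():
    """Upstream selection requires co-orientation (operon semantics)."""
    seq = "A" * 2000
    feats = [GeneFeature("antisense", 400, 600, "-"),
             GeneFeature("sense", 100, 300, "+"),
             GeneFeature("rel", 700, 1200, "+")]
    ann = RepliconAnnotation("r", seq, feats)
    ctx = gene_context(ann, "rel")
    assert ctx.upstream1 == "sense"
    assert ctx.distance1 == 700 - 300 - 1


def test_context_invariant_under_reverse_complement(triplet_annotations):
    """Reverse-complementing the replicon maps contexts onto each other."""
    annotations, manifest = triplet_annotations
    for ann, ctx in _relaxase_contexts(annotations, manifest):
        rc = reverse_complement_annotation(ann)
        ctx_rc = gene_context(rc, ctx.gene_id)
        assert ctx_rc.upstream1 == ctx.upstream1
        assert ctx_rc.upstream2 == ctx.upstream2
        assert ctx_rc.distance1 == ctx.distance1
        assert ctx_rc.distance2 == ctx.distance2
        assert ctx_rc.strand != ctx.strand


def test_cross_cooccurrence_closed_loop(zero_noise_replicons):
    """Twenty planted triplets at zero noise give 20 rows, all flags true."""
    annotations, manifest = zero_noise_replicons
    rel = sorted(manifest.family_ids("relaxase"))
    contexts = []
    for ann in annotations:
        for f in ann.features:
            if f.gene_id in rel:
                contexts.append(gene_context(ann, f.gene_id))
    rel_hits = [_hit("relaxase_query", g) for g in rel]
    aux1_hits = [_hit("aux1_query", g) for g in sorted(manifest.family_ids("aux1-like"))]
    aux2_hits = [_hit("aux2_query", g) for g in sorted(manifest.family_ids("aux2-like"))]
    table = cross_cooccurrence(rel_hits, aux1_hits, aux2_hits, contexts)
    assert len(table) == 20
    assert table.has_aux2.all()
    assert table.has_aux1.all()


def test_cross_cooccurrence_empty_aux_lists(zero_noise_replicons):
    annotations, manifest = zero_noise_replicons
    rel = sorted(manifest.family_ids("relaxase"))
    ann0 = annotations[0]
    gid = next(f.gene_id for f in ann0.features if f.gene_id in rel)
    contexts = [gene_context(ann0, gid)]
    table = cross_cooccurrence([_hit("relaxase_query", gid)], [], [], contexts)
    assert not table.has_aux2.any()
    assert not table.has_aux1.any()


def test_cross_cooccurrence_aux2_only():
    """An aux2-only architecture sets has_aux2 without has_aux1 (nested flags)."""
    cfg = SynthConfig(seed=8, n_replicons=8, p_aux2_upstream=1.0,
                      p_aux1_upstream=0.0, mutation_rate=0.0)
    annotations, manifest = generate_replicons(cfg)
    rel = sorted(manifest.family_ids("relaxase"))
    contexts = []
    for ann in annotations:
        for f in ann.features:
            if f.gene_id in rel:
                contexts.append(gene_context(ann, f.gene_id))
    table = cross_cooccurrence(
        [_hit("r", g) for g in rel],
        [_hit("a1", g) for g in manifest.family_ids("aux1-like")],
        [_hit("a2", g) for g in manifest.family_ids("aux2-like")],
        contexts)
    assert table.has_aux2.all()
    assert not table.has_aux1.any()


def test_unresolved_hit_flagged_not_dropped():
    table = cross_cooccurrence([_hit("r", "ghost")], [], [], [])
    assert len(table) == 1
    assert not table.resolved.item()


def test_summary_counts_match_brute_force(zero_noise_replicons, mined_summary):
    summary, out_dir, _ = mined_summary
    table = pd.read_csv(out_dir / "cooccurrence.tsv", sep="\t")
    assert summary["n_with_aux2"] == int(table.has_aux2.sum())
    assert summary["n_with_aux1_and_aux2"] == int(table.has_aux1.sum())


def test_summarize_empty_table_no_division_error():
    empty = pd.DataFrame(columns=["relaxase_gene", "upstream1", "upstream2",
                                  "has_aux2", "has_aux1"])
    s = summarize(empty, None)
    assert s["n_relaxases"] == 0
    assert s["pct_aux1_rhh"] == 0.0
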