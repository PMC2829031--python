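import numpy as np
import pandas as pd
import pytest

from lncdev.annotation import NCRNA, PROTEIN_CODING, TranscriptModel
from lncdev.context import (
    associate_enhancer,
    classify_context,
    classify_contexts,
    intersect_structures,
    positional_conservation,
)
from oracles import brute_force_context, random_loci


def gene(gene_id, start, strand="+", chrom="c"):
    exons = [(start, start + 300), (start + 1300, start + 1600),
             (start + 2600, start + 2900)]
    return TranscriptModel(gene_id=gene_id, chrom=chrom, start=start,
                           end=start + 2900, strand=strand,
                           biotype=PROTEIN_CODING, exons=exons, cds=list(exons))


def ncrna(nc_id, exons, strand="+", chrom="c"):
    return TranscriptModel(gene_id=nc_id, chrom=chrom, start=exons[0][0],
                           end=exons[-1][1], strand=strand, biotype=NCRNA,
                           exons=exons)


def test_antisense_exon_overlap():
    # Dlx1-like arrangement: ncRNA exon overlapping a gene exon, opposite strand
    g = gene("dlx1", 10_000, "+")
    nc = ncrna("dlx1as", [(11_200, 11_700)], "-")
    call = classify_context(nc, [g])
    assert call.context_class == "antisense"
    assert call.host_gene_id == "dlx1"


def test_bidirectional_divergent_promoters():
    # Sox8-like arrangement: head-to-head TSSs 400 bp apart, non-overlapping
    g = gene("sox8", 10_000, "+")
    nc = ncrna("sox8ot", [(8_800, 9_600)], "-")
    call = classify_context(nc, [g])
    assert call.context_class == "bidirectional"
    assert call.distance_to_tss == 401
    assert call.distance_to_tss <= 1000


def test_intronic_containment():
    # Bai3-like arrangement: ncRNA wholly inside intron 1
    g = gene("bai3", 10_000, "+")
    call = classify_context(ncrna("ak", [(10_500, 10_900)], "+"), [g])
    assert call.context_class == "intronic_sense"
    call = classify_context(ncrna("ak", [(10_500, 10_900)], "-"), [g])
    assert call.context_class == "intronic_antisense"


def test_distant_ncrna_is_intergenic():
    g = gene("g", 10_000)
    call = classify_context(ncrna("far", [(60_000, 60_500)], "+"), [g])
    assert call.context_class == "intergenic"
    assert call.host_gene_id is None


def test_bidirectional_window_boundary():
    g = gene("g", 10_000, "+")
    at_window = ncrna("nc", [(8_401, 9_001)], "-")  # distance exactly 1000
    assert classify_context(at_window, [g]).context_class == "bidirectional"
    past = ncrna("nc", [(8_400, 9_000)], "-")  # distance 1001
    assert classify_context(past, [g]).context_class == "intergenic"


def test_precedence_antisense_over_intronic_and_matches_retained():
    host = gene("host", 10_000, "+")
    other = gene("other", 10_350, "-")  # exon at 10350-10650 inside host intron 1
    nc = ncrna("nc", [(10_400, 10_800)], "+")  # inside host intron, overlaps other's exon
    call = classify_context(nc, [host, other])
    assert call.context_class == "antisense"
    assert call.host_gene_id == "other"
    assert ("intronic_sense", "host") in call.all_matches


def test_gene_order_never_changes_call():
    rng = np.random.default_rng(0)
    genes, ncrnas = random_loci(rng, 30, 20, 200_000)
    for nc in ncrnas:
        calls = set()
        for _ in range(4):
            perm = [genes[i] for i in rng.permutation(len(genes))]
            c = classify_context(nc, perm)
            calls.add((c.context_class, c.host_gene_id))
        assert len(calls) == 1


def test_classifier_agrees_with_brute_force_on_random_loci():
    rng = np.random.default_rng(12345)
    genes, ncrnas = random_loci(rng, 60, 200, 600_000)
    for nc in ncrnas:
        call = classify_context(nc, genes)
        cls, host = brute_force_context(nc, genes)
        assert call.context_class == cls, nc.gene_id
        assert (call.host_gene_id or None) == host, nc.gene_id


# ---------------------------------------------------------------------------
# positional conservation
# ---------------------------------------------------------------------------

def _shifted(models, shift, rename):
    out = []
    for m in models:
        out.append(TranscriptModel(
            gene_id=rename(m.gene_id), chrom="c2", start=m.start + shift,
            end=m.end + shift, strand=m.strand, biotype=m.biotype,
            exons=[(s + shift, e + shift) for s, e in m.exons],
            cds=[(s + shift, e + shift) for s, e in m.cds],
        ))
    return out


def test_conservation_on_shifted_copy_and_planted_loss():
    genes = [gene("gA1", 10_000, "+"), gene("gA2", 30_000, "-")]
    ncs = [
        ncrna("ncA1", [(11_200, 11_700)], "-"),   # antisense to gA1
        ncrna("ncA2", [(30_500, 30_900)], "-"),   # intronic in gA2
        ncrna("ncA3", [(80_000, 80_400)], "+"),   # intergenic: not evaluable
    ]
    calls = classify_contexts(ncs, genes)
    orth = pd.DataFrame({"gene_a": ["gA1", "gA2"], "gene_b": ["gB1", "gB2"]})
    genes_b = _shifted(genes, 5_000, lambda g: g.replace("gA", "gB"))
    ncs_b = _shifted(ncs[:2], 5_000, lambda g: g.replace("ncA", "ncB"))
    cons = positional_conservation(calls, orth, ncs_b, genes_b).set_index("ncrna_id")
    assert bool(cons.loc["ncA1", "conserved"]) and bool(cons.loc["ncA2", "conserved"])
    assert not bool(cons.loc["ncA3", "conserved"]) and not bool(cons.loc["ncA3", "evaluable"])
    # deleting the counterpart removes conservation but stays evaluable
    cons2 = positional_conservation(calls, orth, ncs_b[1:], genes_b).set_index("ncrna_id")
    assert not bool(cons2.loc["ncA1", "conserved"]) and bool(cons2.loc["ncA1", "evaluable"])


def test_conservation_agrees_with_oracle_join(annotation_bundle):
    """Re-derive conservation independently: classify genome B ncRNAs with
    the brute-force rules and join on the ortholog of the host."""
    b = annotation_bundle
    calls = classify_contexts(b.genome_a.ncrnas(), b.genome_a.genes())
    cons = positional_conservation(
        calls, b.ortholog_map, b.genome_b.ncrnas(), b.genome_b.genes()
    ).set_index("ncrna_id")
    orth = dict(zip(b.ortholog_map.gene_a, b.ortholog_map.gene_b))
    genes_b = b.genome_b.genes()
    b_pairs = set()
    for nc in b.genome_b.ncrnas():
        cls, host = brute_force_context(nc, genes_b)
        if host:
            b_pairs.add((host, cls))
    for row in calls.itertuples():
        expected = bool(
            row.host_gene
            and row.host_gene in orth
            and (orth[row.host_gene], row.context_class) in b_pairs
        )
        assert bool(cons.loc[row.ncrna_id, "conserved"]) == expected


def test_generator_truth_recovered(annotation_bundle):
    b = annotation_bundle
    calls = classify_contexts(b.genome_a.ncrnas(), b.genome_a.genes())
    merged = b.context_truth.merge(calls, on="ncrna_id", suffixes=("_t", ""))
    assert (merged.context_class_t == merged.context_class).all()
    cons = positional_conservation(
        calls, b.ortholog_map, b.genome_b.ncrnas(), b.genome_b.genes()
    )
    merged = b.context_truth.merge(cons, on="ncrna_id", suffixes=("_t", ""))
    anchored = merged[merged.host_gene != ""]
    assert (anchored.conserved_t == anchored.conserved).all()


# ---------------------------------------------------------------------------
# enhancers and structure windows
# ---------------------------------------------------------------------------

def _enh(start, end):
    return pd.DataFrame([{"chrom": "c", "start": start, "end": end,
                          "name": "e1", "score": 500, "strand": "."}])


def test_enhancer_boundary_arithmetic():
    nc = ncrna("nc", [(20_000, 20_250), (20_350, 20_600)], "+")
    inside = associate_enhancer(nc, _enh(20_260, 20_340))  # within first intron
    assert len(inside) == 1 and inside.distance.iloc[0] == 0
    near = associate_enhancer(nc, _enh(14_900, 15_002))  # 4999 bp upstream of TSS
    assert len(near) == 1 and near.distance.iloc[0] == 4999
    far = associate_enhancer(nc, _enh(14_900, 15_000))  # 5001 bp upstream
    assert len(far) == 0
    assert len(associate_enhancer(nc, _enh(0, 0).iloc[0:0])) == 0


def _win(start, end, p):
    return pd.DataFrame([{"chrom": "c", "start": start, "end": end,
                          "name": "w", "score": 0, "strand": ".", "P": p}])


def test_structure_threshold_bracketing_and_exonic_rule():
    nc = ncrna("nc", [(1_000, 1_250), (1_350, 1_600)], "+")
    hi, _ = intersect_structures(nc, _win(1_100, 1_200, 0.95), 0.9)
    assert hi
    mid_hi, _ = intersect_structures(nc, _win(1_100, 1_200, 0.7), 0.9)
    mid_lo, _ = intersect_structures(nc, _win(1_100, 1_200, 0.7), 0.5)
    assert not mid_hi and mid_lo
    # intron-only window never qualifies regardless of confidence; an
    # exhaustive interval check confirms there is no exon overlap
    win = _win(1_260, 1_340, 0.99)
    assert not any(
        ws < ee and es < we
        for ws, we in [(1_260, 1_340)]
        for es, ee in nc.exons
    )
    intronic, _ = intersect_structures(nc, win, 0.9)
    assert not intronic
    with pytest.raises(ValueError, match="P outside"):
        intersect_structures(nc, _win(1_100, 1_200, 1.2), 0.9)
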