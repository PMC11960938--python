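"""Simulator ground truth: determinism, event mechanics, drift model."""

import json

import numpy as np
import pytest

from tandemtrace.families import (
    audit_catalytic_motifs,
    classify_family,
    detect_insertion,
    parse_domain_tsv,
)
from tandemtrace.loci import call_loci, load_annotations, load_genome, segment_locus
from tandemtrace.phylo import unlinked
from tandemtrace.simulate import (
    SimConfig,
    apply_domain_duplication,
    apply_domain_loss,
    apply_insertion_15bp,
    apply_motif_knockout,
    apply_tmd_gain,
    apply_transposition,
    apply_unequal_crossover,
    build_tandem_locus,
    emit,
    jc_expected_p,
    jc_mutate,
    make_ancestral_genome,
    random_dna,
    render,
    replay,
    simulate_support_tree,
    true_loci,
)


def _gene_hits(domains_df, gene_id):
    sub = domains_df[domains_df.gene_id == gene_id]
    from tandemtrace.families import DomainHit

    hits = [
        DomainHit(
            gene_id=r.gene_id, kind=r.kind, start=int(r.start), end=int(r.end),
            i_evalue=float(r.i_evalue),
        )
        for r in sub.itertuples(index=False)
    ]
    return sorted(hits, key=lambda h: h.start)


def test_ancestral_genome_default_layout():
    state = make_ancestral_genome(SimConfig(seed=3))
    genome, genes, domains = render(state)
    assert list(genome) == ["ctg001"]
    assert len(genes) == 1
    call = classify_family(_gene_hits(domains, genes[0].id))
    assert call.architecture == "SP-C-A"
    assert call.family == "CA"


def test_telomere_planting_option():
    state = make_ancestral_genome(SimConfig(seed=3, plant_telomeres=True))
    genome, _, _ = render(state)
    seq = genome["ctg001"]
    assert seq.startswith("CCCTAA" * 5)
    assert seq.endswith("TTAGGG" * 5)


def test_determinism_under_seed():
    g1 = render(build_tandem_locus(9, n_genes=4, igr_drift=0.2))[0]
    g2 = render(build_tandem_locus(9, n_genes=4, igr_drift=0.2))[0]
    g3 = render(build_tandem_locus(10, n_genes=4, igr_drift=0.2))[0]
    assert g1 == g2
    assert g1 != g3


def test_unequal_crossover_mechanics():
    state = make_ancestral_genome(SimConfig(seed=5, igr_length=500))
    anchor = state.genes()[0].gene_id
    new = apply_unequal_crossover(state, anchor)
    genome, genes, _ = render(state)
    assert len(genes) == 2
    loci = call_loci(genes, {g.id for g in genes})
    segs = segment_locus(loci[0], genome)
    labels = [s.label for s in segs]
    assert labels == ["LF", "G1", "IGR1", "G2", "RF"]
    g1, igr, g2 = segs[1], segs[2], segs[3]
    assert g1.sequence == g2.sequence  # copy initially identical
    assert igr.sequence == genome["ctg001"][g2.end : g2.end + 500]  # IGR1 == duplicated spacer
    # repeated application: n genes, n-1 intergenic segments
    apply_unequal_crossover(state, new)
    genome, genes, _ = render(state)
    loci = call_loci(genes, {g.id for g in genes})
    segs = segment_locus(loci[0], genome)
    assert sum(1 for s in segs if s.kind == "GENE") == 3
    assert sum(1 for s in segs if s.kind == "IGR") == 2
    for prev, nxt in zip(segs, segs[1:]):
        assert prev.end == nxt.start  # tiling conserved


def test_locus_recovery_matches_truth_log():
    state = build_tandem_locus(13, n_genes=4)
    genome, genes, _ = render(state)
    lengths = {c: len(s) for c, s in genome.items()}
    called = call_loci(genes, {g.id for g in genes}, contig_lengths=lengths)
    truth = true_loci(state, lengths)
    assert [(l.contig, [g.id for g in l.genes]) for l in called] == [
        (l.contig, [g.id for g in l.genes]) for l in truth
    ]


def test_transposition_creates_unlinked_locus():
    cfg = SimConfig(seed=17, contig_sizes=(60_000,))
    state = make_ancestral_genome(cfg)
    anchor = state.genes()[0].gene_id
    apply_unequal_crossover(state, anchor)
    src_gene = state.genes()[0].gene_id
    new_ids = apply_transposition(state, [src_gene], "ctg002")
    genome, genes, _ = render(state)
    lengths = {c: len(s) for c, s in genome.items()}
    called = call_loci(genes, {g.id for g in genes}, contig_lengths=lengths)
    assert len(called) == 2
    assert unlinked(called[0], called[1])
    moved = next(g for g in genes if g.id == new_ids[0])
    source = next(g for g in genes if g.id == src_gene)
    assert genome["ctg002"][moved.start : moved.end] == genome["ctg001"][source.start : source.end]


def test_jc_zero_time_is_identity_and_rates_calibrate(rng):
    seq = random_dna(rng, 2000)
    assert jc_mutate(seq, 0.0, rng=np.random.default_rng(1)) == seq
    t, L = 0.4, 10_000
    p = jc_expected_p(t)
    seq = random_dna(rng, L)
    mut = jc_mutate(seq, t, rng=np.random.default_rng(2))
    frac = sum(a != b for a, b in zip(seq, mut)) / L
    assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / L)


def test_jc_composition_chapman_kolmogorov(rng):
    """Drifting t then t' matches a single t+t' drift in distribution."""
    L = 20_000
    seq = random_dna(rng, L)
    two_step = jc_mutate(
        jc_mutate(seq, 0.2, rng=np.random.default_rng(3)), 0.3, rng=np.random.default_rng(4)
    )
    frac2 = sum(a != b for a, b in zip(seq, two_step)) / L
    p = jc_expected_p(0.5)
    assert abs(frac2 - p) < 4 * np.sqrt(p * (1 - p) / L)


def test_domain_events_are_recovered_by_the_classifiers():
    state = make_ancestral_genome(SimConfig(seed=23))
    gid = state.genes()[0].gene_id
    _, _, gblock = state.find_gene(gid)
    ref_a_nt = next(p for p in gblock.gene.parts if p.kind == "A").nt

    apply_insertion_15bp(state, gid, aa_offset=150)
    ins_nt = next(p for p in gblock.gene.parts if p.kind == "A").nt
    call = detect_insertion(ins_nt, ref_a_nt)
    assert call.has_insertion and call.insertion_length == 15

    # C loss -> A_only subfamily of CA
    apply_domain_loss(state, gid, kind="C")
    _, _, domains = render(state)
    fc = classify_family(_gene_hits(domains, gid))
    assert fc.family == "CA" and fc.subfamily == "A_only"

    # A duplication + TMD gain -> AnTMD
    apply_domain_duplication(state, gid, kind="A")
    apply_tmd_gain(state, gid, seed=99)
    _, _, domains = render(state)
    fc = classify_family(_gene_hits(domains, gid))
    assert fc.family == "AnTMD" and fc.n_A == 2

    # motif knockout breaks exactly the targeted catalytic region
    part = next(p for p in gblock.gene.parts if p.kind == "A")
    assert audit_catalytic_motifs(part.aa).intact
    apply_motif_knockout(state, gid, region="B")
    part = next(p for p in gblock.gene.parts if p.kind == "A")
    audit = audit_catalytic_motifs(part.aa)
    assert not audit.intact
    assert audit.matched == {"A": True, "B": False, "C": True}


def test_domain_duplication_with_c_yields_ancn():
    state = make_ancestral_genome(SimConfig(seed=29))
    gid = state.genes()[0].gene_id
    apply_domain_duplication(state, gid, kind="A")
    _, _, domains = render(state)
    fc = classify_family(_gene_hits(domains, gid))
    assert fc.family == "AnCn"


def test_emit_roundtrip_and_truth_replay(tmp_path):
    state = build_tandem_locus(41, n_genes=3, igr_drift=0.1)
    newick, leaf_map, _, _ = simulate_support_tree(41)
    paths = emit(state, tmp_path, tree_newick=newick, leaf_map=leaf_map)

    genome, genes, domains = render(state)
    re_genome = load_genome(paths["fasta"])
    assert re_genome == genome
    re_genes = load_annotations(paths["gff3"], genome=re_genome)
    assert [(g.id, g.contig, g.start, g.end, g.strand) for g in re_genes] == [
        (g.id, g.contig, g.start, g.end, g.strand) for g in genes
    ]
    hits = parse_domain_tsv(paths["domains"])
    assert {h.gene_id for h in hits} == {g.id for g in genes}

    from tandemtrace.simulate import load_truth

    cfg, events = load_truth(paths["truth"])
    replayed = replay(cfg, events)
    assert render(replayed)[0] == genome

    lm_lines = paths["leaf_map"].read_text().strip().splitlines()
    assert len(lm_lines) - 1 == len(leaf_map)


def test_simulated_tree_covers_all_leaves_and_plants_one_event():
    newick, leaf_map, loci, truth = simulate_support_tree(77)
    from tandemtrace.phylo import infer_transpositions, parse_newick_with_support

    st = parse_newick_with_support(newick)
    assert set(st.leaf_names) == set(leaf_map)
    events = infer_transpositions(st, leaf_map, loci)
    assert {e.loci for e in events} == set(truth)
    # decoy clade sits at support 80: visible at a looser threshold
    events80 = infer_transpositions(st, leaf_map, loci, min_support=80)
    assert len(events80) == 2


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimConfig(igr_length=0)
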