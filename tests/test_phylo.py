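"""Support-tree parsing, unlinked loci, transposition inference, sampling."""

import numpy as np
import pandas as pd
import pytest

from tandemtrace.loci import Gene, Locus
from tandemtrace.phylo import (
    infer_transpositions,
    parse_newick_with_support,
    read_blast_tab,
    sample_blast_hits,
    unlinked,
)


def _locus(lid, contig, start=0, end=1000):
    g = Gene(id=f"L{lid}g", contig=contig, start=start, end=end, strand="+")
    return Locus(id=lid, contig=contig, genes=[g], span=(start, end))


def test_newick_support_parsing_roundtrip():
    nwk = "((a:0.1,b:0.2)100:0.05,(c:0.1,d:0.3)87:0.02);"
    st = parse_newick_with_support(nwk)
    assert sorted(st.leaf_names) == ["a", "b", "c", "d"]
    supports = sorted(
        nd.support for nd in st.tree.preorder_internal_node_iter() if nd.support is not None
    )
    assert supports == [87, 100]
    lengths = {lf.taxon.label: lf.edge.length for lf in st.tree.leaf_node_iter()}
    assert lengths["b"] == pytest.approx(0.2)


def test_newick_missing_support_tolerated_and_duplicates_rejected():
    st = parse_newick_with_support("((a:1,b:1):1,(c:1,d:1)95:1);")
    supports = [nd.support for nd in st.tree.preorder_internal_node_iter()]
    assert None in supports and 95 in supports
    with pytest.raises(ValueError, match="duplicate"):
        parse_newick_with_support("((a:1,a:1):1,c:1);")


def test_unlinked_boundary():
    assert unlinked(_locus(1, "c1"), _locus(2, "c2"))
    assert not unlinked(_locus(1, "c1", 0, 1000), _locus(2, "c1", 6000, 7000))
    assert unlinked(_locus(1, "c1", 0, 1000), _locus(2, "c1", 11_001, 12_000))
    assert not unlinked(_locus(1, "c1", 0, 1000), _locus(2, "c1", 11_000, 12_000))


def _aly_fixture():
    """Two A2C2-style genes at unlinked loci 25/27 in a 100-support clade;
    locus 1 background leaves."""
    nwk = (
        "(((L25_g_A1:0.1,L27_g_A1:0.1)100:0.1,(L25_g_A2:0.1,L27_g_A2:0.1)100:0.1)100:0.2,"
        "((L1_a_A1:0.1,L1_b_A1:0.1)100:0.1,L1_c_A1:0.2)60:0.3);"
    )
    leaf_map = {
        "L25_g_A1": 25, "L25_g_A2": 25, "L27_g_A1": 27, "L27_g_A2": 27,
        "L1_a_A1": 1, "L1_b_A1": 1, "L1_c_A1": 1,
    }
    loci = {25: _locus(25, "c5"), 27: _locus(27, "c7"), 1: _locus(1, "c1")}
    return nwk, leaf_map, loci


def test_cross_locus_clade_reported_once_and_maximal():
    nwk, leaf_map, loci = _aly_fixture()
    events = infer_transpositions(parse_newick_with_support(nwk), leaf_map, loci)
    assert len(events) == 1
    assert events[0].loci == frozenset({25, 27})
    assert events[0].support == 100
    assert events[0].locus_coverage == {25: 1.0, 27: 1.0}


def test_single_locus_tree_yields_no_events():
    nwk = "((L1_a:1,L1_b:1)100:1,L1_c:1);"
    leaf_map = {"L1_a": 1, "L1_b": 1, "L1_c": 1}
    events = infer_transpositions(
        parse_newick_with_support(nwk), leaf_map, {1: _locus(1, "c1")}
    )
    assert events == []


def test_unmapped_leaf_is_named():
    nwk = "((a:1,b:1)100:1,c:1);"
    with pytest.raises(ValueError, match="'c'"):
        infer_transpositions(
            parse_newick_with_support(nwk), {"a": 1, "b": 1}, {1: _locus(1, "c1")}
        )


def test_linked_loci_do_not_form_events():
    nwk = "((L1_a:1,L2_a:1)100:1,(L3_a:1,L3_b:1)100:1);"
    leaf_map = {"L1_a": 1, "L2_a": 2, "L3_a": 3, "L3_b": 3}
    loci = {
        1: _locus(1, "c1", 0, 1000),
        2: _locus(2, "c1", 3000, 4000),  # only 2 kb away: linked
        3: _locus(3, "c2"),
    }
    events = infer_transpositions(parse_newick_with_support(nwk), leaf_map, loci)
    assert events == []


def test_low_coverage_clades_are_not_reported():
    # only 1 of locus 2's three domains joins the clade
    nwk = "((L1_a:1,L2_a:1)100:1,((L2_b:1,L2_c:1)100:1,L9_x:1)60:1);"
    leaf_map = {"L1_a": 1, "L2_a": 2, "L2_b": 2, "L2_c": 2, "L9_x": 9}
    loci = {1: _locus(1, "c1"), 2: _locus(2, "c2"), 9: _locus(9, "c9")}
    events = infer_transpositions(
        parse_newick_with_support(nwk), leaf_map, loci, min_locus_coverage=0.5
    )
    assert events == []
    events = infer_transpositions(
        parse_newick_with_support(nwk), leaf_map, loci, min_locus_coverage=0.3
    )
    assert [e.loci for e in events] == [frozenset({1, 2})]


def test_events_invariant_to_leaf_order_and_rooting():
    nwk, leaf_map, loci = _aly_fixture()
    swapped = (
        "(((L1_c_A1:0.2,(L1_b_A1:0.1,L1_a_A1:0.1)100:0.1)60:0.3),"
        "((L27_g_A2:0.1,L25_g_A2:0.1)100:0.1,(L27_g_A1:0.1,L25_g_A1:0.1)100:0.1)100:0.2);"
    )
    e1 = infer_transpositions(parse_newick_with_support(nwk), leaf_map, loci)
    e2 = infer_transpositions(parse_newick_with_support(swapped), leaf_map, loci)
    assert {e.loci for e in e1} == {e.loci for e in e2}

    # explicit re-rooting on an edge outside the reported clade
    st = parse_newick_with_support(nwk)
    outgroup = [lf for lf in st.tree.leaf_node_iter() if lf.taxon.label == "L1_c_A1"][0]
    st.tree.is_rooted = True
    st.tree.reroot_at_edge(outgroup.edge, update_bipartitions=True)
    e3 = infer_transpositions(st, leaf_map, loci)
    assert {e.loci for e in e3} == {e.loci for e in e1}


def _hits_frame(rng, n=300, lo=100.0, hi=600.0):
    scores = rng.uniform(lo, hi, size=n)
    return pd.DataFrame(
        {
            "qseqid": "q",
            "sseqid": [f"s{i}" for i in range(n)],
            "pident": 50.0,
            "length": 200,
            "mismatch": 10,
            "gapopen": 1,
            "qstart": 1,
            "qend": 200,
            "sstart": 1,
            "send": 200,
            "evalue": 1e-30,
            "bitscore": scores,
            "stitle": [f"alginate lyase [Species sp{i}]" for i in range(n)],
        }
    )


def test_sample_blast_hits_bins_and_determinism(rng):
    hits = _hits_frame(rng)
    s1 = sample_blast_hits(hits, seed=5)
    s2 = sample_blast_hits(hits, seed=5)
    assert len(s1.bins) == 10
    assert all(len(sub) <= 25 for _, sub in s1.bins)
    assert list(s1.retained["sseqid"]) == list(s2.retained["sseqid"])
    s3 = sample_blast_hits(hits, seed=6)
    assert list(s1.retained["sseqid"]) != list(s3.retained["sseqid"])


def test_sample_blast_small_bin_kept_whole(rng):
    hits = _hits_frame(rng, n=40, lo=100, hi=140)  # all within one 50-wide bin
    extra = _hits_frame(rng, n=7, lo=460, hi=490)
    extra["sseqid"] = [f"e{i}" for i in range(7)]
    extra["stitle"] = [f"alginate lyase [Other sp{i}]" for i in range(7)]
    df = pd.concat([hits, extra], ignore_index=True)
    sampled = sample_blast_hits(df, seed=1)
    last_nonempty = [sub for _, sub in sampled.bins if len(sub)][-1]
    assert len(last_nonempty) == 7  # fewer than 25: all retained


def test_sample_blast_species_dedupe_and_filter(rng):
    hits = _hits_frame(rng, n=30, lo=100, hi=120)
    hits["stitle"] = "alginate lyase [Vibrio casei]"  # all the same species
    sampled = sample_blast_hits(hits, seed=2)
    assert len(sampled.retained) == 1

    hits2 = _hits_frame(rng, n=30, lo=100, hi=120)
    sampled2 = sample_blast_hits(
        hits2, seed=2, label_filter=lambda row: "lyase" in row.stitle
    )
    assert len(sampled2.retained) > 0
    sampled3 = sample_blast_hits(
        hits2, seed=2, label_filter=lambda row: "amylase" in row.stitle
    )
    assert len(sampled3.retained) == 0


def test_read_blast_tab_missing_score_column(tmp_path, rng):
    path = tmp_path / "h.tsv"
    _hits_frame(rng, n=5).to_csv(path, sep="\t", header=False, index=False)
    df = read_blast_tab(path)
    assert "bitscore" in df.columns and len(df) == 5
    bad = tmp_path / "bad.tsv"
    bad.write_text("a\tb\tc\n")
    with pytest.raises(ValueError, match="12 or 13"):
        read_blast_tab(bad)
    with pytest.raises(ValueError, match="bitscore"):
        sample_blast_hits(df.drop(columns=["bitscore"]))
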