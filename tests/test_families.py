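"""Domain ingestion, family rules, motif audit, insertion and TARP ops."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tandemtrace.families import (
    DomainHit,
    architecture_string,
    audit_catalytic_motifs,
    classify_family,
    count_tarp_repeats,
    detect_insertion,
    parse_domain_tsv,
    parse_domtblout,
    summarize_families,
)
from tandemtrace.simulate import random_dna


def _domtblout_line(target, query, i_evalue, ali_from, ali_to):
    # 23 whitespace-separated columns of hmmscan --domtblout
    return (
        f"{target} PF00000.1 300 {query} - 900 1e-50 150.0 0.0 1 1 "
        f"{i_evalue / 10:g} {i_evalue:g} 70.0 0.0 1 280 {ali_from} {ali_to} "
        f"{ali_from} {ali_to} 0.98 description here\n"
    )


@pytest.fixture()
def domtblout_file(tmp_path):
    path = tmp_path / "hits.domtblout"
    lines = [
        "# comment\n",
        _domtblout_line("PL7", "gene1", 1e-20, 400, 700),
        _domtblout_line("PL7", "gene1", 1e-15, 30, 330),
        _domtblout_line("CBM32", "gene1", 5e-3, 750, 890),  # above cutoff
    ]
    path.write_text("".join(lines))
    return path


def test_parse_domtblout_filters_and_orders(domtblout_file):
    hits = parse_domtblout(domtblout_file, i_evalue_max=1e-3)
    assert len(hits) == 2  # the 5e-3 CBM32 hit is dropped
    assert [(h.kind, h.order_index) for h in hits] == [("A", 1), ("A", 2)]
    assert hits[0].start < hits[1].start


def test_parse_domtblout_keeps_weak_hit_at_looser_cutoff(domtblout_file):
    hits = parse_domtblout(domtblout_file, i_evalue_max=1e-2)
    assert [(h.kind, h.order_index) for h in hits] == [("A", 1), ("A", 2), ("C", 1)]


def test_overlap_resolution_matches_hand_worked_fixture(tmp_path):
    """Five overlapping hits reduce to the hand-resolved three."""
    tsv = tmp_path / "d.tsv"
    tsv.write_text(
        "gene_id\tkind\tstart\tend\ti_evalue\n"
        "g\tPL7\t0\t100\t1e-50\n"  # keep -> A1
        "g\tPL7\t40\t140\t1e-20\n"  # 60% overlap with kept A -> drop
        "g\tCBM32\t90\t200\t1e-30\n"  # 10/110 overlap -> keep -> C1
        "g\tPL7\t150\t260\t1e-10\n"  # 50/110 overlap with C -> keep -> A2
        "g\tCBM32\t150\t180\t1e-05\n"  # fully inside kept A2 -> drop\n"
    )
    hits = parse_domain_tsv(tsv)
    assert [(h.kind, h.start, h.end, h.order_index) for h in hits] == [
        ("A", 0, 100, 1), ("C", 90, 200, 1), ("A", 150, 260, 2),
    ]


def test_malformed_tsv_line_is_located(tmp_path):
    tsv = tmp_path / "d.tsv"
    tsv.write_text(
        "gene_id\tkind\tstart\tend\ti_evalue\n"
        "g\tPL7\t100\t50\t1e-50\n"
    )
    with pytest.raises(ValueError, match="line 2"):
        parse_domain_tsv(tsv)


def _hits(layout, gene="g"):
    out = []
    pos = 0
    for kind, ln in layout:
        out.append(DomainHit(gene_id=gene, kind=kind, start=pos, end=pos + ln, i_evalue=1e-30))
        pos += ln + 5
    return out


@pytest.mark.parametrize(
    "layout, family, sub, n_a, n_c",
    [
        ([("SP", 20), ("C", 150), ("A", 280)], "CA", "none", 1, 1),
        ([("SP", 20)] + [("A", 280), ("C", 150)] * 5, "AnCn", "none", 5, 5),
        ([("SP", 20), ("A", 280), ("A", 280), ("A", 280), ("TMD", 25)], "AnTMD", "none", 3, 0),
        ([("SP", 20), ("C", 150), ("C", 150), ("A", 280)], "CA", "CCA", 1, 2),
        ([("SP", 20), ("A", 280)], "CA", "A_only", 1, 0),
    ],
)
def test_published_architectures_classify_correctly(layout, family, sub, n_a, n_c):
    call = classify_family(_hits(layout))
    assert call.family == family
    assert call.subfamily == sub
    assert (call.n_A, call.n_C) == (n_a, n_c)


def test_no_a_domain_is_not_a_family_member():
    assert classify_family(_hits([("SP", 20), ("C", 150)])) is None
    assert classify_family([]) is None


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    kinds=st.lists(
        st.sampled_from(["A", "C", "TMD", "SP"]), min_size=1, max_size=8
    ).filter(lambda ks: "A" in ks)
)
def test_family_rules_total_and_exclusive(kinds):
    """Any architecture with >=1 A maps to exactly one family, consistently."""
    hits = _hits([(k, 50) for k in kinds])
    call = classify_family(hits)
    assert call.family in {"CA", "AnTMD", "AnCn"}
    n_c = kinds.count("C")
    last_a = max(i for i, k in enumerate(kinds) if k == "A")
    cterm_tmd = any(k == "TMD" for k in kinds[last_a:])
    if call.family == "AnTMD":
        assert cterm_tmd and n_c == 0
    elif call.family == "AnCn":
        assert kinds.count("A") >= 2 and n_c >= 1
    else:
        assert not (cterm_tmd and n_c == 0)
        assert not (kinds.count("A") >= 2 and n_c >= 1)
    # architecture string round-trips the ordered kinds
    assert call.architecture.split("-") == kinds


def test_architecture_string_orders_by_position():
    hits = _hits([("C", 150), ("A", 280)])
    hits = list(reversed(hits))
    assert architecture_string(hits) == "C-A"


def test_catalytic_motif_audit():
    seq = "G" * 30 + "RAELR" + "G" * 30 + "QIH" + "G" * 30 + "YFKAGAYAQ" + "G" * 10
    audit = audit_catalytic_motifs(seq)
    assert audit.intact and audit.matched == {"A": True, "B": True, "C": True}

    broken = seq.replace("QIH", "NIH")
    audit = audit_catalytic_motifs(broken)
    assert not audit.intact
    assert audit.matched["B"] is False and audit.matched["A"] and audit.matched["C"]

    # bracketed alternatives: RxE(L/V)R and Q(I/V)H
    assert audit_catalytic_motifs("RYEVR" + "QVH" + "YFKWGWYWQ").intact

    with pytest.raises(ValueError, match="non-amino-acid"):
        audit_catalytic_motifs("RAELR123")


def test_detect_insertion_planted_and_negative(rng):
    ref = random_dna(rng, 600)
    ins = "GGTACCGGTACCGGT"  # 15 bp, in frame
    query = ref[:300] + ins + ref[300:]
    call = detect_insertion(query, ref)
    assert call.has_insertion
    assert call.insertion_length == 15
    assert abs(call.position - 300) <= 6  # placement within alignment wobble

    self_call = detect_insertion(ref, ref)
    assert not self_call.has_insertion and self_call.insertion_length == 0

    frameshift = ref[:300] + "GGTACCG" + ref[300:]  # 7 bp: below 15, off-frame
    assert not detect_insertion(frameshift, ref).has_insertion


def test_tarp_counting():
    assert count_tarp_repeats("TARPTPRPTSRPTVRP") == 4
    assert count_tarp_repeats("") == 0
    assert count_tarp_repeats("TTRPP") == 0  # T-T is outside the consensus
    nine = "".join(["TARP", "TPRP", "TSRP"] * 3)
    assert count_tarp_repeats("GGS" + nine + "SSG") == 9


def test_summarize_families_counts():
    calls = [
        classify_family(_hits([("SP", 20), ("C", 150), ("A", 280)], gene=f"g{i}"))
        for i in range(3)
    ] + [classify_family(_hits([("A", 280), ("A", 280), ("TMD", 25)], gene="g9"))]
    s = summarize_families(calls)
    assert s["n_family_genes"] == 4
    assert s["n_with_C"] == 3
    assert s["n_CA"] == 3 and s["n_AnTMD"] == 1 and s["n_AnCn"] == 0
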