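"""Self-contained validation experiments over the simulator.

Each function builds its own synthetic inputs, runs the relevant pipeline
stages, and reports summary statistics.  They are used by the analysis
drivers, the test suite and the acceptance script, so problem sizes are
kept small enough for a single CPU.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from .align import ScoringParams, align_overlap
from .families import DomainHit, classify_family
from .homology import call_recent_duplications, pairwise_matrix
from .loci import call_loci, find_telomeric_ends, infer_min_chromosomes, segment_locus
from .phylo import infer_transpositions, parse_newick_with_support
from .simulate import (
    build_tandem_locus,
    jc_expected_p,
    jc_mutate,
    random_dna,
    render,
    simulate_support_tree,
)

# ---------------------------------------------------------------------------
# exhaustive alignment oracle


@lru_cache(maxsize=None)
def _all_paths(n: int, m: int) -> tuple[str, ...]:
    """Every monotone move string (D=diagonal, U=gap in b, L=gap in a)."""
    if n == 0 and m == 0:
        return ("",)
    out = []
    if n > 0 and m > 0:
        out.extend(p + "D" for p in _all_paths(n - 1, m - 1))
    if n > 0:
        out.extend(p + "U" for p in _all_paths(n - 1, m))
    if m > 0:
        out.extend(p + "L" for p in _all_paths(n, m - 1))
    return tuple(out)


def _score_path(path: str, a: str, b: str, params: ScoringParams) -> int:
    """Score one explicit alignment: substitution scores for paired
    columns, gap runs at open + extend * length, terminal runs free when
    end gaps are free."""
    groups = [(ch, len(list(g))) for ch, g in itertools.groupby(path)]
    score = 0
    i = j = 0
    for gi, (ch, length) in enumerate(groups):
        if ch == "D":
            for _ in range(length):
                score += params.substitution_matrix[(a[i], b[j])]
                i += 1
                j += 1
        else:
            terminal = gi == 0 or gi == len(groups) - 1
            if not (params.free_end_gaps and terminal):
                score -= params.gap_open + params.gap_extend * length
            if ch == "U":
                i += length
            else:
                j += length
    return score


def oracle_align_score(a: str, b: str, params: ScoringParams) -> int:
    """Maximum alignment score by exhaustive enumeration of alignments."""
    return max(_score_path(p, a, b, params) for p in _all_paths(len(a), len(b)))


def aligner_oracle_check(n_pairs: int = 200, max_len: int = 7, seed: int = 0) -> dict:
    """Compare the DP engine to the exhaustive oracle on random pairs,
    in both end-gap modes.  Returns the agreement fraction (expect 1.0)."""
    rng = np.random.default_rng(seed)
    agree = total = 0
    for free in (True, False):
        params = ScoringParams(free_end_gaps=free)
        for _ in range(n_pairs // 2):
            a = random_dna(rng, int(rng.integers(1, max_len + 1)))
            b = random_dna(rng, int(rng.integers(1, max_len + 1)))
            total += 1
            if align_overlap(a, b, params).score == oracle_align_score(a, b, params):
                agree += 1
    return {"agreement": agree / total, "n": total}


# ---------------------------------------------------------------------------
# recency benchmark


def recency_benchmark(
    n_recent: int = 25,
    n_ancient: int = 25,
    drift_recent: float = 0.02,
    drift_ancient: float = 0.8,
    igr_length: int = 800,
    alpha: float = 0.05,
    floor: float = 50.0,
    n_shuffles: int = 100,
    seed: int = 0,
) -> dict:
    """Sensitivity/specificity of the recency caller on simulated loci.

    Each locus carries three tandem genes, hence one consecutive
    intergenic pair whose two members drifted independently for the stated
    time since duplication.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_recent + n_ancient)
    flags = []
    for k, child in enumerate(children):
        drift = drift_recent if k < n_recent else drift_ancient
        locus_seed = int(child.generate_state(1)[0] % (2**31))
        state = build_tandem_locus(locus_seed, n_genes=3, igr_drift=drift, igr_length=igr_length)
        genome, genes, _ = render(state)
        loci = call_loci(
            genes,
            {g.id for g in genes},
            contig_lengths={c: len(s) for c, s in genome.items()},
        )
        segs = segment_locus(loci[0], genome)
        mat = pairwise_matrix(segs, subset="intergenic_only")
        calls = call_recent_duplications(
            mat, segs, n_shuffles=n_shuffles, alpha=alpha, floor=floor, seed=locus_seed
        )
        flags.append(any(c.is_recent for c in calls))
    sens = float(np.mean(flags[:n_recent]))
    spec = float(np.mean([not f for f in flags[n_recent:]]))
    return {"sensitivity": sens, "specificity": spec, "n": n_recent + n_ancient}


# ---------------------------------------------------------------------------
# transposition benchmark


def transposition_benchmark(n_seeds: int = 20, min_support: int = 100, seed: int = 0) -> dict:
    """Planted-clade recovery over seeded simulated trees.

    Counts exact recovery of the planted cross-locus clades; decoys sit at
    support 80 and must never be reported at the default threshold.
    """
    ss = np.random.SeedSequence(seed)
    tp = fp = fn = 0
    for child in ss.spawn(n_seeds):
        tree_seed = int(child.generate_state(1)[0] % (2**31))
        newick, leaf_map, loci, truth = simulate_support_tree(tree_seed)
        stree = parse_newick_with_support(newick)
        events = infer_transpositions(stree, leaf_map, loci, min_support=min_support)
        found = {e.loci for e in events}
        expected = set(truth)
        tp += len(found & expected)
        fp += len(found - expected)
        fn += len(expected - found)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {"precision": precision, "recall": recall, "n": n_seeds}


# ---------------------------------------------------------------------------
# neutral-drift calibration


def jc_calibration(
    t: float = 0.3, mu: float = 1.0, L: int = 10_000, n_seeds: int = 20, seed: int = 0
) -> dict:
    """Observed substituted fraction vs the Jukes-Cantor expectation.

    Returns per-replicate z-scores against the binomial standard deviation
    at p = 3/4 (1 - exp(-4 mu t / 3))."""
    p = jc_expected_p(t, mu)
    sd = float(np.sqrt(p * (1 - p) / L))
    ss = np.random.SeedSequence(seed)
    zs = []
    for child in ss.spawn(n_seeds):
        rng = np.random.default_rng(child)
        seq = random_dna(rng, L)
        mut = jc_mutate(seq, t, mu, rng)
        frac = sum(1 for x, y in zip(seq, mut) if x != y) / L
        zs.append((frac - p) / sd)
    return {"expected_p": p, "z_scores": zs, "max_abs_z": float(np.max(np.abs(zs))), "n": n_seeds}


# ---------------------------------------------------------------------------
# worked examples


def telomere_worked_example(seed: int = 0) -> dict:
    """The published census: one contig telomeric at both ends plus 22
    contigs telomeric at one end implies at least 12 chromosomes."""
    rng = np.random.default_rng(seed)
    genome = {}
    genome["chr_both"] = "CCCTAA" * 5 + random_dna(rng, 4000) + "TTAGGG" * 5
    for k in range(22):
        inner = random_dna(rng, 3000)
        if k % 2 == 0:
            genome[f"chr_one_{k:02d}"] = inner + "TTAGGG" * 5
        else:
            genome[f"chr_one_{k:02d}"] = "CCCTAA" * 5 + inner
    for k in range(5):
        genome[f"chr_none_{k}"] = random_dna(rng, 2500)
    report = find_telomeric_ends(genome)
    return {
        "report": report,
        "total_ends": report.total_telomeric_ends,
        "min_chromosomes": infer_min_chromosomes(report),
    }


def worked_family_examples() -> dict:
    """The three published architecture exemplars, classified from their
    stated domain layouts."""

    def hits(gene, layout):
        out = []
        pos = 0
        for kind, ln in layout:
            out.append(DomainHit(gene_id=gene, kind=kind, start=pos, end=pos + ln, i_evalue=1e-30))
            pos += ln + 10
        for h in out:  # order indices per kind
            h.order_index = sum(
                1 for o in out if o.kind == h.kind and o.start <= h.start
            )
        return out

    ca = classify_family(hits("ALY77", [("SP", 20), ("C", 150), ("A", 280)]))
    ancn = classify_family(
        hits("ALY48", [("SP", 20)] + [("A", 280), ("C", 150)] * 5)
    )
    antmd = classify_family(
        hits("ALY49", [("SP", 20), ("A", 280), ("A", 280), ("A", 280), ("TMD", 25)])
    )
    return {"ALY77": ca, "ALY48_A5C5": ancn, "ALY49_A3": antmd}
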