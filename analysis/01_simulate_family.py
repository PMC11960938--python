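#!/usr/bin/env python
"""Simulate a gene-family genome with known evolutionary history.

Builds a genome in which an ancestral C+A gene expands by unequal crossing
over at two loci with different drift ages, disperses by transposition to
a second contig, and accumulates domain events (C loss, A duplication, TMD
gain, a 15-bp insertion, a catalytic knockout).  Telomeres are planted at
the first contig's ends.  Emits FASTA/GFF3/domain-TSV/Newick plus the
replayable truth log under results/simulated_genome/.
"""

import json
from pathlib import Path

from tandemtrace.simulate import (
    SimConfig,
    apply_domain_duplication,
    apply_domain_loss,
    apply_igr_drift,
    apply_insertion_15bp,
    apply_motif_knockout,
    apply_tmd_gain,
    apply_transposition,
    apply_unequal_crossover,
    emit,
    make_ancestral_genome,
    render,
    simulate_support_tree,
)

SEED = 2024
OUT = Path(__file__).resolve().parents[1] / "results" / "simulated_genome"


def main() -> None:
    cfg = SimConfig(seed=SEED, contig_sizes=(40_000,), plant_telomeres=True)
    state = make_ancestral_genome(cfg)
    anchor = state.genes()[0].gene_id

    # old expansion (drifted junctions), then one fresh duplication
    g2 = apply_unequal_crossover(state, anchor)
    apply_unequal_crossover(state, g2)
    apply_igr_drift(state, "ctg001", 0.7, seed=SEED + 1)
    apply_unequal_crossover(state, anchor)

    # dispersal to an unlinked contig
    moved = apply_transposition(state, [anchor], "ctg002")

    # domain evolution on the transposed copy: towards AnTMD
    apply_domain_duplication(state, moved[0], kind="A")
    apply_domain_loss(state, moved[0], kind="C")
    apply_tmd_gain(state, moved[0], seed=SEED + 2)
    apply_motif_knockout(state, moved[0], region="B")

    # a 15-bp insertion in the anchor's A-domain (AnCn-style novelty)
    apply_insertion_15bp(state, g2, aa_offset=150)

    newick, leaf_map, _, planted = simulate_support_tree(SEED)
    paths = emit(state, OUT, tree_newick=newick, leaf_map=leaf_map)

    genome, genes, _ = render(state)
    print(f"simulated {len(genome)} contigs, {len(genes)} genes")
    print(f"planted transposition truth (support tree): {[sorted(s) for s in planted]}")
    print(f"event log: {len(state.log)} entries")
    for name, p in paths.items():
        print(f"  {name}: {p}")
    (OUT / "planted_tree_truth.json").write_text(
        json.dumps({"planted_loci_sets": [sorted(s) for s in planted]}, indent=1)
    )


if __name__ == "__main__":
    main()
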