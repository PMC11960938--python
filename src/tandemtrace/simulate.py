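"""Ground-truth simulator for tandem gene-family evolution.

Builds a genome carrying an ancestral three-part gene (C-domain,
low-complexity TARP linker, A-domain, optionally signal peptide) and
evolves it by the mechanisms the downstream analyses are meant to detect:

* unequal crossing over — a gene is duplicated together with its
  downstream intergenic spacer, preserving head-to-tail orientation;
* transposition — gene copies move to unlinked positions;
* domain events — C-domain loss/duplication, A-domain duplication,
  C-terminal TMD gain, an in-frame 15-bp coding insertion, and catalytic
  motif knockouts;
* neutral drift — Jukes-Cantor substitutions applied to intergenic DNA
  only (coding sequence is held fixed, standing in for purifying
  selection).

Every operation appends a replayable record to the event log, and all
randomness flows from explicit seeds, so emitted FASTA/GFF3/TSV/Newick
files are deterministic functions of (config, seed).
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .families import CATALYTIC_MOTIFS
from .loci import Gene, Locus

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# one fixed sense codon per amino acid (back-translation)
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

#: concrete catalytic motif instances planted in every simulated A-domain,
#: at fixed amino-acid offsets within the domain
PLANTED_MOTIFS = {"A": (40, "RAELR"), "B": (110, "QIH"), "C": (200, "YFKAGAYAQ")}

TARP_UNITS = ["TARP", "TPRP", "TSRP", "TVRP"]


def backtranslate(aa: str) -> str:
    return "".join(CODON[c] for c in aa)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def jc_mutate(seq: str, t: float, mu: float = 1.0, rng: np.random.Generator | None = None) -> str:
    """Apply Jukes-Cantor drift for time ``t`` (expected mu*t subs/site).

    Per-site substitution probability p = 3/4 (1 - exp(-4 mu t / 3));
    substituted sites draw uniformly among the three alternatives.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if t <= 0:
        return seq
    p = 0.75 * (1.0 - np.exp(-4.0 * mu * t / 3.0))
    chars = list(seq)
    hit = np.nonzero(rng.random(len(chars)) < p)[0]
    picks = rng.integers(0, 3, size=len(hit))
    alternatives = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for i, k in zip(hit, picks):
        chars[i] = alternatives.get(chars[i], "ACG")[k]
    return "".join(chars)


def jc_expected_p(t: float, mu: float = 1.0) -> float:
    return 0.75 * (1.0 - float(np.exp(-4.0 * mu * t / 3.0)))


@dataclass
class Part:
    kind: str  # SP | C | LINKER | A | TMD
    aa: str
    nt: str = ""
    motif_spans: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.nt:
            self.nt = backtranslate(self.aa)


@dataclass
class GeneModel:
    gene_id: str
    parts: list[Part]
    strand: str = "+"

    @property
    def protein(self) -> str:
        return "".join(p.aa for p in self.parts)

    @property
    def nt(self) -> str:
        return "".join(p.nt for p in self.parts)

    def part_aa_offset(self, index: int) -> int:
        return sum(len(p.aa) for p in self.parts[:index])

    def domain_rows(self) -> list[dict]:
        rows = []
        off = 0
        for p in self.parts:
            if p.kind in ("SP", "C", "A", "TMD"):
                rows.append(
                    {
                        "gene_id": self.gene_id,
                        "kind": p.kind,
                        "start": off,
                        "end": off + len(p.aa),
                        "i_evalue": 1e-30,
                    }
                )
            off += len(p.aa)
        return rows


@dataclass
class Block:
    kind: str  # seq | gene
    tag: str  # flank | igr | spacer | telomere | gene
    seq: str | None = None
    gene: GeneModel | None = None
    block_id: int = -1


@dataclass
class SimConfig:
    seed: int = 0
    domain_spec: tuple = (("SP", 20), ("C", 150), ("LINKER", 60), ("A", 280))
    tarp_units: int = 9
    igr_length: int = 800
    flank_length: int = 2500
    mu: float = 1.0
    contig_sizes: tuple = ()
    plant_telomeres: bool = False
    telomere_copies: int = 5

    def __post_init__(self) -> None:
        if self.igr_length <= 0 or self.flank_length <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class GenomeState:
    config: SimConfig
    contigs: dict[str, list[Block]] = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)
    _next_gene: int = 1
    _next_block: int = 1

    def new_gene_id(self) -> str:
        gid = f"g{self._next_gene:03d}"
        self._next_gene += 1
        return gid

    def new_block_id(self) -> int:
        b = self._next_block
        self._next_block += 1
        return b

    def genes(self) -> list[GeneModel]:
        return [b.gene for blocks in self.contigs.values() for b in blocks if b.kind == "gene"]

    def find_gene(self, gene_id: str) -> tuple[str, int, Block]:
        for contig, blocks in self.contigs.items():
            for i, b in enumerate(blocks):
                if b.kind == "gene" and b.gene.gene_id == gene_id:
                    return contig, i, b
        raise KeyError(f"gene {gene_id} not found")


def _scrub_motifs(aa: str, keep_spans: list[tuple[int, int]]) -> str:
    """Break accidental catalytic-motif matches outside the planted spans."""
    chars = list(aa)
    changed = True
    while changed:
        changed = False
        s = "".join(chars)
        for pattern in CATALYTIC_MOTIFS.values():
            for m in re.finditer(pattern, s):
                if not any(m.start() >= lo and m.end() <= hi for lo, hi in keep_spans):
                    chars[m.start()] = "G"
                    changed = True
            if changed:
                break
    return "".join(chars)


def _make_part(kind: str, length: int, tarp_units: int, rng: np.random.Generator) -> Part:
    if kind == "LINKER":
        units = "".join(TARP_UNITS[i % len(TARP_UNITS)] for i in range(tarp_units))
        filler = "".join(rng.choice(list("GS"), size=max(0, length - len(units))))
        return Part(kind=kind, aa=(units + filler)[: max(length, len(units))])
    if kind == "A":
        aa = list("".join(rng.choice(list(AA20), size=length)))
        spans = {}
        for region, (off, motif) in PLANTED_MOTIFS.items():
            aa[off : off + len(motif)] = motif
            spans[region] = (off, off + len(motif))
        scrubbed = _scrub_motifs("".join(aa), list(spans.values()))
        return Part(kind=kind, aa=scrubbed, motif_spans=spans)
    if kind == "TMD":
        return Part(kind=kind, aa="".join(rng.choice(list("LIVFA"), size=length)))
    return Part(kind=kind, aa="".join(rng.choice(list(AA20), size=length)))


def _make_gene(state: GenomeState, rng: np.random.Generator) -> GeneModel:
    cfg = state.config
    parts = [_make_part(kind, length, cfg.tarp_units, rng) for kind, length in cfg.domain_spec]
    return GeneModel(gene_id=state.new_gene_id(), parts=parts)


def make_ancestral_genome(config: SimConfig) -> GenomeState:
    """One contig bearing a single ancestral gene between two flanks."""
    state = GenomeState(config=config)
    rng = np.random.default_rng(config.seed)
    gene = _make_gene(state, rng)
    blocks = [
        Block("seq", "flank", seq=random_dna(rng, config.flank_length), block_id=state.new_block_id()),
        Block("gene", "gene", gene=gene, block_id=state.new_block_id()),
        Block("seq", "flank", seq=random_dna(rng, config.flank_length), block_id=state.new_block_id()),
    ]
    if config.plant_telomeres:
        n = config.telomere_copies
        blocks.insert(0, Block("seq", "telomere", seq="CCCTAA" * n, block_id=state.new_block_id()))
        blocks.append(Block("seq", "telomere", seq="TTAGGG" * n, block_id=state.new_block_id()))
    state.contigs["ctg001"] = blocks
    for k, size in enumerate(config.contig_sizes, start=2):
        state.contigs[f"ctg{k:03d}"] = [
            Block("seq", "spacer", seq=random_dna(rng, size), block_id=state.new_block_id())
        ]
    state.log.append({"event": "ancestral_genome", "seed": config.seed})
    return state


def apply_unequal_crossover(state: GenomeState, gene_id: str) -> str:
    """Duplicate a gene together with its downstream intergenic region.

    The copy is inserted head-to-tail immediately after the duplicated
    unit and is initially identical to the template (drift time 0).
    """
    contig, i, gblock = state.find_gene(gene_id)
    blocks = state.contigs[contig]
    igr_len = state.config.igr_length
    nxt = blocks[i + 1]
    if nxt.kind != "seq":
        raise ValueError(f"gene {gene_id} has no downstream sequence to duplicate")
    if nxt.tag != "igr":
        if len(nxt.seq) < igr_len:
            raise ValueError("downstream sequence shorter than the intergenic length")
        igr_block = Block("seq", "igr", seq=nxt.seq[:igr_len], block_id=state.new_block_id())
        rest = Block("seq", nxt.tag, seq=nxt.seq[igr_len:], block_id=nxt.block_id)
        blocks[i + 1 : i + 2] = [igr_block, rest]
    else:
        igr_block = nxt

    new_gene = copy.deepcopy(gblock.gene)
    new_gene.gene_id = state.new_gene_id()
    gcopy = Block("gene", "gene", gene=new_gene, block_id=state.new_block_id())
    icopy = Block("seq", "igr", seq=igr_block.seq, block_id=state.new_block_id())
    j = blocks.index(igr_block)
    blocks[j + 1 : j + 1] = [gcopy, icopy]
    state.log.append(
        {
            "event": "tandem_duplication",
            "contig": contig,
            "template_gene": gene_id,
            "new_gene": new_gene.gene_id,
            "junction_block": igr_block.block_id,
        }
    )
    return new_gene.gene_id


def apply_igr_drift(state: GenomeState, contig: str, t: float, seed: int, tags: tuple = ("igr",)) -> None:
    """Mutate each designated non-coding block independently under JC."""
    ss = np.random.SeedSequence(seed)
    targets = [b for b in state.contigs[contig] if b.kind == "seq" and b.tag in tags]
    for block, child in zip(targets, ss.spawn(max(1, len(targets)))):
        block.seq = jc_mutate(block.seq, t, state.config.mu, np.random.default_rng(child))
    state.log.append(
        {"event": "igr_drift", "contig": contig, "t": t, "seed": seed, "tags": list(tags)}
    )


def apply_transposition(state: GenomeState, gene_ids: list[str], dest_contig: str) -> list[str]:
    """Copy a contiguous run of genes (with internal spacers) to another
    contig, splitting the destination sequence at its midpoint."""
    src_contig, i0, _ = state.find_gene(gene_ids[0])
    _, i1, _ = state.find_gene(gene_ids[-1])
    if i1 < i0:
        i0, i1 = i1, i0
    run = state.contigs[src_contig][i0 : i1 + 1]
    clones: list[Block] = []
    new_ids: list[str] = []
    for b in run:
        if b.kind == "gene":
            ng = copy.deepcopy(b.gene)
            ng.gene_id = state.new_gene_id()
            new_ids.append(ng.gene_id)
            clones.append(Block("gene", "gene", gene=ng, block_id=state.new_block_id()))
        else:
            clones.append(Block("seq", b.tag, seq=b.seq, block_id=state.new_block_id()))

    dest = state.contigs[dest_contig]
    # split the largest sequence block of the destination at its midpoint
    k, big = max(
        ((k, b) for k, b in enumerate(dest) if b.kind == "seq"),
        key=lambda kb: len(kb[1].seq or ""),
    )
    mid = len(big.seq) // 2
    left = Block("seq", big.tag, seq=big.seq[:mid], block_id=big.block_id)
    right = Block("seq", big.tag, seq=big.seq[mid:], block_id=state.new_block_id())
    dest[k : k + 1] = [left, *clones, right]
    state.log.append(
        {
            "event": "transposition",
            "source_contig": src_contig,
            "source_genes": list(gene_ids),
            "dest_contig": dest_contig,
            "new_genes": new_ids,
        }
    )
    return new_ids


def _refresh_nt(part: Part) -> None:
    part.nt = backtranslate(part.aa)


def _find_part(gene: GeneModel, kind: str, index: int) -> int:
    seen = 0
    for i, p in enumerate(gene.parts):
        if p.kind == kind:
            seen += 1
            if seen == index:
                return i
    raise ValueError(f"gene {gene.gene_id}: no {kind} part #{index}")


def apply_domain_loss(state: GenomeState, gene_id: str, kind: str = "C", index: int = 1) -> None:
    _, _, gblock = state.find_gene(gene_id)
    i = _find_part(gblock.gene, kind, index)
    del gblock.gene.parts[i]
    state.log.append({"event": "domain_loss", "gene": gene_id, "kind": kind, "index": index})


def apply_domain_duplication(state: GenomeState, gene_id: str, kind: str = "A", index: int = 1) -> None:
    _, _, gblock = state.find_gene(gene_id)
    i = _find_part(gblock.gene, kind, index)
    gblock.gene.parts.insert(i + 1, copy.deepcopy(gblock.gene.parts[i]))
    state.log.append({"event": "domain_duplication", "gene": gene_id, "kind": kind, "index": index})


def apply_tmd_gain(state: GenomeState, gene_id: str, seed: int = 0, length: int = 25) -> None:
    _, _, gblock = state.find_gene(gene_id)
    rng = np.random.default_rng(seed)
    gblock.gene.parts.append(_make_part("TMD", length, 0, rng))
    state.log.append({"event": "tmd_gain", "gene": gene_id, "seed": seed, "length": length})


def apply_insertion_15bp(
    state: GenomeState, gene_id: str, a_index: int = 1, aa_offset: int = 150, ins_aa: str = "GTGTG"
) -> None:
    """Insert an in-frame 5-codon (15 bp) segment into an A-domain CDS."""
    _, _, gblock = state.find_gene(gene_id)
    i = _find_part(gblock.gene, "A", a_index)
    part = gblock.gene.parts[i]
    part.aa = part.aa[:aa_offset] + ins_aa + part.aa[aa_offset:]
    _refresh_nt(part)
    part.motif_spans = {
        r: ((lo + len(ins_aa), hi + len(ins_aa)) if lo >= aa_offset else (lo, hi))
        for r, (lo, hi) in part.motif_spans.items()
    }
    state.log.append(
        {"event": "insertion_15bp", "gene": gene_id, "a_index": a_index, "aa_offset": aa_offset, "ins_aa": ins_aa}
    )


def apply_motif_knockout(state: GenomeState, gene_id: str, a_index: int = 1, region: str = "B") -> None:
    _, _, gblock = state.find_gene(gene_id)
    i = _find_part(gblock.gene, "A", a_index)
    part = gblock.gene.parts[i]
    lo, _ = part.motif_spans[region]
    part.aa = part.aa[:lo] + "G" + part.aa[lo + 1 :]
    _refresh_nt(part)
    state.log.append({"event": "motif_knockout", "gene": gene_id, "a_index": a_index, "region": region})


_EVENT_DISPATCH = {
    "tandem_duplication": lambda st, e: apply_unequal_crossover(st, e["template_gene"]),
    "igr_drift": lambda st, e: apply_igr_drift(st, e["contig"], e["t"], e["seed"], tuple(e["tags"])),
    "transposition": lambda st, e: apply_transposition(st, e["source_genes"], e["dest_contig"]),
    "domain_loss": lambda st, e: apply_domain_loss(st, e["gene"], e["kind"], e["index"]),
    "domain_duplication": lambda st, e: apply_domain_duplication(st, e["gene"], e["kind"], e["index"]),
    "tmd_gain": lambda st, e: apply_tmd_gain(st, e["gene"], e["seed"], e["length"]),
    "insertion_15bp": lambda st, e: apply_insertion_15bp(
        st, e["gene"], e["a_index"], e["aa_offset"], e["ins_aa"]
    ),
    "motif_knockout": lambda st, e: apply_motif_knockout(st, e["gene"], e["a_index"], e["region"]),
}


def replay(config: SimConfig, log: list[dict]) -> GenomeState:
    """Re-apply an event log to a fresh ancestral genome.

    Because every operation derives its randomness from recorded seeds and
    identifier assignment is deterministic, replay reproduces the emitted
    genome byte for byte.
    """
    state = make_ancestral_genome(config)
    for entry in log:
        if entry["event"] == "ancestral_genome":
            continue
        _EVENT_DISPATCH[entry["event"]](state, entry)
    return state


def load_truth(path: str | Path) -> tuple[SimConfig, list[dict]]:
    """Read an emitted truth file back into (config, event log)."""
    data = json.loads(Path(path).read_text())
    cfg_dict = dict(data["config"])
    cfg_dict["domain_spec"] = tuple(tuple(x) for x in cfg_dict["domain_spec"])
    cfg_dict["contig_sizes"] = tuple(cfg_dict["contig_sizes"])
    return SimConfig(**cfg_dict), data["events"]


def render(state: GenomeState) -> tuple[dict[str, str], list[Gene], pd.DataFrame]:
    """Materialise (genome map, gene records, domain-hit table)."""
    genome: dict[str, str] = {}
    genes: list[Gene] = []
    rows: list[dict] = []
    for contig, blocks in state.contigs.items():
        pos = 0
        parts: list[str] = []
        for b in blocks:
            seq = b.gene.nt if b.kind == "gene" else b.seq
            if b.kind == "gene":
                genes.append(
                    Gene(
                        id=b.gene.gene_id,
                        contig=contig,
                        start=pos,
                        end=pos + len(seq),
                        strand=b.gene.strand,
                    )
                )
                rows.extend(b.gene.domain_rows())
            parts.append(seq)
            pos += len(seq)
        genome[contig] = "".join(parts)
    domains = pd.DataFrame(rows, columns=["gene_id", "kind", "start", "end", "i_evalue"])
    return genome, genes, domains


def true_loci(state: GenomeState, contig_lengths: dict[str, int]) -> list[Locus]:
    """Ground-truth loci: maximal runs of gene blocks separated only by
    igr blocks, numbered like the caller (contig size desc, then position)."""
    clusters: list[tuple[str, list[str]]] = []
    for contig, blocks in state.contigs.items():
        current: list[str] = []
        for b in blocks:
            if b.kind == "gene":
                current.append(b.gene.gene_id)
            elif b.tag != "igr" and current:
                clusters.append((contig, current))
                current = []
        if current:
            clusters.append((contig, current))
    genome, genes, _ = render(state)
    gmap = {g.id: g for g in genes}
    ordered = sorted(
        clusters,
        key=lambda cl: (-contig_lengths[cl[0]], cl[0], gmap[cl[1][0]].start),
    )
    return [
        Locus(
            id=i + 1,
            contig=c,
            genes=[gmap[g] for g in ids],
            span=(gmap[ids[0]].start, gmap[ids[-1]].end),
        )
        for i, (c, ids) in enumerate(ordered)
    ]


# ---------------------------------------------------------------------------
# high-level builders


def build_tandem_locus(
    seed: int,
    n_genes: int = 3,
    igr_drift: float = 0.0,
    igr_length: int = 800,
    flank_length: int = 2500,
) -> GenomeState:
    """A single locus expanded head-to-tail, with optional IGR drift.

    Each intergenic copy drifts independently for ``igr_drift`` time units,
    so a junction "at drift t" separates two copies at divergence 2t.
    """
    cfg = SimConfig(seed=seed, igr_length=igr_length, flank_length=flank_length)
    state = make_ancestral_genome(cfg)
    anchor = state.genes()[0].gene_id
    for _ in range(n_genes - 1):
        apply_unequal_crossover(state, anchor)
    if igr_drift > 0:
        drift_seed = int(np.random.SeedSequence(seed).generate_state(2)[1] % (2**31))
        apply_igr_drift(state, "ctg001", igr_drift, drift_seed)
    return state


def simulate_support_tree(
    seed: int,
    n_loci: int = 6,
    min_leaves: int = 2,
    max_leaves: int = 4,
    decoy_support: int = 80,
):
    """A bootstrap-labelled Newick tree with one planted cross-locus clade.

    Two unlinked loci form a 100-support clade (the planted transposition
    signal); two other loci form a decoy clade at ``decoy_support``; every
    within-locus clade has support 100.  Returns (newick, leaf->locus map,
    loci dict, planted truth).
    """
    if n_loci < 5:
        raise ValueError("need at least 5 loci for planted + decoy + outgroup")
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.arange(1, n_loci + 1))
    planted = (int(order[0]), int(order[1]))
    decoy = (int(order[2]), int(order[3]))

    leaf_map: dict[str, int] = {}
    loci: dict[int, Locus] = {}

    def bl() -> str:
        return f"{rng.uniform(0.01, 0.15):.4f}"

    def locus_subtree(lid: int) -> str:
        k = int(rng.integers(min_leaves, max_leaves + 1))
        names = [f"L{lid}_g{j}_A1" for j in range(1, k + 1)]
        for nm in names:
            leaf_map[nm] = lid
        genes = [
            Gene(id=nm, contig=f"ctg{lid:03d}", start=5000 * j, end=5000 * j + 1000, strand="+")
            for j, nm in enumerate(names, start=1)
        ]
        loci[lid] = Locus(id=lid, contig=f"ctg{lid:03d}", genes=genes, span=(5000, 5000 * len(names) + 1000))
        node = f"{names[0]}:{bl()}"
        for nm in names[1:]:
            node = f"({node},{nm}:{bl()})100:{bl()}"
        return node

    planted_clade = f"({locus_subtree(planted[0])},{locus_subtree(planted[1])})100:{bl()}"
    decoy_clade = f"({locus_subtree(decoy[0])},{locus_subtree(decoy[1])}){decoy_support}:{bl()}"
    rest = [locus_subtree(int(l)) for l in order[4:]]

    top = planted_clade
    for clade in [decoy_clade, *rest]:
        top = f"({top},{clade})60:{bl()}"
    # emitted rooted, as a midpoint-rooted input tree would be
    newick = "[&R]" + top + ";"
    truth = [frozenset(planted)]
    return newick, leaf_map, loci, truth


def emit(
    state: GenomeState,
    outdir: str | Path,
    tree_newick: str | None = None,
    leaf_map: dict[str, int] | None = None,
) -> dict[str, Path]:
    """Write FASTA + GFF3 + domain TSV (+ Newick/leaf map) + truth log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, domains = render(state)
    paths = {}

    fasta = outdir / "genome.fasta"
    with open(fasta, "w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["fasta"] = fasta

    gff = outdir / "genes.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"#seed={state.config.seed}\n")
        for g in genes:
            fh.write(
                f"{g.contig}\ttandemtrace-sim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n"
            )
    paths["gff3"] = gff

    dom = outdir / "domains.tsv"
    with open(dom, "w") as fh:
        fh.write(f"#seed={state.config.seed}\n")
        domains.to_csv(fh, sep="\t", index=False)
    paths["domains"] = dom

    truth = outdir / "truth.json"
    from dataclasses import asdict

    truth.write_text(
        json.dumps(
            {
                "seed": state.config.seed,
                "config": asdict(state.config),
                "events": state.log,
            },
            indent=1,
        )
    )
    paths["truth"] = truth

    if tree_newick is not None:
        nwk = outdir / "domains.nwk"
        nwk.write_text(tree_newick + "\n")
        paths["newick"] = nwk
    if leaf_map is not None:
        lm = outdir / "leaf_map.tsv"
        with open(lm, "w") as fh:
            fh.write("leaf_id\tlocus_id\n")
            for leaf, lid in leaf_map.items():
                fh.write(f"{leaf}\t{lid}\n")
        paths["leaf_map"] = lm
    return paths
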