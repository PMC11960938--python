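"""Genome/annotation ingestion, locus calling and segmentation.

A *locus* is a cluster of gene-family members on one contig; each locus is
cut into typed segments — left flank (LF), genes (G1..Gn), intergenic
regions (IGR1..IGRn-1) and right flank (RF) — which are the units compared
by the intergenic-homology analysis.  Coordinates are 0-based half-open
internally; GFF3 (1-based inclusive) is converted at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

TELOMERE_MOTIF = "TTAGGG"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class Gene:
    id: str
    contig: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    is_family_member: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")


@dataclass
class Locus:
    id: int
    contig: str
    genes: list[Gene]
    span: tuple[int, int]


@dataclass
class Segment:
    locus_id: int
    kind: str  # LF | GENE | IGR | RF
    label: str
    contig: str
    start: int
    end: int
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class OrientationCall:
    locus_id: int
    orientation: str  # unidirectional_head_to_tail | mixed | not_applicable
    has_intervening_genes: bool


@dataclass
class TelomereReport:
    flags: dict[str, tuple[bool, bool]] = field(default_factory=dict)

    @property
    def total_telomeric_ends(self) -> int:
        return sum(int(a) + int(b) for a, b in self.flags.values())


def load_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA assembly into a contig -> uppercase sequence map."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise ValueError(f"no sequences found in {path}")
    return genome


def load_annotations(
    path: str | Path,
    feature_type: str = "gene",
    genome: dict[str, str] | None = None,
) -> list[Gene]:
    """Parse gene features from GFF3, converting to 0-based half-open."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            Gene(
                id=gid,
                contig=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
            )
        )
    if genome is not None:
        for g in genes:
            if g.contig not in genome:
                raise ValueError(f"gene {g.id}: contig {g.contig} not in genome")
            if g.end > len(genome[g.contig]):
                raise ValueError(
                    f"gene {g.id} extends past the end of contig {g.contig}"
                )
    return genes


def emit_gff3(genes: list[Gene], path: str | Path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines or []:
            fh.write(f"#{line}\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start)):
            fh.write(
                f"{g.contig}\ttandemtrace\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n"
            )


def call_loci(
    genes: list[Gene],
    family_ids: set[str],
    max_gap: int = 20_000,
    contig_lengths: dict[str, int] | None = None,
) -> list[Locus]:
    """Cluster family genes into loci by single linkage at ``max_gap``.

    Loci are numbered by position on contigs ordered from largest to
    smallest (falling back to name order when lengths are unknown).
    """
    if not family_ids:
        raise ValueError("family_ids must be non-empty")
    known = {g.id for g in genes}
    missing = family_ids - known
    if missing:
        raise ValueError(f"unknown family gene ids: {sorted(missing)}")
    for g in genes:
        g.is_family_member = g.id in family_ids

    by_contig: dict[str, list[Gene]] = {}
    for g in genes:
        if g.is_family_member:
            by_contig.setdefault(g.contig, []).append(g)

    clusters: list[tuple[str, list[Gene]]] = []
    for contig, members in by_contig.items():
        members = sorted(members, key=lambda g: g.start)
        current = [members[0]]
        for g in members[1:]:
            if g.start - current[-1].end <= max_gap:
                current.append(g)
            else:
                clusters.append((contig, current))
                current = [g]
        clusters.append((contig, current))

    def contig_rank(c: str):
        if contig_lengths is not None:
            return (-contig_lengths.get(c, 0), c)
        return (0, c)

    clusters.sort(key=lambda cl: (contig_rank(cl[0]), cl[1][0].start))
    return [
        Locus(id=i + 1, contig=c, genes=gs, span=(gs[0].start, gs[-1].end))
        for i, (c, gs) in enumerate(clusters)
    ]


def segment_locus(locus: Locus, genome: dict[str, str], flank: int = 2500) -> list[Segment]:
    """Cut a locus into LF, G1, IGR1, ..., Gn, RF segments.

    Flanks extend ``flank`` bp beyond the outermost genes or to the contig
    end, whichever comes first.  Intergenic segments may be zero-length for
    abutting genes.
    """
    seq = genome[locus.contig]
    segs: list[Segment] = []

    def add(kind: str, label: str, start: int, end: int) -> None:
        segs.append(
            Segment(
                locus_id=locus.id,
                kind=kind,
                label=label,
                contig=locus.contig,
                start=start,
                end=end,
                sequence=seq[start:end],
            )
        )

    first, last = locus.genes[0], locus.genes[-1]
    add("LF", "LF", max(0, first.start - flank), first.start)
    for k, g in enumerate(locus.genes, start=1):
        add("GENE", f"G{k}", g.start, g.end)
        if k < len(locus.genes):
            nxt = locus.genes[k]
            add("IGR", f"IGR{k}", g.end, nxt.start)
    add("RF", "RF", last.end, min(len(seq), last.end + flank))
    return segs


def classify_orientation(locus: Locus, all_genes: list[Gene]) -> OrientationCall:
    """Orientation class of a tandem locus plus an intervening-gene flag."""
    fam = [g for g in locus.genes if g.is_family_member]
    span_lo, span_hi = locus.span
    intervening = any(
        (not g.is_family_member)
        and g.contig == locus.contig
        and g.start >= span_lo
        and g.end <= span_hi
        for g in all_genes
    )
    if len(fam) < 2:
        return OrientationCall(locus.id, "not_applicable", intervening)
    strands = {g.strand for g in fam}
    orient = "unidirectional_head_to_tail" if len(strands) == 1 else "mixed"
    return OrientationCall(locus.id, orient, intervening)


def find_telomeric_ends(
    genome: dict[str, str],
    motif: str = TELOMERE_MOTIF,
    min_copies: int = 3,
    window: int = 500,
) -> TelomereReport:
    """Flag contig ends carrying a tandem run of the telomeric repeat.

    An end is telomeric iff at least ``min_copies`` tandem copies of the
    motif (either strand) occur within ``window`` bp of that end.
    """
    pat = re.compile(
        f"(?:{motif}){{{min_copies},}}|(?:{revcomp(motif)}){{{min_copies},}}"
    )
    report = TelomereReport()
    for contig, seq in genome.items():
        head = seq[:window]
        tail = seq[-window:]
        report.flags[contig] = (bool(pat.search(head)), bool(pat.search(tail)))
    return report


def infer_min_chromosomes(report: TelomereReport) -> int:
    """Each chromosome contributes two telomeric ends."""
    total = report.total_telomeric_ends
    return (total + 1) // 2


def segments_to_bed(segments: list[Segment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\tL{s.locus_id}:{s.label}\n")


def segments_to_fasta(segments: list[Segment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            if len(s) == 0:
                continue
            fh.write(f">L{s.locus_id}:{s.label} {s.contig}:{s.start}-{s.end}\n")
            for i in range(0, len(s.sequence), 80):
                fh.write(s.sequence[i : i + 80] + "\n")


def telomere_report_tsv(report: TelomereReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\ttelomere_at_5prime\ttelomere_at_3prime\n")
        for contig, (t5, t3) in report.flags.items():
            fh.write(f"{contig}\t{int(t5)}\t{int(t3)}\n")
        fh.write(f"# total_telomeric_ends={report.total_telomeric_ends}\n")
        fh.write(f"# min_chromosomes={infer_min_chromosomes(report)}\n")
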