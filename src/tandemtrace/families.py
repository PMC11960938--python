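"""Domain-architecture family classification and protein-level audits.

Gene-family members are proteins carrying at least one catalytic
alginate-lyase domain (PL7, "A").  Architectures over {SP, C, A, TMD} in
N->C order define three families:

* ``CA`` — the canonical single C-domain + single A-domain layout (with
  ``CCA`` and ``A_only`` subfamilies for C duplication/loss),
* ``AnTMD`` — multiple A-domains, no C-domain, a C-terminal transmembrane
  domain,
* ``AnCn`` — repeated A/C units.

The module also audits the three conserved catalytic regions of A-domains
(A: RxE[LV]R, B: Q[IV]H, C: YFKxGxYxQ), detects the shared in-frame
15-bp coding insertion that separates the derived families from the CA
ancestor, and counts T-(A/P/S/V)-R-P ("TARP") tetrapeptide repeats in
linker sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import ScoringParams, align_overlap

#: per-domain independent E-value cutoffs
I_EVALUE_GENERAL = 1e-3
I_EVALUE_CAZYME = 1e-10

#: regexes for the three conserved catalytic regions of the A-domain
CATALYTIC_MOTIFS = {"A": r"R.E[LV]R", "B": r"Q[IV]H", "C": r"YFK.G.Y.Q"}

TARP_PATTERN = re.compile(r"T[APSV]RP")

_AA = set("ACDEFGHIKLMNPQRSTVWYX*")

#: map HMM/annotation names to architecture letters
DEFAULT_KIND_MAP = {
    "PL7": "A",
    "ALGINATE_LYASE": "A",
    "CBM32": "C",
    "TMD": "TMD",
    "TRANSMEMBRANE": "TMD",
    "SP": "SP",
    "SIGNAL": "SP",
}


@dataclass
class DomainHit:
    gene_id: str
    kind: str  # A | C | TMD | SP
    start: int  # protein coordinates, 0-based half-open
    end: int
    i_evalue: float
    order_index: int = 0  # 1-based per kind per gene, N- to C-terminus
    domain: str = ""  # original HMM/annotation name


@dataclass
class FamilyCall:
    gene_id: str
    architecture: str  # e.g. "SP-C-A"
    family: str  # CA | AnTMD | AnCn
    subfamily: str  # none | CCA | A_only
    n_A: int
    n_C: int
    has_SP: bool
    has_TMD: bool


@dataclass
class MotifAudit:
    domain_id: str
    matched: dict[str, bool] = field(default_factory=dict)

    @property
    def intact(self) -> bool:
        return all(self.matched.values())


@dataclass
class InsertionCall:
    domain_id: str
    has_insertion: bool
    insertion_length: int
    position: int  # reference coordinate where the insertion opens


def _kind_for(name: str, kind_map: dict[str, str]) -> str | None:
    up = name.upper()
    if up in ("A", "C", "TMD", "SP"):  # already-canonical kind letters
        return up
    if up in kind_map:
        return kind_map[up]
    for key, kind in kind_map.items():
        if key in up:
            return kind
    return None


def _resolve_and_index(hits: list[DomainHit]) -> list[DomainHit]:
    """Drop overlapping hits (keep lower i-evalue) and assign order indices.

    A hit is dropped when it overlaps an already-kept hit by more than half
    the shorter hit's length.
    """
    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    out: list[DomainHit] = []
    for gene_hits in by_gene.values():
        kept: list[DomainHit] = []
        for h in sorted(gene_hits, key=lambda h: (h.i_evalue, h.start)):
            clash = False
            for k in kept:
                ov = min(h.end, k.end) - max(h.start, k.start)
                shorter = min(h.end - h.start, k.end - k.start)
                if ov > 0.5 * shorter:
                    clash = True
                    break
            if not clash:
                kept.append(h)
        kept.sort(key=lambda h: h.start)
        counters: dict[str, int] = {}
        for h in kept:
            counters[h.kind] = counters.get(h.kind, 0) + 1
            h.order_index = counters[h.kind]
        out.extend(kept)
    return out


def parse_domtblout(
    path: str | Path,
    i_evalue_max: float = I_EVALUE_GENERAL,
    kind_map: dict[str, str] | None = None,
) -> list[DomainHit]:
    """Read hmmscan --domtblout output into filtered, ordered domain hits.

    Protein coordinates come from the alignment columns; hits above the
    i-evalue cutoff or whose HMM name maps to no known kind are dropped.
    """
    from Bio import SearchIO

    kind_map = kind_map or DEFAULT_KIND_MAP
    hits: list[DomainHit] = []
    for qres in SearchIO.parse(str(path), "hmmscan3-domtab"):
        for hit in qres.hits:
            kind = _kind_for(hit.id, kind_map)
            if kind is None:
                continue
            for hsp in hit.hsps:
                if hsp.evalue > i_evalue_max:  # independent (i-)E-value
                    continue
                hits.append(
                    DomainHit(
                        gene_id=qres.id,
                        kind=kind,
                        start=hsp.query_start,
                        end=hsp.query_end,
                        i_evalue=float(hsp.evalue),
                        domain=hit.id,
                    )
                )
    return _resolve_and_index(hits)


def parse_domain_tsv(
    path: str | Path,
    i_evalue_max: float = I_EVALUE_GENERAL,
    kind_map: dict[str, str] | None = None,
) -> list[DomainHit]:
    """Read the TSV fallback schema (gene_id, kind, start, end, i_evalue)."""
    kind_map = kind_map or DEFAULT_KIND_MAP
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "kind", "start", "end", "i_evalue"}
    if not required.issubset(df.columns):
        raise ValueError(f"domain TSV must have columns {sorted(required)}")
    hits = []
    for i, row in enumerate(df.itertuples(index=False)):
        kind = _kind_for(str(row.kind), kind_map)
        if kind is None or row.i_evalue > i_evalue_max:
            continue
        if row.start >= row.end:
            raise ValueError(f"malformed domain TSV line {i + 2}: start >= end")
        hits.append(
            DomainHit(
                gene_id=str(row.gene_id),
                kind=kind,
                start=int(row.start),
                end=int(row.end),
                i_evalue=float(row.i_evalue),
                domain=str(row.kind),
            )
        )
    return _resolve_and_index(hits)


def architecture_string(hits: list[DomainHit]) -> str:
    return "-".join(h.kind for h in sorted(hits, key=lambda h: h.start))


def classify_family(hits: list[DomainHit]) -> FamilyCall | None:
    """Assign a gene to CA / AnTMD / AnCn from its ordered domain hits.

    Returns None for genes without an A-domain (not family members).
    Rules, in order: a C-terminal TMD with no C-domain -> AnTMD; at least
    two A plus at least one C -> AnCn; otherwise CA, with subfamilies CCA
    (tandem C-C preceding the A) and A_only (no C at all).
    """
    if not hits:
        return None
    ordered = sorted(hits, key=lambda h: h.start)
    n_A = sum(1 for h in ordered if h.kind == "A")
    if n_A == 0:
        return None
    n_C = sum(1 for h in ordered if h.kind == "C")
    has_SP = any(h.kind == "SP" for h in ordered)
    last_a_start = max(h.start for h in ordered if h.kind == "A")
    has_cterm_tmd = any(h.kind == "TMD" and h.start >= last_a_start for h in ordered)
    has_TMD = any(h.kind == "TMD" for h in ordered)
    arch = architecture_string(ordered)

    if has_cterm_tmd and n_C == 0:
        family, sub = "AnTMD", "none"
    elif n_A >= 2 and n_C >= 1:
        family, sub = "AnCn", "none"
    else:
        family = "CA"
        if "C-C-A" in arch:
            sub = "CCA"
        elif n_C == 0:
            sub = "A_only"
        else:
            sub = "none"
    gene_id = ordered[0].gene_id
    return FamilyCall(
        gene_id=gene_id,
        architecture=arch,
        family=family,
        subfamily=sub,
        n_A=n_A,
        n_C=n_C,
        has_SP=has_SP,
        has_TMD=has_TMD,
    )


def audit_catalytic_motifs(a_domain_protein_seq: str, domain_id: str = "") -> MotifAudit:
    """Check the three conserved catalytic regions of an A-domain."""
    seq = a_domain_protein_seq.upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"non-amino-acid character(s) {sorted(bad)} in sequence")
    audit = MotifAudit(domain_id=domain_id)
    for region, pattern in CATALYTIC_MOTIFS.items():
        audit.matched[region] = re.search(pattern, seq) is not None
    return audit


def detect_insertion(
    a_domain_nt: str,
    reference_a_domain_nt: str,
    params: ScoringParams | None = None,
    min_len: int = 15,
    require_in_frame: bool = True,
    domain_id: str = "",
) -> InsertionCall:
    """Find the longest internal insertion relative to a reference CDS.

    Both sequences are aligned globally with end gaps penalised; runs of
    gaps opened in the reference (i.e. extra sequence in the query) that do
    not touch the alignment ends are candidate insertions.
    """
    if params is None:
        params = ScoringParams(free_end_gaps=False)
    r = align_overlap(a_domain_nt, reference_a_domain_nt, params)
    ref = r.aligned_b  # gaps here are insertions in the query
    best_len, best_pos = 0, -1
    ref_pos = 0
    i = 0
    while i < len(ref):
        if ref[i] == "-":
            j = i
            while j < len(ref) and ref[j] == "-":
                j += 1
            internal = i > 0 and j < len(ref)
            if internal and (j - i) > best_len:
                best_len, best_pos = j - i, ref_pos
            i = j
        else:
            ref_pos += 1
            i += 1
    has = best_len >= min_len and (not require_in_frame or best_len % 3 == 0)
    return InsertionCall(
        domain_id=domain_id,
        has_insertion=bool(has),
        insertion_length=best_len,
        position=best_pos,
    )


def count_tarp_repeats(linker_protein_seq: str) -> int:
    """Count non-overlapping T-(A/P/S/V)-R-P tetrapeptides, scanning N->C."""
    return len(TARP_PATTERN.findall(linker_protein_seq.upper()))


def family_table(calls: list[FamilyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "architecture": c.architecture,
                "family": c.family,
                "subfamily": c.subfamily,
                "n_A": c.n_A,
                "n_C": c.n_C,
                "SP": int(c.has_SP),
                "TMD": int(c.has_TMD),
            }
            for c in calls
        ]
    )


def summarize_families(calls: list[FamilyCall]) -> dict[str, int]:
    """Headline census over a set of family calls."""
    return {
        "n_family_genes": len(calls),
        "n_with_C": sum(1 for c in calls if c.n_C >= 1),
        "n_CA": sum(1 for c in calls if c.family == "CA"),
        "n_AnTMD": sum(1 for c in calls if c.family == "AnTMD"),
        "n_AnCn": sum(1 for c in calls if c.family == "AnCn"),
    }
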