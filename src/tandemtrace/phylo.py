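"""Transposition inference from a bootstrap-supported domain phylogeny.

Gene copies dispersed to unlinked loci (different contigs, or the same
contig with >10 kb of unique sequence between loci) are attributed to
transposition when their domains form a monophyletic clade with full
bootstrap support.  Also provides the bit-score-binned subsampling scheme
used to thin large tabular protein-similarity searches to a representative
set for phylogenetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .loci import Locus

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class SupportTree:
    """A phylogeny whose internal nodes carry integer bootstrap supports."""

    tree: dendropy.Tree

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


@dataclass
class TranspositionEvent:
    clade_id: str
    loci: frozenset[int]
    support: int
    locus_coverage: dict[int, float] = field(default_factory=dict)


@dataclass
class SampledHitSet:
    bins: list[tuple[tuple[float, float], pd.DataFrame]]
    seed: int
    filters_applied: list[str] = field(default_factory=list)

    @property
    def retained(self) -> pd.DataFrame:
        frames = [df for _, df in self.bins if len(df)]
        if not frames:
            return pd.DataFrame(columns=BLAST_COLUMNS)
        return pd.concat(frames, ignore_index=True)


def parse_newick_with_support(source: str | Path) -> SupportTree:
    """Read Newick with integer bootstrap labels on internal nodes.

    Accepts a path or a Newick string.  Missing internal labels are kept as
    None; duplicate leaf names raise.
    """
    text = str(source)
    if "(" not in text:
        text = Path(source).read_text()
    from dendropy.dataio.newickreader import NewickReader

    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf name in tree: {exc}") from exc
    seen = set()
    for lf in tree.leaf_node_iter():
        name = lf.taxon.label
        if name in seen:
            raise ValueError(f"duplicate leaf name {name!r}")
        seen.add(name)
    for nd in tree.preorder_internal_node_iter():
        if nd.label is not None and nd.label != "":
            try:
                nd.support = int(nd.label)
            except ValueError:
                nd.support = None
        else:
            nd.support = None
    return SupportTree(tree=tree)


def unlinked(locus_a: Locus, locus_b: Locus, min_unique_bp: int = 10_000) -> bool:
    """True iff the loci sit on different contigs or >min_unique_bp apart."""
    if locus_a.contig != locus_b.contig:
        return True
    gap = max(
        locus_a.span[0] - locus_b.span[1],
        locus_b.span[0] - locus_a.span[1],
    )
    return gap > min_unique_bp


def infer_transpositions(
    support_tree: SupportTree,
    leaf_to_locus: dict[str, int],
    loci: dict[int, Locus],
    min_support: int = 100,
    min_locus_coverage: float = 0.5,
    min_unique_bp: int = 10_000,
) -> list[TranspositionEvent]:
    """Report maximal well-supported clades spanning unlinked loci.

    A clade qualifies when its support is >= min_support, its leaves span
    two or more pairwise-unlinked loci, and for every involved locus the
    clade contains at least ``min_locus_coverage`` of that locus's domains.
    Qualifying clades nested inside a qualifying ancestor are collapsed
    into the maximal one.
    """
    tree = support_tree.tree.clone(depth=1)
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in leaf_to_locus:
            raise ValueError(f"leaf {leaf.taxon.label!r} has no locus mapping")

    # supports belong to bipartitions, not nodes: remember them by leaf set
    # (and complement) so that rerooting cannot detach them
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    support_own: dict[frozenset, int] = {}
    support_comp: dict[frozenset, int] = {}
    for nd in tree.preorder_internal_node_iter():
        s = getattr(nd, "support", None)
        if s is None:
            continue
        fs = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        support_own[fs] = s
        support_comp[all_leaves - fs] = s

    if not tree.is_rooted:
        tree.reroot_at_midpoint(update_bipartitions=True)

    def support_of(node) -> int | None:
        fs = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if fs in support_own:
            return support_own[fs]
        return support_comp.get(fs)

    totals: dict[int, int] = {}
    for name, locus_id in leaf_to_locus.items():
        totals[locus_id] = totals.get(locus_id, 0) + 1

    events: list[TranspositionEvent] = []

    def visit(node) -> None:
        if node.is_leaf():
            return
        support = support_of(node)
        if support is not None and support >= min_support and node.parent_node is not None:
            leaves = [lf.taxon.label for lf in node.leaf_iter()]
            counts: dict[int, int] = {}
            for name in leaves:
                lid = leaf_to_locus[name]
                counts[lid] = counts.get(lid, 0) + 1
            coverage = {lid: counts[lid] / totals[lid] for lid in counts}
            involved = sorted(counts)
            if (
                len(involved) >= 2
                and all(coverage[lid] >= min_locus_coverage for lid in involved)
                and all(
                    unlinked(loci[x], loci[y], min_unique_bp)
                    for i, x in enumerate(involved)
                    for y in involved[i + 1 :]
                )
            ):
                events.append(
                    TranspositionEvent(
                        clade_id=",".join(sorted(leaves)),
                        loci=frozenset(involved),
                        support=int(support),
                        locus_coverage=coverage,
                    )
                )
                return  # maximal clade: do not descend
        for child in node.child_nodes():
            visit(child)

    visit(tree.seed_node)
    return events


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Read 12-column tabular similarity-search output (optional 13th
    column carrying the hit description)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 12:
        df.columns = BLAST_COLUMNS
    elif df.shape[1] == 13:
        df.columns = BLAST_COLUMNS + ["stitle"]
    else:
        raise ValueError(f"expected 12 or 13 columns, found {df.shape[1]}")
    return df


def _default_species_of(row) -> str:
    title = getattr(row, "stitle", None)
    if isinstance(title, str) and title:
        if "[" in title and "]" in title:
            return title[title.index("[") + 1 : title.index("]")]
        return " ".join(title.split()[:2])
    return str(row.sseqid)


def sample_blast_hits(
    hits: pd.DataFrame,
    bin_width: float = 50.0,
    n_bins: int = 10,
    per_bin: int = 25,
    seed: int = 0,
    species_dedupe: bool = True,
    label_filter=None,
    species_of=None,
) -> SampledHitSet:
    """Bit-score-binned random subsample of similarity-search hits.

    Hits are binned from the minimum bit score in intervals of
    ``bin_width`` (scores beyond the top boundary fall into the last bin),
    ``per_bin`` hits are drawn uniformly without replacement per bin, then
    description filtering and one-per-species dedupe are applied.
    """
    if "bitscore" not in hits.columns:
        raise ValueError("hits table is missing the bitscore column")
    if hits["bitscore"].isna().any():
        raise ValueError("missing bit score in hits table")
    species_of = species_of or _default_species_of
    rng = np.random.default_rng(seed)
    lo = float(hits["bitscore"].min())
    idx_bin = np.minimum(
        ((hits["bitscore"] - lo) // bin_width).astype(int), n_bins - 1
    )
    filters = []
    bins: list[tuple[tuple[float, float], pd.DataFrame]] = []
    for b in range(n_bins):
        interval = (lo + b * bin_width, lo + (b + 1) * bin_width)
        sub = hits[idx_bin == b]
        if len(sub) > per_bin:
            take = rng.choice(len(sub), size=per_bin, replace=False)
            sub = sub.iloc[np.sort(take)]
        sub = sub.copy()
        if label_filter is not None:
            keep = [bool(label_filter(row)) for row in sub.itertuples(index=False)]
            sub = sub[keep]
        bins.append((interval, sub.reset_index(drop=True)))
    if label_filter is not None:
        filters.append("label_filter")
    if species_dedupe:
        filters.append("one_per_species")
        deduped = []
        seen: set[str] = set()
        for interval, sub in bins:
            if len(sub):
                sub = sub.copy()
                sub["_species"] = [
                    species_of(row) for row in sub.itertuples(index=False)
                ]
                sub = sub.sort_values("bitscore", ascending=False)
                keep_rows = []
                for _, row in sub.iterrows():
                    if row["_species"] not in seen:
                        seen.add(row["_species"])
                        keep_rows.append(row)
                sub = (
                    pd.DataFrame(keep_rows).drop(columns=["_species"]).reset_index(drop=True)
                    if keep_rows
                    else sub.iloc[0:0].drop(columns=["_species"])
                )
            deduped.append((interval, sub))
        bins = deduped
    return SampledHitSet(bins=bins, seed=seed, filters_applied=filters)


def events_tsv(events: list[TranspositionEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("clade_id\tloci\tsupport\tcoverage\n")
        for e in events:
            cov = ";".join(f"{k}:{v:.2f}" for k, v in sorted(e.locus_coverage.items()))
            fh.write(f"{e.clade_id}\t{','.join(map(str, sorted(e.loci)))}\t{e.support}\t{cov}\n")
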