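"""Segment-vs-segment percent-identity matrices and recency calling.

Consecutive intergenic regions of a tandem locus are born identical when a
gene is duplicated together with its downstream spacer by unequal crossing
over, and then decay by neutral drift.  High percent identity between a
consecutive intergenic pair therefore marks a recent duplication.  Because
"high" is qualitative, the caller calibrates each comparison against a
mononucleotide-shuffle null and additionally applies an absolute floor:
overlap alignments of short random sequences can reach inflated PID3, and
the floor keeps saturated (ancient) junctions out of the recent set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import ScoringParams, align_overlap
from .loci import Segment

#: segments shorter than this are reported as not assessable
MIN_ASSESSABLE_LEN = 30


@dataclass
class PIDMatrix:
    locus_id: int
    labels: list[str]
    values: np.ndarray  # symmetric percent matrix, diagonal 100
    self_mask: np.ndarray  # True on the diagonal

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def get(self, label_a: str, label_b: str) -> float:
        i = self.labels.index(label_a)
        j = self.labels.index(label_b)
        return float(self.values[i, j])


@dataclass
class RecencyCall:
    locus_id: int
    igr_pair: tuple[str, str]
    pid3: float
    null_quantile: float  # percent of shuffle-null values below the observed
    is_recent: bool


def pairwise_matrix(
    segments: list[Segment],
    params: ScoringParams | None = None,
    subset: str = "all",
) -> PIDMatrix:
    """All-vs-all PID3 over a locus's segments (each unordered pair once)."""
    if params is None:
        params = ScoringParams()
    if subset == "intergenic_only":
        segs = [s for s in segments if s.kind == "IGR"]
    elif subset == "all":
        segs = list(segments)
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if len(segs) < 2:
        raise ValueError("need at least two segments to build a matrix")

    n = len(segs)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = segs[i], segs[j]
            if len(a) < MIN_ASSESSABLE_LEN or len(b) < MIN_ASSESSABLE_LEN:
                continue  # not assessable: PID3 on tiny segments is meaningless
            r = align_overlap(a.sequence, b.sequence, params)
            values[i, j] = values[j, i] = r.pid3
    return PIDMatrix(
        locus_id=segs[0].locus_id,
        labels=[s.label for s in segs],
        values=values,
        self_mask=np.eye(n, dtype=bool),
    )


def shuffle_null(
    seq_a: str,
    seq_b: str,
    n_shuffles: int = 100,
    seed: int = 0,
    params: ScoringParams | None = None,
) -> np.ndarray:
    """PID3 distribution of seq_a vs mononucleotide-shuffled copies of seq_b."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if params is None:
        params = ScoringParams()
    rng = np.random.default_rng(seed)
    letters = np.array(list(seq_b))
    out = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = "".join(letters[rng.permutation(len(letters))])
        out[k] = align_overlap(seq_a, shuffled, params).pid3
    return out


def call_recent_duplications(
    matrix: PIDMatrix,
    segments: list[Segment],
    n_shuffles: int = 100,
    alpha: float = 0.05,
    floor: float = 50.0,
    seed: int = 0,
    params: ScoringParams | None = None,
) -> list[RecencyCall]:
    """Flag consecutive intergenic pairs whose identity beats the null.

    A pair (IGRk, IGRk+1) is called recent iff its PID3 exceeds the
    empirical 1-alpha quantile of the shuffle null for that pair and is at
    least ``floor`` percent.  Pairs involving segments shorter than
    MIN_ASSESSABLE_LEN are omitted.
    """
    igrs = sorted(
        (s for s in segments if s.kind == "IGR"),
        key=lambda s: int(s.label[3:]),
    )
    if len(igrs) < 2:
        return []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(igrs) - 1)]
    calls = []
    for k in range(len(igrs) - 1):
        a, b = igrs[k], igrs[k + 1]
        if len(a) < MIN_ASSESSABLE_LEN or len(b) < MIN_ASSESSABLE_LEN:
            continue
        observed = matrix.get(a.label, b.label)
        null = shuffle_null(a.sequence, b.sequence, n_shuffles, child_seeds[k], params)
        threshold = float(np.quantile(null, 1.0 - alpha))
        calls.append(
            RecencyCall(
                locus_id=matrix.locus_id,
                igr_pair=(a.label, b.label),
                pid3=observed,
                null_quantile=100.0 * float(np.mean(null < observed)),
                is_recent=bool(observed > threshold and observed >= floor),
            )
        )
    return calls


def export_matrix(matrix: PIDMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", float_format="%.2f")


def read_matrix(path, locus_id: int = 0) -> PIDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    return PIDMatrix(
        locus_id=locus_id,
        labels=list(df.index),
        values=values,
        self_mask=np.eye(len(df), dtype=bool),
    )


def recency_calls_tsv(calls: list[RecencyCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tigr_a\tigr_b\tpid3\tnull_quantile\tis_recent\n")
        for c in calls:
            fh.write(
                f"{c.locus_id}\t{c.igr_pair[0]}\t{c.igr_pair[1]}\t"
                f"{c.pid3:.2f}\t{c.null_quantile:.1f}\t{int(c.is_recent)}\n"
            )


def matrix_plot(matrix: PIDMatrix, ax=None):
    """Render the per-locus matrix with per-cell percent labels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.6 * len(matrix.labels) + 2,) * 2)
    vals = np.ma.masked_invalid(matrix.values)
    ax.imshow(vals, vmin=0, vmax=100, cmap="magma")
    ax.set_xticks(range(len(matrix.labels)), matrix.labels, rotation=90)
    ax.set_yticks(range(len(matrix.labels)), matrix.labels)
    for i in range(len(matrix.labels)):
        for j in range(len(matrix.labels)):
            if not np.isnan(matrix.values[i, j]):
                ax.text(j, i, f"{matrix.values[i, j]:.0f}", ha="center", va="center", fontsize=7)
    ax.set_title(f"Locus {matrix.locus_id}")
    return ax
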