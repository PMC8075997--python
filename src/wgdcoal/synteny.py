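"""Colinear (syntenic) block detection and syntenic depth ratios.

Anchors (candidate homologous gene pairs) are chained per chromosome pair with
a DAGchainer-style sparse dynamic program over gene *ranks* (0-based order
indices, not base pairs): a chain scores the sum of its anchor scores minus a
gap penalty per skipped rank, must advance strictly monotonically in both
genomes (antiparallel chains model inversions), and may not jump more than
``max_gap`` ranks between consecutive anchors.  Non-overlapping chains are
extracted greedily by score; blocks below ``min_block`` anchors are discarded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ChainParams:
    min_block: int = 10  # minimum anchor pairs per reported block
    max_gap: int = 25  # maximum rank gap between consecutive anchors
    gap_open: float = 0.05  # score penalty per skipped rank
    allow_inversions: bool = True

    def __post_init__(self) -> None:
        if self.min_block < 2:
            raise ValueError("min_block must be >= 2")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")


@dataclass
class SyntenicBlock:
    genome_a: str
    genome_b: str
    chromosome_a: str
    chromosome_b: str
    orientation: str  # "+" or "-"
    anchors: list[tuple[str, str, int, int]]  # (gene_a, gene_b, rank_a, rank_b)
    score: float
    ks_values: list[float] = field(default_factory=list)
    median_ks: float | None = None

    def __len__(self) -> int:
        return len(self.anchors)


def _position_index(genomes: dict[str, pd.DataFrame]) -> dict[str, tuple[str, str, int]]:
    """gene id -> (genome, chromosome, rank)."""
    index: dict[str, tuple[str, str, int]] = {}
    for name, table in genomes.items():
        for chrom, rank, gid in zip(table["chrom"], table["rank"], table["gene_id"]):
            if gid in index:
                raise ValueError(f"duplicate gene id {gid!r}")
            index[gid] = (name, chrom, int(rank))
    return index


def _best_chain(
    anchors: list[tuple[int, int, float, int]], params: ChainParams, sign: int
) -> tuple[float, list[int]] | None:
    """Highest-scoring chain, ranks strictly increasing in a and, for sign=+1,
    increasing in b (sign=-1: decreasing).  Anchors are (ra, rb, score, idx)."""
    if not anchors:
        return None
    pts = sorted(anchors, key=lambda t: (t[0], sign * t[1]))
    n = len(pts)
    # two DP states per anchor: best chain ending here of length 1 (the anchor
    # alone) vs length >= 2; only the latter is reportable as a block
    best1 = [p[2] for p in pts]
    best2 = [-np.inf] * n
    len2 = [0] * n
    prev: list[tuple[int, int]] = [(-1, 0)] * n
    for i in range(n):
        ra_i, rb_i, sc_i, _ = pts[i]
        for j in range(i):
            ra_j, rb_j, _, _ = pts[j]
            da = ra_i - ra_j
            db = sign * (rb_i - rb_j)
            if da < 1 or db < 1 or da > params.max_gap or db > params.max_gap:
                continue
            if best2[j] >= best1[j]:
                base, state, blen = best2[j], 2, len2[j]
            else:
                base, state, blen = best1[j], 1, 1
            cand = base + sc_i - params.gap_open * (da - 1 + db - 1)
            if (cand, blen + 1) > (best2[i] + 1e-12, len2[i]):
                best2[i] = cand
                len2[i] = blen + 1
                prev[i] = (j, state)
    ends = [i for i in range(n) if len2[i] >= 2]
    if not ends:
        return None
    end = max(ends, key=lambda i: (best2[i], len2[i]))
    top = float(best2[end])
    chain = [pts[end][3]]
    while True:
        j, state = prev[end]
        chain.append(pts[j][3])
        if state == 1:
            break
        end = j
    return top, chain[::-1]


def chain_anchors(
    anchors: pd.DataFrame,
    genomes: dict[str, pd.DataFrame],
    params: ChainParams = ChainParams(),
) -> list[SyntenicBlock]:
    """Chain an anchor table into syntenic blocks.

    ``anchors`` has columns gene_a, gene_b, score; ``genomes`` maps genome name
    to a positions table (chrom, rank, strand, gene_id).  Anchors between every
    genome pair present (including within-genome paralogy, self-pairs of a gene
    with itself excluded) are chained independently per chromosome pair.
    """
    index = _position_index(genomes)
    groups: dict[tuple[str, str, str, str], list] = {}
    for gene_a, gene_b, score in zip(
        anchors["gene_a"], anchors["gene_b"], anchors.get("score", [1.0] * len(anchors))
    ):
        for gid in (gene_a, gene_b):
            if gid not in index:
                raise KeyError(f"anchor gene {gid!r} absent from position tables")
        if gene_a == gene_b:
            continue
        (ga, ca, ra), (gb, cb, rb) = index[gene_a], index[gene_b]
        # canonical orientation of the pair so grouping is stable
        if (ga, ca, ra) > (gb, cb, rb):
            ga, ca, ra, gb, cb, rb = gb, cb, rb, ga, ca, ra
            gene_a, gene_b = gene_b, gene_a
        groups.setdefault((ga, gb, ca, cb), []).append(
            (ra, rb, float(score), gene_a, gene_b)
        )

    blocks: list[SyntenicBlock] = []
    for (ga, gb, ca, cb), items in sorted(groups.items()):
        live = [(ra, rb, sc, i) for i, (ra, rb, sc, _, _) in enumerate(items)]
        while True:
            candidates = []
            fwd = _best_chain(live, params, +1)
            if fwd:
                candidates.append((fwd[0], len(fwd[1]), "+", fwd[1]))
            if params.allow_inversions:
                rev = _best_chain(live, params, -1)
                if rev:
                    candidates.append((rev[0], len(rev[1]), "-", rev[1]))
            candidates = [c for c in candidates if c[1] >= 2]
            if not candidates:
                break
            score, _, orient, chain = max(candidates, key=lambda c: (c[0], c[1]))
            anchor_rows = [
                (items[i][3], items[i][4], items[i][0], items[i][1]) for i in chain
            ]
            blocks.append(
                SyntenicBlock(ga, gb, ca, cb, orient, anchor_rows, score)
            )
            used = set(chain)
            live = [t for t in live if t[3] not in used]
    blocks = [b for b in blocks if len(b) >= params.min_block]
    blocks.sort(key=lambda b: (b.genome_a, b.genome_b, b.chromosome_a, b.chromosome_b,
                               -len(b)))
    return blocks


@dataclass
class DepthResult:
    target: str
    other: str
    modal_depth_on_other: int  # target regions stacked over a window of `other`
    modal_depth_on_target: int
    histogram_other: dict[int, int]
    histogram_target: dict[int, int]

    @property
    def ratio(self) -> tuple[int, int]:
        """Syntenic depth ratio target:other, e.g. (2, 1)."""
        return (self.modal_depth_on_other, self.modal_depth_on_target)


def _coverage_histogram(
    spans: list[tuple[str, int, int]], window: int
) -> dict[int, int]:
    """Depth histogram over fixed windows of gene ranks, covered windows only."""
    hist: Counter[int] = Counter()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, lo, hi in spans:
        by_chrom.setdefault(chrom, []).append((lo, hi))
    for chrom, ivals in by_chrom.items():
        top = max(hi for _, hi in ivals)
        for start in range(0, top + 1, window):
            stop = start + window - 1
            depth = sum(1 for lo, hi in ivals if lo <= stop and hi >= start)
            if depth > 0:
                hist[depth] += 1
    return dict(hist)


def syntenic_depth(
    blocks: list[SyntenicBlock], target: str, window: int = 50
) -> DepthResult:
    """Depth histograms and modal syntenic depth ratio for one genome pair.

    Every block must involve ``target`` on one side.  Coverage is counted in
    windows of ``window`` gene ranks; the modal depth over covered windows on
    each side gives the ratio (e.g. 2:1 after one full-retention WGD in the
    target lineage).
    """
    if not blocks:
        raise ValueError("empty block list")
    others = {b.genome_b if b.genome_a == target else b.genome_a for b in blocks}
    if len(others) != 1 or any(target not in (b.genome_a, b.genome_b) for b in blocks):
        raise ValueError("blocks must all pair the target genome with one other genome")
    other = others.pop()
    spans_t, spans_o = [], []
    for b in blocks:
        ra = [a[2] for a in b.anchors]
        rb = [a[3] for a in b.anchors]
        span_a = (b.chromosome_a, min(ra), max(ra))
        span_b = (b.chromosome_b, min(rb), max(rb))
        if b.genome_a == target:
            spans_t.append(span_a)
            spans_o.append(span_b)
        else:
            spans_t.append(span_b)
            spans_o.append(span_a)
    hist_o = _coverage_histogram(spans_o, window)
    hist_t = _coverage_histogram(spans_t, window)
    modal_o = max(hist_o.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    modal_t = max(hist_t.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return DepthResult(target, other, modal_o, modal_t, hist_o, hist_t)
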