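"""Collinear syntenic-block chaining, syntenic depth and coverage.

Homologous gene pairs (anchors) between two chromosomes are chained into
collinear blocks by sparse dynamic programming on gene order, in the
style of DAGChainer: a chain's score is the sum of its anchor scores
minus a per-gene gap penalty on both sides; adjacent anchors may skip at
most ``max_gap_genes`` genes on each side; chains run either parallel
(both orders increasing) or antiparallel. Chains are extracted greedily
by descending score with used anchors removed, and chains with fewer
than ``min_anchors`` anchors are discarded.

Syntenic depth counts, for windows of consecutive genes along a genome,
how many blocks cover the window — a proxy for the number of
whole-genome duplications (a region present in k other places has depth
1:k). Syntenic coverage is the length fraction of genes participating in
at least one block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MAX_GAP = 40
DEFAULT_MIN_ANCHORS = 5
DEFAULT_MAX_EVALUE = 1e-4


@dataclass
class SyntenicBlock:
    block_id: int
    chrom_a: str
    chrom_b: str
    orientation: str              # "parallel" | "antiparallel"
    anchors: pd.DataFrame         # gene_a, gene_b, order_a, order_b, score
    score: float

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        return int(self.anchors["order_a"].min()), int(self.anchors["order_a"].max())

    @property
    def span_b(self) -> tuple[int, int]:
        return int(self.anchors["order_b"].min()), int(self.anchors["order_b"].max())


def filter_anchors(
    hits: pd.DataFrame,
    genes: pd.DataFrame,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    self_comparison: bool = True,
) -> pd.DataFrame:
    """Turn a hit table into positioned anchor pairs.

    ``hits`` needs gene_a, gene_b, score, evalue; ``genes`` needs gene_id,
    chrom, order_index. Hits above the e-value cutoff, self-hits, and (for
    self-comparison) one of each symmetric duplicate are removed. Unknown
    gene ids raise.
    """
    pos = genes.set_index("gene_id")[["chrom", "order_index"]]
    unknown = set(hits["gene_a"]) | set(hits["gene_b"])
    unknown -= set(pos.index)
    if unknown:
        raise KeyError(f"hit table references unknown genes: {sorted(unknown)[:5]}")
    df = hits[hits["evalue"] <= max_evalue].copy()
    df = df[df["gene_a"] != df["gene_b"]]
    if self_comparison:
        a, b = df["gene_a"].copy(), df["gene_b"].copy()
        swap = a > b
        df.loc[swap, ["gene_a", "gene_b"]] = df.loc[swap, ["gene_b", "gene_a"]].values
        df = df.drop_duplicates(subset=["gene_a", "gene_b"])
    df["chrom_a"] = pos.loc[df["gene_a"], "chrom"].to_numpy()
    df["order_a"] = pos.loc[df["gene_a"], "order_index"].to_numpy()
    df["chrom_b"] = pos.loc[df["gene_b"], "chrom"].to_numpy()
    df["order_b"] = pos.loc[df["gene_b"], "order_index"].to_numpy()
    return df.reset_index(drop=True)


def collapse_tandem(anchors: pd.DataFrame, max_spacing: int = 5) -> pd.DataFrame:
    """Drop tandem-duplicate self anchors (same chromosome, close in order).

    Anchors joining two genes on one chromosome within ``max_spacing``
    order positions are tandem duplications, not segmental synteny, and
    would inflate the self-diagonal; they are removed before chaining.
    """
    tandem = (
        (anchors["chrom_a"] == anchors["chrom_b"])
        & ((anchors["order_a"] - anchors["order_b"]).abs() <= max_spacing)
    )
    return anchors[~tandem].reset_index(drop=True)


def _best_chain(
    order_a: np.ndarray,
    order_b: np.ndarray,
    scores: np.ndarray,
    max_gap: int,
    gap_penalty: float,
) -> tuple[list[int], float]:
    """Highest-scoring collinear chain (both orders strictly increasing)."""
    n = len(order_a)
    idx = np.lexsort((order_b, order_a))
    oa, ob, sc = order_a[idx], order_b[idx], scores[idx]
    best = sc.astype(float).copy()
    prev = np.full(n, -1)
    for i in range(n):
        for j in range(i):
            gap_a = oa[i] - oa[j] - 1
            gap_b = ob[i] - ob[j] - 1
            if gap_a < 0 or gap_b < 0 or gap_a > max_gap or gap_b > max_gap:
                continue
            if oa[j] == oa[i] or ob[j] == ob[i]:
                continue
            cand = best[j] + sc[i] - gap_penalty * (gap_a + gap_b)
            if cand > best[i]:
                best[i] = cand
                prev[i] = j
    end = int(np.argmax(best))
    chain = []
    k = end
    while k != -1:
        chain.append(int(idx[k]))
        k = int(prev[k])
    return chain[::-1], float(best[end])


def chain_collinear_blocks(
    anchors: pd.DataFrame,
    max_gap_genes: int = DEFAULT_MAX_GAP,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    anchor_score: float | None = 10.0,
    gap_penalty: float = 1.0,
) -> list[SyntenicBlock]:
    """Chain anchors into syntenic blocks per chromosome pair and orientation.

    With ``anchor_score`` set, every anchor contributes that fixed score
    (hit scores are often on incomparable scales); pass None to use the
    hit scores themselves.
    """
    if anchors.empty:
        return []
    work = anchors.copy()
    if anchor_score is not None:
        work["score"] = float(anchor_score)
    blocks: list[SyntenicBlock] = []
    block_id = 0
    for (ca, cb), grp in work.groupby(["chrom_a", "chrom_b"], sort=True):
        for orientation in ("parallel", "antiparallel"):
            sub = grp.reset_index(drop=True)
            ob = sub["order_b"].to_numpy()
            if orientation == "antiparallel":
                ob = -ob
            remaining = np.ones(len(sub), dtype=bool)
            while remaining.sum() >= min_anchors:
                live = np.nonzero(remaining)[0]
                chain_local, score = _best_chain(
                    sub["order_a"].to_numpy()[live], ob[live],
                    sub["score"].to_numpy()[live],
                    max_gap_genes, gap_penalty,
                )
                chain = live[chain_local]
                remaining[chain] = False
                if len(chain) < min_anchors:
                    continue
                block_id += 1
                blocks.append(SyntenicBlock(
                    block_id=block_id, chrom_a=str(ca), chrom_b=str(cb),
                    orientation=orientation,
                    anchors=sub.iloc[chain][
                        ["gene_a", "gene_b", "order_a", "order_b", "score"]
                    ].reset_index(drop=True),
                    score=score,
                ))
    blocks.sort(key=lambda b: -b.score)
    return blocks


def blocks_table(blocks: list[SyntenicBlock]) -> pd.DataFrame:
    rows = []
    for b in blocks:
        rows.append({
            "block_id": b.block_id, "chrom_a": b.chrom_a,
            "span_a_start": b.span_a[0], "span_a_end": b.span_a[1],
            "chrom_b": b.chrom_b,
            "span_b_start": b.span_b[0], "span_b_end": b.span_b[1],
            "orientation": b.orientation, "n_anchors": b.n_anchors,
            "score": b.score,
        })
    return pd.DataFrame(rows, columns=[
        "block_id", "chrom_a", "span_a_start", "span_a_end", "chrom_b",
        "span_b_start", "span_b_end", "orientation", "n_anchors", "score"])


def syntenic_depth(
    blocks: list[SyntenicBlock],
    genes: pd.DataFrame,
    window: int = 20,
    self_synteny: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Windowed syntenic depth along a genome.

    Genes are grouped into consecutive non-overlapping windows of
    ``window`` order positions per chromosome; a window's depth is the
    number of blocks whose span overlaps it (for self-synteny both block
    sides count). Returns (per-window table, per-chromosome max depth,
    depth histogram as the fraction of windows at depth 1:k).
    """
    spans: list[tuple[str, int, int]] = []
    for b in blocks:
        spans.append((b.chrom_a, *b.span_a))
        if self_synteny:
            spans.append((b.chrom_b, *b.span_b))
    rows = []
    for chrom, grp in genes.groupby("chrom", sort=True):
        n = int(grp["order_index"].max()) + 1
        for start in range(0, n, window):
            end = min(start + window - 1, n - 1)
            depth = sum(
                1 for c, lo, hi in spans
                if c == chrom and lo <= end and hi >= start
            )
            rows.append({"chrom": chrom, "window_start": start,
                         "window_end": end, "depth": depth})
    table = pd.DataFrame(rows)
    per_chrom = table.groupby("chrom")["depth"].max().rename(
        "max_depth").reset_index()
    hist = (
        table["depth"].value_counts(normalize=True).sort_index()
        .rename("fraction").reset_index()
    )
    return table, per_chrom, hist


def syntenic_coverage(blocks: list[SyntenicBlock], genes: pd.DataFrame) -> float:
    """Length fraction of genes participating in at least one block."""
    lengths = genes["end"] - genes["start"] + 1
    total = float(lengths.sum())
    if total == 0:
        raise ValueError("zero total gene length")
    anchored: set[str] = set()
    for b in blocks:
        anchored.update(b.anchors["gene_a"])
        anchored.update(b.anchors["gene_b"])
    in_block = genes["gene_id"].isin(anchored)
    return float(lengths[in_block].sum()) / total
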