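"""Pseudo-testcross linkage mapping from RAD-style marker genotypes.

Markers heterozygous in one parent segregate 1:1 ('a' vs 'b') in the
progeny. Phase is unknown, so the recombination fraction between two
markers is r = min(m, n - m) / n over the n pairwise-complete progeny with
m discordant calls. Map distances use Haldane's function (no crossover
interference): d = -50 * ln(1 - 2r) cM.

Grouping links two markers when r <= r_max and the LOD score of linkage
(binomial likelihood ratio against r = 1/2) reaches a threshold; linkage
groups are the connected components. Completely linked markers (r = 0)
collapse into blocks, and blocks are ordered by minimizing the sum of
adjacent recombination fractions (exact dynamic program for small groups,
greedy seriation with 2-opt refinement otherwise) — a deliberately simple
stand-in for full maximum-likelihood map ordering, sufficient to recover
block order on planted data.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

CALL_A, CALL_B, MISSING = 0, 1, -1
_CALL_CODE = {"a": CALL_A, "b": CALL_B, "-": MISSING}
_CODE_CALL = {v: k for k, v in _CALL_CODE.items()}


@dataclass
class GenotypeTable:
    """Marker x progeny genotype calls for a pseudo-testcross.

    ``markers``: DataFrame with marker_id, scaffold_id, position (bp).
    ``calls``: int8 array (n_markers x n_progeny) over {0: a, 1: b,
    -1: missing}.
    """

    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        if len(self.markers) != self.calls.shape[0]:
            raise ValueError("marker table and call matrix row counts differ")

    @property
    def n_progeny(self) -> int:
        return self.calls.shape[1]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    def subset(self, index: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            markers=self.markers.iloc[index].reset_index(drop=True),
            calls=self.calls[index],
        )


@dataclass
class MarkerBlock:
    """Markers with identical segregation (up to global phase flip)."""

    marker_ids: list[str]
    pattern: np.ndarray  # consensus call vector
    position_cM: float = 0.0


@dataclass
class LinkageGroup:
    lg_id: str
    marker_ids: list[str]
    blocks: list[MarkerBlock] = field(default_factory=list)


_PROGENY_COL = re.compile(r"^p\d+$")


def write_genotype_tsv(gt: GenotypeTable, path) -> None:
    calls = np.vectorize(_CODE_CALL.get)(gt.calls)
    prog = pd.DataFrame(calls, columns=[f"p{j + 1:03d}"
                                        for j in range(gt.n_progeny)])
    pd.concat([gt.markers.reset_index(drop=True), prog], axis=1).to_csv(
        path, sep="\t", index=False)


def read_genotype_tsv(path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold_id": str})
    meta_cols = [c for c in df.columns if not _PROGENY_COL.match(c)]
    prog_cols = [c for c in df.columns if _PROGENY_COL.match(c)]
    calls = df[prog_cols].apply(lambda col: col.map(_CALL_CODE)).to_numpy(
        dtype=np.int8)
    return GenotypeTable(markers=df[meta_cols].copy(), calls=calls)


def filter_markers(gt: GenotypeTable, min_call_rate: float = 0.90) -> GenotypeTable:
    """Keep markers genotyped in at least ``min_call_rate`` of the progeny."""
    if not 0 < min_call_rate <= 1:
        raise ValueError("min_call_rate must be in (0, 1]")
    call_rate = (gt.calls != MISSING).mean(axis=1)
    keep = np.nonzero(call_rate >= min_call_rate)[0]
    return gt.subset(keep)


def recombination_fraction(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Phase-unknown recombination fraction over pairwise-complete progeny.

    Returns (r, n_informative); r is NaN when no progeny is informative.
    """
    ok = (x != MISSING) & (y != MISSING)
    n = int(ok.sum())
    if n == 0:
        return math.nan, 0
    m = int((x[ok] != y[ok]).sum())
    return min(m, n - m) / n, n


def haldane_distance(r: float) -> float:
    """Haldane map distance in cM: d = -50 ln(1 - 2r). Requires 0 <= r < 0.5."""
    if not 0 <= r < 0.5:
        raise ValueError(f"r = {r} out of Haldane domain [0, 0.5)")
    return -50.0 * math.log(1.0 - 2.0 * r)


def haldane_recombination(d_cM: float) -> float:
    """Inverse of haldane_distance: r = (1 - exp(-2d/100)) / 2."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cM / 100.0))


def _pairwise_r_lod(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs (r, LOD, n_informative) matrices, vectorized.

    LOD compares the binomial likelihood at r_hat = m/n (phase-resolved,
    m = min(discordant, concordant)) against independence (r = 1/2).
    """
    is_a = (calls == CALL_A).astype(np.float64)
    is_b = (calls == CALL_B).astype(np.float64)
    valid = is_a + is_b
    n = valid @ valid.T
    m = is_a @ is_b.T + is_b @ is_a.T  # discordant counts
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.minimum(m, n - m)
        r = np.where(n > 0, m / np.maximum(n, 1), np.nan)
        # log10 likelihood ratio: m*log10(r) + (n-m)*log10(1-r) + n*log10(2)
        term_m = np.where(m > 0, m * np.log10(np.where(r > 0, r, 1.0)), 0.0)
        term_nm = (n - m) * np.log10(np.where(r < 1, 1.0 - r, 1.0))
        lod = term_m + term_nm + n * math.log10(2.0)
    return r, lod, n


def group_markers(
    gt: GenotypeTable,
    r_max: float = 0.35,
    lod_min: float = 3.0,
    familywise: bool = True,
) -> tuple[list[LinkageGroup], list[str]]:
    """Linkage groups as connected components of the linkage graph.

    An edge joins two markers when r <= r_max and LOD >= lod_min. With
    hundreds of markers the number of pairwise tests is large enough that
    a per-test LOD threshold admits spurious cross-chromosome edges, any
    one of which fuses two groups; with ``familywise`` (default) the LOD
    threshold is therefore applied family-wise, raised by log10 of the
    number of pairs tested (a Bonferroni correction on the likelihood-
    ratio scale). Genuine within-group linkage is far stronger than any
    such threshold, so group connectivity is unaffected.

    Returns (groups, singletons); groups are sorted by decreasing size
    and named LG01, LG02, ...
    """
    r, lod, n = _pairwise_r_lod(gt.calls)
    n_pairs = gt.n_markers * (gt.n_markers - 1) / 2
    lod_cut = lod_min + (math.log10(n_pairs) if familywise and n_pairs > 1 else 0.0)
    adj = (r <= r_max) & (lod >= lod_cut) & (n > 0)
    np.fill_diagonal(adj, False)
    n_comp, labels = _cc(csr_matrix(adj), directed=False)
    ids = gt.markers["marker_id"].to_numpy()
    groups, singles = [], []
    for comp in range(n_comp):
        members = ids[labels == comp]
        if len(members) == 1:
            singles.append(str(members[0]))
        else:
            groups.append(list(map(str, members)))
    groups.sort(key=lambda g: (-len(g), g[0]))
    return (
        [LinkageGroup(lg_id=f"LG{i + 1:02d}", marker_ids=g)
         for i, g in enumerate(groups)],
        singles,
    )


def collapse_blocks(group: LinkageGroup, gt: GenotypeTable) -> LinkageGroup:
    """Merge completely linked markers (r = 0) into blocks.

    Block pattern is the consensus of the phase-aligned member vectors
    (missing filled from any non-missing member).
    """
    if not group.marker_ids:
        raise ValueError("cannot collapse an empty linkage group")
    idx_of = {m: i for i, m in enumerate(gt.markers["marker_id"])}
    rows = np.asarray([idx_of[m] for m in group.marker_ids])
    calls = gt.calls[rows]
    r, _, n = _pairwise_r_lod(calls)
    adj = (r == 0) & (n > 0)
    np.fill_diagonal(adj, True)
    n_comp, labels = _cc(csr_matrix(adj), directed=False)
    blocks = []
    for comp in range(n_comp):
        members = np.nonzero(labels == comp)[0]
        anchor = calls[members[0]].copy()
        pattern = anchor.copy()
        for row in members[1:]:
            vec = calls[row]
            ok = (vec != MISSING) & (anchor != MISSING)
            flip = ok.any() and (vec[ok] != anchor[ok]).mean() > 0.5
            aligned = np.where(vec == MISSING, MISSING,
                               1 - vec if flip else vec)
            fill = (pattern == MISSING) & (aligned != MISSING)
            pattern[fill] = aligned[fill]
        blocks.append(MarkerBlock(
            marker_ids=[group.marker_ids[i] for i in members],
            pattern=pattern.astype(np.int8),
        ))
    return replace(group, blocks=blocks)


def _block_r_matrix(blocks: list[MarkerBlock]) -> np.ndarray:
    calls = np.vstack([b.pattern for b in blocks])
    r, _, n = _pairwise_r_lod(calls)
    r = np.where(n > 0, r, 0.5)
    np.fill_diagonal(r, 0.0)
    return r


def _exact_path_order(r: np.ndarray) -> list[int]:
    """Minimum-weight Hamiltonian path by Held-Karp dynamic programming."""
    k = r.shape[0]
    full = (1 << k) - 1
    cost = {(1 << i, i): 0.0 for i in range(k)}
    parent: dict[tuple[int, int], int] = {}
    for mask in range(1, full + 1):
        for last in range(k):
            if not mask & (1 << last) or (mask, last) not in cost:
                continue
            base = cost[(mask, last)]
            for nxt in range(k):
                if mask & (1 << nxt):
                    continue
                new = (mask | (1 << nxt), nxt)
                cand = base + r[last, nxt]
                if cand < cost.get(new, math.inf):
                    cost[new] = cand
                    parent[new] = last
    last = min(range(k), key=lambda i: cost[(full, i)])
    order = [last]
    mask = full
    while (mask, order[-1]) in parent:
        prev = parent[(mask, order[-1])]
        mask ^= 1 << order[-1]
        order.append(prev)
    return order[::-1]


def _greedy_two_opt_order(r: np.ndarray) -> list[int]:
    k = r.shape[0]
    unvisited = set(range(1, k))
    order = [0]
    while unvisited:
        nxt = min(unvisited, key=lambda j: r[order[-1], j])
        order.append(nxt)
        unvisited.remove(nxt)

    def path_cost(o: list[int]) -> float:
        return sum(r[o[i], o[i + 1]] for i in range(len(o) - 1))

    improved = True
    while improved:
        improved = False
        for i, j in itertools.combinations(range(k), 2):
            cand = order[:i] + order[i:j + 1][::-1] + order[j + 1:]
            if path_cost(cand) < path_cost(order) - 1e-12:
                order = cand
                improved = True
    return order


def order_blocks(group: LinkageGroup, exact_limit: int = 10) -> LinkageGroup:
    """Order blocks minimizing the sum of adjacent recombination fractions.

    Exact Held-Karp search for <= ``exact_limit`` blocks, greedy
    nearest-neighbor with 2-opt refinement beyond. Positions are cumulative
    Haldane distances; the order is canonicalized so the first block holds
    the lexicographically smallest endpoint marker id.
    """
    if not group.blocks:
        raise ValueError("order_blocks needs collapsed blocks; run collapse_blocks")
    blocks = group.blocks
    if len(blocks) == 1:
        blocks[0].position_cM = 0.0
        return group
    r = _block_r_matrix(blocks)
    order = (_exact_path_order(r) if len(blocks) <= exact_limit
             else _greedy_two_opt_order(r))
    first_id = min(blocks[order[0]].marker_ids)
    last_id = min(blocks[order[-1]].marker_ids)
    if last_id < first_id:
        order = order[::-1]
    ordered = [blocks[i] for i in order]
    pos = 0.0
    ordered[0].position_cM = 0.0
    for prev, cur in itertools.pairwise(range(len(order))):
        rf = min(r[order[prev], order[cur]], 0.4999)
        pos += haldane_distance(rf)
        ordered[cur].position_cM = round(pos, 6)
    return replace(group, blocks=ordered)


def linkage_map_table(groups: list[LinkageGroup], gt: GenotypeTable) -> pd.DataFrame:
    """Flatten ordered groups into the linkage-map TSV layout."""
    meta = gt.markers.set_index("marker_id")
    rows = []
    for group in groups:
        for b_idx, block in enumerate(group.blocks):
            for marker in block.marker_ids:
                rows.append({
                    "lg_id": group.lg_id,
                    "block_index": b_idx,
                    "position_cM": block.position_cM,
                    "marker_id": marker,
                    "scaffold_id": meta.loc[marker, "scaffold_id"],
                    "scaffold_position": meta.loc[marker, "position"],
                })
    return pd.DataFrame(rows)


def build_linkage_map(
    gt: GenotypeTable,
    min_call_rate: float = 0.90,
    r_max: float = 0.35,
    lod_min: float = 3.0,
) -> tuple[pd.DataFrame, list[LinkageGroup], list[str]]:
    """Full pipeline: filter, group, collapse, order. Returns (map, groups,
    singletons)."""
    filtered = filter_markers(gt, min_call_rate)
    groups, singles = group_markers(filtered, r_max=r_max, lod_min=lod_min)
    ordered = [order_blocks(collapse_blocks(g, filtered)) for g in groups]
    return linkage_map_table(ordered, filtered), ordered, singles
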