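"""Reconcile a proximity-ligation scaffold ordering with a linkage map.

Proximity-guided assembly (LACHESIS-style clustering/ordering/orienting of
scaffolds from Hi-C contact maps) is accurate locally but can commit
large-scale errors, chiefly inversions of multi-scaffold segments. A
linkage map built from a genetic cross orders marker blocks correctly at
chromosome scale but at coarser resolution. This module combines the two:

* scaffolds are anchored to linkage groups (LGs) through their markers;
  scaffolds whose markers hit more than one LG are chimera candidates and
  are split at single-N junctions whenever possible;
* proximity clusters are matched one-to-one to LGs by maximizing shared bp;
* segments of scaffolds whose linkage ranks run backwards relative to the
  proximity order are detected and reversed when that strictly improves
  adjacent-pair concordance;
* every scaffold is assigned a confidence tier and per-tier bp accounting
  is emitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import kendalltau

from .genomeio import Scaffold, find_n_runs

TIERS = ("both_consistent", "proximity_only", "clustered_unordered", "unclustered")

UNORDERED = -1


@dataclass
class ProximityOrdering:
    """Per-scaffold cluster / order / orientation assignments.

    ``assignments``: DataFrame with scaffold_id, cluster_id,
    order_index (int; -1 for clustered-but-unordered), orientation in
    {+, -, ?}.
    """

    assignments: pd.DataFrame

    def __post_init__(self) -> None:
        ordered = self.assignments[self.assignments["order_index"] != UNORDERED]
        dup = ordered.duplicated(subset=["cluster_id", "order_index"])
        if dup.any():
            raise ValueError("duplicate order_index within a cluster")

    def cluster(self, cluster_id: str) -> pd.DataFrame:
        sub = self.assignments[self.assignments["cluster_id"] == cluster_id]
        ordered = sub[sub["order_index"] != UNORDERED].sort_values("order_index")
        unordered = sub[sub["order_index"] == UNORDERED]
        return pd.concat([ordered, unordered]).reset_index(drop=True)


def write_ordering_tsv(po: ProximityOrdering, path) -> None:
    po.assignments.to_csv(path, sep="\t", index=False)


def read_ordering_tsv(path) -> ProximityOrdering:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold_id": str, "cluster_id": str})
    return ProximityOrdering(assignments=df)


@dataclass
class LgAssignment:
    assigned: dict[str, str]                  # scaffold -> LG (unambiguous)
    conflicts: dict[str, pd.DataFrame]        # scaffold -> per-LG ranges
    unassigned: list[str] = field(default_factory=list)


def assign_scaffolds_to_lgs(
    marker_map: pd.DataFrame, all_scaffolds: list[str] | None = None
) -> LgAssignment:
    """Anchor scaffolds to LGs by their mapped markers.

    ``marker_map`` is the linkage-map table (lg_id, block_index,
    position_cM, marker_id, scaffold_id, scaffold_position). Scaffolds
    whose markers hit more than one LG are reported as conflicts with
    per-LG marker coordinate ranges (min/max bp, marker count), ordered by
    position on the scaffold.
    """
    assigned: dict[str, str] = {}
    conflicts: dict[str, pd.DataFrame] = {}
    for scaffold, grp in marker_map.groupby("scaffold_id"):
        lgs = grp["lg_id"].unique()
        if len(lgs) == 1:
            assigned[str(scaffold)] = str(lgs[0])
        else:
            ranges = (
                grp.groupby("lg_id")["scaffold_position"]
                .agg(start="min", end="max", n_markers="count")
                .reset_index()
                .sort_values("start")
                .reset_index(drop=True)
            )
            conflicts[str(scaffold)] = ranges
    unassigned = []
    if all_scaffolds is not None:
        seen = set(assigned) | set(conflicts)
        unassigned = [s for s in all_scaffolds if s not in seen]
    return LgAssignment(assigned=assigned, conflicts=conflicts,
                        unassigned=unassigned)


def _find_cut(sequence: str, lo: int, hi: int) -> int | None:
    """Best cut position (1-based) in the open interval (lo, hi).

    Prefers a lone N (neighbors not N); falls back to the midpoint of the
    first N-run; None when the interval contains no N.
    """
    window = sequence[lo:hi - 1]  # 0-based slice of positions lo+1 .. hi-1
    n = len(sequence)
    for i, base in enumerate(window):
        pos = lo + i  # 0-based position in sequence
        if base != "N":
            continue
        left_ok = pos == 0 or sequence[pos - 1] != "N"
        right_ok = pos == n - 1 or sequence[pos + 1] != "N"
        if left_ok and right_ok:
            return pos + 1
    runs = [
        (s, e) for s, e in find_n_runs(sequence, min_len=1)
        if s > lo and e < hi
    ]
    if runs:
        s, e = runs[0]
        return (s + e) // 2
    return None


@dataclass
class SplitResult:
    subscaffolds: list[Scaffold]
    report: pd.DataFrame  # sub_id, parent_id, parent_start, parent_end, lg_id
    resolved: bool


def split_chimeric_scaffold(
    scaffold: Scaffold, conflict_ranges: pd.DataFrame
) -> SplitResult:
    """Split a chimera candidate at N positions between its LG ranges.

    For each boundary between adjacent LG marker ranges, the scaffold is
    cut at a lone N within the boundary interval if one exists, else at
    the midpoint of the first N-run there. The cut base (an N) is removed
    from both parts. Subscaffolds are named ``<id>_1``, ``<id>_2``, ...
    left to right and inherit the LG of their markers. If any boundary
    interval contains no N the scaffold is left unsplit and flagged
    unresolved.
    """
    ranges = conflict_ranges.sort_values("start").reset_index(drop=True)
    if len(ranges) < 2:
        raise ValueError("split requires a conflict across >= 2 LGs")
    cuts: list[int] = []
    for i in range(len(ranges) - 1):
        lo = int(ranges.loc[i, "end"])
        hi = int(ranges.loc[i + 1, "start"])
        cut = _find_cut(scaffold.sequence, lo, hi)
        if cut is None:
            return SplitResult(
                subscaffolds=[scaffold],
                report=pd.DataFrame([{
                    "sub_id": scaffold.id, "parent_id": scaffold.id,
                    "parent_start": 1, "parent_end": scaffold.length,
                    "lg_id": "unresolved", "cut_position": np.nan,
                }]),
                resolved=False,
            )
        cuts.append(cut)
    bounds = [0] + cuts + [scaffold.length + 1]
    subs, rows = [], []
    for k in range(len(bounds) - 1):
        start = bounds[k] + 1       # skip the removed junction N
        end = bounds[k + 1] - 1
        sub_id = f"{scaffold.id}_{k + 1}"
        seq = scaffold.sequence[start - 1:end]
        subs.append(Scaffold(sub_id, seq))
        mids = ranges[(ranges["start"] >= start - 1) & (ranges["end"] <= end + 1)]
        lg = str(mids["lg_id"].iloc[0]) if len(mids) else ""
        rows.append({
            "sub_id": sub_id, "parent_id": scaffold.id,
            "parent_start": start, "parent_end": end, "lg_id": lg,
            "cut_position": cuts[k] if k < len(cuts) else np.nan,
        })
    return SplitResult(subscaffolds=subs, report=pd.DataFrame(rows), resolved=True)


def split_chimeras(
    scaffolds: dict[str, Scaffold],
    assignment: LgAssignment,
    marker_map: pd.DataFrame,
) -> tuple[dict[str, Scaffold], pd.DataFrame, pd.DataFrame]:
    """Apply chimera splitting across an assembly.

    Returns (updated scaffolds, updated marker map with marker coordinates
    lifted onto subscaffolds, split report).
    """
    new_scaffolds = dict(scaffolds)
    new_map = marker_map.copy()
    reports = []
    for sid, ranges in assignment.conflicts.items():
        result = split_chimeric_scaffold(scaffolds[sid], ranges)
        reports.append(result.report)
        if not result.resolved:
            continue
        del new_scaffolds[sid]
        for sub in result.subscaffolds:
            new_scaffolds[sub.id] = sub
        on_scaffold = new_map["scaffold_id"] == sid
        for row in result.report.itertuples(index=False):
            inside = (
                on_scaffold
                & (new_map["scaffold_position"] >= row.parent_start)
                & (new_map["scaffold_position"] <= row.parent_end)
            )
            new_map.loc[inside, "scaffold_id"] = row.sub_id
            new_map.loc[inside, "scaffold_position"] -= row.parent_start - 1
    report = (pd.concat(reports, ignore_index=True) if reports
              else pd.DataFrame(columns=["sub_id", "parent_id", "parent_start",
                                         "parent_end", "lg_id", "cut_position"]))
    return new_scaffolds, new_map, report


def apply_split_to_ordering(
    po: ProximityOrdering,
    split_report: pd.DataFrame,
    scaffold_lengths: dict[str, int],
) -> ProximityOrdering:
    """Carry proximity assignments of split scaffolds onto their largest part.

    The proximity ordering was computed on the unsplit assembly; after
    chimera splitting each parent's slot (cluster, order, orientation) is
    inherited by its largest subscaffold, which dominates the contact
    signal. The remaining parts enter the assembly as new, proximity-
    unplaced scaffolds.
    """
    df = po.assignments.copy()
    for parent, grp in split_report.groupby("parent_id"):
        subs = [s for s in grp["sub_id"] if s != parent]
        if not subs:
            continue
        largest = max(subs, key=lambda s: scaffold_lengths.get(s, 0))
        df.loc[df["scaffold_id"] == parent, "scaffold_id"] = largest
    return ProximityOrdering(assignments=df)


def map_clusters_to_lgs(
    po: ProximityOrdering,
    lg_of_scaffold: dict[str, str],
    scaffold_lengths: dict[str, int],
) -> pd.DataFrame:
    """One-to-one cluster-to-LG correspondence maximizing shared bp.

    Returns a DataFrame (cluster_id, lg_id, shared_bp, cluster_bp, purity);
    clusters with zero overlap to any LG get lg_id = "" (unmatched).
    """
    clusters = sorted(po.assignments["cluster_id"].unique())
    lgs = sorted(set(lg_of_scaffold.values()))
    shared = np.zeros((len(clusters), len(lgs)))
    cluster_bp = np.zeros(len(clusters))
    lg_idx = {lg: j for j, lg in enumerate(lgs)}
    for rec in po.assignments.itertuples(index=False):
        i = clusters.index(rec.cluster_id)
        bp = scaffold_lengths.get(rec.scaffold_id, 0)
        cluster_bp[i] += bp
        lg = lg_of_scaffold.get(rec.scaffold_id)
        if lg is not None:
            shared[i, lg_idx[lg]] += bp
    rows_i, cols_j = linear_sum_assignment(-shared)
    rows = []
    matched = {}
    for i, j in zip(rows_i, cols_j):
        if shared[i, j] > 0:
            matched[clusters[i]] = (lgs[j], shared[i, j])
    for i, cluster in enumerate(clusters):
        lg, bp = matched.get(cluster, ("", 0.0))
        rows.append({
            "cluster_id": cluster, "lg_id": lg, "shared_bp": int(bp),
            "cluster_bp": int(cluster_bp[i]),
            "purity": bp / cluster_bp[i] if cluster_bp[i] else math.nan,
        })
    return pd.DataFrame(rows)


def scaffold_linkage_ranks(marker_map: pd.DataFrame) -> pd.DataFrame:
    """Per-scaffold linkage rank: median block index of its markers per LG."""
    return (
        marker_map.groupby(["lg_id", "scaffold_id"])["block_index"]
        .median()
        .rename("linkage_rank")
        .reset_index()
    )


def _aligned_ranks(ordered: pd.DataFrame) -> np.ndarray:
    """Linkage ranks aligned to proximity direction (map reversal allowed)."""
    ranks = ordered["linkage_rank"].to_numpy(dtype=float)
    if len(ranks) >= 2:
        tau = kendalltau(np.arange(len(ranks)), ranks).statistic
        if tau is not None and not math.isnan(tau) and tau < 0:
            ranks = -ranks
    return ranks


def compare_orderings(
    po: ProximityOrdering,
    marker_map: pd.DataFrame,
    correspondence: pd.DataFrame,
) -> pd.DataFrame:
    """Per-LG concordance between proximity order and linkage block order.

    Kendall tau-b over scaffolds ordered by both methods (scaffolds within
    one linkage block are order-tied). Reports the count of discordant
    adjacent pairs in proximity order.
    """
    ranks = scaffold_linkage_ranks(marker_map)
    rows = []
    for rec in correspondence.itertuples(index=False):
        if not rec.lg_id:
            continue
        cluster = po.cluster(rec.cluster_id)
        cluster = cluster[cluster["order_index"] != UNORDERED]
        merged = cluster.merge(
            ranks[ranks["lg_id"] == rec.lg_id], on="scaffold_id", how="inner"
        ).sort_values("order_index")
        if len(merged) < 2:
            rows.append({"lg_id": rec.lg_id, "cluster_id": rec.cluster_id,
                         "n_common": len(merged), "tau": math.nan,
                         "n_discordant_adjacent": 0})
            continue
        rank = merged["linkage_rank"].to_numpy(dtype=float)
        tau = kendalltau(np.arange(len(rank)), rank).statistic
        disc = int(np.sum(np.diff(rank) < 0))
        if tau is not None and tau < 0:  # map direction is arbitrary
            disc = int(np.sum(np.diff(-rank) < 0))
        rows.append({"lg_id": rec.lg_id, "cluster_id": rec.cluster_id,
                     "n_common": len(merged), "tau": tau,
                     "n_discordant_adjacent": disc})
    return pd.DataFrame(rows)


def _concordant_adjacent(ranks: np.ndarray) -> int:
    return int(np.sum(np.diff(ranks) >= 0))


def detect_inversions(
    ordered: pd.DataFrame, min_segment: int = 2
) -> list[tuple[int, int]]:
    """Inverted segments in one cluster's proximity order.

    ``ordered`` must contain scaffold_id and linkage_rank sorted by
    proximity order. Returns (start, end) index pairs (inclusive, 0-based)
    of maximal runs of >= ``min_segment`` scaffolds whose linkage ranks
    decrease (ties — co-segregating scaffolds — never break a run but are
    not evidence on their own), kept only when reversing the run strictly
    increases the count of concordant adjacent pairs.
    """
    ranks = _aligned_ranks(ordered)
    n = len(ranks)
    segments = []
    i = 0
    while i < n - 1:
        if ranks[i + 1] > ranks[i]:
            i += 1
            continue
        j = i
        has_strict = False
        while j < n - 1 and ranks[j + 1] <= ranks[j]:
            if ranks[j + 1] < ranks[j]:
                has_strict = True
            j += 1
        if has_strict and j - i + 1 >= min_segment:
            base = _concordant_adjacent(ranks)
            flipped = ranks.copy()
            flipped[i:j + 1] = flipped[i:j + 1][::-1]
            if _concordant_adjacent(flipped) > base:
                segments.append((i, j))
        i = j if j > i else i + 1
    return segments


_FLIP = {"+": "-", "-": "+", "?": "?"}


@dataclass
class ReconciledAssembly:
    """Final tiered chromosome-scale ordering with accounting."""

    ordering: pd.DataFrame    # lg_id, rank, scaffold_id, orientation, tier
    accounting: pd.DataFrame  # tier, n_scaffolds, total_bp
    inversions: pd.DataFrame  # lg_id, segment scaffold ids
    correspondence: pd.DataFrame


def reconcile(
    po: ProximityOrdering,
    marker_map: pd.DataFrame,
    scaffolds: dict[str, Scaffold],
    min_segment: int = 2,
) -> ReconciledAssembly:
    """Correct the proximity ordering against the linkage map and tier it.

    Base order and orientation come from the proximity ordering; detected
    inversion segments are reversed (order and orientations flipped;
    unknown orientations stay unknown). Tiers: ``both_consistent``
    (ordered by both methods, no residual adjacent discordance),
    ``proximity_only`` (ordered by proximity; absent from the map, or
    residually discordant with it), ``clustered_unordered``,
    ``unclustered``. Scaffolds from unresolved chimeras are excluded from
    ``both_consistent`` upstream (they remain conflicted in the map).
    """
    assignment = assign_scaffolds_to_lgs(marker_map)
    lengths = {sid: s.length for sid, s in scaffolds.items()}
    correspondence = map_clusters_to_lgs(po, assignment.assigned, lengths)
    ranks = scaffold_linkage_ranks(marker_map)
    conflicted = set(assignment.conflicts)

    order_rows, inv_rows = [], []
    for rec in correspondence.itertuples(index=False):
        lg_label = rec.lg_id or rec.cluster_id
        cluster = po.cluster(rec.cluster_id)
        ordered = cluster[cluster["order_index"] != UNORDERED].copy()
        unordered = cluster[cluster["order_index"] == UNORDERED]

        lg_ranks = ranks[ranks["lg_id"] == rec.lg_id] if rec.lg_id else ranks.iloc[:0]
        ordered = ordered.merge(lg_ranks[["scaffold_id", "linkage_rank"]],
                                on="scaffold_id", how="left")
        have = ordered.dropna(subset=["linkage_rank"]).reset_index(drop=True)
        segs = detect_inversions(have, min_segment=min_segment) if len(have) >= 2 else []

        # reverse each detected segment in the full ordered list
        ids = ordered["scaffold_id"].tolist()
        orients = ordered["orientation"].tolist()
        for s, e in segs:
            seg_ids = have["scaffold_id"].iloc[s:e + 1].tolist()
            lo = ids.index(seg_ids[0])
            hi = ids.index(seg_ids[-1])
            ids[lo:hi + 1] = ids[lo:hi + 1][::-1]
            orients[lo:hi + 1] = [_FLIP[o] for o in orients[lo:hi + 1]][::-1]
            inv_rows.append({"lg_id": lg_label, "scaffold_ids": ",".join(seg_ids)})

        # residual discordance after correction
        rank_of = dict(zip(have["scaffold_id"], _aligned_ranks(have)))
        seq = [(sid, rank_of[sid]) for sid in ids if sid in rank_of]
        residual: set[str] = set()
        for (a, ra), (b, rb) in zip(seq, seq[1:]):
            if rb < ra:
                residual.update((a, b))

        for rank_i, (sid, orient) in enumerate(zip(ids, orients)):
            if sid in rank_of and sid not in residual and sid not in conflicted:
                tier = "both_consistent"
            else:
                tier = "proximity_only"
            order_rows.append({"lg_id": lg_label, "rank": rank_i,
                               "scaffold_id": sid, "orientation": orient,
                               "tier": tier})
        for rec2 in unordered.itertuples(index=False):
            order_rows.append({"lg_id": lg_label, "rank": UNORDERED,
                               "scaffold_id": rec2.scaffold_id,
                               "orientation": rec2.orientation,
                               "tier": "clustered_unordered"})

    in_po = set(po.assignments["scaffold_id"])
    for sid in sorted(set(scaffolds) - in_po):
        order_rows.append({"lg_id": "", "rank": UNORDERED, "scaffold_id": sid,
                           "orientation": "?", "tier": "unclustered"})

    ordering = pd.DataFrame(order_rows)
    acct_rows = []
    for tier in TIERS:
        sub = ordering[ordering["tier"] == tier]
        acct_rows.append({
            "tier": tier,
            "n_scaffolds": len(sub),
            "total_bp": int(sum(lengths.get(s, 0) for s in sub["scaffold_id"])),
        })
    acct_rows.append({
        "tier": "total",
        "n_scaffolds": len(ordering),
        "total_bp": int(sum(lengths.get(s, 0) for s in ordering["scaffold_id"])),
    })
    return ReconciledAssembly(
        ordering=ordering,
        accounting=pd.DataFrame(acct_rows),
        inversions=pd.DataFrame(inv_rows, columns=["lg_id", "scaffold_ids"]),
        correspondence=correspondence,
    )
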