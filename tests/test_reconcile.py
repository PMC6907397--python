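import math

import numpy as np
import pandas as pd
import pytest

from paleoscaf.genomeio import Scaffold
from paleoscaf.linkage import build_linkage_map, filter_markers
from paleoscaf.reconcile import (
    ProximityOrdering,
    apply_split_to_ordering,
    assign_scaffolds_to_lgs,
    compare_orderings,
    detect_inversions,
    map_clusters_to_lgs,
    reconcile,
    split_chimeras,
    split_chimeric_scaffold,
)
from paleoscaf.synthetic_data import lift_genotype_to_scaffolds, simulate_cross


def _marker_map(rows):
    return pd.DataFrame(rows, columns=[
        "lg_id", "block_index", "position_cM", "marker_id", "scaffold_id",
        "scaffold_position"])


class TestAssignment:
    def test_unambiguous_scaffold(self):
        lmap = _marker_map([("LG2", 0, 0.0, f"m{i}", "s1", 100 * i)
                            for i in range(3)])
        result = assign_scaffolds_to_lgs(lmap)
        assert result.assigned == {"s1": "LG2"}
        assert not result.conflicts

    def test_conflicting_scaffold_recorded_with_ranges(self):
        lmap = _marker_map([
            ("LG2", 0, 0.0, "m1", "s1", 100),
            ("LG2", 1, 5.0, "m2", "s1", 900),
            ("LG7", 0, 0.0, "m3", "s1", 5000),
        ])
        result = assign_scaffolds_to_lgs(lmap)
        assert "s1" not in result.assigned
        ranges = result.conflicts["s1"]
        assert ranges["lg_id"].tolist() == ["LG2", "LG7"]
        assert ranges.loc[0, ["start", "end"]].tolist() == [100, 900]

    def test_markerless_scaffold_unassigned(self):
        lmap = _marker_map([("LG1", 0, 0.0, "m1", "s1", 10)])
        result = assign_scaffolds_to_lgs(lmap, all_scaffolds=["s1", "s2"])
        assert result.unassigned == ["s2"]


class TestChimeraSplit:
    def _conflict(self, *rows):
        return pd.DataFrame(list(rows), columns=["lg_id", "start", "end",
                                                 "n_markers"])

    def test_split_at_lone_n(self):
        seq = "A" * 100 + "N" + "G" * 100
        scaffold = Scaffold("s1", seq)
        conflict = self._conflict(("LG1", 10, 60, 2), ("LG2", 150, 190, 2))
        result = split_chimeric_scaffold(scaffold, conflict)
        assert result.resolved
        assert [s.sequence for s in result.subscaffolds] == ["A" * 100, "G" * 100]
        assert [s.id for s in result.subscaffolds] == ["s1_1", "s1_2"]
        assert "N" not in "".join(s.sequence for s in result.subscaffolds)

    def test_no_n_in_interval_unresolved(self):
        scaffold = Scaffold("s1", "A" * 100 + "G" * 100)
        conflict = self._conflict(("LG1", 10, 60, 2), ("LG2", 150, 190, 2))
        result = split_chimeric_scaffold(scaffold, conflict)
        assert not result.resolved
        assert result.subscaffolds == [scaffold]

    def test_lone_n_preferred_over_run(self):
        # N-run at 81-130, lone N at 160: cut must use the lone N
        seq = "A" * 80 + "N" * 50 + "C" * 29 + "N" + "G" * 40
        scaffold = Scaffold("s1", seq)
        conflict = self._conflict(("LG1", 10, 50, 2), ("LG2", 170, 195, 2))
        result = split_chimeric_scaffold(scaffold, conflict)
        assert result.resolved
        assert result.report["cut_position"].dropna().tolist() == [160]

    def test_run_midpoint_fallback(self):
        seq = "A" * 80 + "N" * 51 + "G" * 80
        scaffold = Scaffold("s1", seq)
        conflict = self._conflict(("LG1", 10, 50, 2), ("LG2", 150, 200, 2))
        result = split_chimeric_scaffold(scaffold, conflict)
        assert result.resolved
        cut = result.report["cut_position"].dropna().iloc[0]
        assert 81 <= cut <= 131  # inside the run, near the middle
        assert abs(cut - 106) <= 1


class TestClusterMapping:
    def _po(self, assignments):
        return ProximityOrdering(assignments=pd.DataFrame(
            assignments, columns=["scaffold_id", "cluster_id", "order_index",
                                  "orientation"]))

    def test_identity_mapping(self):
        po = self._po([("s1", "c1", 0, "+"), ("s2", "c2", 0, "+")])
        table = map_clusters_to_lgs(po, {"s1": "LG1", "s2": "LG2"},
                                    {"s1": 100, "s2": 100})
        assert dict(zip(table["cluster_id"], table["lg_id"])) == \
            {"c1": "LG1", "c2": "LG2"}
        assert (table["purity"] == 1.0).all()

    def test_label_permutation_recovered(self):
        po = self._po([(f"s{i}", f"c{(i + 1) % 4}", 0, "+") for i in range(4)])
        lg_of = {f"s{i}": f"LG{i}" for i in range(4)}
        lengths = {f"s{i}": 50 for i in range(4)}
        table = map_clusters_to_lgs(po, lg_of, lengths)
        mapping = dict(zip(table["cluster_id"], table["lg_id"]))
        assert mapping == {f"c{(i + 1) % 4}": f"LG{i}" for i in range(4)}

    def test_majority_bp_wins_with_purity(self):
        po = self._po([("s1", "c1", 0, "+"), ("s2", "c1", 1, "+")])
        table = map_clusters_to_lgs(
            po, {"s1": "LG1", "s2": "LG2"}, {"s1": 60, "s2": 40})
        assert table.loc[0, "lg_id"] == "LG1"
        assert table.loc[0, "purity"] == pytest.approx(0.6)


def _tau_brute(x, y):
    """Kendall tau-b by direct pair enumeration (independent oracle)."""
    n = len(x)
    conc = disc = tie_x = tie_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tie_x += 1
                tie_y += 1
            elif dx == 0:
                tie_x += 1
            elif dy == 0:
                tie_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / math.sqrt((n0 - tie_x) * (n0 - tie_y))


class TestCompareOrderings:
    def _setup(self, ranks):
        po = ProximityOrdering(assignments=pd.DataFrame(
            [(f"s{i}", "c1", i, "+") for i in range(len(ranks))],
            columns=["scaffold_id", "cluster_id", "order_index", "orientation"]))
        lmap = _marker_map([
            ("LG1", rank, 0.0, f"m{i}", f"s{i}", 10)
            for i, rank in enumerate(ranks)])
        corr = pd.DataFrame([{"cluster_id": "c1", "lg_id": "LG1",
                              "shared_bp": 1, "cluster_bp": 1, "purity": 1.0}])
        return po, lmap, corr

    def test_identical_orders_tau_one(self):
        po, lmap, corr = self._setup(list(range(8)))
        report = compare_orderings(po, lmap, corr)
        assert report.loc[0, "tau"] == pytest.approx(1.0)

    def test_reversed_order_tau_minus_one(self):
        po, lmap, corr = self._setup(list(range(8))[::-1])
        report = compare_orderings(po, lmap, corr)
        assert report.loc[0, "tau"] == pytest.approx(-1.0)

    def test_tau_matches_brute_force(self, rng):
        ranks = list(rng.permutation(20))
        ranks[5:9] = ranks[5:9][::-1]
        po, lmap, corr = self._setup(ranks)
        report = compare_orderings(po, lmap, corr)
        assert report.loc[0, "tau"] == pytest.approx(
            _tau_brute(list(range(20)), ranks), abs=1e-12)


class TestDetectInversions:
    def _frame(self, ranks):
        return pd.DataFrame({
            "scaffold_id": [f"s{i}" for i in range(len(ranks))],
            "linkage_rank": ranks,
        })

    def test_concordant_no_inversions(self):
        assert detect_inversions(self._frame([0, 1, 2, 3, 4])) == []

    def test_planted_reversal_found(self):
        # proximity order s0..s5 with ranks 0,1,[4,3,2],5
        segs = detect_inversions(self._frame([0, 1, 4, 3, 2, 5]))
        assert segs == [(2, 4)]

    def test_ties_are_not_evidence(self):
        # two scaffolds in one linkage block, either order: no call
        assert detect_inversions(self._frame([0, 1, 1, 2])) == []
        assert detect_inversions(self._frame([1, 1])) == []

    def test_whole_group_reversal_is_map_orientation(self):
        # a fully reversed group reflects arbitrary map direction, not error
        assert detect_inversions(self._frame([5, 4, 3, 2, 1, 0])) == []


@pytest.fixture(scope="module")
def pipeline(flat_genome, corrupted_assembly):
    genome, _ = flat_genome
    assembly, po, truth = corrupted_assembly
    gt, _ = simulate_cross(genome, 110, 50, seed=5)
    gts = filter_markers(lift_genotype_to_scaffolds(gt, assembly))
    lmap, _, _ = build_linkage_map(gts)
    assignment = assign_scaffolds_to_lgs(lmap)
    scaffolds, lmap2, report = split_chimeras(
        dict(assembly.scaffolds), assignment, lmap)
    po2 = apply_split_to_ordering(
        po, report, {s: sc.length for s, sc in scaffolds.items()})
    result = reconcile(po2, lmap2, scaffolds)
    return assembly, truth, scaffolds, report, result, po2, lmap2


class TestReconcileEndToEnd:
    def test_chimeric_junctions_split_within_1kb(self, pipeline):
        _, truth, _, report, _, _, _ = pipeline
        junctions = truth.chimeric_joins.set_index("scaffold_id")[
            "junction_position"]
        hits = 0
        for parent, grp in report.groupby("parent_id"):
            cuts = grp["cut_position"].dropna()
            if parent in junctions.index and len(cuts):
                if min(abs(cuts - junctions[parent])) <= 1000:
                    hits += 1
        assert hits / len(junctions) >= 0.95

    def test_planted_inversions_corrected(self, pipeline):
        assembly, truth, scaffolds, report, result, _, _ = pipeline
        replacement = {}
        for parent, grp in report.groupby("parent_id"):
            subs = [s for s in grp["sub_id"] if s != parent and s in scaffolds]
            if subs:
                replacement[parent] = max(subs, key=lambda s: scaffolds[s].length)
        corrected = 0
        for rec in truth.planted_inversions.itertuples(index=False):
            ids = [replacement.get(s, s) for s in rec.scaffold_ids.split(",")]
            sub = result.ordering[result.ordering["scaffold_id"].isin(ids)]
            sub = sub[sub["rank"] != -1].sort_values("rank")
            got = sub["scaffold_id"].tolist()
            if got == ids or got == ids[::-1]:
                corrected += 1
        assert corrected == len(truth.planted_inversions)

    def test_tier_accounting_conserves_totals(self, pipeline):
        _, _, scaffolds, _, result, _, _ = pipeline
        acct = result.accounting.set_index("tier")
        tiers = acct.drop(index="total")
        assert tiers["n_scaffolds"].sum() == acct.loc["total", "n_scaffolds"]
        assert tiers["total_bp"].sum() == acct.loc["total", "total_bp"]
        assert acct.loc["total", "total_bp"] == \
            sum(s.length for s in scaffolds.values())
        # every scaffold appears exactly once
        assert result.ordering["scaffold_id"].is_unique
        assert set(result.ordering["scaffold_id"]) == set(scaffolds)

    def test_planted_error_recovery_across_seeds(self):
        """23 chimeras split within 1 kb and all inversions corrected,
        aggregated over 20 independent simulations."""
        from paleoscaf.synthetic_data import (SimConfig, fragment_and_corrupt,
                                              simulate_proximity_ordering,
                                              simulate_wgd_genome)
        junction_hits = junction_total = 0
        inv_hits = inv_total = 0
        for seed in range(20):
            config = SimConfig(n_chromosomes=13, genes_per_chromosome=20,
                               wgd_events=[], seed=seed)
            genome, _ = simulate_wgd_genome(config)
            assembly, truth = fragment_and_corrupt(genome, 1500, 23,
                                                   seed=seed + 100)
            po, truth = simulate_proximity_ordering(assembly, truth, 3,
                                                    seed=seed + 200)
            gt, _ = simulate_cross(genome, 110, 50, seed=seed + 300)
            gts = filter_markers(lift_genotype_to_scaffolds(gt, assembly))
            lmap, _, _ = build_linkage_map(gts)
            assignment = assign_scaffolds_to_lgs(lmap)
            scaffolds, lmap2, report = split_chimeras(
                dict(assembly.scaffolds), assignment, lmap)
            po2 = apply_split_to_ordering(
                po, report, {s: sc.length for s, sc in scaffolds.items()})
            result = reconcile(po2, lmap2, scaffolds)

            junctions = truth.chimeric_joins.set_index("scaffold_id")[
                "junction_position"]
            junction_total += len(junctions)
            for parent, grp in report.groupby("parent_id"):
                cuts = grp["cut_position"].dropna()
                if parent in junctions.index and len(cuts) and \
                        min(abs(cuts - junctions[parent])) <= 1000:
                    junction_hits += 1

            replacement = {}
            for parent, grp in report.groupby("parent_id"):
                subs = [s for s in grp["sub_id"]
                        if s != parent and s in scaffolds]
                if subs:
                    replacement[parent] = max(
                        subs, key=lambda s: scaffolds[s].length)
            for rec in truth.planted_inversions.itertuples(index=False):
                inv_total += 1
                ids = [replacement.get(s, s)
                       for s in rec.scaffold_ids.split(",")]
                sub = result.ordering[
                    result.ordering["scaffold_id"].isin(ids)]
                sub = sub[sub["rank"] != -1].sort_values("rank")
                got = sub["scaffold_id"].tolist()
                if got == ids or got == ids[::-1]:
                    inv_hits += 1
        assert junction_hits / junction_total >= 0.95
        assert inv_hits == inv_total

    def test_reconcile_idempotent(self, pipeline):
        _, _, scaffolds, _, result, _, lmap2 = pipeline
        placed = result.ordering[result.ordering["rank"] != -1]
        po_again = ProximityOrdering(assignments=pd.DataFrame({
            "scaffold_id": placed["scaffold_id"],
            "cluster_id": placed["lg_id"],
            "order_index": placed["rank"],
            "orientation": placed["orientation"],
        }))
        second = reconcile(po_again, lmap2, scaffolds)
        assert len(second.inversions) == 0
        merged = placed.merge(
            second.ordering, on="scaffold_id", suffixes=("_1", "_2"))
        assert (merged["rank_1"] == merged["rank_2"]).all()
        assert (merged["orientation_1"] == merged["orientation_2"]).all()
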