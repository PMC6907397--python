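import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleoscaf.synteny import (
    chain_collinear_blocks,
    collapse_tandem,
    filter_anchors,
    syntenic_coverage,
    syntenic_depth,
)


def _genes(n_per_chrom, chroms, length=300):
    rows = []
    for chrom in chroms:
        for i in range(n_per_chrom):
            rows.append({"gene_id": f"{chrom}_g{i}", "chrom": chrom,
                         "order_index": i, "start": 1 + i * 1000,
                         "end": length + i * 1000, "strand": "+"})
    return pd.DataFrame(rows)


def _anchors(pairs, chrom_a="c1", chrom_b="c2", score=10.0):
    return pd.DataFrame([{
        "gene_a": f"{chrom_a}_g{a}", "gene_b": f"{chrom_b}_g{b}",
        "score": score, "evalue": 1e-10,
        "chrom_a": chrom_a, "order_a": a, "chrom_b": chrom_b, "order_b": b,
    } for a, b in pairs])


class TestFilterAnchors:
    def test_evalue_cutoff(self):
        genes = _genes(5, ["c1", "c2"])
        hits = pd.DataFrame([
            ("c1_g0", "c2_g0", 50.0, 1e-5),
            ("c1_g1", "c2_g1", 50.0, 1e-3),
        ], columns=["gene_a", "gene_b", "score", "evalue"])
        out = filter_anchors(hits, genes)
        assert out["gene_a"].tolist() == ["c1_g0"]

    def test_self_hit_removed(self):
        genes = _genes(3, ["c1"])
        hits = pd.DataFrame([("c1_g0", "c1_g0", 99.0, 1e-20)],
                            columns=["gene_a", "gene_b", "score", "evalue"])
        assert filter_anchors(hits, genes).empty

    def test_symmetric_duplicates_collapsed(self):
        genes = _genes(10, ["c1"])
        hits = pd.DataFrame([
            ("c1_g0", "c1_g8", 50.0, 1e-9),
            ("c1_g8", "c1_g0", 50.0, 1e-9),
        ], columns=["gene_a", "gene_b", "score", "evalue"])
        assert len(filter_anchors(hits, genes)) == 1

    def test_unknown_gene_raises(self):
        genes = _genes(2, ["c1"])
        hits = pd.DataFrame([("c1_g0", "nope", 5.0, 1e-9)],
                            columns=["gene_a", "gene_b", "score", "evalue"])
        with pytest.raises(KeyError):
            filter_anchors(hits, genes)

    def test_tandem_self_anchors_dropped(self):
        anchors = _anchors([(0, 3), (0, 50)], chrom_a="c1", chrom_b="c1")
        out = collapse_tandem(anchors)
        assert out["order_b"].tolist() == [50]


def _brute_best_chain(order_a, order_b, scores, max_gap, gap_penalty):
    """Exhaustive chain enumeration (oracle for small anchor sets)."""
    n = len(order_a)
    best = 0.0
    for size in range(1, n + 1):
        for subset in itertools.combinations(range(n), size):
            sub = sorted(subset, key=lambda i: (order_a[i], order_b[i]))
            ok = True
            score = scores[sub[0]]
            for p, q in zip(sub, sub[1:]):
                ga = order_a[q] - order_a[p] - 1
                gb = order_b[q] - order_b[p] - 1
                if ga < 0 or gb < 0 or ga > max_gap or gb > max_gap or \
                        order_a[q] == order_a[p] or order_b[q] == order_b[p]:
                    ok = False
                    break
                score += scores[q] - gap_penalty * (ga + gb)
            if ok and score > best:
                best = score
    return best


class TestChaining:
    def test_ten_anchor_diagonal_single_parallel_block(self):
        blocks = chain_collinear_blocks(_anchors([(i, i) for i in range(10)]))
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 10
        assert blocks[0].orientation == "parallel"

    def test_four_anchor_diagonal_below_minimum(self):
        blocks = chain_collinear_blocks(_anchors([(i, i) for i in range(4)]))
        assert blocks == []

    def test_antiparallel_block_detected(self):
        pairs = [(i, 9 - i) for i in range(10)]
        blocks = chain_collinear_blocks(_anchors(pairs))
        assert len(blocks) == 1
        assert blocks[0].orientation == "antiparallel"

    def test_forty_one_gene_gap_never_merged(self):
        pairs = [(i, i) for i in range(5)]
        pairs += [(i + 46, i + 46) for i in range(5)]  # gap of 41 genes
        blocks = chain_collinear_blocks(_anchors(pairs))
        assert len(blocks) == 2
        assert all(b.n_anchors == 5 for b in blocks)

    def test_forty_gene_gap_within_reach(self):
        # a 40-gene gap is traversable (only 41 is excluded); with no gap
        # penalty the two runs chain into one block
        pairs = [(i, i) for i in range(5)]
        pairs += [(i + 45, i + 45) for i in range(5)]  # gap of exactly 40
        blocks = chain_collinear_blocks(_anchors(pairs), gap_penalty=0.0)
        assert len(blocks) == 1 and blocks[0].n_anchors == 10

    def test_nearby_runs_merge_into_one_chain(self):
        pairs = [(i, i) for i in range(5)] + [(i + 8, i + 8) for i in range(5)]
        blocks = chain_collinear_blocks(_anchors(pairs))
        assert len(blocks) == 1 and blocks[0].n_anchors == 10

    def test_chain_score_matches_exhaustive_oracle(self, rng):
        for _ in range(5):
            n = 9
            pairs = list(zip(rng.integers(0, 30, n), rng.integers(0, 30, n)))
            anchors = _anchors(pairs).drop_duplicates(["order_a", "order_b"])
            blocks = chain_collinear_blocks(anchors, min_anchors=1)
            for orientation, sign in [("parallel", 1), ("antiparallel", -1)]:
                ours = max((b.score for b in blocks
                            if b.orientation == orientation), default=0.0)
                brute = _brute_best_chain(
                    anchors["order_a"].to_numpy(),
                    sign * anchors["order_b"].to_numpy(),
                    anchors["score"].to_numpy(), 40, 1.0)
                assert ours == pytest.approx(brute)

    def test_cross_genome_symmetry(self, rng):
        pairs = [(i, i + 2) for i in range(8)] + [(20 + i, 3 * i) for i in range(6)]
        fwd = _anchors(pairs)
        rev = fwd.rename(columns={
            "gene_a": "gene_b", "gene_b": "gene_a", "chrom_a": "chrom_b",
            "chrom_b": "chrom_a", "order_a": "order_b", "order_b": "order_a"})
        blocks_fwd = chain_collinear_blocks(fwd)
        blocks_rev = chain_collinear_blocks(rev)
        assert len(blocks_fwd) == len(blocks_rev)
        for bf, br in zip(blocks_fwd, blocks_rev):
            assert bf.span_a == br.span_b and bf.span_b == br.span_a
            assert bf.n_anchors == br.n_anchors

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([10, 20, 40]),
           st.sampled_from([5, 7]))
    def test_tighter_settings_never_gain_anchors(self, seed, max_gap, min_anchors):
        rng = np.random.default_rng(seed)
        n = 25
        pairs = list(zip(rng.integers(0, 60, n), rng.integers(0, 60, n)))
        anchors = _anchors(pairs).drop_duplicates(["order_a", "order_b"])
        loose = sum(b.n_anchors for b in chain_collinear_blocks(
            anchors, max_gap_genes=40, min_anchors=5))
        tight = sum(b.n_anchors for b in chain_collinear_blocks(
            anchors, max_gap_genes=max_gap, min_anchors=min_anchors))
        assert tight <= loose


class TestDepthAndCoverage:
    def test_single_region_pair_depth_one(self):
        genes = _genes(30, ["c1", "c2"])
        blocks = chain_collinear_blocks(_anchors([(i, i) for i in range(8)]))
        table, per_chrom, _ = syntenic_depth(blocks, genes, window=20)
        assert per_chrom.set_index("chrom").loc["c1", "max_depth"] == 1

    def test_no_blocks_all_zero(self):
        genes = _genes(30, ["c1"])
        table, per_chrom, _ = syntenic_depth([], genes, window=20)
        assert (table["depth"] == 0).all()

    def test_planted_five_copy_region(self):
        from paleoscaf.synthetic_data import (
            SimConfig, copy_segment_to_chromosomes, make_truth_anchors,
            simulate_wgd_genome)
        config = SimConfig(n_chromosomes=6, genes_per_chromosome=60,
                           wgd_events=[], seed=1)
        genome, truth = simulate_wgd_genome(config)
        genome, truth = copy_segment_to_chromosomes(
            genome, truth, "chr01", 10, 30,
            ["chr02", "chr03", "chr04", "chr05", "chr06"],
            retention_rate=0.8, seed=1)
        hits = make_truth_anchors(genome, truth)
        anchors = collapse_tandem(filter_anchors(hits, genome.genes))
        blocks = chain_collinear_blocks(anchors)
        _, per_chrom, _ = syntenic_depth(blocks, genome.genes, window=20)
        assert per_chrom["max_depth"].max() == 5
        assert per_chrom.set_index("chrom").loc["chr01", "max_depth"] == 5

    def test_all_blocks_meet_anchor_minimum(self, rng):
        # settings compliance on random anchor sets
        for _ in range(5):
            n = 60
            pairs = list(zip(rng.integers(0, 80, n), rng.integers(0, 80, n)))
            anchors = _anchors(pairs).drop_duplicates(["order_a", "order_b"])
            for block in chain_collinear_blocks(anchors):
                assert block.n_anchors >= 5

    def test_coverage_half(self):
        genes = _genes(10, ["c1", "c2"])
        blocks = chain_collinear_blocks(_anchors([(i, i) for i in range(5)]))
        # 5 genes anchored on each side = 10 of 20 equal-length genes
        assert syntenic_coverage(blocks, genes) == pytest.approx(0.5)

    def test_no_blocks_zero_coverage(self):
        assert syntenic_coverage([], _genes(5, ["c1"])) == 0.0

    def test_zero_gene_length_raises(self):
        genes = pd.DataFrame(columns=["gene_id", "chrom", "order_index",
                                      "start", "end", "strand"])
        with pytest.raises(ValueError):
            syntenic_coverage([], genes)
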