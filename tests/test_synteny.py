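"""Anchor filtering, chain scoring vs exhaustive oracle, rearrangements."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from d2finemap.synteny import (best_chain_score, chain_blocks,
                               detect_rearrangements, dotplot_data,
                               filter_anchors, pair_score, project_interval)
from d2finemap.synthdata import simulate_anchor_tables


def anchors_frame(pos_a, pos_b, evalues, chr_a="A1", chr_b="B1"):
    n = len(pos_a)
    return pd.DataFrame({
        "gene_a": [f"ga{i}" for i in range(n)], "chr_a": chr_a,
        "pos_a": pos_a,
        "gene_b": [f"gb{i}" for i in range(n)], "chr_b": chr_b,
        "pos_b": pos_b, "evalue": evalues})


def exhaustive_best_chain(pos_a, pos_b, scores, gap_unit=10000.0):
    """Oracle: enumerate every monotone chain (both orientations) by DFS."""
    n = len(pos_a)
    best = -math.inf

    def extend(chain, orient):
        nonlocal best
        total = sum(scores[i] for i in chain)
        for u, v in zip(chain, chain[1:]):
            total -= max(abs(pos_a[v] - pos_a[u]),
                         abs(pos_b[v] - pos_b[u])) / gap_unit
        best = max(best, total)
        last = chain[-1]
        for j in range(n):
            if pos_a[j] <= pos_a[last]:
                continue
            if orient == "+" and pos_b[j] <= pos_b[last]:
                continue
            if orient == "-" and pos_b[j] >= pos_b[last]:
                continue
            extend(chain + [j], orient)

    for i in range(n):
        extend([i], "+")
        extend([i], "-")
    return best


class TestPairScore:
    def test_cap_formula_and_zero(self):
        assert pair_score(1e-60) == 50
        assert pair_score(1e-40) == pytest.approx(40)
        assert pair_score(1.0) == 0
        assert pair_score(0.0) == 50

    def test_negative_evalue_rejected(self):
        with pytest.raises(ValueError):
            pair_score(-1e-3)


class TestFilterAnchors:
    def test_threshold_and_best_four_per_gene(self):
        rows = anchors_frame(list(range(7)), list(range(7)),
                             [1e-4, 1e-30, 1e-20, 1e-10, 1e-8, 1e-7, 1e-6])
        rows["gene_a"] = ["g0"] + ["g1"] * 6
        out = filter_anchors(rows)
        assert "g0" not in set(out["gene_a"])  # 1e-4 >= 1e-5 removed
        kept = out[out["gene_a"] == "g1"]
        assert len(kept) == 4
        assert set(kept["evalue"]) == {1e-30, 1e-20, 1e-10, 1e-8}

    def test_empty_input(self):
        empty = anchors_frame([], [], [])
        assert filter_anchors(empty).empty

    def test_missing_column_reported(self):
        with pytest.raises(ValueError, match="evalue"):
            filter_anchors(pd.DataFrame({"gene_a": []}))


class TestChainBlocks:
    def test_two_anchor_chain_score(self):
        a = anchors_frame([0, 25_000], [0, 25_000], [1e-60, 1e-40])
        blocks = chain_blocks(a, score_min=0)
        assert len(blocks) == 1
        assert blocks[0].score == pytest.approx(50 + 40 - 2.5)

    def test_ten_collinear_anchors_retained_above_300(self):
        pos = [i * 5_000 for i in range(10)]
        a = anchors_frame(pos, pos, [1e-60] * 10)
        blocks = chain_blocks(a)
        assert len(blocks) == 1
        assert blocks[0].score == pytest.approx(50 * 10 - 9 * 0.5)

    def test_reported_scores_recompute_exactly(self):
        anchors, _ = simulate_anchor_tables(120, inversions=[(40, 55)],
                                            seed=2)
        for blk in chain_blocks(filter_anchors(anchors)):
            assert blk.score == pytest.approx(blk.recompute_score(),
                                              rel=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_dp_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        pos_a = rng.choice(10**6, size=n, replace=False)
        pos_b = rng.choice(10**6, size=n, replace=False)
        ev = 10.0 ** (-rng.uniform(6, 60, size=n))
        a = anchors_frame(list(pos_a), list(pos_b), list(ev))
        best_dp = best_chain_score(a)
        best_oracle = exhaustive_best_chain(pos_a.astype(float),
                                            pos_b.astype(float),
                                            [pair_score(e) for e in ev])
        assert best_dp == pytest.approx(best_oracle, rel=1e-9)

    def test_reversing_b_axis_flips_orientations_preserves_scores(self):
        anchors, _ = simulate_anchor_tables(100, inversions=[(30, 45)],
                                            seed=5)
        blocks = chain_blocks(filter_anchors(anchors))
        flipped = anchors.copy()
        flipped["pos_b"] = int(anchors["pos_b"].max()) + 1 - flipped["pos_b"]
        blocks_f = chain_blocks(filter_anchors(flipped))
        key = lambda bs: sorted((round(b.score, 6), b.orientation)
                                for b in bs)
        assert [s for s, _ in key(blocks)] == [s for s, _ in key(blocks_f)]
        orient = {round(b.score, 6): b.orientation for b in blocks}
        for b in blocks_f:
            assert b.orientation != orient[round(b.score, 6)]


class TestDotplotAndRearrangements:
    def test_identity_order_single_block_on_diagonal(self):
        anchors, _ = simulate_anchor_tables(40, seed=1)
        blocks = chain_blocks(filter_anchors(anchors))
        assert len(blocks) == 1 and blocks[0].orientation == "+"
        dot = dotplot_data(anchors, blocks)
        assert (dot["block_id"] == 0).all()
        assert detect_rearrangements(blocks) == []

    def test_planted_inversion_labeled_negative(self):
        anchors, _ = simulate_anchor_tables(150, inversions=[(50, 69)],
                                            seed=4)
        blocks = chain_blocks(filter_anchors(anchors))
        dot = dotplot_data(anchors, blocks)
        inverted = dot[dot["orientation"] == "-"]
        assert set(inverted.index) == set(range(50, 70))

    def test_empty_block_list_gives_null_ids(self):
        anchors, _ = simulate_anchor_tables(10, seed=6)
        dot = dotplot_data(anchors, [])
        assert dot["block_id"].isna().all()

    def test_two_planted_inversions_called_in_order(self):
        anchors, truth = simulate_anchor_tables(
            260, inversions=[(40, 59), (150, 179)], seed=7)
        blocks = chain_blocks(filter_anchors(anchors))
        calls = [c for c in detect_rearrangements(blocks)
                 if c.kind == "inversion"]
        assert len(calls) == 2
        calls.sort(key=lambda c: c.breakpoint_a_left[0])
        for call, tr in zip(calls, truth.inversions):
            for det, exp in [(call.breakpoint_a_left, tr["gap_a_left"]),
                             (call.breakpoint_a_right, tr["gap_a_right"]),
                             (call.breakpoint_b_left, tr["gap_b_left"]),
                             (call.breakpoint_b_right, tr["gap_b_right"])]:
                assert exp[0] <= det[0] and det[1] <= exp[1]


class TestProjectInterval:
    def test_reference_boundaries_give_410_kb(self):
        iv = project_interval(("Ca_Sb07g023810", "chr7", 58_780_000),
                              ("Ca_Sb07g023430", "chr7", 58_370_000))
        assert iv.length_bp == 410_000
        assert iv.start_bp == 58_370_000 and iv.end_bp == 58_780_000

    def test_zero_length_interval_warns(self):
        with pytest.warns(UserWarning):
            iv = project_interval(("m1", "c", 100), ("m2", "c", 100))
        assert iv.length_bp == 0

    def test_genes_inside_closed_interval_listed(self):
        rng = np.random.default_rng(9)
        inside = rng.integers(1_000, 2_000, size=7)
        outside = np.concatenate([rng.integers(0, 999, size=5),
                                  rng.integers(2_001, 3_000, size=5)])
        ann = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(17)],
            "chrom": "c1",
            "start": np.concatenate([inside, outside])})
        iv = project_interval(("m1", "c1", 1_000), ("m2", "c1", 2_000), ann)
        assert len(iv.genes) == 7

    def test_markers_on_different_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="m1.*m2"):
            project_interval(("m1", "c1", 5), ("m2", "c2", 9))

    def test_bed_row_is_zero_based_half_open(self):
        iv = project_interval(("m1", "c1", 101), ("m2", "c1", 200))
        assert iv.to_bed_row().split("\t")[:3] == ["c1", "100", "200"]
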