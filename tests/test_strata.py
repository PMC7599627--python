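"""Alignment filtering, windowed similarity, stratum segmentation and the
gametolog origin test."""

import itertools

import numpy as np
import pytest

from zwstrata import simdata, strata
from zwstrata.strata import AlignmentBlock, SimilarityWindow

from conftest import make_windows


def blk(z_start, z_end, matches, length, frac=1.0):
    return AlignmentBlock("Z", z_start, z_end, "W", length, matches, frac)


class TestFilterBlocks:
    @pytest.mark.parametrize(
        "block,kept",
        [
            (blk(0, 100, 97, 100), False),  # identity 0.97 > 96%
            (blk(0, 100, 96, 100), True),  # boundary identity kept
            (blk(0, 64, 50, 64), False),  # 64 bp too short
            (blk(0, 65, 50, 65), True),  # 65 bp kept
            (blk(0, 100, 80, 100, frac=0.59), False),
            (blk(0, 100, 80, 100, frac=0.60), True),
        ],
    )
    def test_filter_rules(self, block, kept):
        assert (strata.filter_blocks([block]) == [block]) is kept

    def test_idempotent_and_subset(self):
        blocks = [blk(0, 100, m, 100, f) for m in (50, 80, 97) for f in (0.5, 0.7)]
        once = strata.filter_blocks(blocks)
        assert strata.filter_blocks(once) == once
        assert all(b in blocks for b in once)


class TestWindowedSimilarity:
    def test_length_weighted_mean(self):
        blocks = [blk(0, 100, 80, 100), blk(200, 500, 270, 300)]
        ws = strata.windowed_similarity(blocks, window=100_000)
        assert ws[0].mean_identity == pytest.approx((80 + 270) / 400)

    def test_block_split_pro_rata(self):
        b = blk(50_000, 150_000, 9000, 10_000)
        ws = strata.windowed_similarity([b], window=100_000)
        assert ws[0].aligned_bp == pytest.approx(5000)
        assert ws[1].aligned_bp == pytest.approx(5000)
        assert ws[0].mean_identity == pytest.approx(0.9)

    def test_totals_conserved(self):
        rng = np.random.default_rng(3)
        blocks = []
        for _ in range(200):
            s = int(rng.integers(0, 900_000))
            ln = int(rng.integers(65, 5000))
            m = int(rng.integers(0, ln))
            blocks.append(blk(s, s + ln, m, ln))
        ws = strata.windowed_similarity(blocks, window=100_000)
        assert sum(w.aligned_bp for w in ws) == pytest.approx(sum(b.aligned_length for b in blocks))

    def test_empty_window_nan(self):
        ws = strata.windowed_similarity([blk(0, 100, 80, 100)], window=100_000, z_length=300_000)
        assert np.isnan(ws[2].mean_identity) and ws[2].aligned_bp == 0


class TestDirectColinear:
    def test_identical(self):
        ws = strata.direct_colinear_similarity("ACGT" * 50_000, "ACGT" * 50_000)
        assert all(w.mean_identity == 1.0 for w in ws)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            strata.direct_colinear_similarity("ACGT", "ACG")

    def test_fully_deleted_window_undefined(self):
        z = "ACGT" * 25
        w = "-" * 100
        ws = strata.direct_colinear_similarity(z, w, window=100)
        assert np.isnan(ws[0].mean_identity)

    @pytest.mark.parametrize("div,expected", [(0.30, 0.70), (0.06, 0.94)])
    def test_simulated_divergence_recovery(self, div, expected):
        cfg = simdata.SimulationConfig(
            seed=21, z_length=2_000_000,
            strata=(simdata.StratumSpec(0, 2_000_000, "S0", div),),
        )
        z, w, _ = simdata.simulate_zw_pair(cfg)
        ws = strata.direct_colinear_similarity(z, w)
        assert np.mean([x.mean_identity for x in ws]) == pytest.approx(expected, abs=0.01)

    def test_agrees_with_block_route_on_lossless_blocks(self):
        """Truth-emitted alignment blocks reproduce the alignment-free
        identity within half a percentage point."""
        cfg = simdata.SimulationConfig(
            seed=8, z_length=1_000_000,
            strata=(simdata.StratumSpec(0, 1_000_000, "S0", 0.25),),
        )
        z, w, _ = simdata.simulate_zw_pair(cfg)
        zc, wc = simdata.str_to_codes(z), simdata.str_to_codes(w)
        blocks = []
        for s in range(0, 1_000_000, 10_000):  # lossless 10-kb blocks
            e = s + 10_000
            m = int((zc[s:e] == wc[s:e]).sum())
            blocks.append(blk(s, e, m, 10_000))
        via_blocks = strata.windowed_similarity(blocks, window=100_000)
        direct = strata.direct_colinear_similarity(z, w)
        for a, b in zip(via_blocks, direct):
            assert abs(a.mean_identity - b.mean_identity) < 0.005


def sse_oracle(values, k, min_size):
    """Brute-force minimal-SSE changepoints for k <= 2."""
    values = np.asarray(values, float)
    n = len(values)

    def cost(segs):
        return sum(((values[a:b] - values[a:b].mean()) ** 2).sum() for a, b in segs)

    best, best_b = None, None
    if k == 1:
        cands = ([b] for b in range(min_size, n - min_size + 1))
    else:
        cands = (
            [b1, b2]
            for b1 in range(min_size, n)
            for b2 in range(b1 + min_size, n - min_size + 1)
        )
    for bounds in cands:
        segs = list(zip([0] + bounds, bounds + [n]))
        if any(b - a < min_size for a, b in segs):
            continue
        c = cost(segs)
        if best is None or c < best - 1e-12:
            best, best_b = c, bounds
    return best_b, best


class TestSegmentation:
    def test_constant_single_segment(self):
        annos = strata.segment_strata(make_windows([0.8] * 30))
        assert len(annos) == 1

    def test_two_level_boundary_recovery(self):
        rng = np.random.default_rng(17)
        vals = np.concatenate([rng.normal(0.70, 0.01, 20), rng.normal(0.90, 0.01, 20)])
        annos = strata.segment_strata(make_windows(vals))
        assert len(annos) == 2
        assert abs(annos[0].z_end // 100_000 - 20) <= 2
        assert annos[0].label == "S0" and annos[1].label == "S1"

    def test_three_level_recovery(self):
        rng = np.random.default_rng(19)
        vals = np.concatenate(
            [rng.normal(0.70, 0.01, 20), rng.normal(0.80, 0.01, 20), rng.normal(0.92, 0.01, 20)]
        )
        annos = strata.segment_strata(make_windows(vals))
        assert [a.label for a in annos] == ["S0", "S1", "S2"]
        assert abs(annos[0].z_end // 100_000 - 20) <= 2
        assert abs(annos[1].z_end // 100_000 - 40) <= 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 3))
        sizes = rng.integers(6, 20, size=k + 1)
        levels = rng.uniform(0.6, 0.95, size=k + 1)
        vals = np.concatenate([rng.normal(l, 0.01, s) for l, s in zip(levels, sizes)])
        bounds, _ = strata._optimal_partition(vals, k, 5)
        oracle_bounds, _ = sse_oracle(vals, k, 5)
        assert bounds == oracle_bounds

    def test_min_segment_size_enforced(self):
        vals = [0.7] * 3 + [0.9] * 30  # true boundary at 3 < min size 5
        bounds, _ = strata._optimal_partition(np.asarray(vals, float), 1, 5)
        assert bounds[0] >= 5

    def test_too_few_windows_warns_single(self):
        with pytest.warns(UserWarning):
            annos = strata.segment_strata(make_windows([0.7, 0.9] * 3))
        assert len(annos) == 1

    def test_boundary_override(self):
        vals = [0.7] * 20 + [0.9] * 20
        annos = strata.segment_strata(make_windows(vals), boundaries=[1_500_000])
        assert annos[0].z_end == 1_500_000

    def test_par_labeled_by_threshold(self):
        vals = [0.999] * 10 + [0.7] * 10 + [0.94] * 10
        annos = strata.segment_strata(make_windows(vals))
        assert [a.label for a in annos] == ["PAR", "S0", "S1"]


class TestPDistance:
    def test_examples(self):
        d, labels = strata.p_distance_matrix({"a": "ACGT", "b": "AGGT", "c": "ACGT"})
        i, j, k = labels.index("a"), labels.index("b"), labels.index("c")
        assert d[i, j] == 0.25 and d[i, k] == 0.0

    def test_gap_columns_excluded(self):
        d, labels = strata.p_distance_matrix({"a": "AC-T", "b": "ACGT", "c": "ACGA"})
        assert d[labels.index("a"), labels.index("b")] == 0.0

    def test_no_comparable_sites(self):
        with pytest.raises(ValueError, match="comparable"):
            strata.p_distance_matrix({"a": "--AA", "b": "AA--", "c": "AAAA"})


class TestNeighborJoining:
    def test_additive_four_taxon_split(self):
        # tree ((A:1,B:1):1,(C:1,D:1):1)
        d = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
        )
        tree = strata.neighbor_joining(d, ["A", "B", "C", "D"])
        parts = strata._bipartitions(tree)
        assert frozenset({"A", "B"}) in parts and frozenset({"C", "D"}) in parts

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = strata.neighbor_joining(d, ["a", "b", "c"])
        center = next(n for n in tree.nodes if isinstance(n, tuple))
        assert tree.edges["a", center]["length"] == pytest.approx(1.0)
        assert tree.edges["b", center]["length"] == pytest.approx(2.0)
        assert tree.edges["c", center]["length"] == pytest.approx(3.0)

    def test_matches_skbio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        # random additive matrix from a random tree via simulated sequences
        seqs = simdata.simulate_gametologs(99, cds_length=5000, n_species=4, shared=True)
        d, labels = strata.p_distance_matrix({f"{s}_{c}": v for (s, c), v in seqs.items()})
        dm = skbio.DistanceMatrix(d, ids=labels)
        sk_tree = skbio.tree.nj(dm)
        mine = strata.neighbor_joining(d, labels)
        my_parts = {p for p in strata._bipartitions(mine) if 1 < len(p) < len(labels) - 1}
        sk_parts = set()
        leafset = frozenset(labels)
        for node in sk_tree.non_tips(include_self=False):
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < len(labels) - 1:
                sk_parts.add(tips)
                sk_parts.add(leafset - tips)
        assert my_parts == sk_parts

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            strata.neighbor_joining(np.array([[0, 1], [1, 0]]), ["a", "b"])
        bad = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], dtype=float)
        with pytest.raises(ValueError):
            strata.neighbor_joining(bad, ["a", "b", "c"])

    def test_tie_break_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        t1 = strata.neighbor_joining(d, list("abcd"))
        t2 = strata.neighbor_joining(d, list("abcd"))
        assert sorted(map(str, t1.edges)) == sorted(map(str, t2.edges))


class TestOriginClassification:
    def test_constructed_shared(self):
        # W copies much closer to each other than to any Z
        order = [("sp1", "Z"), ("sp2", "Z"), ("sp1", "W"), ("sp2", "W")]
        d = np.zeros((4, 4))
        for (i, j), v in {(0, 1): 0.05, (0, 2): 0.3, (0, 3): 0.3,
                          (1, 2): 0.3, (1, 3): 0.3, (2, 3): 0.05}.items():
            d[i, j] = d[j, i] = v
        assert strata.classify_origin(d, order) == "shared"

    def test_constructed_independent(self):
        order = [("sp1", "Z"), ("sp1", "W"), ("sp2", "Z"), ("sp2", "W")]
        d = np.zeros((4, 4))
        for (i, j), v in {(0, 1): 0.05, (0, 2): 0.3, (0, 3): 0.3,
                          (1, 2): 0.3, (1, 3): 0.3, (2, 3): 0.05}.items():
            d[i, j] = d[j, i] = v
        assert strata.classify_origin(d, order) == "independent"

    def test_missing_w_copies_error(self):
        order = [("sp1", "Z"), ("sp1", "W"), ("sp2", "Z")]
        with pytest.raises(ValueError):
            strata.classify_origin(np.zeros((3, 3)), order)

    @pytest.mark.parametrize("shared", [True, False])
    def test_simulated_history_recovered(self, shared):
        expected = "shared" if shared else "independent"
        hits = 0
        for seed in range(25):
            seqs = simdata.simulate_gametologs(seed, cds_length=3000, shared=shared)
            hits += strata.classify_origin(seqs) == expected
        assert hits >= 24

    def test_outgroup_participates_without_breaking_call(self):
        seqs = simdata.simulate_gametologs(3, shared=True, with_outgroup=True)
        assert strata.classify_origin(seqs) == "shared"
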