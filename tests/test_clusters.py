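"""Itineraries, thresholding sweep and the spatio-spectral cluster search."""

import numpy as np
import pytest

from spikevcr.clusters import (
    find_clusters,
    itineraries,
    itinerary_name,
    sequential_search,
    threshold_active,
)
from spikevcr.config import PipelineConfig
from spikevcr.resection import CCStack, label_roles

N_BANDS = 12


def make_stack(cc: np.ndarray, labels: np.ndarray | None = None) -> CCStack:
    """CCStack from a (bands, 2, n) CC array; labels derived if not given."""
    if labels is None:
        labels = np.stack(
            [
                [label_roles(cc[b, s], 0.10) for s in range(2)]
                for b in range(cc.shape[0])
            ]
        ).astype(np.int8)
    return CCStack(
        s=np.ones(cc.shape[:2]),
        cc=cc,
        labels=labels,
        band_indices=tuple(range(1, cc.shape[0] + 1)),
    )


def line_pairs(n: int) -> np.ndarray:
    """Adjacency of n sources on a 5 mm line: consecutive pairs only."""
    return np.column_stack([np.arange(n - 1), np.arange(1, n)])


class TestItineraries:
    def test_role_pairs_map_to_transition_names(self):
        labels = np.zeros((1, 2, 3), dtype=np.int8)
        labels[0, 0] = [1, -1, 0]    # pre:  D, S, B
        labels[0, 1] = [1, -1, -1]   # spike: D, S, S
        stack = make_stack(np.zeros((1, 2, 3)), labels)
        codes = itineraries(stack)
        assert [itinerary_name(c) for c in codes[:, 0]] == ["D->D", "S->S", "B->S"]

    def test_nine_possible_names(self):
        names = {itinerary_name(c) for c in range(9)}
        assert len(names) == 9
        assert {"D->D", "S->S", "B->B", "D->S", "S->D"} <= names


class TestThresholdActive:
    def test_full_threshold_activates_everything(self):
        stack = make_stack(np.random.default_rng(0).standard_normal((3, 2, 10)))
        assert threshold_active(stack, 1.0).all()

    def test_one_percent_keeps_the_single_top_magnitude(self):
        rng = np.random.default_rng(1)
        cc = rng.standard_normal((1, 2, 100))
        stack = make_stack(cc)
        active = threshold_active(stack, 0.01)
        top_pre = np.argmax(np.abs(cc[0, 0]))
        top_spike = np.argmax(np.abs(cc[0, 1]))
        expect = np.zeros(100, dtype=bool)
        if top_pre == top_spike:
            expect[top_pre] = True
        np.testing.assert_array_equal(active[:, 0], expect)

    def test_active_sets_grow_monotonically_with_threshold(self):
        stack = make_stack(np.random.default_rng(2).standard_normal((4, 2, 30)))
        prev = None
        for t in np.arange(0.01, 1.001, 0.01):
            cur = threshold_active(stack, round(float(t), 2))
            if prev is not None:
                assert np.all(cur | prev == cur)  # prev subset of cur
            prev = cur


def _patch_inputs(n_src=25, patch=range(20), bands=range(5, 9)):
    """Active/itinerary fields with one D->D patch on a line of sources."""
    active = np.zeros((n_src, N_BANDS), dtype=bool)
    itins = np.full((n_src, N_BANDS), 0)            # S->S background code
    dd = (1 + 1) * 3 + (1 + 1)                       # D->D code
    for b in bands:
        for s in patch:
            active[s, b] = True
            itins[s, b] = dd
    stack = make_stack(np.zeros((N_BANDS, 2, n_src)))
    return active, itins, stack


class TestFindClusters:
    def test_patch_locked_over_four_bands_is_one_cluster(self):
        active, itins, stack = _patch_inputs(bands=range(5, 9))  # bands 6..9
        out = find_clusters(active, itins, line_pairs(25), stack,
                            min_sources=15, min_bands=4)
        assert len(out) == 1
        assert out[0].size == 20
        assert out[0].band_run == (5, 8)
        assert out[0].itinerary == "D->D"

    def test_three_band_patch_is_not_enough(self):
        active, itins, stack = _patch_inputs(bands=range(5, 8))
        out = find_clusters(active, itins, line_pairs(25), stack,
                            min_sources=15, min_bands=4)
        assert out == []

    def test_undersized_patch_is_not_enough(self):
        active, itins, stack = _patch_inputs(patch=range(10))
        out = find_clusters(active, itins, line_pairs(25), stack,
                            min_sources=15, min_bands=4)
        assert out == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_src, n_bands = 16, 8  # <= 200 cells
        active = rng.random((n_src, n_bands)) < 0.5
        itins = rng.integers(0, 3, size=(n_src, n_bands)) * 4  # 3 codes
        pairs = line_pairs(n_src)
        cc = rng.standard_normal((n_bands, 2, n_src))
        stack = CCStack(
            s=np.ones((n_bands, 2)), cc=cc,
            labels=np.zeros((n_bands, 2, n_src), dtype=np.int8),
            band_indices=tuple(range(1, n_bands + 1)),
        )
        got = {
            (frozenset(c.sources.tolist()), c.band_run, c.itinerary_code)
            for c in find_clusters(active, itins, pairs, stack,
                                   min_sources=3, min_bands=2)
        }
        assert got == _oracle_clusters(active, itins, pairs, 3, 2)


def _oracle_clusters(active, itins, pairs, min_sources, min_bands):
    """Independent BFS flood fill plus exhaustive band-interval scan."""
    n_src, n_bands = active.shape
    neigh = {i: set() for i in range(n_src)}
    for a, b in pairs:
        neigh[int(a)].add(int(b))
        neigh[int(b)].add(int(a))
    cells = {(s, b) for s in range(n_src) for b in range(n_bands) if active[s, b]}
    seen, comps = set(), []
    for start in sorted(cells):
        if start in seen:
            continue
        comp, stack_ = set(), [start]
        while stack_:
            s, b = stack_.pop()
            if (s, b) in comp:
                continue
            comp.add((s, b))
            code = itins[s, b]
            for s2 in neigh[s]:
                if (s2, b) in cells and itins[s2, b] == code:
                    stack_.append((s2, b))
            for b2 in (b - 1, b + 1):
                if (s, b2) in cells and itins[s, b2] == code:
                    stack_.append((s, b2))
        seen |= comp
        comps.append(comp)
    out = set()
    for comp in comps:
        best = None
        for b0 in range(n_bands):
            for b1 in range(b0 + min_bands - 1, n_bands):
                members = [
                    s for s in {c[0] for c in comp}
                    if all((s, b) in comp for b in range(b0, b1 + 1))
                ]
                if len(members) < min_sources:
                    continue
                key = (b1 - b0 + 1, len(members), -b0)
                if best is None or key > best[0]:
                    best = (key, b0, b1, frozenset(members))
        if best is not None:
            _, b0, b1, members = best
            code = itins[next(iter(members)), b0]
            out.add((members, (b0, b1), int(code)))
    return out


class TestSequentialSearch:
    def test_all_tied_magnitudes_emerge_at_the_first_step(self):
        cc = np.full((N_BANDS, 2, 20), 0.5)
        result = sequential_search(make_stack(cc), line_pairs(20))
        assert result.found
        assert result.candidate.threshold == pytest.approx(0.01)
        # the per-tail bulk quota removes one source from the D tail
        assert result.candidate.size == 19
        assert result.candidate.itinerary == "D->D"

    def test_planted_top_magnitude_block_is_recovered(self):
        rng = np.random.default_rng(4)
        n = 40
        cc = rng.uniform(-0.05, 0.05, size=(N_BANDS, 2, n))
        block = np.arange(10, 26)  # 16 contiguous sources
        for b in range(3, 9):      # six consecutive bands
            cc[b, :, block] = np.linspace(1.0, 1.15, 16)[:, None]
        result = sequential_search(make_stack(cc), line_pairs(n))
        assert result.found
        c = result.candidate
        assert set(c.sources.tolist()) <= set(block.tolist())
        assert c.itinerary == "D->D"
        assert c.threshold <= 16 / 40 + 0.01
        assert c.band_interval[1] - c.band_interval[0] + 1 >= 4

    def test_emergence_threshold_is_minimal(self):
        rng = np.random.default_rng(4)
        n = 40
        cc = rng.uniform(-0.05, 0.05, size=(N_BANDS, 2, n))
        block = np.arange(10, 26)
        for b in range(3, 9):
            cc[b, :, block] = np.linspace(1.0, 1.15, 16)[:, None]
        stack = make_stack(cc)
        pairs = line_pairs(n)
        result = sequential_search(stack, pairs)
        t = result.candidate.threshold
        if t > 0.01:
            from spikevcr.clusters import itineraries as itins_fn

            active = threshold_active(stack, round(t - 0.01, 10))
            below = find_clusters(
                active, itins_fn(stack), pairs, stack,
                min_sources=result.candidate.min_size_level, min_bands=4,
            )
            assert below == []

    def test_fallback_ladder_reaches_five(self):
        # only 9 sources exist, so sizes 15 and 10 must be swept in full
        cc = np.full((N_BANDS, 2, 9), 0.01)
        cc[:, :, :7] = 1.0  # 7-source block dominates
        labels = np.full((N_BANDS, 2, 9), 1, dtype=np.int8)
        labels[:, :, 7:] = -1
        result = sequential_search(make_stack(cc, labels), line_pairs(9))
        assert result.found
        assert result.candidate.min_size_level == 5
        assert result.candidate.size == 7
        sizes_swept = {m for m, _, _ in result.trace}
        assert sizes_swept == {15, 10, 5}
        assert len([1 for m, _, _ in result.trace if m == 15]) == 100

    def test_no_solution_is_typed_not_raised(self):
        # alternating labels prevent any spatial cluster of two
        labels = np.empty((N_BANDS, 2, 30), dtype=np.int8)
        labels[:, :, ::2] = 1
        labels[:, :, 1::2] = -1
        cc = np.where(labels > 0, 0.5, -0.5).astype(float)
        result = sequential_search(make_stack(cc, labels), line_pairs(30))
        assert not result.found
        assert result.candidate is None
        assert result.min_sizes_tried == (15, 10, 5)

    def test_fixed_stack_gives_identical_candidates(self):
        cc = np.random.default_rng(9).standard_normal((N_BANDS, 2, 25))
        stack = make_stack(cc)
        r1 = sequential_search(stack, line_pairs(25))
        r2 = sequential_search(stack, line_pairs(25))
        assert r1.found == r2.found
        if r1.found:
            np.testing.assert_array_equal(r1.candidate.sources, r2.candidate.sources)
            assert r1.candidate.threshold == r2.candidate.threshold
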