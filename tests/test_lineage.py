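"""Lineage graph, overlap tracking, anomalies and tree-edit distance."""

import itertools

import numpy as np
import pytest

from segcurate import (
    CellTree,
    LineageGraph,
    Selection,
    SynthConfig,
    build_lineage,
    cell_tree,
    detect_lineage_anomalies,
    edit_links,
    generate_nuclei_timelapse,
    inject_errors,
    symmetric_pair_distances,
    track_by_overlap,
    tree_edit_distance,
)
from segcurate.lineage import division_delay_between_pairs
from segcurate.properties import RegionPropertyTable


class TestGraphBasics:
    def test_chain_of_three_frames_is_one_cell(self):
        g = build_lineage([((0, 1), (1, 1)), ((1, 1), (2, 1))])
        assert g.cells() == [[(0, 1), (1, 1), (2, 1)]]
        assert g.lifetimes() == {(0, 1): 3}

    def test_two_successors_is_one_division(self):
        g = build_lineage([((0, 1), (1, 2)), ((0, 1), (1, 3))])
        assert g.divisions() == [(0, 1)]

    def test_two_predecessors_flagged_by_validation(self):
        g = build_lineage([((0, 1), (1, 3)), ((0, 2), (1, 3))])
        assert any("predecessors" in issue for issue in g.validate())

    def test_non_consecutive_edge_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            build_lineage([((0, 1), (2, 1))])


class TestEditLinks:
    def test_add_across_three_frames_creates_two_edges(self):
        g = LineageGraph()
        for t in range(3):
            g.add_node((t, 5))
        sel = Selection(groups={"A": {(t, 0, 5) for t in range(3)}})
        out = edit_links(g, "add", sel)
        assert out.edges() == [((0, 5), (1, 5)), ((1, 5), (2, 5))]

    def test_remove_mid_chain_edge_splits_cell(self):
        g = build_lineage([((0, 1), (1, 1)), ((1, 1), (2, 1))])
        sel = Selection(groups={"A": {(1, 0, 1), (2, 0, 1)}})
        out = edit_links(g, "remove", sel)
        assert len(out.cells()) == 2

    def test_remove_absent_edge_warns(self):
        g = build_lineage([((0, 1), (1, 1))])
        sel = Selection(groups={"A": {(0, 0, 9), (1, 0, 9)}})
        with pytest.warns(UserWarning, match="absent"):
            edit_links(g, "remove", sel)

    def test_add_creating_second_predecessor_rejected(self):
        g = build_lineage([((0, 1), (1, 3))])
        sel = Selection(groups={"A": {(0, 0, 2), (1, 0, 3)}})
        with pytest.raises(ValueError, match="predecessor"):
            edit_links(g, "add", sel)


class TestTracking:
    def test_identical_frames_give_identity_links(self):
        cfg = SynthConfig(seed=4, n_objects=5, n_frames=3, motion=0.0)
        ds, gt = generate_nuclei_timelapse(cfg)
        for mode in ("bbox", "voxel"):
            graph = track_by_overlap(ds, mode=mode)
            assert set(graph.edges()) == set(gt.edges())

    def test_translated_movie_reconstructed_exactly(self):
        # displacement below object radius: tracking must recover the truth
        cfg = SynthConfig(seed=11, n_objects=6, n_frames=4, motion=1.5,
                          radius_mean=6.0)
        ds, gt = generate_nuclei_timelapse(cfg)
        graph = track_by_overlap(ds, mode="voxel")
        assert set(graph.edges()) == set(gt.edges())

    def test_division_links_both_daughters_to_mother(self):
        cfg = SynthConfig(seed=21, n_objects=5, n_frames=3, motion=0.5,
                          force_division_at=1)
        ds, gt = generate_nuclei_timelapse(cfg)
        graph = track_by_overlap(ds, mode="voxel")
        gt_div = gt.divisions()
        assert gt_div
        mother = gt_div[0]
        assert set(graph.successors(mother)) == set(gt.successors(mother))
        assert len(graph.successors(mother)) == 2


class TestAnomalies:
    @staticmethod
    def volume_table(values):
        return RegionPropertyTable.from_records(
            {"time": t, "channel": 0, "label": l, "property": "volume",
             "value": v}
            for (t, l), v in values.items()
        )

    def test_volume_halving_without_division_is_flagged(self):
        g = build_lineage([((0, 1), (1, 1)), ((1, 1), (2, 1))])
        table = self.volume_table({(0, 1): 100, (1, 1): 100, (2, 1): 50})
        sel = detect_lineage_anomalies(g, table)
        assert (2, 0, 1) in sel.items

    def test_constant_volume_chain_not_flagged(self):
        g = build_lineage([((0, 1), (1, 1)), ((1, 1), (2, 1))])
        table = self.volume_table({(0, 1): 100, (1, 1): 104, (2, 1): 98})
        assert len(detect_lineage_anomalies(g, table)) == 0

    def test_injected_missed_division_flagged_at_separation(self):
        cfg = SynthConfig(seed=21, n_objects=5, n_frames=6, motion=0.5,
                          force_division_at=1)
        ds, gt = generate_nuclei_timelapse(cfg)
        corrupted, manifest = inject_errors(ds, [("missed_division", 1)], seed=1)
        entry = manifest.of_kind("missed_division")[0]
        assert entry["params"]["separation_time"] is not None
        records = []
        for t in corrupted.times():
            vol = corrupted.label_volume(t)
            labs, counts = np.unique(vol.data[vol.data > 0], return_counts=True)
            for l, c in zip(labs, counts):
                records.append({"time": t, "channel": 0, "label": int(l),
                                "property": "volume", "value": int(c)})
        table = RegionPropertyTable.from_records(records)
        flagged = detect_lineage_anomalies(corrupted.lineage, table)
        t_sep = entry["params"]["separation_time"]
        flagged_at_sep = {l for tt, c, l in flagged.items if tt == t_sep}
        assert flagged_at_sep  # the fused cell is caught when it splits


# ---------------------------------------------------------------- TED oracle

def ted_brute_force(f1: tuple, f2: tuple, memo=None) -> float:
    """Forest edit distance by direct recursion over rightmost roots --
    an implementation independent of the keyroot-based dynamic program."""
    if memo is None:
        memo = {}
    key = (f1, f2)
    if key in memo:
        return memo[key]
    if not f1 and not f2:
        return 0.0
    def total(f):
        return sum(n[0] + total(n[1]) for n in f)
    if not f1:
        return total(f2)
    if not f2:
        return total(f1)
    t1, rest1 = f1[-1], f1[:-1]
    t2, rest2 = f2[-1], f2[:-1]
    best = min(
        ted_brute_force(rest1 + t1[1], f2, memo) + t1[0],
        ted_brute_force(f1, rest2 + t2[1], memo) + t2[0],
        ted_brute_force(t1[1], t2[1], memo)
        + ted_brute_force(rest1, rest2, memo)
        + abs(t1[0] - t2[0]),
    )
    memo[key] = best
    return best


def to_tuple(tree: CellTree) -> tuple:
    return (tree.lifetime, tuple(to_tuple(c) for c in tree.children))


def random_tree(rng, max_nodes=7) -> CellTree:
    n = int(rng.integers(1, max_nodes + 1))
    nodes = [CellTree(lifetime=int(rng.integers(1, 10)))]
    for _ in range(n - 1):
        parent = nodes[int(rng.integers(len(nodes)))]
        child = CellTree(lifetime=int(rng.integers(1, 10)))
        parent.children.append(child)
        nodes.append(child)
    return nodes[0]


class TestTreeEditDistance:
    def test_identical_trees_have_distance_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            t = random_tree(rng)
            assert tree_edit_distance(t, t) == 0.0

    def test_single_cell_trees_differ_by_lifetime_gap(self):
        a = CellTree(lifetime=5)
        b = CellTree(lifetime=8)
        assert tree_edit_distance(a, b) == 3.0

    def test_matches_brute_force_on_small_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            a, b = random_tree(rng), random_tree(rng)
            got = tree_edit_distance(a, b)
            expected = ted_brute_force((to_tuple(a),), (to_tuple(b),))
            assert got == pytest.approx(expected), (to_tuple(a), to_tuple(b))

    def test_metric_axioms_on_sampled_triples(self):
        rng = np.random.default_rng(7)
        trees = [random_tree(rng) for _ in range(30)]
        for _ in range(200):
            a, b, c = (trees[int(i)] for i in rng.integers(0, len(trees), 3))
            dab = tree_edit_distance(a, b)
            dba = tree_edit_distance(b, a)
            dac = tree_edit_distance(a, c)
            dcb = tree_edit_distance(c, b)
            assert dab == pytest.approx(dba)
            assert dab <= dac + dcb + 1e-9
            assert dab >= 0


def mirrored_lineage(delays: dict[str, int], base_division: int = 3):
    """Two lineage 'sides' (X and X*), each a cell dividing into two leaves;
    the starred side divides ``delays[name]`` frames later."""
    g = LineageGraph()
    names = {}
    label = 1
    for i, (name, delay) in enumerate(delays.items()):
        for star, shift in ((False, 0), (True, delay)):
            div_t = base_division + shift
            root = label
            for t in range(div_t):
                if t < div_t - 1:
                    g.add_link((t, root), (t + 1, root))
            d1, d2 = label + 1, label + 2
            g.add_link((div_t - 1, root), (div_t, d1))
            g.add_link((div_t - 1, root), (div_t, d2))
            for d in (d1, d2):
                g.add_link((div_t, d), (div_t + 1, d))
            suffix = "*" if star else ""
            names[(0, root)] = f"{name}{suffix}"
            names[(div_t, d1)] = f"{name}.d1{suffix}"
            names[(div_t, d2)] = f"{name}.d2{suffix}"
            label += 3
    g.names = names
    return g


class TestSymmetricPairs:
    def test_perfect_mirror_has_zero_distances(self):
        g = mirrored_lineage({"a7.1": 0, "a7.2": 0})
        table = symmetric_pair_distances(g)
        root_rows = table.df[table.df["property"] == "lineage_distance"]
        named = [v for v in root_rows["value"] if not np.isnan(v)]
        assert named and all(v == 0 for v in named)

    def test_unpaired_cell_gets_missing_value(self):
        g = LineageGraph(names={(0, 1): "b7.3"})
        g.add_node((0, 1))
        table = symmetric_pair_distances(g)
        assert np.isnan(table.df["value"].iloc[0])

    def test_one_sided_missed_division_stands_out(self):
        # left side divides at t=3; right side never divides: the edit
        # distance at that cell exceeds every mirrored cell's distance
        g = mirrored_lineage({"b7.11": 0, "b7.12": 0})
        # remove the starred b7.11 division: fuse its daughters into a chain
        to_kill = [n for n, nm in g.names.items() if nm == "b7.11.d2*"]
        assert to_kill
        (t_div, lab2) = to_kill[0]
        for node in [n for n in g.nodes() if n[1] == lab2]:
            g.g.remove_node(node)
        table = symmetric_pair_distances(g)
        df = table.df
        def dist_for(name):
            nodes = [n for n, nm in g.names.items() if nm == name]
            t, l = nodes[0]
            rows = df[(df["time"] == t) & (df["label"] == l)]
            return rows["value"].iloc[0]
        assert dist_for("b7.11") > dist_for("b7.12")
        assert dist_for("b7.12") == 0

    def test_division_delay_histogram_matches_injected_delays(self):
        delays = {"a7.1": 0, "a7.2": 2, "a7.3": 5}
        g = mirrored_lineage(delays)
        got = division_delay_between_pairs(g)
        # X* divides `delay` frames after X, so t(X) - t(X*) = -delay
        assert got == {k: -d for k, d in delays.items()}
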