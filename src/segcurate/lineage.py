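"""Temporal layer: lineage graphs, overlap tracking and tree-edit distance.

A lineage graph links each segmented object (a ``(time, label)`` node) to
its successor(s) at the next time point; a node with two successors is a
cell division.  For quality control of bilaterally symmetric embryos, each
cell's lineage subtree is compared against its contralateral homolog
(Conklin naming: ``a7.5`` pairs with ``a7.5*``) by an ordered-tree edit
distance whose costs are cell lifetimes: relabeling a cell costs the
lifetime difference, inserting or deleting a cell costs its lifetime.  A
missed division on one side therefore shows up as a localized, strictly
positive distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .properties import RegionPropertyTable
from .selection import Selection
from .volume_io import Dataset

Node = tuple[int, int]  # (time, label)


class LineageGraph:
    """Directed temporal-link graph over (time, label) nodes.

    Edges connect consecutive times only.  In a curated graph each node has
    at most one predecessor and at most two successors (divisions are
    binary); violations are reported by :meth:`validate`, not rejected, so
    that anomaly detection can operate on uncurated graphs.
    """

    def __init__(self, names: dict[Node, str] | None = None):
        self.g = nx.DiGraph()
        self.names: dict[Node, str] = dict(names or {})

    # ------------------------------------------------------------ building
    def add_node(self, node: Node) -> None:
        self.g.add_node((int(node[0]), int(node[1])))

    def add_link(self, a: Node, b: Node) -> None:
        a = (int(a[0]), int(a[1]))
        b = (int(b[0]), int(b[1]))
        if b[0] != a[0] + 1:
            raise ValueError(f"link {a} -> {b} does not span consecutive times")
        self.g.add_edge(a, b)

    def remove_link(self, a: Node, b: Node) -> bool:
        if self.g.has_edge(tuple(a), tuple(b)):
            self.g.remove_edge(tuple(a), tuple(b))
            return True
        return False

    def copy(self) -> "LineageGraph":
        out = LineageGraph(names=dict(self.names))
        out.g = self.g.copy()
        return out

    # ----------------------------------------------------------- structure
    def nodes(self) -> list[Node]:
        return sorted(self.g.nodes)

    def edges(self) -> list[tuple[Node, Node]]:
        return sorted(self.g.edges)

    def successors(self, n: Node) -> list[Node]:
        return sorted(self.g.successors(tuple(n)))

    def predecessors(self, n: Node) -> list[Node]:
        return sorted(self.g.predecessors(tuple(n)))

    def divisions(self) -> list[Node]:
        return sorted(n for n in self.g.nodes if self.g.out_degree(n) >= 2)

    def roots(self) -> list[Node]:
        return sorted(n for n in self.g.nodes if self.g.in_degree(n) == 0)

    def validate(self) -> list[str]:
        issues = []
        for n in self.nodes():
            if self.g.in_degree(n) > 1:
                issues.append(f"node {n} has {self.g.in_degree(n)} predecessors")
            if self.g.out_degree(n) >= 3:
                issues.append(f"node {n} has {self.g.out_degree(n)} successors")
        return issues

    def cells(self) -> list[list[Node]]:
        """Maximal chains of single-successor nodes ('cells').

        A chain starts at a root or at a daughter of a division and follows
        unique-successor links until the movie ends or the cell divides.
        """
        starts = []
        for n in self.nodes():
            preds = self.predecessors(n)
            if not preds or self.g.out_degree(preds[0]) >= 2:
                starts.append(n)
        chains = []
        for start in starts:
            chain = [start]
            cur = start
            while True:
                succ = self.successors(cur)
                if len(succ) != 1:
                    break
                nxt = succ[0]
                if self.g.in_degree(nxt) > 1:
                    break
                chain.append(nxt)
                cur = nxt
            chains.append(chain)
        return chains

    def lifetimes(self) -> dict[Node, int]:
        """Lifetime (frame count) of the cell each chain-start node heads."""
        return {chain[0]: len(chain) for chain in self.cells()}

    def cell_name(self, chain: Sequence[Node]) -> str | None:
        for n in chain:
            if n in self.names:
                return self.names[n]
        return None

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        rows = [
            {"t": a[0], "label": a[1], "t_next": b[0], "label_next": b[1]}
            for a, b in self.edges()
        ]
        pd.DataFrame(rows, columns=["t", "label", "t_next", "label_next"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, names_csv=None) -> "LineageGraph":
        df = pd.read_csv(path)
        links = [
            ((int(r.t), int(r.label)), (int(r.t_next), int(r.label_next)))
            for r in df.itertuples()
        ]
        names = None
        if names_csv is not None:
            nd = pd.read_csv(names_csv)
            names = {
                (int(row["t"]), int(row["label"])): str(row["name"])
                for _, row in nd.iterrows()
            }
        return build_lineage(links, names=names)


def build_lineage(
    links: Iterable[tuple[Node, Node]] | str,
    names: dict[Node, str] | None = None,
    dataset: Dataset | None = None,
) -> LineageGraph:
    """Build a lineage graph from an edge list (or a links CSV path)."""
    if isinstance(links, (str, bytes)) or hasattr(links, "read"):
        return LineageGraph.from_csv(links)
    graph = LineageGraph(names=names)
    for a, b in links:
        graph.add_link(a, b)
    if dataset is not None:
        for t, lab in graph.nodes():
            vols = [v for (tt, _), v in dataset.labels.items() if tt == t]
            if vols and not any(lab in v.data for v in vols):
                raise ValueError(f"lineage node ({t}, {lab}) absent from dataset")
    return graph


def edit_links(
    graph: LineageGraph,
    action: Literal["add", "remove"],
    selection: Selection,
) -> LineageGraph:
    """Add or remove temporal links between grouped objects.

    For each label group, members at consecutive times are linked (``add``)
    or their links removed (``remove``).  Adding a link that would give a
    node two predecessors is rejected."""
    out = graph.copy()
    groups = selection.groups or {"_all": selection.items}
    warns: list[str] = []
    for name, items in groups.items():
        by_time: dict[int, list[Node]] = {}
        for t, _c, l in items:
            by_time.setdefault(t, []).append((t, l))
        times = sorted(by_time)
        if action == "add" and len(times) < 2:
            raise ValueError(f"group {name!r}: add needs >= 2 consecutive times")
        for t0, t1 in zip(times, times[1:]):
            if t1 != t0 + 1:
                if action == "add":
                    raise ValueError(
                        f"group {name!r}: times {t0} and {t1} are not consecutive"
                    )
                continue
            for a in by_time[t0]:
                for b in by_time[t1]:
                    if action == "add":
                        if out.g.in_degree(b) >= 1 and not out.g.has_edge(a, b):
                            raise ValueError(
                                f"adding {a} -> {b} would create a 2nd predecessor"
                            )
                        out.add_link(a, b)
                    else:
                        if not out.remove_link(a, b):
                            warns.append(f"link {a} -> {b} absent: no change")
    if warns:
        import warnings

        warnings.warn("; ".join(warns), stacklevel=2)
    return out


# ----------------------------------------------------------------- tracking

def _bboxes(vol) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    from scipy import ndimage as ndi

    out = {}
    objs = ndi.find_objects(vol.data)
    for lab in vol.labels().tolist():
        sl = objs[lab - 1]
        out[int(lab)] = (
            np.array([s.start for s in sl]),
            np.array([s.stop for s in sl]),
        )
    return out


def _bbox_overlap(a, b) -> int:
    lo = np.maximum(a[0], b[0])
    hi = np.minimum(a[1], b[1])
    if np.any(hi <= lo):
        return 0
    return int(np.prod(hi - lo))


def track_by_overlap(
    ds: Dataset,
    mode: Literal["bbox", "voxel"] = "bbox",
    time_range: tuple[int, int] | None = None,
    channel: int = 0,
) -> LineageGraph:
    """Greedy overlap tracking: each object at t+1 links back to the object
    at t with which it overlaps most (bounding-box intersection volume in
    ``bbox`` mode, voxel intersection in ``voxel`` mode).

    Zero-overlap objects receive no link.  Divisions arise naturally when
    two objects at t+1 both overlap the same object at t most.  Every node
    keeps at most one predecessor, so the result is a valid curated graph."""
    times = ds.times() if time_range is None else list(
        range(time_range[0], time_range[1] + 1)
    )
    if len(times) < 2:
        raise ValueError("tracking needs >= 2 time points")
    graph = LineageGraph()
    for t in times:
        for lab in ds.label_volume(t, channel).labels().tolist():
            graph.add_node((t, int(lab)))
    for t0, t1 in zip(times, times[1:]):
        a = ds.label_volume(t0, channel)
        b = ds.label_volume(t1, channel)
        if mode == "voxel":
            from .quality import overlap_pairs

            df = overlap_pairs(a, b)
            best: dict[int, tuple[int, int]] = {}
            for la, lb, ov in df.itertuples(index=False):
                la, lb, ov = int(la), int(lb), int(ov)
                cur = best.get(lb)
                if cur is None or (ov, -la) > (cur[0], -cur[1]):
                    best[lb] = (ov, la)
            for lb, (ov, la) in best.items():
                if ov > 0:
                    graph.add_link((t0, la), (t1, lb))
        else:
            boxes_a = _bboxes(a)
            boxes_b = _bboxes(b)
            for lb, box_b in boxes_b.items():
                scored = [
                    (_bbox_overlap(box_a, box_b), -la, la)
                    for la, box_a in boxes_a.items()
                ]
                ov, _, la = max(scored, default=(0, 0, 0))
                if ov > 0:
                    graph.add_link((t0, la), (t1, lb))
    return graph


def detect_lineage_anomalies(
    graph: LineageGraph,
    props: RegionPropertyTable,
    volume_jump_factor: float = 1.6,
    min_lifetime: int = 1,
    channel: int = 0,
) -> Selection:
    """Flag candidate lineage errors from volume projections onto the tree.

    Flags (a) nodes whose volume changes by at least ``volume_jump_factor``
    (up or down) between consecutive nodes of one cell without an
    intervening division -- the signature of a missed division or merge;
    (b) cells with lifetime below ``min_lifetime``; (c) cells whose Conklin
    sibling is absent (one-daughter divisions), when names are available."""
    vols = {
        (int(r["time"]), int(r["label"])): float(r["value"])
        for _, r in props.values("volume", channel=channel).iterrows()
    }
    items: set[tuple[int, int, int]] = set()
    for chain in graph.cells():
        if len(chain) < min_lifetime:
            items.add((chain[0][0], channel, chain[0][1]))
        for a, b in zip(chain, chain[1:]):
            va, vb = vols.get(a), vols.get(b)
            if va is None or vb is None or va <= 0 or vb <= 0:
                continue
            ratio = max(va / vb, vb / va)
            if ratio >= volume_jump_factor:
                items.add((b[0], channel, b[1]))
        name = graph.cell_name(chain)
        if name:
            sib = _sibling_name(name)
            if sib is not None:
                all_names = set(graph.names.values())
                if sib not in all_names:
                    items.add((chain[0][0], channel, chain[0][1]))
    return Selection(items=items)


def _sibling_name(name: str) -> str | None:
    """Conklin sibling: daughters k of generation g pair as (2k-1, 2k)."""
    star = name.endswith("*")
    core = name[:-1] if star else name
    try:
        prefix, k = core.rsplit(".", 1)
        k = int(k)
    except ValueError:
        return None
    sib_k = k + 1 if k % 2 == 1 else k - 1
    return f"{prefix}.{sib_k}" + ("*" if star else "")


# ---------------------------------------------------------------- cell trees

@dataclass
class CellTree:
    """Rooted tree of cells; node weight = lifetime (frame count)."""

    lifetime: int
    children: list["CellTree"] = field(default_factory=list)
    name: str | None = None
    key: Node | None = None

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)

    def total_lifetime(self) -> int:
        return self.lifetime + sum(c.total_lifetime() for c in self.children)

    def __hash__(self) -> int:  # identity hash: trees are built once
        return id(self)


def cell_tree(graph: LineageGraph, root: Node) -> CellTree:
    """The cell tree of the lineage subtree rooted at ``root``'s cell.

    Children are ordered by (total subtree lifetime, start label) for
    determinism; each tree node is one maximal single-successor chain."""
    chain = [tuple(root)]
    cur = tuple(root)
    while True:
        succ = graph.successors(cur)
        if len(succ) != 1:
            break
        chain.append(succ[0])
        cur = succ[0]
    children = [cell_tree(graph, s) for s in graph.successors(cur)]
    children.sort(key=lambda c: (c.total_lifetime(), c.key))
    return CellTree(
        lifetime=len(chain),
        children=children,
        name=graph.cell_name(chain),
        key=chain[0],
    )


# --------------------------------------------------------- tree edit distance

def _postorder(root: CellTree) -> list[CellTree]:
    out: list[CellTree] = []

    def rec(n: CellTree) -> None:
        for c in n.children:
            rec(c)
        out.append(n)

    rec(root)
    return out


def tree_edit_distance(
    a: CellTree,
    b: CellTree,
    normalized: bool = False,
) -> float:
    """Ordered-tree edit distance (Zhang–Shasha) with lifetime costs.

    Relabeling costs ``|lifetime_a - lifetime_b|``; inserting or deleting a
    node costs its lifetime.  With these costs the distance is a metric.
    ``normalized=True`` divides by the sum of total lifetimes (the distance
    between a tree and an empty tree equals its total lifetime, so the
    normalized value lies in [0, 1])."""
    A = _postorder(a)
    B = _postorder(b)
    ia = {n: i for i, n in enumerate(A)}
    ib = {n: i for i, n in enumerate(B)}

    def leftmost(nodes, index):
        lm = [0] * len(nodes)
        for i, n in enumerate(nodes):
            cur = n
            while cur.children:
                cur = cur.children[0]
            lm[i] = index[cur]
        return lm

    la = leftmost(A, ia)
    lb = leftmost(B, ib)
    keyroots_a = _keyroots(la)
    keyroots_b = _keyroots(lb)

    cost_del = [n.lifetime for n in A]
    cost_ins = [n.lifetime for n in B]
    td = np.zeros((len(A), len(B)))

    for i in keyroots_a:
        for j in keyroots_b:
            _treedist(i, j, la, lb, cost_del, cost_ins, A, B, td)
    dist = float(td[len(A) - 1, len(B) - 1])
    if normalized:
        denom = a.total_lifetime() + b.total_lifetime()
        return dist / denom if denom else 0.0
    return dist


def _keyroots(lm: list[int]) -> list[int]:
    seen: set[int] = set()
    out = []
    for i in range(len(lm) - 1, -1, -1):
        if lm[i] not in seen:
            out.append(i)
            seen.add(lm[i])
    return sorted(out)


def _treedist(i, j, la, lb, cdel, cins, A, B, td):
    m = i - la[i] + 2
    n = j - lb[j] + 2
    fd = np.zeros((m, n))
    ioff = la[i] - 1
    joff = lb[j] - 1
    for x in range(1, m):
        fd[x, 0] = fd[x - 1, 0] + cdel[x + ioff]
    for y in range(1, n):
        fd[0, y] = fd[0, y - 1] + cins[y + joff]
    for x in range(1, m):
        for y in range(1, n):
            if la[i] == la[x + ioff] and lb[j] == lb[y + joff]:
                rel = abs(A[x + ioff].lifetime - B[y + joff].lifetime)
                fd[x, y] = min(
                    fd[x - 1, y] + cdel[x + ioff],
                    fd[x, y - 1] + cins[y + joff],
                    fd[x - 1, y - 1] + rel,
                )
                td[x + ioff, y + joff] = fd[x, y]
            else:
                p = la[x + ioff] - 1 - ioff
                q = lb[y + joff] - 1 - joff
                fd[x, y] = min(
                    fd[x - 1, y] + cdel[x + ioff],
                    fd[x, y - 1] + cins[y + joff],
                    fd[p, q] + td[x + ioff, y + joff],
                )


def division_delay_between_pairs(graph: LineageGraph) -> dict[str, int]:
    """Frames separating the divisions of bilateral cell pairs.

    For every named cell ``X`` whose contralateral partner ``X*`` exists and
    where both cells divide, returns ``division_time(X) -
    division_time(X*)`` keyed by the unstarred name.  In a perfectly
    synchronous embryo all values are 0; segmentation errors (missed or
    spurious divisions) show up as large delays."""
    chains = graph.cells()
    division_time: dict[str, int] = {}
    for chain in chains:
        nm = graph.cell_name(chain)
        if not nm:
            continue
        last = chain[-1]
        if len(graph.successors(last)) >= 2:
            division_time[nm] = last[0]
    out: dict[str, int] = {}
    for nm, t in division_time.items():
        if nm.endswith("*"):
            continue
        partner = nm + "*"
        if partner in division_time:
            out[nm] = t - division_time[partner]
    return out


def symmetric_pair_distances(
    graph: LineageGraph,
    normalized: bool = False,
    channel: int = 0,
) -> RegionPropertyTable:
    """Lineage distance of each cell to its contralateral homolog.

    Cells pair by name: ``X`` with ``X*``.  For each paired cell the
    tree-edit distance between the subtrees rooted at the two homologs is
    assigned (as property ``lineage_distance``) to every node of the cell's
    chain; unpaired cells get NaN."""
    chains = graph.cells()
    by_name: dict[str, list[Node]] = {}
    for chain in chains:
        nm = graph.cell_name(chain)
        if nm:
            by_name[nm] = chain
    records = []
    for chain in chains:
        nm = graph.cell_name(chain)
        value = float("nan")
        if nm:
            partner = nm[:-1] if nm.endswith("*") else nm + "*"
            if partner in by_name:
                ta = cell_tree(graph, chain[0])
                tb = cell_tree(graph, by_name[partner][0])
                value = tree_edit_distance(ta, tb, normalized=normalized)
        for t, lab in chain:
            records.append(
                {"time": t, "channel": channel, "label": lab,
                 "property": "lineage_distance", "value": value}
            )
    return RegionPropertyTable.from_records(records)
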