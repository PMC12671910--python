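"""Distribution-based error flagging and annotation/segmentation matching.

The automatic error-detection layer: per-object metric values are turned
into candidate-error selections by simple, auditable rules (quartiles, IQR
fences, fixed thresholds).  Thresholds are never chosen automatically -- the
flagged selection is a candidate list for expert curation, not a verdict.

Matching utilities associate point annotations (tracked nucleus positions)
with segmented objects, and pair objects across channels by voxel overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .properties import RegionPropertyTable
from .selection import Selection
from .volume_io import LabeledVolume

__all__ = [
    "FlagRule",
    "flag_outliers",
    "PointMatchResult",
    "match_points_to_labels",
    "match_labels_across_channels",
    "oversegmentation_audit",
]


@dataclass(frozen=True)
class FlagRule:
    """One flagging rule over a single property distribution.

    rules and their params:
      - ``upper_quartile`` / ``lower_quartile``: no params; strictly beyond
        Q3 / Q1 (boundary values are not flagged)
      - ``threshold_gt`` / ``threshold_lt``: (x,)
      - ``iqr_fence``: optional (k,) fence factor, default 1.5
      - ``range``: (lo, hi); flags values outside [lo, hi]
    """

    property: str
    rule: Literal[
        "upper_quartile", "lower_quartile", "threshold_gt", "threshold_lt",
        "iqr_fence", "range",
    ]
    params: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        arity = {"upper_quartile": 0, "lower_quartile": 0, "threshold_gt": 1,
                 "threshold_lt": 1, "iqr_fence": (0, 1), "range": 2}[self.rule]
        n = len(self.params)
        ok = n in arity if isinstance(arity, tuple) else n == arity
        if not ok:
            raise ValueError(f"rule {self.rule!r} takes {arity} params, got {n}")

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of flagged entries for one pooled distribution."""
        v = np.asarray(values, dtype=float)
        if self.rule == "upper_quartile":
            return v > np.quantile(v, 0.75)
        if self.rule == "lower_quartile":
            return v < np.quantile(v, 0.25)
        if self.rule == "threshold_gt":
            return v > self.params[0]
        if self.rule == "threshold_lt":
            return v < self.params[0]
        if self.rule == "iqr_fence":
            k = self.params[0] if self.params else 1.5
            q1, q3 = np.quantile(v, [0.25, 0.75])
            iqr = q3 - q1
            return (v < q1 - k * iqr) | (v > q3 + k * iqr)
        if self.rule == "range":
            lo, hi = self.params
            return (v < lo) | (v > hi)
        raise ValueError(f"unknown rule {self.rule!r}")


def flag_outliers(
    table: RegionPropertyTable,
    rule: FlagRule,
    time_scope: Literal["one", "all"] = "one",
) -> Selection:
    """Flag labels whose property value satisfies the rule.

    Quantile-based rules compute their quantiles per time point when
    ``time_scope="one"`` (linear-interpolation quantiles), pooled over all
    times otherwise.  NaN values are never flagged.
    """
    df = table.values(rule.property, time=None, channel=None)
    if df.empty:
        raise ValueError(f"property {rule.property!r} not present in table")
    df = df[pd.to_numeric(df["value"], errors="coerce").notna()].copy()
    df["value"] = df["value"].astype(float)
    items: set[tuple[int, int, int]] = set()
    group_cols = ["channel"] if time_scope == "all" else ["time", "channel"]
    for _, sub in df.groupby(group_cols):
        flagged = rule.apply(sub["value"].to_numpy())
        for (_, row), f in zip(sub.iterrows(), flagged):
            if f:
                items.add((int(row["time"]), int(row["channel"]), int(row["label"])))
    return Selection(items=items)


@dataclass
class PointMatchResult:
    """Assignment of point annotations to segmented objects.

    ``assignment[i]`` is the label hit by point ``i`` (None for background or
    out-of-bounds).  Labels hit by several points are listed in
    ``shared_labels`` -- in curation these mark candidate missed splits.
    """

    assignment: list[int | None]
    n_unassigned: int
    reasons: list[str]
    shared_labels: dict[int, list[int]] = field(default_factory=dict)

    def unassigned_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.assignment) if a is None]


def match_points_to_labels(
    points: Sequence[tuple[float, float, float, float]],
    labels: LabeledVolume,
) -> PointMatchResult:
    """Assign each (t, z, y, x) physical-coordinate point to the label of the
    voxel it falls in.

    Points at other time indices than the volume's, in background, or out of
    bounds are unassigned (with a reason).  Voxel ``i`` covers the physical
    interval ``[i * voxel_size, (i+1) * voxel_size)``.
    """
    vs = np.asarray(labels.voxel_size, dtype=float)
    shape = np.asarray(labels.shape)
    assignment: list[int | None] = []
    reasons: list[str] = []
    hits: dict[int, list[int]] = {}
    for i, (t, z, y, x) in enumerate(points):
        if int(round(t)) != labels.time:
            assignment.append(None)
            reasons.append(f"time {t} != volume time {labels.time}")
            continue
        idx = np.floor(np.asarray([z, y, x]) / vs).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            assignment.append(None)
            reasons.append("out of bounds")
            continue
        lab = int(labels.data[tuple(idx)])
        if lab == 0:
            assignment.append(None)
            reasons.append("background (point not inside any object)")
        else:
            assignment.append(lab)
            reasons.append("")
            hits.setdefault(lab, []).append(i)
    shared = {lab: idxs for lab, idxs in hits.items() if len(idxs) > 1}
    n_unassigned = sum(a is None for a in assignment)
    return PointMatchResult(assignment, n_unassigned, reasons, shared)


def read_points_csv(path) -> list[tuple[float, float, float, float]]:
    """Read point annotations from a t,z,y,x CSV (physical units)."""
    df = pd.read_csv(path)
    cols = [c for c in ("t", "z", "y", "x") if c in df.columns]
    if len(cols) != 4:
        raise ValueError("points CSV must have columns t,z,y,x")
    return [tuple(map(float, row)) for row in df[["t", "z", "y", "x"]].to_numpy()]


def overlap_pairs(a: LabeledVolume, b: LabeledVolume) -> pd.DataFrame:
    """Voxel-overlap contingency of two co-registered label volumes."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    both = (a.data > 0) & (b.data > 0)
    la, lb = a.data[both], b.data[both]
    pairs, counts = np.unique(
        np.stack([la, lb]), axis=1, return_counts=True
    )
    return pd.DataFrame(
        {"label_a": pairs[0], "label_b": pairs[1], "overlap": counts}
    )


def match_labels_across_channels(
    a: LabeledVolume,
    b: LabeledVolume,
    min_overlap_frac: float = 0.5,
) -> list[tuple[int, int, int]]:
    """Greedy one-to-one matching of labels across two channels by voxel
    overlap (descending); pairs overlapping less than ``min_overlap_frac``
    of the smaller object are excluded."""
    df = overlap_pairs(a, b)
    if df.empty:
        return []
    sizes_a = dict(zip(*np.unique(a.data[a.data > 0], return_counts=True)))
    sizes_b = dict(zip(*np.unique(b.data[b.data > 0], return_counts=True)))
    df = df.sort_values(
        ["overlap", "label_a", "label_b"], ascending=[False, True, True]
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    out: list[tuple[int, int, int]] = []
    for la, lb, ov in df.itertuples(index=False):
        la, lb, ov = int(la), int(lb), int(ov)
        if la in used_a or lb in used_b:
            continue
        smaller = min(sizes_a[la], sizes_b[lb])
        if ov < min_overlap_frac * smaller:
            continue
        used_a.add(la)
        used_b.add(lb)
        out.append((la, lb, ov))
    return out


def oversegmentation_audit(
    seg: LabeledVolume,
    gt: LabeledVolume,
    matched: Iterable[tuple[int, int]] | None = None,
    min_frac: float = 0.05,
) -> dict[int, list[int]]:
    """Classify unmatched segmentation objects as over-segmentations of a
    ground-truth object when they overlap it by at least ``min_frac`` of
    their own volume.

    Returns ``{gt_label: [over-segmented seg labels]}``.
    """
    matched = list(matched or [])
    matched_seg = {s for s, _ in matched}
    df = overlap_pairs(seg, gt)
    if df.empty:
        return {}
    sizes_seg = dict(zip(*np.unique(seg.data[seg.data > 0], return_counts=True)))
    out: dict[int, list[int]] = {}
    for ls, lg, ov in df.itertuples(index=False):
        ls, lg, ov = int(ls), int(lg), int(ov)
        if ls in matched_seg:
            continue
        if ov >= min_frac * sizes_seg[ls]:
            out.setdefault(lg, []).append(ls)
    return out
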