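"""Selections: sets of (time, channel, label) targets for curation operators.

A :class:`Selection` is the unit of targeted editing: every operator that acts
"on the selected objects" receives one.  Optional *groups* tag subsets of the
items so that batch operators (fusion, link editing) can act per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

Item = tuple[int, int, int]  # (time, channel, label)


@dataclass
class Selection:
    """A set of (time, channel, label) items with optional group tags.

    Groups partition a subset of the items; an item may belong to at most one
    group.  Labels are not required to be validated against a volume at
    construction time -- operators validate on use.
    """

    items: set[Item] = field(default_factory=set)
    groups: dict[str, set[Item]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.items = {(int(t), int(c), int(l)) for t, c, l in self.items}
        grouped: set[Item] = set()
        for name, sub in self.groups.items():
            sub = {(int(t), int(c), int(l)) for t, c, l in sub}
            if sub & grouped:
                raise ValueError(f"group {name!r} overlaps another group")
            grouped |= sub
            self.groups[name] = sub
            self.items |= sub

    @classmethod
    def from_labels(
        cls, labels: Iterable[int], time: int = 0, channel: int = 0
    ) -> "Selection":
        return cls(items={(time, channel, int(l)) for l in labels})

    def labels_at(self, time: int, channel: int = 0) -> set[int]:
        return {l for t, c, l in self.items if t == time and c == channel}

    def times(self) -> list[int]:
        return sorted({t for t, _, _ in self.items})

    def __len__(self) -> int:
        return len(self.items)

    def __bool__(self) -> bool:
        return bool(self.items)

    def __or__(self, other: "Selection") -> "Selection":
        return Selection(items=self.items | other.items)

    def __contains__(self, item: Item) -> bool:
        return tuple(item) in self.items

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        rows = []
        group_of: dict[Item, str] = {}
        for name, sub in self.groups.items():
            for it in sub:
                group_of[it] = name
        for t, c, l in sorted(self.items):
            rows.append(
                {"time": t, "channel": c, "label": l,
                 "group": group_of.get((t, c, l), "")}
            )
        pd.DataFrame(rows, columns=["time", "channel", "label", "group"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "Selection":
        df = pd.read_csv(path, dtype={"group": str}, keep_default_na=False)
        if "channel" not in df.columns:
            df["channel"] = 0
        items: set[Item] = set()
        groups: dict[str, set[Item]] = {}
        for _, row in df.iterrows():
            it = (int(row["time"]), int(row["channel"]), int(row["label"]))
            items.add(it)
            g = str(row.get("group", "") or "")
            if g:
                groups.setdefault(g, set()).add(it)
        return cls(items=items, groups=groups)


def as_selection(
    sel: "Selection | Iterable[int] | None",
    time: int = 0,
    channel: int = 0,
) -> Selection | None:
    """Coerce a bare iterable of label ids into a Selection at (time, channel)."""
    if sel is None or isinstance(sel, Selection):
        return sel
    if isinstance(sel, Mapping):
        raise TypeError("cannot coerce a mapping into a Selection")
    return Selection.from_labels(sel, time=time, channel=channel)
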