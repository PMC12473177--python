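"""Domain types and I/O for two-arm ordinal trial data.

The universal input object is :class:`TwoArmCounts`: a 2 x K contingency
table of ordered outcome categories (row 0 = control, row 1 = treatment)
together with an :class:`OrdinalScale` that fixes the category order and the
clinical orientation (whether lower or higher categories are better, as for
the mRS vs the GOS-E).

Category order always comes from an explicit scale specification, never from
file order or lexical sorting: ordinal labels such as mRS "0".."6" or GOS-E
"1".."8" sort incorrectly as strings.  Orientation is metadata only at this
layer; sign conventions are applied downstream by the model and diagnostic
modules.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Orientation",
    "OrdinalScale",
    "TwoArmCounts",
    "MergeSpec",
    "read_counts_csv",
    "read_long_csv",
    "read_utilities_csv",
    "write_counts_csv",
    "write_long_csv",
    "merge_categories",
    "drop_empty_categories",
]


class Orientation(str, enum.Enum):
    """Clinical direction of the scale: which end is the good end."""

    lower_better = "lower_better"
    higher_better = "higher_better"


@dataclass(frozen=True)
class OrdinalScale:
    """An ordered outcome scale with K >= 2 named categories.

    Parameters
    ----------
    labels
        Category names in scale order (index 0 = first category).
    orientation
        Whether lower-indexed or higher-indexed categories are clinically
        better.  Default ``lower_better`` (the mRS convention).
    """

    labels: tuple[str, ...]
    orientation: Orientation = Orientation.lower_better

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if isinstance(self.orientation, str) and not isinstance(
            self.orientation, Orientation
        ):
            object.__setattr__(
                self,
                "orientation",
                Orientation(self.orientation.replace("-", "_")),
            )
        if len(labels) < 2:
            raise ValueError("an ordinal scale needs at least 2 categories")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate category labels: {labels}")

    @property
    def k(self) -> int:
        return len(self.labels)

    def reversed(self) -> "OrdinalScale":
        flip = {
            Orientation.lower_better: Orientation.higher_better,
            Orientation.higher_better: Orientation.lower_better,
        }
        return OrdinalScale(tuple(reversed(self.labels)), flip[self.orientation])


@dataclass(frozen=True)
class TwoArmCounts:
    """A 2 x K table of category counts; row 0 = control, row 1 = treatment."""

    scale: OrdinalScale
    counts: np.ndarray
    arm_names: tuple[str, str] = ("control", "treatment")

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (2, self.scale.k):
            raise ValueError(
                f"counts must be 2x{self.scale.k}, got shape {counts.shape}"
            )
        if not np.all(np.equal(np.mod(counts, 1), 0)):
            raise ValueError("counts must be integers (proportions are rejected)")
        counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(counts.sum(axis=1) < 1):
            raise ValueError(f"empty arm: each arm needs at least one observation")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "arm_names", tuple(self.arm_names))

    @property
    def k(self) -> int:
        return self.scale.k

    @property
    def n_control(self) -> int:
        return int(self.counts[0].sum())

    @property
    def n_treatment(self) -> int:
        return int(self.counts[1].sum())

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def pooled(self) -> np.ndarray:
        """Per-category counts summed over both arms."""
        return self.counts.sum(axis=0)

    def proportions(self) -> np.ndarray:
        """2 x K per-arm category proportions."""
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    def goodness_counts(self) -> np.ndarray:
        """Counts reordered so that column 0 is the clinically best category."""
        if self.scale.orientation is Orientation.lower_better:
            return self.counts
        return self.counts[:, ::-1]

    def reversed(self) -> "TwoArmCounts":
        """Reverse the category order (and flip the orientation metadata)."""
        return TwoArmCounts(self.scale.reversed(), self.counts[:, ::-1], self.arm_names)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long frame with columns arm, category, count."""
        rows = [
            (arm, lab, int(self.counts[g, j]))
            for g, arm in enumerate(self.arm_names)
            for j, lab in enumerate(self.scale.labels)
        ]
        return pd.DataFrame(rows, columns=["arm", "category", "count"])


@dataclass(frozen=True)
class MergeSpec:
    """A partition of category indices into ordered, contiguous blocks.

    ``groups=[(0, 1), (2,), (3,)]`` merges the first two categories, as done
    when adjacent cells are too sparse for a chi-square test.
    """

    groups: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        groups = tuple(tuple(int(i) for i in g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        if any(len(g) == 0 for g in groups):
            raise ValueError("merge blocks must be non-empty")
        flat: list[int] = []
        for g in groups:
            if list(g) != list(range(g[0], g[0] + len(g))):
                raise ValueError(f"categories must be adjacent to merge: {g}")
            flat.extend(g)
        if flat != list(range(len(flat))):
            raise ValueError(
                "merge blocks must be in order and cover all categories exactly once"
            )

    @classmethod
    def from_string(cls, text: str, k: int) -> "MergeSpec":
        """Parse e.g. ``"0+1"`` or ``"0+1,5+6"`` against a K-category scale.

        Indices not mentioned stay as singleton blocks.
        """
        merged: dict[int, tuple[int, ...]] = {}
        taken: set[int] = set()
        for part in text.split(","):
            part = part.strip()
            if not part:
                continue
            idx = tuple(sorted(int(t) for t in part.split("+")))
            if any(i in taken for i in idx):
                raise ValueError(f"category index repeated across blocks: {part}")
            taken.update(idx)
            merged[idx[0]] = idx
        groups: list[tuple[int, ...]] = []
        j = 0
        while j < k:
            if j in merged:
                groups.append(merged[j])
                j = merged[j][-1] + 1
            else:
                if j in taken:
                    raise ValueError(f"block starting before index {j} overlaps it")
                groups.append((j,))
                j += 1
        return cls(tuple(groups))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _resolve_arms(
    arms: Sequence[str], control_arm: str | None
) -> tuple[str, str]:
    unique = list(dict.fromkeys(arms))
    if len(unique) != 2:
        raise ValueError(
            f"expected exactly two arms, found {len(unique)}: {unique}"
        )
    if control_arm is None:
        # Deterministic fallback: first arm in file order is control.
        return unique[0], unique[1]
    if control_arm not in unique:
        raise ValueError(f"control arm {control_arm!r} not among arms {unique}")
    other = unique[0] if unique[1] == control_arm else unique[1]
    return control_arm, other


def _tabulate(
    frame: pd.DataFrame, scale: OrdinalScale, control_arm: str | None
) -> TwoArmCounts:
    frame = frame.copy()
    frame["arm"] = frame["arm"].astype(str).str.strip()
    frame["category"] = frame["category"].astype(str).str.strip()
    unknown = set(frame["category"]) - set(scale.labels)
    if unknown:
        raise ValueError(
            f"unknown category label(s) {sorted(unknown)}; scale has {scale.labels}"
        )
    control, treatment = _resolve_arms(frame["arm"].tolist(), control_arm)
    counts = np.zeros((2, scale.k), dtype=np.int64)
    pos = {lab: j for j, lab in enumerate(scale.labels)}
    arm_row = {control: 0, treatment: 1}
    for (arm, cat), n in frame.groupby(["arm", "category"])["count"].sum().items():
        counts[arm_row[arm], pos[cat]] = n
    return TwoArmCounts(scale, counts, (control, treatment))


def read_counts_csv(
    path, scale: OrdinalScale, control_arm: str | None = None
) -> TwoArmCounts:
    """Read an aggregated counts CSV with header ``arm,category,count``.

    Missing (arm, category) pairs are filled with 0; duplicate pairs are an
    error; categories are ordered by ``scale``, not by file order.
    """
    frame = pd.read_csv(path, dtype=str)
    required = {"arm", "category", "count"}
    if not required.issubset(frame.columns):
        raise ValueError(f"counts CSV must have columns {sorted(required)}")
    if frame.empty:
        raise ValueError("counts CSV is empty")
    as_num = pd.to_numeric(frame["count"], errors="raise")
    if not np.all(np.mod(as_num, 1) == 0) or np.any(as_num < 0):
        raise ValueError("counts must be non-negative integers")
    frame["count"] = as_num.astype(np.int64)
    key = frame[["arm", "category"]].apply(lambda s: s.str.strip())
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate (arm, category) pair: {dup}")
    return _tabulate(frame, scale, control_arm)


def read_long_csv(
    path, scale: OrdinalScale, control_arm: str | None = None
) -> TwoArmCounts:
    """Read a long-format CSV (one row per participant) with header ``arm,category``."""
    frame = pd.read_csv(path, dtype=str)
    if not {"arm", "category"}.issubset(frame.columns):
        raise ValueError("long CSV must have columns arm, category")
    if frame.empty:
        raise ValueError("long CSV is empty")
    frame = frame.assign(count=1)
    out = _tabulate(frame, scale, control_arm)
    assert out.n_total == len(frame)
    return out


def read_utilities_csv(path, scale: OrdinalScale) -> np.ndarray:
    """Read a utility value set CSV with header ``category,utility``.

    Returns one finite float per category, in scale order.
    """
    frame = pd.read_csv(path, dtype={"category": str})
    if not {"category", "utility"}.issubset(frame.columns):
        raise ValueError("utility CSV must have columns category, utility")
    frame["category"] = frame["category"].str.strip()
    mapping = dict(zip(frame["category"], frame["utility"].astype(float)))
    missing = [lab for lab in scale.labels if lab not in mapping]
    if missing:
        raise ValueError(f"utility CSV missing categories: {missing}")
    values = np.array([mapping[lab] for lab in scale.labels], dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("utilities must be finite")
    return values


def write_counts_csv(data: TwoArmCounts, path) -> None:
    data.to_frame().to_csv(path, index=False)


def write_long_csv(data: TwoArmCounts, path) -> None:
    frame = data.to_frame()
    frame = frame.loc[frame.index.repeat(frame["count"])][["arm", "category"]]
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Category manipulation
# ---------------------------------------------------------------------------

MERGE_JOIN = "+"  # display convention for merged labels, e.g. "0+1"


def merge_categories(data: TwoArmCounts, spec: MergeSpec) -> TwoArmCounts:
    """Collapse adjacent categories per ``spec``, summing counts within blocks.

    Mirrors the standard sparse-cell remedy for chi-square tests on ordinal
    tables (e.g. merging mRS 0 and 1); totals are preserved and merged labels
    are joined with ``"+"``.
    """
    flat = [i for g in spec.groups for i in g]
    if sorted(flat) != list(range(data.k)):
        raise ValueError(
            f"merge spec covers {len(flat)} categories but table has {data.k}"
        )
    if len(spec.groups) == data.k:
        return data
    labels = tuple(
        MERGE_JOIN.join(data.scale.labels[i] for i in g) for g in spec.groups
    )
    counts = np.column_stack(
        [data.counts[:, list(g)].sum(axis=1) for g in spec.groups]
    )
    scale = OrdinalScale(labels, data.scale.orientation)
    return TwoArmCounts(scale, counts, data.arm_names)


def drop_empty_categories(data: TwoArmCounts) -> tuple[TwoArmCounts, list[int]]:
    """Remove categories with zero pooled count, preserving order.

    Needed so likelihood fits are well-posed on sparse simulated samples.
    Returns the reduced table and the dropped original indices.
    """
    keep = data.pooled() > 0
    dropped = [int(i) for i in np.flatnonzero(~keep)]
    if not dropped:
        return data, []
    if keep.sum() < 2:
        raise ValueError("fewer than 2 categories remain after dropping empty ones")
    scale = OrdinalScale(
        tuple(lab for lab, k in zip(data.scale.labels, keep) if k),
        data.scale.orientation,
    )
    return TwoArmCounts(scale, data.counts[:, keep], data.arm_names), dropped
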