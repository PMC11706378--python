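"""Hierarchical composite health-security scores and cutoff-based treatment.

The composite index is a tree: 96 sub-indicators average (with equal weights)
into 37 indicators, indicators into 6 categories, categories into one overall
score, all on a 0-100 scale. Because the outcome of the analysis (vaccination
coverage) is itself one of the indicators, the index is re-computed with that
indicator removed and every ancestor re-averaged over its remaining children.

Treatment assignment is a deterministic partition at a cutoff: countries with
score >= cutoff are treated (ties treated), the rest are controls; the years
2020-2022 define the post period.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DegenerateAssignmentError, HierarchyError, ValidationError

LEVELS = ("overall", "category", "indicator", "sub-indicator")
ROOT = "overall"

#: tolerance for "parent equals mean of children" after recomputation
AGG_TOL = 1e-9


@dataclass(frozen=True)
class HierarchySpec:
    """Structure of the score tree: node id -> (parent id, level)."""

    parents: Mapping[str, str | None]
    levels: Mapping[str, str]

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parents.items() if p is None]
        if roots != [ROOT] and set(roots) != {ROOT}:
            raise HierarchyError(f"hierarchy must have the single root {ROOT!r}, got {roots}")
        for node, parent in self.parents.items():
            if parent is not None and parent not in self.parents:
                raise HierarchyError(f"node {node!r} has unknown parent {parent!r}")
            if self.levels.get(node) not in LEVELS:
                raise HierarchyError(f"node {node!r} has invalid level {self.levels.get(node)!r}")

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.parents)

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(n for n, p in self.parents.items() if p == node)

    def leaves(self) -> tuple[str, ...]:
        non_leaves = set(p for p in self.parents.values() if p is not None)
        return tuple(n for n in self.parents if n not in non_leaves)

    def ancestors(self, node: str) -> tuple[str, ...]:
        out = []
        parent = self.parents[node]
        while parent is not None:
            out.append(parent)
            parent = self.parents[parent]
        return tuple(out)

    def subtree(self, node: str) -> tuple[str, ...]:
        out = [node]
        stack = list(self.children(node))
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children(n))
        return tuple(out)

    def drop(self, node: str) -> "HierarchySpec":
        gone = set(self.subtree(node))
        return HierarchySpec(
            parents={n: p for n, p in self.parents.items() if n not in gone},
            levels={n: l for n, l in self.levels.items() if n not in gone},
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "HierarchySpec":
        """Build from a definition table with columns node_id, parent_id, level."""
        parents = {}
        levels = {}
        for row in frame.itertuples(index=False):
            parent = None if pd.isna(row.parent_id) or row.parent_id == "" else str(row.parent_id)
            parents[str(row.node_id)] = parent
            levels[str(row.node_id)] = str(row.level)
        return cls(parents=parents, levels=levels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": list(self.parents),
                "parent_id": ["" if p is None else p for p in self.parents.values()],
                "level": [self.levels[n] for n in self.parents],
            }
        )


@dataclass
class ScoreHierarchy:
    """Per-country composite scores over a shared hierarchy.

    ``values`` is a wide table: index = ISO3 country codes, one column per
    node id, all values in [0, 100]. Non-leaf values equal the unweighted
    mean of their children (within :data:`AGG_TOL` after recomputation).
    """

    spec: HierarchySpec
    values: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.spec.nodes) - set(self.values.columns)
        if missing:
            raise HierarchyError(f"score table lacks columns for nodes {sorted(missing)}")
        vals = self.values[list(self.spec.nodes)]
        if ((vals < 0) | (vals > 100)).any().any():
            raise ValidationError("score values must lie in [0, 100]")

    def score(self, node: str = ROOT) -> pd.Series:
        """Per-country values of one node, indexed by ISO3."""
        if node not in self.values.columns:
            raise HierarchyError(f"unknown node id {node!r}")
        return self.values[node]

    def to_long(self) -> pd.DataFrame:
        """Serialize to the long CSV dialect: iso3, node_id, value."""
        long = self.values[list(self.spec.nodes)].stack().reset_index()
        long.columns = ["iso3", "node_id", "value"]
        return long

    @classmethod
    def from_long(cls, frame: pd.DataFrame, spec: HierarchySpec) -> "ScoreHierarchy":
        wide = frame.pivot(index="iso3", columns="node_id", values="value")
        wide.columns.name = None
        return cls(spec=spec, values=wide)

    @classmethod
    def aggregate_from_leaves(
        cls, spec: HierarchySpec, leaf_values: pd.DataFrame
    ) -> "ScoreHierarchy":
        """Fill every non-leaf node bottom-up as the mean of its children."""
        values = leaf_values.copy()
        for node in _bottom_up_nonleaves(spec):
            kids = spec.children(node)
            values[node] = values[list(kids)].mean(axis=1)
        return cls(spec=spec, values=values)


def _bottom_up_nonleaves(spec: HierarchySpec) -> list[str]:
    # deepest first: sub-indicator parents (indicators), then categories, then root
    order = {"indicator": 0, "category": 1, "overall": 2}
    non_leaves = [n for n in spec.nodes if spec.children(n)]
    return sorted(non_leaves, key=lambda n: order[spec.levels[n]])


def recompute_equal_weight(hierarchy: ScoreHierarchy, removed_node: str) -> ScoreHierarchy:
    """Remove one node (and its subtree) and re-average every ancestor.

    Every ancestor of the removed node is recomputed bottom-up as the
    unweighted mean of its remaining children; all other nodes keep their
    values bit-identically.

    Raises
    ------
    HierarchyError
        if the node is unknown, is the root, or is an only child.
    """
    spec = hierarchy.spec
    if removed_node not in spec.parents:
        raise HierarchyError(f"unknown node id {removed_node!r}")
    parent = spec.parents[removed_node]
    if parent is None:
        raise HierarchyError("cannot remove the root of the hierarchy")
    if len(spec.children(parent)) < 2:
        raise HierarchyError(
            f"removing {removed_node!r} would leave its parent {parent!r} childless"
        )
    new_spec = spec.drop(removed_node)
    values = hierarchy.values[list(new_spec.nodes)].copy()
    # only the chain of ancestors changes; recompute from the removed node's
    # parent upwards
    node = parent
    while node is not None:
        kids = new_spec.children(node)
        values[node] = values[list(kids)].mean(axis=1)
        node = new_spec.parents[node]
    return ScoreHierarchy(spec=new_spec, values=values)


def percentile_of_cutoff(scores: pd.Series, cutoff: float) -> tuple[float, float]:
    """Fraction of countries scoring strictly below ``cutoff``.

    Returns ``(raw_fraction, fraction rounded to two decimals)`` — the
    rounded value is the reporting convention used alongside each cutoff.
    """
    scores = scores.dropna()
    if scores.empty:
        raise ValidationError("cannot compute a percentile from an empty score set")
    raw = float((scores < cutoff).mean())
    return raw, round(raw, 2)


@dataclass(frozen=True)
class TreatmentAssignment:
    """Deterministic partition of countries at a score cutoff."""

    score_id: str
    cutoff: float
    treated: frozenset[str]
    control: frozenset[str]
    post_years: tuple[int, ...] = (2020, 2021, 2022)

    @property
    def n_treated(self) -> int:
        return len(self.treated)

    @property
    def n_control(self) -> int:
        return len(self.control)


def assign_treatment(
    scores: pd.Series,
    cutoff: float,
    post_years: Iterable[int] = (2020, 2021, 2022),
    score_id: str = ROOT,
) -> TreatmentAssignment:
    """Partition countries into treated (score >= cutoff) and control.

    Raises
    ------
    DegenerateAssignmentError
        when either group would be empty; sweeps treat this as a failed
        gate rather than a crash.
    """
    scores = scores.dropna()
    treated = frozenset(scores.index[scores >= cutoff])
    control = frozenset(scores.index[scores < cutoff])
    if not treated or not control:
        raise DegenerateAssignmentError(
            f"cutoff {cutoff} yields {len(treated)} treated / {len(control)} control countries"
        )
    return TreatmentAssignment(
        score_id=score_id,
        cutoff=float(cutoff),
        treated=treated,
        control=control,
        post_years=tuple(sorted(post_years)),
    )


def read_hierarchy(path: str | Path) -> HierarchySpec:
    """Read a hierarchy definition CSV (node_id, parent_id, level)."""
    return HierarchySpec.from_frame(pd.read_csv(path, dtype=str, keep_default_na=False))


def read_scores(path: str | Path, spec: HierarchySpec) -> ScoreHierarchy:
    """Read a long score CSV (iso3, node_id, value) against a hierarchy."""
    frame = pd.read_csv(path)
    return ScoreHierarchy.from_long(frame, spec)
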