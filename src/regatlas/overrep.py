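"""Module composition percentages and the overrepresentation score.

The score is observed/expected - 1 for a gene list's count in a
module, with the expectation proportional to module size and the
list's share of total list membership:

    score = w / ((x / y) * z) - 1

where ``w`` = list genes in the module, ``x`` = list size over the
clustered universe, ``y`` = total list membership over that universe
(a gene in several lists counts once per list), ``z`` = module size.
Zero means exact proportional allocation; -1 is the floor at w = 0.

A literal left-to-right reading of the source equation,
``(w / (x / y)) * z - 1``, is kept behind ``formula="literal"`` for
audit; it is not zero under proportional allocation and is not used
anywhere by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .exprio import GeneList
from .modules import ModuleAssignment

__all__ = [
    "OverrepresentationInput",
    "OverrepresentationTable",
    "module_composition",
    "overrepresentation_score",
    "overrepresentation_table",
]


@dataclass(frozen=True)
class OverrepresentationInput:
    """Counts feeding one (module, list) score."""

    w: int  # genes from the list in the module
    x: int  # genes in the list (within the clustered universe)
    y: int  # total list membership over the clustered universe
    z: int  # genes in the module

    def __post_init__(self) -> None:
        if min(self.x, self.y, self.z) < 1:
            raise ValueError(f"x, y, z must be >= 1, got {self}")
        if not 0 <= self.w <= min(self.x, self.z):
            raise ValueError(f"w must satisfy 0 <= w <= min(x, z), got {self}")
        if self.x > self.y:
            raise ValueError(f"x must not exceed y, got {self}")


def overrepresentation_score(
    inp: OverrepresentationInput, formula: str = "paper"
) -> float:
    """Deviation of a list's module count from proportional allocation."""
    if formula == "paper":
        expected = (inp.x / inp.y) * inp.z
        return inp.w / expected - 1.0
    if formula == "literal":
        return (inp.w / (inp.x / inp.y)) * inp.z - 1.0
    raise ValueError(f"unknown formula {formula!r}")


@dataclass
class OverrepresentationTable:
    """Long-format (module, list) composition and scores."""

    table: pd.DataFrame  # columns: module, list_name, w, z, x, y, percentage, score
    module_sizes: dict[int, int]
    list_sizes: dict[str, int]
    excluded_unassigned: int = 0


def _universe_and_counts(
    assignment: ModuleAssignment,
    lists: Sequence[GeneList],
    include_unassigned: bool,
) -> tuple[set[str], dict[int, list[str]], int]:
    if include_unassigned:
        universe = set(assignment.module_of)
    else:
        universe = {g for g, m in assignment.module_of.items() if m > 0}
    members: dict[int, list[str]] = {}
    for g, m in assignment.module_of.items():
        if g in universe:
            members.setdefault(m, []).append(g)
    n_excluded = len(assignment.module_of) - len(universe)
    return universe, members, n_excluded


def module_composition(
    assignment: ModuleAssignment,
    lists: Sequence[GeneList],
    include_unassigned: bool = False,
) -> pd.DataFrame:
    """Per (module, list): count ``w`` and percentage 100*w/z.

    A gene belonging to several lists contributes w = 1 to each of its
    lists (multi-category genes counted in all relevant categories).
    Empty modules after filtering are excluded.
    """
    universe, members, _ = _universe_and_counts(assignment, lists, include_unassigned)
    rows = []
    for m in sorted(members):
        z = len(members[m])
        if z == 0:
            continue
        member_set = set(members[m])
        for gl in lists:
            w = sum(1 for g in gl.genes if g in member_set)
            rows.append((m, gl.name, w, z, 100.0 * w / z))
    return pd.DataFrame(rows, columns=["module", "list_name", "w", "z", "percentage"])


def overrepresentation_table(
    assignment: ModuleAssignment,
    lists: Sequence[GeneList],
    formula: str = "paper",
    include_unassigned: bool = False,
) -> OverrepresentationTable:
    """Score every (module, list) pair over the clustered universe.

    ``x`` per list and ``y`` (= sum of x over lists) count only genes
    present in the universe; unassigned genes (module 0) are excluded
    by default and reported.
    """
    if not lists:
        raise ValueError("need at least one gene list")
    universe, members, n_excluded = _universe_and_counts(
        assignment, lists, include_unassigned
    )
    modules = sorted(m for m in members if members[m])
    if len([m for m in modules if m != 0 or include_unassigned]) < 2:
        raise ValueError("need at least 2 modules to score overrepresentation")
    x_of = {gl.name: sum(1 for g in gl.genes if g in universe) for gl in lists}
    empty = [name for name, x in x_of.items() if x == 0]
    if empty:
        raise ValueError(f"lists with no genes in the clustered universe: {empty}")
    y = sum(x_of.values())
    comp = module_composition(assignment, lists, include_unassigned)
    scores = []
    for row in comp.itertuples(index=False):
        inp = OverrepresentationInput(
            w=int(row.w), x=x_of[row.list_name], y=y, z=int(row.z)
        )
        scores.append(overrepresentation_score(inp, formula=formula))
    table = comp.assign(
        x=[x_of[n] for n in comp["list_name"]], y=y, score=scores
    )[["module", "list_name", "w", "z", "x", "y", "percentage", "score"]]
    return OverrepresentationTable(
        table=table,
        module_sizes={m: len(members[m]) for m in modules},
        list_sizes=x_of,
        excluded_unassigned=n_excluded,
    )
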