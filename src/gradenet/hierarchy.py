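"""Hierarchy-height layering of TFs and cross-grade level dynamics.

A TF with out-degree O and in-degree I in a grade network has hierarchy
height h = (O - I)/(O + I) in [-1, 1]: near +1 it mostly regulates (a
master regulator), near -1 it is mostly regulated (low-level), near 0 both
(intermediate). Default level cutoffs split [-1, 1] into equal thirds;
isolated TFs (O + I = 0) have no defined height and are left unassigned.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError
from .network import DirectedNetwork

LEVELS = ("master", "intermediate", "low")


def hierarchy_height(out_degree: int, in_degree: int) -> float:
    """h = (O - I) / (O + I); requires O + I >= 1."""
    if out_degree < 0 or in_degree < 0:
        raise ConfigurationError("degrees must be non-negative")
    total = out_degree + in_degree
    if total == 0:
        raise ConfigurationError("hierarchy height undefined for isolated TF")
    return (out_degree - in_degree) / total


@dataclass(frozen=True)
class HierarchyAssignment:
    tf: str
    out_degree: int
    in_degree: int
    h: float
    level: str
    grade: str | None = None


def classify_levels(net: DirectedNetwork, upper: float = 1.0 / 3.0,
                    lower: float = -1.0 / 3.0) -> list[HierarchyAssignment]:
    """Assign each connected TF to master (h > upper), low (h < lower) or
    intermediate (otherwise); isolated nodes are excluded."""
    if not -1.0 <= lower < upper <= 1.0:
        raise ConfigurationError("need -1 <= lower < upper <= 1")
    out_deg = net.out_degree()
    in_deg = net.in_degree()
    assignments = []
    for tf in sorted(net.nodes):
        o, i = out_deg[tf], in_deg[tf]
        if o + i == 0:
            continue
        h = hierarchy_height(o, i)
        level = "master" if h > upper else ("low" if h < lower else "intermediate")
        assignments.append(HierarchyAssignment(tf=tf, out_degree=o, in_degree=i,
                                               h=h, level=level, grade=net.grade))
    return assignments


def assignment_frame(assignments: list[HierarchyAssignment]) -> pd.DataFrame:
    return pd.DataFrame({
        "tf": [a.tf for a in assignments],
        "grade": [a.grade for a in assignments],
        "out_degree": [a.out_degree for a in assignments],
        "in_degree": [a.in_degree for a in assignments],
        "h": [a.h for a in assignments],
        "level": [a.level for a in assignments],
    })


def level_proportions(assignments: list[HierarchyAssignment]) -> dict[str, float]:
    """Fractions of assigned TFs per level; sums to 1."""
    if not assignments:
        raise ConfigurationError("no assignments")
    n = len(assignments)
    return {lvl: sum(1 for a in assignments if a.level == lvl) / n
            for lvl in LEVELS}


def level_transitions(assignments_by_grade: dict[str, list[HierarchyAssignment]]
                      ) -> dict:
    """Level changes of each TF between grade pairs.

    For every ordered grade pair (adjacent and distant), records per-TF
    (from-level, to-level) for TFs assigned in both grades — TFs absent from
    the later grade are recorded as dropped — plus a per-level retention
    summary: the fraction of TFs of that level in the earlier grade that
    keep the same level in the later grade (among those still assigned).
    """
    grades = list(assignments_by_grade)
    if len(grades) < 2:
        raise ConfigurationError("need at least two grades")
    by_grade = {g: {a.tf: a.level for a in assignments_by_grade[g]}
                for g in grades}
    pairs = [(grades[i], grades[j]) for i in range(len(grades))
             for j in range(i + 1, len(grades))]
    transitions: list[dict] = []
    retention: dict[tuple[str, str], dict[str, float]] = {}
    for g_from, g_to in pairs:
        lv_from, lv_to = by_grade[g_from], by_grade[g_to]
        kept_per_level: dict[str, list[int]] = {lvl: [] for lvl in LEVELS}
        for tf, level in lv_from.items():
            if tf in lv_to:
                transitions.append({"tf": tf, "from_grade": g_from,
                                    "to_grade": g_to, "from_level": level,
                                    "to_level": lv_to[tf]})
                kept_per_level[level].append(1 if lv_to[tf] == level else 0)
            else:
                transitions.append({"tf": tf, "from_grade": g_from,
                                    "to_grade": g_to, "from_level": level,
                                    "to_level": "dropped"})
        retention[(g_from, g_to)] = {
            lvl: (sum(kept) / len(kept) if kept else float("nan"))
            for lvl, kept in kept_per_level.items()}
    overall = [t for t in transitions if t["to_level"] != "dropped"]
    return {
        "transitions": transitions,
        "retention_by_level": retention,
        "overall_retention": (
            sum(1 for t in overall if t["from_level"] == t["to_level"]) / len(overall)
            if overall else float("nan")),
    }
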