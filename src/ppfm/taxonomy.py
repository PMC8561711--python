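"""Genome-based species delimitation and synonym grouping.

Two genomes are called conspecific when both whole-genome statistics clear
their conventional species cutoffs — ANI >= 95% (the lower bound of the
95-96% convention) and dDDH >= 70% — as a conjunction by default.
Synonym groups are the connected components of the conspecific graph;
within a component, the proposed name follows the lexicographically
smallest member unless an explicit nomenclatural-priority table is
supplied (priority is curatorial input, never inferred from strings).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .similarity import SimilarityResult


@dataclass(frozen=True)
class PairCall:
    genome_a: str
    genome_b: str
    ani: float
    ddh: float
    gc_diff: float
    conspecific: bool


@dataclass(frozen=True)
class SynonymGroup:
    members: frozenset[str]
    proposed_name: str


def conspecific_pairs(
    results: Iterable[SimilarityResult],
    ani_cutoff: float = 95.0,
    ddh_cutoff: float = 70.0,
    rule: str = "and",
) -> list[PairCall]:
    """One conspecificity call per input pair.

    ``rule`` selects the combination of the two thresholds: ``"and"``
    (default; both must be met), ``"ani"`` or ``"ddh"`` (single criterion).
    """
    if rule not in ("and", "ani", "ddh"):
        raise ValueError("rule must be 'and', 'ani' or 'ddh'")
    calls = []
    for r in results:
        ani_ok = r.ani >= ani_cutoff
        ddh_ok = r.ddh_d4 >= ddh_cutoff
        flag = {"and": ani_ok and ddh_ok, "ani": ani_ok, "ddh": ddh_ok}[rule]
        calls.append(
            PairCall(
                genome_a=r.genome_a,
                genome_b=r.genome_b,
                ani=r.ani,
                ddh=r.ddh_d4,
                gc_diff=r.gc_diff,
                conspecific=flag,
            )
        )
    return calls


def synonym_groups(
    calls: Sequence[PairCall],
    priority: Mapping[str, int] | None = None,
) -> list[SynonymGroup]:
    """Connected components of the conspecific graph.

    Every genome mentioned in ``calls`` lands in exactly one group
    (singletons allowed). A component whose members are not pairwise
    conspecific (non-transitivity) is still merged — components are the
    transitive closure — but triggers a warning. With a ``priority``
    table (lower value = earlier priority), the proposed name is the
    highest-priority member; otherwise the lexicographically smallest.
    """
    graph = nx.Graph()
    called: dict[frozenset[str], bool] = {}
    for c in calls:
        graph.add_node(c.genome_a)
        graph.add_node(c.genome_b)
        called[frozenset((c.genome_a, c.genome_b))] = c.conspecific
        if c.conspecific:
            graph.add_edge(c.genome_a, c.genome_b)
    groups = []
    for component in nx.connected_components(graph):
        for x, y in combinations(sorted(component), 2):
            key = frozenset((x, y))
            if key in called and not called[key]:
                warnings.warn(
                    f"non-transitive conspecificity: {x} and {y} share a "
                    "synonym group but are not conspecific pairwise"
                )
        if priority:
            name = min(sorted(component), key=lambda g: (priority.get(g, float("inf")), g))
        else:
            name = min(component)
        groups.append(SynonymGroup(members=frozenset(component), proposed_name=name))
    return sorted(groups, key=lambda g: g.proposed_name)
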