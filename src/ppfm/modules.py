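"""Metabolic module completion profiling and clade-specificity calls.

A module definition is an ordered list of steps, each step a set of
alternative gene names (any one present satisfies the step). The module
completion ratio (MCR) of a genome is the percentage of steps satisfied by
its gene content. MCR matrices are binarized (a module "occurs" in a
genome only when complete, by default) and filtered to modules occurring
in at least ``min_occ`` but fewer than ``max_occ_exclusive`` genomes
before clade-specificity screening: a module is specific to a clade (or
clade union) when it is present in at least ``presence_floor`` of that
clade's members and absent from every other genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml


@dataclass(frozen=True)
class ModuleDef:
    """A metabolic module: ordered steps of alternative genes."""

    module_id: str
    steps: tuple[frozenset[str], ...]

    def __post_init__(self):
        if not self.steps:
            raise ValueError(f"module {self.module_id!r} has no steps")
        if any(not s for s in self.steps):
            raise ValueError(f"module {self.module_id!r} has an empty step")

    def __len__(self) -> int:
        return len(self.steps)


def load_module_defs(path: str | Path) -> list[ModuleDef]:
    """Load module definitions from YAML.

    Layout::

        modules:
          - id: M_serine
            steps:
              - [sga, hprA]     # alternatives for one step
              - [gck]
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return [
        ModuleDef(
            module_id=m["id"],
            steps=tuple(frozenset(step) for step in m["steps"]),
        )
        for m in cfg["modules"]
    ]


def module_completion(genome_genes: set[str], module: ModuleDef) -> float:
    """MCR: 100 x satisfied steps / total steps."""
    satisfied = sum(1 for step in module.steps if step & genome_genes)
    return 100.0 * satisfied / len(module.steps)


def mcr_matrix(
    genes_by_genome: Mapping[str, set[str]], modules: Iterable[ModuleDef]
) -> pd.DataFrame:
    """Modules x genomes matrix of MCR percentages."""
    modules = list(modules)
    return pd.DataFrame(
        {
            genome: [module_completion(genes, m) for m in modules]
            for genome, genes in genes_by_genome.items()
        },
        index=[m.module_id for m in modules],
    )


def binarize(mcr: pd.DataFrame, threshold: float = 100.0) -> pd.DataFrame:
    """1 where MCR >= threshold (default: only complete modules occur)."""
    return (mcr >= threshold).astype(int)


def binarize_and_filter(
    mcr: pd.DataFrame,
    min_occ: int = 4,
    max_occ_exclusive: int = 65,
    binarize_threshold: float = 100.0,
) -> pd.DataFrame:
    """Binarize, then keep modules occurring in [min_occ, max_occ_exclusive).

    The occurrence count of a module is the number of genomes whose binary
    cell is 1; the filter is idempotent.
    """
    binary = mcr if set(mcr.to_numpy().ravel()) <= {0, 1} else binarize(
        mcr, binarize_threshold
    )
    binary = binary.astype(int)
    occ = binary.sum(axis=1)
    keep = (occ >= min_occ) & (occ < max_occ_exclusive)
    return binary.loc[keep]


def clade_specific(
    binary: pd.DataFrame,
    labels: Mapping[str, str],
    presence_floor: float = 1.0,
    max_union: int = 2,
) -> pd.DataFrame:
    """Per-module clade-specificity calls on a filtered binary matrix.

    A module is specific to a clade set S (a single clade or a union of up
    to ``max_union`` clades) when it is present in at least
    ``presence_floor`` of the members of every clade in S and absent from
    all genomes outside S. The smallest qualifying S is reported;
    non-qualifying modules are "nonspecific".
    """
    genomes = list(binary.columns)
    missing = [g for g in genomes if g not in labels]
    if missing:
        raise ValueError(f"genomes without clade labels: {missing}")
    clades = sorted(set(labels[g] for g in genomes))
    members = {c: [g for g in genomes if labels[g] == c] for c in clades}
    rows = []
    for module_id, cells in binary.iterrows():
        call = "nonspecific"
        for size in range(1, max_union + 1):
            for combo in combinations(clades, size):
                inside = [g for c in combo for g in members[c]]
                outside = [g for g in genomes if g not in inside]
                if any(cells[g] for g in outside):
                    continue
                ok = all(
                    sum(cells[g] for g in members[c]) >= presence_floor * len(members[c])
                    for c in combo
                )
                if ok:
                    call = "+".join(combo)
                    break
            if call != "nonspecific":
                break
        rows.append({"module_id": module_id, "specific_to": call})
    return pd.DataFrame(rows).set_index("module_id")
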