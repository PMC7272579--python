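"""Candidate drug-target mining from directed pathways.

For each molecular subtype, the DNB genes detected at patient transition
points are pooled (the DNB set) together with the transition-point driver
genes and their immediate predecessors in each patient's order (the
driver set).  A gene is nominated as a candidate target when, in some
directed pathway,

  1. the pathway contains at least two driver-set genes,
  2. two of those drivers d1, d2 are connected by a directed path
     d1 -> ... -> d2 whose orientation matches the consensus mutation
     order (d1 mutates before d2), and
  3. the gene lies strictly between them on such a path and belongs to
     the DNB set but not the driver set.

Path enumeration considers simple paths up to a configurable edge budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io import PathwayGraph

__all__ = [
    "TargetContext",
    "CandidateTarget",
    "find_candidate_targets",
    "verify_candidate",
]

DEFAULT_MAX_PATH_LEN = 6


@dataclass
class TargetContext:
    """Subtype-level inputs for target mining."""

    subtype: str
    dnb_set: set[str]
    driver_set: set[str]
    consensus: list[str]  # driver order, earliest first

    def precedes(self, d1: str, d2: str) -> bool:
        return self.consensus.index(d1) < self.consensus.index(d2)


@dataclass(frozen=True, order=True)
class CandidateTarget:
    pathway_id: str
    gene: str
    upstream_driver: str
    downstream_driver: str


def find_candidate_targets(
    pathways: list[PathwayGraph],
    context: TargetContext,
    max_path_len: int = DEFAULT_MAX_PATH_LEN,
) -> list[CandidateTarget]:
    """Enumerate candidate targets satisfying the three pathway conditions.

    Returns a sorted, de-duplicated list.  Pathways with fewer than two
    driver-set genes are skipped; driver pairs whose pathway direction
    contradicts the consensus order yield nothing.
    """
    ordered_drivers = [d for d in context.consensus if d in context.driver_set]
    eligible_dnb = context.dnb_set - context.driver_set
    found: set[CandidateTarget] = set()
    for pw in pathways:
        present = [d for d in ordered_drivers if d in pw.nodes]
        if len(present) < 2:
            continue
        for i, d1 in enumerate(present):
            for d2 in present[i + 1:]:
                # d1 precedes d2 in the consensus order by construction
                try:
                    paths = nx.all_simple_paths(pw.graph, d1, d2, cutoff=max_path_len)
                except nx.NodeNotFound:  # pragma: no cover - filtered above
                    continue
                for path in paths:
                    for gene in path[1:-1]:
                        if gene in eligible_dnb:
                            found.add(
                                CandidateTarget(
                                    pathway_id=pw.pathway_id,
                                    gene=gene,
                                    upstream_driver=d1,
                                    downstream_driver=d2,
                                )
                            )
    return sorted(found)


def verify_candidate(
    candidate: CandidateTarget,
    pathways: list[PathwayGraph],
    context: TargetContext,
    max_path_len: int = DEFAULT_MAX_PATH_LEN,
) -> bool:
    """Independently re-check the three conditions for one candidate.

    Deliberately avoids the generator's enumeration: condition 2 and 3 are
    re-established by a breadth-first reachability argument restricted to
    paths through the candidate gene.
    """
    pw = next((p for p in pathways if p.pathway_id == candidate.pathway_id), None)
    if pw is None:
        return False
    d1, d2, gene = candidate.upstream_driver, candidate.downstream_driver, candidate.gene
    # condition 1: at least two driver-set genes in the pathway
    if len(context.driver_set & pw.nodes) < 2:
        return False
    # order agreement
    if d1 not in context.consensus or d2 not in context.consensus or not context.precedes(d1, d2):
        return False
    # condition 3 membership
    if gene not in context.dnb_set or gene in context.driver_set:
        return False
    # condition 2+3: a simple d1 -> gene -> d2 path within the budget
    if gene not in pw.nodes:
        return False
    for path in nx.all_simple_paths(pw.graph, d1, d2, cutoff=max_path_len):
        if gene in path[1:-1]:
            return True
    return False
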