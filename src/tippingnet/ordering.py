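"""Greedy mutation-order inference and consensus ranking.

Somatic mutations are ordered per patient by a greedy selection rule that
balances two opposing forces: the next mutation must connect to the genes
already affected (its propagation module overlaps the current module
union), and among connecting candidates the one whose addition keeps the
growing connected cluster smallest is chosen.  One sequence is generated
per eligible (non-driver) initial mutation; counting, across sequences,
how often gene i precedes gene j yields a pairwise precedence matrix from
which a total driver order is derived by Copeland scoring.  Matrices from
patients sharing a molecular subtype are summed to give a subtype-level
consensus order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io import GeneNetwork
from .patient import PatientNetwork
from .propagation import PropagationModule

__all__ = [
    "MutationSequence",
    "PrecedenceMatrix",
    "ConsensusOrder",
    "merged_cluster_size",
    "enumerate_sequences",
    "pairwise_precedence",
    "derive_order",
    "consensus_order",
    "kendall_tau",
]


@dataclass
class MutationSequence:
    """One ordered realization of a patient's mutations.

    ``fallback_flags[k]`` is True when position k was filled by the
    no-overlap fallback (smallest remaining module) instead of the greedy
    rule.
    """

    patient_id: str
    genes: list[str]
    fallback_flags: list[bool]


@dataclass
class PrecedenceMatrix:
    """counts[i][j] = number of sequences in which i occurs before j."""

    genes: list[str]
    counts: dict[str, dict[str, int]]

    def get(self, i: str, j: str) -> int:
        return self.counts.get(i, {}).get(j, 0)

    def add(self, other: "PrecedenceMatrix") -> "PrecedenceMatrix":
        genes = sorted(set(self.genes) | set(other.genes))
        counts = {i: {j: self.get(i, j) + other.get(i, j) for j in genes if j != i} for i in genes}
        return PrecedenceMatrix(genes=genes, counts=counts)


@dataclass
class ConsensusOrder:
    """A total driver order with per-gene Copeland scores."""

    scope: str
    genes: list[str]
    copeland: dict[str, int] = field(default_factory=dict)

    def position(self, gene: str) -> int:
        return self.genes.index(gene)


def merged_cluster_size(
    current: set[str], candidate: PropagationModule, network: GeneNetwork
) -> int:
    """Size of the connected cluster after adding a candidate's module.

    Specifically: the order of the connected component containing the
    candidate's seed in the subgraph induced by ``current`` union the
    candidate's members.  The candidate must overlap ``current``.
    """
    if not current & candidate.members:
        raise ValueError(
            f"candidate module for {candidate.seed} does not overlap the current cluster"
        )
    union = current | candidate.members
    sub = network.graph.subgraph(union)
    anchor = candidate.seed if candidate.seed in sub else next(iter(current & candidate.members))
    return len(nx.node_connected_component(sub, anchor))


def _greedy_sequence(
    initial: str,
    seeds: list[str],
    modules: dict[str, PropagationModule],
    network: GeneNetwork,
    patient_id: str,
) -> MutationSequence:
    chosen = [initial]
    flags = [False]
    current = set(modules[initial].members)
    remaining = [s for s in seeds if s != initial]
    while remaining:
        overlapping = [s for s in remaining if modules[s].members & current]
        if overlapping:
            # greedy rule: smallest merged connected cluster, ties lexicographic
            pick = min(
                overlapping,
                key=lambda s: (merged_cluster_size(current, modules[s], network), s),
            )
            flags.append(False)
        else:
            # dead end: no module touches the cluster; take the smallest module
            pick = min(remaining, key=lambda s: (modules[s].size, s))
            flags.append(True)
        chosen.append(pick)
        current |= modules[pick].members
        remaining.remove(pick)
    return MutationSequence(patient_id=patient_id, genes=chosen, fallback_flags=flags)


def enumerate_sequences(
    patient: PatientNetwork,
    modules: dict[str, PropagationModule],
    drivers: set[str],
) -> list[MutationSequence]:
    """One greedy sequence per eligible non-driver initial mutation.

    Initial mutations are the patient's non-driver seeds; drivers may
    still appear later within each sequence.  Patients whose seeds are all
    drivers yield an empty list.
    """
    seeds = sorted(s for s in patient.seeds if s in modules and modules[s].members)
    initials = [s for s in seeds if s not in drivers]
    return [
        _greedy_sequence(init, seeds, modules, patient.network, patient.patient_id)
        for init in initials
    ]


def pairwise_precedence(sequences: list[MutationSequence]) -> PrecedenceMatrix:
    """Count, over sequences, how often each gene precedes each other gene."""
    if not sequences:
        raise ValueError("at least one sequence is required")
    genes = sorted({g for s in sequences for g in s.genes})
    counts = {i: {j: 0 for j in genes if j != i} for i in genes}
    for seq in sequences:
        order = seq.genes
        for a in range(len(order)):
            for b in range(a + 1, len(order)):
                counts[order[a]][order[b]] += 1
    return PrecedenceMatrix(genes=genes, counts=counts)


def derive_order(
    matrix: PrecedenceMatrix, restrict_to: set[str], scope: str = "patient"
) -> ConsensusOrder:
    """Total order by Copeland score over the restricted genes.

    Gene i beats j when C[i][j] > C[j][i].  Genes are ranked by descending
    Copeland score (wins minus losses); ties are broken by descending net
    margin sum_j (C[i][j] - C[j][i]), then lexicographically.
    """
    genes = sorted(set(restrict_to) & set(matrix.genes))
    if not genes:
        raise ValueError("no genes to order after restriction")
    copeland: dict[str, int] = {}
    margin: dict[str, int] = {}
    for i in genes:
        wins = losses = net = 0
        for j in genes:
            if i == j:
                continue
            cij, cji = matrix.get(i, j), matrix.get(j, i)
            net += cij - cji
            if cij > cji:
                wins += 1
            elif cij < cji:
                losses += 1
        copeland[i] = wins - losses
        margin[i] = net
    ordered = sorted(genes, key=lambda g: (-copeland[g], -margin[g], g))
    return ConsensusOrder(scope=scope, genes=ordered, copeland=copeland)


def consensus_order(
    matrices: list[PrecedenceMatrix], drivers: set[str], label: str
) -> ConsensusOrder:
    """Sum per-patient precedence matrices, then derive a driver order."""
    if not matrices:
        raise ValueError(f"no precedence matrices for label {label}")
    total = matrices[0]
    for m in matrices[1:]:
        total = total.add(m)
    restrict = set(total.genes) & drivers
    if not restrict:
        raise ValueError(f"no driver genes appear in any sequence for label {label}")
    return derive_order(total, restrict, scope=label)


def kendall_tau(order_a: list[str], order_b: list[str]) -> float:
    """Kendall rank correlation between two orders by direct pair counting.

    Computed over the genes common to both orders; returns 0.0 when fewer
    than two genes are shared.
    """
    common = [g for g in order_a if g in set(order_b)]
    if len(common) < 2:
        return 0.0
    pos_b = {g: i for i, g in enumerate(order_b)}
    concordant = discordant = 0
    for x in range(len(common)):
        for y in range(x + 1, len(common)):
            if pos_b[common[x]] < pos_b[common[y]]:
                concordant += 1
            else:
                discordant += 1
    return (concordant - discordant) / (concordant + discordant)
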