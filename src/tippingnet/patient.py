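"""Patient-specific network construction.

Each patient's network is the global interaction network filtered by that
patient's paired expression: an interaction survives only if both endpoint
genes are expressed in at least one of the two tissues (tumor or adjacent).
A gene with zero abundance in both tissues — or absent from the expression
table altogether — is considered unexpressed in this patient and all its
interactions are removed.  Mutated genes that survive the filter become the
seeds for mutation-effect propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import ClinicalTable, ExpressionTable, GeneNetwork, MutationCatalog

__all__ = ["PatientProfile", "PatientNetwork", "build_patient_network", "build_profiles"]


class DegeneratePatientError(ValueError):
    """The expression filter removed every interaction for this patient."""


@dataclass
class PatientProfile:
    """One patient's paired expression, mutations and clinical labels."""

    patient_id: str
    tumor_expr: dict[str, float]
    adjacent_expr: dict[str, float]
    mutations: set[str] = field(default_factory=set)
    stage: str = "unknown"
    subtype: str = "unknown"

    def expressed(self, gene: str) -> bool:
        """True unless the gene is zero (or unmeasured) in both tissues."""
        t = self.tumor_expr.get(gene, 0.0)
        a = self.adjacent_expr.get(gene, 0.0)
        return not (t == 0.0 and a == 0.0)


@dataclass
class PatientNetwork:
    """The patient's expressed subnetwork plus mutant seed nodes."""

    patient_id: str
    network: GeneNetwork
    seeds: set[str]


def build_patient_network(global_net: GeneNetwork, profile: PatientProfile) -> PatientNetwork:
    """Filter the global network by the patient's expression.

    An edge (u, v) is retained iff both u and v pass the per-gene filter
    (nonzero in at least one tissue).  Nodes left without edges are pruned.
    Seeds are the patient's mutated genes that remain in the network.

    Raises :class:`DegeneratePatientError` if nothing survives.  A patient
    with zero seeds is returned as-is; downstream propagation skips them.
    """
    expressed = {g for g in global_net.nodes if profile.expressed(g)}
    sub = global_net.subgraph(expressed)
    if sub.n_edges == 0:
        raise DegeneratePatientError(
            f"patient {profile.patient_id}: no interactions survive the expression filter"
        )
    seeds = profile.mutations & sub.nodes
    return PatientNetwork(patient_id=profile.patient_id, network=sub, seeds=seeds)


def build_profiles(
    expression: ExpressionTable,
    catalog: MutationCatalog,
    clinical: ClinicalTable | None = None,
    require_mutations: bool = True,
) -> list[PatientProfile]:
    """Assemble per-patient profiles from the loaded tables.

    Patients must have a tumor/adjacent expression pair; with
    ``require_mutations`` (default) they must also appear in the mutation
    catalog, mirroring the usual cohort intersection of expression and
    mutation assays.
    """
    profiles = []
    for pid in expression.patients:
        if require_mutations and pid not in catalog.mutations:
            continue
        tumor, adjacent = expression.patient_pair(pid)
        profiles.append(
            PatientProfile(
                patient_id=pid,
                tumor_expr=tumor.to_dict(),
                adjacent_expr=adjacent.to_dict(),
                mutations=set(catalog.mutations.get(pid, set())),
                stage=clinical.stage.get(pid, "unknown") if clinical else "unknown",
                subtype=clinical.subtype.get(pid, "unknown") if clinical else "unknown",
            )
        )
    return profiles
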