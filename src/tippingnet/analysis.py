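"""In-memory orchestration of the full analysis over a loaded cohort.

This is the library-level pipeline: given the global network, patient
profiles, driver list and clinical labels, it runs patient-network
construction, propagation, giant-cluster assembly, greedy mutation
ordering, per-subtype consensus, DNB transition-point detection, clinical
consistency validation, gene-set enrichment and (optionally) drug-target
mining.  The file-based runner in :mod:`tippingnet.pipeline` is a thin
wrapper around this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import dnb as dnb_mod
from . import ordering as ord_mod
from .dnb import CISeries, LogRatioMatrix, TransitionPoint, log_ratio_matrix
from .enrichment import EnrichmentResult, compare_subtype_profiles, enrich_gc, profile_summary
from .io import ClinicalTable, GeneNetwork, GeneSetCollection, PathwayGraph
from .ordering import ConsensusOrder, MutationSequence, PrecedenceMatrix
from .patient import PatientNetwork, PatientProfile, build_patient_network
from .propagation import (
    DEFAULT_RESTART,
    DEFAULT_THRESHOLD,
    DEFAULT_TOL,
    GiantCluster,
    PropagationModule,
    build_giant_cluster,
    propagate_patient,
    seed_coverage,
)
from .targets import CandidateTarget, TargetContext, find_candidate_targets

log = logging.getLogger(__name__)

__all__ = ["AnalysisParams", "PatientResult", "CohortResult", "analyze_patient", "analyze_cohort"]


@dataclass
class AnalysisParams:
    restart: float = DEFAULT_RESTART
    tol: float = DEFAULT_TOL
    module_threshold: float = DEFAULT_THRESHOLD
    de_quantile: float = dnb_mod.DEFAULT_DE_QUANTILE
    cluster_seed: int = dnb_mod.DEFAULT_CLUSTER_SEED
    max_path_len: int = 6


@dataclass
class PatientResult:
    patient_id: str
    network: PatientNetwork
    modules: dict[str, PropagationModule]
    gc: GiantCluster
    seed_coverage: float
    sequences: list[MutationSequence] = field(default_factory=list)
    precedence: PrecedenceMatrix | None = None
    driver_order: ConsensusOrder | None = None
    ci: CISeries | None = None
    transition: TransitionPoint | None = None


@dataclass
class CohortResult:
    patients: dict[str, PatientResult]
    consensus: dict[str, ConsensusOrder] = field(default_factory=dict)
    clinical_report: object = None
    enrichment: dict[str, list[EnrichmentResult]] = field(default_factory=dict)
    subtype_comparison: list[dict] = field(default_factory=list)
    targets: dict[str, list[CandidateTarget]] = field(default_factory=dict)


def analyze_patient(
    global_net: GeneNetwork,
    profile: PatientProfile,
    drivers: set[str],
    params: AnalysisParams,
    cohort_matrix_genes: set[str] | None = None,
    cohort: list[PatientProfile] | None = None,
    driver_sequence: list[str] | None = None,
) -> PatientResult:
    """Run network construction through transition-point detection for one patient.

    ``driver_sequence`` overrides the greedy-derived driver order as the
    x-axis of the CI series (used for experiments that condition on a
    known order); by default the order inferred from the patient's own
    greedy sequences is used.
    """
    pnet = build_patient_network(global_net, profile)
    if not pnet.seeds:
        raise ValueError(f"patient {profile.patient_id} has no usable mutant seeds")
    modules = propagate_patient(
        pnet.network, pnet.seeds, r=params.restart, tol=params.tol,
        threshold=params.module_threshold,
    )
    gc = build_giant_cluster(modules, pnet.network)
    cov = seed_coverage(gc, pnet.seeds)
    result = PatientResult(
        patient_id=profile.patient_id, network=pnet, modules=modules, gc=gc, seed_coverage=cov
    )
    result.sequences = ord_mod.enumerate_sequences(pnet, modules, drivers)
    if result.sequences:
        result.precedence = ord_mod.pairwise_precedence(result.sequences)
        driver_seeds = pnet.seeds & drivers
        if driver_seeds & set(result.precedence.genes):
            result.driver_order = ord_mod.derive_order(
                result.precedence, driver_seeds, scope=profile.patient_id
            )

    sequence = driver_sequence
    if sequence is None and result.driver_order is not None:
        sequence = result.driver_order.genes
    if sequence and cohort and len(cohort) >= 3:
        genes = gc.genes if cohort_matrix_genes is None else (gc.genes & cohort_matrix_genes)
        matrix = log_ratio_matrix(cohort, genes)
        result.ci = dnb_mod.ci_series(
            profile.patient_id, sequence, modules, gc, matrix,
            de_quantile=params.de_quantile, seed=params.cluster_seed,
        )
        result.transition = dnb_mod.transition_point(result.ci)
    return result


def analyze_cohort(
    global_net: GeneNetwork,
    profiles: list[PatientProfile],
    drivers: set[str],
    clinical: ClinicalTable,
    params: AnalysisParams | None = None,
    gene_sets: GeneSetCollection | None = None,
    pathways: list[PathwayGraph] | None = None,
) -> CohortResult:
    """Full cohort analysis with greedy-derived per-patient driver orders."""
    params = params or AnalysisParams()
    patients: dict[str, PatientResult] = {}
    for profile in profiles:
        try:
            patients[profile.patient_id] = analyze_patient(
                global_net, profile, drivers, params, cohort=profiles
            )
        except ValueError as exc:
            log.warning("skipping patient %s: %s", profile.patient_id, exc)
    result = CohortResult(patients=patients)

    # per-subtype consensus orders from summed precedence matrices
    by_subtype: dict[str, list[str]] = {}
    for pid in patients:
        sub = clinical.subtype.get(pid, "unknown")
        if sub != "unknown":
            by_subtype.setdefault(sub, []).append(pid)
    for sub, pids in sorted(by_subtype.items()):
        matrices = [patients[p].precedence for p in pids if patients[p].precedence]
        if matrices:
            try:
                result.consensus[sub] = ord_mod.consensus_order(matrices, drivers, sub)
            except ValueError as exc:
                log.warning("no consensus for %s: %s", sub, exc)

    # clinical-stage consistency of transition points
    validated = {
        pid: (pr.transition, pr.driver_order.genes)
        for pid, pr in patients.items()
        if pr.transition is not None and pr.driver_order is not None
    }
    if validated:
        result.clinical_report = dnb_mod.validate_clinical_order(validated, clinical)

    # gene-set enrichment of giant clusters + subtype comparison
    if gene_sets is not None:
        universe = global_net.nodes
        summaries = {}
        for pid, pr in patients.items():
            res = enrich_gc(pr.gc, gene_sets, universe, patient_id=pid)
            result.enrichment[pid] = res
            summaries[pid] = profile_summary(res)
        result.subtype_comparison = compare_subtype_profiles(summaries, clinical)

    # pathway-based candidate target mining per subtype
    if pathways:
        for sub, pids in sorted(by_subtype.items()):
            if sub not in result.consensus:
                continue
            dnb_set: set[str] = set()
            driver_set: set[str] = set()
            for pid in pids:
                pr = patients[pid]
                if pr.transition is None or pr.driver_order is None:
                    continue
                dnb_set |= pr.transition.dnb_genes
                order = pr.driver_order.genes
                step = pr.transition.step
                driver_set.add(order[step - 1])
                if step >= 2:
                    driver_set.add(order[step - 2])
            if not driver_set:
                continue
            consensus_genes = result.consensus[sub].genes
            context = TargetContext(
                subtype=sub,
                dnb_set=dnb_set,
                driver_set=driver_set & set(consensus_genes),
                consensus=consensus_genes,
            )
            result.targets[sub] = find_candidate_targets(
                pathways, context, max_path_len=params.max_path_len
            )
    return result
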