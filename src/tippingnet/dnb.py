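"""Dynamic-network-biomarker (DNB) analysis: criticality index and tipping points.

A dominant gene group signals an approaching critical transition when its
members (1) fluctuate strongly, (2) correlate tightly with one another,
and (3) decouple from the rest of the network.  The three criteria are
combined into a single criticality index

    CI = size * SD_i * PCC_i / PCC_o

where size is the group's gene count, SD_i the average standard deviation
of its members, PCC_i the average absolute Pearson correlation of
within-group pairs, and PCC_o the average absolute Pearson correlation of
group-to-background pairs.  Fluctuation and correlation are measured
across patients on per-patient tumor-vs-adjacent log expression ratios,
which puts every patient's pair of samples on a common "how far from
normal" scale.

Indexing the candidate pool by the patient's cumulative driver-mutation
steps produces a CI series whose peak marks the patient's transition
point; its dominant group is the patient's DNB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .io import ClinicalTable
from .patient import PatientProfile
from .propagation import GiantCluster, PropagationModule

__all__ = [
    "LogRatioMatrix",
    "DominantGroup",
    "CISeries",
    "TransitionPoint",
    "ClinicalConsistencyReport",
    "log_ratio_matrix",
    "compute_ci",
    "dominant_group_at_step",
    "ci_series",
    "transition_point",
    "validate_clinical_order",
    "kmedoids",
]

EPS_PCC_O = 1e-8
DEFAULT_DE_QUANTILE = 0.5
DEFAULT_CLUSTER_SEED = 17
MAX_CLUSTERS = 8


@dataclass
class LogRatioMatrix:
    """Genes x patients matrix of log2((tumor + 1) / (adjacent + 1))."""

    values: pd.DataFrame  # genes x patients

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def patients(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DominantGroup:
    """Candidate DNB group at one mutation step, with CI components."""

    step: int
    members: set[str]
    ci: float
    sd_in: float
    pcc_in: float
    pcc_out: float
    flags: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class CISeries:
    patient_id: str
    driver_sequence: list[str]
    groups: list[DominantGroup]

    @property
    def ci_values(self) -> list[float]:
        return [g.ci for g in self.groups]


@dataclass
class TransitionPoint:
    patient_id: str
    step: int  # 1-based index into the driver sequence
    driver: str
    dnb_genes: set[str]
    ci: float
    flags: list[str] = field(default_factory=list)


@dataclass
class ClinicalConsistencyReport:
    per_subtype: dict[str, dict[str, int]]
    consistent: int = 0
    inconsistent: int = 0
    not_evaluable: int = 0

    @property
    def fraction_consistent(self) -> float | None:
        total = self.consistent + self.inconsistent
        return self.consistent / total if total else None


def log_ratio_matrix(cohort: list[PatientProfile], genes: set[str]) -> LogRatioMatrix:
    """Per-patient tumor/adjacent log2 ratios with a +1 pseudo-count.

    A gene unmeasured in a patient contributes 0 (no change).  At least
    three patients are required for the downstream SD/correlation
    statistics to be meaningful.
    """
    if len(cohort) < 3:
        raise ValueError(f"need >= 3 patients for log-ratio statistics, got {len(cohort)}")
    gene_list = sorted(genes)
    data = np.zeros((len(gene_list), len(cohort)))
    for j, p in enumerate(cohort):
        for i, g in enumerate(gene_list):
            t = p.tumor_expr.get(g, 0.0)
            a = p.adjacent_expr.get(g, 0.0)
            data[i, j] = math.log2((t + 1.0) / (a + 1.0))
    df = pd.DataFrame(data, index=gene_list, columns=[p.patient_id for p in cohort])
    return LogRatioMatrix(values=df)


def _abs_corr(block_a: np.ndarray, block_b: np.ndarray | None = None) -> np.ndarray:
    """|Pearson r| between rows; zero-variance rows contribute 0."""
    if block_b is None:
        block_b = block_a
    sa = block_a.std(axis=1)
    sb = block_b.std(axis=1)
    a = block_a - block_a.mean(axis=1, keepdims=True)
    b = block_b - block_b.mean(axis=1, keepdims=True)
    n = block_a.shape[1]
    cov = a @ b.T / n
    denom = np.outer(sa, sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    return np.abs(np.clip(r, -1.0, 1.0))


def compute_ci(
    matrix: LogRatioMatrix, group: set[str], background: set[str] | None = None
) -> tuple[float, float, float, float, list[str]]:
    """Criticality index of a group against a background.

    Returns ``(ci, sd_in, pcc_in, pcc_out, flags)``.  SD uses the sample
    standard deviation (ddof=1).  Pairs involving a zero-variance gene
    contribute |r| = 0.  PCC_o is floored at 1e-8 to keep CI finite; the
    floor engaging is flagged as ``outer-correlation-floor``.
    """
    if len(group) < 2:
        raise ValueError(f"dominant group needs >= 2 genes, got {len(group)}")
    if background is None:
        background = set(matrix.genes) - group
    if not background:
        raise ValueError("background gene set is empty")
    if len(matrix.patients) < 3:
        raise ValueError("need >= 3 patients")
    g_sorted = sorted(group)
    b_sorted = sorted(background)
    gm = matrix.values.loc[g_sorted].to_numpy()
    bm = matrix.values.loc[b_sorted].to_numpy()
    sd_in = float(gm.std(axis=1, ddof=1).mean())
    r_in = _abs_corr(gm)
    iu = np.triu_indices(len(g_sorted), k=1)
    pcc_in = float(r_in[iu].mean())
    pcc_out = float(_abs_corr(gm, bm).mean())
    flags = []
    denom = pcc_out
    if denom < EPS_PCC_O:
        denom = EPS_PCC_O
        flags.append("outer-correlation-floor")
    ci = len(group) * sd_in * pcc_in / denom
    return ci, sd_in, pcc_in, pcc_out, flags


def kmedoids(
    dist: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> np.ndarray:
    """Partition-around-medoids on a precomputed distance matrix.

    Greedy k-means++-style seeding followed by alternating assignment and
    medoid update; deterministic given the generator state.  Returns a
    label vector of length n.
    """
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} points")
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        d_near = dist[:, medoids].min(axis=1)
        total = d_near.sum()
        if total <= 0:
            # all remaining points coincide with a medoid; pick arbitrarily
            rest = [i for i in range(n) if i not in medoids]
            medoids.append(rest[0])
            continue
        probs = d_near / total
        medoids.append(int(rng.choice(n, p=probs)))
    medoids = sorted(medoids)
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new_medoids = []
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                new_medoids.append(medoids[c])
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids.append(int(members[np.argmin(within)]))
        new_medoids = sorted(new_medoids)
        if new_medoids == medoids:
            break
        medoids = new_medoids
    return np.argmin(dist[:, medoids], axis=1)


def _correlation_distance(block: np.ndarray) -> np.ndarray:
    d = 1.0 - _abs_corr(block)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def _refine_group(matrix: LogRatioMatrix, members: set[str]) -> set[str]:
    """Trim a cluster to its coherent core by excess-correlation scoring.

    Correlation clusters attract weakly coupled genes whose pairwise
    correlations sit at the background (null) level; the CI's linear size
    factor alone cannot shed them.  True group members must satisfy the
    criteria jointly: within-group correlation clearly above the
    group-to-background level.  We therefore walk a prune path — remove
    the least-coherent member (lowest mean within-group |r|) one at a
    time — and return the subgroup along the path maximizing the excess
    signal size * SD_i * max(PCC_i - PCC_o, 0), which is size-stable
    because genes correlating at the background level contribute nothing.
    """
    current = sorted(members)
    best, best_score = set(current), -1.0
    while len(current) >= 2:
        gm = matrix.values.loc[current].to_numpy()
        r = _abs_corr(gm)
        np.fill_diagonal(r, 0.0)
        _, sd_i, pcc_i, pcc_o, _ = compute_ci(matrix, set(current))
        score = len(current) * sd_i * max(pcc_i - pcc_o, 0.0)
        if score > best_score:
            best_score, best = score, set(current)
        if len(current) == 2:
            break
        coherence = r.sum(axis=1) / (len(current) - 1)
        current.pop(int(np.argmin(coherence)))
    return best


def dominant_group_at_step(
    patient_id: str,
    step_k: int,
    sequence: list[str],
    modules: dict[str, PropagationModule],
    gc: GiantCluster,
    matrix: LogRatioMatrix,
    de_quantile: float = DEFAULT_DE_QUANTILE,
    seed: int = DEFAULT_CLUSTER_SEED,
) -> DominantGroup:
    """Select the dominant group for mutation step ``step_k`` (1-based).

    Pool = (union of the first k drivers' modules) restricted to the giant
    cluster and the measured genes.  A differential filter keeps genes
    whose mean absolute log-ratio reaches the ``de_quantile`` pool
    quantile.  The filtered pool is partitioned by k-medoids on the
    distance 1 - |r| with the cluster count chosen by average silhouette;
    the cluster with the highest CI, trimmed to its coherent core (see
    :func:`_refine_group`), is returned.  Degenerate pools (< 4 genes
    after filtering) fall back to the whole pool as a single group.
    """
    if not 1 <= step_k <= len(sequence):
        raise ValueError(f"step {step_k} outside sequence of length {len(sequence)}")
    pool: set[str] = set()
    for d in sequence[:step_k]:
        if d in modules:
            pool |= modules[d].members
    pool &= gc.genes
    pool &= set(matrix.genes)
    flags: list[str] = []
    if len(pool) < 2:
        return DominantGroup(
            step=step_k, members=pool, ci=0.0, sd_in=0.0, pcc_in=0.0, pcc_out=0.0,
            flags=["pool-too-small", "no-signal"],
        )

    pool_sorted = sorted(pool)
    block = matrix.values.loc[pool_sorted].to_numpy()
    de_stat = np.abs(block).mean(axis=1)
    cutoff = float(np.quantile(de_stat, de_quantile))
    filtered = [g for g, s in zip(pool_sorted, de_stat) if s >= cutoff]

    def _single_group(members: list[str], why: str) -> DominantGroup:
        grp = set(members)
        if len(grp) < 2 or len(set(matrix.genes) - grp) == 0:
            return DominantGroup(
                step=step_k, members=grp, ci=0.0, sd_in=0.0, pcc_in=0.0, pcc_out=0.0,
                flags=[why, "no-signal"],
            )
        ci, sd_i, p_i, p_o, f = compute_ci(matrix, grp)
        return DominantGroup(
            step=step_k, members=grp, ci=ci, sd_in=sd_i, pcc_in=p_i, pcc_out=p_o,
            flags=[why] + f,
        )

    if len(filtered) < 4:
        return _single_group(pool_sorted, "pool-too-small")

    fblock = matrix.values.loc[filtered].to_numpy()
    dist = _correlation_distance(fblock)
    n = len(filtered)
    rng = np.random.default_rng(seed)
    best_labels, best_sil = None, -np.inf
    for k in range(2, min(MAX_CLUSTERS, n - 1) + 1):
        labels = kmedoids(dist, k, rng)
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_score(dist, labels, metric="precomputed")
        if sil > best_sil:
            best_sil, best_labels = sil, labels
    if best_labels is None:
        return _single_group(filtered, "clustering-degenerate")

    best: DominantGroup | None = None
    for c in np.unique(best_labels):
        members = {filtered[i] for i in np.flatnonzero(best_labels == c)}
        if len(members) < 2:
            continue
        ci, sd_i, p_i, p_o, f = compute_ci(matrix, members)
        cand = DominantGroup(
            step=step_k, members=members, ci=ci, sd_in=sd_i, pcc_in=p_i, pcc_out=p_o, flags=f
        )
        if (
            best is None
            or cand.ci > best.ci
            or (cand.ci == best.ci and sorted(cand.members) < sorted(best.members))
        ):
            best = cand
    if best is None:
        return _single_group(filtered, "all-clusters-singletons")
    refined = _refine_group(matrix, best.members)
    if refined != best.members:
        ci, sd_i, p_i, p_o, f = compute_ci(matrix, refined)
        best = DominantGroup(
            step=step_k, members=refined, ci=ci, sd_in=sd_i, pcc_in=p_i, pcc_out=p_o,
            flags=f + ["refined"],
        )
    return best


def ci_series(
    patient_id: str,
    sequence: list[str],
    modules: dict[str, PropagationModule],
    gc: GiantCluster,
    matrix: LogRatioMatrix,
    de_quantile: float = DEFAULT_DE_QUANTILE,
    seed: int = DEFAULT_CLUSTER_SEED,
) -> CISeries:
    """One dominant group per driver step 1..L of the patient's sequence."""
    if not sequence:
        raise ValueError(f"patient {patient_id}: empty driver sequence")
    groups = [
        dominant_group_at_step(
            patient_id, k, sequence, modules, gc, matrix, de_quantile=de_quantile, seed=seed
        )
        for k in range(1, len(sequence) + 1)
    ]
    return CISeries(patient_id=patient_id, driver_sequence=list(sequence), groups=groups)


def transition_point(series: CISeries) -> TransitionPoint:
    """Earliest step attaining the maximum CI; its group is the DNB."""
    if not series.groups:
        raise ValueError("empty CI series")
    ci = series.ci_values
    peak = max(ci)
    step = ci.index(peak) + 1
    flags = []
    if peak == 0.0:
        flags.append("no-signal")
    group = series.groups[step - 1]
    return TransitionPoint(
        patient_id=series.patient_id,
        step=step,
        driver=series.driver_sequence[step - 1],
        dnb_genes=set(group.members),
        ci=peak,
        flags=flags,
    )


def validate_clinical_order(
    results: dict[str, tuple[TransitionPoint, list[str]]],
    clinical: ClinicalTable,
) -> ClinicalConsistencyReport:
    """Check that early-stage transition genes mutate before late-stage ones.

    Within each molecular subtype, for every ordered patient pair (e, l)
    with stage(e) < stage(l): the pair is consistent when every transition
    gene of e appears in l's driver order at a position no later than
    every transition gene of l; it is inconsistent when a transition gene
    of e appears strictly after one of l's; pairs whose genes are absent
    from l's order are not evaluable.  (Position equality covers patients
    that share the same transition gene.)
    """
    report = ClinicalConsistencyReport(per_subtype={})
    by_subtype: dict[str, list[str]] = {}
    for pid in results:
        sub = clinical.subtype.get(pid, "unknown")
        if sub != "unknown":
            by_subtype.setdefault(sub, []).append(pid)
    for sub, pids in sorted(by_subtype.items()):
        counts = {"consistent": 0, "inconsistent": 0, "not_evaluable": 0}
        for e in pids:
            for l in pids:
                st_e, st_l = clinical.stage.get(e, "unknown"), clinical.stage.get(l, "unknown")
                if "unknown" in (st_e, st_l) or not int(st_e) < int(st_l):
                    continue
                tp_e, _ = results[e]
                tp_l, order_l = results[l]
                pos = {g: i for i, g in enumerate(order_l)}
                genes_e = {tp_e.driver}
                genes_l = {tp_l.driver}
                if not all(g in pos for g in genes_e) or not all(g in pos for g in genes_l):
                    counts["not_evaluable"] += 1
                    continue
                ok = all(pos[ge] <= pos[gl] for ge in genes_e for gl in genes_l)
                counts["consistent" if ok else "inconsistent"] += 1
        report.per_subtype[sub] = counts
        report.consistent += counts["consistent"]
        report.inconsistent += counts["inconsistent"]
        report.not_evaluable += counts["not_evaluable"]
    return report
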