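"""Gene-set enrichment of giant clusters and between-subtype comparison.

Each patient's giant cluster is tested against every gene set of a
collection with the upper-tail hypergeometric test (universe = nodes of
the preprocessed global network), corrected per collection by
Benjamini-Hochberg.  Per-patient enrichment profiles are then reduced to
a scalar (median -log10 adjusted p) and compared between molecular
subtypes with the exact two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io import ClinicalTable, GeneSetCollection
from .propagation import GiantCluster

__all__ = [
    "EnrichmentResult",
    "hypergeometric_pvalue",
    "enrich_gc",
    "profile_summary",
    "compare_subtype_profiles",
]


@dataclass
class EnrichmentResult:
    patient_id: str
    set_name: str
    overlap: int
    gc_size: int
    set_size: int
    universe_size: int
    pvalue: float
    adjusted_pvalue: float = float("nan")


def hypergeometric_pvalue(overlap: int, gc_size: int, set_size: int, universe: int) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeom(N=universe, K=set_size, n=gc_size)."""
    if overlap > min(gc_size, set_size):
        raise ValueError(f"overlap {overlap} exceeds min(gc_size, set_size)")
    if gc_size > universe or set_size > universe:
        raise ValueError("draw or category size exceeds the universe")
    if min(overlap, gc_size, set_size) < 0 or universe <= 0:
        raise ValueError("counts must be nonnegative with a positive universe")
    return float(hypergeom.sf(overlap - 1, universe, set_size, gc_size))


def enrich_gc(
    gc: GiantCluster,
    sets: GeneSetCollection,
    universe: set[str],
    patient_id: str = "",
) -> list[EnrichmentResult]:
    """One hypergeometric test per gene set, BH-adjusted across the collection.

    Gene sets are intersected with the universe before testing; the giant
    cluster must be contained in the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gc.genes <= universe:
        raise ValueError("giant cluster contains genes outside the universe")
    n_universe = len(universe)
    gc_genes = gc.genes
    results = []
    for name in sorted(sets.sets):
        members = sets.sets[name] & universe
        overlap = len(gc_genes & members)
        p = hypergeometric_pvalue(overlap, len(gc_genes), len(members), n_universe) if members else 1.0
        results.append(
            EnrichmentResult(
                patient_id=patient_id,
                set_name=name,
                overlap=overlap,
                gc_size=len(gc_genes),
                set_size=len(members),
                universe_size=n_universe,
                pvalue=p,
            )
        )
    if results:
        adjusted = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adjusted):
            r.adjusted_pvalue = float(q)
    return results


def profile_summary(results: list[EnrichmentResult]) -> float:
    """Reduce one patient's enrichment profile to median -log10(adjusted p)."""
    if not results:
        raise ValueError("empty enrichment profile")
    qs = np.array([max(r.adjusted_pvalue, 1e-300) for r in results])
    return float(np.median(-np.log10(qs)))


def compare_subtype_profiles(
    summaries: dict[str, float], clinical: ClinicalTable
) -> list[dict]:
    """Exact two-sided rank-sum test between every pair of subtypes.

    ``summaries`` maps patient id to the scalar enrichment summary.
    Subtypes with fewer than two summarized patients are skipped.
    """
    groups: dict[str, list[float]] = {}
    for pid, value in summaries.items():
        sub = clinical.subtype.get(pid, "unknown")
        if sub != "unknown":
            groups.setdefault(sub, []).append(value)
    labels = sorted(g for g, v in groups.items() if len(v) >= 2)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            stat, p = mannwhitneyu(
                groups[a], groups[b], alternative="two-sided", method="exact"
            )
            rows.append(
                {
                    "subtype_a": a,
                    "subtype_b": b,
                    "n_a": len(groups[a]),
                    "n_b": len(groups[b]),
                    "statistic": float(stat),
                    "pvalue": float(p),
                }
            )
    return rows
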