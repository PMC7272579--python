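"""Random-walk-with-restart propagation of mutation effects.

A walker starts at a single mutant seed and at each step either moves to a
uniformly chosen neighbor (probability 1 - r) or restarts at the seed
(probability r).  Its stationary distribution

    p = r (I - (1 - r) M)^(-1) e_seed,

with M the column-normalized adjacency, scores every node's proximity to
the seed.  We obtain it by power iteration of

    P(t+1) = (1 - r) M P(t) + r P(0)

until the max-norm difference between successive iterates falls below a
tolerance.  Nodes scoring above a threshold form the seed's propagation
module; the largest connected component of the union of a patient's
modules is the mutant giant cluster (GC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .io import GeneNetwork

__all__ = [
    "TransitionMatrix",
    "PropagationResult",
    "PropagationModule",
    "GiantCluster",
    "column_normalize",
    "rwr",
    "build_module",
    "propagate_patient",
    "build_giant_cluster",
    "seed_coverage",
]

log = logging.getLogger(__name__)

DEFAULT_RESTART = 0.7
DEFAULT_TOL = 1e-10
DEFAULT_THRESHOLD = 0.001


class ConvergenceError(RuntimeError):
    pass


@dataclass
class TransitionMatrix:
    """Column-stochastic walk matrix over a fixed node order."""

    nodes: list[str]
    matrix: sp.csr_matrix
    index: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.index = {n: i for i, n in enumerate(self.nodes)}


@dataclass
class PropagationResult:
    """Stationary RWR scores from one seed."""

    seed: str
    restart: float
    tol: float
    nodes: list[str]
    scores: np.ndarray
    iterations: int = 0

    def score(self, gene: str) -> float:
        return float(self.scores[self.nodes.index(gene)])

    def as_dict(self) -> dict[str, float]:
        return {g: float(s) for g, s in zip(self.nodes, self.scores)}


@dataclass
class PropagationModule:
    """Genes whose stationary score from one seed exceeds the threshold."""

    seed: str
    members: set[str]
    scores: dict[str, float]
    threshold: float = DEFAULT_THRESHOLD

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GiantCluster:
    """Largest connected component of the union of propagation modules."""

    genes: set[str]
    contributing_seeds: set[str]

    @property
    def size(self) -> int:
        return len(self.genes)


def column_normalize(network: GeneNetwork) -> TransitionMatrix:
    """Column-normalize the adjacency matrix.

    M[i, j] = A[i, j] / degree(j); every column of an isolated-node-free
    network sums to exactly 1.
    """
    nodes = sorted(network.nodes)
    adj = nx.to_scipy_sparse_array(network.graph, nodelist=nodes, format="csc", dtype=float)
    degrees = np.asarray(adj.sum(axis=0)).ravel()
    if (degrees == 0).any():
        bad = nodes[int(np.argmax(degrees == 0))]
        raise ValueError(f"degree-0 node {bad} violates the network contract")
    m = adj @ sp.diags(1.0 / degrees)
    return TransitionMatrix(nodes=nodes, matrix=sp.csr_matrix(m))


def rwr(
    network: GeneNetwork | TransitionMatrix,
    seed: str,
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = 10000,
) -> PropagationResult:
    """Iterate P(t+1) = (1-r) M P(t) + r P(0) to stationarity.

    ``network`` may be a :class:`GeneNetwork` or a precomputed
    :class:`TransitionMatrix` (reused across the seeds of one patient).
    Stops when the max-norm difference between iterates drops below
    ``tol``.  The walk never leaves the seed's connected component, so
    scores elsewhere are exactly zero.
    """
    if not 0.0 < r < 1.0:
        raise ValueError(f"restart probability must lie in (0, 1), got {r}")
    tm = network if isinstance(network, TransitionMatrix) else column_normalize(network)
    if seed not in tm.index:
        raise KeyError(f"seed {seed} is not a node of the network")
    p0 = np.zeros(len(tm.nodes))
    p0[tm.index[seed]] = 1.0
    p = p0.copy()
    for it in range(1, max_iter + 1):
        p_next = (1.0 - r) * (tm.matrix @ p) + r * p0
        residual = np.max(np.abs(p_next - p))
        p = p_next
        if residual < tol:
            return PropagationResult(
                seed=seed, restart=r, tol=tol, nodes=tm.nodes, scores=p, iterations=it
            )
    raise ConvergenceError(
        f"RWR from {seed} did not converge in {max_iter} iterations (residual {residual:.3e})"
    )


def build_module(result: PropagationResult, threshold: float = DEFAULT_THRESHOLD) -> PropagationModule:
    """Keep genes scoring strictly above the threshold.

    With any threshold below the restart probability the module contains at
    least the seed (its score is at least r).  An empty module is allowed
    but logged.
    """
    members = {g for g, s in zip(result.nodes, result.scores) if s > threshold}
    if not members:
        log.warning("module for seed %s is empty at threshold %g", result.seed, threshold)
    scores = {g: float(result.scores[i]) for i, g in enumerate(result.nodes) if g in members}
    return PropagationModule(seed=result.seed, members=members, scores=scores, threshold=threshold)


def propagate_patient(
    network: GeneNetwork,
    seeds: set[str],
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    threshold: float = DEFAULT_THRESHOLD,
    max_iter: int = 10000,
) -> dict[str, PropagationModule]:
    """One RWR per seed over a shared transition matrix."""
    tm = column_normalize(network)
    return {
        s: build_module(rwr(tm, s, r=r, tol=tol, max_iter=max_iter), threshold=threshold)
        for s in sorted(seeds)
    }


def build_giant_cluster(
    modules: list[PropagationModule] | dict[str, PropagationModule],
    network: GeneNetwork,
) -> GiantCluster:
    """Largest connected component of the module-union subgraph.

    Ties on component size are broken by the number of contributing seeds,
    then by the lexicographically smallest sorted gene tuple, so the result
    is deterministic.
    """
    if isinstance(modules, dict):
        modules = list(modules.values())
    union: set[str] = set()
    for m in modules:
        union |= m.members
    if not union:
        raise ValueError("all propagation modules are empty; no giant cluster exists")
    sub = network.graph.subgraph(union)
    components = [set(c) for c in nx.connected_components(sub)]
    # singletons (module genes with no retained neighbors) still count as components

    def seeds_in(comp: set[str]) -> set[str]:
        return {m.seed for m in modules if m.members & comp}

    best = min(
        components,
        key=lambda c: (-len(c), -len(seeds_in(c)), tuple(sorted(c))),
    )
    return GiantCluster(genes=best, contributing_seeds=seeds_in(best))


def seed_coverage(gc: GiantCluster, all_seeds: set[str]) -> float:
    """Fraction of the patient's seeds whose module reaches the GC."""
    if not all_seeds:
        raise ValueError("seed coverage is undefined for an empty seed set")
    return len(gc.contributing_seeds & all_seeds) / len(all_seeds)
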