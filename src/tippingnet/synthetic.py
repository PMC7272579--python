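"""Synthetic cohorts with planted ground truth.

The generator emulates the pipeline's real inputs at desk scale: a
scale-free interaction network (preferential attachment), paired
tumor/adjacent expression per patient, per-patient somatic mutations, a
driver list, clinical stage/subtype labels, gene-set collections and
directed pathways — together with a truth record holding the planted
driver mutation order, the planted DNB gene group and the planted
transition step k*.

Planting scheme
---------------
* Drivers sit on the highest-degree nodes so their propagation modules
  are large and overlap; the planted order is a seeded permutation.
* Each patient mutates a prefix of the planted driver order whose length
  determines the clinical stage (quartile bands), observed through a
  noisy-rank channel: each driver's rank is jittered with Gaussian noise
  calibrated so adjacent driver pairs invert with probability ``p_swap``
  (``p_swap`` >= 0.5 degenerates to a uniformly random order).  Passenger
  mutations are drawn from network neighborhoods of the mutated drivers,
  which guarantees module overlap for the greedy ordering rule.
* Expression is generated in log-ratio space: a latent cohort factor
  gives the planted DNB group pairwise correlation ~ rho_in and
  group-to-background correlation ~ rho_out; DNB amplitudes are inflated
  by ``sd_ratio`` in patients whose driver prefix reaches k*.  Tumor and
  adjacent abundances are then reconstructed so that
  log2((tumor+1)/(adjacent+1)) reproduces the planted values exactly.
* The DNB genes are non-driver neighbors of the k*-th driver, preferring
  nodes far from the earlier drivers so that the full group only enters
  the candidate pool once driver k* has mutated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.stats import norm

from .io import ClinicalTable, GeneNetwork, MutationCatalog, write_json
from .patient import PatientProfile

__all__ = ["SyntheticConfig", "SyntheticTruth", "SyntheticCohort", "generate_cohort",
           "generate_network", "generate_mutations", "generate_expression", "write_cohort"]

SUBTYPE_CYCLE = ["CMS1", "CMS2", "CMS3", "CMS4"]


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults define the reference study conditions."""

    seed: int = 0
    n_genes: int = 300
    attachment_m: int = 2
    n_patients: int = 24
    n_drivers: int = 8
    k_star: int = 5  # planted transition step (1-based within the driver order)
    dnb_size: int = 6
    rho_in: float = 0.8
    rho_out: float = 0.1
    sd_ratio: float = 3.0
    p_swap: float = 0.1
    passengers_per_patient: tuple[int, int] = (6, 14)
    baseline_sd: float = 0.5  # background log2-ratio standard deviation
    base_log_level: tuple[float, float] = (4.0, 8.0)  # adjacent abundance, log2
    p_silent: float = 0.02  # chance a non-driver, non-DNB gene is unexpressed in a patient
    n_gene_sets: int = 20
    gene_set_size: tuple[int, int] = (10, 30)

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.attachment_m >= self.n_genes:
            raise ValueError("attachment parameter m must be < n_genes")
        if self.n_drivers > self.n_genes:
            raise ValueError("more drivers than genes")
        if not 1 <= self.k_star <= self.n_drivers:
            raise ValueError("k_star must index into the driver order")
        if self.dnb_size < 2:
            raise ValueError("planted DNB group needs >= 2 genes")
        if not (0.0 <= self.rho_out <= self.rho_in < 1.0):
            raise ValueError("need 0 <= rho_out <= rho_in < 1")
        if not 0.0 <= self.p_swap <= 1.0:
            raise ValueError("p_swap must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    planted_order: list[str]
    dnb_genes: set[str]
    k_star: int
    patient_driver_order: dict[str, list[str]]  # observed (noisy) per-patient order
    patient_prefix_len: dict[str, int]
    eligible_patients: list[str] = field(default_factory=list)  # prefix reaches k*

    def as_dict(self) -> dict:
        return {
            "planted_order": self.planted_order,
            "dnb_genes": sorted(self.dnb_genes),
            "k_star": self.k_star,
            "patient_driver_order": self.patient_driver_order,
            "patient_prefix_len": self.patient_prefix_len,
            "eligible_patients": self.eligible_patients,
        }


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    network: GeneNetwork
    profiles: list[PatientProfile]
    catalog: MutationCatalog
    clinical: ClinicalTable
    drivers: set[str]
    truth: SyntheticTruth
    gene_sets: dict[str, set[str]] = field(default_factory=dict)
    pathways: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)


def _gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


def generate_network(config: SyntheticConfig, rng: np.random.Generator) -> GeneNetwork:
    """Preferential-attachment network seeded with an m-clique.

    Edge count is C(m, 2) + m * (n - m); the graph is connected with no
    self-loops or duplicate edges, and byte-identical for a given seed.
    """
    config.validate()
    nx_seed = int(rng.integers(2**31 - 1))
    g = nx.barabasi_albert_graph(
        config.n_genes,
        config.attachment_m,
        seed=nx_seed,
        initial_graph=nx.complete_graph(config.attachment_m),
    )
    g = nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes})
    return GeneNetwork(g)


def _pick_drivers(network: GeneNetwork, config: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    by_degree = sorted(network.nodes, key=lambda n: (-network.degree(n), n))
    drivers = by_degree[: config.n_drivers]
    order = list(drivers)
    rng.shuffle(order)
    return order


def _noisy_order(order: list[str], p_swap: float, rng: np.random.Generator) -> list[str]:
    """Rank-jitter channel: adjacent pairs invert with probability p_swap."""
    if p_swap <= 0.0:
        return list(order)
    if p_swap >= 0.5:
        shuffled = list(order)
        rng.shuffle(shuffled)
        return shuffled
    sigma = 1.0 / (math.sqrt(2.0) * norm.ppf(1.0 - p_swap))
    keys = np.arange(len(order)) + sigma * rng.standard_normal(len(order))
    return [order[i] for i in np.argsort(keys, kind="stable")]


def _pick_dnb_genes(
    network: GeneNetwork, planted_order: list[str], config: SyntheticConfig
) -> set[str]:
    """Non-driver neighbors of the k*-th driver, far from earlier drivers."""
    anchor = planted_order[config.k_star - 1]
    drivers = set(planted_order)
    earlier = planted_order[: config.k_star - 1]
    lengths = {d: nx.single_source_shortest_path_length(network.graph, d, cutoff=6) for d in earlier}

    def remoteness(gene: str) -> tuple:
        dists = [lengths[d].get(gene, 7) for d in earlier] or [7]
        return (-min(dists), -sum(dists), network.degree(gene), gene)

    candidates = [n for n in network.graph.neighbors(anchor) if n not in drivers]
    if len(candidates) < config.dnb_size:  # extend to 2-hop neighborhood
        two_hop = {
            n
            for nb in network.graph.neighbors(anchor)
            for n in network.graph.neighbors(nb)
            if n not in drivers and n != anchor
        }
        candidates = sorted(set(candidates) | two_hop)
    if len(candidates) < config.dnb_size:
        raise ValueError("anchor driver neighborhood too small for the planted DNB group")
    return set(sorted(candidates, key=remoteness)[: config.dnb_size])


def generate_mutations(
    config: SyntheticConfig,
    network: GeneNetwork,
    planted_order: list[str],
    rng: np.random.Generator,
) -> tuple[MutationCatalog, ClinicalTable, SyntheticTruth]:
    """Per-patient mutations, stages and subtypes, plus the truth record.

    Each patient mutates a noisy prefix of the planted driver order; the
    prefix length sets the stage (quartile bands over 1..n_drivers), so
    early-stage transition genes precede late-stage ones by construction.
    Passengers are sampled from the mutated drivers' neighborhoods.
    """
    catalog: dict[str, set[str]] = {}
    stage: dict[str, str] = {}
    subtype: dict[str, str] = {}
    driver_order: dict[str, list[str]] = {}
    prefix_len: dict[str, int] = {}
    eligible: list[str] = []
    drivers = set(planted_order)
    lo, hi = config.passengers_per_patient
    for idx in range(config.n_patients):
        pid = f"P{idx + 1:03d}"
        # cycle prefix lengths so every stage band is populated
        length = (idx % config.n_drivers) + 1
        observed = _noisy_order(planted_order[:length], config.p_swap, rng)
        n_pass = int(rng.integers(lo, hi + 1))
        neighborhood = sorted(
            {
                n
                for d in observed
                for n in network.graph.neighbors(d)
                if n not in drivers
            }
        )
        passengers = set(
            rng.choice(neighborhood, size=min(n_pass, len(neighborhood)), replace=False)
        )
        catalog[pid] = set(observed) | passengers
        stage[pid] = str(min(4, 1 + (4 * (length - 1)) // config.n_drivers))
        subtype[pid] = SUBTYPE_CYCLE[idx % len(SUBTYPE_CYCLE)]
        driver_order[pid] = observed
        prefix_len[pid] = length
        if length >= config.k_star:
            eligible.append(pid)
    truth = SyntheticTruth(
        planted_order=list(planted_order),
        dnb_genes=set(),  # filled by generate_expression
        k_star=config.k_star,
        patient_driver_order=driver_order,
        patient_prefix_len=prefix_len,
        eligible_patients=eligible,
    )
    return MutationCatalog(catalog), ClinicalTable(stage=stage, subtype=subtype), truth


def generate_expression(
    config: SyntheticConfig,
    network: GeneNetwork,
    catalog: MutationCatalog,
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> list[PatientProfile]:
    """Paired expression with the planted DNB correlation structure.

    Log-ratios follow a one-factor model: DNB genes load sqrt(rho_in) on a
    latent per-patient factor (pairwise correlation rho_in), background
    genes load rho_out / sqrt(rho_in) (group-to-background correlation
    rho_out).  DNB entries are further scaled by ``sd_ratio`` in patients
    whose driver prefix reaches k*.  Tumor and adjacent abundances are
    reconstructed so the +1 pseudo-count log2 ratio equals the planted
    value exactly; all values are nonnegative.
    """
    genes = sorted(network.nodes)
    n_genes, n_patients = len(genes), config.n_patients
    dnb = _pick_dnb_genes(network, truth.planted_order, config)
    truth.dnb_genes = dnb
    drivers = set(truth.planted_order)
    protected = dnb | drivers

    a_in = math.sqrt(config.rho_in)
    a_bg = config.rho_out / math.sqrt(config.rho_in) if config.rho_in > 0 else 0.0
    z = rng.standard_normal(n_patients)  # latent cohort factor
    noise = rng.standard_normal((n_genes, n_patients))
    base_levels = rng.uniform(*config.base_log_level, size=n_genes)
    silent = rng.random((n_genes, n_patients)) < config.p_silent

    pids = sorted(catalog.mutations)
    profiles = []
    gene_index = {g: i for i, g in enumerate(genes)}
    dnb_rows = np.array([gene_index[g] for g in sorted(dnb)])
    log_ratio = np.empty((n_genes, n_patients))
    for j in range(n_patients):
        loading = np.full(n_genes, a_bg)
        scale = np.full(n_genes, config.baseline_sd)
        loading[dnb_rows] = a_in
        pid = pids[j]
        if truth.patient_prefix_len[pid] >= config.k_star:
            scale[dnb_rows] = config.baseline_sd * config.sd_ratio
        resid = np.sqrt(1.0 - loading**2)
        log_ratio[:, j] = scale * (loading * z[j] + resid * noise[:, j])

    for j, pid in enumerate(pids):
        adjacent = np.power(2.0, base_levels) - 1.0
        tumor = np.power(2.0, base_levels + log_ratio[:, j]) - 1.0
        tumor = np.maximum(tumor, 0.0)
        t_expr, a_expr = {}, {}
        for i, g in enumerate(genes):
            if silent[i, j] and g not in protected:
                t_expr[g] = 0.0
                a_expr[g] = 0.0
            else:
                t_expr[g] = float(tumor[i])
                a_expr[g] = float(adjacent[i])
        profiles.append(
            PatientProfile(
                patient_id=pid,
                tumor_expr=t_expr,
                adjacent_expr=a_expr,
                mutations=set(catalog.mutations[pid]),
            )
        )
    return profiles


def _generate_gene_sets(
    config: SyntheticConfig, network: GeneNetwork, rng: np.random.Generator
) -> dict[str, set[str]]:
    """Half neighborhood-derived (enrichable) sets, half uniform draws."""
    genes = sorted(network.nodes)
    sets: dict[str, set[str]] = {}
    lo, hi = config.gene_set_size
    for i in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        if i % 2 == 0:
            center = genes[int(rng.integers(len(genes)))]
            ball = list(nx.single_source_shortest_path_length(network.graph, center, cutoff=3))
            members = set(rng.choice(ball, size=min(size, len(ball)), replace=False))
            sets[f"NEIGHBORHOOD_SET_{i + 1:02d}"] = members
        else:
            sets[f"RANDOM_SET_{i + 1:02d}"] = set(
                rng.choice(genes, size=size, replace=False)
            )
    return sets


def _generate_pathways(
    config: SyntheticConfig, truth: SyntheticTruth, rng: np.random.Generator
) -> dict[str, list[tuple[str, str, str]]]:
    """Toy directed pathways linking consecutive planted drivers via DNB genes.

    Pathway PW01 routes driver k*-1 -> DNB gene -> driver k* (consistent
    with the planted order); PW02 is the direction-reversed decoy; PW03
    contains a single driver only.
    """
    order = truth.planted_order
    dnb = sorted(truth.dnb_genes)
    k = truth.k_star
    d_prev = order[k - 2] if k >= 2 else order[0]
    d_k = order[k - 1]
    if d_prev == d_k:  # k* = 1 corner: use the following driver instead
        d_k = order[1]
    via = dnb[0]
    via2 = dnb[1 % len(dnb)]
    pathways = {
        "PW01": [(d_prev, "activates", via), (via, "activates", d_k),
                 (d_prev, "activates", via2), (via2, "inhibits", d_k)],
        "PW02": [(d_k, "activates", via), (via, "activates", d_prev)],
        "PW03": [(d_k, "activates", via)],
    }
    return pathways


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate a full cohort; byte-identical for identical configs."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    network = generate_network(config, rng)
    planted_order = _pick_drivers(network, config, rng)
    catalog, clinical, truth = generate_mutations(config, network, planted_order, rng)
    profiles = generate_expression(config, network, catalog, truth, rng)
    for p in profiles:
        p.stage = clinical.stage[p.patient_id]
        p.subtype = clinical.subtype[p.patient_id]
    gene_sets = _generate_gene_sets(config, network, rng)
    pathways = _generate_pathways(config, truth, rng)
    return SyntheticCohort(
        config=config,
        network=network,
        profiles=profiles,
        catalog=catalog,
        clinical=clinical,
        drivers=set(planted_order),
        truth=truth,
        gene_sets=gene_sets,
        pathways=pathways,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write all standard input formats plus truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    edges = sorted("\t".join(sorted(e)) for e in cohort.network.graph.edges)
    (out / "ppi.tsv").write_text("\n".join(edges) + "\n")

    genes = sorted(cohort.network.nodes)
    header = ["gene"]
    manifest = ["sample_id\tpatient_id\trole"]
    columns = []
    for p in cohort.profiles:
        for role, expr in (("tumor", p.tumor_expr), ("adjacent", p.adjacent_expr)):
            sid = f"{p.patient_id}_{'T' if role == 'tumor' else 'N'}"
            header.append(sid)
            manifest.append(f"{sid}\t{p.patient_id}\t{role}")
            columns.append(expr)
    rows = ["\t".join(header)]
    for g in genes:
        rows.append("\t".join([g] + [f"{c.get(g, 0.0):.6g}" for c in columns]))
    (out / "expression.tsv").write_text("\n".join(rows) + "\n")
    (out / "manifest.tsv").write_text("\n".join(manifest) + "\n")

    mut_rows = ["sample_id\tgene_symbol"]
    for pid in sorted(cohort.catalog.mutations):
        for g in sorted(cohort.catalog.mutations[pid]):
            mut_rows.append(f"{pid}\t{g}")
    (out / "mutations.tsv").write_text("\n".join(mut_rows) + "\n")

    clin_rows = ["patient_id\tstage\tsubtype"]
    for pid in sorted(cohort.clinical.stage):
        clin_rows.append(f"{pid}\t{cohort.clinical.stage[pid]}\t{cohort.clinical.subtype[pid]}")
    (out / "clinical.tsv").write_text("\n".join(clin_rows) + "\n")

    (out / "drivers.txt").write_text("\n".join(sorted(cohort.drivers)) + "\n")

    gmt_rows = [
        "\t".join([name, "synthetic gene set"] + sorted(members))
        for name, members in sorted(cohort.gene_sets.items())
    ]
    (out / "sets.gmt").write_text("\n".join(gmt_rows) + "\n")

    pw_dir = out / "pathways"
    pw_dir.mkdir(exist_ok=True)
    for pw_id, edges_ in sorted(cohort.pathways.items()):
        lines = [f"{s}\t{rel}\t{t}" for s, rel, t in edges_]
        (pw_dir / f"{pw_id}.sif").write_text("\n".join(lines) + "\n")

    write_json(cohort.truth.as_dict(), out / "truth.json")
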