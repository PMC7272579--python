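"""File-based end-to-end pipeline runner.

A single YAML config names every input file and every tunable parameter;
:func:`run_pipeline` loads and validates the inputs, runs the in-memory
analysis (:mod:`tippingnet.analysis`) and writes one output per stage
plus a run manifest with a parameter hash and per-stage record counts.
Re-running an unchanged config reproduces an identical manifest.

Config layout::

    inputs:
      ppi: ppi.tsv
      expression: expression.tsv
      manifest: manifest.tsv
      mutations: mutations.tsv
      clinical: clinical.tsv
      drivers: drivers.txt
      gene_sets: sets.gmt          # optional
      pathways: pathways/          # optional directory of .sif files
    parameters:
      restart: 0.7
      tol: 1.0e-10
      module_threshold: 0.001
      de_quantile: 0.5
      cluster_seed: 17
      max_path_len: 6
    output: results/
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import io as tio
from .analysis import AnalysisParams, analyze_cohort
from .patient import build_profiles

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

STAGES = [
    "build-networks", "propagate", "gc", "order", "consensus",
    "dnb", "validate", "enrich", "targets",
]


@dataclasses.dataclass
class PipelineConfig:
    ppi: Path
    expression: Path
    manifest: Path
    mutations: Path
    clinical: Path
    drivers: Path
    output: Path
    gene_sets: Path | None = None
    pathways: Path | None = None
    params: AnalysisParams = dataclasses.field(default_factory=AnalysisParams)

    def validate(self) -> None:
        for name in ("ppi", "expression", "manifest", "mutations", "clinical", "drivers"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config input '{name}' does not exist: {p}")
        for name in ("gene_sets", "pathways"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config input '{name}' does not exist: {p}")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    base = Path(path).parent
    inputs = raw.get("inputs", {})

    def resolve(key):
        return (base / inputs[key]).resolve() if key in inputs and inputs[key] else None

    params = AnalysisParams(**raw.get("parameters", {}))
    cfg = PipelineConfig(
        ppi=resolve("ppi"),
        expression=resolve("expression"),
        manifest=resolve("manifest"),
        mutations=resolve("mutations"),
        clinical=resolve("clinical"),
        drivers=resolve("drivers"),
        gene_sets=resolve("gene_sets"),
        pathways=resolve("pathways"),
        output=(base / raw["output"]).resolve(),
    )
    cfg.params = params
    cfg.validate()
    return cfg


def _param_hash(params: AnalysisParams) -> str:
    blob = json.dumps(dataclasses.asdict(params), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    config.validate()
    out = Path(config.output)
    out.mkdir(parents=True, exist_ok=True)

    network, load_report = tio.read_ppi_edgelist(config.ppi)
    expression = tio.read_expression_table(config.expression, config.manifest)
    catalog = tio.read_mutation_table(config.mutations)
    clinical = tio.read_clinical_table(config.clinical)
    drivers = tio.read_driver_list(config.drivers)
    gene_sets = tio.read_gmt(config.gene_sets) if config.gene_sets else None
    pathways = tio.read_pathway_dir(config.pathways) if config.pathways else None

    profiles = build_profiles(expression, catalog, clinical)
    result = analyze_cohort(
        network, profiles, drivers, clinical,
        params=config.params, gene_sets=gene_sets, pathways=pathways,
    )

    counts: dict[str, int] = {}

    net_rows = ["patient_id\tn_nodes\tn_edges\tn_seeds"]
    for pid, pr in sorted(result.patients.items()):
        net_rows.append(
            f"{pid}\t{pr.network.network.n_nodes}\t{pr.network.network.n_edges}\t{len(pr.network.seeds)}"
        )
    (out / "networks.tsv").write_text("\n".join(net_rows) + "\n")
    counts["build-networks"] = len(result.patients)

    modules_obj = {
        pid: {seed: sorted(m.members) for seed, m in pr.modules.items()}
        for pid, pr in result.patients.items()
    }
    tio.write_json(modules_obj, out / "modules.json")
    counts["propagate"] = sum(len(m) for m in modules_obj.values())

    gc_obj = {
        pid: {
            "genes": sorted(pr.gc.genes),
            "contributing_seeds": sorted(pr.gc.contributing_seeds),
            "seed_coverage": pr.seed_coverage,
        }
        for pid, pr in result.patients.items()
    }
    tio.write_json(gc_obj, out / "giant_clusters.json")
    counts["gc"] = len(gc_obj)

    order_obj = {
        pid: {
            "sequences": [s.genes for s in pr.sequences],
            "driver_order": pr.driver_order.genes if pr.driver_order else None,
        }
        for pid, pr in result.patients.items()
    }
    tio.write_json(order_obj, out / "orders.json")
    counts["order"] = sum(len(v["sequences"]) for v in order_obj.values())

    cons_rows = ["subtype\trank\tgene\tcopeland"]
    for sub, order in sorted(result.consensus.items()):
        for rank, gene in enumerate(order.genes, start=1):
            cons_rows.append(f"{sub}\t{rank}\t{gene}\t{order.copeland[gene]}")
    (out / "consensus.tsv").write_text("\n".join(cons_rows) + "\n")
    counts["consensus"] = len(result.consensus)

    dnb_obj = {
        pid: {
            "ci": pr.ci.ci_values if pr.ci else None,
            "transition_step": pr.transition.step if pr.transition else None,
            "transition_driver": pr.transition.driver if pr.transition else None,
            "dnb_genes": sorted(pr.transition.dnb_genes) if pr.transition else None,
        }
        for pid, pr in result.patients.items()
    }
    tio.write_json(dnb_obj, out / "dnb.json")
    counts["dnb"] = sum(1 for v in dnb_obj.values() if v["transition_step"] is not None)

    if result.clinical_report is not None:
        rep = result.clinical_report
        tio.write_json(
            {
                "per_subtype": rep.per_subtype,
                "consistent": rep.consistent,
                "inconsistent": rep.inconsistent,
                "not_evaluable": rep.not_evaluable,
                "fraction_consistent": rep.fraction_consistent,
            },
            out / "validation.json",
        )
        counts["validate"] = rep.consistent + rep.inconsistent + rep.not_evaluable
    else:
        counts["validate"] = 0

    enr_rows = ["patient_id\tset_name\toverlap\tgc_size\tset_size\tuniverse\tpvalue\tadj_pvalue"]
    for pid, results_ in sorted(result.enrichment.items()):
        for r in results_:
            enr_rows.append(
                f"{pid}\t{r.set_name}\t{r.overlap}\t{r.gc_size}\t{r.set_size}"
                f"\t{r.universe_size}\t{r.pvalue:.6g}\t{r.adjusted_pvalue:.6g}"
            )
    (out / "enrichment.tsv").write_text("\n".join(enr_rows) + "\n")
    tio.write_json(result.subtype_comparison, out / "subtype_comparison.json")
    counts["enrich"] = len(enr_rows) - 1

    tgt_rows = ["subtype\tpathway\tgene\tupstream_driver\tdownstream_driver"]
    for sub, cands in sorted(result.targets.items()):
        for c in cands:
            tgt_rows.append(
                f"{sub}\t{c.pathway_id}\t{c.gene}\t{c.upstream_driver}\t{c.downstream_driver}"
            )
    (out / "targets.tsv").write_text("\n".join(tgt_rows) + "\n")
    counts["targets"] = len(tgt_rows) - 1

    manifest = {
        "stages": [{"name": s, "records": counts.get(s, 0)} for s in STAGES],
        "parameter_hash": _param_hash(config.params),
        "parameters": dataclasses.asdict(config.params),
        "inputs": {
            "ppi": str(config.ppi),
            "expression": str(config.expression),
            "mutations": str(config.mutations),
            "clinical": str(config.clinical),
            "drivers": str(config.drivers),
        },
        "load_report": load_report.as_dict(),
        "n_patients": len(result.patients),
    }
    tio.write_json(manifest, out / "run_manifest.json")
    return manifest
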