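"""Readers, writers and validated containers for all external formats.

The pipeline consumes five plain-text formats: a two-column interaction
edge list (TSV or SIF), a genes x samples expression TSV with a sample
manifest, a minimal mutation table (sample_id / gene_symbol), GMT gene-set
collections, and three-column SIF pathway files.  Gene symbols are
whitespace-trimmed and uppercased on input so that case drift between
resources cannot split one gene into two nodes.

Interaction networks are preprocessed on load: self-interactions are
dropped, duplicate unordered pairs are collapsed, and isolated nodes never
enter the graph (an edge list cannot express them; after self-loop removal
every remaining node has degree >= 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "GeneNetwork",
    "ExpressionTable",
    "MutationCatalog",
    "ClinicalTable",
    "GeneSetCollection",
    "PathwayGraph",
    "LoadReport",
    "ParseError",
    "ValidationError",
    "read_ppi_edgelist",
    "write_ppi_edgelist",
    "read_expression_table",
    "read_mutation_table",
    "read_clinical_table",
    "read_driver_list",
    "read_gmt",
    "read_pathway_sif",
    "read_pathway_dir",
    "normalize_symbol",
]

STAGES = {"1", "2", "3", "4", "unknown"}
SUBTYPES = {"CMS1", "CMS2", "CMS3", "CMS4", "unknown"}


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""


class ValidationError(ValueError):
    """An input parsed but violated a container invariant."""


def normalize_symbol(raw: str) -> str:
    """Trim and uppercase a gene symbol."""
    sym = raw.strip().upper()
    if not sym:
        raise ParseError("empty gene symbol")
    return sym


@dataclass
class LoadReport:
    """Per-file accounting of kept and dropped records.

    Conservation holds by construction: ``total_lines`` equals the sum of
    kept, dropped self-loops, dropped duplicates, dropped malformed and
    skipped blank/comment lines.
    """

    path: str = ""
    total_lines: int = 0
    kept: int = 0
    dropped_self_loops: int = 0
    dropped_duplicates: int = 0
    dropped_malformed: int = 0
    skipped_blank: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class GeneNetwork:
    """Undirected interaction network after preprocessing.

    Invariants: no self-loops, no duplicate unordered edges, every node has
    degree >= 1, symbols are non-empty uppercase strings.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def validate(self) -> None:
        for u, v in self.graph.edges:
            if u == v:
                raise ValidationError(f"self-loop on {u}")
        for n in self.graph.nodes:
            if self.graph.degree(n) == 0:
                raise ValidationError(f"isolated node {n}")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "GeneNetwork":
        g = nx.Graph()
        for u, v in edges:
            u, v = normalize_symbol(u), normalize_symbol(v)
            if u != v:
                g.add_edge(u, v)
        return cls(g)

    def subgraph(self, nodes: Iterable[str]) -> "GeneNetwork":
        """Induced subgraph with isolated nodes pruned."""
        sub = self.graph.subgraph(nodes).copy()
        sub.remove_nodes_from([n for n in sub.nodes if sub.degree(n) == 0])
        return GeneNetwork(sub)


@dataclass
class ExpressionTable:
    """Genes x samples abundance matrix with tumor/adjacent pairing.

    ``values`` holds nonnegative abundances (the pipeline treats them as
    arbitrary nonnegative expression measures, not specifically counts).
    Each patient contributes exactly one tumor and one adjacent sample.
    """

    values: pd.DataFrame  # genes x samples
    sample_role: dict[str, str]  # sample -> {"tumor", "adjacent"}
    sample_patient: dict[str, str]  # sample -> patient id

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_patient[s], None)
        return list(seen)

    def patient_pair(self, patient_id: str) -> tuple[pd.Series, pd.Series]:
        """Return (tumor, adjacent) expression vectors for a patient."""
        tumor = adjacent = None
        for s in self.values.columns:
            if self.sample_patient[s] != patient_id:
                continue
            if self.sample_role[s] == "tumor":
                tumor = self.values[s]
            else:
                adjacent = self.values[s]
        if tumor is None or adjacent is None:
            raise KeyError(f"patient {patient_id} lacks a tumor/adjacent pair")
        return tumor, adjacent

    def validate(self) -> None:
        if (self.values.values < 0).any():
            bad = self.values[(self.values < 0).any(axis=1)].index[0]
            raise ValidationError(f"negative expression value for gene {bad}")
        counts: dict[str, dict[str, int]] = {}
        for s in self.values.columns:
            pid = self.sample_patient[s]
            role = self.sample_role[s]
            counts.setdefault(pid, {"tumor": 0, "adjacent": 0})[role] += 1
        for pid, c in counts.items():
            if c["tumor"] != 1 or c["adjacent"] != 1:
                raise ValidationError(
                    f"patient {pid} has {c['tumor']} tumor and "
                    f"{c['adjacent']} adjacent samples (need exactly 1 each)"
                )


@dataclass
class MutationCatalog:
    """Per-patient sets of mutated gene symbols."""

    mutations: dict[str, set[str]]

    def patients(self) -> list[str]:
        return list(self.mutations)

    def __getitem__(self, patient_id: str) -> set[str]:
        return self.mutations[patient_id]


@dataclass
class ClinicalTable:
    """Stage (1-4 or unknown) and molecular subtype (CMS1-4 or unknown)."""

    stage: dict[str, str]
    subtype: dict[str, str]

    def patients_with_subtype(self, label: str) -> list[str]:
        return [p for p, s in self.subtype.items() if s == label]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. a cancer-hallmark GMT collection)."""

    sets: dict[str, set[str]]

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class PathwayGraph:
    """Directed regulatory pathway; edges carry an optional relation label."""

    pathway_id: str
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


# ---------------------------------------------------------------------------
# readers


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            yield lineno, line.rstrip("\n")


def read_ppi_edgelist(
    path: str | Path, dedupe: bool = True, tolerant: bool = False
) -> tuple[GeneNetwork, LoadReport]:
    """Read a two-or-more-column interaction edge list.

    Only the first two columns are used.  Self-interactions are removed,
    duplicate unordered pairs collapsed (when ``dedupe``) and the returned
    network therefore has no degree-0 nodes.  In strict mode (default) a
    line with fewer than two columns raises :class:`ParseError` with its
    line number; ``tolerant`` logs it in the report and skips it.
    """
    path = Path(path)
    report = LoadReport(path=str(path))
    g = nx.Graph()
    seen: set[frozenset] = set()
    for lineno, line in _data_lines(path):
        report.total_lines += 1
        if not line.strip() or line.startswith("#"):
            report.skipped_blank += 1
            continue
        fields = line.split()
        if len(fields) < 2:
            if tolerant:
                report.dropped_malformed += 1
                continue
            raise ParseError(f"{path}:{lineno}: expected >= 2 columns, got {len(fields)}")
        u, v = normalize_symbol(fields[0]), normalize_symbol(fields[1])
        if u == v:
            report.dropped_self_loops += 1
            continue
        key = frozenset((u, v))
        if key in seen:
            if dedupe:
                report.dropped_duplicates += 1
                continue
        seen.add(key)
        g.add_edge(u, v)
        report.kept += 1
    if g.number_of_edges() == 0:
        raise ValidationError(f"{path}: no usable interactions after preprocessing")
    return GeneNetwork(g), report


def write_ppi_edgelist(network: GeneNetwork, path: str | Path) -> None:
    """Write one edge per line, endpoints sorted, lines sorted (diff-friendly)."""
    lines = sorted("\t".join(sorted((u, v))) for u, v in network.graph.edges)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_expression_table(path: str | Path, manifest: str | Path) -> ExpressionTable:
    """Read an expression TSV (first column = gene) plus a sample manifest.

    The manifest is a TSV with columns ``sample_id``, ``patient_id``,
    ``role`` (tumor|adjacent).  Every sample column must be listed; each
    patient must contribute exactly one tumor and one adjacent sample.
    """
    man = pd.read_csv(manifest, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "role"}
    if not required.issubset(man.columns):
        raise ParseError(f"{manifest}: manifest needs columns {sorted(required)}")
    roles = dict(zip(man["sample_id"], man["role"]))
    patients = dict(zip(man["sample_id"], man["patient_id"]))
    bad_roles = {r for r in roles.values() if r not in {"tumor", "adjacent"}}
    if bad_roles:
        raise ValidationError(f"{manifest}: unknown sample roles {sorted(bad_roles)}")

    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [normalize_symbol(g) for g in df.index]
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate gene row {dup}")
    missing = [s for s in df.columns if s not in roles]
    if missing:
        raise ValidationError(f"{path}: samples missing from manifest: {missing}")
    neg = df.lt(0)
    if neg.any().any():
        col = neg.any()[neg.any()].index[0]
        gene = neg[col][neg[col]].index[0]
        raise ValidationError(f"{path}: negative value for gene {gene}, sample {col}")
    table = ExpressionTable(
        values=df,
        sample_role={s: roles[s] for s in df.columns},
        sample_patient={s: patients[s] for s in df.columns},
    )
    table.validate()
    return table


def read_mutation_table(path: str | Path) -> MutationCatalog:
    """Read a minimal mutation table: TSV with sample_id and gene_symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "gene_symbol"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}, got {list(df.columns)}")
    catalog: dict[str, set[str]] = {}
    for pid, gene in zip(df["sample_id"], df["gene_symbol"]):
        catalog.setdefault(str(pid), set()).add(normalize_symbol(gene))
    return MutationCatalog(catalog)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read patient_id / stage / subtype; NA or blank becomes 'unknown'."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    required = {"patient_id", "stage", "subtype"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate patient {dup}")
    stage, subtype = {}, {}
    for _, row in df.iterrows():
        st = row["stage"].strip() or "unknown"
        sub = row["subtype"].strip() or "unknown"
        if st.upper() == "NA":
            st = "unknown"
        if sub.upper() == "NA":
            sub = "unknown"
        if st not in STAGES:
            raise ValidationError(f"{path}: bad stage {st!r} for {row['patient_id']}")
        if sub not in SUBTYPES:
            raise ValidationError(f"{path}: bad subtype {sub!r} for {row['patient_id']}")
        stage[row["patient_id"]] = st
        subtype[row["patient_id"]] = sub
    return ClinicalTable(stage=stage, subtype=subtype)


def read_driver_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blanks and # comments ignored."""
    drivers = set()
    for _, line in _data_lines(Path(path)):
        s = line.strip()
        if s and not s.startswith("#"):
            drivers.add(normalize_symbol(s))
    return drivers


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for lineno, line in _data_lines(Path(path)):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
        name = fields[0].strip()
        if name in sets:
            raise ValidationError(f"{path}:{lineno}: duplicate gene-set name {name}")
        genes = {normalize_symbol(g) for g in fields[2:] if g.strip()}
        if not genes:
            raise ParseError(f"{path}:{lineno}: gene set {name} is empty")
        sets[name] = genes
    return GeneSetCollection(sets)


def read_pathway_sif(path: str | Path) -> PathwayGraph:
    """Read one directed pathway from a SIF file (source relation target).

    The pathway id is the file stem.  Self-loops are dropped with a note in
    the pathway graph's ``dropped_self_loops`` attribute.
    """
    path = Path(path)
    g = nx.DiGraph()
    dropped = 0
    for lineno, line in _data_lines(path):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: SIF line needs 3 columns")
        src, rel, dst = normalize_symbol(fields[0]), fields[1], normalize_symbol(fields[2])
        if src == dst:
            dropped += 1
            continue
        g.add_edge(src, dst, relation=rel)
    g.graph["dropped_self_loops"] = dropped
    return PathwayGraph(pathway_id=path.stem, graph=g)


def read_pathway_dir(directory: str | Path) -> list[PathwayGraph]:
    """Read every ``*.sif`` file in a directory, sorted by name."""
    return [read_pathway_sif(p) for p in sorted(Path(directory).glob("*.sif"))]


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if hasattr(o, "item"):  # numpy scalar
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
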