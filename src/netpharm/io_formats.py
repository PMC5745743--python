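"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* compound tables and interaction tables: TSV/CSV with a header row
* pathway collections: GMT (one set per line: id, description, members...)
* graphs: Pajek ``.net`` (``*Vertices`` / ``*Edges`` sections, 1-based
  indices, quoted labels) plus an optional ``.clu`` partition file carrying
  node roles (1=ingredient, 2=target, 3=pathway)
* metric reports: TSV or JSON

All readers validate their input and report malformed lines by number;
row-count accounting (kept + rejected = input) is emitted on the module
logger rather than dropped silently.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

from .exceptions import IOFormatError, SchemaError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .metrics import MetricsReport

logger = logging.getLogger(__name__)

#: node roles of the tripartite ingredient-target-pathway graph
ROLES = ("ingredient", "target", "pathway")
#: Pajek .clu class numbers for each role
ROLE_TO_CLASS = {"ingredient": 1, "target": 2, "pathway": 3}
CLASS_TO_ROLE = {v: k for k, v in ROLE_TO_CLASS.items()}

COMPOUND_COLUMNS = ("compound_id", "name", "abundance_pct", "mw", "hbd", "hba", "mlogp")
_COMPOUND_NUMERIC = ("abundance_pct", "mw", "hbd", "hba", "mlogp")
INTERACTION_COLUMNS = ("compound_id", "target_id")


def _infer_sep(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise IOFormatError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
        return "\t" if dialect == "tsv" else ","
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# compound tables
# ---------------------------------------------------------------------------

def read_compound_table(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a compound table with columns compound_id, name, abundance_pct,
    mw, hbd, hba, mlogp (header matched case-insensitively).

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for malformed numeric cells (reported with
    1-based data line numbers) or duplicate compound ids.
    """
    path = Path(path)
    sep = _infer_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in COMPOUND_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[list(COMPOUND_COLUMNS)]
    for col in _COMPOUND_NUMERIC:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col].str.strip() != "")
        empty = df[col].str.strip() == ""
        bad_lines = [i + 2 for i in df.index[bad | empty]]  # +1 header, +1 one-based
        if bad_lines:
            raise ValidationError(
                f"{path}: malformed numeric value in column {col!r} "
                f"on line(s) {bad_lines}"
            )
        df[col] = converted
    for col in ("hbd", "hba"):
        df[col] = df[col].astype(int)
    validate_compound_table(df, source=str(path))
    logger.info("read_compound_table: %d rows kept, 0 rejected from %s", len(df), path)
    return df.reset_index(drop=True)


def validate_compound_table(df: pd.DataFrame, source: str = "<table>") -> None:
    dup = df["compound_id"][df["compound_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{source}: duplicate compound_id: {sorted(set(dup))}")
    if (df["compound_id"].str.len() == 0).any():
        raise ValidationError(f"{source}: empty compound_id")
    if (df["mw"] <= 0).any():
        bad = df.loc[df["mw"] <= 0, "compound_id"].tolist()
        raise ValidationError(f"{source}: non-positive molecular weight for {bad}")
    if (df["hbd"] < 0).any() or (df["hba"] < 0).any():
        raise ValidationError(f"{source}: negative H-bond donor/acceptor count")


def write_compound_table(table: pd.DataFrame, path: str | Path,
                         dialect: str | None = None) -> None:
    path = Path(path)
    sep = _infer_sep(path, dialect)
    table.to_csv(path, sep=sep, index=False, columns=list(COMPOUND_COLUMNS))


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------

def read_interaction_table(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a compound->target edge list (columns compound_id, target_id).

    Duplicate rows are removed (with a logged count); empty ids are an error.
    """
    path = Path(path)
    sep = _infer_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[list(INTERACTION_COLUMNS)]
    if (df["compound_id"].str.len() == 0).any() or (df["target_id"].str.len() == 0).any():
        raise ValidationError(f"{path}: empty compound_id or target_id")
    n_in = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    logger.info("read_interaction_table: %d rows kept, %d duplicate rows rejected from %s",
                len(df), n_in - len(df), path)
    return df


def write_interaction_table(table: pd.DataFrame, path: str | Path,
                            dialect: str | None = None) -> None:
    path = Path(path)
    sep = _infer_sep(path, dialect)
    table.to_csv(path, sep=sep, index=False, columns=list(INTERACTION_COLUMNS))


# ---------------------------------------------------------------------------
# pathway collections (GMT)
# ---------------------------------------------------------------------------

@dataclass
class Pathway:
    """One named set of protein ids."""

    pathway_id: str
    description: str
    members: frozenset[str]


@dataclass
class PathwayCollection:
    """An ordered collection of pathways with unique, nonempty member sets."""

    pathways: dict[str, Pathway] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.pathways.values():
            if not p.members:
                raise ValidationError(f"pathway {p.pathway_id!r} has no members")

    @classmethod
    def from_entries(cls, entries: Iterable[tuple[str, str, Iterable[str]]]
                     ) -> "PathwayCollection":
        pathways: dict[str, Pathway] = {}
        for pid, desc, members in entries:
            if pid in pathways:
                raise ValidationError(f"duplicate pathway_id {pid!r}")
            pathways[pid] = Pathway(pid, desc, frozenset(members))
        return cls(pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways.values())

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.pathways

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self.pathways[pathway_id]

    def members_of(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id].members

    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self:
            out |= p.members
        return frozenset(out)

    def restrict(self, targets: Iterable[str]) -> "PathwayCollection":
        """Intersect every pathway with *targets*, dropping emptied pathways."""
        keep = set(targets)
        entries = []
        for p in self:
            members = p.members & keep
            if members:
                entries.append((p.pathway_id, p.description, members))
        return PathwayCollection.from_entries(entries)

    def membership_counts(self) -> dict[str, int]:
        """Number of pathways each protein belongs to."""
        counts: dict[str, int] = {}
        for p in self:
            for m in p.members:
                counts[m] = counts.get(m, 0) + 1
        return counts


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT file: tab-separated ``id  description  member...`` lines."""
    path = Path(path)
    entries = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise IOFormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "expected at least 3 (id, description, members...)"
                )
            pid, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise IOFormatError(f"{path}:{lineno}: pathway {pid!r} has no members")
            entries.append((pid, desc, members))
    coll = PathwayCollection.from_entries(entries)
    logger.info("read_gmt: %d pathways read from %s", len(coll), path)
    return coll


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in collection:
            fh.write("\t".join([p.pathway_id, p.description, *sorted(p.members)]) + "\n")


# ---------------------------------------------------------------------------
# Pajek .net / .clu
# ---------------------------------------------------------------------------

def write_pajek(graph: nx.Graph, net_path: str | Path,
                clu_path: str | Path | None = None) -> None:
    """Write an undirected graph in Pajek format (1-based vertex indices,
    double-quoted labels, edges under ``*Edges``).

    When *clu_path* is given, node roles (``role`` attribute) are written as a
    Pajek partition file with classes 1=ingredient, 2=target, 3=pathway,
    0=unassigned, in the same vertex order as the .net file.
    """
    nodes = list(graph.nodes())
    index = {node: i + 1 for i, node in enumerate(nodes)}
    with open(net_path, "w", encoding="utf-8") as fh:
        fh.write(f"*Vertices {len(nodes)}\n")
        for node in nodes:
            label = str(node).replace('"', "'")
            fh.write(f'{index[node]} "{label}"\n')
        fh.write("*Edges\n")
        for u, v in graph.edges():
            fh.write(f"{index[u]} {index[v]}\n")
    if clu_path is not None:
        with open(clu_path, "w", encoding="utf-8") as fh:
            fh.write(f"*Vertices {len(nodes)}\n")
            for node in nodes:
                role = graph.nodes[node].get("role")
                fh.write(f"{ROLE_TO_CLASS.get(role, 0)}\n")


def read_pajek(net_path: str | Path, clu_path: str | Path | None = None) -> nx.Graph:
    """Read a Pajek ``.net`` file (``*Vertices`` / ``*Edges`` sections) into an
    undirected simple graph keyed by vertex label; an optional ``.clu``
    partition assigns node roles.

    Raises :class:`IOFormatError` on malformed sections, out-of-range edge
    indices, or a vertex-count mismatch.
    """
    net_path = Path(net_path)
    n_declared: int | None = None
    labels: dict[int, str] = {}
    edges: list[tuple[int, int]] = []
    section = None
    with open(net_path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                parts = line.split()
                if len(parts) < 2 or not parts[1].isdigit():
                    raise IOFormatError(f"{net_path}:{lineno}: malformed *Vertices line")
                n_declared = int(parts[1])
                section = "vertices"
                continue
            if low.startswith("*edges"):
                section = "edges"
                continue
            if low.startswith("*arcs") or low.startswith("*"):
                raise IOFormatError(
                    f"{net_path}:{lineno}: unsupported Pajek section {line.split()[0]!r}"
                )
            if section == "vertices":
                idx_str, _, rest = line.partition(" ")
                try:
                    idx = int(idx_str)
                except ValueError:
                    raise IOFormatError(f"{net_path}:{lineno}: bad vertex index {idx_str!r}")
                rest = rest.strip()
                if rest.startswith('"'):
                    end = rest.find('"', 1)
                    if end < 0:
                        raise IOFormatError(f"{net_path}:{lineno}: unterminated label quote")
                    label = rest[1:end]
                else:
                    label = rest.split()[0] if rest else str(idx)
                if idx in labels:
                    raise IOFormatError(f"{net_path}:{lineno}: duplicate vertex index {idx}")
                labels[idx] = label
            elif section == "edges":
                parts = line.split()
                if len(parts) < 2:
                    raise IOFormatError(f"{net_path}:{lineno}: malformed edge line")
                try:
                    u, v = int(parts[0]), int(parts[1])
                except ValueError:
                    raise IOFormatError(f"{net_path}:{lineno}: non-integer edge endpoints")
                if n_declared is None or not (1 <= u <= n_declared and 1 <= v <= n_declared):
                    raise IOFormatError(
                        f"{net_path}:{lineno}: edge ({u},{v}) references a vertex "
                        f"outside 1..{n_declared}"
                    )
                edges.append((u, v))
            else:
                raise IOFormatError(f"{net_path}:{lineno}: content before *Vertices section")
    if n_declared is None:
        raise IOFormatError(f"{net_path}: no *Vertices section")
    if len(labels) != n_declared:
        raise IOFormatError(
            f"{net_path}: *Vertices declares {n_declared} vertices but "
            f"{len(labels)} vertex lines found"
        )
    graph = nx.Graph()
    for idx in sorted(labels):
        graph.add_node(labels[idx])
    for u, v in edges:
        if u == v:
            raise IOFormatError(f"{net_path}: self-loop on vertex {u}")
        graph.add_edge(labels[u], labels[v])

    if clu_path is not None:
        classes = _read_clu(Path(clu_path), n_declared)
        for idx, cls in enumerate(classes, start=1):
            role = CLASS_TO_ROLE.get(cls)
            if role is not None:
                graph.nodes[labels[idx]]["role"] = role
    return graph


def _read_clu(clu_path: Path, n_expected: int) -> list[int]:
    values: list[int] = []
    with open(clu_path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            if line.lower().startswith("*vertices"):
                continue
            try:
                values.append(int(line.split()[0]))
            except ValueError:
                raise IOFormatError(f"{clu_path}:{lineno}: non-integer partition value")
    if len(values) != n_expected:
        raise IOFormatError(
            f"{clu_path}: partition has {len(values)} values for {n_expected} vertices"
        )
    return values


# ---------------------------------------------------------------------------
# metric reports
# ---------------------------------------------------------------------------

def _round_or_none(value, ndigits: int):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return round(float(value), ndigits)


def render_metrics_report(report: "MetricsReport") -> dict:
    """Serializable view of a report: global statistics at 2 decimals,
    centralities at 3 (round-half-even at serialization only); the per-node
    table sorted by descending degree then ascending node id."""
    globals_ = {
        "n_nodes": report.n_nodes,
        "n_edges": report.n_edges,
        "connected": report.connected,
        "mean_degree": _round_or_none(report.mean_degree, 2),
        "average_path_length": _round_or_none(report.average_path_length, 2),
        "diameter": None if report.diameter is None else int(report.diameter),
        "mean_clustering": _round_or_none(report.mean_clustering, 2),
        "mean_clustering_k2": _round_or_none(report.mean_clustering_k2, 2),
    }
    if report.powerlaw is not None:
        globals_["powerlaw_gamma"] = _round_or_none(report.powerlaw[0], 2)
        globals_["powerlaw_r_squared"] = _round_or_none(report.powerlaw[1], 2)
    else:
        globals_["powerlaw_gamma"] = None
        globals_["powerlaw_r_squared"] = None
    per_node = None
    if report.per_node is not None and len(report.per_node):
        df = report.per_node.sort_values(
            ["k", "node"], ascending=[False, True]).reset_index(drop=True)
        per_node = {
            "node": df["node"].tolist(),
            "k": df["k"].tolist(),
        }
        for col in ("C_i", "Cd", "Cb_raw", "Cb", "Cc"):
            if col in df.columns:
                per_node[col] = [_round_or_none(v, 3) for v in df[col]]
    return {"global": globals_, "per_node": per_node}


def write_metrics_report(report: "MetricsReport", path: str | Path,
                         format: str = "json") -> None:
    """Write a metrics report as JSON or as a two-section TSV file."""
    if format not in ("tsv", "json"):
        raise IOFormatError(f"unknown report format {format!r}; expected 'tsv' or 'json'")
    rendered = render_metrics_report(report)
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(rendered, indent=2) + "\n", encoding="utf-8")
        return
    lines = ["# global statistics"]
    for key, value in rendered["global"].items():
        lines.append(f"{key}\t{'' if value is None else value}")
    per_node = rendered["per_node"]
    if per_node:
        lines.append("# per-node statistics")
        cols = list(per_node.keys())
        lines.append("\t".join(cols))
        for i in range(len(per_node["node"])):
            lines.append("\t".join(
                "" if per_node[c][i] is None else str(per_node[c][i]) for c in cols))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
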