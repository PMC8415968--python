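"""Readers and writers for every external format the pipeline touches.

Expression matrices, sample metadata and miRNA-target interaction tables
travel as plain TSV; gene sets as GMT; networks are exported in
Cytoscape-loadable SIF and GraphML plus a node-attribute TSV.

All readers validate and reject malformed input rather than coercing it,
and every writer/reader pair is a lossless round trip.  Exports are
deterministic: the same in-memory object always produces byte-identical
files (edges ordered lexicographically by source then target).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError, FormatError

if TYPE_CHECKING:  # pragma: no cover
    from .cerna import CeRNANetwork

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("mRNA", "miRNA", "lncRNA")
TARGET_KINDS = ("mRNA", "lncRNA")
GROUP_CONTROL = "Lean"
GROUP_CASE = "MetS"
GROUPS = (GROUP_CONTROL, GROUP_CASE)
SCALES = ("counts", "cpm", "log2cpm")

#: relation tokens used on network edges: a lncRNA *sponges* a miRNA,
#: a miRNA *targets* an mRNA.
RELATION_SPONGES = "sponges"
RELATION_TARGETS = "targets"


@dataclass
class ExpressionMatrix:
    """A feature-by-sample abundance table for one RNA kind.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and sample ids as columns.
    kind
        One of ``mRNA``, ``miRNA``, ``lncRNA``.
    groups
        Series mapping sample id to group label (``Lean`` control /
        ``MetS`` case).
    scale
        ``counts`` (non-negative integers), ``cpm`` or ``log2cpm``.
    """

    values: pd.DataFrame
    kind: str
    groups: pd.Series
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise FormatError(f"unknown feature kind {self.kind!r}")
        if self.scale not in SCALES:
            raise FormatError(f"unknown scale {self.scale!r}")
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise FormatError(f"sample {missing[0]!r} missing from metadata")
        bad = set(self.groups.loc[list(self.values.columns)]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group label {sorted(bad)[0]!r}")
        vals = self.values.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise FormatError("non-numeric expression value")
        if vals.size and not np.all(np.isfinite(vals)):
            raise FormatError("non-finite expression value")
        if self.scale in ("counts", "cpm") and vals.size and (vals < 0).any():
            raise FormatError("negative expression value")
        if self.scale == "counts" and vals.size and not np.allclose(vals, np.round(vals)):
            raise FormatError("counts matrix contains non-integer values")
        # keep only metadata rows for samples actually present, in column order
        self.groups = self.groups.loc[list(self.values.columns)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]


@dataclass
class InteractionTable:
    """Deduplicated miRNA-to-target pairs (targets are mRNAs or lncRNAs).

    Stands in for miRTarBase-style (miRNA, mRNA) and miRcode/LncBase-style
    (miRNA, lncRNA) download tables, normalised to four columns:
    ``mirna_id``, ``target_id``, ``target_kind``, ``source``.
    """

    frame: pd.DataFrame

    REQUIRED = ("mirna_id", "target_id", "target_kind", "source")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise FormatError(f"interaction table missing column {missing[0]!r}")
        bad = set(self.frame["target_kind"]) - set(TARGET_KINDS)
        if bad:
            raise FormatError(f"unknown target_kind {sorted(bad)[0]!r}")
        # first occurrence wins on duplicate (mirna, target) pairs
        self.frame = self.frame.drop_duplicates(
            subset=["mirna_id", "target_id"], keep="first"
        ).reset_index(drop=True)
        kinds = self.frame.groupby("target_id")["target_kind"].nunique()
        conflicted = kinds[kinds > 1]
        if len(conflicted):
            raise FormatError(
                f"conflicting target_kind for target {conflicted.index[0]!r}"
            )

    def pairs(self, target_kind: str | None = None) -> set[tuple[str, str]]:
        """Unique (mirna_id, target_id) pairs, optionally of one target kind."""
        f = self.frame
        if target_kind is not None:
            f = f[f["target_kind"] == target_kind]
        return set(zip(f["mirna_id"], f["target_id"]))

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# expression / metadata TSV


def read_metadata(path: str | Path, group_aliases: Mapping[str, str] | None = None) -> pd.Series:
    """Read a two-column sample metadata TSV (sample_id, group).

    ``group_aliases`` optionally maps foreign labels (e.g. ``control``)
    onto the canonical ``Lean``/``MetS`` vocabulary.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise FormatError(f"metadata file missing column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample id {dup!r} in metadata")
    groups = meta.set_index("sample_id")["group"]
    if group_aliases:
        groups = groups.replace(dict(group_aliases))
    bad = set(groups) - set(GROUPS)
    if bad:
        raise FormatError(f"unknown group label {sorted(bad)[0]!r} in metadata")
    return groups


def read_expression(
    matrix_path: str | Path,
    metadata_path: str | Path,
    kind: str,
    group_aliases: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a count matrix TSV (feature rows, sample columns) plus metadata."""
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"duplicate feature id {dup!r} in {matrix_path}")
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            raise FormatError(f"non-numeric value in sample column {col!r}")
    groups = read_metadata(metadata_path, group_aliases)
    return ExpressionMatrix(values=frame, kind=kind, groups=groups, scale="counts")


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    frame = matrix.values.copy()
    if matrix.scale == "counts":
        frame = frame.astype(np.int64)
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", lineterminator="\n")
    return path


def write_metadata(groups: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    out = pd.DataFrame({"sample_id": groups.index, "group": groups.to_numpy()})
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# interaction tables


def read_interactions(path: str | Path) -> InteractionTable:
    """Read a 4-column interaction TSV; duplicates collapse to first source."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    n_raw = len(frame)
    table = InteractionTable(frame)
    logger.info("read %d interaction rows from %s (%d after dedup)", n_raw, path, len(table))
    return table


def write_interactions(table: InteractionTable, path: str | Path) -> Path:
    path = Path(path)
    table.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into ``{set name: member set}``; empty sets dropped."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"malformed GMT line {lineno}: fewer than 2 fields")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                logger.warning("dropping empty gene set %r (line %d)", name, lineno)
                continue
            sets[name] = set(members)
    return sets


def write_gmt(sets: Mapping[str, set[str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sets:
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{members}\n")
    return path


# ---------------------------------------------------------------------------
# network export


def _sorted_edges(network: "CeRNANetwork") -> list[tuple[str, str, str]]:
    return sorted(network.edges, key=lambda e: (e[0], e[2], e[1]))


def network_to_graphml_graph(network: "CeRNANetwork") -> nx.DiGraph:
    """Build a DiGraph with deterministic node/edge insertion order."""
    g = nx.DiGraph()
    for node_id in sorted(network.nodes):
        kind, direction = network.nodes[node_id]
        g.add_node(node_id, kind=kind, direction=direction)
    for src, relation, dst in _sorted_edges(network):
        g.add_edge(src, dst, relation=relation)
    return g


def export_network(
    network: "CeRNANetwork",
    sif_path: str | Path,
    graphml_path: str | Path,
    attrs_path: str | Path,
) -> list[Path]:
    """Write a ceRNA network as Cytoscape SIF + GraphML + node attribute TSV.

    SIF carries one edge per line (``lncRNA<TAB>sponges<TAB>miRNA`` or
    ``miRNA<TAB>targets<TAB>mRNA``) in lexicographic (source, target)
    order; the attribute table lists node_id, kind, direction and degree.
    """
    for node_id, (kind, _direction) in network.nodes.items():
        if kind not in FEATURE_KINDS:
            raise DataError(f"node {node_id!r} has invalid kind {kind!r}")
    sif_path, graphml_path, attrs_path = Path(sif_path), Path(graphml_path), Path(attrs_path)

    with open(sif_path, "w") as fh:
        for src, relation, dst in _sorted_edges(network):
            fh.write(f"{src}\t{relation}\t{dst}\n")

    g = network_to_graphml_graph(network)
    nx.write_graphml(g, graphml_path)

    degree: dict[str, int] = {n: 0 for n in network.nodes}
    for src, _rel, dst in network.edges:
        degree[src] += 1
        degree[dst] += 1
    rows = [
        (n, network.nodes[n][0], network.nodes[n][1], degree[n])
        for n in sorted(network.nodes)
    ]
    attrs = pd.DataFrame(rows, columns=["node_id", "kind", "direction", "degree"])
    attrs.to_csv(attrs_path, sep="\t", index=False, lineterminator="\n")
    return [sif_path, graphml_path, attrs_path]
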