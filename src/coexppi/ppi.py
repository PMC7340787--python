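"""Projecting co-expression modules onto a PPI network.

A confidence-filtered PPI edge list is intersected with the genes that
carry a co-expression module label; edges whose two endpoints are both
labeled survive, nodes are the endpoints of surviving edges (the network
is edge-defined, so isolated mapped genes drop out), and each node carries
its module label and degree.  The critical module's nodes, ranked by
degree, are the candidate targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from coexppi.coexpression import GREY, ModuleAssignment
from coexppi.utils import CoexppiError

__all__ = [
    "read_ppi",
    "ppi_from_frame",
    "filter_confidence",
    "map_modules",
    "MappedModularNetwork",
    "rank_nodes",
    "candidate_targets",
]

logger = logging.getLogger(__name__)


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Drop self-loops, collapse duplicate/reversed pairs keeping the max
    score, order each pair lexicographically."""
    a = df["protein1"].astype(str)
    b = df["protein2"].astype(str)
    first = a.where(a <= b, b)
    second = b.where(a <= b, a)
    out = pd.DataFrame(
        {"protein1": first, "protein2": second, "combined_score": df["combined_score"]}
    )
    loops = out.protein1 == out.protein2
    if loops.any():
        logger.info("dropping %d self-loop(s)", int(loops.sum()))
        out = out[~loops]
    out = (
        out.groupby(["protein1", "protein2"], as_index=False, sort=True)["combined_score"]
        .max()
    )
    return out.reset_index(drop=True)


def read_ppi(path, score_dialect: str = "unit") -> pd.DataFrame:
    """Read a STRING-style PPI TSV (two id columns plus a score column).

    ``unit`` scores are already in [0, 1]; ``string999`` scores are on the
    0-999 scale and get divided by 1000.  Reversed duplicates collapse to
    one edge keeping the larger score; self-loops are dropped (logged).
    """
    if score_dialect not in ("unit", "string999"):
        raise CoexppiError(f"unknown score dialect {score_dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise CoexppiError(f"malformed PPI file {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise CoexppiError(f"PPI file {path} needs two id columns and a score column")
    df = df.iloc[:, :3]
    df.columns = ["protein1", "protein2", "combined_score"]
    score = pd.to_numeric(df["combined_score"], errors="coerce")
    if score.isna().any():
        line = int(score.index[score.isna()][0]) + 2  # 1-based, after header
        raise CoexppiError(f"malformed score in {path} at line {line}")
    df["combined_score"] = score / 1000.0 if score_dialect == "string999" else score
    if (df["combined_score"] < 0).any() or (df["combined_score"] > 1).any():
        raise CoexppiError("scores outside [0, 1] after dialect normalization")
    return _canonicalize(df)


def ppi_from_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize an in-memory edge frame (protein1, protein2, combined_score)."""
    if (df["combined_score"] < 0).any() or (df["combined_score"] > 1).any():
        raise CoexppiError("scores must lie in [0, 1]")
    return _canonicalize(df)


def filter_confidence(ppi: pd.DataFrame, min_score: float = 0.4) -> pd.DataFrame:
    """Keep edges with combined score >= min_score (inclusive, matching the
    STRING medium-confidence convention)."""
    if not 0 <= min_score <= 1:
        raise CoexppiError("min_score must lie in [0, 1]")
    out = ppi[ppi["combined_score"] >= min_score].reset_index(drop=True)
    if out.empty:
        raise CoexppiError(f"no edges remain at min_score={min_score}")
    return out


def apply_id_mapping(ppi: pd.DataFrame, mapping: pd.Series) -> pd.DataFrame:
    """Translate protein ids to gene symbols via a two-column mapping;
    unmapped ids are dropped."""
    out = ppi.copy()
    out["protein1"] = out["protein1"].map(mapping)
    out["protein2"] = out["protein2"].map(mapping)
    out = out.dropna(subset=["protein1", "protein2"])
    if out.empty:
        raise CoexppiError("no PPI edges survive the id mapping")
    return _canonicalize(out)


@dataclass
class MappedModularNetwork:
    """PPI subgraph restricted to module-labeled genes."""

    graph: nx.Graph  # node attrs: module, degree

    @property
    def node_table(self) -> pd.DataFrame:
        rows = [
            (n, d["module"], d["degree"]) for n, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene", "module", "degree"]).set_index("gene")

    @property
    def edge_table(self) -> pd.DataFrame:
        rows = [(a, b, d.get("score")) for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])

    def module_summary(self) -> pd.DataFrame:
        nodes = self.node_table
        rows = []
        for label, sub in nodes.groupby("module"):
            within = self.graph.subgraph(sub.index).number_of_edges()
            rows.append((label, len(sub), within, float(sub.degree.mean())))
        return (
            pd.DataFrame(rows, columns=["module", "n_nodes", "within_edges", "mean_degree"])
            .set_index("module")
            .sort_values("n_nodes", ascending=False)
        )


def map_modules(
    ppi: pd.DataFrame,
    assignment: ModuleAssignment,
    drop_grey: bool = True,
    keep_isolates: bool = False,
    tom: pd.DataFrame | None = None,
    tom_floor: float | None = None,
) -> MappedModularNetwork:
    """Project the module partition onto the (filtered) PPI network.

    Edges survive when both endpoints carry a module label (grey excluded
    when ``drop_grey``); the node set is the endpoints of surviving edges
    unless ``keep_isolates``.  An optional TOM floor additionally requires
    co-expression support (topological overlap >= ``tom_floor``) for each
    surviving edge.
    """
    if assignment.labels.empty:
        raise CoexppiError("empty module assignment")
    labels = assignment.labels
    eligible = labels[labels != GREY] if drop_grey else labels
    lab = eligible.to_dict()

    mask = ppi["protein1"].isin(lab) & ppi["protein2"].isin(lab)
    edges = ppi[mask]
    if tom is not None and tom_floor is not None and not edges.empty:
        ok = [
            (a in tom.index and b in tom.index and tom.loc[a, b] >= tom_floor)
            for a, b in zip(edges.protein1, edges.protein2)
        ]
        edges = edges[ok]
    if edges.empty and not keep_isolates:
        raise CoexppiError("no PPI edges connect module-labeled genes")

    g = nx.Graph()
    if keep_isolates:
        g.add_nodes_from(lab)
    g.add_weighted_edges_from(
        zip(edges.protein1, edges.protein2, edges.combined_score), weight="score"
    )
    for node in g.nodes:
        g.nodes[node]["module"] = lab[node]
    degrees = dict(g.degree())
    nx.set_node_attributes(g, degrees, "degree")
    return MappedModularNetwork(graph=g)


def rank_nodes(network: MappedModularNetwork) -> pd.DataFrame:
    """Nodes ordered by degree descending, ties lexicographic by gene id."""
    table = network.node_table.reset_index()
    if table.empty:
        raise CoexppiError("empty mapped network")
    return table.sort_values(
        ["degree", "gene"], ascending=[False, True]
    ).set_index("gene")


def candidate_targets(network: MappedModularNetwork, critical_module: str) -> list[str]:
    """All nodes of the critical module, in degree-rank order."""
    ranked = rank_nodes(network)
    hits = ranked[ranked["module"] == critical_module]
    if hits.empty:
        raise CoexppiError(f"module {critical_module!r} has no nodes in the mapped network")
    return list(hits.index)
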