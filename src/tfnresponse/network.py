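"""Signed transcription-factor network (TFN) assembly and topology.

Builds the gene-level signed directed graph of TF regulation from
curated interaction tables: TF→gene, TF→TF, TF→operon and TF→TU
assertions are expanded so that a factor regulating a polycistronic unit
regulates every member gene.  From the merged graph the module derives each
gene's regulatory logic — the number of distinct input TFs ``K_TF`` and the
regulatory bias ``b = |Σ r|``, where ``r`` is +1 for an activating input,
−1 for a repressing one and 0 when the mode is unknown or dual — plus
standard node-level topology metrics and minimum directed path lengths
between gene pairs.
"""

from __future__ import annotations

import logging
import unicodedata
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "UnitAnnotation",
    "TFNGraph",
    "DEFAULT_EFFECT_TOKENS",
    "normalize_name",
    "parse_interactions",
    "records_from_frame",
    "load_annotations",
    "annotations_from_frame",
    "expand_to_gene_graph",
    "regulatory_profile",
    "min_path_lengths",
    "topology_metrics",
    "export_graph",
    "import_graph",
]

TARGET_KINDS = ("gene", "tf", "operon", "tu")

#: Token → regulatory effect r. Activators map to +1, repressors to −1 and
#: unknown or dual-mode regulation to 0 (a dual regulator has no single sign,
#: so treating it as unknown keeps b ≤ K_TF).
DEFAULT_EFFECT_TOKENS: dict[str, int] = {
    "+": 1,
    "activator": 1,
    "activation": 1,
    "-": -1,
    "repressor": -1,
    "repression": -1,
    "+-": 0,
    "-+": 0,
    "?": 0,
    "unknown": 0,
    "dual": 0,
}


def normalize_name(name: str) -> str:
    """Normalize a gene/TF name: Unicode NFC then lowercase."""
    return unicodedata.normalize("NFC", str(name).strip()).lower()


@dataclass(frozen=True)
class InteractionRecord:
    """One regulator→target assertion with its signed effect r ∈ {−1, 0, +1}."""

    regulator: str
    target: str
    target_kind: str
    effect: int

    def __post_init__(self) -> None:
        if not self.regulator or not self.target:
            raise ValueError("regulator and target names must be non-empty")
        if self.target_kind not in TARGET_KINDS:
            raise ValueError(f"unknown target_kind {self.target_kind!r}")
        if self.effect not in (-1, 0, 1):
            raise ValueError(f"effect must be in {{-1, 0, +1}}, got {self.effect}")


@dataclass(frozen=True)
class UnitAnnotation:
    """An operon or transcription unit: ordered member genes of one promoter.

    Position 1 is the promoter-proximal gene.  A unit may hold a single gene
    (a TU is one *or more* genes transcribed from a single promoter).
    """

    unit_id: str
    unit_kind: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.unit_kind not in ("operon", "tu"):
            raise ValueError(f"unit_kind must be 'operon' or 'tu', got {self.unit_kind!r}")
        if not self.members:
            raise ValueError(f"unit {self.unit_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"unit {self.unit_id!r} lists a duplicate gene")


class TFNGraph:
    """Gene-level signed directed regulatory graph.

    Thin wrapper over a :class:`networkx.DiGraph` whose edges carry the merged
    regulatory effect in the integer attribute ``r``, with provenance back to
    the contributing interaction records.
    """

    def __init__(self, graph: nx.DiGraph | None = None,
                 provenance: dict[tuple[str, str], list[InteractionRecord]] | None = None):
        self.g = graph if graph is not None else nx.DiGraph()
        self.provenance = provenance if provenance is not None else {}

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, int]]) -> "TFNGraph":
        """Build a graph directly from (regulator, target, r) triples."""
        g = nx.DiGraph()
        for u, v, r in edges:
            g.add_edge(u, v, r=int(r))
        return cls(g)

    # -- container protocol -------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self.g.nodes)

    def edges(self) -> list[tuple[str, str, int]]:
        return [(u, v, int(d["r"])) for u, v, d in self.g.edges(data=True)]

    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def effect(self, regulator: str, target: str) -> int:
        return int(self.g.edges[regulator, target]["r"])

    def in_inputs(self, gene: str) -> list[tuple[str, int]]:
        """Distinct input TFs of *gene* with their merged effects."""
        if gene not in self.g:
            return []
        return [(u, int(d["r"])) for u, _, d in self.g.in_edges(gene, data=True)]

    def __contains__(self, gene: str) -> bool:
        return gene in self.g

    def __eq__(self, other) -> bool:
        if not isinstance(other, TFNGraph):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and set(self.edges()) == set(other.edges())


def parse_interactions(path, effect_tokens: Mapping[str, int] | None = None) -> list[InteractionRecord]:
    """Read a regulator/target/target_kind/effect table into records.

    The file is tab-separated with a header declaring the four columns.  The
    effect column holds dialect tokens (``+``, ``-``, ``+-``, ``?`` by
    default); *effect_tokens* overrides the token→r map.  Unknown effect
    tokens or target kinds raise, naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return records_from_frame(df, effect_tokens, source=str(path))


def records_from_frame(df: pd.DataFrame,
                       effect_tokens: Mapping[str, int] | None = None,
                       source: str = "interaction table") -> list[InteractionRecord]:
    """Turn an in-memory interaction table (same dialect) into records."""
    tokens = dict(DEFAULT_EFFECT_TOKENS if effect_tokens is None else effect_tokens)
    required = {"regulator", "target", "target_kind", "effect"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{source} is missing columns {sorted(missing)}")
    records: list[InteractionRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        tok = str(row.effect).strip().lower()
        if tok not in tokens:
            raise ValueError(f"row {i + 1}: unknown effect token {row.effect!r}")
        kind = str(row.target_kind).strip().lower()
        if kind not in TARGET_KINDS:
            raise ValueError(f"row {i + 1}: unknown target_kind {row.target_kind!r}")
        records.append(InteractionRecord(
            regulator=str(row.regulator).strip(),
            target=str(row.target).strip(),
            target_kind=kind,
            effect=tokens[tok],
        ))
    return records


def load_annotations(path) -> dict[str, UnitAnnotation]:
    """Read operon/TU membership: ``unit_id  unit_kind  gene  position`` TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"unit_id": str, "unit_kind": str, "gene": str,
                                            "position": int})
    return annotations_from_frame(df, source=str(path))


def annotations_from_frame(df: pd.DataFrame,
                           source: str = "annotation table") -> dict[str, UnitAnnotation]:
    """Turn an in-memory annotation table (same dialect) into units."""
    required = {"unit_id", "unit_kind", "gene", "position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{source} is missing columns {sorted(missing)}")
    units: dict[str, UnitAnnotation] = {}
    for unit_id, grp in df.groupby("unit_id", sort=False):
        grp = grp.sort_values("position")
        kinds = grp["unit_kind"].str.lower().unique()
        if len(kinds) != 1:
            raise ValueError(f"unit {unit_id!r} has inconsistent unit_kind")
        units[str(unit_id)] = UnitAnnotation(
            unit_id=str(unit_id),
            unit_kind=kinds[0],
            members=tuple(normalize_name(g) for g in grp["gene"]),
        )
    return units


def _merge_effects(effects: Iterable[int]) -> int:
    """Merge the effects asserted for one (regulator, target-gene) pair.

    A consistent sign is kept; the pair {+1, −1} conflicts and collapses to 0.
    Unknown (0) assertions never erase a known sign.
    """
    signs = {e for e in effects if e != 0}
    if len(signs) == 1:
        return signs.pop()
    return 0


def expand_to_gene_graph(records: Sequence[InteractionRecord],
                         annotations: Mapping[str, UnitAnnotation] | None = None,
                         synonyms: Mapping[str, str] | None = None,
                         known_genes: Iterable[str] | None = None) -> TFNGraph:
    """Expand unit-level interactions to gene-level edges and merge duplicates.

    A TF→operon/TU record with effect r contributes one edge TF→g with effect
    r for *every* member gene g of the unit.  Multiple records landing on the
    same (regulator, target gene) pair merge into a single edge — so K_TF
    counts distinct TFs, not interaction assertions.  Names are matched after
    NFC + lowercase normalization; *synonyms* maps regulator protein names to
    gene names; if *known_genes* is given, regulators that do not resolve into
    it are skipped with a logged warning (never silently).
    """
    annotations = annotations or {}
    syn = {normalize_name(k): normalize_name(v) for k, v in (synonyms or {}).items()}
    known = {normalize_name(g) for g in known_genes} if known_genes is not None else None

    collected: dict[tuple[str, str], list[InteractionRecord]] = {}
    n_skipped = 0
    for rec in records:
        reg = normalize_name(rec.regulator)
        reg = syn.get(reg, reg)
        if known is not None and reg not in known:
            logger.warning("regulator %r not resolvable to a known gene; record skipped", rec.regulator)
            n_skipped += 1
            continue
        if rec.target_kind in ("gene", "tf"):
            genes: tuple[str, ...] = (normalize_name(rec.target),)
        else:
            unit_id = str(rec.target).strip()
            if unit_id not in annotations:
                raise KeyError(f"{rec.target_kind} target {rec.target!r} has no unit annotation")
            genes = annotations[unit_id].members
        for g in genes:
            collected.setdefault((reg, g), []).append(rec)
    if n_skipped:
        logger.warning("expand_to_gene_graph: %d records skipped (unresolvable regulator)", n_skipped)

    g = nx.DiGraph()
    for (reg, tgt), recs in collected.items():
        r = _merge_effects(rec.effect for rec in recs)
        g.add_edge(reg, tgt, r=r)
    return TFNGraph(g, provenance=collected)


def regulatory_profile(graph: TFNGraph, gene_universe: Iterable[str]) -> pd.DataFrame:
    """Per-gene regulatory logic: K_TF, Σr and the bias b = |Σr|.

    Genes of the universe absent from the graph (no known input TFs) get
    K_TF = 0, Σr = 0, b = 0.
    """
    universe = [normalize_name(g) for g in gene_universe]
    if not universe:
        raise ValueError("gene universe is empty")
    if len(set(universe)) != len(universe):
        raise ValueError("gene universe contains duplicates")
    rows = []
    for gene in universe:
        inputs = graph.in_inputs(gene)
        sum_r = sum(r for _, r in inputs)
        rows.append((gene, len(inputs), sum_r, abs(sum_r)))
    return pd.DataFrame(rows, columns=["gene", "k_tf", "sum_r", "b"]).set_index("gene")


def min_path_lengths(graph: TFNGraph, max_L: int = 8) -> pd.DataFrame:
    """Minimum directed path length L between every (input, output) gene pair.

    Breadth-first traversal from every regulator node on the unsigned directed
    graph; each ordered pair appears once, at its minimum L ≤ *max_L*.
    Self-pairs (input = output, e.g. via a loop) are excluded.
    """
    if max_L < 1:
        raise ValueError("max_L must be >= 1")
    rows = []
    for src in graph.g.nodes:
        if graph.g.out_degree(src) == 0:
            continue
        dist = nx.single_source_shortest_path_length(graph.g, src, cutoff=max_L)
        for tgt, L in dist.items():
            if tgt == src or L == 0:
                continue
            rows.append((src, tgt, L))
    return pd.DataFrame(rows, columns=["input_gene", "output_gene", "L"])


def _bfs_counts(adj: list[list[int]], src: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Distances and shortest-path counts from *src* by BFS."""
    dist = np.full(n, -1, dtype=np.int64)
    sigma = np.zeros(n, dtype=np.float64)
    dist[src] = 0
    sigma[src] = 1.0
    q = deque([src])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                q.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def _stress_centrality(g: nx.DiGraph) -> dict[str, float]:
    """Stress centrality: number of shortest directed paths through each node."""
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [[] for _ in range(n)]
    for u, v in g.edges:
        if u != v:
            adj[idx[u]].append(idx[v])
    dist = np.empty((n, n), dtype=np.int64)
    sigma = np.empty((n, n), dtype=np.float64)
    for i in range(n):
        dist[i], sigma[i] = _bfs_counts(adj, i, n)
    stress = np.zeros(n)
    reach = dist >= 0
    for v in range(n):
        # paths s→v→t that are shortest: d(s,v) + d(v,t) == d(s,t)
        dv_in = dist[:, v][:, None]   # d(s, v)
        dv_out = dist[v][None, :]     # d(v, t)
        ok = reach[:, v][:, None] & reach[v][None, :] & reach
        ok &= (dv_in + dv_out) == dist
        ok[v, :] = False
        ok[:, v] = False
        np.fill_diagonal(ok, False)
        contrib = sigma[:, v][:, None] * sigma[v][None, :]
        stress[v] = contrib[ok].sum()
    return {nodes[i]: float(stress[i]) for i in range(n)}


def topology_metrics(graph: TFNGraph, include_stress: bool = True
                     ) -> tuple[pd.DataFrame, dict]:
    """Node-level topology metrics plus a global summary.

    Clustering is computed on the underlying undirected graph; eccentricity
    and the average shortest path length are taken over each node's reachable
    set in the directed graph (0 when nothing is reachable).  Betweenness and
    stress are unnormalized directed path counts.  Stress is O(n^3) and can
    be switched off for large graphs.
    """
    g = graph.g
    nodes = list(g.nodes)
    und = g.to_undirected()
    clustering = nx.clustering(nx.Graph(und))
    betweenness = nx.betweenness_centrality(g, normalized=False)
    stress = _stress_centrality(g) if include_stress else {v: np.nan for v in nodes}

    rows = []
    for v in nodes:
        dist = nx.single_source_shortest_path_length(g, v)
        dist.pop(v, None)
        ecc = max(dist.values()) if dist else 0
        aspl = float(np.mean(list(dist.values()))) if dist else 0.0
        nbrs = [u for u in und.neighbors(v) if u != v]
        nc = float(np.mean([und.degree(u) for u in nbrs])) if nbrs else 0.0
        rows.append({
            "gene": v,
            "in_degree": g.in_degree(v),
            "out_degree": g.out_degree(v),
            "edge_count": g.in_degree(v) + g.out_degree(v),
            "clustering_coefficient": clustering[v],
            "eccentricity": ecc,
            "average_shortest_path_length": aspl,
            "betweenness": betweenness[v],
            "stress_centrality": stress[v],
            "neighbourhood_connectivity": nc,
        })
    table = pd.DataFrame(rows).set_index("gene")
    n_self = nx.number_of_selfloops(g)
    summary = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_connected_components": nx.number_connected_components(und) if nodes else 0,
        "n_isolated_nodes": sum(1 for v in nodes if und.degree(v) == 0),
        "n_self_loops": n_self,
    }
    return table, summary


def export_graph(graph: TFNGraph, path, format: str = "tsv") -> None:
    """Write the signed edge list as TSV (``regulator  target  r``) or GraphML."""
    if format == "tsv":
        df = pd.DataFrame(graph.edges(), columns=["regulator", "target", "r"])
        df.to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(graph.g, path)
    else:
        raise ValueError(f"format must be 'tsv' or 'graphml', got {format!r}")


def import_graph(path, format: str = "tsv") -> TFNGraph:
    """Round-trip counterpart of :func:`export_graph`."""
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str, "r": int})
        g = nx.DiGraph()
        for row in df.itertuples(index=False):
            g.add_edge(row.regulator, row.target, r=int(row.r))
        return TFNGraph(g)
    if format == "graphml":
        g = nx.DiGraph(nx.read_graphml(path))
        for u, v, d in g.edges(data=True):
            d["r"] = int(d["r"])
        return TFNGraph(g)
    raise ValueError(f"format must be 'tsv' or 'graphml', got {format!r}")
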