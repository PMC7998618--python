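"""Regulatory-network assembly from heterogeneous interaction resources.

Curated interaction databases disagree on gene naming (capitalization,
punctuation, outright aliases) and vary wildly in coverage and reliability.
This module canonicalizes names, resolves aliases through a union alias
graph, merges per-resource records into single edges, restricts to the gene
co-expression modules of interest, reconnects stranded module genes through
short paths in the full network, scores each edge by its evidence, prunes
high in-degree nodes with an evidence threshold that tightens as in-degree
grows, and finally removes sinks and small components — sinks cannot drive
the dynamics, and tiny components cannot carry module-level behavior.

The edge score is::

    score = (N_references + N_resources + 10 * mean_confidence) * TFMUL

with ``N_references`` the summed reference counts over all merged records,
``N_resources`` the number of distinct resources, ``mean_confidence`` the
per-record average confidence, and ``TFMUL = 2`` when the source gene is a
transcription factor (1 otherwise). Records always have at least one
reference and one resource, so the minimum score is 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger("pbnet")

_STRIP = str.maketrans("", "", ".-_")
#: Transcription-factor multiplier applied to the edge score.
TF_MULTIPLIER = 2.0
#: Number of top-scored in-edges always retained per node.
ALWAYS_KEEP = 3
#: Maximum number of nodes (inclusive of endpoints) in a connecting path.
MAX_PATH_NODES = 4
#: Minimum weakly-connected-component size kept by finalization.
MIN_COMPONENT_SIZE = 4

_EFFECT_MAP = {
    "+": "positive", "positive": "positive", "activates": "positive",
    "-": "negative", "−": "negative", "negative": "negative", "inhibits": "negative",
    "?": "unknown", "unknown": "unknown", "": "unknown",
}


def canonicalize_name(name: str) -> str:
    """Uppercase and strip '.', '-', '_' — idempotent by construction."""
    if not isinstance(name, str) or not name:
        raise ValueError("gene name must be a nonempty string")
    return name.upper().translate(_STRIP)


# ---------------------------------------------------------------------------
# alias resolution
# ---------------------------------------------------------------------------

class AliasResolver:
    """Total map name -> alias-component representative.

    Built from the union of alias pair tables: two names resolve identically
    iff a path connects them in the alias graph (canonicalization is applied
    before lookup, so 'a-b' and 'AB' resolve alike). Unknown names resolve to
    their own canonical form. The representative is the lexicographically
    smallest member of the component, for reproducibility.
    """

    def __init__(self, component_of: dict[str, str]):
        self._component_of = component_of

    def resolve(self, name: str) -> str:
        canonical = canonicalize_name(name)
        return self._component_of.get(canonical, canonical)

    __call__ = resolve


def build_alias_resolver(alias_tables: list[pd.DataFrame]) -> AliasResolver:
    """Union all alias pair tables into one alias graph and take connected
    components as synonym classes."""
    g = nx.Graph()
    for table in alias_tables:
        for row in table.itertuples(index=False):
            a, b = canonicalize_name(str(row[0])), canonicalize_name(str(row[1]))
            g.add_edge(a, b)
    component_of = {}
    for comp in nx.connected_components(g):
        rep = min(comp)
        for name in comp:
            component_of[name] = rep
    return AliasResolver(component_of)


# ---------------------------------------------------------------------------
# record merging
# ---------------------------------------------------------------------------

@dataclass
class InteractionRecord:
    source: str
    target: str
    effect: str  # positive | negative | unknown
    n_references: int
    confidence: float
    resource: str

    def __post_init__(self) -> None:
        if self.n_references < 1:
            raise ValueError("every record needs at least one reference")
        if not 0 <= self.confidence <= 1:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class MergedEdge:
    source: str
    target: str
    records: list[InteractionRecord] = field(default_factory=list)

    @property
    def n_resources(self) -> int:
        return len({r.resource for r in self.records})

    @property
    def n_entries(self) -> int:
        return len(self.records)

    @property
    def n_references(self) -> int:
        return sum(r.n_references for r in self.records)

    @property
    def mean_confidence(self) -> float:
        return sum(r.confidence for r in self.records) / len(self.records)

    @property
    def sign(self) -> str:
        """Majority effect over records; unknown-only (or tied) edges default
        to positive, the assumption for unannotated regulation."""
        pos = sum(r.effect == "positive" for r in self.records)
        neg = sum(r.effect == "negative" for r in self.records)
        return "negative" if neg > pos else "positive"


def records_from_table(table: pd.DataFrame) -> list[InteractionRecord]:
    """Parse one resource table (source, target, effect, n_references,
    confidence, resource); extra columns are ignored."""
    out = []
    for row in table.itertuples(index=False):
        d = row._asdict()
        out.append(
            InteractionRecord(
                source=str(d["source"]),
                target=str(d["target"]),
                effect=_EFFECT_MAP.get(str(d["effect"]).strip().lower(), "unknown"),
                n_references=int(d["n_references"]),
                confidence=float(d["confidence"]),
                resource=str(d["resource"]),
            )
        )
    return out


def merge_interaction_sources(
    tables: list[pd.DataFrame], resolver: AliasResolver
) -> dict[tuple[str, str], MergedEdge]:
    """Group records by resolved endpoint pair; parallel records collapse
    into one MergedEdge (self-loops are retained)."""
    merged: dict[tuple[str, str], MergedEdge] = {}
    for table in tables:
        for rec in records_from_table(table):
            key = (resolver.resolve(rec.source), resolver.resolve(rec.target))
            edge = merged.get(key)
            if edge is None:
                edge = merged[key] = MergedEdge(source=key[0], target=key[1])
            edge.records.append(rec)
    return merged


def merged_to_graph(merged: dict[tuple[str, str], MergedEdge]) -> nx.DiGraph:
    g = nx.DiGraph()
    for (u, v), edge in merged.items():
        g.add_edge(u, v, merged=edge, sign=edge.sign)
    return g


# ---------------------------------------------------------------------------
# module subgraphs and connecting paths
# ---------------------------------------------------------------------------

def extract_module_subnetwork(
    graph: nx.DiGraph, modules: dict[str, str], focus_modules
) -> nx.DiGraph:
    """Induced subgraph on genes whose module label is in ``focus_modules``."""
    focus = set(focus_modules)
    unknown = focus - set(modules.values())
    if unknown:
        raise ValueError(f"unknown module label(s): {sorted(unknown)}")
    keep = [n for n in graph.nodes if modules.get(n) in focus]
    return graph.subgraph(keep).copy()


def _bounded_paths(graph: nx.DiGraph, start: str, goals: set[str],
                   blocked: set[str], max_nodes: int) -> list[list[str]]:
    """All minimum-length directed paths start -> goal with at most
    ``max_nodes`` nodes, intermediate nodes outside ``blocked``."""
    frontier = [[start]]
    found: list[list[str]] = []
    for _ in range(max_nodes - 1):
        nxt = []
        for path in frontier:
            for succ in graph.successors(path[-1]):
                if succ in path:
                    continue
                if succ in goals:
                    found.append(path + [succ])
                elif succ not in blocked:
                    nxt.append(path + [succ])
        if found:
            return found
        frontier = nxt
    return []


def find_connecting_paths(
    full: nx.DiGraph,
    components: list[set[str]],
    orphan_nodes,
    max_path_nodes: int = MAX_PATH_NODES,
) -> set[tuple[str, str]]:
    """Edges of the shortest qualifying paths tying each orphan into a
    component.

    Paths may run orphan -> component or component -> orphan and contain at
    most ``max_path_nodes`` nodes including both endpoints; intermediates are
    drawn from outside the components. Only the minimum-length paths per
    orphan are used; when several are equally short, all are added. Orphans
    with no qualifying path contribute nothing.
    """
    comp_nodes = set().union(*components) if components else set()
    reverse = full.reverse(copy=False)
    edges: set[tuple[str, str]] = set()
    for orphan in sorted(orphan_nodes):
        blocked = comp_nodes | {orphan}
        best: list[list[str]] = []
        fwd = _bounded_paths(full, orphan, comp_nodes, blocked, max_path_nodes)
        bwd = [
            list(reversed(p))
            for p in _bounded_paths(reverse, orphan, comp_nodes, blocked, max_path_nodes)
        ]
        candidates = fwd + bwd
        if not candidates:
            continue
        shortest = min(len(p) for p in candidates)
        best = [p for p in candidates if len(p) == shortest]
        for path in best:
            edges.update(zip(path, path[1:]))
    return edges


# ---------------------------------------------------------------------------
# scoring and pruning
# ---------------------------------------------------------------------------

def score_edge(edge: MergedEdge, tf_flags) -> float:
    """Evidence score; see the module docstring for the formula."""
    if not edge.records:
        raise ValueError("cannot score an edge with no records")
    if isinstance(tf_flags, dict):
        is_tf = bool(tf_flags.get(edge.source, False))
    else:
        is_tf = edge.source in tf_flags
    tfmul = TF_MULTIPLIER if is_tf else 1.0
    return (edge.n_references + edge.n_resources + 10.0 * edge.mean_confidence) * tfmul


def prune_in_edges(scored_in_edges, with_trace: bool = False):
    """Retain a node's strongest in-edges under the tightening threshold.

    Edges are sorted by descending score (ties by source id); the top three
    are always kept, and each subsequent edge is kept only if its score
    strictly exceeds (number already retained) - 1. The first failure drops
    that edge and everything below it. With ``with_trace`` the per-edge
    decisions (score, threshold, kept) are returned alongside.
    """
    def _source_id(edge):
        return getattr(edge, "source", str(edge))

    ranked = sorted(scored_in_edges, key=lambda es: (-es[1], _source_id(es[0])))
    retained = []
    trace = []
    for edge, score in ranked:
        if len(retained) < ALWAYS_KEEP:
            retained.append(edge)
            trace.append({"edge": edge, "score": score, "threshold": None, "kept": True})
            continue
        threshold = len(retained) - 1
        kept = score > threshold
        trace.append({"edge": edge, "score": score, "threshold": threshold, "kept": kept})
        if not kept:
            break
        retained.append(edge)
    if with_trace:
        return retained, trace
    return retained


def prune_network_in_edges(graph: nx.DiGraph, tf_flags) -> nx.DiGraph:
    """Score every edge and apply in-degree pruning per target node."""
    g = graph.copy()
    for node in list(g.nodes):
        scored = []
        for u, _, data in g.in_edges(node, data=True):
            edge = data.get("merged") or MergedEdge(
                u, node, [InteractionRecord(u, node, "unknown", 1, 0.0, "added")]
            )
            s = score_edge(edge, tf_flags)
            data["score"] = s
            scored.append(((u, node), s))
        keep = set(prune_in_edges(scored))
        for u, v in [e for e, _ in scored]:
            if (u, v) not in keep:
                g.remove_edge(u, v)
    return g


def finalize_network(graph: nx.DiGraph) -> nx.DiGraph:
    """Remove sinks to a fixed point, then drop weakly connected components
    smaller than 4 nodes. A sink (out-degree 0) cannot drive the dynamics;
    removing one can expose another, hence the fixed point."""
    g = graph.copy()
    while True:
        sinks = [n for n in g.nodes if g.out_degree(n) == 0]
        if not sinks:
            break
        g.remove_nodes_from(sinks)
    for comp in list(nx.weakly_connected_components(g)):
        if len(comp) < MIN_COMPONENT_SIZE:
            g.remove_nodes_from(comp)
    if g.number_of_nodes() == 0:
        logger.warning("finalized network is empty")
    return g


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def assemble_network(
    interaction_tables: list[pd.DataFrame],
    alias_tables: list[pd.DataFrame],
    tf_list,
    module_map: dict[str, str] | None = None,
    focus_modules=None,
    max_path_nodes: int = MAX_PATH_NODES,
    min_seed_component: int = 5,
) -> nx.DiGraph:
    """Full assembly: resolve, merge, module-restrict, reconnect, score,
    prune, finalize.

    When a module map is given, the assembly keeps the focus-module genes
    (default: every labeled module), seeds components of at least
    ``min_seed_component`` nodes (falling back to the largest component when
    none qualify), and pulls stranded module genes back in through short
    connecting paths found in the full merged network.
    Node attributes: ``module``, ``tf``; edge attributes: ``merged``,
    ``sign``, ``score``.
    """
    resolver = build_alias_resolver(alias_tables)
    tf_set = {resolver.resolve(t) for t in tf_list}
    merged = merge_interaction_sources(interaction_tables, resolver)
    full = merged_to_graph(merged)
    if module_map is not None:
        module_map = {resolver.resolve(g): m for g, m in module_map.items()}
        if focus_modules is None:
            focus_modules = {m for m in module_map.values() if m != "unassigned"}
        working = extract_module_subnetwork(full, module_map, focus_modules)
        comps = sorted(nx.weakly_connected_components(working), key=len, reverse=True)
        seeds = [c for c in comps if len(c) >= min_seed_component] or comps[:1]
        seed_nodes = set().union(*seeds) if seeds else set()
        orphans = set(working.nodes) - seed_nodes
        extra = find_connecting_paths(full, seeds, orphans, max_path_nodes)
        keep = set(working.nodes) | {n for e in extra for n in e}
        working = full.subgraph(keep).copy()
    else:
        module_map = {}
        working = full.copy()
    # sinks cannot be drivers: clear them before scoring
    while True:
        sinks = [n for n in working.nodes if working.out_degree(n) == 0]
        if not sinks:
            break
        working.remove_nodes_from(sinks)
    pruned = prune_network_in_edges(working, tf_set)
    final = finalize_network(pruned)
    for n in final.nodes:
        final.nodes[n]["module"] = module_map.get(n, "unassigned")
        final.nodes[n]["tf"] = n in tf_set
        final.nodes[n]["role"] = "plain"
    return final


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_interactions_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_alias_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None)


def read_tf_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_module_map(path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t")
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))


def write_edge_list(graph: nx.DiGraph, path) -> None:
    rows = [
        {
            "source": u,
            "target": v,
            "sign": d.get("sign", "positive"),
            "regulation_type": d.get("regulation_type", ""),
            "score": d.get("score", float("nan")),
        }
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.DiGraph, path) -> None:
    g = nx.DiGraph()
    for n, d in graph.nodes(data=True):
        g.add_node(n, module=str(d.get("module", "")), tf=bool(d.get("tf", False)),
                   role=str(d.get("role", "plain")))
    for u, v, d in graph.edges(data=True):
        g.add_edge(u, v, sign=str(d.get("sign", "positive")),
                   score=float(d.get("score", 0.0)))
    nx.write_graphml(g, path)
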