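"""Confidence-thresholded interaction graph and native centrality.

Edges carry a confidence score in [0, 1] (STRING exports use integers
0–1000, normalized here by /1000). Building the graph keeps edges at or
above the cutoff (0.7 = the conventional "high confidence" level), drops
self-loops, symmetrizes duplicates keeping the maximum score, and leaves
the protein universe untouched so isolated proteins remain and later enter
the threshold means.

Shortest paths are unweighted: the score gates edge inclusion only.
Betweenness is computed with Brandes' single-source dependency
accumulation over unordered source–target pairs, endpoints excluded, no
normalization — so a node on the single geodesic between one pair of
neighbours scores exactly 1.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError, FormatError
from .id_mapping import GeneSet

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


@dataclass(frozen=True)
class InteractionEdge:
    a: str
    b: str
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise DomainError(f"edge {self.a}-{self.b}: score {self.score} outside [0,1]")


@dataclass
class InteractionGraph:
    """Undirected simple graph over a fixed, ordered protein universe."""

    universe: tuple[str, ...]
    edges: frozenset[tuple[str, str]]  # each pair stored sorted

    def __post_init__(self) -> None:
        members = set(self.universe)
        if len(members) != len(self.universe):
            raise DomainError("universe contains duplicate symbols")
        for a, b in self.edges:
            if a == b:
                raise DomainError(f"self-loop {a}")
            if a not in members or b not in members:
                raise DomainError(f"edge {a}-{b} endpoint outside universe")

    @property
    def n_nodes(self) -> int:
        return len(self.universe)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {v: [] for v in self.universe}
        for a, b in sorted(self.edges):
            adj[a].append(b)
            adj[b].append(a)
        return adj


@dataclass(frozen=True)
class CentralityRecord:
    protein: str
    degree: int
    betweenness: float


def read_edge_table(path: str | Path, dialect: str = "string_export") -> list[InteractionEdge]:
    """Read an interaction edge TSV.

    ``string_export``: three columns (protein1, protein2, combined_score)
    with an integer score 0–1000, normalized to [0, 1]. ``plain``: a real
    score already in [0, 1]. A header row is auto-detected by a non-numeric
    third field.
    """
    if dialect not in ("string_export", "plain"):
        raise DomainError(f"unknown edge-table dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge table not found: {path}")
    edges: list[InteractionEdge] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns, found {len(fields)}"
                )
            a, b, raw = (f.strip() for f in fields)
            try:
                value = float(raw)
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise FormatError(f"{path}:{lineno}: non-numeric score {raw!r}") from None
            if dialect == "string_export":
                if value != int(value) or not (0 <= value <= 1000):
                    raise DomainError(
                        f"{path}:{lineno}: combined score {raw} outside integer 0-1000"
                    )
                score = value / 1000.0
            else:
                if not (0.0 <= value <= 1.0):
                    raise DomainError(f"{path}:{lineno}: score {raw} outside [0,1]")
                score = value
            edges.append(InteractionEdge(a=a, b=b, score=score))
    return edges


def build_graph(
    edges: Iterable[InteractionEdge],
    universe: GeneSet | Sequence[str],
    min_score: float = 0.7,
) -> InteractionGraph:
    """Threshold, restrict to the universe, symmetrize, deduplicate.

    The score cutoff is inclusive (>=). Reversed duplicates collapse to one
    undirected edge keeping the maximum score before thresholding, so a
    pair passes if any of its records does.
    """
    if not (0.0 <= min_score <= 1.0):
        raise DomainError(f"min_score {min_score} outside [0,1]")
    symbols = tuple(universe.symbols) if isinstance(universe, GeneSet) else tuple(universe)
    if not symbols:
        raise DomainError("empty universe")
    members = set(symbols)
    best: dict[tuple[str, str], float] = {}
    for e in edges:
        if e.a == e.b:
            continue
        if e.a not in members or e.b not in members:
            continue
        key = (e.a, e.b) if e.a < e.b else (e.b, e.a)
        if e.score > best.get(key, -1.0):
            best[key] = e.score
    kept = frozenset(pair for pair, score in best.items() if score >= min_score)
    return InteractionGraph(universe=symbols, edges=kept)


def degree_all(g: InteractionGraph) -> dict[str, int]:
    """Degree of every universe protein (isolated proteins get 0)."""
    deg = {v: 0 for v in g.universe}
    for a, b in g.edges:
        deg[a] += 1
        deg[b] += 1
    return deg


def betweenness_all(g: InteractionGraph) -> dict[str, float]:
    """Unnormalized betweenness over unordered pairs, endpoints excluded.

    Brandes' algorithm: one BFS per source accumulates, for each node, the
    fraction of geodesics it lies on; summing over sources double-counts
    each unordered pair, hence the final /2.
    """
    adj = g.adjacency()
    bc = {v: 0.0 for v in g.universe}
    for s in g.universe:
        stack: list[str] = []
        preds: dict[str, list[str]] = {v: [] for v in adj}
        sigma = {v: 0 for v in adj}
        sigma[s] = 1
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = {v: 0.0 for v in stack}
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return {v: value / 2.0 for v, value in bc.items()}


def centrality_table(g: InteractionGraph) -> list[CentralityRecord]:
    """One record per universe protein, betweenness-descending order."""
    deg = degree_all(g)
    btw = betweenness_all(g)
    records = [
        CentralityRecord(protein=v, degree=deg[v], betweenness=btw[v]) for v in g.universe
    ]
    records.sort(key=lambda r: (-r.betweenness, r.protein))
    return records


# ---------------------------------------------------------------------------
# serialization


def centrality_to_frame(records: Sequence[CentralityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [r.protein for r in records],
            "degree": [r.degree for r in records],
            "betweenness": [r.betweenness for r in records],
        }
    )


def write_centrality_table(records: Sequence[CentralityRecord], path: str | Path) -> None:
    centrality_to_frame(records).to_csv(path, sep="\t", index=False)


def read_centrality_table(path: str | Path) -> list[CentralityRecord]:
    """Read a centrality TSV (extra columns such as accessions are ignored)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"protein", "degree", "betweenness"}
    if not required <= set(frame.columns):
        raise FormatError(f"{path}: centrality table needs columns {sorted(required)}")
    return [
        CentralityRecord(
            protein=str(row.protein), degree=int(row.degree), betweenness=float(row.betweenness)
        )
        for row in frame.itertuples(index=False)
    ]


def write_sif(g: InteractionGraph, path: str | Path, relation: str = "pp") -> None:
    """Simple-interaction-format export; isolated nodes appear on their own line."""
    connected = {v for pair in g.edges for v in pair}
    lines = [f"{a}\t{relation}\t{b}" for a, b in sorted(g.edges)]
    lines += [v for v in g.universe if v not in connected]
    Path(path).write_text("".join(f"{l}\n" for l in lines), encoding="utf-8")


def write_graphml(
    path: str | Path,
    nodes: Mapping[str, Mapping[str, object]],
    edges: Sequence[tuple[str, str, Mapping[str, object]]],
) -> None:
    """Write an attribute-typed GraphML file.

    ``nodes`` maps node id -> attribute dict; ``edges`` is a sequence of
    (source, target, attribute dict). Attribute GraphML types are inferred
    (bool before int: Python bools are ints).
    """
    keys: dict[str, str] = {}

    def _type(value: object) -> str:
        if isinstance(value, bool):
            return "boolean"
        if isinstance(value, int):
            return "long"
        if isinstance(value, float):
            return "double"
        return "string"

    for attrs in list(nodes.values()) + [a for (_, _, a) in edges]:
        for name, value in attrs.items():
            keys.setdefault(name, _type(value))

    root = ET.Element("graphml", xmlns=GRAPHML_NS)
    for name, gtype in keys.items():
        ET.SubElement(
            root, "key", id=name, **{"for": "all", "attr.name": name, "attr.type": gtype}
        )
    graph = ET.SubElement(root, "graph", id="G", edgedefault="undirected")
    for node_id, attrs in nodes.items():
        el = ET.SubElement(graph, "node", id=node_id)
        for name, value in attrs.items():
            data = ET.SubElement(el, "data", key=name)
            data.text = str(value).lower() if isinstance(value, bool) else str(value)
    for source, target, attrs in edges:
        el = ET.SubElement(graph, "edge", source=source, target=target)
        for name, value in attrs.items():
            data = ET.SubElement(el, "data", key=name)
            data.text = str(value).lower() if isinstance(value, bool) else str(value)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


def read_graphml(
    path: str | Path,
) -> tuple[dict[str, dict[str, object]], list[tuple[str, str, dict[str, object]]]]:
    """Reparse a GraphML file written by :func:`write_graphml`."""
    ns = {"g": GRAPHML_NS}
    root = ET.parse(path).getroot()
    types = {k.get("id"): k.get("attr.type") for k in root.findall("g:key", ns)}

    def _parse(key: str, text: str) -> object:
        gtype = types.get(key, "string")
        if gtype == "boolean":
            return text == "true"
        if gtype == "long":
            return int(text)
        if gtype == "double":
            return float(text)
        return text

    nodes: dict[str, dict[str, object]] = {}
    edges: list[tuple[str, str, dict[str, object]]] = []
    graph = root.find("g:graph", ns)
    if graph is None:
        raise FormatError(f"{path}: no <graph> element")
    for el in graph.findall("g:node", ns):
        attrs = {
            d.get("key"): _parse(d.get("key"), d.text or "") for d in el.findall("g:data", ns)
        }
        nodes[el.get("id")] = attrs
    for el in graph.findall("g:edge", ns):
        attrs = {
            d.get("key"): _parse(d.get("key"), d.text or "") for d in el.findall("g:data", ns)
        }
        edges.append((el.get("source"), el.get("target"), attrs))
    return nodes, edges


def graph_to_graphml(g: InteractionGraph, path: str | Path) -> None:
    write_graphml(
        path,
        nodes={v: {"layer": "protein"} for v in g.universe},
        edges=[(a, b, {"interaction": "pp"}) for a, b in sorted(g.edges)],
    )
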