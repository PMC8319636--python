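"""Pathway over-representation analysis (ORA) and top-pathway extraction.

Each pathway gene set is scored with the hypergeometric upper tail: the
probability of drawing at least ``k`` pathway members in ``n`` query genes
sampled without replacement from a background of ``N`` annotated genes of
which ``K`` belong to the pathway. Raw p-values drive the ranking (ties:
larger overlap first, then lexicographic name); Benjamini–Hochberg adjusted
values are reported alongside. Query genes outside the annotation background
are dropped before ``n`` is computed, the standard ORA contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, FormatError
from .id_mapping import GeneSet


@dataclass(frozen=True)
class PathwayAnnotation:
    """One pathway gene set: stable id, display name, member symbols."""

    pathway_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise DomainError(f"pathway {self.pathway_id}: empty member set")


@dataclass
class PathwayCollection:
    """A GMT-derived collection plus the shared annotation background."""

    pathways: list[PathwayAnnotation]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for p in self.pathways:
            if not p.members <= self.background:
                raise DomainError(
                    f"pathway {p.pathway_id}: members outside the background"
                )

    def __len__(self) -> int:
        return len(self.pathways)

    def by_id(self, pathway_id: str) -> PathwayAnnotation:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise DomainError(f"unknown pathway_id {pathway_id!r}")


@dataclass(frozen=True)
class EnrichmentRow:
    pathway_id: str
    name: str
    k: int  # query genes in the pathway
    K: int  # pathway size within the background
    n: int  # query size within the background
    N: int  # background size
    p_value: float
    q_value: float
    rank: int


def read_gmt(path: str | Path, background: set[str] | None = None) -> PathwayCollection:
    """Parse a standard GMT file (name TAB description TAB member...).

    The background defaults to the union of all members; an explicit
    background (e.g. from :func:`read_background`) overrides it and must
    cover every member.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
    pathways: list[PathwayAnnotation] = []
    union: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, description = fields[0], fields[1]
            members = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not members:
                raise FormatError(f"{path}:{lineno}: pathway {name!r} has no members")
            pathways.append(
                PathwayAnnotation(pathway_id=name, name=description or name, members=members)
            )
            union |= members
    bg = frozenset(s.upper() for s in background) if background is not None else frozenset(union)
    return PathwayCollection(pathways=pathways, background=bg)


def read_background(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line background file."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip().upper() for line in fh if line.strip()}


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The survival function is evaluated in a numerically stable form; the
    result is clipped to [0, 1] against floating-point overshoot.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError(f"invalid hypergeometric sizes K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise DomainError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def adjust_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, order-aligned with the input."""
    if len(p_values) == 0:
        return []
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise DomainError(f"p-value {p} outside [0, 1]")
    _, q, _, _ = multipletests(list(p_values), method="fdr_bh")
    return [float(v) for v in q]


def enrich(query: GeneSet, annotations: PathwayCollection) -> list[EnrichmentRow]:
    """Score every pathway against the query and rank by p-value.

    Pathways with zero overlap are retained at p = 1 so the output covers
    the full collection. Ranks are 1..m with the deterministic tie order
    (p ascending, overlap descending, name, then id).
    """
    if not annotations.background:
        raise DomainError("empty annotation background")
    background = annotations.background
    query_in_bg = {s.upper() for s in query.symbols} & background
    n = len(query_in_bg)
    N = len(background)
    scored = []
    for pathway in annotations.pathways:
        K = len(pathway.members)
        k = len(query_in_bg & pathway.members)
        p = hypergeom_upper_tail(k, K, n, N)
        scored.append((pathway, k, K, p))
    q_values = adjust_bh([p for (_, _, _, p) in scored])
    order = sorted(
        range(len(scored)),
        key=lambda i: (
            scored[i][3],
            -scored[i][1],
            scored[i][0].name,
            scored[i][0].pathway_id,
        ),
    )
    rows: list[EnrichmentRow] = [None] * len(scored)  # type: ignore[list-item]
    for rank, i in enumerate(order, start=1):
        pathway, k, K, p = scored[i]
        rows[rank - 1] = EnrichmentRow(
            pathway_id=pathway.pathway_id,
            name=pathway.name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            q_value=q_values[i],
            rank=rank,
        )
    return rows


def top_pathways(rows: Sequence[EnrichmentRow], top_k: int) -> list[EnrichmentRow]:
    """The first ``top_k`` rows by rank (all rows if fewer exist)."""
    if top_k < 1:
        raise DomainError(f"top_k must be >= 1, got {top_k}")
    ordered = sorted(rows, key=lambda r: r.rank)
    return list(ordered[:top_k])


def pathway_protein_union(
    top: Sequence[EnrichmentRow],
    annotations: PathwayCollection,
    query: GeneSet,
) -> GeneSet:
    """Query records whose symbol belongs to at least one top pathway.

    Order follows the query (first occurrence), mirroring the study step
    that retains the proteins of the most enriched pathways for network
    analysis.
    """
    member_union: set[str] = set()
    for row in top:
        member_union |= annotations.by_id(row.pathway_id).members
    records = tuple(r for r in query.records if r.gene_symbol in member_union)
    return GeneSet(
        name=f"{query.name}_top{len(top)}_pathways",
        records=records,
        provenance=f"{len(records)} of {len(query)} query proteins in top {len(top)} pathways",
    )


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in rows],
            "name": [r.name for r in rows],
            "k": [r.k for r in rows],
            "K": [r.K for r in rows],
            "n": [r.n for r in rows],
            "N": [r.N for r in rows],
            "p_value": [r.p_value for r in rows],
            "q_value": [r.q_value for r in rows],
            "rank": [r.rank for r in rows],
        }
    )


def write_enrichment(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    enrichment_to_frame(rows).to_csv(path, sep="\t", index=False)
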