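"""Dual above-mean key-node selection.

A protein is a key node when its degree AND betweenness both meet or
exceed the respective arithmetic means taken over the full protein
universe — including isolated proteins, whose zero centralities pull the
thresholds down. Comparisons are inclusive (>=); the selection is sorted
by betweenness descending with the symbol as deterministic tie-break.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .errors import DomainError
from .network import CentralityRecord, centrality_to_frame


@dataclass(frozen=True)
class SelectionThresholds:
    mean_degree: float
    mean_betweenness: float
    universe_size: int

    def __post_init__(self) -> None:
        if self.mean_degree < 0 or self.mean_betweenness < 0:
            raise DomainError("thresholds must be non-negative")
        if self.universe_size < 1:
            raise DomainError("universe_size must be positive")


@dataclass
class KeyNodeResult:
    thresholds: SelectionThresholds
    selected: tuple[CentralityRecord, ...]

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(r.protein for r in self.selected)

    def summary(self) -> dict:
        return {
            "mean_degree": self.thresholds.mean_degree,
            "mean_betweenness": self.thresholds.mean_betweenness,
            "universe_size": self.thresholds.universe_size,
            "n_selected": len(self.selected),
            "selected": [
                {"protein": r.protein, "degree": r.degree, "betweenness": r.betweenness}
                for r in self.selected
            ],
        }

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        centrality_to_frame(list(self.selected)).to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            Path(json_path).write_text(
                json.dumps(self.summary(), indent=2) + "\n", encoding="utf-8"
            )


def compute_thresholds(table: Sequence[CentralityRecord]) -> SelectionThresholds:
    """Arithmetic means of degree and betweenness over the whole table."""
    if not table:
        raise DomainError("cannot compute thresholds from an empty centrality table")
    n = len(table)
    return SelectionThresholds(
        mean_degree=sum(r.degree for r in table) / n,
        mean_betweenness=sum(r.betweenness for r in table) / n,
        universe_size=n,
    )


def select_key_nodes(
    table: Sequence[CentralityRecord], thresholds: SelectionThresholds
) -> KeyNodeResult:
    """Records meeting both thresholds inclusively, betweenness-descending."""
    selected = [
        r
        for r in table
        if r.degree >= thresholds.mean_degree and r.betweenness >= thresholds.mean_betweenness
    ]
    selected.sort(key=lambda r: (-r.betweenness, r.protein))
    return KeyNodeResult(thresholds=thresholds, selected=tuple(selected))
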