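"""Gene/protein identifier ingestion and cross-namespace mapping.

A query list arrives as raw identifiers in any of three namespaces
(Ensembl gene accession, HGNC-style gene symbol, UniProtKB accession).
Mapping against a three-column association table produces a deduplicated
:class:`GeneSet` of :class:`ProteinRecord` triplets — the "N unique
proteins" that seed the downstream enrichment and network stages.

Matching is case-insensitive; symbols are stored uppercase. Deduplication
is by gene symbol, first occurrence wins, so the query is counted at gene
level even when several UniProt isoform accessions map to one gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError, FormatError

logger = logging.getLogger(__name__)

#: Header names recognised as identifier columns in TSV input, in priority order.
_ID_COLUMNS = (
    "gene_symbol",
    "symbol",
    "gene",
    "ensembl_gene_id",
    "ensembl",
    "uniprot_accession",
    "uniprot",
    "id",
)

_MAPPING_COLUMNS = ("ensembl_gene_id", "gene_symbol", "uniprot_accession")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein identity triplet.

    At least one of the two accessions must be present; the symbol is the
    primary key used for deduplication and for all downstream joins.
    """

    gene_symbol: str
    ensembl_gene_id: str | None = None
    uniprot_accession: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise DomainError("ProteinRecord requires a non-empty gene_symbol")
        if not (self.ensembl_gene_id or self.uniprot_accession):
            raise DomainError(
                f"ProteinRecord {self.gene_symbol!r}: at least one of "
                "ensembl_gene_id / uniprot_accession must be present"
            )


@dataclass
class GeneSet:
    """An ordered, symbol-deduplicated collection of protein records."""

    name: str
    records: tuple[ProteinRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        symbols = [r.gene_symbol for r in self.records]
        if len(symbols) != len(set(symbols)):
            raise DomainError(f"GeneSet {self.name!r}: duplicate gene symbols")
        self.records = tuple(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(r.gene_symbol for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ensembl_gene_id": [r.ensembl_gene_id or "" for r in self.records],
                "gene_symbol": [r.gene_symbol for r in self.records],
                "uniprot_accession": [r.uniprot_accession or "" for r in self.records],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "") -> "GeneSet":
        frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        records = tuple(
            ProteinRecord(
                gene_symbol=row["gene_symbol"],
                ensembl_gene_id=row["ensembl_gene_id"] or None,
                uniprot_accession=row["uniprot_accession"] or None,
            )
            for _, row in frame.iterrows()
        )
        return cls(name=name or str(path), records=records, provenance=f"read from {path}")


def read_gene_list(
    path: str | Path,
    dialect: str = "plain",
    id_column: str | None = None,
) -> list[str]:
    """Read raw identifiers from a plain list or a headered TSV.

    ``plain``: one identifier per line, whitespace-trimmed, blank lines
    skipped. ``tsv``: the first recognised identifier column (or the
    explicit ``id_column``) is extracted in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene list not found: {path}")
    if dialect == "plain":
        with open(path, encoding="utf-8") as fh:
            return [line.strip() for line in fh if line.strip()]
    if dialect == "tsv":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        lower = {c.lower(): c for c in frame.columns}
        if id_column is not None:
            if id_column.lower() not in lower:
                raise FormatError(f"{path}: no column named {id_column!r}")
            column = lower[id_column.lower()]
        else:
            for candidate in _ID_COLUMNS:
                if candidate in lower:
                    column = lower[candidate]
                    break
            else:
                raise FormatError(
                    f"{path}: no recognizable identifier column among {list(frame.columns)}"
                )
        values = frame[column].dropna().astype(str).str.strip()
        return [v for v in values if v]
    raise DomainError(f"unknown gene-list dialect {dialect!r}")


def read_mapping_table(path: str | Path) -> pd.DataFrame:
    """Read a three-column Ensembl / symbol / UniProt association TSV."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _MAPPING_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: mapping table missing columns {missing}")
    return frame


def map_identifiers(
    raw_ids: Sequence[str],
    mapping_table: pd.DataFrame,
    name: str = "query",
) -> tuple[GeneSet, list[str]]:
    """Resolve raw identifiers against the association table.

    Every unique raw identifier ends up exactly once on one side of the
    partition: as the matching key of a mapped record, or in ``unmapped``.
    One-to-many gene→UniProt rows collapse to the first accession in table
    order; alternatives are logged. The returned GeneSet is deduplicated by
    gene symbol, keeping the first occurrence.
    """
    missing = [c for c in _MAPPING_COLUMNS if c not in mapping_table.columns]
    if missing:
        raise FormatError(f"mapping table missing columns {missing}")

    # first row per symbol wins; later rows are alternative isoform accessions
    by_symbol: dict[str, ProteinRecord] = {}
    lookup: dict[str, str] = {}  # any uppercase identifier -> owning symbol
    for _, row in mapping_table.iterrows():
        symbol = str(row["gene_symbol"]).strip().upper()
        if not symbol:
            continue
        ensembl = str(row["ensembl_gene_id"]).strip() or None
        uniprot = str(row["uniprot_accession"]).strip() or None
        if symbol in by_symbol:
            prior = by_symbol[symbol]
            if uniprot and uniprot != prior.uniprot_accession:
                logger.info(
                    "gene %s: keeping %s, alternative accession %s ignored",
                    symbol, prior.uniprot_accession, uniprot,
                )
        else:
            by_symbol[symbol] = ProteinRecord(
                gene_symbol=symbol, ensembl_gene_id=ensembl, uniprot_accession=uniprot
            )
        for key in (ensembl, symbol, uniprot):
            if key:
                lookup.setdefault(key.upper(), symbol)

    mapped: dict[str, ProteinRecord] = {}
    unmapped: list[str] = []
    seen_raw: set[str] = set()
    for raw in raw_ids:
        cleaned = raw.strip()
        key = cleaned.upper()
        if not key or key in seen_raw:
            continue
        seen_raw.add(key)
        symbol = lookup.get(key)
        if symbol is None:
            unmapped.append(cleaned)
        elif symbol not in mapped:
            mapped[symbol] = by_symbol[symbol]
    gene_set = GeneSet(
        name=name,
        records=tuple(mapped.values()),
        provenance=f"mapped {len(mapped)} of {len(seen_raw)} unique identifiers",
    )
    return gene_set, unmapped


def write_unmapped(unmapped: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{u}\n" for u in unmapped), encoding="utf-8")
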