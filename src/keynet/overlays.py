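"""Regulatory-RNA and drug layers over the key-protein set.

Two overlay families are attached to the selected key proteins:

* regulators — experimentally supported miRNA→target edges (optionally
  required to carry a blood-profile log2 fold change, whose sign splits
  them into up-/down-regulated) and lncRNA→target edges;
* drugs — drug→target edges with modality (small molecule vs biologic)
  and FDA-approval flags, summarized per protein and per modality.

Filtering is a projection onto edges whose target is a key protein, so
applying an overlay twice changes nothing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError, FormatError
from .id_mapping import GeneSet, ProteinRecord
from .keynode import KeyNodeResult
from .network import write_graphml

logger = logging.getLogger(__name__)

_MODALITIES = ("small_molecule", "biologic")


@dataclass(frozen=True)
class RegulatorEdge:
    regulator_id: str
    regulator_class: str  # "mirna" | "lncrna"
    target: str
    evidence: str = ""
    log2fc: float | None = None

    def __post_init__(self) -> None:
        if self.regulator_class not in ("mirna", "lncrna"):
            raise DomainError(f"unknown regulator class {self.regulator_class!r}")
        if self.regulator_class == "lncrna" and self.log2fc is not None:
            raise DomainError(f"lncRNA {self.regulator_id}: log2fc not applicable")
        if not self.target:
            raise DomainError(f"regulator {self.regulator_id}: empty target")


@dataclass(frozen=True)
class DrugEdge:
    drug_name: str
    target: str
    modality: str  # "small_molecule" | "biologic"
    fda_approved: bool
    interaction_type: str = ""

    def __post_init__(self) -> None:
        if not self.drug_name or not self.target:
            raise DomainError("drug edge requires drug_name and target")
        if self.modality not in _MODALITIES:
            raise DomainError(f"unknown modality {self.modality!r}")


@dataclass
class MultilayerNetwork:
    key_proteins: GeneSet
    regulator_edges: tuple[RegulatorEdge, ...] = ()
    drug_edges: tuple[DrugEdge, ...] = ()
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = set(self.key_proteins.symbols)
        for e in self.regulator_edges:
            if e.target not in keys:
                raise DomainError(f"regulator edge target {e.target} not a key protein")
        for e in self.drug_edges:
            if e.target not in keys:
                raise DomainError(f"drug edge target {e.target} not a key protein")


def _key_gene_set(key: KeyNodeResult) -> GeneSet:
    records = tuple(
        ProteinRecord(gene_symbol=r.protein, ensembl_gene_id=f"KEY:{r.protein}")
        for r in key.selected
    )
    return GeneSet(name="key_proteins", records=records, provenance="dual above-mean selection")


# ---------------------------------------------------------------------------
# readers


def read_regulator_tables(
    mirna_path: str | Path,
    dysregulation_path: str | Path,
    lncrna_path: str | Path,
) -> list[RegulatorEdge]:
    """Read miRNA-target, miRNA dysregulation and lncRNA-target TSVs.

    miRNA edges are joined to log2 fold changes by exact mature-ID match
    (e.g. hsa-miR-26a-5p); miRNAs absent from the dysregulation table carry
    no log2fc. Duplicate (regulator, target) rows collapse with a warning.
    """
    mirna = pd.read_csv(mirna_path, sep="\t", dtype=str)
    for col in ("mirna_id", "target"):
        if col not in mirna.columns:
            raise FormatError(f"{mirna_path}: missing column {col!r}")
    dys = pd.read_csv(dysregulation_path, sep="\t", dtype=str)
    for col in ("mirna_id", "log2fc"):
        if col not in dys.columns:
            raise FormatError(f"{dysregulation_path}: missing column {col!r}")
    log2fc: dict[str, float] = {}
    for row in dys.itertuples(index=False):
        try:
            log2fc[str(row.mirna_id)] = float(row.log2fc)
        except (TypeError, ValueError):
            raise FormatError(
                f"{dysregulation_path}: non-numeric log2fc {row.log2fc!r} "
                f"for {row.mirna_id}"
            ) from None
    lnc = pd.read_csv(lncrna_path, sep="\t", dtype=str)
    for col in ("lncrna_id", "target"):
        if col not in lnc.columns:
            raise FormatError(f"{lncrna_path}: missing column {col!r}")

    edges: dict[tuple[str, str, str], RegulatorEdge] = {}
    for row in mirna.itertuples(index=False):
        rid, target = str(row.mirna_id), str(row.target).upper()
        evidence = str(getattr(row, "evidence", "") or "")
        key = ("mirna", rid, target)
        if key in edges:
            logger.warning("duplicate miRNA edge %s -> %s collapsed", rid, target)
            continue
        edges[key] = RegulatorEdge(
            regulator_id=rid,
            regulator_class="mirna",
            target=target,
            evidence=evidence,
            log2fc=log2fc.get(rid),
        )
    for row in lnc.itertuples(index=False):
        rid, target = str(row.lncrna_id), str(row.target).upper()
        evidence = str(getattr(row, "assay", "") or "")
        key = ("lncrna", rid, target)
        if key in edges:
            logger.warning("duplicate lncRNA edge %s -> %s collapsed", rid, target)
            continue
        edges[key] = RegulatorEdge(
            regulator_id=rid, regulator_class="lncrna", target=target, evidence=evidence
        )
    return list(edges.values())


def read_drug_table(path: str | Path) -> list[DrugEdge]:
    """Read a drug–gene interaction TSV with strict modality/boolean tokens."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ("drug_name", "target", "modality", "fda_approved")
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    edges: list[DrugEdge] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        modality = str(row.modality)
        if modality not in _MODALITIES:
            raise FormatError(f"{path}:{i}: unknown modality token {modality!r}")
        token = str(row.fda_approved)
        if token not in ("true", "false"):
            raise FormatError(f"{path}:{i}: fda_approved must be true/false, got {token!r}")
        edges.append(
            DrugEdge(
                drug_name=str(row.drug_name),
                target=str(row.target).upper(),
                modality=modality,
                fda_approved=token == "true",
                interaction_type=str(getattr(row, "interaction_type", "") or ""),
            )
        )
    return edges


# ---------------------------------------------------------------------------
# overlays


def overlay_regulators(
    key: KeyNodeResult,
    regulators: Iterable[RegulatorEdge],
    require_dysregulation: bool = True,
) -> MultilayerNetwork:
    """Project regulator edges onto the key proteins and count by class.

    With ``require_dysregulation`` a miRNA edge must carry a nonzero
    log2fc; an exact zero is excluded with a warning since it belongs to
    neither the up- nor the down-regulated class.
    """
    if not key.selected:
        raise DomainError("empty key-protein set")
    keys = set(key.symbols)
    kept: list[RegulatorEdge] = []
    for e in regulators:
        if e.target not in keys:
            continue
        if e.regulator_class == "mirna" and require_dysregulation:
            if e.log2fc is None:
                continue
            if e.log2fc == 0.0:
                logger.warning(
                    "miRNA %s has log2fc 0 (neither up nor down); excluded", e.regulator_id
                )
                continue
        kept.append(e)
    mirnas = {e.regulator_id: e.log2fc for e in kept if e.regulator_class == "mirna"}
    up = {m for m, fc in mirnas.items() if fc is not None and fc > 0}
    down = {m for m, fc in mirnas.items() if fc is not None and fc < 0}
    summary = {
        "n_mirna": len(mirnas),
        "n_mirna_up": len(up),
        "n_mirna_down": len(down),
        "n_lncrna": len({e.regulator_id for e in kept if e.regulator_class == "lncrna"}),
        "n_regulator_edges": len(kept),
    }
    return MultilayerNetwork(
        key_proteins=_key_gene_set(key), regulator_edges=tuple(kept), summary=summary
    )


def overlay_drugs(key: KeyNodeResult, drugs: Iterable[DrugEdge]) -> MultilayerNetwork:
    """Project drug edges onto the key proteins and summarize targetability."""
    if not key.selected:
        raise DomainError("empty key-protein set")
    keys = set(key.symbols)
    kept = tuple(e for e in drugs if e.target in keys)
    per_protein: dict[str, int] = {}
    for e in kept:
        per_protein[e.target] = per_protein.get(e.target, 0) + 1
    per_protein_sorted = dict(
        sorted(per_protein.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    cross: dict[str, int] = {}
    for modality in _MODALITIES:
        names = {e.drug_name for e in kept if e.modality == modality}
        approved = {
            e.drug_name for e in kept if e.modality == modality and e.fda_approved
        }
        cross[f"n_{modality}"] = len(names)
        cross[f"n_{modality}_approved"] = len(approved)
    summary = {
        "n_drugs": len({e.drug_name for e in kept}),
        "n_drug_edges": len(kept),
        "n_targeted_proteins": len(per_protein),
        "per_protein_drug_counts": per_protein_sorted,
        **cross,
    }
    return MultilayerNetwork(
        key_proteins=_key_gene_set(key), drug_edges=kept, summary=summary
    )


def combine_layers(
    regulator_net: MultilayerNetwork, drug_net: MultilayerNetwork
) -> MultilayerNetwork:
    """Merge the regulator and drug projections over the same key set."""
    if regulator_net.key_proteins.symbols != drug_net.key_proteins.symbols:
        raise DomainError("layer key-protein sets differ")
    return MultilayerNetwork(
        key_proteins=regulator_net.key_proteins,
        regulator_edges=regulator_net.regulator_edges,
        drug_edges=drug_net.drug_edges,
        summary={**regulator_net.summary, **drug_net.summary},
    )


# ---------------------------------------------------------------------------
# export


def export_multilayer(net: MultilayerNetwork, out_dir: str | Path) -> dict[str, Path]:
    """Write GraphML, SIF and a JSON summary; returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes: dict[str, dict[str, object]] = {
        s: {"layer": "protein"} for s in net.key_proteins.symbols
    }
    edges: list[tuple[str, str, dict[str, object]]] = []
    for e in net.regulator_edges:
        attrs: dict[str, object] = {"layer": e.regulator_class}
        if e.log2fc is not None:
            attrs["log2fc"] = e.log2fc
        nodes.setdefault(e.regulator_id, attrs)
        edges.append((e.regulator_id, e.target, {"interaction": "reg"}))
    for e in net.drug_edges:
        nodes.setdefault(
            e.drug_name,
            {"layer": "drug", "modality": e.modality, "fda_approved": e.fda_approved},
        )
        edges.append((e.drug_name, e.target, {"interaction": "drug"}))

    graphml_path = out / "multilayer.graphml"
    write_graphml(graphml_path, nodes=nodes, edges=edges)
    sif_path = out / "multilayer.sif"
    sif_lines = [f"{s}\t{i['interaction']}\t{t}" for s, t, i in edges]
    sif_lines += [n for n in nodes if not any(n in (s, t) for s, t, _ in edges)]
    sif_path.write_text("".join(f"{l}\n" for l in sif_lines), encoding="utf-8")
    summary_path = out / "multilayer_summary.json"
    summary_path.write_text(json.dumps(net.summary, indent=2) + "\n", encoding="utf-8")
    return {"graphml": graphml_path, "sif": sif_path, "summary": summary_path}
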