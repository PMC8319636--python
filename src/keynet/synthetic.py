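"""Ground-truthed synthetic input bundles for the whole pipeline.

The generator emulates the statistical structure of the study inputs with
no network access: a query of ~94 proteins with a full identifier mapping,
a pathway collection in which a known subset of pathways is stuffed with
query genes (so over-representation must rank them on top), a
confidence-scored edge table in which a few planted hub proteins attach
densely with supra-threshold scores while background pairs mostly fall
below the 0.7 cutoff, signed miRNA fold changes, lncRNA target maps, and
a drug table with modality/approval flags. Ground truth (planted hubs,
enriched pathway ids, regulator and drug maps) ships with the bundle so
every stage's recovery is checkable offline.

All randomness flows from one integer seed through a single generator
consumed in a fixed order (genes -> pathways -> edges -> regulators ->
drugs), so identical config + seed reproduces the bundle byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError

#: Packaged default seed; the bundle it generates is the repository's
#: standing worked example and must let the pipeline recover all hubs.
DEFAULT_SEED = 20210715


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = DEFAULT_SEED
    n_proteins: int = 94
    n_pathways: int = 40
    enriched_pathway_count: int = 10
    enriched_overlap_fraction: float = 0.15
    enriched_pathway_pad: int = 25  # decoy genes padding each enriched pathway
    decoy_pathway_size: int = 40
    background_extra_genes: int = 900
    n_hubs: int = 3
    hub_attach_prob: float = 0.5
    background_edge_prob: float = 0.05
    subthreshold_edge_prob: float = 0.05
    score_low: tuple[float, float] = (0.15, 0.69)
    score_high: tuple[float, float] = (0.70, 0.999)
    n_mirnas: int = 80
    frac_mirna_dysregulated: float = 0.8
    log2fc_sd: float = 1.0
    n_lncrnas: int = 13
    n_drugs: int = 63
    frac_drugs_approved: float = 16 / 63
    frac_drugs_biologic: float = 8 / 63

    def __post_init__(self) -> None:
        for name in (
            "enriched_overlap_fraction",
            "hub_attach_prob",
            "background_edge_prob",
            "subthreshold_edge_prob",
            "frac_mirna_dysregulated",
            "frac_drugs_approved",
            "frac_drugs_biologic",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise DomainError(f"config field {name}={value} outside [0,1]")
        for name in ("n_proteins", "n_pathways", "n_hubs", "n_mirnas", "n_lncrnas", "n_drugs"):
            if getattr(self, name) < 1:
                raise DomainError(f"config field {name} must be >= 1")
        if self.n_hubs >= self.n_proteins:
            raise DomainError("config field n_hubs must be < n_proteins")
        if self.enriched_pathway_count > self.n_pathways:
            raise DomainError("config field enriched_pathway_count exceeds n_pathways")
        if not (self.score_low[1] < 0.7 <= self.score_high[0]):
            raise DomainError("config score ranges must be disjoint around the 0.7 cutoff")
        if self.log2fc_sd <= 0:
            raise DomainError("config field log2fc_sd must be positive")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "SyntheticConfig":
        """Load a flat ``key = value`` config file; unset fields keep defaults."""
        values: dict = {}
        field_types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise DomainError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in field_types:
                raise DomainError(f"{path}:{lineno}: unknown config field {key!r}")
            if key in ("score_low", "score_high"):
                lo, hi = (float(v) for v in raw.split(","))
                values[key] = (lo, hi)
            elif field_types[key] == "int" or key.startswith("n_") or key == "seed":
                values[key] = int(raw)
            else:
                values[key] = float(raw)
        values.update(overrides)
        return cls(**values)


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    gene_list: list[str]
    mapping_table: pd.DataFrame
    gmt_lines: list[str]
    background: list[str]
    edge_table: pd.DataFrame  # string_export dialect (protein1, protein2, combined_score)
    mirna_targets: pd.DataFrame
    dysregulation: pd.DataFrame
    lncrna_targets: pd.DataFrame
    drug_table: pd.DataFrame
    ground_truth: dict


def _symbols(n: int) -> list[str]:
    return [f"SYNP{i:04d}" for i in range(1, n + 1)]


def generate_bundle(config: SyntheticConfig | None = None) -> SyntheticBundle:
    """Generate one complete, ground-truthed input bundle."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    # --- genes -------------------------------------------------------------
    symbols = _symbols(cfg.n_proteins)
    hubs = sorted(rng.choice(symbols, size=cfg.n_hubs, replace=False).tolist())
    mapping = pd.DataFrame(
        {
            "ensembl_gene_id": [f"ENSG{90000000 + i:011d}" for i in range(cfg.n_proteins)],
            "gene_symbol": symbols,
            "uniprot_accession": [f"Q9SY{i:03d}" for i in range(cfg.n_proteins)],
        }
    )
    decoy_genes = [f"SYNB{i:04d}" for i in range(1, cfg.background_extra_genes + 1)]

    # --- pathways ----------------------------------------------------------
    overlap = max(cfg.n_hubs, math.ceil(cfg.enriched_overlap_fraction * cfg.n_proteins))
    non_hubs = [s for s in symbols if s not in hubs]
    enriched_ids = [f"SYNPW{i:03d}" for i in range(1, cfg.enriched_pathway_count + 1)]
    decoy_ids = [
        f"SYNPW{i:03d}"
        for i in range(cfg.enriched_pathway_count + 1, cfg.n_pathways + 1)
    ]
    gmt_lines: list[str] = []
    for pid in enriched_ids:
        extra = rng.choice(non_hubs, size=overlap - cfg.n_hubs, replace=False).tolist()
        pad = rng.choice(decoy_genes, size=cfg.enriched_pathway_pad, replace=False).tolist()
        members = sorted(hubs + extra + pad)
        gmt_lines.append("\t".join([pid, f"planted enriched pathway {pid}"] + members))
    for pid in decoy_ids:
        members = sorted(
            rng.choice(decoy_genes, size=cfg.decoy_pathway_size, replace=False).tolist()
        )
        gmt_lines.append("\t".join([pid, f"decoy pathway {pid}"] + members))
    background = sorted(set(symbols) | set(decoy_genes))

    # --- edges (string_export dialect, scores as integer 0-1000) -----------
    lo_low, hi_low = cfg.score_low
    lo_high, hi_high = cfg.score_high
    rows: list[tuple[str, str, int]] = []
    hub_set = set(hubs)
    for i in range(cfg.n_proteins):
        for j in range(i + 1, cfg.n_proteins):
            a, b = symbols[i], symbols[j]
            attach = cfg.hub_attach_prob if (a in hub_set or b in hub_set) else cfg.background_edge_prob
            u = rng.random()
            if u < attach:
                score = rng.uniform(lo_high, hi_high)
            elif u < attach + cfg.subthreshold_edge_prob:
                score = rng.uniform(lo_low, hi_low)
            else:
                continue
            rows.append((a, b, int(round(score * 1000))))
    edge_table = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])

    # --- regulators ---------------------------------------------------------
    mirna_ids = [f"syn-miR-{i:03d}-5p" for i in range(1, cfg.n_mirnas + 1)]
    regulator_map: dict[str, list[str]] = {}
    mirna_rows: list[tuple[str, str, str]] = []
    for idx, mid in enumerate(mirna_ids):
        targets = set()
        if idx < cfg.n_hubs:  # guarantee the map covers every hub
            targets.add(hubs[idx])
        n_extra = int(rng.integers(1, 4))
        pool = hubs if rng.random() < 0.5 else symbols
        targets |= set(rng.choice(pool, size=min(n_extra, len(pool)), replace=False).tolist())
        regulator_map[mid] = sorted(targets)
        for t in regulator_map[mid]:
            mirna_rows.append((mid, t, "synthetic-luciferase"))
    mirna_targets = pd.DataFrame(mirna_rows, columns=["mirna_id", "target", "evidence"])

    n_dys = int(round(cfg.frac_mirna_dysregulated * cfg.n_mirnas))
    dys_ids = sorted(rng.choice(mirna_ids, size=n_dys, replace=False).tolist())
    log2fc = rng.normal(0.0, cfg.log2fc_sd, size=n_dys)
    while np.any(log2fc == 0.0):  # the up/down partition must be total
        log2fc[log2fc == 0.0] = rng.normal(0.0, cfg.log2fc_sd, size=int(np.sum(log2fc == 0.0)))
    dysregulation = pd.DataFrame(
        {"mirna_id": dys_ids, "log2fc": [f"{v:.4f}" for v in log2fc]}
    )

    lnc_ids = [f"SYNLNC{i:02d}" for i in range(1, cfg.n_lncrnas + 1)]
    lnc_rows: list[tuple[str, str, str]] = []
    lnc_map: dict[str, list[str]] = {}
    for lid in lnc_ids:
        n_targets = int(rng.integers(1, 3))
        pool = hubs if rng.random() < 0.7 else symbols
        targets = sorted(rng.choice(pool, size=min(n_targets, len(pool)), replace=False).tolist())
        lnc_map[lid] = targets
        for t in targets:
            lnc_rows.append((lid, t, "RT-qPCR"))
    lncrna_targets = pd.DataFrame(lnc_rows, columns=["lncrna_id", "target", "assay"])

    # --- drugs (targets drawn from the planted hubs) ------------------------
    drug_names = [f"SYND{i:03d}" for i in range(1, cfg.n_drugs + 1)]
    n_biologic = int(round(cfg.frac_drugs_biologic * cfg.n_drugs))
    n_approved = int(round(cfg.frac_drugs_approved * cfg.n_drugs))
    biologic = set(rng.choice(drug_names, size=n_biologic, replace=False).tolist())
    approved = set(rng.choice(drug_names, size=n_approved, replace=False).tolist())
    drug_rows: list[tuple[str, str, str, str, str]] = []
    drug_map: dict[str, list[str]] = {}
    for name in drug_names:
        n_targets = int(rng.integers(1, 3))
        targets = sorted(rng.choice(hubs, size=min(n_targets, len(hubs)), replace=False).tolist())
        drug_map[name] = targets
        modality = "biologic" if name in biologic else "small_molecule"
        for t in targets:
            drug_rows.append(
                (
                    name,
                    t,
                    modality,
                    "true" if name in approved else "false",
                    "antibody" if modality == "biologic" else "inhibitor",
                )
            )
    drug_table = pd.DataFrame(
        drug_rows,
        columns=["drug_name", "target", "modality", "fda_approved", "interaction_type"],
    )

    ground_truth = {
        "planted_hubs": hubs,
        "enriched_pathway_ids": enriched_ids,
        "regulator_map": regulator_map,
        "lncrna_map": lnc_map,
        "drug_map": drug_map,
        "dysregulated_mirnas": dys_ids,
    }
    return SyntheticBundle(
        config=cfg,
        gene_list=list(symbols),
        mapping_table=mapping,
        gmt_lines=gmt_lines,
        background=background,
        edge_table=edge_table,
        mirna_targets=mirna_targets,
        dysregulation=dysregulation,
        lncrna_targets=lncrna_targets,
        drug_table=drug_table,
        ground_truth=ground_truth,
    )


#: Fixed bundle file layout (10 files).
BUNDLE_FILES = (
    "gene_list.txt",
    "mapping_table.tsv",
    "pathways.gmt",
    "background.txt",
    "edges.tsv",
    "mirna_targets.tsv",
    "mirna_dysregulation.tsv",
    "lncrna_targets.tsv",
    "drug_table.tsv",
    "ground_truth.json",
)


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every input dialect plus ground_truth.json; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / name for name in BUNDLE_FILES}
    paths["gene_list.txt"].write_text(
        "".join(f"{s}\n" for s in bundle.gene_list), encoding="utf-8"
    )
    bundle.mapping_table.to_csv(paths["mapping_table.tsv"], sep="\t", index=False)
    paths["pathways.gmt"].write_text(
        "".join(f"{l}\n" for l in bundle.gmt_lines), encoding="utf-8"
    )
    paths["background.txt"].write_text(
        "".join(f"{s}\n" for s in bundle.background), encoding="utf-8"
    )
    bundle.edge_table.to_csv(paths["edges.tsv"], sep="\t", index=False)
    bundle.mirna_targets.to_csv(paths["mirna_targets.tsv"], sep="\t", index=False)
    bundle.dysregulation.to_csv(paths["mirna_dysregulation.tsv"], sep="\t", index=False)
    bundle.lncrna_targets.to_csv(paths["lncrna_targets.tsv"], sep="\t", index=False)
    bundle.drug_table.to_csv(paths["drug_table.tsv"], sep="\t", index=False)
    paths["ground_truth.json"].write_text(
        json.dumps(bundle.ground_truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths
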