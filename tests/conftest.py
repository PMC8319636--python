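from __future__ import annotations

import json
from pathlib import Path

import pytest

from keynet import RunConfig, SyntheticConfig, generate_bundle, run_pipeline, write_bundle


def run_bundle_pipeline(seed: int, workdir: Path):
    """Generate a default-config bundle at ``seed`` and run the full pipeline."""
    bundle = generate_bundle(SyntheticConfig(seed=seed))
    manifest = write_bundle(bundle, workdir / "bundle")
    config = RunConfig(
        gene_list=str(manifest["gene_list.txt"]),
        mapping_table=str(manifest["mapping_table.tsv"]),
        gmt=str(manifest["pathways.gmt"]),
        background=str(manifest["background.txt"]),
        edge_table=str(manifest["edges.tsv"]),
        mirna_targets=str(manifest["mirna_targets.tsv"]),
        dysregulation=str(manifest["mirna_dysregulation.tsv"]),
        lncrna_targets=str(manifest["lncrna_targets.tsv"]),
        drug_table=str(manifest["drug_table.tsv"]),
        out_dir=str(workdir / "out"),
    )
    report = run_pipeline(config)
    return bundle, manifest, report, workdir / "out"


@pytest.fixture(scope="session")
def default_bundle():
    return generate_bundle(SyntheticConfig())


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the packaged default seed, shared across tests."""
    workdir = tmp_path_factory.mktemp("default_run")
    return run_bundle_pipeline(SyntheticConfig().seed, workdir)


@pytest.fixture()
def key_nodes_of(default_run):
    _, _, report, out_dir = default_run
    data = json.loads((out_dir / "key_nodes.json").read_text())
    return {row["protein"] for row in data["selected"]}
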