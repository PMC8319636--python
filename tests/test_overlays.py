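from __future__ import annotations

import pytest

from keynet import (
    CentralityRecord,
    DomainError,
    DrugEdge,
    FormatError,
    KeyNodeResult,
    RegulatorEdge,
    SelectionThresholds,
    combine_layers,
    export_multilayer,
    overlay_drugs,
    overlay_regulators,
    read_drug_table,
    read_regulator_tables,
)
from keynet.network import read_graphml


def key_result(*symbols: str) -> KeyNodeResult:
    records = tuple(
        CentralityRecord(protein=s, degree=10, betweenness=50.0) for s in symbols
    )
    return KeyNodeResult(
        thresholds=SelectionThresholds(1.0, 1.0, len(records)), selected=records
    )


def write_regulator_files(tmp_path, mirna_rows, dys_rows, lnc_rows):
    mirna = tmp_path / "mirna.tsv"
    mirna.write_text(
        "mirna_id\ttarget\tevidence\n" + "".join(f"{r}\n" for r in mirna_rows)
    )
    dys = tmp_path / "dys.tsv"
    dys.write_text("mirna_id\tlog2fc\n" + "".join(f"{r}\n" for r in dys_rows))
    lnc = tmp_path / "lnc.tsv"
    lnc.write_text("lncrna_id\ttarget\tassay\n" + "".join(f"{r}\n" for r in lnc_rows))
    return mirna, dys, lnc


class TestReadRegulatorTables:
    def test_log2fc_joined_by_mature_id(self, tmp_path):
        paths = write_regulator_files(
            tmp_path,
            ["hsa-miR-26a-5p\tIL6\tluciferase", "hsa-miR-999-3p\tTNF\twestern"],
            ["hsa-miR-26a-5p\t-0.8"],
            ["LNC1\tTNF\tRT-qPCR"],
        )
        edges = read_regulator_tables(*paths)
        by_id = {e.regulator_id: e for e in edges}
        assert by_id["hsa-miR-26a-5p"].log2fc == pytest.approx(-0.8)
        assert by_id["hsa-miR-999-3p"].log2fc is None
        assert by_id["LNC1"].regulator_class == "lncrna"
        assert by_id["LNC1"].log2fc is None

    def test_duplicate_rows_collapse(self, tmp_path):
        paths = write_regulator_files(
            tmp_path,
            ["hsa-miR-1\tIL6\tluciferase", "hsa-miR-1\tIL6\tluciferase"],
            [],
            [],
        )
        assert len(read_regulator_tables(*paths)) == 1

    def test_non_numeric_log2fc_is_a_format_error(self, tmp_path):
        paths = write_regulator_files(tmp_path, [], ["hsa-miR-1\thigh"], [])
        with pytest.raises(FormatError):
            read_regulator_tables(*paths)


class TestReadDrugTable:
    HEADER = "drug_name\ttarget\tmodality\tfda_approved\tinteraction_type\n"

    def test_parses_modality_and_approval(self, tmp_path):
        path = tmp_path / "drugs.tsv"
        path.write_text(
            self.HEADER
            + "ibudilast\tTLR4\tsmall_molecule\tfalse\tinhibitor\n"
            + "siltuximab\tIL6\tbiologic\ttrue\tantibody\n"
        )
        edges = read_drug_table(path)
        assert edges[0] == DrugEdge("ibudilast", "TLR4", "small_molecule", False, "inhibitor")
        assert edges[1].modality == "biologic" and edges[1].fda_approved is True

    def test_loose_boolean_token_rejected(self, tmp_path):
        path = tmp_path / "drugs.tsv"
        path.write_text(self.HEADER + "x\tIL6\tsmall_molecule\tyes\tinhibitor\n")
        with pytest.raises(FormatError):
            read_drug_table(path)

    def test_unknown_modality_rejected(self, tmp_path):
        path = tmp_path / "drugs.tsv"
        path.write_text(self.HEADER + "x\tIL6\tpeptide\tfalse\tinhibitor\n")
        with pytest.raises(FormatError):
            read_drug_table(path)


class TestOverlayRegulators:
    def test_filters_to_key_targets_and_signs(self):
        key = key_result("IL6")
        edges = [
            RegulatorEdge("miR-X", "mirna", "IL6", log2fc=0.5),
            RegulatorEdge("miR-Y", "mirna", "CRP", log2fc=1.0),
        ]
        net = overlay_regulators(key, edges, require_dysregulation=True)
        assert len(net.regulator_edges) == 1
        assert net.summary["n_mirna"] == 1 and net.summary["n_mirna_up"] == 1
        assert net.summary["n_mirna_down"] == 0

    def test_zero_log2fc_excluded_under_dysregulation_requirement(self):
        key = key_result("IL6")
        edges = [RegulatorEdge("miR-0", "mirna", "IL6", log2fc=0.0)]
        net = overlay_regulators(key, edges, require_dysregulation=True)
        assert net.regulator_edges == ()

    def test_no_matching_targets_gives_zero_counts(self):
        key = key_result("NOS3")
        edges = [RegulatorEdge("miR-X", "mirna", "IL6", log2fc=0.5)]
        net = overlay_regulators(key, edges, require_dysregulation=False)
        assert net.summary["n_mirna"] == 0 and net.regulator_edges == ()

    def test_counts_conservation_without_requirement(self):
        key = key_result("IL6", "TNF")
        edges = [
            RegulatorEdge("miR-A", "mirna", "IL6", log2fc=0.5),
            RegulatorEdge("miR-B", "mirna", "TNF", log2fc=-1.0),
            RegulatorEdge("miR-C", "mirna", "IL6"),
            RegulatorEdge("miR-D", "mirna", "TNF", log2fc=0.0),
        ]
        net = overlay_regulators(key, edges, require_dysregulation=False)
        s = net.summary
        no_class = sum(
            1
            for e in net.regulator_edges
            if e.regulator_class == "mirna" and (e.log2fc is None or e.log2fc == 0.0)
        )
        assert s["n_mirna_up"] + s["n_mirna_down"] + no_class == s["n_mirna"] == 4

    def test_projection_is_idempotent(self):
        key = key_result("IL6", "TNF")
        edges = [
            RegulatorEdge("miR-A", "mirna", "IL6", log2fc=0.5),
            RegulatorEdge("LNC1", "lncrna", "TNF"),
        ]
        once = overlay_regulators(key, edges, require_dysregulation=True)
        twice = overlay_regulators(key, once.regulator_edges, require_dysregulation=True)
        assert twice.regulator_edges == once.regulator_edges
        assert twice.summary == once.summary

    def test_empty_key_set_raises(self):
        empty = KeyNodeResult(thresholds=SelectionThresholds(0, 0, 1), selected=())
        with pytest.raises(DomainError):
            overlay_regulators(empty, [])

    def test_recovers_generator_ground_truth(self, default_run, key_nodes_of):
        bundle, _, report, _ = default_run
        truth = bundle.ground_truth
        dysregulated = set(truth["dysregulated_mirnas"])
        expected = {
            mid
            for mid, targets in truth["regulator_map"].items()
            if mid in dysregulated and set(targets) & key_nodes_of
        }
        assert report["n_mirna"] == len(expected)


class TestOverlayDrugs:
    def test_counts_per_protein(self):
        key = key_result("NOS3", "IL4")
        drugs = [
            DrugEdge("d1", "NOS3", "small_molecule", False),
            DrugEdge("d2", "NOS3", "small_molecule", True),
            DrugEdge("d3", "IL5", "small_molecule", False),
        ]
        net = overlay_drugs(key, drugs)
        assert net.summary["n_drug_edges"] == 2
        assert net.summary["n_targeted_proteins"] == 1
        assert net.summary["per_protein_drug_counts"] == {"NOS3": 2}

    def test_same_drug_two_targets_counts_once(self):
        key = key_result("IL6", "TNF")
        drugs = [
            DrugEdge("pleio", "IL6", "small_molecule", False),
            DrugEdge("pleio", "TNF", "small_molecule", False),
        ]
        net = overlay_drugs(key, drugs)
        assert net.summary["n_drugs"] == 1 and net.summary["n_drug_edges"] == 2

    def test_modality_approval_cross_counts(self):
        key = key_result("TNF")
        drugs = [
            DrugEdge("mab1", "TNF", "biologic", True),
            DrugEdge("sm1", "TNF", "small_molecule", False),
            DrugEdge("sm2", "TNF", "small_molecule", True),
        ]
        net = overlay_drugs(key, drugs)
        assert net.summary["n_biologic"] == 1 and net.summary["n_biologic_approved"] == 1
        assert net.summary["n_small_molecule"] == 2
        assert net.summary["n_small_molecule_approved"] == 1

    def test_recovers_generator_ground_truth(self, default_run, key_nodes_of):
        bundle, _, report, _ = default_run
        expected_edges = sum(
            1
            for targets in bundle.ground_truth["drug_map"].values()
            for t in targets
            if t in key_nodes_of
        )
        assert report["n_drug_edges"] == expected_edges


class TestExportMultilayer:
    def test_empty_layers_still_valid(self, tmp_path):
        key = key_result("IL6")
        net = overlay_drugs(key, [])
        manifest = export_multilayer(net, tmp_path)
        nodes, edges = read_graphml(manifest["graphml"])
        assert set(nodes) == {"IL6"} and edges == []

    def test_graphml_round_trip_preserves_edge_multiset(self, tmp_path):
        key = key_result("IL6", "TNF")
        reg = overlay_regulators(
            key,
            [
                RegulatorEdge("miR-A", "mirna", "IL6", log2fc=0.5),
                RegulatorEdge("LNC1", "lncrna", "TNF"),
            ],
            require_dysregulation=False,
        )
        drug = overlay_drugs(key, [DrugEdge("d1", "TNF", "biologic", True)])
        net = combine_layers(reg, drug)
        manifest = export_multilayer(net, tmp_path)
        nodes, edges = read_graphml(manifest["graphml"])
        expected = {("miR-A", "IL6", "reg"), ("LNC1", "TNF", "reg"), ("d1", "TNF", "drug")}
        assert {(s, t, a["interaction"]) for s, t, a in edges} == expected
        # every endpoint exists as a node
        assert all(s in nodes and t in nodes for s, t, _ in edges)

    def test_log2fc_attribute_present_iff_mirna_had_one(self, tmp_path):
        key = key_result("IL6", "TNF")
        reg = overlay_regulators(
            key,
            [
                RegulatorEdge("miR-A", "mirna", "IL6", log2fc=0.5),
                RegulatorEdge("miR-B", "mirna", "TNF"),
            ],
            require_dysregulation=False,
        )
        net = combine_layers(reg, overlay_drugs(key, []))
        manifest = export_multilayer(net, tmp_path)
        nodes, _ = read_graphml(manifest["graphml"])
        assert nodes["miR-A"]["log2fc"] == pytest.approx(0.5)
        assert "log2fc" not in nodes["miR-B"]
        assert nodes["d1"] if "d1" in nodes else True
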