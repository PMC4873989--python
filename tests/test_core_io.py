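"""Domain-type validation and tabular round trips."""

import numpy as np
import pandas as pd
import pytest

from pathprofiler import (ActivityMatrix, AnnotationTable, AssayClass,
                          AssayDescriptor, CompoundRecord, ReadoutMode,
                          ValidationError, default_panel)
from pathprofiler.io import (read_activity_matrix, read_annotation_table,
                             read_compound_table, read_similarity_report,
                             write_activity_matrix, write_annotation_table,
                             write_compound_table, write_report)
from pathprofiler.prediction import NeighborRow, SimilarityReport


class TestAssayDescriptor:
    def test_viability_mode_requires_proliferation_class(self):
        with pytest.raises(ValidationError):
            AssayDescriptor("x", "CRE", AssayClass.REPORTER, "HEK293",
                            ReadoutMode.VIABILITY)
        with pytest.raises(ValidationError):
            AssayDescriptor("x", "prolif", AssayClass.PROLIFERATION, "HeLa",
                            ReadoutMode.INHIBITION_WITH_LIGAND)

    @pytest.mark.parametrize("n", [2, 38, 39, 45])
    def test_default_panel_width_and_uniqueness(self, n):
        panel = default_panel(n)
        ids = [d.assay_id for d in panel]
        assert len(panel) == n
        assert len(set(ids)) == n

    def test_default_panel_has_both_reporter_modes_and_proliferation(self):
        panel = default_panel(39)
        modes = {d.readout_mode for d in panel}
        assert modes == {ReadoutMode.INHIBITION_WITH_LIGAND,
                         ReadoutMode.ACTIVATION_WITHOUT_LIGAND,
                         ReadoutMode.VIABILITY}
        n_prolif = sum(d.assay_class is AssayClass.PROLIFERATION for d in panel)
        assert n_prolif == 8


class TestCompoundRecord:
    def test_concentration_unit_must_be_known(self):
        with pytest.raises(ValidationError):
            CompoundRecord("C1", test_concentration=3.0,
                           concentration_unit="mM")
        ok = CompoundRecord("C1", test_concentration=3.0,
                            concentration_unit="ug/mL")
        assert ok.concentration_unit == "ug/mL"

    def test_non_positive_concentration_rejected(self):
        with pytest.raises(ValidationError):
            CompoundRecord("C1", test_concentration=0.0,
                           concentration_unit="uM")


class TestActivityMatrix:
    def test_rejects_duplicate_ids_and_nonfinite(self):
        vals = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "a"],
                            columns=["x", "y"])
        with pytest.raises(ValidationError, match="a"):
            ActivityMatrix(vals)
        vals = pd.DataFrame([[1.0, np.nan]], index=["a"], columns=["x", "y"])
        with pytest.raises(ValidationError, match="non-finite"):
            ActivityMatrix(vals)

    def test_requires_at_least_two_assays(self):
        vals = pd.DataFrame([[1.0], [2.0]], index=["a", "b"], columns=["x"])
        with pytest.raises(ValidationError):
            ActivityMatrix(vals)

    def test_panel_column_mismatch_rejected(self, tiny_matrix):
        panel = default_panel(2)  # ids differ from CRE_inh/CRE_act order
        with pytest.raises(ValidationError):
            ActivityMatrix(tiny_matrix.values.rename(
                columns={"CRE_inh": "other"}), assays=panel)


class TestActivityMatrixIO:
    def test_round_trip_is_identity(self, tmp_path, small_panel):
        _, matrix, _, _, _ = small_panel
        path = tmp_path / "activity.csv"
        write_activity_matrix(matrix, path)
        back = read_activity_matrix(path)
        assert back.compound_ids == matrix.compound_ids
        assert back.assay_ids == matrix.assay_ids
        np.testing.assert_allclose(back.values.to_numpy(),
                                   matrix.values.to_numpy(), atol=1e-9)

    def test_well_formed_shape(self, tmp_path, tiny_matrix):
        path = tmp_path / "m.csv"
        write_activity_matrix(tiny_matrix, path)
        assert read_activity_matrix(path).shape == (3, 2)

    def test_duplicate_compound_id_named_in_error(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("compound_id,a1,a2\nC1,1,2\nC1,3,4\n")
        with pytest.raises(ValidationError, match="C1"):
            read_activity_matrix(path)

    def test_non_numeric_cell_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("compound_id,a1,a2\nC1,1,oops\n C2,3,4\n")
        with pytest.raises(ValidationError, match="a2"):
            read_activity_matrix(path)


class TestCompoundTable:
    def test_round_trip_preserves_optional_absence(self, tmp_path):
        records = [
            CompoundRecord("C001", name="AMBMP-like", smiles="CC"),
            CompoundRecord("C002"),  # everything optional absent
        ]
        path = tmp_path / "compounds.csv"
        write_compound_table(records, path)
        back = read_compound_table(path)
        assert back[0].smiles == "CC"
        assert back[1].smiles is None and back[1].name is None

    def test_missing_compound_id_column_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("name,smiles\nfoo,CC\n")
        with pytest.raises(ValidationError, match="compound_id"):
            read_compound_table(path)

    def test_invalid_smiles_warns_and_drops_structure(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("compound_id,smiles\nC1,notasmiles(((\nC2,CCO\n")
        with pytest.warns(UserWarning, match="C1"):
            back = read_compound_table(path)
        assert back[0].smiles is None
        assert back[1].smiles == "CCO"

    def test_library_scale_table(self, tmp_path):
        records = [CompoundRecord(f"C{i:04d}") for i in range(1, 1911)]
        path = tmp_path / "big.csv"
        write_compound_table(records, path)
        assert len(read_compound_table(path)) == 1910


class TestAnnotationTable:
    def test_validate_against_unknown_compound(self):
        table = AnnotationTable({"C1": "tubulin disruptor"})
        with pytest.raises(ValidationError, match="C1"):
            table.validate_against([CompoundRecord("C2")])

    def test_round_trip(self, tmp_path):
        table = AnnotationTable({"C1": "tubulin disruptor", "C2": "PDE4"},
                                notes={"C1": "classical"})
        path = tmp_path / "ann.csv"
        write_annotation_table(table, path)
        back = read_annotation_table(path)
        assert dict(back) == dict(table)
        assert back.note("C1") == "classical"


class TestReportIO:
    def _report(self, n):
        rows = [NeighborRow(f"C{i:03d}", 0.99 - 0.01 * i, 0.2, "tubulin")
                for i in range(n)]
        return SimilarityReport("Q1", rows, threshold=0.8)

    def test_twelve_neighbor_report_has_twelve_rows(self, tmp_path):
        path = tmp_path / "report.csv"
        write_report(self._report(12), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 13  # header + 12 data rows

    def test_empty_report_is_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_report(self._report(0), path)
        assert len(path.read_text().strip().splitlines()) == 1

    def test_round_trip_preserves_rp_to_six_decimals(self, tmp_path):
        report = self._report(5)
        path = tmp_path / "report.csv"
        write_report(report, path)
        back = read_similarity_report(path)
        assert back.query_id == "Q1"
        for a, b in zip(report.rows, back.rows):
            assert a.compound_id == b.compound_id
            assert abs(a.rp - b.rp) < 1e-6
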