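import logging

import numpy as np
import pytest

from barreljoint import (
    MissingFileError,
    ParseError,
    ResidueId,
    UnknownChainError,
    generate_barrel,
    membrane_barrel_spec,
    read_calpha_trace,
    read_segment_table,
    read_sheet_strands,
    read_stride_strands,
    write_pdb,
)

PDB_ALTLOC = """\
SHEET    1   A 2 ALA A   1  ALA A   2  0
SHEET    2   A 2 ALA A   4  ALA A   5 -1
SHEET    1   B 1 ALA B  10  ALA B  11  0
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA AALA A   2       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   2       9.000   9.000   9.000  0.40  0.00           C
ATOM      4  CB  GLY A   3       2.000   0.000   0.000  1.00  0.00           C
ATOM      5  CA  ALA A   4       3.000   0.000   0.000  1.00  0.00           C
ATOM      6  CA  ALA A   5       4.000   0.000   0.000  1.00  0.00           C
ATOM      7  CA  ALA B  10       5.000   0.000   0.000  1.00  0.00           C
ATOM      8  CA  ALA B  11       6.000   0.000   0.000  1.00  0.00           C
END
"""

STRIDE_TEXT = """\
REM  -------------------- Secondary structure summary -------------------
LOC  Strand       THR     5 A      THR      7 A
ASG  THR A    5    1    E        Strand    -120.00    130.00      40.0
ASG  THR A    6    2    E        Strand    -120.00    130.00      40.0
ASG  THR A    7    3    E        Strand    -120.00    130.00      40.0
ASG  GLY A    8    4    C         Coil      -80.00     80.00      90.0
ASG  GLY A    9    5    C         Coil      -80.00     80.00      90.0
ASG  VAL A   10    6    E        Strand    -120.00    130.00      40.0
ASG  VAL A   11    7    E        Strand    -120.00    130.00      40.0
"""


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "fixture.pdb"
    path.write_text(PDB_ALTLOC)
    return path


class TestReadCalphaTrace:
    def test_round_trip_of_generated_barrel(self, tmp_path):
        trace, ann = generate_barrel(membrane_barrel_spec(8))
        path = write_pdb(trace, ann, tmp_path / "barrel.pdb")
        back = read_calpha_trace(path, "A")
        assert len(back) == len(trace)
        assert back.residue_ids == trace.residue_ids
        assert np.abs(back.coords - trace.coords).max() <= 1e-3

    def test_unknown_chain(self, altloc_pdb):
        with pytest.raises(UnknownChainError):
            read_calpha_trace(altloc_pdb, "Z")

    def test_missing_file(self, tmp_path):
        with pytest.raises(MissingFileError):
            read_calpha_trace(tmp_path / "absent.pdb", "A")

    def test_altloc_resolved_by_occupancy(self, altloc_pdb):
        trace = read_calpha_trace(altloc_pdb, "A")
        idx = trace.index_of(ResidueId(2))
        assert np.allclose(trace.coords[idx], [1.0, 0.0, 0.0])

    def test_residue_without_calpha_skipped_with_warning(
        self, altloc_pdb, caplog
    ):
        with caplog.at_level(logging.WARNING):
            trace = read_calpha_trace(altloc_pdb, "A")
        assert ResidueId(3) not in trace.residue_ids
        assert len(trace) == 4
        assert any("no C-alpha" in r.message for r in caplog.records)


class TestReadSheetStrands:
    def test_records_in_order_with_sheet_id(self, altloc_pdb):
        strands = read_sheet_strands(altloc_pdb, "A")
        assert [(s.start, s.end) for s in strands] == [
            (ResidueId(1), ResidueId(2)),
            (ResidueId(4), ResidueId(5)),
        ]
        assert {s.sheet_id for s in strands} == {"A"}
        assert {s.source for s in strands} == {"sheet_record"}

    def test_filters_by_chain(self, altloc_pdb):
        strands = read_sheet_strands(altloc_pdb, "B")
        assert [(s.start, s.end) for s in strands] == [
            (ResidueId(10), ResidueId(11))
        ]

    def test_no_records_warns_not_raises(self, tmp_path, caplog):
        path = tmp_path / "bare.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           C\nEND\n"
        )
        with caplog.at_level(logging.WARNING):
            assert read_sheet_strands(path, "A") == []
        assert any("no SHEET" in r.message for r in caplog.records)


class TestReadStrideStrands:
    def test_run_length_encoding(self, tmp_path):
        path = tmp_path / "out.stride"
        path.write_text(STRIDE_TEXT)
        strands = read_stride_strands(path, "A")
        assert [(s.start, s.end) for s in strands] == [
            (ResidueId(5), ResidueId(7)),
            (ResidueId(10), ResidueId(11)),
        ]
        assert {s.source for s in strands} == {"stride"}

    def test_no_extended_states(self, tmp_path):
        path = tmp_path / "out.stride"
        path.write_text("ASG  GLY A    8    4    C         Coil   1 2 3\n")
        assert read_stride_strands(path, "A") == []

    def test_single_residue_strand(self, tmp_path):
        path = tmp_path / "out.stride"
        path.write_text("ASG  THR A    5    1    E        Strand  1 2 3\n")
        strands = read_stride_strands(path, "A")
        assert [(s.start, s.end) for s in strands] == [
            (ResidueId(5), ResidueId(5))
        ]

    def test_other_chain_ignored(self, tmp_path):
        path = tmp_path / "out.stride"
        path.write_text(STRIDE_TEXT)
        assert read_stride_strands(path, "B") == []

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "out.stride"
        path.write_text("ASG  THR A\n")
        with pytest.raises(ParseError, match=":1:"):
            read_stride_strands(path, "A")

    def test_insertion_code_parsed(self, tmp_path):
        path = tmp_path / "out.stride"
        path.write_text(
            "ASG  THR A   52A    1    E        Strand  1 2 3\n"
            "ASG  THR A   52B    2    E        Strand  1 2 3\n"
        )
        strands = read_stride_strands(path, "A")
        assert [(s.start, s.end) for s in strands] == [
            (ResidueId(52, "A"), ResidueId(52, "B"))
        ]


class TestReadSegmentTable:
    def test_rows_parsed(self, tmp_path):
        path = tmp_path / "segments.tsv"
        path.write_text(
            "chain\tstart\tend\nA\t5\t10\nA\t12\t18\nA\t52A\t60\n"
        )
        strands = read_segment_table(path)
        assert len(strands) == 3
        assert strands[2].start == ResidueId(52, "A")
        assert {s.source for s in strands} == {"user_table"}

    def test_end_before_start_rejected(self, tmp_path):
        path = tmp_path / "segments.tsv"
        path.write_text("chain\tstart\tend\nA\t10\t5\n")
        with pytest.raises(ParseError, match=":2:"):
            read_segment_table(path)

    def test_header_only_is_empty(self, tmp_path):
        path = tmp_path / "segments.tsv"
        path.write_text("chain\tstart\tend\n")
        assert read_segment_table(path) == []

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "segments.tsv"
        path.write_text("a\tb\tc\nA\t5\t10\n")
        with pytest.raises(ParseError):
            read_segment_table(path)
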