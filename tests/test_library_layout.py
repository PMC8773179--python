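import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gsis_screen.errors import (
    ConfigurationError,
    LibraryLookupError,
    LibraryParseError,
)
from gsis_screen import library_layout as ll
from gsis_screen import synthetic_screen as ss


def _write_library(tmp_path, rows):
    path = tmp_path / "lib.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


class TestWellGrammar:
    @pytest.mark.parametrize(
        "label,expected",
        [("A1", (0, 0)), ("A24", (0, 23)), ("P24", (15, 23)), ("B02", (1, 1)), ("h7", (7, 6))],
    )
    def test_parse(self, label, expected):
        assert ll.parse_well(label) == expected

    @pytest.mark.parametrize("label", ["Q1", "A0", "A25", "AA1", "", "A-1", "1A"])
    def test_parse_rejects(self, label):
        with pytest.raises(ValueError):
            ll.parse_well(label)

    def test_format_roundtrip_all_wells(self):
        wells = ll.all_wells()
        assert len(wells) == 384
        assert wells[0] == "A1" and wells[-1] == "P24"
        for w in wells:
            assert ll.format_well(*ll.parse_well(w)) == w

    def test_zero_pad_dialect(self):
        assert ll.format_well(0, 0, zero_pad=True) == "A01"
        assert ll.parse_well("A01") == ll.parse_well("A1")


class TestLoadLibrary:
    def test_three_rows(self, tmp_path):
        path = _write_library(
            tmp_path,
            [
                {"uniprot_id": f"P0000{i}", "gene_symbol": f"G{i}",
                 "source_plate": "S1", "source_well": f"A{i + 1}"}
                for i in range(3)
            ],
        )
        entries = ll.load_library(path)
        assert len(entries) == 3
        assert entries[0].gene_symbol == "G0"

    def test_duplicate_uniprot_rejected(self, tmp_path):
        path = _write_library(
            tmp_path,
            [
                {"uniprot_id": "P1", "gene_symbol": "A", "source_plate": "S1", "source_well": "A1"},
                {"uniprot_id": "P1", "gene_symbol": "B", "source_plate": "S1", "source_well": "A2"},
            ],
        )
        with pytest.raises(LibraryParseError, match="duplicate uniprot_id"):
            ll.load_library(path)

    def test_malformed_well_names_row(self, tmp_path):
        path = _write_library(
            tmp_path,
            [
                {"uniprot_id": "P1", "gene_symbol": "A", "source_plate": "S1", "source_well": "A1"},
                {"uniprot_id": "P2", "gene_symbol": "B", "source_plate": "S1", "source_well": "Z9"},
            ],
        )
        with pytest.raises(LibraryParseError, match="row 3"):
            ll.load_library(path)

    def test_full_size_fixture_library(self, tmp_path, library521):
        path = tmp_path / "full.csv"
        ll.write_library(library521, path)
        entries = ll.load_library(path)
        candidates = [e for e in entries if e.gene_symbol.startswith("GENE")]
        assert len(candidates) == 521


class TestAssignWells:
    def test_521_genes_make_seven_sets(self, plate_sets7):
        assert len(plate_sets7) == 7

    def test_single_gene_single_set(self, small_library):
        one = [e for e in small_library if e.gene_symbol == "GENE0001"]
        sets = ll.assign_wells(one, replicates=3, capacity=75, seed=0)
        assert len(sets) == 1
        cand = [a for a in sets[0].layout if a.role == "candidate"]
        assert len(cand) == 3
        assert {a.gene_symbol for a in cand} == {"GENE0001"}

    def test_same_seed_identical_different_seed_differs(self, small_library):
        a = ll.assign_wells(small_library, seed=5)
        b = ll.assign_wells(small_library, seed=5)
        c = ll.assign_wells(small_library, seed=6)
        assert ll.layout_to_frame(a).equals(ll.layout_to_frame(b))
        fa, fc = ll.layout_to_frame(a), ll.layout_to_frame(c)
        assert not fa.equals(fc)
        # same per-gene well counts either way
        counts = lambda f: f[f.role == "candidate"].groupby("gene_symbol").size().to_dict()
        assert counts(fa) == counts(fc)

    def test_capacity_violation(self, small_library):
        with pytest.raises(ConfigurationError, match="capacity"):
            ll.assign_wells(small_library, replicates=3, capacity=110)

    def test_control_reservation_counts(self, plate_sets7):
        for ps in plate_sets7:
            roles = {}
            for a in ps.layout:
                roles.setdefault((a.role, a.gene_symbol), 0)
                roles[(a.role, a.gene_symbol)] += 1
            assert roles[("nt", None)] == 33
            for gene in ll.CONTROL_GENES:
                assert roles[("control", gene)] == 8

    def test_last_set_padded_with_empty(self, plate_sets7):
        last = plate_sets7[-1]
        genes = last.genes()
        assert len(genes) == 521 - 6 * 75  # 71 genes on the last set
        assert any(a.role == "empty" for a in last.layout)
        assert len(last.layout) == 384

    def test_fixed_control_positions(self, small_library):
        controls = ll.ControlSpec(
            nt_wells=2,
            control_wells={"INSULIN": 1},
            fixed_positions={"NT": ["A1", "A2"], "INSULIN": ["P24"]},
        )
        sets = ll.assign_wells(small_library, controls=controls, seed=0)
        by_well = {a.well: a for a in sets[0].layout}
        assert by_well["A1"].role == "nt" and by_well["A2"].role == "nt"
        assert by_well["P24"].gene_symbol == "INSULIN"

    def test_conservation_over_sets(self, plate_sets7):
        total = sum(len([a for a in ps.layout if a.role == "candidate"]) for ps in plate_sets7)
        assert total == 521 * 3
        wells = set(ll.all_wells())
        for ps in plate_sets7:
            assert all(a.well in wells for a in ps.layout)


class TestRandomizationUniformity:
    def test_row_occupancy_uniform_over_seeds(self, small_library):
        # over 200 seeds the row index of a fixed gene's wells should be
        # uniform over the 16 rows (chi-square, alpha = 0.01)
        rows = []
        for seed in range(200):
            sets = ll.assign_wells(small_library, seed=seed)
            for a in sets[0].layout:
                if a.gene_symbol == "GENE0001":
                    rows.append(ll.parse_well(a.well)[0])
        observed = np.bincount(rows, minlength=16)
        assert observed.sum() == 600
        _, p = stats.chisquare(observed)
        assert p > 0.01


class TestPicklist:
    def _manual_set(self, n_candidate=10, n_control=5):
        wells = ll.all_wells()
        layout = []
        for i in range(n_candidate):
            layout.append(ll.WellAssignment("SET1", wells[i], "candidate", "GENE0001", i + 1))
        layout.append(ll.WellAssignment("SET1", wells[n_candidate], "control", "INSULIN", 1))
        for j in range(n_control - 1):
            layout.append(ll.WellAssignment("SET1", wells[n_candidate + 1 + j], "nt", None, j + 1))
        return ll.PlateSet(1, layout, {c: f"SET1_{c}" for c in ll.DEFAULT_CONDITIONS})

    def test_row_count_wells_times_conditions(self, small_library):
        ps = self._manual_set()
        rows = ll.generate_picklist([ps], small_library)
        assert len(rows) == (10 + 5) * 3

    def test_empty_layout_empty_picklist(self, small_library):
        ps = ll.PlateSet(1, [], {c: f"SET1_{c}" for c in ll.DEFAULT_CONDITIONS})
        assert ll.generate_picklist([ps], small_library) == []

    def test_source_plates_form_contiguous_blocks(self, library521, plate_sets7):
        rows = ll.generate_picklist(plate_sets7, library521)
        plates = [r.source_plate for r in rows]
        blocks = 1 + sum(1 for a, b in zip(plates, plates[1:]) if a != b)
        assert blocks == len(set(plates))

    def test_source_wells_sorted_within_plate(self, library521, plate_sets7):
        rows = ll.generate_picklist(plate_sets7, library521)
        for i in range(1, len(rows)):
            if rows[i].source_plate == rows[i - 1].source_plate:
                assert ll.well_sort_key(rows[i].source_well) >= ll.well_sort_key(
                    rows[i - 1].source_well
                )

    def test_missing_gene_raises_lookup(self, small_library):
        ps = self._manual_set()
        lib = [e for e in small_library if e.gene_symbol != "GENE0001"]
        with pytest.raises(LibraryLookupError, match="GENE0001"):
            ll.generate_picklist([ps], lib)

    def test_default_volume_and_echo_header(self, small_library, tmp_path):
        ps = self._manual_set()
        rows = ll.generate_picklist([ps], small_library)
        assert all(r.volume_nl == 100.0 for r in rows)
        path = tmp_path / "picklist.csv"
        ll.write_picklist(rows, path)
        header = path.read_text().splitlines()[0]
        assert header == ",".join(ll.ECHO_HEADER)


class TestValidateLayout:
    def test_assign_wells_output_is_valid(self, plate_sets7):
        assert ll.validate_layout(plate_sets7).ok

    def test_incomplete_replicates_flagged(self, small_library):
        sets = ll.assign_wells(small_library, seed=0)
        ps = sets[0]
        drop = next(a for a in ps.layout if a.role == "candidate")
        ps2 = ll.PlateSet(
            ps.set_id,
            [a if a is not drop else ll.WellAssignment(a.destination_plate, a.well, "empty", None, 1)
             for a in ps.layout],
            ps.condition_plates,
        )
        report = ll.validate_layout([ps2])
        assert any("incomplete replicates" in v for v in report.violations)

    def test_duplicate_well_flagged(self):
        layout = [
            ll.WellAssignment("SET1", "B2", "candidate", "G1", 1),
            ll.WellAssignment("SET1", "B2", "candidate", "G1", 2),
            ll.WellAssignment("SET1", "B3", "candidate", "G1", 3),
        ]
        ps = ll.PlateSet(1, layout, {"0mM": "SET1_0mM"})
        report = ll.validate_layout([ps])
        assert any("duplicate well B2" in v for v in report.violations)

    def test_gene_split_across_sets_flagged(self):
        mk = lambda sid: ll.PlateSet(
            sid,
            [ll.WellAssignment(f"SET{sid}", w, "candidate", "G1", i + 1)
             for i, w in enumerate(["A1", "A2", "A3"])],
            {"0mM": f"SET{sid}_0mM"},
        )
        report = ll.validate_layout([mk(1), mk(2)])
        assert any("split across sets" in v for v in report.violations)


class TestLayoutRoundtrip:
    def test_csv_roundtrip(self, plate_sets7, tmp_path):
        path = tmp_path / "layout.csv"
        ll.write_layout(plate_sets7, path)
        back = ll.read_layout(path)
        assert ll.layout_to_frame(back).equals(ll.layout_to_frame(plate_sets7))
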