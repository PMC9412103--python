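"""Template builders, semantic-parameter constraints and table loading."""

import io
import math

import numpy as np
import pytest

from bionicvein.errors import FormatError, ValidationError
from bionicvein.templates import (
    ImplantType,
    ParameterSet,
    check_constraints,
    count_free_parameters,
    load_parameter_table,
    make_template,
    template_definition,
)
from bionicvein.vein_core import VeinGrade, build_adjacency, graph_to_json, validate_graph


class TestTPlate:
    def test_ten_points_nine_veins(self, t_params):
        g = make_template(ImplantType.T_PLATE, t_params)
        assert g.n_points == 10
        assert g.n_edges == 9
        assert validate_graph(g) == []

    def test_grade_census(self, t_params):
        g = make_template(ImplantType.T_PLATE, t_params)
        census = {grade: 0 for grade in VeinGrade}
        for p in g.points:
            census[p.grade] += 1
        assert census[VeinGrade.MAIN] == 2
        assert census[VeinGrade.LATERAL] == 4
        assert census[VeinGrade.MINOR] == 4

    def test_layout_respects_vein_length_semantics(self, t_params):
        """The printed parameter meanings hold in the layout: head lateral
        length l2 = |O2 A2|, minor length u1 = |A2 C1|, tail width = l1 + m1."""
        g = make_template(ImplantType.T_PLATE, t_params)
        pos = {p.label: np.array(p.position) for p in g.points}
        assert np.linalg.norm(pos["A2"] - pos["O2"]) == pytest.approx(t_params["l2"])
        assert np.linalg.norm(pos["C1"] - pos["A2"]) == pytest.approx(t_params["u1"])
        assert np.linalg.norm(pos["O2"] - pos["O1"]) == pytest.approx(t_params["h1"])
        assert pos["B1"][0] - pos["A1"][0] == pytest.approx(
            t_params["l1"] + t_params["m1"]
        )

    def test_tail_numbered_below_head(self, t_params):
        g = make_template(ImplantType.T_PLATE, t_params)
        idx = {p.label: p.id for p in g.points}
        for tail in ("O1", "A1", "B1"):
            for head in ("O2", "A2", "B2", "C1", "D1", "C2", "D2"):
                assert idx[tail] < idx[head]

    def test_missing_parameter_named(self, t_values):
        del t_values["alpha2"]
        params = ParameterSet(ImplantType.T_PLATE, t_values)
        with pytest.raises(KeyError, match="alpha2"):
            make_template(ImplantType.T_PLATE, params)

    def test_determinism(self, t_params):
        a = make_template(ImplantType.T_PLATE, t_params)
        b = make_template(ImplantType.T_PLATE, t_params)
        assert graph_to_json(a) == graph_to_json(b)


class TestConstraints:
    def test_valid_set_has_no_violations(self, t_params):
        assert check_constraints(t_params) == []

    def test_acute_head_angle_flagged(self, t_values):
        t_values["alpha1"] = 80.0
        bad = ParameterSet(ImplantType.T_PLATE, t_values)
        violations = check_constraints(bad)
        assert violations == ["90 < alpha1"]
        with pytest.raises(ValidationError):
            make_template(ImplantType.T_PLATE, bad)

    def test_screw_hole_versus_minor_width(self, t_values):
        t_values["d1"] = 8.0  # t1 = 4 -> d1 < 2 t1 fails
        violations = check_constraints(ParameterSet(ImplantType.T_PLATE, t_values))
        assert violations == ["d1 < 2*t1"]

    def test_symmetry_relations(self, t_values):
        t_values["u1"] = 5.0  # u1 != t1
        violations = check_constraints(ParameterSet(ImplantType.T_PLATE, t_values))
        assert violations == ["u1 == t1"]

    def test_non_t_templates_only_range_checked(self, clover_rows):
        # Table rows 3 and 6 break u = t pairing; they must still be valid
        for row in clover_rows:
            assert check_constraints(row) == []

    def test_angle_range_enforced_everywhere(self, stem_rows):
        values = dict(stem_rows[0].values)
        values["beta1"] = 200.0
        violations = check_constraints(
            ParameterSet(ImplantType.FEMORAL_STEM_REGION, values)
        )
        assert violations == ["0 < beta1 <= 180"]


class TestParameterCounts:
    @pytest.mark.parametrize(
        "implant_type, expected",
        [
            (ImplantType.CLOVER_HEAD, 32),
            (ImplantType.FEMORAL_STEM_REGION, 18),
            (ImplantType.T_PLATE, 11),
            (ImplantType.L_PLATE_LEFT, 8),
        ],
    )
    def test_semantic_parameter_counts(self, implant_type, expected):
        assert count_free_parameters(implant_type) == expected

    def test_builders_consume_exactly_the_declared_names(self, clover_rows, stem_rows):
        """Dropping any single declared parameter must break the build."""
        for itype, row in (
            (ImplantType.CLOVER_HEAD, clover_rows[0]),
            (ImplantType.FEMORAL_STEM_REGION, stem_rows[0]),
        ):
            for name in template_definition(itype).parameter_names:
                values = dict(row.values)
                del values[name]
                with pytest.raises(KeyError, match=name):
                    make_template(itype, ParameterSet(itype, values))


class TestPrintedTables:
    def test_all_clover_rows_build(self, clover_rows):
        assert len(clover_rows) == 7
        for row in clover_rows:
            g = make_template(ImplantType.CLOVER_HEAD, row)
            assert g.n_points == 19 and g.n_edges == 18
            assert validate_graph(g) == []

    def test_all_stem_rows_build(self, stem_rows):
        assert len(stem_rows) == 8
        for row in stem_rows:
            g = make_template(ImplantType.FEMORAL_STEM_REGION, row)
            assert g.n_points == 23 and g.n_edges == 22
            assert validate_graph(g) == []

    def test_stem_minor_leaves_lateral_midpoint(self, stem_rows):
        g = make_template(ImplantType.FEMORAL_STEM_REGION, stem_rows[0])
        pos = {p.label: np.array(p.position) for p in g.points}
        mid = (pos["O1"] + pos["A11"]) / 2.0
        assert pos["C1"] == pytest.approx(mid)
        assert np.linalg.norm(pos["A10"] - pos["C1"]) == pytest.approx(
            stem_rows[0]["u1"]
        )


class TestLPlate:
    def test_head_veins_collinear_opposite(self, l_params):
        g = make_template(ImplantType.L_PLATE_LEFT, l_params)
        pos = {p.label: np.array(p.position) for p in g.points}
        va = pos["A2"] - pos["O2"]
        vb = pos["B2"] - pos["O2"]
        cos = np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
        assert cos == pytest.approx(-1.0)

    def test_right_plate_is_mirror(self, l_params):
        left = make_template(ImplantType.L_PLATE_LEFT, l_params)
        right_params = ParameterSet(ImplantType.L_PLATE_RIGHT, l_params.values)
        right = make_template(ImplantType.L_PLATE_RIGHT, right_params)
        lx = {p.label: p.position for p in left.points}
        rx = {p.label: p.position for p in right.points}
        for label, (x, y) in lx.items():
            assert rx[label][0] == pytest.approx(-x, abs=1e-9)
            assert rx[label][1] == pytest.approx(y, abs=1e-9)

    def test_eight_points(self, l_params):
        g = make_template(ImplantType.L_PLATE_LEFT, l_params)
        assert g.n_points == 8 and g.n_edges == 7
        assert build_adjacency(g).n == 8


class TestTableLoader:
    def test_missing_column_is_format_error(self, clover_rows):
        csv = "alpha4,alpha5\n90,90\n"
        with pytest.raises(FormatError, match="missing column"):
            load_parameter_table(io.StringIO(csv), ImplantType.CLOVER_HEAD)

    def test_non_numeric_cell_reports_row_and_column(self):
        header = ",".join(
            template_definition(ImplantType.FEMORAL_STEM_REGION).parameter_names
        )
        row = ",".join(["abc"] + ["1"] * 17)
        with pytest.raises(FormatError, match="row 1.*beta1"):
            load_parameter_table(io.StringIO(header + "\n" + row + "\n"), ImplantType.FEMORAL_STEM_REGION)

    def test_empty_file_is_format_error(self):
        with pytest.raises(FormatError):
            load_parameter_table(io.StringIO(""), ImplantType.CLOVER_HEAD)

    def test_header_only_is_format_error(self):
        header = ",".join(
            template_definition(ImplantType.CLOVER_HEAD).parameter_names
        )
        with pytest.raises(FormatError, match="no data rows"):
            load_parameter_table(io.StringIO(header + "\n"), ImplantType.CLOVER_HEAD)

    def test_left_right_symmetry_of_printed_clover_angles(self, clover_rows):
        """Rows 1-5 and 7 pair left/right minor angles symmetrically; row 6
        deliberately breaks the symmetry (it is a printed asymmetric case)."""
        sym = [
            all(
                math.isclose(row[f"alpha{i}"], row[f"alpha{i + 4}"])
                for i in (10, 11, 12, 13)
            )
            for row in clover_rows
        ]
        assert sym == [True, True, True, True, True, False, True]
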