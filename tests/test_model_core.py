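"""Core data model: formulas, editing, balance checks, stoichiometric matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metanex.gpr import Gpr, GprSyntaxError
from metanex.model import (
    Compound,
    DanglingReferenceError,
    DuplicateIdError,
    FormulaError,
    Model,
    ModelIntegrityError,
    Reaction,
    UnknownIdError,
    check_charge_balance,
    check_mass_balance,
    export_matrix,
    formula_to_string,
    parse_formula,
    stoichiometric_matrix,
)


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("H", {"H": 1}),
            ("C10H16N5O13P3", {"C": 10, "H": 16, "N": 5, "O": 13, "P": 3}),
            ("HO4P", {"H": 1, "O": 4, "P": 1}),
            ("CR2", {"C": 1, "R": 2}),  # database pseudo-element
            ("Fe4S4", {"Fe": 4, "S": 4}),
        ],
    )
    def test_valid(self, text, expected):
        assert parse_formula(text) == expected

    @pytest.mark.parametrize("bad", ["", "c6", "C6h", "C 6", "6C", "C0", "C6!"])
    def test_malformed(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    def test_error_names_position(self):
        with pytest.raises(FormulaError, match="position 2"):
            parse_formula("C6x2")

    def test_hill_order_round_trip(self):
        assert formula_to_string(parse_formula("O6C6H12")) == "C6H12O6"
        assert formula_to_string({"S": 1, "Fe": 2}) == "Fe2S"


class TestModelEditing:
    def test_add_reaction(self):
        m = Model(compounds=[Compound(id="A"), Compound(id="B")])
        m.add_reaction(Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0}))
        assert set(m.reactions) == {"R1"}

    def test_duplicate_reaction_id_is_error(self):
        m = Model(compounds=[Compound(id="A"), Compound(id="B")])
        m.add_reaction(Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0}))
        with pytest.raises(DuplicateIdError):
            m.add_reaction(Reaction(id="R1", stoichiometry={"B": -1.0, "A": 1.0}))

    def test_dangling_reference_is_error(self):
        m = Model(compounds=[Compound(id="A")])
        with pytest.raises(DanglingReferenceError, match="X"):
            m.add_reaction(Reaction(id="R1", stoichiometry={"A": -1.0, "X": 1.0}))

    def test_auto_add_policy(self):
        m = Model(compounds=[Compound(id="A")])
        m.add_reaction(Reaction(id="R1", stoichiometry={"A": -1.0, "X": 1.0}),
                       auto_add_compounds=True)
        assert "X" in m.compounds

    def test_remove_reaction(self):
        m = Model(compounds=[Compound(id="A"), Compound(id="B")],
                  reactions=[Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0})])
        m.remove_reaction("R1")
        assert not m.reactions
        with pytest.raises(UnknownIdError):
            m.remove_reaction("R1")

    def test_remove_referenced_compound_requires_cascade(self):
        m = Model(compounds=[Compound(id="A"), Compound(id="B")],
                  reactions=[Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0})])
        with pytest.raises(ModelIntegrityError):
            m.remove_compound("B", cascade=False)
        m.remove_compound("B", cascade=True)
        assert "B" not in m.compounds and "R1" not in m.reactions

    def test_zero_coefficient_rejected(self):
        with pytest.raises(ValueError):
            Reaction(id="R", stoichiometry={"A": 0.0})
        with pytest.raises(ValueError):
            Reaction(id="R", stoichiometry={})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["add_r", "rm_r", "rm_c"]),
                              st.integers(0, 5), st.integers(0, 5)), max_size=30))
    def test_referential_integrity_under_random_edits(self, ops):
        """Any sequence of add/remove operations leaves no dangling references."""
        m = Model(compounds=[Compound(id=f"C{i}") for i in range(6)])
        for op, i, j in ops:
            try:
                if op == "add_r":
                    m.add_reaction(
                        Reaction(id=f"R{i}{j}", stoichiometry={f"C{i}": -1.0, f"C{j}": 1.0})
                        if i != j
                        else Reaction(id=f"R{i}", stoichiometry={f"C{i}": -1.0})
                    )
                elif op == "rm_r":
                    m.remove_reaction(sorted(m.reactions)[i % max(len(m.reactions), 1)])
                else:
                    m.remove_compound(sorted(m.compounds)[i % max(len(m.compounds), 1)],
                                      cascade=bool(j % 2))
            except (DuplicateIdError, UnknownIdError, ModelIntegrityError,
                    DanglingReferenceError, IndexError):
                pass
            m.check_integrity()


@pytest.fixture
def balance_model():
    return Model(
        compounds=[
            Compound(id="GLC", formula={"C": 6, "H": 12, "O": 6}, charge=0),
            Compound(id="LAC", formula={"C": 3, "H": 6, "O": 3}, charge=0),
            Compound(id="ATP", formula={"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}, charge=-4),
            Compound(id="ADP", formula={"C": 10, "H": 12, "N": 5, "O": 10, "P": 2}, charge=-3),
            Compound(id="PI", formula={"H": 1, "O": 4, "P": 1}, charge=-2),
            Compound(id="H2O", formula={"H": 2, "O": 1}, charge=0),
            Compound(id="H", formula={"H": 1}, charge=1),
            Compound(id="NOFORM", charge=0),
            Compound(id="NOCHARGE", formula={"C": 1}),
        ]
    )


class TestBalance:
    def test_glucose_to_two_lactate_balanced(self, balance_model):
        r = Reaction(id="R", stoichiometry={"GLC": -1.0, "LAC": 2.0})
        assert check_mass_balance(r, balance_model).balanced

    def test_glucose_to_one_lactate_imbalance(self, balance_model):
        r = Reaction(id="R", stoichiometry={"GLC": -1.0, "LAC": 1.0})
        rep = check_mass_balance(r, balance_model)
        assert not rep.balanced
        assert rep.imbalance == {"C": -3.0, "H": -6.0, "O": -3.0}

    def test_missing_formula(self, balance_model):
        r = Reaction(id="R", stoichiometry={"NOFORM": -1.0, "NOCHARGE": 1.0})
        rep = check_mass_balance(r, balance_model)
        assert not rep.balanced and rep.reason == "missing formula"

    def test_atp_hydrolysis_charge_balanced(self, balance_model):
        r = Reaction(id="R", stoichiometry={"ATP": -1.0, "H2O": -1.0,
                                            "ADP": 1.0, "PI": 1.0, "H": 1.0})
        assert check_charge_balance(r, balance_model).balanced
        assert check_mass_balance(r, balance_model).balanced

    def test_charge_difference_reported(self, balance_model):
        r = Reaction(id="R", stoichiometry={"ATP": -1.0, "ADP": 1.0, "PI": 1.0})
        rep = check_charge_balance(r, balance_model)
        assert not rep.balanced and rep.net_charge == -1.0

    def test_missing_charge(self, balance_model):
        r = Reaction(id="R", stoichiometry={"NOCHARGE": -1.0, "H2O": 1.0})
        rep = check_charge_balance(r, balance_model)
        assert not rep.balanced and rep.reason == "missing charge"

    @pytest.mark.parametrize("scale", [0.5, 2.0, 3.0, 1 / 3])
    def test_scaling_invariance(self, balance_model, scale):
        """The balance verdict ignores a positive rescaling of all coefficients."""
        r = Reaction(id="R", stoichiometry={"GLC": -scale, "LAC": 2.0 * scale})
        assert check_mass_balance(r, balance_model).balanced

    def test_reversal_invariance(self, balance_model):
        r = Reaction(id="R", stoichiometry={"GLC": -1.0, "LAC": 1.0})
        fwd = check_mass_balance(r, balance_model)
        rev = check_mass_balance(r.reversed(), balance_model)
        assert fwd.balanced == rev.balanced
        assert rev.imbalance == {k: -v for k, v in fwd.imbalance.items()}


class TestGpr:
    @pytest.mark.parametrize(
        "expr,present,expected",
        [
            ("(g1 and g2) or g3", {"g3"}, True),
            ("(g1 and g2) or g3", {"g1"}, False),
            ("(g1 and g2) or g3", {"g1", "g2"}, True),
            ("", set(), True),  # spontaneous reactions pass
            ("g1 AND g2 OR g3", {"g3"}, True),  # AND binds tighter
            ("g1 and (g2 or g3)", {"g1", "g3"}, True),
        ],
    )
    def test_evaluate(self, expr, present, expected):
        assert Gpr.parse(expr).evaluate(present) is expected

    def test_round_trip_and_equality(self):
        g = Gpr.parse("(b0001 and b0002) or b0003")
        assert Gpr.parse(g.to_string()) == g
        assert Gpr.parse("b0003 or (b0002 and b0001)") == g

    @pytest.mark.parametrize("bad", ["g1 and", "(g1", "and g1", "g1 or or g2"])
    def test_syntax_errors(self, bad):
        with pytest.raises(GprSyntaxError):
            Gpr.parse(bad)

    def test_prune_to(self):
        g = Gpr.parse("(m1 and m2) or m3")
        assert g.prune_to({"m3"}) == Gpr.parse("m3")
        assert g.prune_to({"m1", "m2"}) == Gpr.parse("m1 and m2")
        assert g.prune_to({"m1"}).is_empty


class TestStoichiometricMatrix:
    def test_single_reaction(self):
        m = Model(compounds=[Compound(id="A"), Compound(id="B")],
                  reactions=[Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0})])
        mat, rows, cols = stoichiometric_matrix(m)
        assert rows == ["A", "B"] and cols == ["R1"]
        assert mat.toarray().tolist() == [[-1.0], [1.0]]

    def test_empty_model(self):
        mat, rows, cols = stoichiometric_matrix(Model())
        assert mat.shape == (0, 0) and rows == [] and cols == []

    def test_two_reactions(self):
        m = Model(compounds=[Compound(id="A"), Compound(id="B")],
                  reactions=[Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0}),
                             Reaction(id="R2", stoichiometry={"B": -1.0, "A": 1.0})])
        mat, _, _ = stoichiometric_matrix(m)
        assert mat.toarray().tolist() == [[-1.0, 1.0], [1.0, -1.0]]

    def test_balanced_columns_annihilate_formula_vectors(self, toy):
        """N^T e = 0 for every element vector e on a balanced network."""
        mat, rows, cols = stoichiometric_matrix(toy)
        elements = sorted({el for c in toy.compounds.values() for el in c.formula})
        for el in elements:
            e = np.array([toy.compounds[c].formula.get(el, 0) for c in rows], dtype=float)
            assert np.allclose(mat.T @ e, 0.0), el

    def test_mtx_export_round_trip(self, toy, tmp_path):
        from scipy.io import mmread

        mtx, rows_f, cols_f = export_matrix(toy, str(tmp_path / "nn"))
        mat = mmread(mtx)
        rows = (tmp_path / "nn.rows.txt").read_text().splitlines()
        cols = (tmp_path / "nn.cols.txt").read_text().splitlines()
        assert mat.shape == (len(toy.compounds), len(toy.reactions))
        assert rows == sorted(toy.compounds) and cols == sorted(toy.reactions)
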