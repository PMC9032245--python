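"""Homology-hit filtering, GPR-enforced reconstruction, gap filling."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metanex.curation import (
    GapFillProblem,
    GapFillStatus,
    HitTableError,
    HomologyHit,
    candidate_reactions,
    gapfill,
    read_hit_table,
    reconstruct_from_hits,
)
from metanex.expansion import Seed, expand
from metanex.gpr import Gpr
from metanex.model import Compound, Model, Reaction
from metanex.synthetic import GeneratorSpec, generate_gapfill_instance


def write_hits(path, rows):
    lines = []
    for q, s, pident, evalue in rows:
        lines.append(
            f"{q}\t{s}\t{pident}\t100\t5\t0\t1\t100\t1\t100\t{evalue}\t200.0"
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return str(path)


class TestHitTable:
    def test_evalue_threshold(self, tmp_path):
        path = write_hits(tmp_path / "h.tsv", [
            ("q1", "m1", 80.0, 1e-10),
            ("q2", "m2", 80.0, 1e-6),
            ("q3", "m3", 80.0, 1e-3),
        ])
        hits = read_hit_table(path, thresholds={"max_evalue": 1e-5})
        assert [h.query for h in hits] == ["q1", "q2"]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert read_hit_table(str(p)) == []

    def test_identity_strictly_below_threshold_dropped(self, tmp_path):
        path = write_hits(tmp_path / "h.tsv", [("q1", "m1", 39.9, 1e-10)])
        assert read_hit_table(path, thresholds={"min_identity": 40.0}) == []

    def test_all_passing_hits_kept(self, tmp_path):
        path = write_hits(tmp_path / "h.tsv", [
            ("q1", "m1", 80.0, 1e-10),
            ("q1", "m2", 70.0, 1e-10),
        ])
        assert len(read_hit_table(path)) == 2

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q1\tm1\tnot_a_number\t100\t5\t0\t1\t100\t1\t100\t1e-10\t200\n")
        with pytest.raises(HitTableError, match="line 1"):
            read_hit_table(str(p))

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q1\tm1\t80.0\n")
        with pytest.raises(HitTableError, match="columns"):
            read_hit_table(str(p))

    def test_coverage_filter_with_13th_column(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(
            "q1\tm1\t80.0\t100\t5\t0\t1\t100\t1\t100\t1e-10\t200\t95\n"
            "q2\tm2\t80.0\t100\t5\t0\t1\t100\t1\t100\t1e-10\t200\t50\n"
        )
        hits = read_hit_table(str(p), thresholds={"min_coverage": 70.0})
        assert [h.query for h in hits] == ["q1"]


@pytest.fixture
def reference():
    m = Model(
        compounds=[Compound(id=c) for c in "ABCDE"],
        reactions=[
            Reaction(id="R_AND", stoichiometry={"A": -1.0, "B": 1.0},
                     gpr=Gpr.parse("m1 and m2")),
            Reaction(id="R_OR", stoichiometry={"B": -1.0, "C": 1.0},
                     gpr=Gpr.parse("m1 or m3")),
            Reaction(id="R_SPONT", stoichiometry={"C": -1.0, "D": 1.0}),
            Reaction(id="R_OTHER", stoichiometry={"D": -1.0, "E": 1.0},
                     gpr=Gpr.parse("m4")),
        ],
    )
    return m


MONOMERS = {"m1": "gene1", "m2": "gene2", "m3": "gene3", "m4": "gene4"}


def hit(q, s):
    return HomologyHit(query=q, subject=s, percent_identity=80.0, evalue=1e-20, bitscore=100.0)


class TestReconstruction:
    def test_and_requires_all_subunits(self, reference):
        draft = reconstruct_from_hits(reference, MONOMERS, [hit("q1", "m1")])
        assert "R_AND" not in draft.reactions

    def test_and_satisfied_and_leaves_rewritten(self, reference):
        draft = reconstruct_from_hits(reference, MONOMERS,
                                      [hit("qa", "m1"), hit("qb", "m2")])
        assert draft.reactions["R_AND"].gpr == Gpr.parse("qa and qb")
        # the OR reaction is satisfied through m1 alone; the unmatched
        # m3 alternative is pruned
        assert draft.reactions["R_OR"].gpr == Gpr.parse("qa")

    def test_multiple_queries_become_or(self, reference):
        draft = reconstruct_from_hits(reference, MONOMERS,
                                      [hit("qa", "m1"), hit("qb", "m1"), hit("qc", "m2")])
        assert draft.reactions["R_AND"].gpr == Gpr.parse("(qa or qb) and qc")

    def test_spontaneous_policy(self, reference):
        hits = [hit("qa", "m1"), hit("qb", "m2")]
        excl = reconstruct_from_hits(reference, MONOMERS, hits)
        assert "R_SPONT" not in excl.reactions
        incl = reconstruct_from_hits(reference, MONOMERS, hits, include_spontaneous=True)
        assert "R_SPONT" in incl.reactions and incl.reactions["R_SPONT"].gpr.is_empty

    def test_unknown_subject_warns_and_ignored(self, reference):
        with pytest.warns(UserWarning, match="mystery"):
            draft = reconstruct_from_hits(reference, MONOMERS, [hit("qa", "mystery")])
        assert not draft.reactions

    def test_compounds_restricted_to_referenced(self, reference):
        draft = reconstruct_from_hits(reference, MONOMERS, [hit("qa", "m4")])
        assert set(draft.reactions) == {"R_OTHER"}
        assert set(draft.compounds) == {"D", "E"}


def linear_problem():
    """Draft A->B; repair B->C, C->D, B->D; seed {A}, target {D}."""
    draft = Model(
        compounds=[Compound(id=c) for c in "AB"],
        reactions=[Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0})],
    )
    repair = Model(
        compounds=[Compound(id=c) for c in "BCD"],
        reactions=[
            Reaction(id="R2", stoichiometry={"B": -1.0, "C": 1.0}),
            Reaction(id="R3", stoichiometry={"C": -1.0, "D": 1.0}),
            Reaction(id="R4", stoichiometry={"B": -1.0, "D": 1.0}),
        ],
    )
    return GapFillProblem(draft=draft, repair=repair,
                          seed=Seed(["A"], include_water=False), targets=frozenset("D"))


class TestGapFill:
    def test_shortcut_chosen(self):
        sol = gapfill(linear_problem())
        assert sol.reactions == {"R4"}
        assert sol.cardinality == 1 and sol.status is GapFillStatus.OPTIMAL

    def test_brute_force_agrees_on_linear_problem(self):
        problem = linear_problem()
        best = None
        for k in range(4):
            for combo in itertools.combinations(["R2", "R3", "R4"], k):
                merged = problem.draft.copy()
                for rid in combo:
                    r = problem.repair.reactions[rid].copy()
                    for cid in r.stoichiometry:
                        if cid not in merged.compounds:
                            merged.add_compound(Compound(id=cid))
                    merged.add_reaction(r)
                if "D" in expand(merged, problem.seed).scope:
                    best = k if best is None else best
        assert gapfill(problem).cardinality == best == 1

    def test_candidates_all_fire(self):
        assert candidate_reactions(linear_problem()) == {"R2", "R3", "R4"}

    def test_unreachable_candidate_excluded(self):
        problem = linear_problem()
        problem.repair.add_compound(Compound(id="X"))
        problem.repair.add_compound(Compound(id="Y"))
        problem.repair.add_reaction(Reaction(id="R9", stoichiometry={"X": -1.0, "Y": 1.0}))
        assert "R9" not in candidate_reactions(problem)

    def test_target_already_reachable(self):
        problem = linear_problem()
        problem = GapFillProblem(problem.draft, problem.repair,
                                 problem.seed, frozenset("B"))
        sol = gapfill(problem)
        assert sol.cardinality == 0 and sol.status is GapFillStatus.OPTIMAL

    def test_infeasible(self):
        problem = linear_problem()
        problem.draft.add_compound(Compound(id="Z"))
        problem = GapFillProblem(problem.draft, problem.repair,
                                 problem.seed, frozenset("Z"))
        assert gapfill(problem).status is GapFillStatus.INFEASIBLE

    def test_unknown_target_rejected(self):
        problem = linear_problem()
        with pytest.raises(ValueError, match="unknown"):
            GapFillProblem(problem.draft, problem.repair, problem.seed, frozenset({"NOPE"}))

    def test_enumerate_all_minimum_sets(self):
        problem = linear_problem()
        # make a second optimum: another direct B->D route
        problem.repair.add_reaction(Reaction(id="R0", stoichiometry={"B": -1.0, "D": 1.0}))
        sol = gapfill(problem, enumerate_all=True)
        assert sol.cardinality == 1
        assert {frozenset({"R0"}), frozenset({"R4"})} <= set(sol.all_minimum_sets)

    def test_greedy_fallback_is_irredundant(self):
        problem = linear_problem()
        sol = gapfill(problem, exact_limit=0)
        assert sol.status is GapFillStatus.MINIMAL_IRREDUNDANT
        # removing any reaction from the returned set breaks reachability
        for rid in sol.reactions:
            merged = problem.draft.copy()
            for other in sorted(sol.reactions - {rid}):
                r = problem.repair.reactions[other].copy()
                for cid in r.stoichiometry:
                    if cid not in merged.compounds:
                        merged.add_compound(Compound(id=cid))
                merged.add_reaction(r)
            assert "D" not in expand(merged, problem.seed).scope

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 3))
    def test_planted_instances_match_brute_force(self, seed, n_removed):
        """Returned cardinality equals the brute-force minimum; the set is
        feasible by replay and irredundant."""
        inst = generate_gapfill_instance(
            GeneratorSpec(n_compounds=7, n_reactions=9, reversible_fraction=0.0,
                          rng_seed=seed),
            n_removed=n_removed, n_decoys=3,
        )
        problem = GapFillProblem(inst.draft, inst.repair, inst.seed, inst.targets)
        sol = gapfill(problem)
        assert sol.status is GapFillStatus.OPTIMAL
        assert sol.cardinality <= n_removed  # the planted set bounds the optimum

        # brute force over every repair subset
        rids = sorted(inst.repair.reactions)
        best = None
        for k in range(len(rids) + 1):
            for combo in itertools.combinations(rids, k):
                merged = inst.draft.copy()
                for rid in combo:
                    r = inst.repair.reactions[rid].copy()
                    for cid in r.stoichiometry:
                        if cid not in merged.compounds:
                            merged.add_compound(inst.repair.compounds[cid].copy())
                    merged.add_reaction(r)
                if inst.targets <= expand(merged, inst.seed).scope:
                    best = k
                    break
            if best is not None:
                break
        assert sol.cardinality == best

    def test_zero_removed_gives_empty_solution(self):
        inst = generate_gapfill_instance(
            GeneratorSpec(n_compounds=6, n_reactions=8, reversible_fraction=0.0, rng_seed=5),
            n_removed=0,
        )
        sol = gapfill(GapFillProblem(inst.draft, inst.repair, inst.seed, inst.targets))
        assert sol.cardinality == 0
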