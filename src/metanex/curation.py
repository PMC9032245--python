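"""Draft reconstruction from homology hits and topological gap filling.

Reconstruction: given a reference network whose reactions carry GPR
expressions over enzyme-monomer ids, and a table of similarity-search
hits of the target organism's genes against those monomers, the draft
network contains exactly the reference reactions whose GPR is satisfied
by the set of monomers hit — enforcing that every included reaction has
its full gene-protein-reaction requirement covered, not merely one
subunit.

Gap filling: find a minimum-cardinality set of repair-network reactions
whose addition to a draft makes a list of target compounds producible
from a seed, where "producible" is network-expansion reachability.
Because feasibility is defined through expansion — a compound enters the
scope only via a reaction whose substrates were already in the scope —
solutions can never rest on self-producing (thermodynamically
infeasible) cycles, in contrast to flux-based gap filling.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .expansion import Seed, expand
from .gpr import Gpr
from .model import Model, Origin, Reaction

__all__ = [
    "GapFillProblem",
    "GapFillSolution",
    "GapFillStatus",
    "HitTableError",
    "HomologyHit",
    "candidate_reactions",
    "gapfill",
    "read_hit_table",
    "reconstruct_from_hits",
]

# 12-column BLAST tabular output (-outfmt 6); an optional 13th qcovs
# column carries query coverage
BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class HitTableError(ValueError):
    """Malformed homology hit table (message carries the line number)."""


@dataclass(frozen=True)
class HomologyHit:
    """One similarity-search hit of a query gene against a reference monomer."""

    query: str
    subject: str
    percent_identity: float
    evalue: float
    bitscore: float
    query_coverage: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(f"percent identity out of range: {self.percent_identity}")
        if self.query_coverage is not None and not 0 <= self.query_coverage <= 100:
            raise ValueError(f"query coverage out of range: {self.query_coverage}")
        if self.evalue < 0:
            raise ValueError(f"negative e-value: {self.evalue}")


DEFAULT_THRESHOLDS = {"max_evalue": 1e-5, "min_identity": 40.0, "min_coverage": 70.0}


def read_hit_table(
    path: str,
    thresholds: Mapping[str, float] | None = None,
) -> list[HomologyHit]:
    """Read a BLAST-style tabular hit file, applying filter thresholds.

    Thresholds (``max_evalue``, ``min_identity``, ``min_coverage``)
    default to 1e-5 / 40% / 70% and are strict comparisons: a row at
    39.9% identity fails ``min_identity=40``.  Coverage filtering
    applies only when the optional 13th ``qcovs`` column is present —
    plain 12-column output carries no query length.  All passing hits
    are kept; no best-hit-per-query reduction is applied.
    """
    th = dict(DEFAULT_THRESHOLDS)
    th.update(thresholds or {})
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] not in (12, 13):
        raise HitTableError(f"{path}: expected 12 or 13 tab-separated columns, got {df.shape[1]}")
    df.columns = BLAST_COLUMNS + (["qcovs"] if df.shape[1] == 13 else [])
    hits: list[HomologyHit] = []
    for idx, row in df.iterrows():
        try:
            hit = HomologyHit(
                query=row["qseqid"],
                subject=row["sseqid"],
                percent_identity=float(row["pident"]),
                evalue=float(row["evalue"]),
                bitscore=float(row["bitscore"]),
                query_coverage=float(row["qcovs"]) if "qcovs" in df.columns else None,
            )
        except (TypeError, ValueError) as exc:
            raise HitTableError(f"{path}: malformed row at line {idx + 1}: {exc}") from exc
        if hit.evalue > th["max_evalue"]:
            continue
        if hit.percent_identity < th["min_identity"]:
            continue
        if hit.query_coverage is not None and hit.query_coverage < th["min_coverage"]:
            continue
        hits.append(hit)
    return hits


def reconstruct_from_hits(
    reference: Model,
    monomer_map: Mapping[str, str],
    hits: Iterable[HomologyHit],
    include_spontaneous: bool = False,
) -> Model:
    """Draft network from a reference model and homology hits.

    A reference reaction is included iff its GPR (over monomer ids)
    evaluates true on the set of monomers hit.  GPR leaves are rewritten
    to the query gene ids that matched the monomer (an OR when several
    queries hit the same monomer), and unsatisfied alternatives are
    pruned, so draft GPRs speak the target organism's gene namespace.
    Hits whose subject is not in ``monomer_map`` are ignored with a
    warning.  Spontaneous (GPR-less) reactions are excluded unless
    ``include_spontaneous`` — homology evidence says nothing about them.
    """
    matched: dict[str, set[str]] = {}
    unknown: set[str] = set()
    for hit in hits:
        if hit.subject not in monomer_map:
            unknown.add(hit.subject)
            continue
        matched.setdefault(hit.subject, set()).add(hit.query)
    if unknown:
        warnings.warn(
            f"{len(unknown)} hit subject(s) absent from the monomer map were ignored: "
            f"{sorted(unknown)[:5]}",
            stacklevel=2,
        )

    present = set(matched)
    draft = Model(namespace=reference.namespace, cofactor_pairs=reference.cofactor_pairs)
    for rid in sorted(reference.reactions):
        r = reference.reactions[rid]
        if r.gpr.is_empty:
            if not include_spontaneous:
                continue
            new_gpr = Gpr.empty()
        elif r.gpr.evaluate(present):
            pruned = r.gpr.prune_to(present)
            new_gpr = pruned.map_genes(
                lambda m: Gpr.any_of([Gpr.gene(q) for q in sorted(matched[m])])
            )
        else:
            continue
        new_r = r.copy()
        new_r.gpr = new_gpr
        for cid in new_r.stoichiometry:
            if cid not in draft.compounds:
                draft.add_compound(reference.compounds[cid].copy())
        draft.add_reaction(new_r)
    return draft


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------


class GapFillStatus(str, Enum):
    OPTIMAL = "optimal"
    MINIMAL_IRREDUNDANT = "minimal_irredundant"
    INFEASIBLE = "infeasible"


@dataclass
class GapFillProblem:
    """Draft network, repair network, seed and target compounds."""

    draft: Model
    repair: Model
    seed: Seed
    targets: frozenset[str]

    def __post_init__(self) -> None:
        self.targets = frozenset(self.targets)
        missing = [
            t
            for t in self.targets
            if t not in self.draft.compounds and t not in self.repair.compounds
        ]
        if missing:
            raise ValueError(f"targets unknown in draft and repair: {sorted(missing)}")


@dataclass
class GapFillSolution:
    """A set of repair reactions restoring target reachability."""

    reactions: frozenset[str]
    cardinality: int
    status: GapFillStatus
    all_minimum_sets: list[frozenset[str]] = field(default_factory=list)


def _merged(draft: Model, repair: Model, chosen: Iterable[str] | None = None) -> Model:
    """Draft plus (a subset of) the repair network, repair ids tagged as such."""
    m = draft.copy()
    wanted = None if chosen is None else set(chosen)
    for rid in sorted(repair.reactions):
        if rid in m.reactions:
            continue
        if wanted is not None and rid not in wanted:
            continue
        r = repair.reactions[rid].copy()
        r.origin = Origin.GAPFILL_ADDED
        for cid in r.stoichiometry:
            if cid not in m.compounds:
                m.add_compound(repair.compounds[cid].copy())
        m.add_reaction(r)
    return m


def _reaches(draft: Model, repair: Model, subset: Iterable[str], problem: GapFillProblem) -> bool:
    merged = _merged(draft, repair, subset)
    result = expand(merged, problem.seed)
    return problem.targets <= result.scope


def candidate_reactions(problem: GapFillProblem) -> frozenset[str]:
    """Repair reactions that fire when the full repair network is added.

    Only these can appear in any solution: a repair reaction that never
    fires even with every other repair reaction present can never fire
    in any subset either (expansion is monotone in the reaction set).
    """
    merged = _merged(problem.draft, problem.repair)
    result = expand(merged, problem.seed)
    return frozenset(
        rid
        for rid, r in problem.repair.reactions.items()
        if rid not in problem.draft.reactions
        and r.substrates
        and r.substrates <= result.scope
    )


def gapfill(
    problem: GapFillProblem,
    exact_limit: int = 12,
    enumerate_all: bool = False,
    max_enumerated: int = 100,
) -> GapFillSolution:
    """Minimum-cardinality topological gap filling.

    Feasibility pre-check: the targets must lie in the scope of draft
    plus the full repair network, else the problem is infeasible.  When
    the candidate space is no larger than ``exact_limit``, an exact
    minimum is found by iterative deepening over subset sizes 0, 1, 2, …
    (ties broken lexicographically, so the result is deterministic);
    otherwise a greedy solution is reduced to irredundancy by
    single-reaction removal.  Every returned set is verified by
    replaying the expansion before it is returned.

    Reversible reactions in either network should be made explicit with
    reversibility duplication beforehand; expansion fires annotated
    directions only.
    """
    if not _reaches(problem.draft, problem.repair, None, problem):
        return GapFillSolution(frozenset(), 0, GapFillStatus.INFEASIBLE)

    candidates = sorted(candidate_reactions(problem))

    def feasible(subset: Iterable[str]) -> bool:
        return _reaches(problem.draft, problem.repair, subset, problem)

    solution: frozenset[str] | None = None
    status = GapFillStatus.OPTIMAL
    all_sets: list[frozenset[str]] = []
    if len(candidates) <= exact_limit:
        for size in range(len(candidates) + 1):
            for combo in itertools.combinations(candidates, size):
                if feasible(combo):
                    if solution is None:
                        solution = frozenset(combo)
                        if not enumerate_all:
                            break
                    all_sets.append(frozenset(combo))
                    if len(all_sets) >= max_enumerated:
                        break
            if solution is not None:
                break
    else:
        status = GapFillStatus.MINIMAL_IRREDUNDANT
        working = list(candidates)
        for rid in list(working):  # lexicographic single-removal reduction
            trial = [r for r in working if r != rid]
            if feasible(trial):
                working = trial
        solution = frozenset(working)

    assert solution is not None  # full repair set was feasible
    # replay verification: the solution alone must restore reachability
    merged = _merged(problem.draft, problem.repair, solution)
    result = expand(merged, problem.seed)
    if not problem.targets <= result.scope:  # pragma: no cover - defensive
        raise AssertionError("gap-fill replay failed: solution does not reach targets")
    _assert_no_self_production(result)
    return GapFillSolution(
        reactions=solution,
        cardinality=len(solution),
        status=status,
        all_minimum_sets=all_sets if enumerate_all else [],
    )


def _assert_no_self_production(result) -> None:
    """Every generation's additions rest only on previously available compounds."""
    seen = set(result.expanded_seed)
    for comps, _rids in result.generations:
        for c in comps:
            if c in seen:  # pragma: no cover - defensive
                raise AssertionError(f"compound {c!r} produced twice in the trace")
        seen.update(comps)
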