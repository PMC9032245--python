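"""Core network data model: compounds, reactions, models, balance checks.

The model is a plain in-memory record of a metabolic network: a compound
table, a reaction table with signed stoichiometries (negative coefficient
= substrate, positive = product), registered cofactor pairs and an id
namespace tag.  Stoichiometric coefficients may be non-integer (biomass
style reactions); balance checks compare element and charge totals with
exact rational arithmetic so that fractional coefficients do not produce
spurious float imbalances.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

from .gpr import Gpr

__all__ = [
    "BalanceReport",
    "Compound",
    "CofactorPair",
    "DanglingReferenceError",
    "DuplicateIdError",
    "Model",
    "ModelIntegrityError",
    "Origin",
    "Reaction",
    "FormulaError",
    "UnknownIdError",
    "check_charge_balance",
    "check_mass_balance",
    "export_matrix",
    "formula_to_string",
    "parse_formula",
    "stoichiometric_matrix",
]


class FormulaError(ValueError):
    """Malformed chemical sum formula."""


class DuplicateIdError(KeyError):
    pass


class UnknownIdError(KeyError):
    pass


class DanglingReferenceError(KeyError):
    pass


class ModelIntegrityError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# formulas
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a sum formula such as ``C6H12O6`` into ``{element: count}``.

    An element symbol without a digit suffix counts once.  Symbols are
    validated against the pattern capital-letter + optional lowercase
    letter rather than a periodic table, so database pseudo-elements
    (``R`` groups, ``X``) parse like any other element.

    Raises
    ------
    FormulaError
        On empty input, lowercase-leading tokens, stray characters or an
        explicit zero count; the message names the offending position.
    """
    if not text or text.strip() != text or " " in text:
        raise FormulaError(f"empty or whitespace-containing formula: {text!r}")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        element, digits = m.groups()
        count = int(digits) if digits else 1
        if count == 0:
            raise FormulaError(f"zero count for {element} at position {pos} in {text!r}")
        counts[element] = counts.get(element, 0) + count
        pos = m.end()
    return counts


def formula_to_string(counts: Mapping[str, int]) -> str:
    """Serialize an element-count mapping in Hill order (C, H, then A-Z)."""

    def key(el: str):
        return {"C": (0,), "H": (1,)}.get(el, (2, el))

    parts = []
    for el in sorted(counts, key=key):
        n = counts[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass
class Compound:
    """A metabolite: identifier plus chemical annotation.

    ``formula`` is an element-count mapping (see :func:`parse_formula`);
    ``charge`` is in elementary charge units.  Both are optional —
    balance checks report "missing formula"/"missing charge" rather than
    guessing.  ``is_mock`` marks duplicated cofactor stand-ins, which by
    construction never carry a formula or charge.
    """

    id: str
    name: str | None = None
    formula: dict[str, int] | None = None
    charge: int | None = None
    compartment: str | None = None
    database_links: dict[str, list[str]] = field(default_factory=dict)
    is_mock: bool = False

    def copy(self) -> "Compound":
        return replace(
            self,
            formula=dict(self.formula) if self.formula is not None else None,
            database_links={k: list(v) for k, v in self.database_links.items()},
        )


class Origin(str, Enum):
    """Provenance of a reaction inside a model."""

    BASE = "base"
    REV_DUPLICATE = "rev_duplicate"
    COF_DUPLICATE = "cof_duplicate"
    GAPFILL_ADDED = "gapfill_added"


@dataclass
class Reaction:
    """A reaction as one signed stoichiometry mapping.

    Negative coefficients are substrates, positive are products; the
    annotated direction is substrates -> products.  ``reversible`` marks
    whether the opposite direction is also allowed (expansion only ever
    fires the annotated direction — see reversibility duplication).
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    gpr: Gpr = field(default_factory=Gpr.empty)
    pathways: set[str] = field(default_factory=set)
    database_links: dict[str, list[str]] = field(default_factory=dict)
    bounds: tuple[float, float] | None = None
    origin: Origin = Origin.BASE

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id!r}: empty stoichiometry")
        for cid, coeff in self.stoichiometry.items():
            if coeff == 0:
                raise ValueError(f"reaction {self.id!r}: zero coefficient for {cid!r}")
        if self.origin is Origin.REV_DUPLICATE and self.reversible:
            raise ValueError(f"reaction {self.id!r}: reversed duplicates must be irreversible")

    @property
    def substrates(self) -> frozenset[str]:
        return frozenset(c for c, v in self.stoichiometry.items() if v < 0)

    @property
    def products(self) -> frozenset[str]:
        return frozenset(c for c, v in self.stoichiometry.items() if v > 0)

    def reversed(self, new_id: str | None = None, origin: Origin | None = None) -> "Reaction":
        """The same chemistry written in the opposite direction."""
        r = self.copy()
        r.id = new_id if new_id is not None else self.id
        r.stoichiometry = {c: -v for c, v in self.stoichiometry.items()}
        r.reversible = False
        if origin is not None:
            r.origin = origin
        if r.bounds is not None:
            lo, hi = r.bounds
            r.bounds = (-hi, -lo)
        return r

    def copy(self) -> "Reaction":
        return replace(
            self,
            stoichiometry=dict(self.stoichiometry),
            pathways=set(self.pathways),
            database_links={k: list(v) for k, v in self.database_links.items()},
        )


@dataclass(frozen=True)
class CofactorPair:
    """A charged/discharged cofactor couple, e.g. ATP (donor) / ADP (acceptor)."""

    donor: str
    acceptor: str

    def __post_init__(self) -> None:
        if self.donor == self.acceptor:
            raise ValueError(f"cofactor pair members must differ: {self.donor!r}")


class Model:
    """A metabolic network: compound and reaction tables plus metadata.

    Referential integrity (every compound id referenced by a reaction
    exists in the compound table) is enforced on every edit.
    """

    def __init__(
        self,
        compounds: Iterable[Compound] = (),
        reactions: Iterable[Reaction] = (),
        cofactor_pairs: Iterable[CofactorPair] = (),
        namespace: str = "other",
        notes: str = "",
    ):
        if namespace not in ("metacyc", "bigg", "other"):
            raise ValueError(f"unknown namespace {namespace!r}")
        self.compounds: dict[str, Compound] = {}
        self.reactions: dict[str, Reaction] = {}
        self.cofactor_pairs: list[CofactorPair] = list(cofactor_pairs)
        self.namespace = namespace
        self.notes = notes
        for c in compounds:
            self.add_compound(c)
        for r in reactions:
            self.add_reaction(r)

    # -- editing -------------------------------------------------------
    def add_compound(self, compound: Compound) -> None:
        if compound.id in self.compounds:
            raise DuplicateIdError(f"compound id already present: {compound.id!r}")
        self.compounds[compound.id] = compound

    def add_reaction(self, reaction: Reaction, auto_add_compounds: bool = False) -> None:
        """Add a reaction; an id collision is an error, never an overwrite.

        With ``auto_add_compounds`` unknown participants are registered as
        bare compounds (no formula, no charge) instead of raising.
        """
        if reaction.id in self.reactions:
            raise DuplicateIdError(f"reaction id already present: {reaction.id!r}")
        missing = [c for c in reaction.stoichiometry if c not in self.compounds]
        if missing and not auto_add_compounds:
            raise DanglingReferenceError(
                f"reaction {reaction.id!r} references unknown compounds: {sorted(missing)}"
            )
        for cid in missing:
            self.add_compound(Compound(id=cid))
        self.reactions[reaction.id] = reaction

    def remove_reaction(self, reaction_id: str) -> None:
        if reaction_id not in self.reactions:
            raise UnknownIdError(f"no such reaction: {reaction_id!r}")
        del self.reactions[reaction_id]

    def remove_compound(self, compound_id: str, cascade: bool = False) -> None:
        """Remove a compound; with ``cascade`` also every referencing reaction."""
        if compound_id not in self.compounds:
            raise UnknownIdError(f"no such compound: {compound_id!r}")
        referencing = [r.id for r in self.reactions.values() if compound_id in r.stoichiometry]
        if referencing and not cascade:
            raise ModelIntegrityError(
                f"compound {compound_id!r} still referenced by {sorted(referencing)}; "
                "use cascade=True to remove them as well"
            )
        for rid in referencing:
            del self.reactions[rid]
        del self.compounds[compound_id]

    # -- queries -------------------------------------------------------
    def check_integrity(self) -> None:
        for r in self.reactions.values():
            missing = [c for c in r.stoichiometry if c not in self.compounds]
            if missing:
                raise ModelIntegrityError(
                    f"reaction {r.id!r} references missing compounds {sorted(missing)}"
                )

    def reactions_referencing(self, compound_id: str) -> list[str]:
        return sorted(r.id for r in self.reactions.values() if compound_id in r.stoichiometry)

    def copy(self) -> "Model":
        m = Model(namespace=self.namespace, notes=self.notes)
        m.compounds = {cid: c.copy() for cid, c in self.compounds.items()}
        m.reactions = {rid: r.copy() for rid, r in self.reactions.items()}
        m.cofactor_pairs = list(self.cofactor_pairs)
        return m

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Model):
            return NotImplemented
        return (
            self.compounds == other.compounds
            and self.reactions == other.reactions
            and self.cofactor_pairs == other.cofactor_pairs
            and self.namespace == other.namespace
        )

    def __repr__(self) -> str:
        return (
            f"<Model namespace={self.namespace!r} compounds={len(self.compounds)} "
            f"reactions={len(self.reactions)}>"
        )


# ---------------------------------------------------------------------------
# balance checks
# ---------------------------------------------------------------------------


@dataclass
class BalanceReport:
    """Outcome of a mass- or charge-balance audit of one reaction.

    ``imbalance`` maps each element to product-side minus substrate-side
    totals (mass check); ``net_charge`` is the corresponding signed
    difference for the charge check.  ``reason`` is set when the check
    could not be carried out ("missing formula" / "missing charge").
    """

    reaction_id: str
    balanced: bool
    imbalance: dict[str, float] = field(default_factory=dict)
    net_charge: float | None = None
    reason: str | None = None


def _exact(coeff: float) -> Fraction:
    # snap float coefficients to nearby small rationals so that e.g. a
    # generated coefficient 7/3 balances exactly against integer formulas
    return Fraction(coeff).limit_denominator(10**6)


def check_mass_balance(reaction: Reaction, model: Model) -> BalanceReport:
    """Element-wise mass balance: every element's totals must cancel.

    Any participant lacking a formula makes the reaction unbalanced with
    reason "missing formula" — no guessing, no automatic proton or water
    rebalancing.  The verdict is invariant under scaling all coefficients
    by a positive constant and under reversing the reaction.
    """
    totals: dict[str, Fraction] = {}
    for cid, coeff in reaction.stoichiometry.items():
        compound = model.compounds.get(cid)
        if compound is None or compound.formula is None:
            return BalanceReport(reaction.id, balanced=False, reason="missing formula")
        q = _exact(coeff)
        for element, count in compound.formula.items():
            totals[element] = totals.get(element, Fraction(0)) + q * count
    imbalance = {el: float(v) for el, v in sorted(totals.items()) if v != 0}
    return BalanceReport(reaction.id, balanced=not imbalance, imbalance=imbalance)


def check_charge_balance(reaction: Reaction, model: Model) -> BalanceReport:
    """Net charge balance: sum of coefficient x charge must be zero."""
    net = Fraction(0)
    for cid, coeff in reaction.stoichiometry.items():
        compound = model.compounds.get(cid)
        if compound is None or compound.charge is None:
            return BalanceReport(reaction.id, balanced=False, reason="missing charge")
        net += _exact(coeff) * compound.charge
    return BalanceReport(reaction.id, balanced=net == 0, net_charge=float(net))


# ---------------------------------------------------------------------------
# stoichiometric matrix
# ---------------------------------------------------------------------------


def stoichiometric_matrix(model: Model) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """The compounds x reactions stoichiometric matrix N.

    Rows and columns are ordered lexicographically by id so serialized
    output is byte-stable across runs.  Entry (i, j) is the signed
    coefficient of compound i in reaction j.
    """
    rows = sorted(model.compounds)
    cols = sorted(model.reactions)
    row_idx = {c: i for i, c in enumerate(rows)}
    data, ii, jj = [], [], []
    for j, rid in enumerate(cols):
        for cid, coeff in model.reactions[rid].stoichiometry.items():
            ii.append(row_idx[cid])
            jj.append(j)
            data.append(float(coeff))
    mat = sp.coo_matrix(
        (np.array(data), (np.array(ii, dtype=int), np.array(jj, dtype=int))),
        shape=(len(rows), len(cols)),
    ).tocsr()
    return mat, rows, cols


def export_matrix(model: Model, prefix: str) -> tuple[str, str, str]:
    """Write the stoichiometric matrix as MatrixMarket plus label files.

    Creates ``<prefix>.mtx``, ``<prefix>.rows.txt`` (one compound id per
    line) and ``<prefix>.cols.txt`` (one reaction id per line); returns
    the three paths.
    """
    from scipy.io import mmwrite

    mat, rows, cols = stoichiometric_matrix(model)
    mtx_path = f"{prefix}.mtx"
    rows_path = f"{prefix}.rows.txt"
    cols_path = f"{prefix}.cols.txt"
    mmwrite(mtx_path, mat)
    with open(rows_path, "w") as fh:
        fh.write("".join(f"{c}\n" for c in rows))
    with open(cols_path, "w") as fh:
        fh.write("".join(f"{r}\n" for r in cols))
    return mtx_path, rows_path, cols_path
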