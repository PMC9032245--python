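"""Topological network transforms: reversibility and cofactor duplication.

Network expansion fires reactions only in their annotated direction, and
it has no notion of a compound that is "catalytically available".  Two
standard transforms prepare a network for expansion:

* **Reversibility duplication** adds, for every reversible reaction, an
  explicit reversed irreversible copy, so both directions can fire.

* **Cofactor duplication** adds, for every reaction in which a cofactor
  pair (e.g. ATP/ADP) appears on opposite sides, a copy in which the pair
  members are replaced by *mock* compounds.  Seeding the mock acceptor
  then unblocks cofactor-dependent reactions without granting access to
  the cofactor's degradation chemistry, which would otherwise inflate
  every scope with, say, the breakdown products of ATP.

Both transforms are invertible; the revert functions restore the exact
original model content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .model import CofactorPair, Compound, Model, ModelIntegrityError, Origin

__all__ = [
    "DuplicationTag",
    "DEFAULT_TAG",
    "SuffixCollisionError",
    "default_cofactor_pairs",
    "duplicate_cofactors",
    "duplicate_reversible",
    "revert_cofactors",
    "revert_reversible",
]


class SuffixCollisionError(ValueError):
    """A duplication suffix already occurs in a base identifier."""


@dataclass(frozen=True)
class DuplicationTag:
    """Identifier suffixes marking duplicated reactions and mock compounds."""

    rev_suffix: str = "__rev__"
    cof_suffix: str = "__cof__"

    def __post_init__(self) -> None:
        if not self.rev_suffix or not self.cof_suffix:
            raise ValueError("duplication suffixes must be non-empty")
        if self.rev_suffix == self.cof_suffix:
            raise ValueError("rev and cof suffixes must differ")


DEFAULT_TAG = DuplicationTag()


# Packaged cofactor pair tables (donor = charged form, acceptor =
# discharged form), spelled in each id namespace's conventions.  BiGG ids
# use the cytosolic compartment suffix; MetaCyc ids are compartment-free.
_PAIRS_METACYC = [
    ("ATP", "ADP"),
    ("ATP", "AMP"),
    ("GTP", "GDP"),
    ("CTP", "CDP"),
    ("UTP", "UDP"),
    ("NADH", "NAD"),
    ("NADPH", "NADP"),
    ("FADH2", "FAD"),
    ("ACETYL-COA", "CO-A"),
    ("UBIQUINOL-8", "UBIQUINONE-8"),
    ("REDUCED-MENAQUINONE", "CPD-9728"),
    ("GLUTATHIONE", "OXIDIZED-GLUTATHIONE"),
]

_PAIRS_BIGG = [
    ("atp_c", "adp_c"),
    ("atp_c", "amp_c"),
    ("gtp_c", "gdp_c"),
    ("ctp_c", "cdp_c"),
    ("utp_c", "udp_c"),
    ("nadh_c", "nad_c"),
    ("nadph_c", "nadp_c"),
    ("fadh2_c", "fad_c"),
    ("accoa_c", "coa_c"),
    ("q8h2_c", "q8_c"),
    ("mql8_c", "mqn8_c"),
    ("gthrd_c", "gthox_c"),
]


def default_cofactor_pairs(namespace: str) -> list[CofactorPair]:
    """The packaged cofactor-pair table for a known id namespace.

    Only ``metacyc`` and ``bigg`` tables are shipped; for any other
    namespace the pairs must be declared individually by the user.
    """
    if namespace == "metacyc":
        table = _PAIRS_METACYC
    elif namespace == "bigg":
        table = _PAIRS_BIGG
    else:
        raise ValueError(
            f"no packaged cofactor pairs for namespace {namespace!r}; "
            "declare pairs individually (CofactorPair(donor, acceptor))"
        )
    return [CofactorPair(d, a) for d, a in table]


def _resolve_pairs(
    model: Model, pairs: list[CofactorPair] | None
) -> tuple[list[CofactorPair], bool]:
    """Pairs to use and whether missing members are an error.

    Explicitly passed pairs are binding: a missing member raises.  Pairs
    taken from the model or the packaged default table are filtered to
    those fully resolvable, since default tables intentionally cover more
    chemistry than any one network contains.
    """
    if pairs is not None:
        return list(pairs), True
    if model.cofactor_pairs:
        candidates = list(model.cofactor_pairs)
    else:
        candidates = default_cofactor_pairs(model.namespace)
    return (
        [p for p in candidates if p.donor in model.compounds and p.acceptor in model.compounds],
        False,
    )


# ---------------------------------------------------------------------------
# reversibility duplication
# ---------------------------------------------------------------------------


def duplicate_reversible(model: Model, tag: DuplicationTag = DEFAULT_TAG) -> Model:
    """Add an explicit reversed copy of every reversible reaction.

    Each reversible reaction r gains an irreversible twin ``r.id + rev
    suffix`` with negated stoichiometry; r itself is marked irreversible.
    Irreversible reactions are untouched.  Returns a new model.
    """
    for rid in model.reactions:
        if tag.rev_suffix in rid:
            raise SuffixCollisionError(
                f"reaction id {rid!r} already contains the suffix {tag.rev_suffix!r}"
            )
    out = model.copy()
    for rid in sorted(model.reactions):
        r = out.reactions[rid]
        if not r.reversible:
            continue
        twin = r.reversed(new_id=rid + tag.rev_suffix, origin=Origin.REV_DUPLICATE)
        r.reversible = False
        out.add_reaction(twin)
    return out


def revert_reversible(model: Model, tag: DuplicationTag = DEFAULT_TAG) -> Model:
    """Inverse of :func:`duplicate_reversible` (identity on model content)."""
    out = model.copy()
    for rid in sorted(model.reactions):
        r = out.reactions.get(rid)
        if r is None or r.origin is not Origin.REV_DUPLICATE:
            continue
        parent_id = rid[: -len(tag.rev_suffix)] if rid.endswith(tag.rev_suffix) else None
        if parent_id is None or parent_id not in out.reactions:
            raise ModelIntegrityError(
                f"reversed duplicate {rid!r} has no parent reaction to restore"
            )
        out.reactions[parent_id].reversible = True
        out.remove_reaction(rid)
    return out


# ---------------------------------------------------------------------------
# cofactor duplication
# ---------------------------------------------------------------------------


def duplicate_cofactors(
    model: Model,
    pairs: list[CofactorPair] | None = None,
    tag: DuplicationTag = DEFAULT_TAG,
) -> Model:
    """Duplicate cofactor-using reactions with mock cofactor compounds.

    A reaction matches a pair when both members participate on opposite
    sides — the signature of the cofactor acting in its shuttle role (a
    pair on the same side is ordinary substrate use and does not trigger
    duplication).  The copy gets id ``r.id + cof suffix`` and only the
    matched pair members renamed to ``member + cof suffix``; mock
    compounds carry no formula or charge, so any reaction containing them
    is excluded from balance-filtered exports.  A reaction matching
    several pairs yields a single copy with all matched pairs mocked.

    ``pairs=None`` uses the model's registered pairs, falling back to the
    packaged table for the model's namespace (filtered to members present
    in the model).  Explicitly passed pairs must resolve or raise.
    """
    use_pairs, strict = _resolve_pairs(model, pairs)
    if strict:
        for p in use_pairs:
            for member in (p.donor, p.acceptor):
                if member not in model.compounds:
                    raise ModelIntegrityError(f"cofactor pair member {member!r} not in model")
    for rid in model.reactions:
        if tag.cof_suffix in rid:
            raise SuffixCollisionError(
                f"reaction id {rid!r} already contains the suffix {tag.cof_suffix!r}"
            )
    for cid in model.compounds:
        if tag.cof_suffix in cid:
            raise SuffixCollisionError(
                f"compound id {cid!r} already contains the suffix {tag.cof_suffix!r}"
            )

    out = model.copy()
    for rid in sorted(model.reactions):
        r = out.reactions[rid]
        matched: list[CofactorPair] = []
        for p in use_pairs:
            cd = r.stoichiometry.get(p.donor)
            ca = r.stoichiometry.get(p.acceptor)
            if cd is not None and ca is not None and (cd < 0) != (ca < 0):
                matched.append(p)
        if not matched:
            continue
        twin = r.copy()
        twin.id = rid + tag.cof_suffix
        twin.origin = Origin.COF_DUPLICATE
        members = {m for p in matched for m in (p.donor, p.acceptor)}
        for member in sorted(members):
            mock_id = member + tag.cof_suffix
            twin.stoichiometry[mock_id] = twin.stoichiometry.pop(member)
            if mock_id not in out.compounds:
                base = model.compounds[member]
                out.add_compound(
                    Compound(
                        id=mock_id,
                        name=(base.name + " (mock)") if base.name else None,
                        compartment=base.compartment,
                        is_mock=True,
                    )
                )
        out.add_reaction(twin)
    return out


def revert_cofactors(model: Model, tag: DuplicationTag = DEFAULT_TAG) -> Model:
    """Inverse of :func:`duplicate_cofactors`; idempotent.

    Removes every cofactor-duplicate reaction and every mock compound no
    longer referenced.  A mock compound still referenced by a user-added
    reaction is kept and a warning is emitted.
    """
    out = model.copy()
    for rid in sorted(model.reactions):
        if out.reactions[rid].origin is Origin.COF_DUPLICATE:
            out.remove_reaction(rid)
    for cid in sorted(model.compounds):
        c = out.compounds.get(cid)
        if c is None or not c.is_mock:
            continue
        referencing = out.reactions_referencing(cid)
        if referencing:
            warnings.warn(
                f"mock compound {cid!r} kept: still referenced by {referencing}",
                stacklevel=2,
            )
        else:
            out.remove_compound(cid)
    return out
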