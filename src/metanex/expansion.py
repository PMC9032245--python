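"""Network expansion: scope computation and single-metabolite scans.

Network expansion asks which compounds a network can produce, on purely
topological grounds, from an initial compound set (the *seed*): every
reaction whose substrates are all available fires in its annotated
direction and contributes its products; the sweep repeats until no new
compound appears.  The fixed point is the *scope* of the seed and
characterizes biosynthetic capacity without any kinetic or flux
information.  Stoichiometric coefficients are irrelevant here — the
computation is pure hypergraph reachability.

Reversible reactions must be made explicit beforehand (see
:func:`metanex.topology.duplicate_reversible`); expansion itself never
fires a reaction backwards.  Zero-substrate reactions (exchange/source
reactions) never fire — they would make everything trivially producible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .model import Model, UnknownIdError
from .topology import DEFAULT_TAG, DuplicationTag, _resolve_pairs

__all__ = [
    "COFACTOR_MODES",
    "ExpansionResult",
    "Seed",
    "WATER_IDS",
    "compare_seed_variants",
    "expand",
    "expanded_seed",
    "result_to_json",
    "scope_size",
    "single_metabolite_scan",
]

COFACTOR_MODES = ("none", "real", "mock_acceptor", "mock_both")

# Canonical water identifier per id namespace; configurable everywhere.
WATER_IDS = {"metacyc": "WATER", "bigg": "h2o_c"}


@dataclass(frozen=True)
class Seed:
    """The initial compound set for an expansion.

    ``include_water`` adds the namespace's water id.  ``cofactor_mode``
    controls which cofactor forms are added on top of the named
    compounds:

    * ``none`` — nothing added;
    * ``real`` — both real members of every registered pair (known to
      yield unrealistically large scopes: all cofactor degradation
      chemistry becomes reachable);
    * ``mock_acceptor`` — the mock form of each pair's acceptor
      (discharged) member, e.g. ``ADP__cof__``;
    * ``mock_both`` — mock forms of both members.

    Mock ids exist only after cofactor duplication has been applied.
    """

    compounds: frozenset[str] = frozenset()
    include_water: bool = True
    cofactor_mode: str = "none"

    def __init__(
        self,
        compounds: Iterable[str] = (),
        include_water: bool = True,
        cofactor_mode: str = "none",
    ):
        if cofactor_mode not in COFACTOR_MODES:
            raise ValueError(f"unknown cofactor mode {cofactor_mode!r}; use one of {COFACTOR_MODES}")
        object.__setattr__(self, "compounds", frozenset(compounds))
        object.__setattr__(self, "include_water", include_water)
        object.__setattr__(self, "cofactor_mode", cofactor_mode)


def expanded_seed(
    model: Model,
    seed: Seed,
    water_id: str | None = None,
    tag: DuplicationTag = DEFAULT_TAG,
) -> frozenset[str]:
    """Resolve a seed to the concrete compound-id set used for expansion.

    Named seed compounds must exist in the model; auxiliary additions
    (water, cofactor forms) are filtered to compounds actually present,
    since e.g. not every pair of the packaged table occurs in a given
    network.
    """
    unknown = sorted(c for c in seed.compounds if c not in model.compounds)
    if unknown:
        raise UnknownIdError(f"seed compounds not in model: {unknown}")
    out = set(seed.compounds)
    if seed.include_water:
        wid = water_id if water_id is not None else WATER_IDS.get(model.namespace)
        if wid is not None and wid in model.compounds:
            out.add(wid)
    if seed.cofactor_mode != "none":
        pairs, _ = _resolve_pairs(model, None)
        for p in pairs:
            if seed.cofactor_mode == "real":
                extra = [p.donor, p.acceptor]
            elif seed.cofactor_mode == "mock_acceptor":
                extra = [p.acceptor + tag.cof_suffix]
            else:  # mock_both
                extra = [p.donor + tag.cof_suffix, p.acceptor + tag.cof_suffix]
            out.update(e for e in extra if e in model.compounds)
    return frozenset(out)


@dataclass
class ExpansionResult:
    """Trace and fixed point of one network expansion.

    ``generations`` records, per sweep, the sorted tuple of newly
    producible compound ids and of the reactions that first fired in that
    sweep.  ``scope`` is the expanded seed plus all additions.
    """

    generations: list[tuple[tuple[str, ...], tuple[str, ...]]]
    scope: frozenset[str]
    seed_used: Seed
    expanded_seed: frozenset[str] = field(default_factory=frozenset)

    @property
    def produced(self) -> frozenset[str]:
        """Compounds gained over the expanded seed."""
        return self.scope - self.expanded_seed


def expand(
    model: Model,
    seed: Seed,
    water_id: str | None = None,
    tag: DuplicationTag = DEFAULT_TAG,
) -> ExpansionResult:
    """Compute the scope of a seed by iterated reaction firing.

    Each sweep fires every not-yet-fired reaction whose entire substrate
    set is available and adds its products.  Sweeps stop when no new
    compound appears, so the result is a fixed point and independent of
    the order in which reactions are inspected.
    """
    available = set(expanded_seed(model, seed, water_id=water_id, tag=tag))

    # remaining substrate counts per reaction; fires when count hits zero
    needs: dict[str, set[str]] = {}
    products: dict[str, frozenset[str]] = {}
    for rid, r in model.reactions.items():
        subs = r.substrates
        if not subs:
            continue  # exchange/source reactions never fire
        needs[rid] = set(subs)
        products[rid] = r.products

    consumers: dict[str, list[str]] = {}
    for rid, subs in needs.items():
        for cid in subs:
            consumers.setdefault(cid, []).append(rid)

    # reactions whose missing-substrate sets shrink as compounds arrive
    for rid in needs:
        needs[rid] -= available

    generations: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    fired: set[str] = set()
    ready = {rid for rid, miss in needs.items() if not miss}
    while True:
        new_fired = sorted(ready - fired)
        fired.update(new_fired)
        new_compounds: set[str] = set()
        for rid in new_fired:
            new_compounds.update(products[rid] - available)
        if not new_compounds:
            break
        available.update(new_compounds)
        generations.append((tuple(sorted(new_compounds)), tuple(new_fired)))
        ready = set()
        for cid in new_compounds:
            for rid in consumers.get(cid, ()):
                if rid in fired:
                    continue
                needs[rid].discard(cid)
                if not needs[rid]:
                    ready.add(rid)

    return ExpansionResult(
        generations=generations,
        scope=frozenset(available),
        seed_used=seed,
        expanded_seed=expanded_seed(model, seed, water_id=water_id, tag=tag),
    )


def scope_size(
    result: ExpansionResult,
    counting: str = "producible_non_mock",
    tag: DuplicationTag = DEFAULT_TAG,
) -> int:
    """Size of a scope under one of three counting conventions.

    * ``producible_non_mock`` (default): compounds gained over the
      expanded seed, mock cofactors excluded — the scope as a measure of
      what new real chemistry the seed unlocks;
    * ``producible_all``: gained compounds including mocks;
    * ``full_set``: the entire scope including the seed.
    """
    if counting == "full_set":
        return len(result.scope)
    produced = result.scope - result.expanded_seed
    if counting == "producible_all":
        return len(produced)
    if counting == "producible_non_mock":
        return len({c for c in produced if not c.endswith(tag.cof_suffix)})
    raise ValueError(f"unknown counting convention {counting!r}")


def result_to_json(result: ExpansionResult, indent: int | None = None) -> str:
    """Serialize an expansion trace (generations, fired reactions, scope)."""
    payload = {
        "seed": sorted(result.seed_used.compounds),
        "include_water": result.seed_used.include_water,
        "cofactor_mode": result.seed_used.cofactor_mode,
        "expanded_seed": sorted(result.expanded_seed),
        "generations": [
            {"new_compounds": list(comps), "fired_reactions": list(rxns)}
            for comps, rxns in result.generations
        ],
        "scope": sorted(result.scope),
    }
    return json.dumps(payload, indent=indent)


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def _prepare(model: Model, cofactor_mode: str, pairs, tag: DuplicationTag) -> Model:
    from .topology import duplicate_cofactors, duplicate_reversible

    prepared = model
    if any(r.reversible for r in prepared.reactions.values()):
        prepared = duplicate_reversible(prepared, tag=tag)
    if cofactor_mode in ("mock_acceptor", "mock_both") and not any(
        c.is_mock for c in prepared.compounds.values()
    ):
        prepared = duplicate_cofactors(prepared, pairs=pairs, tag=tag)
    return prepared


def single_metabolite_scan(
    model: Model,
    cofactor_mode: str = "mock_acceptor",
    pairs=None,
    counting: str = "producible_non_mock",
    water_id: str | None = None,
    include_water: bool = True,
    prepare: bool = True,
    tag: DuplicationTag = DEFAULT_TAG,
) -> dict[str, int]:
    """Scope size for every single-metabolite seed.

    For every non-mock compound c the seed {c} + water + the
    mode-dependent cofactor set is expanded and its scope size recorded.
    With ``prepare`` (default) reversibility duplication — and, for mock
    modes, cofactor duplication with the given pairs — is applied first
    if the model does not already carry it.
    """
    prepared = _prepare(model, cofactor_mode, pairs, tag) if prepare else model
    sizes: dict[str, int] = {}
    for cid in sorted(prepared.compounds):
        if prepared.compounds[cid].is_mock:
            continue
        seed = Seed([cid], include_water=include_water, cofactor_mode=cofactor_mode)
        result = expand(prepared, seed, water_id=water_id, tag=tag)
        sizes[cid] = scope_size(result, counting=counting, tag=tag)
    return sizes


def compare_seed_variants(
    model: Model,
    pairs=None,
    counting: str = "producible_non_mock",
    water_id: str | None = None,
    tag: DuplicationTag = DEFAULT_TAG,
) -> pd.DataFrame:
    """Single-metabolite scans under the three seeding variants.

    Variants: no cofactors in the seed; the real cofactor compounds; the
    mock acceptor cofactors after duplication.  Returns a tidy table with
    columns ``compound``, ``variant`` and ``scope_size``, ordered by the
    mock variant's sizes (descending, ties by id) for rank plotting.
    """
    prepared = _prepare(model, "mock_acceptor", pairs, tag)
    scans = {
        mode_name: single_metabolite_scan(
            prepared,
            cofactor_mode=mode,
            pairs=pairs,
            counting=counting,
            water_id=water_id,
            prepare=False,
            tag=tag,
        )
        for mode_name, mode in (("none", "none"), ("real", "real"), ("mock", "mock_acceptor"))
    }
    order = sorted(scans["mock"], key=lambda c: (-scans["mock"][c], c))
    records = [
        {"compound": c, "variant": name, "scope_size": scans[name][c]}
        for name in ("none", "real", "mock")
        for c in order
    ]
    return pd.DataFrame.from_records(records, columns=["compound", "variant", "scope_size"])


def scan_to_tsv(sizes: Mapping[str, int], path: str, variant: str = "mock") -> None:
    """Write a scan as TSV (compound id, scope size, variant)."""
    df = pd.DataFrame(
        {"compound": list(sizes), "scope_size": list(sizes.values()), "variant": variant}
    )
    df.sort_values(["scope_size", "compound"], ascending=[False, True]).to_csv(
        path, sep="\t", index=False
    )
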