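"""Independent oracles shared by the unit and acceptance suites."""

from __future__ import annotations

import itertools

from metanex.expansion import expand
from metanex.model import Model


def oracle_scope(model: Model, seed: set[str]) -> set[str]:
    """Brute-force reachability: enumerate firing sequences one reaction
    at a time, exploring every order (memoized on the fired set).

    Independent of the sweep-based fixed-point implementation in
    ``metanex.expansion``.
    """
    reachable: set[str] = set(seed)
    seen: set[frozenset[str]] = set()

    def rec(avail: frozenset[str], fired: frozenset[str]) -> None:
        if fired in seen:
            return
        seen.add(fired)
        reachable.update(avail)
        for rid in model.reactions:
            if rid in fired:
                continue
            r = model.reactions[rid]
            if r.substrates and r.substrates <= avail:
                rec(avail | r.products, fired | {rid})

    rec(frozenset(seed), frozenset())
    return reachable


def brute_force_gapfill_minimum(draft: Model, repair: Model, seed, targets) -> int | None:
    """Smallest repair subset restoring reachability, by full enumeration."""
    rids = sorted(repair.reactions)
    for k in range(len(rids) + 1):
        for combo in itertools.combinations(rids, k):
            merged = draft.copy()
            for rid in combo:
                r = repair.reactions[rid].copy()
                for cid in r.stoichiometry:
                    if cid not in merged.compounds:
                        merged.add_compound(repair.compounds[cid].copy())
                merged.add_reaction(r)
            if targets <= expand(merged, seed).scope:
                return k
    return None
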