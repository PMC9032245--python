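"""Synthetic network generation for testing and benchmarking.

Generated networks are balanced by construction: every compound is a
"polymer" of a common CH2O building block (compound i carries m_i
blocks), so a reaction is mass-balanced exactly when its coefficients
conserve the block count — which the generator enforces by assigning
product coefficients that split the substrate block total.  Charges are
zero throughout, making charge balance hold trivially.  This emulates
the *connectivity* structure that expansion, duplication and gap
filling operate on; it does not emulate realistic formula diversity,
protonation chemistry or compartments (see the methods note).

The module also packages a small hand-built glycolysis-shaped network
(real formulas and charges, ATP/ADP and NADH/NAD couples) mirroring the
shape of the E. coli core analysis at toy scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .expansion import Seed
from .gpr import Gpr
from .model import CofactorPair, Compound, Model, Reaction, parse_formula

__all__ = [
    "GapFillInstance",
    "GeneratorSpec",
    "generate_gapfill_instance",
    "generate_network",
    "glycolysis_toy",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the random-network generator.

    ``reversible_fraction`` and ``cofactor_reaction_fraction`` are
    probabilities in [0, 1]; ``guarantee_connected_from`` forces a
    directed reaction chain covering all ordinary compounds so that the
    whole network is reachable from the named compound.
    """

    n_compounds: int = 12
    n_reactions: int = 10
    reversible_fraction: float = 0.3
    cofactor_reaction_fraction: float = 0.2
    n_cofactor_pairs: int = 1
    rng_seed: int = 0
    guarantee_connected_from: str | None = None

    def __post_init__(self) -> None:
        if self.n_compounds <= 0 and self.n_reactions > 0:
            raise ValueError("cannot place reactions in a model without compounds")
        if self.n_compounds < 2 and self.n_reactions > 0:
            raise ValueError("need at least 2 compounds to form a reaction")
        for name in ("reversible_fraction", "cofactor_reaction_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_compounds < 0 or self.n_reactions < 0 or self.n_cofactor_pairs < 0:
            raise ValueError("counts must be non-negative")
        if self.guarantee_connected_from is not None and self.n_reactions < self.n_compounds - 1:
            raise ValueError(
                "connectivity guarantee needs n_reactions >= n_compounds - 1 "
                f"({self.n_reactions} < {self.n_compounds - 1})"
            )


def _block_formula(m: int) -> dict[str, int]:
    return {"C": m, "H": 2 * m, "O": m}


def _split_coefficient(total: int, m_product: int) -> float:
    return float(Fraction(total, m_product))


def generate_network(spec: GeneratorSpec) -> Model:
    """A random balanced network; identical seeds give identical models."""
    rng = np.random.default_rng(spec.rng_seed)
    model = Model(namespace="other")

    blocks: dict[str, int] = {}
    for i in range(spec.n_compounds):
        cid = f"C{i}"
        m = int(rng.integers(1, 20))
        blocks[cid] = m
        model.add_compound(Compound(id=cid, formula=_block_formula(m), charge=0))
    for k in range(spec.n_cofactor_pairs):
        m = int(rng.integers(2, 8))
        donor, acceptor = f"CF{k}D", f"CF{k}A"
        blocks[donor] = m + 1  # donor carries one extra transferable block
        blocks[acceptor] = m
        model.add_compound(Compound(id=donor, formula=_block_formula(m + 1), charge=0))
        model.add_compound(Compound(id=acceptor, formula=_block_formula(m), charge=0))
        model.cofactor_pairs.append(CofactorPair(donor, acceptor))

    ordinary = [f"C{i}" for i in range(spec.n_compounds)]
    genes = [f"g{i}" for i in range(max(4, spec.n_compounds // 2))]
    n_rxn = 0

    def random_gpr() -> Gpr:
        roll = rng.random()
        if roll < 0.5:
            return Gpr.empty()
        picks = sorted(rng.choice(len(genes), size=min(2, len(genes)), replace=False))
        leaves = [Gpr.gene(genes[p]) for p in picks]
        if roll < 0.75 or len(leaves) == 1:
            return Gpr.any_of(leaves)
        return Gpr.all_of(leaves)

    def add_rxn(rid: str, subs: list[str], prods: list[str], reversible: bool) -> None:
        nonlocal n_rxn
        stoich: dict[str, float] = {s: -1.0 for s in subs}
        total = sum(blocks[s] for s in subs)
        if len(prods) == 1:
            stoich[prods[0]] = _split_coefficient(total, blocks[prods[0]])
        else:
            half = Fraction(total, 2)
            stoich[prods[0]] = float(half / blocks[prods[0]])
            stoich[prods[1]] = float((total - half) / blocks[prods[1]])
        model.add_reaction(
            Reaction(id=rid, stoichiometry=stoich, reversible=reversible, gpr=random_gpr())
        )
        n_rxn += 1

    if spec.guarantee_connected_from is not None:
        start = spec.guarantee_connected_from
        if start not in model.compounds:
            raise ValueError(f"unknown start compound {start!r}")
        rest = [c for c in ordinary if c != start]
        order = [start] + [rest[i] for i in rng.permutation(len(rest))]
        for i in range(len(order) - 1):
            add_rxn(f"CH{i}", [order[i]], [order[i + 1]], False)

    while n_rxn < spec.n_reactions:
        rid = f"R{n_rxn}"
        reversible = bool(rng.random() < spec.reversible_fraction)
        if spec.n_cofactor_pairs and rng.random() < spec.cofactor_reaction_fraction:
            k = int(rng.integers(spec.n_cofactor_pairs))
            donor, acceptor = f"CF{k}D", f"CF{k}A"
            x, y = (ordinary[i] for i in rng.choice(len(ordinary), size=2, replace=False))
            # X + donor -> acceptor + Y, block-conserving via Y's coefficient
            stoich = {
                x: -1.0,
                donor: -1.0,
                acceptor: 1.0,
                y: float(Fraction(blocks[x] + blocks[donor] - blocks[acceptor], blocks[y])),
            }
            model.add_reaction(
                Reaction(id=rid, stoichiometry=stoich, reversible=reversible, gpr=random_gpr())
            )
            n_rxn += 1
        else:
            n_sub = int(rng.integers(1, 3))
            n_prod = int(rng.integers(1, 3))
            picks = rng.choice(len(ordinary), size=min(n_sub + n_prod, len(ordinary)), replace=False)
            names = [ordinary[i] for i in picks]
            subs, prods = names[:n_sub], names[n_sub:]
            if not prods:
                continue
            add_rxn(rid, subs, prods, reversible)
    return model


@dataclass
class GapFillInstance:
    """A planted gap-filling problem with its known repair set."""

    draft: Model
    repair: Model
    seed: Seed
    targets: frozenset[str]
    planted_solution: frozenset[str]


def generate_gapfill_instance(
    spec: GeneratorSpec,
    n_removed: int,
    n_decoys: int = 4,
) -> GapFillInstance:
    """Remove reactions from a known production chain into a repair network.

    The generated network contains a directed chain from C0 through all
    ordinary compounds; ``n_removed`` randomly chosen chain reactions are
    moved to the repair network (plus ``n_decoys`` unrelated random
    reactions), the seed is {C0} and the target is the chain's end, so
    the planted removal set is always a feasible repair.
    """
    base_spec = spec
    if spec.guarantee_connected_from is None:
        base_spec = GeneratorSpec(
            n_compounds=spec.n_compounds,
            n_reactions=max(spec.n_reactions, spec.n_compounds - 1),
            reversible_fraction=spec.reversible_fraction,
            cofactor_reaction_fraction=spec.cofactor_reaction_fraction,
            n_cofactor_pairs=spec.n_cofactor_pairs,
            rng_seed=spec.rng_seed,
            guarantee_connected_from="C0",
        )
    full = generate_network(base_spec)
    rng = np.random.default_rng(base_spec.rng_seed + 1)

    chain = sorted(r for r in full.reactions if r.startswith("CH"))
    if n_removed > len(chain):
        raise ValueError(f"cannot remove {n_removed} reactions from a chain of {len(chain)}")
    # the chain's terminal compound: product of the last chain reaction
    last = full.reactions[f"CH{len(chain) - 1}"]
    target = next(iter(last.products))

    removed = sorted(chain[i] for i in rng.choice(len(chain), size=n_removed, replace=False))
    draft = full.copy()
    repair = Model(namespace="other")
    for rid in removed:
        r = full.reactions[rid]
        for cid in r.stoichiometry:
            if cid not in repair.compounds:
                repair.add_compound(full.compounds[cid].copy())
        repair.add_reaction(r.copy())
        draft.remove_reaction(rid)

    decoy_spec = GeneratorSpec(
        n_compounds=base_spec.n_compounds,
        n_reactions=n_decoys,
        reversible_fraction=0.0,
        cofactor_reaction_fraction=0.0,
        n_cofactor_pairs=0,
        rng_seed=base_spec.rng_seed + 2,
    )
    for r in generate_network(decoy_spec).reactions.values():
        rid = f"D_{r.id}"
        if rid in repair.reactions:
            continue
        r = r.copy()
        r.id = rid
        r.reversible = False
        for cid in r.stoichiometry:
            if cid not in repair.compounds:
                repair.add_compound(
                    draft.compounds[cid].copy()
                    if cid in draft.compounds
                    else Compound(id=cid, formula=_block_formula(1), charge=0)
                )
        repair.add_reaction(r)

    return GapFillInstance(
        draft=draft,
        repair=repair,
        seed=Seed(["C0"], include_water=False),
        targets=frozenset([target]),
        planted_solution=frozenset(removed),
    )


def glycolysis_toy() -> Model:
    """A hand-built glycolysis/fermentation network at toy scale.

    19 compounds and 12 reactions with genuine formulas and charges
    (every reaction is mass- and charge-balanced), one ATP/ADP and one
    NADH/NAD cofactor couple, and a reversible triose-phosphate
    isomerase — the canonical example for reversibility duplication.
    BiGG-style cytosolic identifiers are used.
    """
    data = [
        # id, formula, charge, name
        ("glc__D_c", "C6H12O6", 0, "D-glucose"),
        ("g6p_c", "C6H11O9P", -2, "glucose 6-phosphate"),
        ("f6p_c", "C6H11O9P", -2, "fructose 6-phosphate"),
        ("fdp_c", "C6H10O12P2", -4, "fructose 1,6-bisphosphate"),
        ("dhap_c", "C3H5O6P", -2, "dihydroxyacetone phosphate"),
        ("g3p_c", "C3H5O6P", -2, "glyceraldehyde 3-phosphate"),
        ("13dpg_c", "C3H4O10P2", -4, "1,3-bisphosphoglycerate"),
        ("3pg_c", "C3H4O7P", -3, "3-phosphoglycerate"),
        ("pep_c", "C3H2O6P", -3, "phosphoenolpyruvate"),
        ("pyr_c", "C3H3O3", -1, "pyruvate"),
        ("lac__D_c", "C3H5O3", -1, "D-lactate"),
        ("atp_c", "C10H12N5O13P3", -4, "ATP"),
        ("adp_c", "C10H12N5O10P2", -3, "ADP"),
        ("amp_c", "C10H12N5O7P", -2, "AMP"),
        ("nad_c", "C21H26N7O14P2", -1, "NAD+"),
        ("nadh_c", "C21H27N7O14P2", -2, "NADH"),
        ("pi_c", "HO4P", -2, "phosphate"),
        ("h_c", "H", 1, "proton"),
        ("h2o_c", "H2O", 0, "water"),
    ]
    compounds = [
        Compound(id=cid, name=name, formula=parse_formula(f), charge=q, compartment="c")
        for cid, f, q, name in data
    ]
    rxns = [
        ("HEX1", {"glc__D_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1}, False, "b2388"),
        ("PGI", {"g6p_c": -1, "f6p_c": 1}, True, "b4025"),
        ("PFK", {"f6p_c": -1, "atp_c": -1, "fdp_c": 1, "adp_c": 1, "h_c": 1}, False, "b3916 or b1723"),
        ("FBA", {"fdp_c": -1, "dhap_c": 1, "g3p_c": 1}, True, "b2925"),
        ("TPI", {"dhap_c": -1, "g3p_c": 1}, True, "b3919"),
        (
            "GAPD",
            {"g3p_c": -1, "nad_c": -1, "pi_c": -1, "13dpg_c": 1, "nadh_c": 1, "h_c": 1},
            True,
            "b1779",
        ),
        ("PGK", {"13dpg_c": -1, "adp_c": -1, "3pg_c": 1, "atp_c": 1}, True, "b2926"),
        ("ENOC", {"3pg_c": -1, "pep_c": 1, "h2o_c": 1}, True, "b3612 and b2779"),
        ("PYK", {"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1, "atp_c": 1}, False, "b1854 or b1676"),
        ("LDH", {"pyr_c": -1, "nadh_c": -1, "h_c": -1, "lac__D_c": 1, "nad_c": 1}, True, "b2133"),
        ("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1}, False, ""),
        ("ADK1", {"amp_c": -1, "atp_c": -1, "adp_c": 2}, True, "b0474"),
    ]
    reactions = [
        Reaction(id=rid, stoichiometry={k: float(v) for k, v in st.items()}, reversible=rev,
                 gpr=Gpr.parse(gpr))
        for rid, st, rev, gpr in rxns
    ]
    return Model(
        compounds=compounds,
        reactions=reactions,
        cofactor_pairs=[CofactorPair("atp_c", "adp_c"), CofactorPair("nadh_c", "nad_c")],
        namespace="bigg",
    )
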