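# Methods

## The network model

A model is a compound table and a reaction table with referential
integrity enforced on every edit. Each reaction stores one signed
stoichiometry mapping (negative = substrate, positive = product) rather
than separate substrate/product lists: reversal is negation, and the
stoichiometric matrix is a direct export. A consequence is that a
compound appearing on both sides of a reaction is stored by its *net*
coefficient; a perfectly catalytic participant (net zero) is not
representable and is dropped on import. Coefficients may be
non-integer, as in biomass-style reactions.

Directionality is explicit: `reversible` is an annotation, and every
algorithm fires reactions only in the direction they are written.
Reversibility duplication materializes the reverse direction as a
separate irreversible reaction; this keeps the expansion and
gap-filling semantics uniform.

## Balance auditing

Mass balance compares per-element totals; charge balance compares the
signed charge sum. The policy is strict: no automatic proton or water
rebalancing is attempted, and a reaction touching any compound without
a formula (or charge) is classified unbalanced with the reason recorded
— guessing would silently change the chemistry. Element symbols are
validated by pattern (capital + optional lowercase letter), not against
a periodic table, so database pseudo-elements (`R` groups, `X`) parse
and balance like any other element.

Because coefficients may be fractional, totals are accumulated as exact
rationals: each float coefficient is snapped to the nearest rational
with denominator ≤ 10⁶ (`Fraction.limit_denominator`). All
stoichiometries that arise in practice — integers, biomass fractions,
the generator's mass-splitting ratios — are exactly representable this
way, so scaling a reaction by 1/3 cannot produce a spurious imbalance.
The same snap is applied to stoichiometries read from SBML, undoing the
~15-significant-digit truncation of XML double serialization.

## PGDB import

BioCyc attribute-value files are parsed into ordered records
(`ATTR - VALUE` lines, `/` continuations, `^SUBATTR` annotations
attached to the preceding value, `//` separators). Decoding tries
UTF-8 and falls back to Latin-1, since distributed flat files have
historically mixed encodings. Direction mapping:
`LEFT-TO-RIGHT`/`PHYSIOL-`/`IRREVERSIBLE-LEFT-TO-RIGHT` → irreversible
as written; the `RIGHT-TO-LEFT` family → sides swapped, irreversible;
`REVERSIBLE` → reversible; a missing direction defaults conservatively
to irreversible left-to-right. GPRs are assembled as an OR over
catalyzing enzymes, with complexes expanded to an AND over their
components' genes (recursion capped to guard against cyclic COMPONENTS
annotations). Reactions with unresolvable participants (including
compound-class placeholders) or symbolic coefficients are rejected and
itemized, never guessed at; compartments default to a single `c`
compartment — multi-compartment curation is out of scope.

## SBML

Export is L3V1 + fbc v2. Identifiers are sanitized to SBML-legal
symbols with a reversible escape scheme (`M_<id>` when already legal,
otherwise an escaped form that encodes underscores too, so decoding is
unambiguous), and model content with no SBML slot — pathway sets,
provenance tags, database links, mock flags, registered cofactor pairs
— is carried in structured notes. Write→read therefore reproduces the
model exactly, which the suite asserts on arbitrary generated models.
On import of foreign files the namespace is inferred from identifier
shape (BiGG-style lowercase `_c`/`_e` suffixes vs. MetaCyc-style
uppercase ids), which selects the packaged cofactor table and water id.

## Topological transforms

Cofactor duplication triggers on a pair participating on *opposite
sides* of a reaction — the signature of shuttle use. A pair on the same
side is ordinary substrate consumption and is left alone. A reaction
matching several pairs yields a single copy with every matched pair
mocked; overlapping pairs sharing a member (ATP/ADP and ADP/AMP) rename
the shared member once. Mock compounds never carry formulas or charges,
so mock-containing reactions are automatically excluded from
balance-filtered exports. Both transforms commute up to identifier
naming, and both reverts restore byte-identical serialized models; a
mock compound referenced by a user-added reaction survives revert with
a warning rather than breaking integrity.

Suffixes default to the machine-safe `__rev__` / `__cof__` and are
configurable (`DuplicationTag`); duplication refuses to run when a
suffix already occurs in an identifier.

The packaged cofactor tables cover the common currency couples
(NTP/NDP, NAD(P)H/NAD(P), FADH2/FAD, acetyl-CoA/CoA, quinols,
glutathione) spelled per namespace. When taken as a default the table
is filtered to pairs actually present in the model; pairs passed
explicitly must resolve or raise — a silent typo in a user-declared
pair would otherwise simply do nothing.

## Network expansion

Expansion is pure hypergraph reachability: coefficients are ignored,
and a reaction fires when its entire substrate set is available.
Zero-substrate reactions (exchange/source stubs) never fire — they
would make everything trivially producible. The implementation keeps a
per-reaction count of missing substrates and processes generations as
sweeps, so each reaction is examined only when a new substrate arrives;
the trace records, per generation, the newly producible compounds and
newly enabled reactions. The fixed point is order-independent, which
the suite checks by renaming/reordering reactions and against an
independent brute-force oracle that enumerates firing sequences one
reaction at a time.

Seeds are declarative: named compounds, plus water (per-namespace id,
`h2o_c`/`WATER`, configurable), plus a cofactor mode — `none`, `real`
(both real members of every registered pair), `mock_acceptor` (the
discharged member's mock, e.g. `adp_c__cof__`), or `mock_both`.
Auxiliary additions are filtered to compounds present in the model;
explicitly named seed compounds must resolve.

Three scope-counting conventions are exposed, because published
analyses are rarely explicit about one: `producible_non_mock`
(default: compounds gained over the expanded seed, mocks dropped),
`producible_all` (gained compounds including mocks), and `full_set`
(the whole scope). Note that when *comparing seeding variants* the
produced-over-seed counts are not mutually comparable — a real-cofactor
seed hides its own seed compounds from its count — so the variant
ordering law (none ≤ mock ≤ real) is asserted on full scopes with mock
carriers dropped, where it follows from seed monotonicity plus the fact
that every mock-enabled firing has a real-enabled counterpart.

## The frozen core-network scan

`metanex.analysis.core_scope_scan` fixes one configuration for the
single-metabolite scan of the *E. coli* core network: mocked pairs
ATP/ADP, NADH/NAD and acetyl-CoA/CoA — the three shuttle roles
(phosphate, electrons, acetyl) — seed = compound + water + acceptor
mocks after reversibility and cofactor duplication, counting
`producible_all`. Under this frozen convention the scan computes a
largest single-metabolite scope of 47 on the core network, attained by
two external compounds, with fifteen further central-metabolism
compounds at 46. The attainment count is sensitive to the exact pair
table and import details: wider tables (adding NADPH/NADP or
ubiquinol) push succinyl-CoA and TCA intermediates upward and change
both the maximum and the plateau, which is why the configuration is
frozen rather than left to defaults.

## Reconstruction from homology hits

Hit tables are 12-column BLAST tabular output (optional 13th `qcovs`
column). Threshold defaults — e-value ≤ 1e-5, identity ≥ 40%, coverage
≥ 70% — are conventional starting points and always overridable;
comparisons are strict, and the coverage filter applies only when the
`qcovs` column exists (12-column output carries no query length). No
best-hit-per-query reduction and no reciprocal-best-hit requirement is
applied; thresholds are the only filter, deliberately, since stricter
schemes embed policy better left to the user.

A reference reaction enters the draft only if its GPR over enzyme
monomers evaluates true on the hit subjects, so multi-subunit
requirements are enforced rather than approximated by any-subunit
matching. Satisfied GPR branches are rewritten to the query (organism)
gene ids — an OR when several queries hit one monomer — and
unsatisfied alternatives are pruned. Spontaneous (GPR-less) reactions
are excluded by default: homology evidence says nothing about them;
a flag includes them.

## Gap filling

Feasibility of a repair set is defined by expansion: targets must lie
in the scope of draft + chosen reactions from the seed. This
definition makes it structurally impossible for a solution to depend on
a self-producing cycle, since a compound only ever enters the scope
through a reaction whose substrates were already in it. The search
space is pruned to *candidates* — repair reactions whose substrates lie
in the scope of draft + full repair network (monotonicity makes any
other reaction useless). When the candidate set has at most
`exact_limit` (default 12) members, iterative deepening over subset
sizes with lexicographic tie-breaking returns a deterministic
minimum-cardinality solution, optionally enumerating all minima up to a
cap; above the limit, a greedy pass reduces the full candidate set to
an irredundant solution (no proper subset feasible). Every returned
set is verified by replay before being returned. Reversibility
duplication should be applied to both networks first (the CLI does this
automatically); expansion never fires a reaction backwards.

## Synthetic networks

The generator emulates the connectivity structure these algorithms
operate on, not realistic chemistry. Every compound is an `m`-fold
"polymer" of a CH₂O building block; reactions conserve the block count
by construction, with product coefficients chosen as exact
mass-splitting rationals, so 100% of generated reactions pass both
balance checks. Charges are uniformly zero. Cofactor pairs carry one
extra block on the donor. Defaults (12 compounds, 10 reactions, 30%
reversible, 20% cofactor-using, 1 pair) give sparse, partially
reachable networks in which expansion outcomes are non-trivial —
scopes neither collapse to the seed nor cover everything. A
connectivity guarantee threads a directed chain through all ordinary
compounds; planted gap-filling instances break that chain and move the
removed reactions (plus decoys) to the repair network, so a feasible
repair of known size always exists, while the brute-force oracle
decides the true minimum.

What passing these tests shows is that the algorithms are correct on
balanced, single-compartment, zero-charge networks of this size; it
does not show robustness to multi-compartment models, protonation-state
inconsistencies between databases, or generic/polymeric compound
classes, which real databases all contain.

The packaged `glycolysis_toy()` is different in kind: 19 compounds and
12 reactions with genuine formulas and charges (all balanced),
ATP/ADP and NADH/NAD couples, an adenylate-kinase reaction so that
mock-seeded scans can bootstrap mock ATP — a miniature of a
core-metabolism analysis that runs in milliseconds.

## Numerical and determinism choices

- Every serialized collection (matrix rows/columns, SBML elements,
  scan tables, JSON traces) is ordered lexicographically, so identical
  inputs give byte-identical outputs.
- Random generation uses `numpy.random.default_rng` seeded from the
  spec; identical specs give identical models.
- Exact rational comparison (denominator ≤ 10⁶) everywhere balance or
  round-trip exactness matters; floats elsewhere.
- Gap-fill ties break lexicographically by reaction id.

## Known limitations

- No flux-based semantics anywhere: no FBA, no thermodynamic (ΔG)
  checks, no flux-consistency filtering. The stoichiometric matrix and
  SBML exports exist precisely to hand off to constraint-based tools.
- Single-compartment worldview on PGDB import; eukaryotic
  compartmentalization needs manual curation upstream.
- MetaCyc generic reactions (compound classes) are rejected on import
  rather than instantiated.
- The exact gap-fill solver is exponential in the candidate count by
  design; larger instances get the irredundant (not necessarily
  minimum) solution, clearly labelled in the result status.
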