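# metanex

Construction, topological analysis and repair of metabolic network
models, for systems biologists who build genome-scale networks from
databases or sequence homology and want their biosynthetic-capacity
analyses reproducible in plain Python.

`metanex` is a hub around four pieces:

- **Model I/O** — read and write SBML (L2/L3 + fbc) and read
  BioCyc/MetaCyc PGDB attribute-value flat files. On PGDB import only
  reactions that are mass- *and* charge-balanced are kept (anything else
  would violate conservation laws and poison downstream constraint-based
  work); the import report itemizes every rejected reaction.
- **Topological transforms** — *reversibility duplication* (add an
  explicit reversed copy `R__rev__` of every reversible reaction) and
  *cofactor duplication* (for every reaction where a cofactor pair such
  as ATP/ADP sits on opposite sides, add a copy `R__cof__` whose pair
  members are replaced by mock compounds `atp_c__cof__`, …). Both are
  invertible.
- **Network expansion** — the scope of a seed *S* is the fixed point of

  ```
  X₀ = S;   Xₖ₊₁ = Xₖ ∪ { products(r) : r a reaction, substrates(r) ⊆ Xₖ }
  ```

  i.e. all compounds topologically producible from *S*, with reactions
  firing only in their annotated direction. Mock cofactors in the seed
  unblock cofactor-dependent reactions without handing the expansion the
  cofactor's degradation chemistry.
- **Curation** — draft reconstruction from BLAST-style homology hit
  tables with gene–protein–reaction (GPR) enforcement (a reaction enters
  the draft only if its full GPR over reference enzyme monomers is
  satisfied by the hits), and topological gap filling: a
  minimum-cardinality set of repair-network reactions that makes target
  compounds producible from a seed, solved exactly over expansion
  semantics — so solutions can never rely on self-producing cycles.

A synthetic-network generator (balanced by construction, seeded,
deterministic) makes every algorithm testable without downloads.

## Worked example

The packaged toy network (`glycolysis_toy()`: 19 compounds, 12
balanced reactions, ATP/ADP and NADH/NAD couples) mirrors the shape of
a core-metabolism analysis:

```python
from metanex.synthetic import glycolysis_toy
from metanex.expansion import single_metabolite_scan

toy = glycolysis_toy()
sizes = single_metabolite_scan(toy, cofactor_mode="mock_acceptor")
for c, v in sorted(sizes.items(), key=lambda kv: (-kv[1], kv[0]))[:3]:
    print(c, v)
```

prints

```
glc__D_c 13
f6p_c 12
g6p_c 12
```

— from glucose, water and the mock acceptor cofactors, 13 further
compounds are producible (the whole glycolytic/fermentative chain);
hexose phosphates reach one fewer (glucose itself is not recoverable).
The same scan on the *E. coli* core network (72 metabolites, 95
reactions):

```python
from metanex.datasets import load_ecoli_core
from metanex.analysis import core_scope_scan

scan = core_scope_scan(load_ecoli_core())
print(scan.max_scope, scan.n_at_max)   # -> 47 2
```

The largest single-metabolite scope is 47, with a further fifteen
central-metabolism compounds (glycolysis, pentose-phosphate and
TCA intermediates) within one of it. See `docs/methods.md` for the
frozen scan convention behind these numbers.

The command line mirrors the library:

```bash
metanex generate --n-compounds 12 --n-reactions 14 --seed 1 -o net.xml
metanex duplicate rev -m net.xml -o net_rev.xml
metanex scan -m net.xml --mode mock-acceptor -o scopes.tsv
metanex gapfill --draft draft.xml --repair repair.xml \
        --seed-file seeds.txt --targets-file targets.txt --dry-run
```

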