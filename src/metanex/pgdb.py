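"""BioCyc/MetaCyc PGDB flat-file import with balance filtering.

Pathway/genome databases (PGDBs) ship as attribute-value flat files:
``ATTR - VALUE`` lines, ``/`` continuation lines, ``^SUBATTR - VALUE``
lines annotating the immediately preceding value, ``//`` record
separators and ``#`` comments.  The importer builds compounds from
``compounds.dat`` (formula, charge), reactions from ``reactions.dat``
(participants with coefficients, direction) and gene associations from
``enzrxns.dat`` / ``proteins.dat`` / ``genes.dat``.

Constraint-based analysis is only physically meaningful on mass- and
charge-conserving networks, so reactions failing either balance check
are excluded at import time and itemized in the report — at the known
price of possibly omitting annotated gene function.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .gpr import Gpr
from .model import (
    Compound,
    FormulaError,
    Model,
    Reaction,
    check_charge_balance,
    check_mass_balance,
    parse_formula,
)

__all__ = [
    "ImportReport",
    "PgdbEntry",
    "PgdbFormatError",
    "PgdbRecord",
    "build_model_from_pgdb",
    "parse_pgdb_file",
]


class PgdbFormatError(ValueError):
    """Structurally invalid attribute-value file (message carries the line number)."""


@dataclass
class PgdbEntry:
    """One attribute line plus its ``^`` sub-attribute annotations."""

    name: str
    value: str
    annotations: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class PgdbRecord:
    """An ordered attribute multimap for one ``//``-terminated record."""

    entries: list[PgdbEntry] = field(default_factory=list)

    def values(self, name: str) -> list[str]:
        return [e.value for e in self.entries if e.name == name]

    def first(self, name: str) -> str | None:
        vals = self.values(name)
        return vals[0] if vals else None

    def typed(self, name: str) -> list[PgdbEntry]:
        return [e for e in self.entries if e.name == name]


def _read_text_permissive(path: Path) -> str:
    # BioCyc flat files historically mix encodings; fall back to latin-1
    data = path.read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def parse_pgdb_file(path: str | Path) -> list[PgdbRecord]:
    """Parse one attribute-value flat file into ordered records."""
    text = _read_text_permissive(Path(path))
    records: list[PgdbRecord] = []
    current = PgdbRecord()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if line.startswith("//"):
            if current.entries:
                records.append(current)
            current = PgdbRecord()
            continue
        if line.startswith("/"):  # continuation of the previous value
            if not current.entries:
                raise PgdbFormatError(f"line {lineno}: continuation with no preceding value")
            current.entries[-1].value += " " + line[1:].strip()
            continue
        if line.startswith("^"):
            m = re.match(r"\^(\S+)\s+-\s*(.*)$", line)
            if not m or not current.entries:
                raise PgdbFormatError(f"line {lineno}: sub-attribute with no preceding value")
            current.entries[-1].annotations.setdefault(m.group(1), []).append(m.group(2).strip())
            continue
        m = re.match(r"(\S+)\s+-\s*(.*)$", line)
        if not m:
            raise PgdbFormatError(f"line {lineno}: unparsable line {line!r}")
        current.entries.append(PgdbEntry(name=m.group(1), value=m.group(2).strip()))
    if current.entries:
        records.append(current)
    return records


@dataclass
class ImportReport:
    """Bookkeeping of a PGDB import.

    ``n_parsed`` + all rejection counts equals the number of reaction
    records seen; every rejected reaction is listed with its reason.
    """

    n_seen: int = 0
    n_parsed: int = 0
    n_rejected_mass: int = 0
    n_rejected_charge: int = 0
    n_rejected_other: int = 0
    rejected_ids: list[tuple[str, str]] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return (
            self.n_parsed + self.n_rejected_mass + self.n_rejected_charge + self.n_rejected_other
            == self.n_seen
        )


# -- compounds.dat ----------------------------------------------------------

_SEXPR = re.compile(r"\(\s*(\S+)\s+(-?\d+)\s*\)")


def _compound_from_record(rec: PgdbRecord) -> Compound | None:
    cid = rec.first("UNIQUE-ID")
    if cid is None:
        return None
    formula: dict[str, int] | None = None
    # MetaCyc writes one "(ELEMENT count)" s-expression per line; plain
    # sum-formula strings are accepted as well
    pieces = rec.values("CHEMICAL-FORMULA")
    if pieces:
        formula = {}
        for piece in pieces:
            m = _SEXPR.match(piece)
            if m:
                el, n = m.group(1), int(m.group(2))
                el = el.capitalize() if len(el) <= 2 else el
                if n > 0:
                    formula[el] = formula.get(el, 0) + n
            else:
                try:
                    for el, n in parse_formula(piece).items():
                        formula[el] = formula.get(el, 0) + n
                except FormulaError:
                    formula = None
                    break
        if formula is not None and not formula:
            formula = None
    charge: int | None = None
    raw_charge = rec.first("CHARGE")
    if raw_charge is not None:
        try:
            charge = int(raw_charge)
        except ValueError:
            charge = None
    elif rec.values("ATOM-CHARGES"):
        total = 0
        for piece in rec.values("ATOM-CHARGES"):
            m = _SEXPR.match(piece)
            if m:
                total += int(m.group(2))
        charge = total
    links: dict[str, list[str]] = {}
    for entry in rec.typed("DBLINKS"):
        m = re.match(r"\(\s*(\S+)\s+\"([^\"]+)\"", entry.value)
        if m:
            links.setdefault(m.group(1), []).append(m.group(2))
    return Compound(
        id=cid,
        name=rec.first("COMMON-NAME"),
        formula=formula,
        charge=charge,
        compartment=None,
        database_links=links,
    )


# -- GPR assembly from enzrxns/proteins/genes -------------------------------


def _protein_to_gpr(protein_id: str, proteins: dict[str, PgdbRecord], depth: int = 0) -> Gpr:
    """Monomers map to their gene; complexes are ANDs over components."""
    if depth > 10:  # cyclic COMPONENTS annotations exist in the wild
        return Gpr.empty()
    rec = proteins.get(protein_id)
    if rec is None:
        return Gpr.empty()
    components = rec.values("COMPONENTS")
    if components:
        return Gpr.all_of([_protein_to_gpr(c, proteins, depth + 1) for c in components])
    gene = rec.first("GENE")
    return Gpr.gene(gene) if gene else Gpr.empty()


_DIRECTION_MAP = {
    "LEFT-TO-RIGHT": ("forward", False),
    "PHYSIOL-LEFT-TO-RIGHT": ("forward", False),
    "IRREVERSIBLE-LEFT-TO-RIGHT": ("forward", False),
    "RIGHT-TO-LEFT": ("backward", False),
    "PHYSIOL-RIGHT-TO-LEFT": ("backward", False),
    "IRREVERSIBLE-RIGHT-TO-LEFT": ("backward", False),
    "REVERSIBLE": ("forward", True),
}


def build_model_from_pgdb(
    pgdb_dir: str | Path,
    default_direction: str = "forward",
    compartment: str = "c",
) -> tuple[Model, ImportReport]:
    """Build a balance-filtered model from a PGDB directory.

    Requires ``reactions.dat`` and ``compounds.dat``; ``enzrxns.dat``,
    ``proteins.dat`` and ``genes.dat`` are used for GPRs when present.
    Reactions whose participants cannot be resolved, whose coefficients
    are symbolic, or which fail mass or charge balance are excluded and
    itemized in the report.
    """
    pgdb_dir = Path(pgdb_dir)
    for mandatory in ("reactions.dat", "compounds.dat"):
        if not (pgdb_dir / mandatory).exists():
            raise FileNotFoundError(f"PGDB directory {pgdb_dir} lacks {mandatory}")

    compound_recs = parse_pgdb_file(pgdb_dir / "compounds.dat")
    reaction_recs = parse_pgdb_file(pgdb_dir / "reactions.dat")

    model = Model(namespace="metacyc")
    for rec in compound_recs:
        c = _compound_from_record(rec)
        if c is not None and c.id not in model.compounds:
            c.compartment = compartment
            model.add_compound(c)

    # gene associations: reaction -> OR over catalyzing enzymes
    proteins: dict[str, PgdbRecord] = {}
    if (pgdb_dir / "proteins.dat").exists():
        for rec in parse_pgdb_file(pgdb_dir / "proteins.dat"):
            pid = rec.first("UNIQUE-ID")
            if pid:
                proteins[pid] = rec
    rxn_gprs: dict[str, list[Gpr]] = {}
    if (pgdb_dir / "enzrxns.dat").exists():
        for rec in parse_pgdb_file(pgdb_dir / "enzrxns.dat"):
            rxn = rec.first("REACTION")
            enzyme = rec.first("ENZYME")
            if rxn and enzyme:
                g = _protein_to_gpr(enzyme, proteins)
                if not g.is_empty:
                    rxn_gprs.setdefault(rxn, []).append(g)

    report = ImportReport()
    for rec in reaction_recs:
        rid = rec.first("UNIQUE-ID")
        if rid is None:
            continue
        report.n_seen += 1

        def reject(reason: str, bucket: str) -> None:
            setattr(report, bucket, getattr(report, bucket) + 1)
            report.rejected_ids.append((rid, reason))

        stoich: dict[str, float] = {}
        ok = True
        for side, sign in (("LEFT", -1), ("RIGHT", +1)):
            for entry in rec.typed(side):
                cid = entry.value
                if cid not in model.compounds:
                    reject(f"unresolved participant {cid!r}", "n_rejected_other")
                    ok = False
                    break
                coeffs = entry.annotations.get("COEFFICIENT", ["1"])
                try:
                    coeff = float(coeffs[0])
                except ValueError:
                    reject(f"symbolic coefficient {coeffs[0]!r}", "n_rejected_other")
                    ok = False
                    break
                stoich[cid] = stoich.get(cid, 0.0) + sign * coeff
            if not ok:
                break
        if not ok:
            continue
        stoich = {c: v for c, v in stoich.items() if v != 0}
        if not stoich:
            reject("empty stoichiometry", "n_rejected_other")
            continue

        direction, reversible = _DIRECTION_MAP.get(
            rec.first("REACTION-DIRECTION") or "", (default_direction, False)
        )
        if direction == "backward":
            stoich = {c: -v for c, v in stoich.items()}

        reaction = Reaction(
            id=rid,
            stoichiometry=stoich,
            reversible=reversible,
            gpr=Gpr.any_of(rxn_gprs.get(rid, [])),
            pathways=set(rec.values("IN-PATHWAY")),
        )
        mass = check_mass_balance(reaction, model)
        if not mass.balanced:
            reject(mass.reason or f"mass imbalance {mass.imbalance}", "n_rejected_mass")
            continue
        charge = check_charge_balance(reaction, model)
        if not charge.balanced:
            reject(charge.reason or f"charge imbalance {charge.net_charge:+g}", "n_rejected_charge")
            continue
        model.add_reaction(reaction)
        report.n_parsed += 1

    # drop compounds never referenced by a surviving reaction? No — the
    # compound table is the database's; downstream editing may need it.
    return model, report
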