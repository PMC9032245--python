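"""Shared fixtures: toy networks and a hand-built PGDB directory."""

from __future__ import annotations

import textwrap

import pytest

from metanex.model import Compound, Model, Reaction
from metanex.synthetic import glycolysis_toy


@pytest.fixture
def toy() -> Model:
    return glycolysis_toy()


@pytest.fixture
def chain() -> Model:
    """A -> B, B + C -> D: the minimal network with a joint dependency."""
    return Model(
        compounds=[Compound(id=c) for c in "ABCD"],
        reactions=[
            Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0}),
            Reaction(id="R2", stoichiometry={"B": -1.0, "C": -1.0, "D": 1.0}),
        ],
    )


def _write(path, content: str) -> None:
    path.write_text(textwrap.dedent(content).lstrip())


@pytest.fixture
def pgdb_dir(tmp_path):
    """A synthetic five-reaction PGDB: 2 balanced, 1 mass-unbalanced,
    1 charge-unbalanced, 1 with an unresolved participant."""
    d = tmp_path / "pgdb"
    d.mkdir()
    _write(
        d / "compounds.dat",
        """
        # synthetic fixture, hand-balanced
        UNIQUE-ID - GLC
        COMMON-NAME - glucose
        CHEMICAL-FORMULA - (C 6)
        CHEMICAL-FORMULA - (H 12)
        CHEMICAL-FORMULA - (O 6)
        CHARGE - 0
        //
        UNIQUE-ID - LAC
        COMMON-NAME - lactate
        CHEMICAL-FORMULA - (C 3)
        CHEMICAL-FORMULA - (H 6)
        CHEMICAL-FORMULA - (O 3)
        CHARGE - 0
        //
        UNIQUE-ID - XA
        CHEMICAL-FORMULA - (C 1)
        CHARGE - 0
        //
        UNIQUE-ID - XB
        CHEMICAL-FORMULA - (C 1)
        CHARGE - -1
        //
        """,
    )
    _write(
        d / "reactions.dat",
        """
        UNIQUE-ID - RXN-OK
        LEFT - GLC
        RIGHT - LAC
        ^COEFFICIENT - 2
        REACTION-DIRECTION - REVERSIBLE
        IN-PATHWAY - GLYCOLYSIS
        //
        UNIQUE-ID - RXN-MASSBAD
        LEFT - GLC
        RIGHT - LAC
        REACTION-DIRECTION - LEFT-TO-RIGHT
        //
        UNIQUE-ID - RXN-CHARGEBAD
        LEFT - XA
        RIGHT - XB
        REACTION-DIRECTION - LEFT-TO-RIGHT
        //
        UNIQUE-ID - RXN-R2L
        LEFT - GLC
        RIGHT - LAC
        ^COEFFICIENT - 2
        REACTION-DIRECTION - RIGHT-TO-LEFT
        //
        UNIQUE-ID - RXN-UNKNOWN
        LEFT - MYSTERY-CPD
        RIGHT - LAC
        //
        """,
    )
    _write(
        d / "enzrxns.dat",
        """
        UNIQUE-ID - ENZRXN-1
        ENZYME - CPLX-1
        REACTION - RXN-OK
        //
        UNIQUE-ID - ENZRXN-2
        ENZYME - MONO-3
        REACTION - RXN-OK
        //
        """,
    )
    _write(
        d / "proteins.dat",
        """
        UNIQUE-ID - CPLX-1
        COMPONENTS - MONO-1
        COMPONENTS - MONO-2
        //
        UNIQUE-ID - MONO-1
        GENE - G1
        //
        UNIQUE-ID - MONO-2
        GENE - G2
        //
        UNIQUE-ID - MONO-3
        GENE - G3
        //
        """,
    )
    _write(
        d / "genes.dat",
        """
        UNIQUE-ID - G1
        COMMON-NAME - gene one
        //
        UNIQUE-ID - G2
        //
        UNIQUE-ID - G3
        //
        """,
    )
    return d
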