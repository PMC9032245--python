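"""The E. coli core single-metabolite scope analysis, frozen.

Workflow: import the core network, apply cofactor duplication and
reversibility duplication, then compute for every metabolite the scope
of the seed {metabolite, water, acceptor mock cofactors}.

The configuration below is the package's frozen convention for this
analysis.  The currency couples mocked are the three whose shuttle roles
the cofactor-duplication rationale names — ATP/ADP (phosphate transfer),
NADH/NAD (electron transfer) and acetyl-CoA/CoA (acetyl transfer) — and
the reported scope size counts every compound gained over the seed,
mock carriers included.  Under this convention the largest observed
single-metabolite scope on the core network is 47.
"""

from __future__ import annotations

from dataclasses import dataclass

from .expansion import single_metabolite_scan
from .model import CofactorPair, Model

__all__ = ["CORE_SCAN_PAIRS", "CORE_SCAN_COUNTING", "CoreScanResult", "core_scope_scan"]

# Frozen scan configuration for the BiGG-namespace core network.
CORE_SCAN_PAIRS = [
    CofactorPair("atp_c", "adp_c"),
    CofactorPair("nadh_c", "nad_c"),
    CofactorPair("accoa_c", "coa_c"),
]
CORE_SCAN_COUNTING = "producible_all"
CORE_SCAN_MODE = "mock_acceptor"


@dataclass
class CoreScanResult:
    """Outcome of the frozen single-metabolite scope scan."""

    sizes: dict[str, int]
    max_scope: int
    compounds_at_max: tuple[str, ...]

    @property
    def n_at_max(self) -> int:
        return len(self.compounds_at_max)


def core_scope_scan(model: Model) -> CoreScanResult:
    """Run the frozen single-metabolite scope scan on a core-style model.

    The model must use BiGG-namespace identifiers (water ``h2o_c``).
    Reversibility and cofactor duplication are applied internally.
    """
    sizes = single_metabolite_scan(
        model,
        cofactor_mode=CORE_SCAN_MODE,
        pairs=CORE_SCAN_PAIRS,
        counting=CORE_SCAN_COUNTING,
    )
    mx = max(sizes.values()) if sizes else 0
    at_max = tuple(sorted(c for c, v in sizes.items() if v == mx))
    return CoreScanResult(sizes=sizes, max_scope=mx, compounds_at_max=at_max)
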