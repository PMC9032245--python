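"""Minimal plotting: scope size versus compound rank."""

from __future__ import annotations

from typing import Mapping

import pandas as pd

__all__ = ["plot_scope_ranks"]


def plot_scope_ranks(scan: Mapping[str, int] | pd.DataFrame, path: str) -> None:
    """Rank plot of single-metabolite scope sizes.

    Accepts either a compound -> size mapping (one line) or the tidy
    variant table from ``compare_seed_variants`` (one line per variant,
    compounds ordered by the mock variant).  Writes the figure to
    ``path``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    if isinstance(scan, pd.DataFrame):
        order = scan[scan["variant"] == "mock"]["compound"].tolist()
        pos = {c: i for i, c in enumerate(order)}
        for variant, sub in scan.groupby("variant"):
            sub = sub.assign(rank=sub["compound"].map(pos)).sort_values("rank")
            ax.plot(sub["rank"], sub["scope_size"], label=variant, lw=1.2)
        ax.legend(title="seed variant")
    else:
        sizes = sorted(scan.values(), reverse=True)
        ax.plot(range(len(sizes)), sizes, lw=1.5)
    ax.set_xlabel("compound rank")
    ax.set_ylabel("scope size")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
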