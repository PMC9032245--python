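"""Bundled example networks.

The *E. coli* core metabolism model (BiGG id ``e_coli_core``: 72
metabolites, 95 reactions, 137 genes) is the standard compact teaching
network for constraint-based and topological analyses.  COBRApy ships a
copy of this model ("textbook") as package data, so it can be loaded
without any download.
"""

from __future__ import annotations

import gzip
import shutil
import tempfile
from pathlib import Path

from .model import Model
from .sbml import read_sbml

__all__ = ["ecoli_core_sbml_path", "load_ecoli_core"]


def ecoli_core_sbml_path(target_dir: str | None = None) -> Path:
    """Materialize the bundled E. coli core SBML file and return its path.

    The gzipped SBML distributed inside COBRApy is decompressed into
    ``target_dir`` (a temporary directory by default).
    """
    import cobra

    src = Path(cobra.__file__).parent / "data" / "textbook.xml.gz"
    if not src.exists():  # pragma: no cover - depends on cobra layout
        raise FileNotFoundError(f"bundled E. coli core model not found at {src}")
    out_dir = Path(target_dir) if target_dir is not None else Path(tempfile.mkdtemp(prefix="metanex_"))
    out_dir.mkdir(parents=True, exist_ok=True)
    out = out_dir / "e_coli_core.xml"
    if not out.exists():
        with gzip.open(src, "rb") as fin, open(out, "wb") as fout:
            shutil.copyfileobj(fin, fout)
    return out


def load_ecoli_core() -> Model:
    """The E. coli core network as a model (BiGG namespace)."""
    return read_sbml(str(ecoli_core_sbml_path()))
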