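"""Default configuration: kernel parameters, shipped data tables, reference.

The kernel shape (sigma, k), the per-position weight table, the residue
similarity matrix and the anchor dictionary are all configuration, not
constants: every pipeline entry point accepts replacements. The shipped
defaults give a sensible rapid start.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

#: default spatial-kernel scale (1/Angstrom) and exponent
DEFAULT_SIGMA = 0.3
DEFAULT_K_EXPONENT = 2.0

#: weight assigned to positions absent from the weight table (soft threshold)
DEFAULT_BACKGROUND_WEIGHT = 0.1

#: canonical superposition reference: the peptide binding domain of
#: HLA-A*02:01 (PDB id 1i4f). Not shipped; point ``reference_pdb`` at a local
#: copy, or at any trimmed structure to use as the common frame.
DEFAULT_REFERENCE_PDB_ID = "1i4f"


def _data_path(name: str) -> Path:
    return Path(str(resources.files("hlaclust").joinpath("data", name)))


def default_weight_table_path() -> Path:
    """CSV of binding-groove contact positions with weight 1.0."""
    return _data_path("default_weights.csv")


def default_anchor_table_path() -> Path:
    """CSV of anchor alleles with subtype and supertype labels."""
    return _data_path("anchor_alleles.csv")
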