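"""Pharmacophore feature definitions (SMARTS rule set).

Six feature kinds: hydrogen-bond donor (D), acceptor (A), positively
charged (P), negatively charged (N), aromatic ring (R) and hydrophobic
(H). Charged features follow the formal charges of the curated
protonation state; aromatic rings are perceived from ring information
rather than SMARTS. The rule set is an editable mapping so alternative
perception schemes can be loaded from YAML.
"""

from __future__ import annotations

from pathlib import Path

import yaml

#: Default SMARTS per feature kind. Each match contributes one feature at the
#: centroid of its matched heavy atoms; matches of the same kind on the same
#: atom set are merged.
DEFAULT_FEATURE_SMARTS: dict[str, list[str]] = {
    # donors: any N-H or O-H, charged ammonium N-H included
    "D": ["[#7;!H0]", "[#8;H1]"],
    # acceptors: carbonyl/carboxylate O, ether/hydroxyl O, basic or aromatic N
    "A": [
        "[OX1]",
        "[OX2;H1,H0;!$(O=*)]",
        "[NX3;H2,H1,H0;+0;!$(N-C=O);!$(N-a);!$(N=*)]",
        "[nX2;+0]",
        "[NX2;+0]",
    ],
    # positively charged groups (protonated amines, guanidinium, aromatic cations)
    "P": ["[NX4+]", "[NX3+;!$(N=O)]", "[n+]", "[NX2+]"],
    # negatively charged groups located at the group centroid
    "N": [
        "[CX3](=O)[O-]",
        "[PX4](=O)[O-]",
        "[SX4](=O)(=O)[O-]",
        "[O-;!$([O-]C=O);!$([O-]P);!$([O-]S)]",
        "[B-]",
    ],
    # hydrophobic: methyls and CH2 embedded in carbon chains, aromatic halogens
    "H": [
        "[CX4;H3;!$(C[!#6;!#1])]",
        "[CX4;H2;$(C([#6])[#6]);!$(C[!#6;!#1])]",
        "c[Cl,Br,I]",
    ],
    # R (aromatic rings) is perceived from ring info, not SMARTS
}

FEATURE_KINDS = ("H", "A", "D", "R", "P", "N")


def load_feature_smarts(path: str | Path) -> dict[str, list[str]]:
    """Load a custom feature rule set from YAML (kind -> list of SMARTS)."""
    data = yaml.safe_load(Path(path).read_text())
    return {str(k): [str(s) for s in v] for k, v in data.items()}
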