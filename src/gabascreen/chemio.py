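"""Compound I/O, physicochemical properties and conformer embedding.

The chemistry backend is RDKit throughout; every derived quantity (clogP
scheme, donor/acceptor SMARTS, embedding algorithm) is pinned by name and
version in :data:`BACKEND_VERSION` so results are reproducible.

Conventions: hydrogens are implicit in molecular graphs and explicit in
conformers; all distances are in Angstrom; SMILES libraries are one record
per line with an optional tab-separated identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski

from .errors import ConformerError, LibraryError, PropertyError

RDLogger.DisableLog("rdApp.*")

#: Named, versioned backend configuration: clogp is Wildman-Crippen as shipped
#: with RDKit; donors/acceptors are the Lipinski SMARTS definitions.
BACKEND_VERSION = {
    "backend": "rdkit",
    "clogp_scheme": "wildman-crippen",
    "hbd_hba_scheme": "lipinski-smarts",
    "embedding": "ETKDGv3",
}

Role = Literal["agonist", "antagonist", "unknown"]


@dataclass(frozen=True)
class PropertyVector:
    """The six DUD-E matching properties of a compound."""

    mw: float  # Da
    clogp: float
    hbd: int
    hba: int
    rotb: int
    net_charge: int

    def as_tuple(self) -> tuple[float, float, int, int, int, int]:
        return (self.mw, self.clogp, self.hbd, self.hba, self.rotb, self.net_charge)


PROPERTY_NAMES = ("mw", "clogp", "hbd", "hba", "rotb", "net_charge")


@dataclass
class Compound:
    """A molecule with identity, role, optional conformers and cached properties.

    ``mol`` is the implicit-hydrogen molecular graph. ``conformer_mol`` (set by
    :func:`embed_conformers` or an SDF reader) carries explicit hydrogens and
    one RDKit conformer per embedded geometry; heavy-atom indices in
    ``conformer_mol`` coincide with those of ``mol``.
    """

    id: str
    mol: Chem.Mol
    role: Role = "unknown"
    conformer_mol: Chem.Mol | None = None
    _properties: PropertyVector | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_smiles(cls, cid: str, smiles: str, role: Role = "unknown") -> "Compound":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise LibraryError(f"unparseable SMILES for compound {cid!r}: {smiles!r}")
        return cls(id=cid, mol=mol, role=role)

    @property
    def smiles(self) -> str:
        """Canonical isomeric SMILES of the molecular graph."""
        return Chem.MolToSmiles(self.mol)

    @property
    def n_conformers(self) -> int:
        return 0 if self.conformer_mol is None else self.conformer_mol.GetNumConformers()

    def with_role(self, role: Role) -> "Compound":
        return replace(self, role=role)


@dataclass(frozen=True)
class ParseReport:
    """Outcome of reading a library: how many records parsed, which were skipped."""

    n_read: int
    skipped: tuple[tuple[int, str], ...]  # (record index, reason)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def read_library(
    path: str | Path,
    format: Literal["smiles", "sdf"] = "smiles",
    role: Role = "unknown",
) -> tuple[list[Compound], ParseReport]:
    """Read a compound library, skipping (and reporting) unparseable records.

    Screening libraries are dirty; a bad record is logged in the parse
    report rather than aborting the run. An empty result is an error.
    """
    path = Path(path)
    if not path.exists():
        raise LibraryError(f"library file not found: {path}")
    compounds: list[Compound] = []
    skipped: list[tuple[int, str]] = []
    if format == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smi = parts[0]
            cid = parts[1] if len(parts) > 1 else f"{path.stem}-{i}"
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                skipped.append((i, f"unparseable SMILES: {smi!r}"))
                continue
            compounds.append(Compound(id=cid, mol=mol, role=role))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped.append((i, "unparseable SDF record"))
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"{path.stem}-{i}"
            graph = Chem.RemoveHs(mol)
            # rebuild explicit Hs from the heavy-atom skeleton so heavy-atom
            # indices in conformer_mol coincide with the graph's
            conf_mol = Chem.AddHs(graph, addCoords=True) if mol.GetNumConformers() else None
            compounds.append(Compound(id=cid, mol=graph, conformer_mol=conf_mol, role=role))
    else:
        raise LibraryError(f"unknown library format: {format!r}")
    if not compounds:
        raise LibraryError(f"no valid records in {path}")
    return compounds, ParseReport(n_read=len(compounds), skipped=tuple(skipped))


def write_library(compounds: Iterable[Compound], path: str | Path) -> None:
    """Write a SMILES library (canonical SMILES, tab, id; one per line)."""
    lines = [f"{c.smiles}\t{c.id}" for c in compounds]
    Path(path).write_text("\n".join(lines) + "\n")


# -- pH 7.4 protonation -------------------------------------------------------

_PROTONATION_RULES = (
    # (SMARTS of the atom to edit, new formal charge, delta explicit/implicit H)
    # aliphatic amines (not amide/aniline N) -> ammonium
    ("[NX3;H2,H1,H0;+0;!$(N-C=O);!$(N-a);!$(N-[!#6;!#1]);!$(N=*)]", +1, +1),
    # carboxylic acids -> carboxylate
    ("[OX2H1;$(O-C=O)]", -1, -1),
    # phosphinic/phosphonic acids -> anion
    ("[OX2H1;$(O-P=O)]", -1, -1),
    # sulfonic acids -> anion
    ("[OX2H1;$(O-S(=O)=O)]", -1, -1),
)


def assign_ph74_protomer(c: Compound) -> Compound:
    """Assign the canonical protonation state at pH 7.4.

    Rule set: aliphatic amines are protonated; carboxylic, phosphinic,
    phosphonic and sulfonic acids are deprotonated. This covers the
    GABA/baclofen chemotypes (zwitterions with net charge 0); anything
    richer belongs in a custom backend. One canonical protomer is kept
    per compound; no tautomer enumeration is performed.
    """
    mol = Chem.RWMol(c.mol)
    for smarts, charge, dh in _PROTONATION_RULES:
        patt = Chem.MolFromSmarts(smarts)
        for (idx,) in mol.GetSubstructMatches(patt):
            atom = mol.GetAtomWithIdx(idx)
            if atom.GetFormalCharge() != 0:
                continue
            atom.SetFormalCharge(charge)
            atom.SetNumExplicitHs(max(0, atom.GetTotalNumHs() + dh))
            atom.SetNoImplicit(True)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return replace(c, mol=out, conformer_mol=None, _properties=None)


# -- properties ---------------------------------------------------------------

def compute_properties(c: Compound) -> PropertyVector:
    """Compute (and cache) the DUD-E matching properties of a compound.

    Pure function of the molecular graph for a fixed backend version.
    """
    if c._properties is not None:
        return c._properties
    try:
        pv = PropertyVector(
            mw=Descriptors.MolWt(c.mol),
            clogp=Crippen.MolLogP(c.mol),
            hbd=Lipinski.NumHDonors(c.mol),
            hba=Lipinski.NumHAcceptors(c.mol),
            rotb=Lipinski.NumRotatableBonds(c.mol),
            net_charge=Chem.GetFormalCharge(c.mol),
        )
    except Exception as exc:  # pragma: no cover - backend failure path
        raise PropertyError(f"property computation failed for {c.id!r}: {exc}") from exc
    c._properties = pv
    return pv


def n_conformers_for(rotb: int, per_rotb: int, max_conf: int) -> int:
    """Conformer-count rule: ``min(max_conf, max(1, per_rotb * rotb))``."""
    return min(max_conf, max(1, per_rotb * rotb))


def embed_conformers(
    c: Compound, per_rotb: int = 10, max_conf: int = 100, seed: int = 0
) -> Compound:
    """Embed 3D conformers: ``per_rotb`` per rotatable bond, capped at ``max_conf``.

    Defaults follow common pharmacophore-generation practice (10 per
    rotatable bond, at most 100 per compound). Rigid molecules get one
    conformer. Reproducible for a fixed seed.
    """
    if per_rotb < 1 or max_conf < 1:
        raise ConformerError("per_rotb and max_conf must be >= 1")
    rotb = compute_properties(c).rotb
    n = n_conformers_for(rotb, per_rotb, max_conf)
    molh = Chem.AddHs(c.mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    params.pruneRmsThresh = -1.0
    ids = AllChem.EmbedMultipleConfs(molh, numConfs=n, params=params)
    if len(ids) < n:
        params.useRandomCoords = True
        molh = Chem.AddHs(c.mol)
        ids = AllChem.EmbedMultipleConfs(molh, numConfs=n, params=params)
    if len(ids) == 0:
        raise ConformerError(f"conformer embedding failed for compound {c.id!r}")
    return replace(c, conformer_mol=molh)
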