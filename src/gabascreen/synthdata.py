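"""Seeded generators for every input the screening pipeline consumes.

The generators emulate the study system — small GABA/baclofen-like
analogue series (zwitterionizable amino acids, at most one aromatic ring,
MW roughly 100-350 Da) with latent activities — plus property-matched
decoy candidate pools, rigid pocket models for the surrogate energy
backend, and LIA descriptor sets with known generating coefficients.
Every generator is a pure function of its spec, seed included.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chemio import Compound
from .chemio import PropertyVector, compute_properties
from .curation import ActivityRecord
from .errors import GenerationError, ParameterError
from .lia import EnergyDescriptors, PocketModel


# -- analogue series ----------------------------------------------------------

@dataclass
class AnalogueSpec:
    """An analogue series: scaffold with attachment points, substituents, latent SAR.

    ``scaffold`` uses atom-map-labelled dummy atoms ([*:1], [*:2], ...);
    ``substituents[k]`` lists SMILES fragments carrying the matching dummy.
    Latent pIC50 = baseline + sum of per-substituent contributions +
    Normal(0, noise_sd).
    """

    scaffold: str
    substituents: dict[int, list[str]]
    baseline_pic50: float = 5.0
    contributions: dict[int, list[float]] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0
    role: str = "agonist"
    max_analogues: int = 500

    def __post_init__(self):
        if Chem.MolFromSmiles(self.scaffold) is None:
            raise GenerationError(f"invalid scaffold SMILES {self.scaffold!r}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        for site, subs in self.substituents.items():
            if not subs:
                raise ParameterError(f"attachment point {site} has no substituents")


#: GABA/baclofen-like default series: 4-aminobutanoic acid backbone with a
#: variable beta-substituent (baclofen is the 4-chlorophenyl member).
def default_analogue_spec(noise_sd: float = 0.0, seed: int = 0) -> AnalogueSpec:
    return AnalogueSpec(
        scaffold="NCC(C[*:1])CC(=O)O",
        substituents={
            1: [
                "[*:1][H]",
                "[*:1]C",
                "[*:1]c1ccccc1",
                "[*:1]c1ccc(Cl)cc1",
                "[*:1]c1ccc(F)cc1",
                "[*:1]c1ccc(C)cc1",
                "[*:1]O",
                "[*:1]CC",
                "[*:1]c1ccc(CC)cc1",
                "[*:1]c1ccc(Cl)c(Cl)c1",
            ]
        },
        baseline_pic50=4.6,
        contributions={1: [0.0, 0.2, 0.9, 1.6, 1.2, 0.8, 0.4, 0.3, 0.6, 1.8]},
        noise_sd=noise_sd,
        seed=seed,
    )


def _attach(scaffold: str, choices: dict[int, str]) -> Chem.Mol:
    mol = Chem.MolFromSmiles(scaffold)
    for frag_smiles in choices.values():
        frag = Chem.MolFromSmiles(frag_smiles, sanitize=False)
        if frag is None:
            raise GenerationError(f"invalid substituent SMILES {frag_smiles!r}")
        mol = Chem.CombineMols(mol, frag)
    out = Chem.molzip(mol)
    Chem.SanitizeMol(out)
    return Chem.MolFromSmiles(Chem.MolToSmiles(out))


def generate_analogues(spec: AnalogueSpec) -> list[tuple[Compound, ActivityRecord]]:
    """Enumerate the substituent combinations of an analogue series.

    Latent pIC50 values are assigned by the spec's additive model and
    emitted as Ki records (Ki = IC50/2 with IC50 = 10^-pIC50 mol/L), the
    inverse of the curation-side x2 conversion, so curation round-trips
    the latent labels exactly.
    """
    rng = np.random.default_rng(spec.seed)
    sites = sorted(spec.substituents)
    combos = list(itertools.product(*(range(len(spec.substituents[s])) for s in sites)))
    combos = combos[: spec.max_analogues]
    out: list[tuple[Compound, ActivityRecord]] = []
    for i, combo in enumerate(combos):
        choices = {s: spec.substituents[s][ci] for s, ci in zip(sites, combo)}
        mol = _attach(spec.scaffold, choices)
        pic50 = spec.baseline_pic50
        for s, ci in zip(sites, combo):
            contribs = spec.contributions.get(s)
            if contribs is not None:
                pic50 += contribs[ci]
        if spec.noise_sd > 0:
            pic50 += rng.normal(0.0, spec.noise_sd)
        cid = f"ana-{i:03d}"
        ic50_nm = 10.0 ** (-pic50) * 1e9
        record = ActivityRecord(
            compound_id=cid,
            measure="Ki",
            value=ic50_nm / 2.0,
            unit="nM",
            source_note=f"latent pIC50 {pic50:.4f}",
        )
        out.append((Compound(id=cid, mol=mol, role=spec.role), record))  # type: ignore[arg-type]
    return out


# -- decoy candidate pools ----------------------------------------------------

#: Linear assembly grammar for the candidate pool: left cap + chain + right
#: cap. The vocabulary is weighted toward amine/amide/acid-bearing aliphatic
#: chemotypes so the pool spans the property envelope (MW, clogP, HBD, HBA,
#: rotatable bonds, neutral charge) of GABA/baclofen-like actives while
#: differing from them in topology.
_POOL_LEFTS = [
    "OC(=O)", "NC(=O)", "OC(=O)C(O)", "NS(=O)(=O)", "OCC(O)", "NC(=O)N",
    "ON=C", "OC(=O)C(N)",
]
# branches are hydrocarbons/halogens only, so a candidate's HBD/HBA counts are
# fixed by its cap pair and cap compatibility can be pre-screened
_POOL_BRANCHES = [
    "", "(C)", "(F)", "(CC)", "(Cl)", "(C(C)C)",
    "(C1CC1)", "(C1CCC1)", "(CCC)", "(C(C)(C)C)", "(CC(C)C)", "(C(F)(F)F)",
]
_POOL_RIGHTS = [
    "N", "O", "NC(C)=O", "C(N)=O", "c1ccccc1", "c1ccc(O)cc1", "c1ccc(Cl)cc1",
    "c1ccncc1", "NC(N)=O", "S(C)(=O)=O", "C(C)O", "c1ccc(F)cc1", "C(O)CN",
    "N(C)C", "c1ccc(C)cc1", "OC(C)=O", "c1ccc(CC)cc1", "c1ccc(C(C)C)cc1",
    "c1cc(C)cc(C)c1", "C1CCCCC1", "C1CCCC1", "c1ccc(Br)cc1", "C(C)(C)O",
    "NC(CC)=O", "c1ccsc1", "c1cc(F)ccc1F",
]

DEFAULT_POOL_RANGES: dict[str, tuple[float, float]] = {
    "mw": (100.0, 350.0),
    "clogp": (-4.0, 3.5),
    "hbd": (0, 5),
    "hba": (1, 8),
    "rotb": (0, 10),
    "net_charge": (0, 0),
}


#: Per-property acceptance window around a reference compound when the pool
#: is generated against reference actives (DUD-E gathers candidates the same
#: way: per-active, binned by physicochemical similarity). hbd/hba/charge
#: must match exactly; the continuous properties within these half-widths.
STRATIFIED_WINDOWS = {"mw": 30.0, "clogp": 1.2, "rotb": 1.0}

#: Rotor-neutral chain decorations with their approximate mass increments,
#: used to close the gap to a reference MW without moving the rotor count.
_DECOR_INCREMENTS = [("(C)", 14.0), ("(F)", 18.0), ("(Cl)", 34.5), ("(C)(C)", 28.0)]


def _cap_pair_table() -> list[tuple[str, str, PropertyVector]]:
    """Probe properties of every (left, right) cap pair on a one-carbon core.

    Branches carry no N/O, so a candidate's HBD, HBA and net charge are
    decided entirely by its cap pair and can be screened here once.
    """
    table = []
    for left in _POOL_LEFTS:
        for right in _POOL_RIGHTS:
            probe = Chem.MolFromSmiles(left + "C" + right)
            if probe is None:
                continue
            p = compute_properties(Compound(id="probe", mol=probe))
            table.append((left, right, p))
    return table


def generate_candidate_pool(
    n: int,
    property_targets: dict[str, tuple[float, float]] | None = None,
    reference_properties: Sequence[PropertyVector] | None = None,
    seed: int = 0,
    max_attempts_factor: int = 200,
) -> list[Compound]:
    """Rejection-sample ``n`` unique decoy candidates from the fragment grammar.

    Molecules are assembled as functional cap + branched aliphatic chain +
    functional cap, validated with the chemistry backend and deduplicated
    by canonical SMILES. Two modes:

    * ``reference_properties`` given (the usual screening setup): the pool
      is stratified over the references — each candidate is manufactured
      around one reference's property vector (equal HBD/HBA/charge,
      continuous properties within :data:`STRATIFIED_WINDOWS`), cycling
      through the references so the pool spans all of them.
    * otherwise candidates are kept iff every property falls inside
      ``property_targets`` (inclusive ranges; defaults span the
      GABA/baclofen-like envelope).

    Raises :class:`GenerationError` if the constraints are unsatisfiable
    within the attempt budget.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    caps = _cap_pair_table()
    seen: set[str] = set()
    out: list[Compound] = []
    budget = max_attempts_factor * n
    attempts = 0

    if reference_properties is not None:
        refs = list(reference_properties)
        if not refs:
            raise ParameterError("reference_properties is empty")
        strata: list[list[tuple[str, str, PropertyVector]]] = []
        for ref in refs:
            compat = [
                t for t in caps
                if t[2].hbd == ref.hbd and t[2].hba == ref.hba
                and t[2].net_charge == ref.net_charge
                # MW/rotor feasibility: decorations only add mass, chains only
                # add rotors, so the probe must start at or below the target
                and t[2].mw <= ref.mw + STRATIFIED_WINDOWS["mw"]
                and t[2].rotb <= ref.rotb + STRATIFIED_WINDOWS["rotb"]
            ]
            strata.append(compat)
        if all(not s for s in strata):
            raise GenerationError("no cap pair matches any reference's HBD/HBA/charge")

        def accept(props: PropertyVector, ref: PropertyVector) -> bool:
            return (
                abs(props.mw - ref.mw) <= STRATIFIED_WINDOWS["mw"]
                and abs(props.clogp - ref.clogp) <= STRATIFIED_WINDOWS["clogp"]
                and abs(props.rotb - ref.rotb) <= STRATIFIED_WINDOWS["rotb"]
                and props.hbd == ref.hbd
                and props.hba == ref.hba
                and props.net_charge == ref.net_charge
            )

        while len(out) < n:
            if attempts >= budget:
                raise GenerationError(
                    f"could not generate {n} candidates within {budget} attempts "
                    f"({len(out)} produced); reference windows may be unsatisfiable"
                )
            attempts += 1
            # strict per-accepted round-robin keeps the strata balanced even
            # when their acceptance rates differ
            k = len(out) % len(refs)
            ref, compat = refs[k], strata[k]
            if not compat:
                raise GenerationError(
                    f"no feasible cap pair for reference with MW {ref.mw:.0f}"
                )
            left, right, probe = compat[rng.integers(len(compat))]
            # chain length aims at the reference rotor count; one chain
            # carbon adds roughly one rotor
            chain_len = int(np.clip(
                ref.rotb - probe.rotb + int(rng.integers(-1, 2)), 1, 8
            ))
            # close the remaining MW gap with rotor-neutral decorations
            decor: list[str] = [""] * chain_len
            gap = ref.mw - (probe.mw + 14.0 * (chain_len - 1)) + rng.normal(0.0, 8.0)
            slots = list(rng.permutation(chain_len))
            while gap > 10.0 and slots:
                name, inc = _DECOR_INCREMENTS[rng.integers(len(_DECOR_INCREMENTS))]
                if inc > gap + 10.0:
                    continue
                decor[slots.pop()] = name
                gap -= inc
            chain = "".join("C" + d for d in decor)
            mol = Chem.MolFromSmiles(left + chain + right)
            if mol is None:
                continue
            c = Compound(id=f"pool-{len(out):05d}", mol=mol)
            if not accept(compute_properties(c), ref):
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical in seen:
                continue
            seen.add(canonical)
            out.append(c)
        return out

    ranges = dict(DEFAULT_POOL_RANGES)
    if property_targets:
        ranges.update(property_targets)
    while len(out) < n:
        if attempts >= budget:
            raise GenerationError(
                f"could not generate {n} candidates within {budget} attempts "
                f"({len(out)} produced); property ranges may be unsatisfiable"
            )
        attempts += 1
        left, right, _ = caps[rng.integers(len(caps))]
        chain_len = int(rng.integers(1, 6))
        chain = "".join(
            "C" + _POOL_BRANCHES[rng.integers(len(_POOL_BRANCHES))]
            for _ in range(chain_len)
        )
        mol = Chem.MolFromSmiles(left + chain + right)
        if mol is None:
            continue
        c = Compound(id=f"pool-{len(out):05d}", mol=mol)
        props = compute_properties(c)
        if not all(ranges[p][0] <= getattr(props, p) <= ranges[p][1] for p in ranges):
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        out.append(c)
    return out


def property_ranges_of(compounds: Sequence[Compound], pad: float = 0.15) -> dict[str, tuple[float, float]]:
    """The property envelope of a compound set, padded by a relative margin."""
    import numpy as _np

    mat = _np.array([compute_properties(c).as_tuple() for c in compounds])
    names = ("mw", "clogp", "hbd", "hba", "rotb", "net_charge")
    out = {}
    for k, name in enumerate(names):
        lo, hi = mat[:, k].min(), mat[:, k].max()
        span = max(hi - lo, 1.0)
        out[name] = (lo - pad * span, hi + pad * span)
    return out


# -- LIA simulation -----------------------------------------------------------

@dataclass
class LiaSimSpec:
    """Forward model of the LIA equation with known generating coefficients."""

    n: int = 11
    alpha: float = -0.1707
    beta: float = 0.0073
    gamma: float = -0.842
    delta_means: tuple[float, float, float] = (-30.0, -15.0, -3.0)
    delta_sds: tuple[float, float, float] = (8.0, 6.0, 1.5)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 3:
            raise ParameterError("n must be >= 3")
        if self.noise_sd < 0 or any(s < 0 for s in self.delta_sds):
            raise ParameterError("standard deviations must be >= 0")


def simulate_lia(spec: LiaSimSpec) -> list[tuple[EnergyDescriptors, float]]:
    """Draw descriptor deltas and pIC50 values from the forward LIA model.

    Free-state terms are set to zero and bound terms to the drawn deltas,
    so each descriptor's bound-minus-free difference equals the drawn value
    exactly; pIC50 = alpha*dvdw + beta*delec + gamma*dcav + Normal(0, noise_sd).
    """
    rng = np.random.default_rng(spec.seed)
    deltas = rng.normal(spec.delta_means, spec.delta_sds, size=(spec.n, 3))
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n) if spec.noise_sd > 0 else np.zeros(spec.n)
    coefs = np.array([spec.alpha, spec.beta, spec.gamma])
    pic50 = deltas @ coefs + noise
    out = []
    for i in range(spec.n):
        d = EnergyDescriptors(
            compound_id=f"sim-{i:03d}",
            u_b_vdw=float(deltas[i, 0]),
            u_f_vdw=0.0,
            u_b_elec=float(deltas[i, 1]),
            u_f_elec=0.0,
            u_b_cav=float(deltas[i, 2]),
            u_f_cav=0.0,
        )
        out.append((d, float(pic50[i])))
    return out


# -- pocket models ------------------------------------------------------------

def generate_pocket(n_sites: int = 12, radius: float = 6.0, seed: int = 0) -> PocketModel:
    """A rigid synthetic pocket: sites on a sphere shell with random charges.

    Labelled synthetic: a stand-in for a receptor binding site, used to
    exercise the surrogate energy backend deterministically.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_sites, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    sites = v * radius
    charges = rng.uniform(-0.4, 0.4, size=n_sites)
    return PocketModel(
        sites=sites,
        charges=charges,
        epsilons=np.full(n_sites, 0.15),
        sigmas=np.full(n_sites, 3.2),
    )
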