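"""Pharmacophore perception, hypothesis representation and 3D matching.

A pharmacophore hypothesis is an arrangement of 3 to 7 typed features
(donor D, acceptor A, positive P, negative N, aromatic R, hydrophobic H)
with pairwise distances. A conformer matches when at least ``min_match``
of its perceived features can be paired with hypothesis features of the
same kind such that (i) every pairwise inter-feature distance agrees
within the tolerance and (ii) the least-squares rigid superposition
(proper rotations only — mirror images are rejected, stereochemistry
matters for this receptor) of the paired points has RMSD within the same
tolerance.

Matching is solved on the correspondence graph: one node per
kind-compatible (hypothesis feature, molecule feature) pairing, an edge
where the two pairings' distances are mutually consistent; feasible
matchings are cliques. Hypothesis generation enumerates feature subsets
of reference compounds and keeps candidates that match at least a given
fraction of the cluster (50% by default).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from rdkit import Chem

from .chemio import Compound
from .errors import ParameterError, PoseError
from .featuredefs import DEFAULT_FEATURE_SMARTS, FEATURE_KINDS

DEFAULT_TOLERANCE = 2.0  # Angstrom, both per-distance and final RMSD gate
DEFAULT_MIN_INTERSITE = 2.0  # Angstrom


@dataclass(frozen=True)
class Feature:
    """A typed pharmacophore feature at a 3D position (Angstrom)."""

    kind: str
    position: tuple[float, float, float]
    source_atoms: tuple[int, ...]

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ParameterError(f"unknown feature kind {self.kind!r}")
        if not self.source_atoms:
            raise ParameterError("feature must reference at least one source atom")
        if not np.all(np.isfinite(self.position)):
            raise ParameterError("feature position must be finite")


def perceive_features(
    c: Compound,
    conformer_index: int = 0,
    feature_defs: dict[str, list[str]] | None = None,
) -> list[Feature]:
    """Perceive typed features on one conformer of a compound.

    SMARTS matches (on the implicit-H graph) place a feature at the centroid
    of the matched heavy atoms in the conformer's coordinates; aromatic rings
    yield one R feature at the ring centroid; charged kinds reflect the formal
    charges of the stored (curated) protonation state.
    """
    if c.conformer_mol is None or c.conformer_mol.GetNumConformers() == 0:
        raise PoseError(f"compound {c.id!r} has no conformers")
    defs = DEFAULT_FEATURE_SMARTS if feature_defs is None else feature_defs
    conf = c.conformer_mol.GetConformer(conformer_index)
    coords = conf.GetPositions()  # heavy atoms first, indices match c.mol

    features: list[Feature] = []
    seen: set[tuple[str, tuple[int, ...]]] = set()

    def add(kind: str, atoms: tuple[int, ...]):
        key = (kind, tuple(sorted(atoms)))
        if key in seen:
            return
        seen.add(key)
        pos = coords[list(key[1])].mean(axis=0)
        features.append(Feature(kind=kind, position=tuple(map(float, pos)), source_atoms=key[1]))

    for kind, patterns in defs.items():
        for smarts in patterns:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ParameterError(f"malformed feature SMARTS {smarts!r} for kind {kind!r}")
            for match in c.mol.GetSubstructMatches(patt):
                add(kind, match)
    for ring in c.mol.GetRingInfo().AtomRings():
        if all(c.mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            add("R", tuple(ring))
    features.sort(key=lambda f: (f.kind, f.source_atoms))
    return features


@dataclass
class PharmacophoreHypothesis:
    """3-7 typed features with coordinates, a tolerance and a match rule."""

    label: str
    kinds: tuple[str, ...]
    coords: np.ndarray  # (n, 3) Angstrom
    tolerance: float = DEFAULT_TOLERANCE
    min_match: int | None = None  # default: all features must match
    min_intersite: float = DEFAULT_MIN_INTERSITE

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.kinds)
        if self.coords.shape != (n, 3):
            raise ParameterError("coords must be (n_features, 3)")
        if not 3 <= n <= 7:
            raise ParameterError(f"hypothesis must have 3-7 features (got {n})")
        for k in self.kinds:
            if k not in FEATURE_KINDS:
                raise ParameterError(f"unknown feature kind {k!r}")
        if self.min_match is None:
            self.min_match = n
        if not 1 <= self.min_match <= n:
            raise ParameterError("min_match must be in [1, n_features]")
        d = self.distance_matrix
        off = d[~np.eye(n, dtype=bool)]
        if off.size and off.min() < self.min_intersite - 1e-9:
            raise ParameterError(
                f"feature pair closer than min_intersite ({off.min():.2f} < {self.min_intersite}) A"
            )

    @property
    def n_features(self) -> int:
        return len(self.kinds)

    @property
    def distance_matrix(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    @classmethod
    def from_features(
        cls,
        features: Sequence[Feature],
        label: str,
        tolerance: float = DEFAULT_TOLERANCE,
        min_match: int | None = None,
        min_intersite: float = DEFAULT_MIN_INTERSITE,
    ) -> "PharmacophoreHypothesis":
        return cls(
            label=label,
            kinds=tuple(f.kind for f in features),
            coords=np.array([f.position for f in features]),
            tolerance=tolerance,
            min_match=min_match,
            min_intersite=min_intersite,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "features": [
                    {"kind": k, "xyz": [round(v, 6) for v in xyz]}
                    for k, xyz in zip(self.kinds, self.coords.tolist())
                ],
                "tolerance": self.tolerance,
                "min_match": self.min_match,
                "min_intersite": self.min_intersite,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PharmacophoreHypothesis":
        data = json.loads(text)
        return cls(
            label=data["label"],
            kinds=tuple(f["kind"] for f in data["features"]),
            coords=np.array([f["xyz"] for f in data["features"]], dtype=float),
            tolerance=float(data.get("tolerance", DEFAULT_TOLERANCE)),
            min_match=data.get("min_match"),
            min_intersite=float(data.get("min_intersite", DEFAULT_MIN_INTERSITE)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PharmacophoreHypothesis":
        return cls.from_json(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


@dataclass(frozen=True)
class MatchResult:
    matched: bool
    n_matched: int
    rmsd: float | None


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD after optimal proper-rotation superposition of P onto Q.

    Reflections are excluded (determinant-corrected Kabsch), so a mirror
    image of a chiral arrangement does not superpose.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = (pc @ r.T) - qc
    return float(np.sqrt((diff**2).sum() / len(p)))


def _pair_distances(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def match(h: PharmacophoreHypothesis, features: Sequence[Feature]) -> MatchResult:
    """Match perceived features (one conformer) against a hypothesis.

    Builds the correspondence graph, enumerates cliques of size >=
    ``min_match`` and gates each candidate pairing by the Kabsch RMSD of
    the paired feature points. Reports the best accepted pairing by
    (size, then lowest RMSD).
    """
    if not features:
        return MatchResult(False, 0, None)
    mol_pos = np.array([f.position for f in features])
    mol_d = _pair_distances(mol_pos)
    hyp_d = h.distance_matrix
    tol = h.tolerance

    nodes = [
        (i, j)
        for i in range(h.n_features)
        for j, f in enumerate(features)
        if f.kind == h.kinds[i]
    ]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a in range(len(nodes)):
        i1, j1 = nodes[a]
        for b in range(a + 1, len(nodes)):
            i2, j2 = nodes[b]
            if i1 == i2 or j1 == j2:
                continue
            if abs(hyp_d[i1, i2] - mol_d[j1, j2]) <= tol:
                g.add_edge(nodes[a], nodes[b])

    best_size, best_rmsd = 0, None
    tested: set[frozenset] = set()
    for clique in nx.find_cliques(g):
        if len(clique) < h.min_match:
            continue
        # a feasible pairing may be a sub-clique that passes the RMSD gate
        # even when its maximal clique does not; sizes are <= 7, so subset
        # enumeration is cheap
        for size in range(len(clique), h.min_match - 1, -1):
            if size < best_size:
                break
            for sub in itertools.combinations(clique, size):
                key = frozenset(sub)
                if key in tested:
                    continue
                tested.add(key)
                hp = h.coords[[i for i, _ in sub]]
                mp = mol_pos[[j for _, j in sub]]
                r = kabsch_rmsd(hp, mp)
                if r <= tol and (size > best_size or (size == best_size and (best_rmsd is None or r < best_rmsd))):
                    best_size, best_rmsd = size, r
    return MatchResult(best_size >= h.min_match, best_size, best_rmsd)


def match_compound(h: PharmacophoreHypothesis, c: Compound, feature_defs=None) -> bool:
    """True iff any conformer of the compound matches the hypothesis."""
    if c.conformer_mol is None or c.conformer_mol.GetNumConformers() == 0:
        raise PoseError(f"compound {c.id!r} has no conformers")
    for ci in range(c.conformer_mol.GetNumConformers()):
        feats = perceive_features(c, ci, feature_defs)
        if match(h, feats).matched:
            return True
    return False


def _kind_equivalent(a: PharmacophoreHypothesis, b: PharmacophoreHypothesis, tol: float) -> bool:
    """True if some kind-preserving bijection puts all pair distances within tol."""
    if sorted(a.kinds) != sorted(b.kinds):
        return False
    da, db = a.distance_matrix, b.distance_matrix
    n = a.n_features
    slots: list[list[int]] = [
        [j for j in range(n) if b.kinds[j] == a.kinds[i]] for i in range(n)
    ]

    def extend(mapping: list[int]) -> bool:
        i = len(mapping)
        if i == n:
            return True
        for j in slots[i]:
            if j in mapping:
                continue
            if all(abs(da[i, k] - db[j, mapping[k]]) <= tol for k in range(i)):
                if extend(mapping + [j]):
                    return True
        return False

    return extend([])


def generate_hypotheses(
    cluster: Sequence[Compound],
    k_range: tuple[int, int] = (3, 5),
    min_intersite: float = DEFAULT_MIN_INTERSITE,
    coverage: float = 0.5,
    tolerance: float = DEFAULT_TOLERANCE,
    feature_defs: dict[str, list[str]] | None = None,
    conformer_index: int = 0,
) -> list[tuple[PharmacophoreHypothesis, float]]:
    """Enumerate common-pharmacophore candidates from a compound cluster.

    Each cluster member in turn acts as the reference: k-subsets of its
    perceived features (k in ``k_range``, all pairwise distances >=
    ``min_intersite``) become candidate hypotheses requiring all k features
    to match. A candidate is valid iff it matches at least ``coverage`` of
    the cluster (the reference included). Duplicates — same kind multiset
    with a distance matrix agreeing within the tolerance — are collapsed.
    Returns (hypothesis, coverage) sorted by coverage descending, then
    fewer features, then label; an empty list when nothing qualifies.
    """
    kmin, kmax = k_range
    if len(cluster) < 2:
        raise ParameterError("hypothesis generation needs a cluster of >= 2 compounds")
    if not (3 <= kmin <= kmax <= 7):
        raise ParameterError("k_range must satisfy 3 <= min <= max <= 7")

    candidates: list[tuple[PharmacophoreHypothesis, float]] = []
    for ref in cluster:
        feats = perceive_features(ref, conformer_index, feature_defs)
        idx = 0
        for k in range(kmin, min(kmax, len(feats)) + 1):
            for subset in itertools.combinations(feats, k):
                pos = np.array([f.position for f in subset])
                d = _pair_distances(pos)
                off = d[~np.eye(k, dtype=bool)]
                if off.min() < min_intersite:
                    continue
                label = f"{ref.id}|{''.join(sorted(f.kind for f in subset))}|{idx}"
                idx += 1
                try:
                    hyp = PharmacophoreHypothesis.from_features(
                        subset, label=label, tolerance=tolerance,
                        min_intersite=min_intersite,
                    )
                except ParameterError:
                    continue
                n_hit = sum(
                    1 for m in cluster if match_compound(hyp, m, feature_defs)
                )
                cov = n_hit / len(cluster)
                if cov >= coverage:
                    candidates.append((hyp, cov))

    candidates.sort(key=lambda t: (-t[1], t[0].n_features, t[0].label))
    kept: list[tuple[PharmacophoreHypothesis, float]] = []
    for hyp, cov in candidates:
        if any(_kind_equivalent(hyp, k, tolerance) for k, _ in kept):
            continue
        kept.append((hyp, cov))
    return kept
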