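"""Atom-environment fingerprints, Tanimoto clustering and modal fingerprints.

Fingerprints are sets of hashed radius-2 circular atom environments
(RDKit Morgan identifiers), a functional equivalent of MOLPRINT-2D:
both describe each atom by its neighbourhood shells. Hierarchical
clustering runs on the 1 - Tanimoto distance matrix; clusters smaller
than ``min_size`` (singletons and doubletons by default) are merged
into a single outlier cluster. A modal fingerprint is the consensus
bit set of a cluster: every environment present in at least a given
fraction of members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit.Chem import rdFingerprintGenerator
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .chemio import Compound
from .errors import ParameterError, UndefinedStatisticError

#: Pinned fingerprint configuration (backend + radius), for reproducibility.
FINGERPRINT_CONFIG = {"backend": "rdkit-morgan-sparse", "radius": 2}

_GENERATOR = rdFingerprintGenerator.GetMorganGenerator(radius=2)


@dataclass(frozen=True)
class Fingerprint:
    """A set of hashed atom-environment identifiers for one compound."""

    bits: frozenset[int]
    compound_id: str


def fingerprint(c: Compound) -> Fingerprint:
    """Radius-2 hashed atom-environment fingerprint of a compound."""
    sparse = _GENERATOR.GetSparseCountFingerprint(c.mol)
    return Fingerprint(bits=frozenset(sparse.GetNonzeroElements()), compound_id=c.id)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a n b| / |a u b| in [0, 1]."""
    if not a.bits and not b.bits:
        raise UndefinedStatisticError("Tanimoto undefined for two empty fingerprints")
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


@dataclass
class Clustering:
    """A partition of compounds into clusters, with an optional outlier cluster."""

    clusters: list[list[str]]
    outlier_cluster_index: int | None
    linkage: str
    n_requested: int

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, int]:
        return {cid: i for i, members in enumerate(self.clusters) for cid in members}


def cluster(
    fps: Sequence[Fingerprint],
    n_clusters: int,
    min_size: int = 3,
    linkage: str = "average",
) -> Clustering:
    """Agglomerative Tanimoto clustering with singleton/doubleton merging.

    The 1 - Tanimoto distance matrix is cut into ``n_clusters`` groups
    (``linkage`` in {average, single, complete}; average is the default as
    the stable choice on small sets). Every group smaller than ``min_size``
    is then merged into one outlier cluster. Deterministic: members and
    clusters are ordered lexicographically by compound id.
    """
    if n_clusters < 1 or min_size < 1:
        raise ParameterError("n_clusters and min_size must be >= 1")
    if n_clusters > len(fps):
        raise ParameterError(
            f"n_clusters={n_clusters} exceeds number of compounds ({len(fps)})"
        )
    if linkage not in ("average", "single", "complete"):
        raise ParameterError(f"unsupported linkage {linkage!r}")
    order = sorted(range(len(fps)), key=lambda i: fps[i].compound_id)
    fps_sorted = [fps[i] for i in order]
    n = len(fps_sorted)
    if n == 1:
        labels = np.array([1])
    else:
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dist[i, j] = dist[j, i] = 1.0 - tanimoto(fps_sorted[i], fps_sorted[j])
        Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for fp, lab in zip(fps_sorted, labels):
        groups.setdefault(int(lab), []).append(fp.compound_id)
    kept = sorted(
        (sorted(m) for m in groups.values() if len(m) >= min_size), key=lambda m: m[0]
    )
    outliers = sorted(
        cid for m in groups.values() if len(m) < min_size for cid in m
    )
    clusters = list(kept)
    outlier_index: int | None = None
    if outliers:
        outlier_index = len(clusters)
        clusters.append(outliers)
    return Clustering(
        clusters=clusters,
        outlier_cluster_index=outlier_index,
        linkage=linkage,
        n_requested=n_clusters,
    )


def modal_fingerprint(
    cluster_fps: Sequence[Fingerprint], freq_threshold: float = 0.5, label: str = "modal"
) -> Fingerprint:
    """Consensus fingerprint: bits present in >= ``freq_threshold`` of members."""
    if not cluster_fps:
        raise ParameterError("modal fingerprint of an empty cluster is undefined")
    if not (0.0 < freq_threshold <= 1.0):
        raise ParameterError("freq_threshold must be in (0, 1]")
    n = len(cluster_fps)
    counts: dict[int, int] = {}
    for fp in cluster_fps:
        for b in fp.bits:
            counts[b] = counts.get(b, 0) + 1
    bits = frozenset(b for b, k in counts.items() if k / n >= freq_threshold)
    return Fingerprint(bits=bits, compound_id=label)


def rank_by_modal(
    modal: Fingerprint, library: Sequence[Fingerprint]
) -> list[tuple[str, float]]:
    """Rank a library by Tanimoto similarity to a modal fingerprint.

    Descending similarity, ties broken by compound id; the full ranking is
    emitted so downstream enrichment statistics can be computed.
    """
    if not modal.bits:
        raise ParameterError("modal fingerprint is empty")
    scored = [(fp.compound_id, tanimoto(modal, fp)) for fp in library]
    return sorted(scored, key=lambda t: (-t[1], t[0]))
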