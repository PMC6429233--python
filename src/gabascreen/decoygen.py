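"""Property-matched, topology-dissimilar decoy selection (DUD-E style).

Decoys are presumed non-binders drawn from a candidate pool so that they
resemble the actives in six physicochemical properties (MW, clogP, HBD,
HBA, rotatable bonds, net charge) while being topologically dissimilar to
every active (maximum fingerprint Tanimoto below a cut-off). Matching is
done in z-scored property space (z-scores over the pool), candidate
ranking by Euclidean distance to the active, greedy per-active assignment
in input order without reuse. Shortages raise rather than silently relax
the constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chemio import PROPERTY_NAMES, Compound, compute_properties
from .errors import DecoyShortageError, ParameterError
from .simprint import Fingerprint, fingerprint, tanimoto


@dataclass
class DecoySet:
    """Per-active decoy assignments plus the parameters that produced them."""

    assignments: dict[str, list[Compound]]
    parameters: dict = field(default_factory=dict)
    max_tanimoto: dict[str, float] = field(default_factory=dict)  # decoy id -> max Tc to actives
    property_deltas: dict[str, np.ndarray] = field(default_factory=dict)  # decoy id -> 6-vector

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.assignments.values())

    def all_decoys(self) -> list[Compound]:
        return [d for ds in self.assignments.values() for d in ds]


def _property_matrix(compounds: Sequence[Compound]) -> np.ndarray:
    return np.array([compute_properties(c).as_tuple() for c in compounds], dtype=float)


def generate_decoys(
    actives: Sequence[Compound],
    pool: Sequence[Compound],
    n_per_active: int = 50,
    tc_cutoff: float = 0.25,
    property_z_window: float = 0.5,
) -> DecoySet:
    """Select ``n_per_active`` property-matched decoys per active from ``pool``.

    A pool candidate is eligible for an active iff (i) its z-scored distance
    to the active is within ``property_z_window`` on each of the six matching
    properties (z-scores over the pool), and (ii) its Tanimoto similarity to
    EVERY active is strictly below ``tc_cutoff``. Eligible candidates are
    ranked by Euclidean distance in z-space; the closest unassigned ones are
    taken, actives processed in input order. Any shortfall raises
    :class:`DecoyShortageError` naming the active.
    """
    if n_per_active < 1:
        raise ParameterError("n_per_active must be >= 1")
    if not actives:
        raise ParameterError("no actives given")
    pool_props = _property_matrix(pool)
    active_props = _property_matrix(actives)
    mean = pool_props.mean(axis=0)
    std = pool_props.std(axis=0)
    std[std == 0.0] = 1.0  # constant property: raw differences count directly
    pool_z = (pool_props - mean) / std
    active_z = (active_props - mean) / std

    active_fps = [fingerprint(a) for a in actives]
    pool_fps = [fingerprint(c) for c in pool]
    max_tc = np.array(
        [max(tanimoto(fp, afp) for afp in active_fps) for fp in pool_fps]
    )
    dissimilar = max_tc < tc_cutoff

    assigned: set[int] = set()
    assignments: dict[str, list[Compound]] = {}
    max_tanimoto: dict[str, float] = {}
    property_deltas: dict[str, np.ndarray] = {}
    for ai, active in enumerate(actives):
        dz = np.abs(pool_z - active_z[ai])
        eligible = np.where(dissimilar & (dz <= property_z_window).all(axis=1))[0]
        eligible = [i for i in eligible if i not in assigned]
        if len(eligible) < n_per_active:
            raise DecoyShortageError(active.id, n_per_active - len(eligible))
        dist = np.linalg.norm(pool_z[eligible] - active_z[ai], axis=1)
        ranked = sorted(zip(eligible, dist), key=lambda t: (t[1], pool[t[0]].id))
        chosen = [i for i, _ in ranked[:n_per_active]]
        assigned.update(chosen)
        assignments[active.id] = [pool[i] for i in chosen]
        for i in chosen:
            max_tanimoto[pool[i].id] = float(max_tc[i])
            property_deltas[pool[i].id] = pool_props[i] - active_props[ai]
    return DecoySet(
        assignments=assignments,
        parameters={
            "n_per_active": n_per_active,
            "tc_cutoff": tc_cutoff,
            "property_z_window": property_z_window,
        },
        max_tanimoto=max_tanimoto,
        property_deltas=property_deltas,
    )


def decoy_report(ds: DecoySet) -> pd.DataFrame:
    """Per-decoy report: assigned active, property deltas, max Tanimoto to actives."""
    rows = []
    for active_id in ds.assignments:
        for d in ds.assignments[active_id]:
            delta = ds.property_deltas.get(d.id, np.full(6, np.nan))
            rows.append(
                {
                    "decoy_id": d.id,
                    "active_id": active_id,
                    **{f"delta_{p}": delta[k] for k, p in enumerate(PROPERTY_NAMES)},
                    "max_tanimoto_to_actives": ds.max_tanimoto.get(d.id, np.nan),
                }
            )
    columns = (
        ["decoy_id", "active_id"]
        + [f"delta_{p}" for p in PROPERTY_NAMES]
        + ["max_tanimoto_to_actives"]
    )
    return pd.DataFrame(rows, columns=columns)
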