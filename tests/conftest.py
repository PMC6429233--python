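"""Shared fixtures: embedded compounds and synthetic datasets.

Everything is generated programmatically with fixed seeds; session scope
keeps expensive conformer embedding shared across tests.
"""

import pytest
from hypothesis import settings

import gabascreen as g
from gabascreen import synthdata as sd

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def gaba_zwitterion():
    """Zwitterionic GABA with a handful of conformers."""
    c = g.Compound.from_smiles("gaba", "NCCCC(=O)O")
    z = g.assign_ph74_protomer(c)
    return g.embed_conformers(z, per_rotb=2, max_conf=6, seed=11)


@pytest.fixture(scope="session")
def analogue_pairs():
    """The default GABA/baclofen-like analogue series with latent activities."""
    return sd.generate_analogues(sd.default_analogue_spec())


@pytest.fixture(scope="session")
def aryl_cluster_neutral(analogue_pairs):
    """The structurally homogeneous aryl sub-series as neutral 2D graphs.

    Decoy matching runs on the neutral forms (decoy generation precedes
    protonation-state assignment in the screening workflow)."""
    by_id = {c.id: c for c, _ in analogue_pairs}
    fps = [g.fingerprint(c) for c in by_id.values()]
    clu = g.cluster(fps, n_clusters=4, min_size=3)
    return [by_id[cid] for cid in clu.clusters[0]]


@pytest.fixture(scope="session")
def aryl_cluster(aryl_cluster_neutral):
    """The aryl sub-series at pH 7.4 protonation, embedded (1 conformer each)."""
    return [
        g.embed_conformers(g.assign_ph74_protomer(c), per_rotb=1, max_conf=1, seed=5)
        for c in aryl_cluster_neutral
    ]


@pytest.fixture(scope="session")
def small_pool(aryl_cluster_neutral):
    """A small property-matched candidate pool around the aryl analogues."""
    refs = [g.compute_properties(c) for c in aryl_cluster_neutral]
    return sd.generate_candidate_pool(1000, reference_properties=refs, seed=23)
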