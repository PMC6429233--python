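"""Feature perception and 3D pharmacophore matching.

The clique-based matcher is checked against an independent brute-force
oracle that enumerates every injective kind-compatible partial assignment.
"""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import gabascreen as g
from gabascreen.errors import ParameterError, PoseError
from gabascreen.pharmacophore import Feature, PharmacophoreHypothesis, kabsch_rmsd


def brute_force_match(h, features):
    """Oracle: enumerate all injective assignments of >= min_match hypothesis
    features to kind-compatible molecule features; accept iff all pairwise
    distances agree within tolerance AND the Kabsch RMSD passes."""
    if not features:
        return False
    mol_pos = np.array([f.position for f in features])
    hyp_d = h.distance_matrix
    n, m = h.n_features, len(features)
    for k in range(min(n, m), h.min_match - 1, -1):
        for hyp_subset in itertools.combinations(range(n), k):
            for mol_perm in itertools.permutations(range(m), k):
                if any(h.kinds[i] != features[j].kind for i, j in zip(hyp_subset, mol_perm)):
                    continue
                ok = True
                for a in range(k):
                    for b in range(a + 1, k):
                        i1, i2 = hyp_subset[a], hyp_subset[b]
                        j1, j2 = mol_perm[a], mol_perm[b]
                        dm = np.linalg.norm(mol_pos[j1] - mol_pos[j2])
                        if abs(hyp_d[i1, i2] - dm) > h.tolerance:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    continue
                r = kabsch_rmsd(h.coords[list(hyp_subset)], mol_pos[list(mol_perm)])
                if r <= h.tolerance:
                    return True
    return False


def random_features(rng, n, kinds="ADPNRH", box=8.0):
    return [
        Feature(
            kind=kinds[rng.integers(len(kinds))],
            position=tuple(rng.uniform(-box, box, 3)),
            source_atoms=(i,),
        )
        for i in range(n)
    ]


def random_hypothesis(rng, k, min_match=None):
    while True:
        feats = random_features(rng, k)
        try:
            return PharmacophoreHypothesis.from_features(
                feats, label="rand", min_match=min_match, min_intersite=2.0
            )
        except ParameterError:
            continue


def rigid_transform(rng, feats):
    r = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return [
        Feature(f.kind, tuple(r @ np.array(f.position) + t), f.source_atoms)
        for f in feats
    ]


class TestPerceiveFeatures:
    def test_benzene_single_aromatic_feature(self):
        c = g.embed_conformers(g.Compound.from_smiles("bz", "c1ccccc1"), seed=1)
        feats = g.perceive_features(c)
        rs = [f for f in feats if f.kind == "R"]
        assert len(rs) == 1
        centroid = c.conformer_mol.GetConformer(0).GetPositions()[:6].mean(axis=0)
        assert np.allclose(rs[0].position, centroid, atol=1e-6)

    def test_methane_has_no_features(self):
        c = g.embed_conformers(g.Compound.from_smiles("met", "C"), seed=1)
        assert g.perceive_features(c) == []

    def test_zwitterionic_gaba_charged_features(self, gaba_zwitterion):
        feats = g.perceive_features(gaba_zwitterion)
        kinds = {f.kind for f in feats}
        assert {"P", "N", "D", "A"} <= kinds
        n_feats = [f for f in feats if f.kind == "N"]
        assert len(n_feats) == 1 and len(n_feats[0].source_atoms) == 3  # carboxylate group

    def test_no_conformer_errors(self):
        with pytest.raises(PoseError):
            g.perceive_features(g.Compound.from_smiles("x", "CCO"))


class TestMatch:
    def test_identity_match_zero_rmsd(self, gaba_zwitterion):
        feats = g.perceive_features(gaba_zwitterion)
        sel = [feats[0], feats[2], feats[3], feats[5]]
        h = PharmacophoreHypothesis.from_features(sel, label="id", min_intersite=1.0)
        res = g.match(h, feats)
        assert res.matched and res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_invariance(self, gaba_zwitterion):
        rng = np.random.default_rng(4)
        feats = g.perceive_features(gaba_zwitterion)
        sel = [feats[0], feats[2], feats[3], feats[5]]
        h = PharmacophoreHypothesis.from_features(sel, label="id", min_intersite=1.0)
        for _ in range(5):
            res = g.match(h, rigid_transform(rng, feats))
            assert res.matched and res.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_displaced_feature_breaks_required_match(self):
        # square of four distinct kinds; unique kinds force the identity
        # assignment, so breaking one pairwise distance must break the match
        coords = np.array([[0, 0, 0], [4, 0, 0], [4, 4, 0], [0, 4, 0.0]])
        h = PharmacophoreHypothesis(label="sq", kinds=("A", "D", "P", "N"), coords=coords)
        feats = [Feature(k, tuple(c), (i,)) for i, (k, c) in enumerate(zip(h.kinds, coords))]
        assert g.match(h, feats).matched
        moved = np.array(feats[0].position) + np.array([5.0, 0, 0])
        broken = [Feature("A", tuple(moved), (0,))] + feats[1:]
        assert not g.match(h, broken).matched

    def test_no_features_unmatched(self, gaba_zwitterion):
        feats = g.perceive_features(gaba_zwitterion)
        h = PharmacophoreHypothesis.from_features(
            [feats[0], feats[2], feats[5]], label="x", min_intersite=1.0
        )
        assert g.match(h, []) == g.MatchResult(False, 0, None)

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(20)
        agree = 0
        for _ in range(120):
            k = int(rng.integers(3, 6))
            h = random_hypothesis(rng, k, min_match=int(rng.integers(3, k + 1)))
            if rng.random() < 0.5:
                feats = random_features(rng, int(rng.integers(0, 11)))
            else:
                # plant a perturbed, rigidly moved copy among distractors
                planted = [
                    Feature(kk, tuple(np.array(c) + rng.uniform(-0.3, 0.3, 3)), (i,))
                    for i, (kk, c) in enumerate(zip(h.kinds, h.coords))
                ]
                feats = rigid_transform(rng, planted) + random_features(
                    rng, int(rng.integers(0, 6))
                )
                feats = [
                    Feature(f.kind, f.position, (i,)) for i, f in enumerate(feats)
                ]
            got = g.match(h, feats).matched
            want = brute_force_match(h, feats)
            assert got == want
            agree += got
        assert 0 < agree < 120  # both outcomes exercised


class TestMatchCompound:
    def test_equals_or_over_conformers(self, gaba_zwitterion):
        feats0 = g.perceive_features(gaba_zwitterion, 0)
        sel = [feats0[0], feats0[2], feats0[3], feats0[5]]
        h = PharmacophoreHypothesis.from_features(sel, label="c0", min_intersite=1.0)
        per_conf = [
            g.match(h, g.perceive_features(gaba_zwitterion, ci)).matched
            for ci in range(gaba_zwitterion.n_conformers)
        ]
        assert g.match_compound(h, gaba_zwitterion) == any(per_conf)
        assert per_conf[0] is True

    def test_no_conformers_errors(self):
        h = PharmacophoreHypothesis(
            label="x", kinds=("A", "D", "N"),
            coords=np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0.0]]),
        )
        with pytest.raises(PoseError):
            g.match_compound(h, g.Compound.from_smiles("x", "CCO"))


class TestHypothesisObject:
    def test_json_roundtrip(self):
        h = PharmacophoreHypothesis(
            label="ext", kinds=("P", "N", "R"),
            coords=np.array([[0, 0, 0], [5, 0, 0], [2.5, 4, 0.0]]),
            tolerance=1.5, min_match=2, min_intersite=2.0,
        )
        back = PharmacophoreHypothesis.from_json(h.to_json())
        assert back.kinds == h.kinds
        assert np.allclose(back.coords, h.coords)
        assert (back.tolerance, back.min_match) == (1.5, 2)

    def test_invariants_enforced(self):
        with pytest.raises(ParameterError):
            PharmacophoreHypothesis(
                label="too-close", kinds=("A", "D", "N"),
                coords=np.array([[0, 0, 0], [0.5, 0, 0], [0, 4, 0.0]]),
            )
        with pytest.raises(ParameterError):
            PharmacophoreHypothesis(
                label="too-few", kinds=("A", "D"),
                coords=np.array([[0, 0, 0], [4, 0, 0.0]]),
            )


class TestGenerateHypotheses:
    def test_identical_copies_full_coverage(self, aryl_cluster):
        twins = [aryl_cluster[0], aryl_cluster[0]]
        ranked = g.generate_hypotheses(twins, k_range=(3, 3), min_intersite=1.5)
        assert ranked
        assert all(cov == 1.0 for _, cov in ranked)

    def test_output_satisfies_own_invariants(self, aryl_cluster):
        ranked = g.generate_hypotheses(aryl_cluster[:3], k_range=(3, 3), min_intersite=1.5)
        for h, cov in ranked:
            d = h.distance_matrix
            assert np.allclose(d, d.T)
            off = d[~np.eye(h.n_features, dtype=bool)]
            assert off.min() >= h.min_intersite - 1e-9
            assert cov >= 0.5

    def test_coverage_filter_rejects_minority_candidates(self, aryl_cluster):
        high = g.generate_hypotheses(aryl_cluster[:3], k_range=(3, 3), min_intersite=1.5,
                                     coverage=1.0)
        low = g.generate_hypotheses(aryl_cluster[:3], k_range=(3, 3), min_intersite=1.5,
                                    coverage=0.5)
        assert len(high) <= len(low)
        assert all(cov >= 1.0 for _, cov in high)

    def test_duplicates_collapsed(self, aryl_cluster):
        twins = [aryl_cluster[0], aryl_cluster[0]]
        ranked = g.generate_hypotheses(twins, k_range=(3, 3), min_intersite=1.5)
        # both references are the same compound: every candidate appears twice
        # before dedup, so each surviving (kinds, distance-matrix) class is unique
        from gabascreen.pharmacophore import _kind_equivalent
        for i, (hi, _) in enumerate(ranked):
            for hj, _ in ranked[i + 1:]:
                assert not _kind_equivalent(hi, hj, hi.tolerance)
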