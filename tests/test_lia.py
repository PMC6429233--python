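"""LIA regression: coefficient recovery, statistics, surrogate backend."""

import numpy as np
import pytest

import gabascreen as g
from gabascreen import synthdata as sd
from gabascreen.errors import FitSizeError, ParameterError, PoseError, SingularFitError
from gabascreen.lia import EnergyDescriptors, LinearInteractionModel

GEN = dict(alpha=-0.1707, beta=0.0073, gamma=-0.842)


def descriptors_from_deltas(deltas):
    return [
        EnergyDescriptors(f"d{i}", d[0], 0.0, d[1], 0.0, d[2], 0.0)
        for i, d in enumerate(deltas)
    ]


class TestFit:
    def test_zero_noise_exact_recovery(self):
        data = sd.simulate_lia(sd.LiaSimSpec(n=11, noise_sd=0.0, seed=5, **GEN))
        res = g.fit_lia(data)
        assert res.alpha == pytest.approx(GEN["alpha"], abs=1e-8)
        assert res.beta == pytest.approx(GEN["beta"], abs=1e-8)
        assert res.gamma == pytest.approx(GEN["gamma"], abs=1e-8)
        assert res.stats.r2 == pytest.approx(1.0, abs=1e-10)
        assert res.stats.sd == pytest.approx(0.0, abs=1e-8)

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        data = sd.simulate_lia(sd.LiaSimSpec(n=15, noise_sd=0.4, seed=8, **GEN))
        res = g.fit_lia(data)
        x = np.array([d.deltas for d, _ in data])
        y = np.array([p for _, p in data])
        ref = sm.OLS(y, x).fit()
        assert [res.alpha, res.beta, res.gamma] == pytest.approx(list(ref.params), abs=1e-10)
        assert res.stats.p == pytest.approx(ref.f_pvalue, rel=1e-8)
        assert res.stats.sd == pytest.approx(np.sqrt(ref.mse_resid), rel=1e-10)

    def test_normal_equations_oracle(self):
        data = sd.simulate_lia(sd.LiaSimSpec(n=9, noise_sd=0.3, seed=2, **GEN))
        res = g.fit_lia(data)
        x = np.array([d.deltas for d, _ in data])
        y = np.array([p for _, p in data])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        assert [res.alpha, res.beta, res.gamma] == pytest.approx(list(beta), abs=1e-10)

    def test_too_few_points(self):
        data = sd.simulate_lia(sd.LiaSimSpec(n=3, seed=1))
        with pytest.raises(FitSizeError):
            g.fit_lia(data[:2])
        with pytest.raises(FitSizeError):
            g.fit_lia(data, use_intercept=True)  # needs >= 4 with intercept

    def test_degenerate_design_singular(self):
        ds = descriptors_from_deltas(np.zeros((5, 3)))
        with pytest.raises(SingularFitError):
            LinearInteractionModel(ds, np.ones(5)).fit()

    def test_r2_invariant_to_reordering(self):
        data = sd.simulate_lia(sd.LiaSimSpec(n=12, noise_sd=0.5, seed=9, **GEN))
        a = g.fit_lia(data)
        b = g.fit_lia(list(reversed(data)))
        assert a.stats.r2 == pytest.approx(b.stats.r2, abs=1e-12)

    def test_unbiased_under_noise_closed_form(self):
        """Mean coefficient estimates over noisy replicates stay within
        Monte-Carlo error of the OLS closed-form sampling variance."""
        sigma, n_rep = 0.3, 200
        base = sd.simulate_lia(sd.LiaSimSpec(n=11, noise_sd=0.0, seed=42, **GEN))
        x = np.array([d.deltas for d, _ in base])
        y0 = np.array([p for _, p in base])
        ds = descriptors_from_deltas(x)
        cov = sigma**2 * np.linalg.inv(x.T @ x)
        se_mean = np.sqrt(np.diag(cov) / n_rep)
        rng = np.random.default_rng(1234)
        estimates = []
        for _ in range(n_rep):
            res = LinearInteractionModel(ds, y0 + rng.normal(0, sigma, len(y0))).fit()
            estimates.append([res.alpha, res.beta, res.gamma])
        bias = np.mean(estimates, axis=0) - np.array([GEN["alpha"], GEN["beta"], GEN["gamma"]])
        assert np.all(np.abs(bias) < 4.0 * se_mean)
        # replicate spread agrees with the closed form within Monte-Carlo slack
        emp_sd = np.std(estimates, axis=0, ddof=1)
        assert np.all(emp_sd < 1.5 * np.sqrt(np.diag(cov)))
        assert np.all(emp_sd > 0.6 * np.sqrt(np.diag(cov)))


@pytest.fixture(scope="module")
def fitted():
    return g.fit_lia(sd.simulate_lia(sd.LiaSimSpec(n=11, noise_sd=0.0, seed=5, **GEN)))


class TestPredictClassify:
    def test_zero_deltas_predict_zero(self, fitted):
        d = EnergyDescriptors("z", 0, 0, 0, 0, 0, 0)
        assert fitted.predict(d) == pytest.approx(0.0)

    def test_linearity(self, fitted):
        d1 = EnergyDescriptors("a", -20, 0, -10, 0, -2, 0)
        d2 = EnergyDescriptors("b", -40, 0, -20, 0, -4, 0)
        assert fitted.predict(d2) == pytest.approx(2 * fitted.predict(d1))

    def test_training_set_reproduced_at_zero_noise(self):
        data = sd.simulate_lia(sd.LiaSimSpec(n=11, noise_sd=0.0, seed=5, **GEN))
        res = g.fit_lia(data)
        preds = res.predict([d for d, _ in data])
        assert preds == pytest.approx([p for _, p in data], abs=1e-8)

    @pytest.mark.parametrize("pic50,want", [(5.5, "active"), (4.99, "inactive"), (5.0, "active")])
    def test_activity_threshold_inclusive(self, pic50, want):
        assert g.classify_predicted(pic50) == want

    def test_summary_mentions_fit(self, fitted):
        s = fitted.summary()
        assert "alpha" in s and "R^2" in s

    def test_from_dataframe_roundtrip(self):
        import pandas as pd

        data = sd.simulate_lia(sd.LiaSimSpec(n=6, noise_sd=0.0, seed=3, **GEN))
        rows = [{"compound_id": d.compound_id, "pic50": p,
                 **{k: getattr(d, k) for k in g.lia.DESCRIPTOR_COLUMNS}}
                for d, p in data]
        model = LinearInteractionModel.from_dataframe(pd.DataFrame(rows))
        res = model.fit()
        assert res.alpha == pytest.approx(GEN["alpha"], abs=1e-8)


@pytest.fixture(scope="module")
def posed(gaba_zwitterion):
    return gaba_zwitterion


@pytest.fixture(scope="module")
def pocket():
    return sd.generate_pocket(n_sites=10, radius=7.0, seed=6)


class TestBackend:
    def test_missing_pose_errors(self, pocket):
        with pytest.raises(PoseError):
            g.compute_descriptors(g.Compound.from_smiles("x", "CCO"), pocket)

    def test_deterministic(self, posed, pocket):
        a = g.compute_descriptors(posed, pocket)
        b = g.compute_descriptors(posed, pocket)
        assert a == b

    def test_interactions_vanish_far_away(self, posed, pocket):
        near = g.compute_descriptors(posed, pocket)
        from rdkit import Chem
        far_mol = Chem.Mol(posed.conformer_mol)
        conf = far_mol.GetConformer(0)
        for i in range(far_mol.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, (p.x + 500.0, p.y, p.z))
        far = g.Compound(id="far", mol=posed.mol, conformer_mol=far_mol)
        d = g.compute_descriptors(far, pocket)
        assert d.u_b_vdw == pytest.approx(d.u_f_vdw, abs=1e-6)
        assert d.u_b_elec == pytest.approx(d.u_f_elec, abs=1e-4)
        assert near.u_f_vdw == pytest.approx(d.u_f_vdw, abs=1e-9)

    def test_zero_pocket_charges_zero_elec_delta(self, posed, pocket):
        import dataclasses
        neutral = dataclasses.replace(pocket, charges=np.zeros(len(pocket.charges)))
        d = g.compute_descriptors(posed, neutral)
        assert d.u_b_elec - d.u_f_elec == pytest.approx(0.0, abs=1e-12)

    def test_elec_delta_linear_in_pocket_charges(self, posed, pocket):
        import dataclasses
        doubled = dataclasses.replace(pocket, charges=2.0 * pocket.charges)
        d1 = g.compute_descriptors(posed, pocket)
        d2 = g.compute_descriptors(posed, doubled)
        assert (d2.u_b_elec - d2.u_f_elec) == pytest.approx(
            2.0 * (d1.u_b_elec - d1.u_f_elec), rel=1e-9
        )

    def test_burial_reduces_cavity_term(self, posed, pocket):
        d = g.compute_descriptors(posed, pocket)
        assert d.u_b_cav < d.u_f_cav  # pocket contact buries ligand surface
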