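"""Linear interaction approximation (LIA) affinity models.

The LIA ansatz expresses binding affinity as a linear combination of
bound-minus-free interaction-energy differences,

    pIC50 ~ alpha * dU_vdw + beta * dU_elec + gamma * dU_cav,

with dU_x = <U_bound^x> - <U_free^x> for the van der Waals, electrostatic
and cavity terms (kcal/mol). The three coefficients are fitted by ordinary
least squares against experimental pIC50 values (no intercept by default;
the target is pIC50 directly, so unit conversion is absorbed into the
coefficients, and negative coefficients are permitted).

Follows the Model -> fit() -> Results idiom:
:class:`LinearInteractionModel` holds data, ``fit()`` returns
:class:`LiaResults` with coefficients, fit statistics (R^2 as the squared
Pearson correlation of predicted vs experimental — the unambiguous choice
for a no-intercept fit — residual SD and the overall F-test p-value), a
``summary()`` table, prediction and activity classification.

Energy descriptors come from a pluggable backend. The shipped
:class:`LJCoulombBackend` is a deterministic desk-scale surrogate:
12-6 Lennard-Jones plus Coulomb with a distance-dependent dielectric
eps(r) = 4r for ligand-pocket interactions, and a cavity term proportional
to an approximate solvent-accessible surface area (pairwise sphere-overlap
reduction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .chemio import Compound
from .errors import FitSizeError, ParameterError, PoseError, SingularFitError
from scipy import stats

PIC50_ACTIVITY_THRESHOLD = 5.0  # conventional activity cut-off


# -- descriptors --------------------------------------------------------------

@dataclass(frozen=True)
class EnergyDescriptors:
    """Bound/free vdW, electrostatic and cavity energies (kcal/mol) for one compound."""

    compound_id: str
    u_b_vdw: float
    u_f_vdw: float
    u_b_elec: float
    u_f_elec: float
    u_b_cav: float
    u_f_cav: float

    def __post_init__(self):
        vals = (self.u_b_vdw, self.u_f_vdw, self.u_b_elec, self.u_f_elec, self.u_b_cav, self.u_f_cav)
        if not all(np.isfinite(vals)):
            raise ParameterError(f"non-finite energy descriptor for {self.compound_id!r}")

    @property
    def deltas(self) -> tuple[float, float, float]:
        """(dU_vdw, dU_elec, dU_cav), bound minus free."""
        return (
            self.u_b_vdw - self.u_f_vdw,
            self.u_b_elec - self.u_f_elec,
            self.u_b_cav - self.u_f_cav,
        )


DESCRIPTOR_COLUMNS = ("u_b_vdw", "u_f_vdw", "u_b_elec", "u_f_elec", "u_b_cav", "u_f_cav")


def read_descriptor_csv(path: str | Path) -> list[EnergyDescriptors]:
    df = pd.read_csv(path)
    return [
        EnergyDescriptors(compound_id=str(r.compound_id), **{c: float(getattr(r, c)) for c in DESCRIPTOR_COLUMNS})
        for r in df.itertuples(index=False)
    ]


# -- statsmodels-style model / results ---------------------------------------

@dataclass(frozen=True)
class LiaFitStats:
    r2: float  # squared Pearson correlation, predicted vs experimental
    sd: float  # residual standard deviation (pIC50 units)
    p: float   # overall regression F-test p-value


class LiaResults:
    """Fitted LIA coefficients with statistics, prediction and classification."""

    def __init__(
        self,
        alpha: float,
        beta: float,
        gamma: float,
        intercept: float | None,
        stats: LiaFitStats,
        training_ids: tuple[str, ...],
        fitted: np.ndarray,
        observed: np.ndarray,
    ):
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.intercept = intercept
        self.stats = stats
        self.training_ids = training_ids
        self.fittedvalues = fitted
        self.observed = observed

    @property
    def params(self) -> dict[str, float]:
        out = {"alpha": self.alpha, "beta": self.beta, "gamma": self.gamma}
        if self.intercept is not None:
            out["intercept"] = self.intercept
        return out

    def predict(self, d: EnergyDescriptors | Sequence[EnergyDescriptors]) -> float | np.ndarray:
        """Predicted pIC50: alpha*dU_vdw + beta*dU_elec + gamma*dU_cav (+ intercept)."""
        single = isinstance(d, EnergyDescriptors)
        ds = [d] if single else list(d)
        x = np.array([e.deltas for e in ds])
        y = x @ np.array([self.alpha, self.beta, self.gamma])
        if self.intercept is not None:
            y = y + self.intercept
        return float(y[0]) if single else y

    def classify(self, pic50: float, threshold: float = PIC50_ACTIVITY_THRESHOLD) -> str:
        return classify_predicted(pic50, threshold)

    def summary(self) -> str:
        lines = [
            "Linear Interaction Approximation — OLS fit",
            "=" * 46,
            f"n training compounds : {len(self.training_ids)}",
            f"intercept            : {'none (through origin)' if self.intercept is None else f'{self.intercept:10.4f}'}",
            f"alpha  (dU_vdw)      : {self.alpha:10.4f}",
            f"beta   (dU_elec)     : {self.beta:10.4f}",
            f"gamma  (dU_cav)      : {self.gamma:10.4f}",
            "-" * 46,
            f"R^2 (pred vs exp)    : {self.stats.r2:10.4f}",
            f"residual SD (pIC50)  : {self.stats.sd:10.4f}",
            f"F-test p-value       : {self.stats.p:10.4g}",
        ]
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.params,
                "stats": {"r2": self.stats.r2, "sd": self.stats.sd, "p": self.stats.p},
                "training_ids": list(self.training_ids),
            },
            indent=2,
        )


class LinearInteractionModel:
    """LIA regression model over (EnergyDescriptors, experimental pIC50) pairs."""

    def __init__(
        self,
        descriptors: Sequence[EnergyDescriptors],
        pic50: Sequence[float],
        use_intercept: bool = False,
    ):
        if len(descriptors) != len(pic50):
            raise ParameterError("descriptors and pIC50 lengths differ")
        self.descriptors = list(descriptors)
        self.pic50 = np.asarray(pic50, dtype=float)
        self.use_intercept = use_intercept

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, pic50_col: str = "pic50", use_intercept: bool = False
    ) -> "LinearInteractionModel":
        """Build from a table with compound_id, the six energy columns and a pIC50 column."""
        ds = [
            EnergyDescriptors(
                compound_id=str(r.compound_id),
                **{c: float(getattr(r, c)) for c in DESCRIPTOR_COLUMNS},
            )
            for r in df.itertuples(index=False)
        ]
        return cls(ds, df[pic50_col].to_numpy(dtype=float), use_intercept=use_intercept)

    def fit(self) -> LiaResults:
        """Ordinary least squares of pIC50 on the three energy deltas."""
        n = len(self.descriptors)
        p = 4 if self.use_intercept else 3
        if n < p:
            raise FitSizeError(f"need >= {p} training points, got {n}")
        x = np.array([d.deltas for d in self.descriptors])
        design = np.column_stack([np.ones(n), x]) if self.use_intercept else x
        if np.linalg.matrix_rank(design) < p:
            raise SingularFitError("rank-deficient design (collinear or constant deltas)")
        coef, _, _, _ = np.linalg.lstsq(design, self.pic50, rcond=None)
        fitted = design @ coef
        resid = self.pic50 - fitted
        ss_res = float(resid @ resid)
        sd = float(np.sqrt(ss_res / (n - p))) if n > p else 0.0
        # R^2 as squared Pearson correlation of predicted vs experimental
        if np.std(fitted) == 0.0 or np.std(self.pic50) == 0.0:
            r2 = 1.0 if ss_res < 1e-24 else 0.0
        else:
            r2 = float(np.corrcoef(fitted, self.pic50)[0, 1] ** 2)
        # overall F-test: all slope coefficients zero; for the no-intercept
        # model the null is the zero function, so the explained sum is uncentered
        if self.use_intercept:
            ss_null = float(((self.pic50 - self.pic50.mean()) ** 2).sum())
            df_num = p - 1
        else:
            ss_null = float((self.pic50**2).sum())
            df_num = p
        df_den = n - p
        if df_den <= 0 or ss_res <= 0:
            pval = np.finfo(float).tiny  # perfect (or saturated) fit
        else:
            f = ((ss_null - ss_res) / df_num) / (ss_res / df_den)
            pval = float(stats.f.sf(max(f, 0.0), df_num, df_den))
        pval = min(max(pval, np.finfo(float).tiny), 1.0)
        if self.use_intercept:
            intercept, alpha, beta, gamma = coef
        else:
            intercept = None
            alpha, beta, gamma = coef
        return LiaResults(
            alpha=float(alpha),
            beta=float(beta),
            gamma=float(gamma),
            intercept=None if intercept is None else float(intercept),
            stats=LiaFitStats(r2=min(max(r2, 0.0), 1.0), sd=sd, p=pval),
            training_ids=tuple(d.compound_id for d in self.descriptors),
            fitted=fitted,
            observed=self.pic50.copy(),
        )


def fit_lia(
    training: Sequence[tuple[EnergyDescriptors, float]], use_intercept: bool = False
) -> LiaResults:
    """Functional wrapper: fit a LIA model from (descriptors, pIC50) pairs."""
    ds = [t[0] for t in training]
    y = [t[1] for t in training]
    return LinearInteractionModel(ds, y, use_intercept=use_intercept).fit()


def predict_pic50(m: LiaResults, d: EnergyDescriptors) -> float:
    return float(m.predict(d))


def classify_predicted(pic50: float, threshold: float = PIC50_ACTIVITY_THRESHOLD) -> str:
    """Active iff predicted pIC50 >= threshold (inclusive boundary)."""
    return "active" if pic50 >= threshold else "inactive"


# -- surrogate energy backend -------------------------------------------------

@dataclass
class PocketModel:
    """A rigid pocket as interaction sites: coordinates, charges, LJ parameters."""

    sites: np.ndarray      # (m, 3) Angstrom
    charges: np.ndarray    # (m,) elementary charges
    epsilons: np.ndarray   # (m,) kcal/mol
    sigmas: np.ndarray     # (m,) Angstrom

    def __post_init__(self):
        self.sites = np.asarray(self.sites, float)
        self.charges = np.asarray(self.charges, float)
        self.epsilons = np.asarray(self.epsilons, float)
        self.sigmas = np.asarray(self.sigmas, float)
        m = len(self.sites)
        if not (len(self.charges) == len(self.epsilons) == len(self.sigmas) == m):
            raise ParameterError("pocket arrays must have equal length")

    def to_json(self) -> str:
        return json.dumps(
            {
                "sites": self.sites.tolist(),
                "charges": self.charges.tolist(),
                "epsilons": self.epsilons.tolist(),
                "sigmas": self.sigmas.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PocketModel":
        d = json.loads(text)
        return cls(
            sites=np.array(d["sites"]),
            charges=np.array(d["charges"]),
            epsilons=np.array(d["epsilons"]),
            sigmas=np.array(d["sigmas"]),
        )


# per-element LJ parameters (sigma Angstrom, epsilon kcal/mol) and vdW radii
_LJ_PARAMS = {
    "H": (2.50, 0.030), "C": (3.40, 0.086), "N": (3.25, 0.170),
    "O": (2.96, 0.210), "F": (2.90, 0.061), "P": (3.70, 0.200),
    "S": (3.60, 0.250), "Cl": (3.40, 0.270), "Br": (3.60, 0.310),
    "I": (3.90, 0.400), "B": (3.60, 0.095),
}
_COULOMB_K = 332.06  # kcal*Angstrom/(mol*e^2)
_PROBE_RADIUS = 1.4  # Angstrom, water probe
_CAVITY_COEF = 0.0072  # kcal/mol per Angstrom^2 of SASA


class LJCoulombBackend:
    """Deterministic surrogate energy backend (single-pose, no sampling).

    Bound terms are the isolated-ligand terms plus ligand-pocket
    interactions evaluated at the stored pose; free terms are the isolated
    ligand's intramolecular non-bonded terms (atom pairs three or more
    bonds apart) and solo SASA. Electrostatics use Gasteiger partial
    charges with a distance-dependent dielectric eps(r) = k*r (k = 4).
    """

    def __init__(self, dielectric_k: float = 4.0, cavity_coef: float = _CAVITY_COEF):
        self.dielectric_k = dielectric_k
        self.cavity_coef = cavity_coef

    def compute_descriptors(
        self, c: Compound, pocket: PocketModel, conformer_index: int = 0
    ) -> EnergyDescriptors:
        if c.conformer_mol is None or c.conformer_mol.GetNumConformers() == 0:
            raise PoseError(f"compound {c.id!r} has no pose/conformer")
        mol = c.conformer_mol
        conf = mol.GetConformer(conformer_index)
        pos = conf.GetPositions()
        AllChem.ComputeGasteigerCharges(mol)
        q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()])
        q = np.nan_to_num(q)
        syms = [a.GetSymbol() for a in mol.GetAtoms()]
        sig = np.array([_LJ_PARAMS.get(s, (3.5, 0.1))[0] for s in syms])
        eps = np.array([_LJ_PARAMS.get(s, (3.5, 0.1))[1] for s in syms])

        # intramolecular non-bonded pairs: topological distance >= 3 bonds
        topo = Chem.GetDistanceMatrix(mol)
        iu, ju = np.triu_indices(len(syms), k=1)
        keep = topo[iu, ju] >= 3
        iu, ju = iu[keep], ju[keep]
        r_intra = np.linalg.norm(pos[iu] - pos[ju], axis=1)
        r_intra = np.maximum(r_intra, 0.5)
        s_ij = 0.5 * (sig[iu] + sig[ju])
        e_ij = np.sqrt(eps[iu] * eps[ju])
        sr6 = (s_ij / r_intra) ** 6
        u_intra_vdw = float(np.sum(4.0 * e_ij * (sr6**2 - sr6)))
        u_intra_elec = float(
            np.sum(_COULOMB_K * q[iu] * q[ju] / (self.dielectric_k * r_intra**2))
        )

        # ligand-pocket interactions
        d = np.linalg.norm(pos[:, None, :] - pocket.sites[None, :, :], axis=-1)
        d = np.maximum(d, 0.5)
        s_lp = 0.5 * (sig[:, None] + pocket.sigmas[None, :])
        e_lp = np.sqrt(eps[:, None] * pocket.epsilons[None, :])
        sr6 = (s_lp / d) ** 6
        u_inter_vdw = float(np.sum(4.0 * e_lp * (sr6**2 - sr6)))
        u_inter_elec = float(
            np.sum(_COULOMB_K * q[:, None] * pocket.charges[None, :] / (self.dielectric_k * d**2))
        )

        radii = sig / 2.0 + _PROBE_RADIUS
        u_f_cav = self.cavity_coef * _approx_sasa(pos, radii)
        pocket_radii = pocket.sigmas / 2.0 + _PROBE_RADIUS
        u_b_cav = self.cavity_coef * _approx_sasa(
            np.vstack([pos, pocket.sites]),
            np.concatenate([radii, pocket_radii]),
            count_first=len(pos),
        )
        return EnergyDescriptors(
            compound_id=c.id,
            u_b_vdw=u_intra_vdw + u_inter_vdw,
            u_f_vdw=u_intra_vdw,
            u_b_elec=u_intra_elec + u_inter_elec,
            u_f_elec=u_intra_elec,
            u_b_cav=u_b_cav,
            u_f_cav=u_f_cav,
        )


def _approx_sasa(pos: np.ndarray, radii: np.ndarray, count_first: int | None = None) -> float:
    """Approximate SASA by pairwise sphere-overlap reduction.

    Each atom starts with its full probe-inflated sphere area; every
    overlapping neighbour removes a fraction proportional to the overlap
    depth. Crude but smooth, deterministic and monotone in burial — all
    a fitted surrogate cavity term needs. Optionally sums only the first
    ``count_first`` atoms (the ligand within a ligand+pocket assembly).
    """
    n = len(pos)
    k = n if count_first is None else count_first
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    sum_r = radii[:, None] + radii[None, :]
    overlap = np.clip((sum_r - d) / sum_r, 0.0, 1.0)
    exposed = np.prod(1.0 - 0.5 * overlap[:k], axis=1)
    areas = 4.0 * np.pi * radii[:k] ** 2
    return float(np.sum(areas * exposed))


def compute_descriptors(
    c: Compound,
    pocket: PocketModel,
    backend: LJCoulombBackend | None = None,
    conformer_index: int = 0,
) -> EnergyDescriptors:
    """Compute bound/free energy descriptors for a posed compound."""
    backend = backend or LJCoulombBackend()
    return backend.compute_descriptors(c, pocket, conformer_index)
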