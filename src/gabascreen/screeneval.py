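"""Screening-enrichment statistics: confusion counts, MCC and Goodness of Hit.

MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as 0
when any marginal factor vanishes.

GH = (Ha(3A + Ht) / (4*Ht*A)) * (1 - (Ht - Ha)/D), with Ha the actives in
the hit list (= TP), Ht the hit-list size (TP + FP), A the total actives
(TP + FN) and D the total decoys (FP + TN). The first factor blends yield
and precision 3:1; the second penalises decoy retrieval. Some sources use
D - A in the penalty denominator; that variant is exposed as a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .chemio import Compound
from ._util import round_half_up
from .errors import EvaluationError, ParameterError, UndefinedStatisticError
from .pharmacophore import PharmacophoreHypothesis, match_compound


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN from screening actives and decoys against a model."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def ha(self) -> int:
        """Actives retrieved in the hit list."""
        return self.tp

    @property
    def ht(self) -> int:
        """Hit-list size."""
        return self.tp + self.fp

    @property
    def a(self) -> int:
        """Total actives screened."""
        return self.tp + self.fn

    @property
    def d(self) -> int:
        """Total decoys screened."""
        return self.fp + self.tn


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 when a marginal is empty."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def gh(c: ConfusionCounts, d_minus_a_denominator: bool = False) -> float:
    """Goodness-of-Hit score in [0, 1].

    Returns 0 for an empty hit list or zero actives. Decoy-free screening
    (D = 0) leaves the penalty factor undefined and raises.
    """
    if c.d == 0:
        raise UndefinedStatisticError("GH undefined with zero decoys (D = 0)")
    if c.ht == 0 or c.a == 0:
        return 0.0
    denom = (c.d - c.a) if d_minus_a_denominator else c.d
    if denom <= 0:
        raise UndefinedStatisticError("GH penalty denominator is not positive")
    yield_factor = c.ha * (3 * c.a + c.ht) / (4 * c.ht * c.a)
    penalty = 1.0 - (c.ht - c.ha) / denom
    return yield_factor * penalty


@dataclass(frozen=True)
class HypothesisEvaluation:
    label: str
    counts: ConfusionCounts
    mcc: float
    gh: float


def evaluate_hypothesis(
    h: PharmacophoreHypothesis,
    actives: Sequence[Compound],
    decoys: Sequence[Compound],
) -> HypothesisEvaluation:
    """Screen actives and decoys through a hypothesis and attach MCC/GH."""
    if not actives or not decoys:
        raise EvaluationError("evaluation needs non-empty actives and decoys")
    tp = sum(1 for c in actives if match_compound(h, c))
    fp = sum(1 for c in decoys if match_compound(h, c))
    counts = ConfusionCounts(tp=tp, fn=len(actives) - tp, fp=fp, tn=len(decoys) - fp)
    return HypothesisEvaluation(label=h.label, counts=counts, mcc=mcc(counts), gh=gh(counts))


def cross_map(
    hypotheses: Sequence[PharmacophoreHypothesis], actives: Sequence[Compound]
) -> pd.DataFrame:
    """Actives retrieved per hypothesis, split by pharmacological role."""
    rows = []
    for h in hypotheses:
        matched = [c for c in actives if match_compound(h, c)]
        rows.append(
            {
                "label": h.label,
                "ar_antagonist": sum(1 for c in matched if c.role == "antagonist"),
                "ar_agonist": sum(1 for c in matched if c.role == "agonist"),
            }
        )
    return pd.DataFrame(rows, columns=["label", "ar_antagonist", "ar_agonist"])


def evaluation_table(evaluations: Sequence[HypothesisEvaluation]) -> pd.DataFrame:
    """Report table (one row per hypothesis) with counts and 2-d.p. statistics.

    Displayed MCC/GH are rounded half-up to 2 decimals; the raw values are
    kept in *_raw columns.
    """
    rows = []
    for ev in evaluations:
        c = ev.counts
        rows.append(
            {
                "label": ev.label,
                "n_actives": c.a,
                "TP": c.tp,
                "FN": c.fn,
                "FP": c.fp,
                "TN": c.tn,
                "MCC": round_half_up(ev.mcc, 2),
                "GH": round_half_up(ev.gh, 2),
                "MCC_raw": ev.mcc,
                "GH_raw": ev.gh,
            }
        )
    return pd.DataFrame(rows)
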