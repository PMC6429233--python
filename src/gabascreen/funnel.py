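"""The combined screening funnel: pharmacophore -> docking score -> LIA.

Stage 1 keeps compounds matching any pharmacophore hypothesis; stage 2
keeps compounds whose (externally computed or surrogate) docking score is
at or below a threshold — scores are in kcal/mol, more negative is better,
boundary inclusive; stage 3 keeps compounds whose LIA-predicted pIC50
reaches the activity threshold (5.0 by default). Each stage only sees
survivors of the previous one, and the full per-compound provenance is
emitted. The score threshold can be fixed, the mean docking score of the
reference actives, or (for sensitivity analysis) the poorest-scoring
reference active.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chemio import Compound
from .errors import MissingScoreError, ParameterError
from .lia import EnergyDescriptors, LiaResults, PIC50_ACTIVITY_THRESHOLD
from .pharmacophore import PharmacophoreHypothesis, match, match_compound, perceive_features

STAGES = ("pharmacophore", "score", "lia")


def derive_score_threshold(
    reference_actives: Sequence[tuple[str, float]], mode: str = "mean_of_actives"
) -> float:
    """Score threshold from reference actives: their mean (default) or worst score."""
    if not reference_actives:
        raise ParameterError("cannot derive a threshold from an empty score list")
    scores = [s for _, s in reference_actives]
    if mode == "mean_of_actives":
        return float(np.mean(scores))
    if mode == "worst_of_actives":
        return float(max(scores))  # least negative = poorest
    raise ParameterError(f"unknown threshold mode {mode!r}")


@dataclass
class FunnelConfig:
    """Stages and thresholds of a screening funnel; a stage is enabled iff configured."""

    hypotheses: Sequence[PharmacophoreHypothesis] = ()
    score_threshold_mode: str = "fixed"  # fixed | mean_of_actives | worst_of_actives
    score_threshold: float | None = None
    reference_scores: Sequence[tuple[str, float]] = ()
    lia_results: LiaResults | None = None
    descriptors: Mapping[str, EnergyDescriptors] | None = None
    pic50_threshold: float = PIC50_ACTIVITY_THRESHOLD

    def resolved_score_threshold(self) -> float | None:
        if self.score_threshold_mode == "fixed":
            return self.score_threshold
        return derive_score_threshold(self.reference_scores, self.score_threshold_mode)

    def enabled_stages(self) -> tuple[str, ...]:
        out = []
        if self.hypotheses:
            out.append("pharmacophore")
        if self.resolved_score_threshold() is not None:
            out.append("score")
        if self.lia_results is not None:
            out.append("lia")
        if not out:
            raise ParameterError("funnel has no enabled stage")
        return tuple(out)


@dataclass
class FunnelResult:
    """Per-compound stage provenance and telescoping per-stage summary counts."""

    table: pd.DataFrame
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def final_hits(self) -> list[str]:
        return self.table.loc[self.table["final_hit"], "compound_id"].tolist()


def run_funnel(
    library: Sequence[Compound],
    scores: Mapping[str, float] | Callable[[Compound], float] | None,
    cfg: FunnelConfig,
) -> FunnelResult:
    """Run the staged funnel over a library with full provenance.

    ``scores`` maps compound id to docking score (kcal/mol) or is a callable
    provider; a compound that reaches the score stage without a score raises
    :class:`MissingScoreError`. Compounds failing a stage are never evaluated
    at later stages.
    """
    stages = cfg.enabled_stages()
    thr = cfg.resolved_score_threshold()
    rows = []
    counts = {"input": len(library), **{s: 0 for s in stages}}
    for c in library:
        row: dict = {
            "compound_id": c.id,
            "matched_hypothesis": None,
            "score": np.nan,
            "predicted_pic50": np.nan,
        }
        alive = True
        if "pharmacophore" in stages:
            label = None
            for h in cfg.hypotheses:
                if match_compound(h, c):
                    label = h.label
                    break
            row["matched_hypothesis"] = label
            row["pass_pharmacophore"] = label is not None
            alive = label is not None
            counts["pharmacophore"] += int(alive)
        if "score" in stages:
            if not alive:
                row["pass_score"] = None
            else:
                if callable(scores):
                    s = scores(c)
                elif scores is not None and c.id in scores:
                    s = scores[c.id]
                else:
                    raise MissingScoreError(c.id)
                row["score"] = float(s)
                row["pass_score"] = bool(s <= thr)
                alive = row["pass_score"]
                counts["score"] += int(alive)
        if "lia" in stages:
            if not alive:
                row["pass_lia"] = None
            else:
                if cfg.descriptors is None or c.id not in cfg.descriptors:
                    raise MissingScoreError(c.id)
                pred = float(cfg.lia_results.predict(cfg.descriptors[c.id]))
                row["predicted_pic50"] = pred
                row["pass_lia"] = bool(pred >= cfg.pic50_threshold)
                alive = row["pass_lia"]
                counts["lia"] += int(alive)
        row["final_hit"] = bool(alive)
        rows.append(row)
    columns = ["compound_id", "matched_hypothesis", "score", "predicted_pic50"]
    columns += [f"pass_{s}" for s in stages] + ["final_hit"]
    table = pd.DataFrame(rows, columns=columns)
    return FunnelResult(table=table, stage_counts=counts)


def surrogate_scores(
    library: Sequence[Compound], hypotheses: Sequence[PharmacophoreHypothesis]
) -> dict[str, float]:
    """Bundled surrogate docking scores: negated pharmacophore fit quality.

    Score = -(n_matched + 1/(1 + best RMSD)) over the best-matching
    hypothesis/conformer, 0.0 for non-matchers. Deterministic; stands in
    for an external docking engine in tests and demonstrations.
    """
    out: dict[str, float] = {}
    for c in library:
        best = 0.0
        for h in hypotheses:
            for ci in range(c.n_conformers):
                res = match(h, perceive_features(c, ci))
                if res.matched and res.rmsd is not None:
                    q = res.n_matched + 1.0 / (1.0 + res.rmsd)
                    best = max(best, q)
        out[c.id] = -best
    return out
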