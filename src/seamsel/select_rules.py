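"""The three interim treatment-selection rules.

* Friede et al. rule: pick the arm with the largest early-endpoint statistic
  (uses no final-endpoint data).
* Stallard rule: pick the arm with the largest score statistic (combines the
  observed final outcomes with the early outcomes).
* Data-driven rule: apply both; if they agree, take the common arm, otherwise
  estimate the endpoint-model parameters from the interim data, plug them
  into each rule's analytic selection probability for its own candidate, and
  go with the rule that believes more strongly in its choice.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from enum import Enum

import numpy as np

from . import select_prob, stats_engine
from .stats_engine import EstimatedModel, StatisticsBundle
from .trial_model import Stage1Data, TrialDesign

__all__ = [
    "RuleUsed",
    "SelectionOutcome",
    "select_friede",
    "select_stallard",
    "select_data_driven",
]


class RuleUsed(str, Enum):
    FRIEDE = "friede"
    STALLARD = "stallard"
    DD_AGREE = "data_driven:agree"
    DD_FRIEDE = "data_driven:friede"
    DD_STALLARD = "data_driven:stallard"


@dataclass(frozen=True)
class SelectionOutcome:
    """Result of an interim selection, with full provenance of the decision."""

    selected: int
    rule_used: RuleUsed
    candidate_friede: int
    candidate_stallard: int
    prob_friede_candidate: float | None
    prob_stallard_candidate: float | None
    statistics: StatisticsBundle | None = None
    estimates: EstimatedModel | None = None

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, (StatisticsBundle,)):
                return asdict(o)
            if isinstance(o, EstimatedModel):
                return {
                    "mu_b": o.mu_b.tolist(),
                    "mu_B": o.mu_B.tolist(),
                    "sigma0": o.sigma0,
                    "sigma": o.sigma,
                    "rho_w": o.rho_w,
                }
            raise TypeError(type(o))

        payload = {
            "selected": self.selected,
            "rule_used": self.rule_used.value,
            "candidate_friede": self.candidate_friede,
            "candidate_stallard": self.candidate_stallard,
            "prob_friede_candidate": self.prob_friede_candidate,
            "prob_stallard_candidate": self.prob_stallard_candidate,
            "statistics": self.statistics,
            "estimates": self.estimates,
        }
        return json.dumps(payload, default=default)


def _argmax_arm(statistics) -> int:
    """Arm index (1..k) of the maximal statistic; ties go to the lowest index."""
    statistics = np.asarray(statistics, dtype=float)
    if statistics.size == 0:
        raise ValueError("empty statistic vector")
    return int(np.argmax(statistics)) + 1


def select_friede(z_early) -> int:
    """Early-endpoint rule: arm with the largest Z~_i."""
    return _argmax_arm(z_early)


def select_stallard(score) -> int:
    """Score-statistic rule: arm with the largest S_i."""
    return _argmax_arm(score)


def select_data_driven(stage1: Stage1Data, design: TrialDesign) -> SelectionOutcome:
    """Data-driven rule choosing between the two candidates.

    When the candidates disagree, both rules' selection probabilities for
    their own candidate are evaluated at the interim parameter estimates and
    the larger one wins; an exact tie goes to the score-statistic candidate
    (it uses more of the data).
    """
    if stage1.n1 < 3:
        raise ValueError("data-driven selection needs n1 >= 3 per arm")
    estimates = stats_engine.estimate_model(stage1)
    z_early = stats_engine.early_z(stage1, estimates.sigma0)
    score, info = stats_engine.score_statistics_estimated(stage1)
    cand_f = select_friede(z_early)
    cand_s = select_stallard(score)
    bundle = StatisticsBundle(
        z_early=z_early,
        z1_final=np.full(stage1.k, np.nan),
        score=score,
        info=info,
    )
    if cand_f == cand_s:
        return SelectionOutcome(
            selected=cand_f,
            rule_used=RuleUsed.DD_AGREE,
            candidate_friede=cand_f,
            candidate_stallard=cand_s,
            prob_friede_candidate=None,
            prob_stallard_candidate=None,
            statistics=bundle,
            estimates=estimates,
        )
    p_f = select_prob.friede_selection_prob(
        cand_f, estimates.mu_b, estimates.sigma0, stage1.N1
    )
    p_s = select_prob.stallard_selection_prob(cand_s, estimates, stage1.n1, stage1.N1)
    if p_f > p_s:
        selected, rule = cand_f, RuleUsed.DD_FRIEDE
    else:
        selected, rule = cand_s, RuleUsed.DD_STALLARD
    return SelectionOutcome(
        selected=selected,
        rule_used=rule,
        candidate_friede=cand_f,
        candidate_stallard=cand_s,
        prob_friede_candidate=p_f,
        prob_stallard_candidate=p_s,
        statistics=bundle,
        estimates=estimates,
    )
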