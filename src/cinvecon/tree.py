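"""Decision-tree dose expectations for genotype-guided antiemetic prophylaxis.

The treatment plan is three chemotherapy cycles (days 1, 22 and 43), each
preceded by one fosaprepitant dose when prophylaxis is prescribed.  Two
strategies are compared:

* **standard** — every patient receives fosaprepitant from cycle 1;
* **genotyping** — high-risk carriers (probability ``p_high_risk``) receive
  it from cycle 1; low-risk patients start without it and escalate onto it
  for all subsequent cycles after a grade >=3 nausea/vomiting episode
  (per-evaluation-phase probability ``p_cinv``).

With a constant per-phase toxicity rate, a low-risk patient is on
fosaprepitant at cycle 2 with probability ``p_cinv`` (one prior exposure
phase) and at cycle 3 with probability ``1 - (1 - p_cinv)**2`` (at least one
episode over two phases).

Two dose-accounting conventions are supported.  *Intent-to-treat* costs all
three planned cycles regardless of dropout; *dropout-adjusted* weights the
cycle-2 and cycle-3 doses by the continuation probabilities ``p_cycle2`` and
``p_cycle2 * p_cycle3_given_cycle2``.  All functions accept NumPy arrays in
the probability fields, so posterior draws can be pushed through the tree
vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "DoseConvention",
    "ProbabilityVector",
    "DoseExpectation",
    "expected_doses_standard",
    "expected_doses_genotyping",
    "dose_expectation",
]


class DoseConvention(str, Enum):
    """How cycle-2/3 doses are counted against treatment dropout."""

    INTENT_TO_TREAT = "intent_to_treat"
    DROPOUT_ADJUSTED = "dropout_adjusted"


@dataclass(frozen=True)
class ProbabilityVector:
    """Joint probabilities feeding the decision tree.

    Components are treated as independent: toxicity does not alter
    continuation probabilities.  ``p_cycle3_given_cycle2`` is conditional on
    having received cycle 2, so unconditional cycle-3 receipt is the product
    ``p_cycle2 * p_cycle3_given_cycle2``.
    """

    p_high_risk: float
    p_cinv: float
    p_cycle2: float
    p_cycle3_given_cycle2: float

    FIELDS = ("p_high_risk", "p_cinv", "p_cycle2", "p_cycle3_given_cycle2")

    def __post_init__(self) -> None:
        for name in self.FIELDS:
            value = np.asarray(getattr(self, name))
            if not np.all((value > 0.0) & (value < 1.0)):
                raise ValueError(f"{name} must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class DoseExpectation:
    """Expected fosaprepitant doses per patient under both strategies."""

    standard_doses: float
    genotyping_doses: float
    convention: DoseConvention


def _cycle_weights(pv: ProbabilityVector, convention: DoseConvention):
    """Probability that a patient is present to receive each cycle's dose."""
    if convention is DoseConvention.INTENT_TO_TREAT:
        return 1.0, 1.0, 1.0
    return 1.0, pv.p_cycle2, pv.p_cycle2 * pv.p_cycle3_given_cycle2


def expected_doses_standard(
    pv: ProbabilityVector,
    convention: DoseConvention = DoseConvention.INTENT_TO_TREAT,
):
    """Expected doses per patient when everyone is prescribed prophylaxis.

    Intent-to-treat gives exactly 3; dropout-adjusted gives
    ``1 + p_cycle2 + p_cycle2 * p_cycle3_given_cycle2``.
    """
    w1, w2, w3 = _cycle_weights(pv, convention)
    return w1 + w2 + w3


def expected_doses_genotyping(
    pv: ProbabilityVector,
    convention: DoseConvention = DoseConvention.INTENT_TO_TREAT,
):
    """Expected doses per patient under genotype-guided prescription.

    High-risk carriers follow the standard schedule.  Low-risk patients get
    no cycle-1 dose, a cycle-2 dose with escalation probability ``p_cinv``
    and a cycle-3 dose with probability ``1 - (1 - p_cinv)**2``, each
    weighted by the convention's cycle presence.
    """
    w1, w2, w3 = _cycle_weights(pv, convention)
    escalated_by_cycle2 = pv.p_cinv
    escalated_by_cycle3 = 1.0 - (1.0 - pv.p_cinv) ** 2
    high = w1 + w2 + w3
    low = escalated_by_cycle2 * w2 + escalated_by_cycle3 * w3
    return pv.p_high_risk * high + (1.0 - pv.p_high_risk) * low


def dose_expectation(pv: ProbabilityVector, convention: DoseConvention) -> DoseExpectation:
    """Bundle both branch expectations under one convention."""
    return DoseExpectation(
        standard_doses=float(expected_doses_standard(pv, convention)),
        genotyping_doses=float(expected_doses_genotyping(pv, convention)),
        convention=convention,
    )
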