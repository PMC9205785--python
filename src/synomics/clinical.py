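"""Clinical and histological data model.

CDAI (Clinical Disease Activity Index) arithmetic and the trial's primary
endpoint (CDAI 50% improvement at 16 weeks), crossover outcome labeling
after the week-16 treatment switch, semiquantitative immunohistochemistry
score aggregation (immune score 0-25), and rule-based classification of
synovial pathotypes (lymphomyeloid / diffuse-myeloid / pauci-immune-fibroid).

Two pathotype rulesets are shipped because the published figure legend and
the published methods text state slightly different criteria; ``figure`` is
the default since it is the variant attached to the stratified response
analyses.  Precedence in both is lymphomyeloid > diffuse_myeloid >
pauci_immune_fibroid, and every "and/or" is read as logical OR.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional


class Pathotype(str, enum.Enum):
    LYMPHOMYELOID = "lymphomyeloid"
    DIFFUSE_MYELOID = "diffuse_myeloid"
    PAUCI_IMMUNE_FIBROID = "pauci_immune_fibroid"
    UNGRADED = "ungraded"


class SwitchOutcome(str, enum.Enum):
    RESPONDER_FIRST = "responder_first"
    PRO_RITUXIMAB = "pro_rituximab"
    PRO_TOCILIZUMAB = "pro_tocilizumab"
    REFRACTORY = "refractory"


RITUXIMAB = "rituximab"
TOCILIZUMAB = "tocilizumab"


class ProtocolViolationError(ValueError):
    """Second-drug response recorded despite response to the first drug."""


class MissingScoreError(ValueError):
    """A required semiquantitative score is absent."""


def _check_ordinal(name: str, value, lo: int, hi: int, allow_missing: bool = True):
    if value is None:
        if allow_missing:
            return None
        raise MissingScoreError(f"{name} is required but missing")
    v = float(value)
    if not (lo <= v <= hi) or v != int(v):
        raise ValueError(f"{name}={value!r} outside ordinal range {lo}-{hi}")
    return int(v)


@dataclass(frozen=True)
class BiopsyScores:
    """Semiquantitative IHC scores (0-4) and Krenn synovitis score (0-9)
    for one biopsy.  Missing scores are ``None`` and tracked explicitly.

    ``cd68l`` / ``cd68sl`` are CD68+ macrophages in the lining and sublining
    respectively; ``cd20_aggregate_grade`` is the grade (0-3) of CD20+
    B cell aggregates used by the methods-text pathotype ruleset.
    """

    cd20: Optional[int] = None
    cd3: Optional[int] = None
    cd138: Optional[int] = None
    cd68l: Optional[int] = None
    cd68sl: Optional[int] = None
    cd79a: Optional[int] = None
    cd20_aggregate_grade: Optional[int] = None
    krenn: Optional[int] = None

    def __post_init__(self):
        for name, hi in (("cd20", 4), ("cd3", 4), ("cd138", 4), ("cd68l", 4),
                         ("cd68sl", 4), ("cd79a", 4), ("cd20_aggregate_grade", 3),
                         ("krenn", 9)):
            object.__setattr__(self, name, _check_ordinal(name, getattr(self, name), 0, hi))


def cdai(tjc: float, sjc: float, patient_global: float, evaluator_global: float) -> float:
    """CDAI: tender joint count (0-28) + swollen joint count (0-28) +
    patient and evaluator global assessments (0-10 each); range 0-76."""
    for name, val, hi in (("tjc", tjc, 28), ("sjc", sjc, 28),
                          ("patient_global", patient_global, 10),
                          ("evaluator_global", evaluator_global, 10)):
        if not (0 <= val <= hi) or not math.isfinite(val):
            raise ValueError(f"{name}={val} outside range 0-{hi}")
    return tjc + sjc + patient_global + evaluator_global


def cdai50_response(baseline_cdai: float, week16_cdai: float) -> bool:
    """Primary endpoint: >=50% improvement in CDAI from baseline at 16 weeks."""
    if baseline_cdai <= 0:
        raise ValueError("improvement undefined for baseline CDAI <= 0")
    if week16_cdai < 0:
        raise ValueError("CDAI cannot be negative")
    return (baseline_cdai - week16_cdai) / baseline_cdai >= 0.5


def classify_switch_outcome(
    response_drug1: bool,
    response_drug2: Optional[bool],
    first_drug: str,
) -> SwitchOutcome:
    """Label a patient's course through the per-protocol crossover.

    Nonresponders to the first biologic switch to the alternative at week 16.
    Response to the first drug -> responder_first; response to rituximab after
    tocilizumab failure -> pro_rituximab (and symmetrically pro_tocilizumab);
    sequential failure of both -> refractory (multidrug resistant).
    """
    if first_drug not in (RITUXIMAB, TOCILIZUMAB):
        raise ValueError(f"unknown medication {first_drug!r}")
    if response_drug1:
        if response_drug2 is not None:
            raise ProtocolViolationError(
                "second-drug response recorded although the first drug succeeded"
            )
        return SwitchOutcome.RESPONDER_FIRST
    if response_drug2 is None:
        raise ValueError("nonresponder to first drug without a recorded switch outcome")
    if not response_drug2:
        return SwitchOutcome.REFRACTORY
    second = TOCILIZUMAB if first_drug == RITUXIMAB else RITUXIMAB
    return (SwitchOutcome.PRO_RITUXIMAB if second == RITUXIMAB
            else SwitchOutcome.PRO_TOCILIZUMAB)


def immune_score(scores: BiopsyScores) -> int:
    """Immune score 0-25: Krenn (0-9) + CD20 + CD3 + CD138 + CD68 sublining
    (0-4 each).  CD68 enters as the sublining score, the component used
    throughout the response analyses."""
    parts = {"krenn": scores.krenn, "cd20": scores.cd20, "cd3": scores.cd3,
             "cd138": scores.cd138, "cd68sl": scores.cd68sl}
    missing = [k for k, v in parts.items() if v is None]
    if missing:
        raise MissingScoreError(f"immune score needs {', '.join(missing)}")
    return sum(parts.values())


def classify_pathotype(scores: BiopsyScores, ruleset: str = "figure") -> Pathotype:
    """Classify a biopsy into a synovial pathotype.

    figure ruleset (default):
      lymphomyeloid        if CD20 >= 2 or CD138 >= 2
      diffuse_myeloid      elif CD68SL >= 2
      pauci_immune_fibroid elif CD68SL < 2 and CD20 < 2 and CD138 < 2

    methods ruleset (the stricter published text, "and/or" read as OR):
      lymphomyeloid        if grade 2-3 CD20 aggregates, or CD20 >= 2, or CD138 >= 2
      diffuse_myeloid      elif CD68SL >= 2 and (CD20 <= 1 or CD3 >= 1) and CD138 <= 2
      pauci_immune_fibroid elif CD68SL < 2 and CD3 < 1 and CD20 < 1 and CD138 < 1
      ungraded             otherwise

    Missing required scores yield ``ungraded`` rather than raising.
    """
    if ruleset not in ("figure", "methods"):
        raise ValueError(f"unknown ruleset {ruleset!r}")
    cd20, cd138, cd68sl = scores.cd20, scores.cd138, scores.cd68sl
    if ruleset == "figure":
        if cd20 is None or cd138 is None or cd68sl is None:
            return Pathotype.UNGRADED
        if cd20 >= 2 or cd138 >= 2:
            return Pathotype.LYMPHOMYELOID
        if cd68sl >= 2:
            return Pathotype.DIFFUSE_MYELOID
        # here cd20 < 2 and cd138 < 2 and cd68sl < 2 hold by elimination
        return Pathotype.PAUCI_IMMUNE_FIBROID

    cd3, agg = scores.cd3, scores.cd20_aggregate_grade
    if cd20 is None or cd138 is None or cd68sl is None or cd3 is None:
        return Pathotype.UNGRADED
    if (agg is not None and agg >= 2) or cd20 >= 2 or cd138 >= 2:
        return Pathotype.LYMPHOMYELOID
    if cd68sl >= 2 and (cd20 <= 1 or cd3 >= 1) and cd138 <= 2:
        return Pathotype.DIFFUSE_MYELOID
    if cd68sl < 2 and cd3 < 1 and cd20 < 1 and cd138 < 1:
        return Pathotype.PAUCI_IMMUNE_FIBROID
    return Pathotype.UNGRADED
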