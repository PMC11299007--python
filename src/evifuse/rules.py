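"""Weight-free combination rules: Dempster, Yager and Murphy.

All three operate on the same evidence bodies as the weighted engine, with
focal elements restricted to singletons plus the whole frame.  Each body's
mass function is simply its belief vector, with the residual ignorance as
the mass on the frame.

Only Dempster's rule is spelled out in full by the weighted recursion (it
is the special case of zero weight remainder); Yager's rule routes the
conflict mass to the frame instead of renormalizing (Yager 1987, Inf. Sci.
41:93-137), and Murphy's rule averages the bodies then self-combines the
average (Murphy 2000, Decis. Support Syst. 29:1-9).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .core import EvidenceBody, Frame, check_frame_conformance
from .engine import FusionResult, conflict_sum, fuse_unweighted
from .errors import DimensionMismatchError

logger = logging.getLogger(__name__)

_EPS = 1e-12


def pairwise_conflict(a: EvidenceBody, b: EvidenceBody) -> float:
    """Total product mass on disjoint proposition pairs of two bodies."""
    if a.n_propositions != b.n_propositions:
        raise DimensionMismatchError(
            f"bodies have {a.n_propositions} and {b.n_propositions} propositions"
        )
    return conflict_sum(a.beliefs, b.beliefs)


def _warn_weights_ignored(weights, rule: str) -> None:
    if weights is not None:
        logger.warning("%s rule is weight-free; supplied weights are ignored", rule)


def dempster_fuse(
    evidence: Sequence[EvidenceBody], frame: Frame, weights=None
) -> FusionResult:
    """Classic Dempster combination folded pairwise left-to-right.

    Agreement products plus singleton-frame cross terms are renormalized by
    one minus the conflict; the final frame mass is reported as uncertainty.
    Raises a complete-conflict error when the conflict reaches one.
    """
    _warn_weights_ignored(weights, "Dempster")
    result = fuse_unweighted(evidence, frame, algorithm="Dempster")
    return result


def yager_fuse(
    evidence: Sequence[EvidenceBody], frame: Frame, weights=None
) -> FusionResult:
    """Yager's rule: Dempster numerators with no renormalization; the
    conflict mass is added to the frame.  Total for all inputs, including
    complete conflict.  Sequential pairwise over more than two bodies is
    order-dependent; the fold is left-to-right in input order.
    """
    _warn_weights_ignored(weights, "Yager")
    evidence = list(evidence)
    if len(evidence) < 1:
        raise DimensionMismatchError("need at least one body of evidence")
    check_frame_conformance(evidence, frame)
    m = evidence[0].beliefs.copy()
    m_theta = evidence[0].ignorance
    for ev in evidence[1:]:
        b, b_theta = ev.beliefs, ev.ignorance
        conflict = conflict_sum(m, b)
        new_m = m * b + m * b_theta + b * m_theta
        m_theta = m_theta * b_theta + conflict
        m = new_m
    return FusionResult(
        beliefs=m, uncertainty=m_theta, algorithm="Yager", frame=frame
    )


def murphy_fuse(
    evidence: Sequence[EvidenceBody], frame: Frame, weights=None
) -> FusionResult:
    """Murphy's averaging rule: take the component-wise mean of the bodies
    (beliefs and ignorance alike), then Dempster-combine the mean with
    itself L - 1 times.  A single body is returned unchanged."""
    _warn_weights_ignored(weights, "Murphy")
    evidence = list(evidence)
    if len(evidence) < 1:
        raise DimensionMismatchError("need at least one body of evidence")
    check_frame_conformance(evidence, frame)
    L = len(evidence)
    if L == 1:
        ev = evidence[0]
        return FusionResult(
            beliefs=ev.beliefs.copy(),
            uncertainty=ev.ignorance,
            algorithm="Murphy",
            frame=frame,
        )
    mean_beliefs = np.mean([ev.beliefs for ev in evidence], axis=0)
    mean_ignorance = float(np.mean([ev.ignorance for ev in evidence]))
    mean_body = EvidenceBody(beliefs=mean_beliefs, ignorance=mean_ignorance)
    # L copies of the mean => L - 1 Dempster self-combinations.  Complete
    # self-conflict of a mean body is unreachable with nonnegative masses,
    # but the pairwise driver guards the division anyway.
    return fuse_unweighted([mean_body] * L, frame, algorithm="Murphy")
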