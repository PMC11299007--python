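"""Recursive weighted combination of mass assignments and final belief
extraction.

The aggregate state is folded left-to-right over the evidence list.  The
operator is order-invariant, so the fold direction only pins down
floating-point reproducibility.  Each step rescales by a normalizing factor
K (the reciprocal of one minus the pairwise conflict) so the four mass
components keep summing to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    EvidenceBody,
    Frame,
    MassAssignment,
    check_frame_conformance,
    masses_from_evidence,
    normalize_weights,
    unweighted_mass,
)
from .errors import (
    CompleteConflictError,
    DegenerateStateError,
    DimensionMismatchError,
)

logger = logging.getLogger(__name__)

#: Conflict denominators at or below this are treated as complete conflict.
CONFLICT_EPS = 1e-12


@dataclass(frozen=True)
class FusionState:
    """Running aggregate after combining the first ``count`` bodies."""

    aggregate: MassAssignment
    count: int
    last_K: float = 1.0


@dataclass(frozen=True)
class FusionResult:
    """Final combined belief degrees plus the overall unassigned belief."""

    beliefs: np.ndarray
    uncertainty: float
    algorithm: str
    frame: Frame

    def __post_init__(self):
        b = np.asarray(self.beliefs, dtype=float)
        b.flags.writeable = False
        object.__setattr__(self, "beliefs", b)

    def as_evidence(self, label: str = "") -> EvidenceBody:
        """Reinterpret this result as one (possibly incomplete) body of
        evidence, carrying the unassigned belief as ignorance."""
        return EvidenceBody(
            beliefs=self.beliefs.copy(), ignorance=self.uncertainty, label=label
        )

    def rounded(self, precision: int = 4) -> "FusionResult":
        """Presentation copy rounded half-even to ``precision`` decimals."""
        return FusionResult(
            beliefs=np.round(self.beliefs, precision),
            uncertainty=round(self.uncertainty, precision),
            algorithm=self.algorithm,
            frame=self.frame,
        )


def initial_state(mass: MassAssignment) -> FusionState:
    """State after the first body: the aggregate is that body's masses."""
    return FusionState(aggregate=mass, count=1, last_K=1.0)


def conflict_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Total product mass on disjoint proposition pairs.

    Computed as (sum a)(sum b) - sum(a*b), identical to the literal double
    sum over n != k but O(N).
    """
    return float(a.sum() * b.sum() - (a * b).sum())


def combine_pair(state: FusionState, next_mass: MassAssignment) -> FusionState:
    """One recursion step: merge the aggregate with the next mass body."""
    agg = state.aggregate
    if agg.n_propositions != next_mass.n_propositions:
        raise DimensionMismatchError(
            f"aggregate has {agg.n_propositions} propositions, next mass has "
            f"{next_mass.n_propositions}"
        )
    a, b = agg.prop_masses, next_mass.prop_masses
    denom = 1.0 - conflict_sum(a, b)
    if denom <= CONFLICT_EPS:
        raise CompleteConflictError(
            f"complete conflict combining evidence {state.count + 1}: "
            "all mass lies on disjoint propositions",
            step=state.count + 1,
        )
    K = 1.0 / denom
    a_theta = agg.total_ignorance
    b_theta = next_mass.total_ignorance
    new_props = K * (a * b + a * b_theta + b * a_theta)
    new_tilde = K * (
        agg.m_tilde * next_mass.m_tilde
        + agg.m_bar * next_mass.m_tilde
        + agg.m_tilde * next_mass.m_bar
    )
    new_bar = K * (agg.m_bar * next_mass.m_bar)
    logger.debug("combine step %d: K=%.12g", state.count + 1, K)
    return FusionState(
        aggregate=MassAssignment(new_props, new_tilde, new_bar),
        count=state.count + 1,
        last_K=K,
    )


def finalize(
    state: FusionState, frame: Frame, algorithm: str = "ER"
) -> FusionResult:
    """Redistribute the weight remainder and read off final beliefs.

    ``p_n = m_n / (1 - m_bar)``; the remaining incompleteness mass becomes
    the reported uncertainty.
    """
    agg = state.aggregate
    denom = 1.0 - agg.m_bar
    if denom <= CONFLICT_EPS:
        raise DegenerateStateError(
            "all mass is weight remainder; final beliefs are undefined"
        )
    return FusionResult(
        beliefs=agg.prop_masses / denom,
        uncertainty=agg.m_tilde / denom,
        algorithm=algorithm,
        frame=frame,
    )


def fuse_masses(
    masses: Sequence[MassAssignment], frame: Frame, algorithm: str = "ER"
) -> FusionResult:
    """Fold ``combine_pair`` over pre-built mass bodies and finalize."""
    if len(masses) < 1:
        raise DimensionMismatchError("need at least one mass body")
    state = initial_state(masses[0])
    for m in masses[1:]:
        state = combine_pair(state, m)
    return finalize(state, frame, algorithm=algorithm)


def er_fuse(
    evidence: Sequence[EvidenceBody],
    raw_weights,
    frame: Frame,
    *,
    _normalize: bool = True,
) -> FusionResult:
    """Weighted recursive fusion of evidence bodies.

    Weights are raw importances (e.g. 10, 8, 5) and are normalized to sum
    to one before discounting, mirroring the automatic normalization of the
    reference implementation.  ``_normalize=False`` is an internal test hook
    that feeds the weights through verbatim (used to check the reduction to
    Dempster's rule at unit weights); it is not part of the public contract.

    Raises a dimension-mismatch error before any computation if the evidence
    count, weight count and frame width disagree.
    """
    evidence = list(evidence)
    w = np.asarray(raw_weights, dtype=float).ravel()
    if len(evidence) < 1:
        raise DimensionMismatchError("need at least one body of evidence")
    if w.size != len(evidence):
        raise DimensionMismatchError(
            f"{len(evidence)} evidence bodies but {w.size} weights"
        )
    check_frame_conformance(evidence, frame)
    if _normalize:
        weights = normalize_weights(w).weights
    else:
        if np.any((w < 0) | (w > 1)):
            raise DimensionMismatchError("un-normalized weights must lie in [0, 1]")
        weights = w
    masses = [
        masses_from_evidence(ev, float(wi)) for ev, wi in zip(evidence, weights)
    ]
    return fuse_masses(masses, frame, algorithm="ER")


def fuse_unweighted(
    evidence: Sequence[EvidenceBody], frame: Frame, algorithm: str
) -> FusionResult:
    """Shared driver for the weight-free rules that reduce to the same
    pairwise recursion with a zero weight remainder (Dempster-style)."""
    evidence = list(evidence)
    if len(evidence) < 1:
        raise DimensionMismatchError("need at least one body of evidence")
    check_frame_conformance(evidence, frame)
    masses = [unweighted_mass(ev) for ev in evidence]
    return fuse_masses(masses, frame, algorithm=algorithm)
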