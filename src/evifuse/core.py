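"""Domain types for frames, evidence, weights and probability masses.

The central transform here maps a belief distribution plus a source weight
into a basic-probability-mass assignment whose unassigned mass is split into
two parts: the part caused by incomplete evidence (``m_tilde``) and the part
caused by weight withheld from the source (``m_bar``).  Keeping the two
apart is what lets the recursive combination redistribute the weight
remainder at the end while preserving genuine ignorance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionMismatchError, ValidationError

#: Tolerated overshoot of a belief row's sum above 1 (covers data printed as
#: rounded percentages).  Sums in (1, 1 + BELIEF_SUM_TOL] are renormalized;
#: anything larger is rejected.
BELIEF_SUM_TOL = 1e-3

_MASS_ATOL = 1e-9


@dataclass(frozen=True)
class Frame:
    """An ordered set of mutually exclusive propositions (evaluation grades).

    Order is significant and preserved end-to-end; labels are never sorted
    or deduplicated silently.
    """

    propositions: tuple[str, ...]

    def __post_init__(self):
        props = tuple(str(p) for p in self.propositions)
        object.__setattr__(self, "propositions", props)
        if len(props) < 1:
            raise ValidationError("frame must contain at least one proposition")
        if any(not p for p in props):
            raise ValidationError("proposition labels must be non-empty")
        if len(set(props)) != len(props):
            raise ValidationError(f"duplicate proposition labels: {props}")

    @property
    def n_propositions(self) -> int:
        return len(self.propositions)

    @classmethod
    def generic(cls, n: int) -> "Frame":
        """A frame with placeholder labels ``Proposition 1..n``."""
        return cls(tuple(f"Proposition {i + 1}" for i in range(n)))


@dataclass(frozen=True)
class EvidenceBody:
    """One source's belief distribution over a frame.

    ``ignorance`` is the belief left unassigned to any proposition,
    ``1 - sum(beliefs)``, clipped at zero.
    """

    beliefs: np.ndarray
    ignorance: float
    label: str = ""

    def __post_init__(self):
        b = np.asarray(self.beliefs, dtype=float)
        b.flags.writeable = False
        object.__setattr__(self, "beliefs", b)

    @property
    def n_propositions(self) -> int:
        return self.beliefs.shape[0]

    def is_complete(self, atol: float = _MASS_ATOL) -> bool:
        return self.ignorance <= atol

    def is_vacuous(self, atol: float = _MASS_ATOL) -> bool:
        return bool(np.all(self.beliefs <= atol))


@dataclass(frozen=True)
class WeightVector:
    """Normalized per-source weights: nonnegative, summing to one."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValidationError("weights must form a non-empty 1-d vector")
        if np.any(w < 0):
            raise ValidationError("weights must be nonnegative")
        if abs(float(w.sum()) - 1.0) > _MASS_ATOL:
            raise ValidationError(
                f"weights must sum to 1 (got {w.sum():.12g}); "
                "use normalize_weights() on raw importances"
            )
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.shape[0]

    def __getitem__(self, i: int) -> float:
        return float(self.weights[i])


@dataclass(frozen=True)
class MassAssignment:
    """Weighted basic probability masses for one body of evidence.

    ``prop_masses[n]`` is the mass committed to proposition *n*; ``m_tilde``
    is unassigned mass due to evidence incompleteness; ``m_bar`` is
    unassigned mass due to the weight not given to this source.  The four
    components always sum to one.
    """

    prop_masses: np.ndarray
    m_tilde: float
    m_bar: float

    def __post_init__(self):
        m = np.asarray(self.prop_masses, dtype=float)
        m.flags.writeable = False
        object.__setattr__(self, "prop_masses", m)
        total = float(m.sum()) + self.m_tilde + self.m_bar
        if np.any(m < -_MASS_ATOL) or self.m_tilde < -_MASS_ATOL or self.m_bar < -_MASS_ATOL:
            raise ValidationError("mass components must be nonnegative")
        if abs(total - 1.0) > _MASS_ATOL:
            raise ValidationError(f"mass components must sum to 1 (got {total:.12g})")

    @property
    def total_ignorance(self) -> float:
        """Unassigned mass from both sources of uncertainty combined."""
        return self.m_tilde + self.m_bar

    @property
    def n_propositions(self) -> int:
        return self.prop_masses.shape[0]


def normalize_weights(raw) -> WeightVector:
    """Scale raw nonnegative importances so they sum to one.

    Raises a validation error on negative entries or an all-zero vector.
    Order is preserved.
    """
    w = np.asarray(raw, dtype=float).ravel()
    if w.size < 1:
        raise ValidationError("weight vector must be non-empty")
    if np.any(w < 0):
        bad = int(np.argmin(w))
        raise ValidationError(f"negative weight {w[bad]!r} at position {bad}")
    total = float(w.sum())
    if total <= 0:
        raise ValidationError("all weights are zero; at least one must be positive")
    return WeightVector(w / total)


def validate_evidence(
    beliefs,
    tol: float = BELIEF_SUM_TOL,
    label: str = "",
) -> EvidenceBody:
    """Check a belief row and attach its residual ignorance.

    Rows whose sum exceeds 1 by at most ``tol`` (rounded-percentage inputs)
    are rescaled to sum exactly 1 with zero ignorance; larger violations and
    out-of-range cells raise a validation error naming the offending row.
    """
    b = np.asarray(beliefs, dtype=float).ravel()
    where = f" in evidence row {label!r}" if label else ""
    if b.size < 1:
        raise ValidationError(f"empty belief vector{where}")
    if np.any(~np.isfinite(b)):
        raise ValidationError(f"non-finite belief value{where}")
    if np.any(b < 0) or np.any(b > 1):
        bad = int(np.argmax((b < 0) | (b > 1)))
        raise ValidationError(
            f"belief degree {b[bad]!r} out of [0, 1] at proposition {bad + 1}{where}"
        )
    total = float(b.sum())
    # machine-eps grace on top of tol so tol=0 still admits exact simplexes
    if total > 1.0 + tol + 1e-12:
        raise ValidationError(
            f"belief degrees sum to {total:.6g} > 1 + tol{where}"
        )
    if total > 1.0:
        b = b / total
        total = 1.0
    return EvidenceBody(beliefs=b, ignorance=max(0.0, 1.0 - total), label=label)


def masses_from_evidence(evidence: EvidenceBody, weight: float) -> MassAssignment:
    """Discount a belief distribution by its source weight.

    ``prop_masses = weight * beliefs``; incompleteness mass is
    ``weight * ignorance``; the remainder ``1 - weight`` is the
    weight-induced unassigned mass.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValidationError(f"weight {weight!r} outside [0, 1]")
    m = weight * evidence.beliefs
    m_tilde = weight * evidence.ignorance
    return MassAssignment(prop_masses=m, m_tilde=m_tilde, m_bar=1.0 - weight)


def unweighted_mass(evidence: EvidenceBody) -> MassAssignment:
    """Mass body for the weight-free rules: no weight remainder, all
    residual mass is incompleteness on the whole frame."""
    return MassAssignment(
        prop_masses=evidence.beliefs.copy(),
        m_tilde=evidence.ignorance,
        m_bar=0.0,
    )


def check_frame_conformance(evidence: list[EvidenceBody], frame: Frame) -> None:
    """Raise on any body whose length differs from the frame's."""
    for i, ev in enumerate(evidence):
        if ev.n_propositions != frame.n_propositions:
            raise DimensionMismatchError(
                f"evidence {ev.label or i + 1} has {ev.n_propositions} belief "
                f"degrees but the frame has {frame.n_propositions} propositions"
            )
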