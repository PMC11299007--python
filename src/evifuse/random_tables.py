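"""Deterministic random evidence generators for property tests and demos."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import Frame, validate_evidence
from .errors import ValidationError
from .tableio import EvidenceTable


def generate_random_evidence(
    seed: int,
    n_evidence: int,
    n_propositions: int,
    incompleteness_max: float = 0.0,
    weight_skew: float = 1.0,
    propositions: Sequence[str] | None = None,
) -> EvidenceTable:
    """Draw a random evidence table, deterministic in ``seed``.

    Each belief row is a uniform point on the simplex (flat Dirichlet)
    scaled by ``1 - u`` with ``u ~ Uniform(0, incompleteness_max)``, so row
    sums land in ``[1 - incompleteness_max, 1]`` and ``incompleteness_max=0``
    yields complete evidence exactly.  Raw weights are gamma draws with
    shape ``1 / weight_skew``: skew 1 is exponential; larger skew makes the
    weights more unequal.
    """
    if n_evidence < 1 or n_propositions < 1:
        raise ValidationError("need at least one evidence row and one proposition")
    if not 0.0 <= incompleteness_max <= 1.0:
        raise ValidationError("incompleteness_max must lie in [0, 1]")
    if weight_skew <= 0:
        raise ValidationError("weight_skew must be positive")

    rng = np.random.default_rng(seed)
    dbf = rng.dirichlet(np.ones(n_propositions), size=n_evidence)
    if incompleteness_max > 0:
        u = rng.uniform(0.0, incompleteness_max, size=n_evidence)
        dbf = dbf * (1.0 - u)[:, None]
    # strictly positive raw weights
    weights = rng.gamma(shape=1.0 / weight_skew, scale=1.0, size=n_evidence) + 1e-9

    frame = (
        Frame(tuple(str(p) for p in propositions))
        if propositions is not None
        else Frame.generic(n_propositions)
    )
    evidence = tuple(
        validate_evidence(dbf[i], tol=0.0, label=f"Evidence {i + 1}")
        for i in range(n_evidence)
    )
    return EvidenceTable(frame=frame, evidence=evidence, weights=weights)
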