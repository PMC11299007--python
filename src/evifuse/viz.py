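"""Bar-chart rendering of fused results (static image output)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .engine import FusionResult
from .errors import ValidationError

UNCERTAINTY_LABEL = "Uncertainty"


def render_result_chart(
    result: FusionResult,
    out: Union[str, Path],
    names: Sequence[str] | None = None,
) -> Path:
    """Write a bar chart: one bar per proposition plus one uncertainty bar.

    Bars follow frame order with uncertainty last.  When ``names`` is not
    given, the result's own frame labels are used; pass ``names=()`` to
    force the generic "Proposition i" fallback.
    """
    n = result.beliefs.shape[0]
    if names is None:
        labels = list(result.frame.propositions)
    elif len(names) == 0:
        labels = [f"Proposition {i + 1}" for i in range(n)]
    else:
        if len(names) != n:
            raise ValidationError(
                f"{len(names)} labels supplied for {n} propositions"
            )
        labels = [str(x) for x in names]
    labels.append(UNCERTAINTY_LABEL)
    heights = list(result.beliefs) + [result.uncertainty]

    fig, ax = plt.subplots(figsize=(max(4.0, 1.2 * len(labels)), 4.0))
    colors = ["#4878a8"] * n + ["#b0b0b0"]
    ax.bar(range(len(labels)), heights, color=colors)
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=30, ha="right")
    ax.set_ylabel("Belief degree")
    ax.set_ylim(0, 1)
    ax.set_title(f"Combined belief degrees ({result.algorithm})")
    for i, h in enumerate(heights):
        ax.text(i, h + 0.01, f"{h:.4f}", ha="center", fontsize=8)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out)
    plt.close(fig)
    return out
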