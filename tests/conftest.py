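"""Shared fixtures: worked examples, independent oracles, tree builders."""

from __future__ import annotations

import numpy as np
import pytest

from evifuse import Frame, validate_evidence

# ---------------------------------------------------------------------------
# Worked example 1: three-expert diagnosis (3 evidence x 3 propositions,
# raw weights 10/8/5).  Published fused result: beliefs
# (0.4332, 0.3071, 0.1639), uncertainty 0.0959 at 4 dp.
# ---------------------------------------------------------------------------

DIAGNOSIS_DBF = np.array(
    [
        [0.9, 0.0, 0.0],
        [0.0, 0.9, 0.0],
        [0.0, 0.0, 0.9],
    ]
)
DIAGNOSIS_WEIGHTS = np.array([10.0, 8.0, 5.0])
DIAGNOSIS_PROPS = ("Cold", "Common pneumonia", "COVID-19")
DIAGNOSIS_EXPECTED = np.array([0.4332, 0.3071, 0.1639])
DIAGNOSIS_EXPECTED_UNCERTAINTY = 0.0959

# ---------------------------------------------------------------------------
# Worked example 2: patient feedback on hospital quality, four perspectives
# (facilities, staff, processes, outcomes) per hospital, equal weights,
# percentages of respondents per grade.  Published fused rows at 4 dp below.
# ---------------------------------------------------------------------------

HOSPITAL_GRADES = ("Excellent", "Good", "Average", "Poor", "Worst")

HOSPITAL_FEEDBACK_PCT = {
    "Hospital A": [
        [19.75, 37.04, 39.51, 2.47, 1.23],
        [18.52, 39.51, 35.80, 3.70, 2.47],
        [12.35, 33.33, 49.38, 4.94, 0.00],
        [14.81, 48.15, 30.86, 6.17, 0.00],
    ],
    "Hospital B": [
        [19.72, 53.52, 23.94, 2.82, 0.00],
        [19.72, 49.30, 28.17, 2.81, 0.00],
        [19.72, 45.07, 35.21, 0.00, 0.00],
        [21.13, 47.89, 28.17, 2.81, 0.00],
    ],
    "Hospital C": [
        [23.68, 50.00, 22.37, 2.63, 1.32],
        [26.32, 47.37, 21.05, 5.26, 0.00],
        [19.74, 43.42, 31.58, 3.95, 1.31],
        [27.63, 46.05, 23.68, 1.32, 1.32],
    ],
}

HOSPITAL_EXPECTED = {
    "Hospital A": [0.1502, 0.4062, 0.3983, 0.0374, 0.0079],
    "Hospital B": [0.1850, 0.5195, 0.2777, 0.0178, 0.0],
    "Hospital C": [0.2318, 0.4964, 0.2352, 0.0282, 0.0084],
}


@pytest.fixture
def diagnosis_frame():
    return Frame(DIAGNOSIS_PROPS)


@pytest.fixture
def diagnosis_evidence():
    return [validate_evidence(row) for row in DIAGNOSIS_DBF]


@pytest.fixture
def hospital_frame():
    return Frame(HOSPITAL_GRADES)


def hospital_bodies(name):
    return [
        validate_evidence(np.asarray(row) / 100.0)
        for row in HOSPITAL_FEEDBACK_PCT[name]
    ]


# ---------------------------------------------------------------------------
# Independent oracles (literal formula transcriptions; kept free of the
# engine's vectorized path on purpose)
# ---------------------------------------------------------------------------


def two_evidence_oracle(p1, p2, w1, w2):
    """Closed-form weighted combination of exactly two evidence bodies,
    written with explicit loops.  Returns (beliefs, uncertainty)."""
    p1, p2 = list(map(float, p1)), list(map(float, p2))
    n_props = len(p1)
    m1 = [w1 * p for p in p1]
    mt1 = w1 * (1.0 - sum(p1))
    mb1 = 1.0 - w1
    m2 = [w2 * p for p in p2]
    mt2 = w2 * (1.0 - sum(p2))
    mb2 = 1.0 - w2
    conflict = sum(
        m1[n] * m2[k]
        for n in range(n_props)
        for k in range(n_props)
        if k != n
    )
    K = 1.0 / (1.0 - conflict)
    combined = [
        K * (m1[n] * m2[n] + m1[n] * (mt2 + mb2) + m2[n] * (mt1 + mb1))
        for n in range(n_props)
    ]
    mt = K * (mt1 * mt2 + mb1 * mt2 + mt1 * mb2)
    mb = K * (mb1 * mb2)
    denom = 1.0 - mb
    return [m / denom for m in combined], mt / denom


def dempster_pair_oracle(p1, ig1, p2, ig2):
    """Brute-force Dempster combination of two singleton+frame bodies by
    enumerating all focal-set pairs.  Returns (masses, frame_mass)."""
    n_props = len(p1)
    focals1 = {i: p1[i] for i in range(n_props)}
    focals1["theta"] = ig1
    focals2 = {i: p2[i] for i in range(n_props)}
    focals2["theta"] = ig2
    agree = [0.0] * n_props
    theta = 0.0
    conflict = 0.0
    for f1, v1 in focals1.items():
        for f2, v2 in focals2.items():
            product = v1 * v2
            if f1 == "theta" and f2 == "theta":
                theta += product
            elif f1 == "theta":
                agree[f2] += product
            elif f2 == "theta":
                agree[f1] += product
            elif f1 == f2:
                agree[f1] += product
            else:
                conflict += product
    denom = 1.0 - conflict
    return [a / denom for a in agree], theta / denom


# ---------------------------------------------------------------------------
# Directory-tree builders for the multilevel protocol
# ---------------------------------------------------------------------------


def write_tree_csv(path, objects, props, weights, beliefs_rows):
    """Write one tree CSV: Object,Weight,<props...> with one row per object."""
    lines = ["Object,Weight," + ",".join(props)]
    for obj, w, row in zip(objects, weights, beliefs_rows):
        cells = ",".join(str(v) for v in row)
        lines.append(f"{obj},{w},{cells}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def zeros_combined(path, folder_name, objects, props, weight=1.0):
    """A combined file with a zero-initialized DBF block."""
    rows = [[0.0] * len(props) for _ in objects]
    write_tree_csv(
        path / f"{folder_name}_combined.csv",
        objects,
        props,
        [weight] * len(objects),
        rows,
    )


def build_flat_tree(root, objects, props, evidence_per_object, weights):
    """Depth-1 tree: root 'Objects' with one leaf 'Panel' holding one
    evidence file per source.

    ``evidence_per_object[obj]`` is a list of belief rows, one per source.
    """
    objects_dir = root / "Objects"
    leaf = objects_dir / "Panel"
    leaf.mkdir(parents=True)
    zeros_combined(objects_dir, "Objects", objects, props)
    zeros_combined(leaf, "Panel", objects, props)
    n_sources = len(weights)
    for s in range(n_sources):
        rows = [evidence_per_object[obj][s] for obj in objects]
        write_tree_csv(
            leaf / f"Evidence{s + 1}.csv",
            objects,
            props,
            [weights[s]] * len(objects),
            rows,
        )
    return objects_dir
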