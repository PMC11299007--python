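# evifuse

Multi-source evidence fusion under uncertainty. `evifuse` implements the
weighted recursive evidential-reasoning (ER) combination of belief
distributions — tracking evidence incompleteness separately from
weight-induced ignorance — together with the classic Dempster, Yager and
Murphy combination rules, flat CSV/XLSX evidence templates, and bottom-up
multi-level fusion over a tree-structured assessment framework stored as a
directory of CSV files.

## Library quick start

```python
import numpy as np
from evifuse import Frame, er_fuse, validate_evidence

frame = Frame(("Cold", "Common pneumonia", "COVID-19"))
evidence = [
    validate_evidence([0.9, 0.0, 0.0]),   # expert 1
    validate_evidence([0.0, 0.9, 0.0]),   # expert 2
    validate_evidence([0.0, 0.0, 0.9]),   # expert 3
]
result = er_fuse(evidence, raw_weights=[10, 8, 5], frame=frame)
print(np.round(result.beliefs, 4), round(result.uncertainty, 4))
# [0.4332 0.3071 0.1639] 0.0959
```

Weights are raw importances and are normalized automatically. Each belief
row may sum to less than one; the shortfall is the row's ignorance and is
carried through the combination. The weight-free rules (`dempster_fuse`,
`yager_fuse`, `murphy_fuse`) take the same evidence bodies and ignore any
weights with a logged warning.

## File template

Flat evidence files follow `templates/evidence_template.csv`:

```
Evidence,Weight,Proposition 1,Proposition 2,Proposition 3
Evidence 1,10,90%,0,0
Evidence 2,8,0,90%,0
Evidence 3,5,0,0,90%
```

Belief cells may be decimals or percent strings; blanks read as zero. The
same layout saved as `.xlsx` (first worksheet) is accepted.
`run_from_file(path, algorithm)` dispatches on the tags `ER` (default),
`Demp`/`Dempster`, `Yager` and `Murphy` (case-insensitive).

## CLI

```bash
evifuse fuse --input diagnosis.csv                       # prints beliefs | uncertainty
evifuse fuse --input diagnosis.csv --algorithm dempster  # weight-free rule
evifuse fuse --input diagnosis.csv --output out.csv --plot chart.png
evifuse multilevel --root path/to/Objects                # tree-structured fusion
```

Exit codes: `0` success, `2` validation error, `3` complete conflict,
`4` I/O or file-format error. Errors print one machine-parsable line to
stderr: `error:<code>: <message>`. Display rounding is half-even at 4
decimals by default (`--precision`).

## Multi-level directory layout

Each folder is one node of the assessment hierarchy and holds one
`<FolderName>_combined.csv` (objects in rows; a `Weight` column with the
node's sibling weight; proposition columns). Internal folders contain
subfolders; leaf folders contain one or more `Evidence*.csv` files with the
same row/column layout, whose `Weight` column holds the source's weight.
Fusion runs bottom-up per object — leaf evidence first, then each node's
fused result feeds its parent as a weighted (possibly incomplete) body of
evidence — and every `*_combined.csv` is rewritten with the fused beliefs
plus an `Uncertainty` column. The root result lands in
`Objects_combined.csv`.

Note: a child's unassigned belief is propagated upward as evidence
incompleteness, and sibling weights are normalized within each parent.
Sequential Yager fusion of more than two bodies is order-dependent; the
fold is left-to-right in input order.

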