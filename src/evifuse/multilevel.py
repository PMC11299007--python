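"""Bottom-up fusion over a tree-structured assessment framework stored as a
directory of CSV files.

Directory dialect
-----------------
Every folder (node) contains exactly one ``<FolderName>_combined.csv``.
Internal folders additionally contain subfolders (the sub-attributes); leaf
folders instead contain one or more ``Evidence*.csv`` files (the sources).

All files share the same layout: the first column holds the object labels,
a ``Weight`` column holds the node's sibling weight (combined files,
constant down the column) or the source's evidence weight (evidence files),
and the remaining columns are the shared propositions.  Combined files may
carry a trailing ``Uncertainty`` column; it is ignored on input and
(re)written after fusion.

Fusion proceeds per object: each leaf fuses its evidence rows with the
weighted recursion; each internal node treats every child's fused result as
one (possibly incomplete) body of evidence weighted by the child's
normalized sibling weight, and fuses upward.  A child's unassigned belief
is carried up as evidence incompleteness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import EvidenceBody, Frame, validate_evidence
from .engine import FusionResult, er_fuse
from .errors import EviFuseError, InputFormatError, ValidationError
from .tableio import UNCERTAINTY_COLUMN, WEIGHT_COLUMN, parse_belief_cell

logger = logging.getLogger(__name__)

COMBINED_SUFFIX = "_combined.csv"
EVIDENCE_GLOB = "Evidence*.csv"


@dataclass
class EvidenceLeafTable:
    """One evidence file of a leaf: per-object belief rows + one weight."""

    name: str
    path: Path
    weight: float
    rows: dict[str, EvidenceBody]  # object label -> body


@dataclass
class TreeNode:
    """One attribute in the assessment hierarchy."""

    name: str
    path: Path
    weight: float
    children: list["TreeNode"] = field(default_factory=list)
    evidence_tables: list[EvidenceLeafTable] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class AttributeTree:
    """A validated hierarchy plus the object list and frame shared by every
    file in it."""

    root: TreeNode
    objects: tuple[str, ...]
    frame: Frame


FusionTable = dict[str, FusionResult]  # object label -> result
TreeResults = dict[str, FusionTable]  # node path (relative, "/"-joined) -> table


def _node_key(node: TreeNode, root: TreeNode) -> str:
    rel = node.path.relative_to(root.path.parent)
    return "/".join(rel.parts)


def _read_node_csv(path: Path):
    """Parse one tree CSV into (objects, propositions, weights, beliefs)."""
    try:
        df = pd.read_csv(path, dtype=object, encoding="utf-8")
    except FileNotFoundError:
        raise InputFormatError(f"file not found: {path}") from None
    except Exception as exc:
        raise InputFormatError(f"cannot parse {path}: {exc}") from exc
    if df.empty or df.shape[1] < 2:
        raise InputFormatError(f"empty or header-only table in {path}")
    columns = [str(c) for c in df.columns]
    if WEIGHT_COLUMN not in columns:
        raise InputFormatError(f"missing {WEIGHT_COLUMN!r} column in {path}")
    label_col = columns[0]
    prop_cols = [
        c
        for c in columns
        if c not in (label_col, WEIGHT_COLUMN, UNCERTAINTY_COLUMN)
    ]
    if not prop_cols:
        raise InputFormatError(f"no proposition columns in {path}")
    objects = tuple(str(v) for v in df[label_col])
    if len(set(objects)) != len(objects):
        raise InputFormatError(f"duplicate object labels in {path}")
    weights = [
        parse_belief_cell(v, where=f"{path} column 'Weight'")
        for v in df[WEIGHT_COLUMN]
    ]
    beliefs = {}
    for i, obj in enumerate(objects):
        row = df.iloc[i]
        beliefs[obj] = [
            parse_belief_cell(row[c], where=f"{path} object {obj!r}, column {c!r}")
            for c in prop_cols
        ]
    return objects, tuple(prop_cols), weights, beliefs


def _check_consistent(path, objects, props, ref_objects, ref_props, ref_path):
    if props != ref_props:
        raise ValidationError(
            f"proposition headers in {path} ({list(props)}) differ from "
            f"{ref_path} ({list(ref_props)})"
        )
    if objects != ref_objects:
        raise ValidationError(
            f"object list in {path} ({list(objects)}) differs from "
            f"{ref_path} ({list(ref_objects)})"
        )


def load_tree_from_directory(path: Union[str, Path]) -> AttributeTree:
    """Load and validate an assessment hierarchy from disk.

    The root folder's name is conventionally "Objects" but not enforced.
    Children are visited in lexicographic folder-name order.
    """
    root_path = Path(path)
    if not root_path.is_dir():
        raise InputFormatError(f"not a directory: {root_path}")

    ref: dict = {"objects": None, "props": None, "path": None}

    def load_node(folder: Path) -> TreeNode:
        combined = folder / f"{folder.name}{COMBINED_SUFFIX}"
        if not combined.is_file():
            raise ValidationError(
                f"missing combined file {combined.name!r} in folder {folder}"
            )
        objects, props, weights, _ = _read_node_csv(combined)
        if ref["objects"] is None:
            ref.update(objects=objects, props=props, path=combined)
        else:
            _check_consistent(
                combined, objects, props, ref["objects"], ref["props"], ref["path"]
            )
        node_weight = float(weights[0]) if weights else 1.0
        if node_weight < 0:
            raise ValidationError(f"negative node weight in {combined}")
        node = TreeNode(name=folder.name, path=folder, weight=node_weight)

        subfolders = sorted(
            (p for p in folder.iterdir() if p.is_dir()), key=lambda p: p.name
        )
        evidence_files = sorted(folder.glob(EVIDENCE_GLOB), key=lambda p: p.name)
        if subfolders:
            node.children = [load_node(sub) for sub in subfolders]
        else:
            if not evidence_files:
                raise ValidationError(
                    f"leaf folder {folder} has no {EVIDENCE_GLOB} files"
                )
            for ev_path in evidence_files:
                objects, props, weights, beliefs = _read_node_csv(ev_path)
                _check_consistent(
                    ev_path, objects, props, ref["objects"], ref["props"], ref["path"]
                )
                rows = {}
                for obj in objects:
                    try:
                        rows[obj] = validate_evidence(
                            beliefs[obj], label=f"{ev_path.name}:{obj}"
                        )
                    except ValidationError as exc:
                        raise ValidationError(f"{exc} (file {ev_path})") from exc
                node.evidence_tables.append(
                    EvidenceLeafTable(
                        name=ev_path.stem,
                        path=ev_path,
                        weight=float(weights[0]) if weights else 1.0,
                        rows=rows,
                    )
                )
        return node

    root = load_node(root_path)
    return AttributeTree(
        root=root, objects=ref["objects"], frame=Frame(ref["props"])
    )


def _fuse_node(
    node: TreeNode, tree: AttributeTree, results: TreeResults
) -> FusionTable:
    key = _node_key(node, tree.root)
    table: FusionTable = {}
    if node.is_leaf:
        weights = [t.weight for t in node.evidence_tables]
        for obj in tree.objects:
            bodies = [t.rows[obj] for t in node.evidence_tables]
            try:
                table[obj] = er_fuse(bodies, weights, tree.frame)
            except EviFuseError as exc:
                raise type(exc)(f"{exc} (node {key}, object {obj!r})") from exc
    else:
        child_tables = [_fuse_node(child, tree, results) for child in node.children]
        weights = [child.weight for child in node.children]
        for obj in tree.objects:
            bodies = [
                ct[obj].as_evidence(label=child.name)
                for ct, child in zip(child_tables, node.children)
            ]
            try:
                table[obj] = er_fuse(bodies, weights, tree.frame)
            except EviFuseError as exc:
                raise type(exc)(f"{exc} (node {key}, object {obj!r})") from exc
    results[key] = table
    return table


def fuse_tree(tree: AttributeTree) -> TreeResults:
    """Fuse every node bottom-up; results for all nodes are retained,
    keyed by "/"-joined path relative to the root folder."""
    results: TreeResults = {}
    _fuse_node(tree.root, tree, results)
    return results


def write_combined_files(
    tree: AttributeTree, results: TreeResults, precision: int = 4
) -> None:
    """Rewrite every node's ``<name>_combined.csv`` with its fused beliefs.

    Rows are objects, columns are propositions plus ``Uncertainty``; the
    node's sibling weight column is preserved.  Deterministic, so re-running
    fusion rewrites identical bytes.
    """
    for node in tree.root.walk():
        key = _node_key(node, tree.root)
        table = results[key]
        records = []
        for obj in tree.objects:
            res = table[obj]
            row = {"Object": obj, WEIGHT_COLUMN: node.weight}
            for prop, val in zip(tree.frame.propositions, res.beliefs):
                row[prop] = round(float(val), precision)
            row[UNCERTAINTY_COLUMN] = round(float(res.uncertainty), precision)
            records.append(row)
        df = pd.DataFrame.from_records(records)
        out = node.path / f"{node.name}{COMBINED_SUFFIX}"
        df.to_csv(out, index=False, encoding="utf-8")


def multi_level_fuse(path: Union[str, Path]) -> FusionTable:
    """Load a tree, fuse it, rewrite all combined files, and return the
    root-level (whole-object) results."""
    tree = load_tree_from_directory(path)
    results = fuse_tree(tree)
    write_combined_files(tree, results)
    return results[_node_key(tree.root, tree.root)]
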