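import numpy as np
import pytest

from evifuse import (
    Frame,
    InputFormatError,
    ValidationError,
    er_fuse,
    fuse_tree,
    load_tree_from_directory,
    multi_level_fuse,
    validate_evidence,
    write_combined_files,
)

from .conftest import build_flat_tree, write_tree_csv, zeros_combined

INSTITUTION_OBJECTS = ("D", "E", "F")
INSTITUTION_GRADES = ("Excellent", "Good", "Average", "Poor", "Worst")

# deterministic survey-style rows for the two-level institution fixture
STUDENT_ROWS = {
    "D": [0.30, 0.40, 0.20, 0.05, 0.05],
    "E": [0.10, 0.30, 0.40, 0.10, 0.10],
    "F": [0.50, 0.30, 0.10, 0.05, 0.05],
}
FACULTY_ROWS = {
    "D": [0.25, 0.35, 0.25, 0.10, 0.05],
    "E": [0.15, 0.25, 0.35, 0.15, 0.10],
    "F": [0.45, 0.35, 0.10, 0.05, 0.00],
}


def build_institution_tree(root):
    """Two-level hierarchy: Objects/{Research,Teaching}/{two leaves each},
    student weight 10, faculty weight 8, all attribute weights 1."""
    objects_dir = root / "Objects"
    leaves = {
        "Research": ("Research_Funding", "Research_Outcomes"),
        "Teaching": ("Teaching_Materials", "Teaching_Methods"),
    }
    objects_dir.mkdir()
    zeros_combined(objects_dir, "Objects", INSTITUTION_OBJECTS, INSTITUTION_GRADES)
    for mid, leaf_names in leaves.items():
        mid_dir = objects_dir / mid
        mid_dir.mkdir()
        zeros_combined(mid_dir, mid, INSTITUTION_OBJECTS, INSTITUTION_GRADES, weight=1.0)
        for leaf_name in leaf_names:
            leaf_dir = mid_dir / leaf_name
            leaf_dir.mkdir()
            zeros_combined(
                leaf_dir, leaf_name, INSTITUTION_OBJECTS, INSTITUTION_GRADES, weight=1.0
            )
            for fname, rows, weight in (
                ("Evidence1_Student.csv", STUDENT_ROWS, 10),
                ("Evidence2_Faculty.csv", FACULTY_ROWS, 8),
            ):
                write_tree_csv(
                    leaf_dir / fname,
                    INSTITUTION_OBJECTS,
                    INSTITUTION_GRADES,
                    [weight] * 3,
                    [rows[obj] for obj in INSTITUTION_OBJECTS],
                )
    return objects_dir


class TestLoadTree:
    def test_institution_layout(self, tmp_path):
        tree = load_tree_from_directory(build_institution_tree(tmp_path))
        assert tree.objects == INSTITUTION_OBJECTS
        assert tree.frame.propositions == INSTITUTION_GRADES
        assert len(tree.root.children) == 2
        leaves = [n for n in tree.root.walk() if n.is_leaf]
        assert len(leaves) == 4
        assert all(len(leaf.evidence_tables) == 2 for leaf in leaves)
        assert leaves[0].evidence_tables[0].weight == 10.0

    def test_depth_one_layout(self, tmp_path):
        objects_dir = build_flat_tree(
            tmp_path,
            ("X", "Y"),
            ("Good", "Bad"),
            {"X": [[0.6, 0.3], [0.2, 0.7]], "Y": [[0.1, 0.8], [0.5, 0.4]]},
            [3, 1],
        )
        tree = load_tree_from_directory(objects_dir)
        assert len(tree.root.children) == 1
        assert tree.root.children[0].is_leaf

    def test_missing_combined_file(self, tmp_path):
        objects_dir = build_institution_tree(tmp_path)
        (objects_dir / "Research" / "Research_combined.csv").unlink()
        with pytest.raises(ValidationError, match="Research"):
            load_tree_from_directory(objects_dir)

    def test_mismatched_propositions_named(self, tmp_path):
        objects_dir = build_institution_tree(tmp_path)
        bad = objects_dir / "Teaching" / "Teaching_Methods" / "Evidence2_Faculty.csv"
        write_tree_csv(
            bad,
            INSTITUTION_OBJECTS,
            ("Wrong", "Headers", "Here", "Now", "Too"),
            [8] * 3,
            [FACULTY_ROWS[o] for o in INSTITUTION_OBJECTS],
        )
        with pytest.raises(ValidationError, match="Evidence2_Faculty"):
            load_tree_from_directory(objects_dir)

    def test_mismatched_objects(self, tmp_path):
        objects_dir = build_institution_tree(tmp_path)
        bad = objects_dir / "Research" / "Research_Funding" / "Evidence1_Student.csv"
        write_tree_csv(
            bad,
            ("D", "E", "G"),
            INSTITUTION_GRADES,
            [10] * 3,
            [STUDENT_ROWS[o] for o in INSTITUTION_OBJECTS],
        )
        with pytest.raises(ValidationError, match="object list"):
            load_tree_from_directory(objects_dir)

    def test_empty_leaf_folder(self, tmp_path):
        objects_dir = build_institution_tree(tmp_path)
        leaf = objects_dir / "Research" / "Research_Funding"
        for f in leaf.glob("Evidence*.csv"):
            f.unlink()
        with pytest.raises(ValidationError, match="Evidence"):
            load_tree_from_directory(objects_dir)

    def test_not_a_directory(self, tmp_path):
        with pytest.raises(InputFormatError):
            load_tree_from_directory(tmp_path / "missing")


class TestFuseTree:
    def test_flat_tree_equals_direct_er_fuse(self, tmp_path):
        evidence = {
            "X": [[0.6, 0.3], [0.2, 0.7]],
            "Y": [[0.1, 0.8], [0.5, 0.4]],
        }
        weights = [3, 1]
        objects_dir = build_flat_tree(
            tmp_path, ("X", "Y"), ("Good", "Bad"), evidence, weights
        )
        tree = load_tree_from_directory(objects_dir)
        results = fuse_tree(tree)
        frame = Frame(("Good", "Bad"))
        for obj in ("X", "Y"):
            # root fuses one child carrying the leaf result at weight 1,
            # which is the identity, so root == leaf == direct er_fuse
            direct = er_fuse(
                [validate_evidence(r) for r in evidence[obj]], weights, frame
            )
            for key in ("Objects", "Objects/Panel"):
                got = results[key][obj]
                np.testing.assert_array_equal(got.beliefs, direct.beliefs)
                assert got.uncertainty == direct.uncertainty

    def test_two_level_matches_manual_bottom_up_construction(self, tmp_path):
        # oracle: replay the propagation by hand with direct er_fuse calls;
        # identical evidence in every leaf makes the chain easy to rebuild
        row = [0.5, 0.3, 0.1, 0.1, 0.0]
        objects_dir = build_institution_tree(tmp_path)
        for leaf in objects_dir.rglob("Evidence*.csv"):
            weight = 10 if "Student" in leaf.name else 8
            write_tree_csv(
                leaf,
                INSTITUTION_OBJECTS,
                INSTITUTION_GRADES,
                [weight] * 3,
                [row for _ in INSTITUTION_OBJECTS],
            )
        tree = load_tree_from_directory(objects_dir)
        results = fuse_tree(tree)
        frame = Frame(INSTITUTION_GRADES)
        body = validate_evidence(row)
        leaf_res = er_fuse([body, body], [10, 8], frame)
        mid_res = er_fuse([leaf_res.as_evidence()] * 2, [1, 1], frame)
        root_res = er_fuse([mid_res.as_evidence()] * 2, [1, 1], frame)
        np.testing.assert_allclose(
            results["Objects/Research"]["D"].beliefs, mid_res.beliefs, atol=1e-12
        )
        np.testing.assert_allclose(
            results["Objects"]["D"].beliefs, root_res.beliefs, atol=1e-12
        )
        assert results["Objects"]["D"].uncertainty == pytest.approx(
            root_res.uncertainty, abs=1e-12
        )

    def test_institution_roots_conserve_mass(self, tmp_path):
        tree = load_tree_from_directory(build_institution_tree(tmp_path))
        results = fuse_tree(tree)
        for node_key, table in results.items():
            for obj, res in table.items():
                assert res.beliefs.sum() + res.uncertainty == pytest.approx(
                    1.0, abs=1e-9
                ), (node_key, obj)

    def test_object_isolation(self, tmp_path):
        # permuting object rows consistently permutes outputs identically
        evidence = {
            "X": [[0.6, 0.3], [0.2, 0.7]],
            "Y": [[0.1, 0.8], [0.5, 0.4]],
        }
        d1 = build_flat_tree(
            tmp_path / "a", ("X", "Y"), ("Good", "Bad"), evidence, [3, 1]
        )
        d2 = build_flat_tree(
            tmp_path / "b", ("Y", "X"), ("Good", "Bad"), evidence, [3, 1]
        )
        r1 = fuse_tree(load_tree_from_directory(d1))
        r2 = fuse_tree(load_tree_from_directory(d2))
        for obj in ("X", "Y"):
            np.testing.assert_array_equal(
                r1["Objects"][obj].beliefs, r2["Objects"][obj].beliefs
            )


class TestWriteCombinedFiles:
    def test_root_file_rewritten_with_fused_rows(self, tmp_path):
        objects_dir = build_institution_tree(tmp_path)
        root_results = multi_level_fuse(objects_dir)
        text = (objects_dir / "Objects_combined.csv").read_text(encoding="utf-8")
        lines = text.strip().splitlines()
        assert len(lines) == 1 + len(INSTITUTION_OBJECTS)
        header = lines[0].split(",")
        assert header[:2] == ["Object", "Weight"]
        assert header[2:7] == list(INSTITUTION_GRADES)
        assert header[7] == "Uncertainty"
        first = lines[1].split(",")
        assert first[0] == "D"
        written = [float(v) for v in first[2:8]]
        assert sum(written) == pytest.approx(1.0, abs=1e-3)
        np.testing.assert_allclose(
            written[:5], root_results["D"].beliefs, atol=5e-5
        )

    def test_rerun_is_idempotent(self, tmp_path):
        objects_dir = build_institution_tree(tmp_path)
        multi_level_fuse(objects_dir)
        first = {
            p: p.read_text(encoding="utf-8")
            for p in objects_dir.rglob("*_combined.csv")
        }
        multi_level_fuse(objects_dir)
        second = {
            p: p.read_text(encoding="utf-8")
            for p in objects_dir.rglob("*_combined.csv")
        }
        assert first == second

    def test_all_nodes_written(self, tmp_path):
        objects_dir = build_institution_tree(tmp_path)
        tree = load_tree_from_directory(objects_dir)
        results = fuse_tree(tree)
        write_combined_files(tree, results)
        combined = list(objects_dir.rglob("*_combined.csv"))
        assert len(combined) == 7  # root + 2 mid + 4 leaves
        for path in combined:
            assert "Uncertainty" in path.read_text(encoding="utf-8").splitlines()[0]
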