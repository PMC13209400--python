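"""KEGG-module completeness categories, score profiles, UPGMA."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pankit.io import ModuleDefinition
from pankit.kegg import (
    CompletenessCategory,
    completeness_matrix,
    module_completeness,
    profile_distance,
    upgma,
)

FIVE_STEP = ModuleDefinition(
    "M001",
    tuple(
        frozenset({f"K{10 + i:05d}", f"K{20 + i:05d}"}) for i in range(5)
    ),
)


def straight_line_completeness(module, kos):
    """Independent re-implementation of the category truth table."""
    missing = 0
    any_present = False
    for group in module.steps:
        hit = any(k in kos for k in group)
        missing += not hit
    any_present = any(k in kos for k in module.all_kos)
    if not any_present:
        return "absent"
    if missing == 0:
        return "complete"
    if missing in (1, 2):
        return "almost_complete"
    return "partially_complete"


class TestModuleCompleteness:
    def test_all_steps_satisfied_is_complete(self):
        kos = {f"K{10 + i:05d}" for i in range(5)}
        result = module_completeness(FIVE_STEP, kos)
        assert result.category == CompletenessCategory.COMPLETE
        assert result.n_missing == 0
        assert result.score == 3

    def test_two_missing_steps_is_almost_complete(self):
        kos = {f"K{10 + i:05d}" for i in range(3)}  # steps 3, 4 unsatisfied
        result = module_completeness(FIVE_STEP, kos)
        assert result.category == CompletenessCategory.ALMOST_COMPLETE
        assert result.n_missing == 2
        assert result.score == 2

    def test_three_missing_steps_is_partially_complete(self):
        kos = {f"K{10 + i:05d}" for i in range(2)}
        result = module_completeness(FIVE_STEP, kos)
        assert result.category == CompletenessCategory.PARTIALLY_COMPLETE
        assert result.n_missing == 3
        assert result.score == 1

    def test_no_module_ko_is_absent(self):
        result = module_completeness(FIVE_STEP, {"K99999"})
        assert result.category == CompletenessCategory.ABSENT
        assert result.score == 0

    def test_alternative_ko_satisfies_step(self):
        kos = {f"K{20 + i:05d}" for i in range(5)}  # second alternative each
        assert (
            module_completeness(FIVE_STEP, kos).category
            == CompletenessCategory.COMPLETE
        )

    def test_category_truth_table_against_straight_line_oracle(self):
        rng = np.random.default_rng(0)
        all_kos = sorted(FIVE_STEP.all_kos) + ["K99990", "K99991"]
        for _ in range(300):
            kos = {k for k in all_kos if rng.random() < 0.4}
            expected = straight_line_completeness(FIVE_STEP, kos)
            got = module_completeness(FIVE_STEP, kos).category.name.lower()
            assert got == expected, sorted(kos)

    def test_adding_kos_never_decreases_score(self):
        rng = np.random.default_rng(1)
        pool = sorted(FIVE_STEP.all_kos)
        for _ in range(50):
            kos = {k for k in pool if rng.random() < 0.3}
            before = module_completeness(FIVE_STEP, kos).score
            extra = set(rng.choice(pool, size=2))
            after = module_completeness(FIVE_STEP, kos | extra).score
            assert after >= before

    def test_non_monotone_score_mapping_rejected(self):
        bad = {
            CompletenessCategory.ABSENT: 0,
            CompletenessCategory.PARTIALLY_COMPLETE: 2,
            CompletenessCategory.ALMOST_COMPLETE: 1,
            CompletenessCategory.COMPLETE: 3,
        }
        with pytest.raises(ValueError):
            module_completeness(FIVE_STEP, set(), scores=bad)


class TestCompletenessMatrix:
    def test_empty_ko_set_gives_zero_column(self):
        kos = {"gA": set(FIVE_STEP.all_kos), "gB": set()}
        matrix = completeness_matrix(kos, [FIVE_STEP])
        assert (matrix["gB"] == 0).all()
        assert (matrix["gA"] == 3).all()

    def test_identical_ko_sets_give_identical_columns(self):
        shared = {"K00010", "K00011"}
        matrix = completeness_matrix(
            {"gA": set(shared), "gB": set(shared)}, [FIVE_STEP]
        )
        assert (matrix["gA"] == matrix["gB"]).all()

    def test_double_entry_per_cell(self):
        rng = np.random.default_rng(2)
        modules = [FIVE_STEP] + [
            ModuleDefinition(
                f"M{j:03d}",
                tuple(
                    frozenset({f"K{100 * j + i:05d}"}) for i in range(4)
                ),
            )
            for j in range(2, 5)
        ]
        pool = sorted({k for m in modules for k in m.all_kos})
        genome_kos = {
            f"g{i}": {k for k in pool if rng.random() < 0.5} for i in range(5)
        }
        matrix = completeness_matrix(genome_kos, modules)
        score_of = {"absent": 0, "partially_complete": 1, "almost_complete": 2, "complete": 3}
        for module in modules:
            for genome, kos in genome_kos.items():
                expected = score_of[straight_line_completeness(module, kos)]
                assert matrix.loc[module.module_id, genome] == expected


class TestProfileDistance:
    def test_identical_columns_are_zero_apart(self):
        matrix = pd.DataFrame({"gA": [1, 2], "gB": [1, 2]}, index=["m1", "m2"])
        dist = profile_distance(matrix)
        assert dist.loc["gA", "gB"] == 0.0

    def test_pythagorean_example(self):
        matrix = pd.DataFrame({"gA": [0, 0], "gB": [3, 4]}, index=["m1", "m2"])
        assert profile_distance(matrix).loc["gA", "gB"] == 5.0

    def test_triangle_inequality_on_random_profiles(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(
            rng.integers(0, 4, size=(6, 8)).astype(float),
            columns=[f"g{i}" for i in range(8)],
        )
        dist = profile_distance(matrix).to_numpy()
        n = dist.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert dist[i, j] <= dist[i, k] + dist[k, j] + 1e-12


class TestUpgma:
    def test_two_leaves(self):
        dist = pd.DataFrame(
            [[0.0, 4.0], [4.0, 0.0]], index=["A", "B"], columns=["A", "B"]
        )
        tree = upgma(dist)
        assert tree.merges == ((("A",), ("B",), 2.0),)
        assert tree.newick() == "(A:2,B:2);"

    def test_three_leaf_hand_computation(self):
        labels = ["A", "B", "C"]
        dist = pd.DataFrame(
            [[0.0, 2.0, 6.0], [2.0, 0.0, 6.0], [6.0, 6.0, 0.0]],
            index=labels, columns=labels,
        )
        tree = upgma(dist)
        (l1, r1, h1), (l2, r2, h2) = tree.merges
        assert (l1, r1, h1) == (("A",), ("B",), 1.0)
        assert {l2, r2} == {("A", "B"), ("C",)}
        assert h2 == 3.0

    def test_ultrametric_input_reproduced_exactly(self):
        # cophenetic distances of an ultrametric matrix equal the input
        labels = ["A", "B", "C", "D"]
        dist = pd.DataFrame(
            [
                [0.0, 2.0, 8.0, 8.0],
                [2.0, 0.0, 8.0, 8.0],
                [8.0, 8.0, 0.0, 4.0],
                [8.0, 8.0, 4.0, 0.0],
            ],
            index=labels, columns=labels,
        )
        tree = upgma(dist)
        assert tree.cophenetic().loc[labels, labels].equals(dist)

    def test_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(4)
        points = rng.random((7, 3))
        diff = points[:, None, :] - points[None, :, :]
        dmat = np.sqrt((diff ** 2).sum(axis=2))
        labels = [f"g{i}" for i in range(7)]
        dist = pd.DataFrame(dmat, index=labels, columns=labels)
        tree = upgma(dist)
        expected = squareform(cophenet(average(squareform(dmat))))
        got = tree.cophenetic().loc[labels, labels].to_numpy()
        assert np.allclose(got, expected)

    def test_heights_nondecreasing(self, small_bundle):
        rng = np.random.default_rng(5)
        matrix = pd.DataFrame(
            rng.integers(0, 4, size=(10, 6)).astype(float),
            columns=[f"g{i}" for i in range(6)],
        )
        tree = upgma(profile_distance(matrix))
        heights = [h for _, _, h in tree.merges]
        assert heights == sorted(heights)

    def test_newick_parses_with_biopython(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        labels = ["A", "B", "C"]
        dist = pd.DataFrame(
            [[0.0, 2.0, 6.0], [2.0, 0.0, 6.0], [6.0, 6.0, 0.0]],
            index=labels, columns=labels,
        )
        tree = Phylo.read(StringIO(upgma(dist).newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == labels

    def test_vent_genomes_merge_first_on_planted_modules(self):
        # two vent genomes share three vent-only modules absent in the
        # other genomes, whose profiles are deliberately perturbed
        vent_profile = [3, 3, 3, 3, 3, 3]
        genome_kos_scores = {
            "V1": vent_profile,
            "V2": vent_profile,
            "N1": [3, 2, 3, 0, 0, 0],
            "N2": [2, 3, 3, 0, 0, 0],
            "N3": [3, 3, 2, 0, 0, 0],
        }
        matrix = pd.DataFrame(genome_kos_scores, index=[f"m{i}" for i in range(6)])
        tree = upgma(profile_distance(matrix.astype(float)))
        first_left, first_right, _ = tree.merges[0]
        assert sorted(first_left + first_right) == ["V1", "V2"]

    def test_asymmetric_input_rejected(self):
        dist = pd.DataFrame(
            [[0.0, 1.0], [2.0, 0.0]], index=["A", "B"], columns=["A", "B"]
        )
        with pytest.raises(ValueError):
            upgma(dist)
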