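"""Fisher exact tests, BH adjustment, and environment association."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from pankit.association import (
    ContingencyTable2x2,
    bh_adjust,
    environment_association,
    fisher_exact_2x2,
    is_below_alpha,
)
from pankit.io import Environment

from conftest import make_metadata


def enumeration_fisher(table: ContingencyTable2x2) -> float:
    """Independent oracle: enumerate every table with the same margins."""
    r1, r2 = table.n_htv, table.n_nonhtv
    k = table.a + table.c
    support = np.arange(max(0, k - r2), min(r1, k) + 1)
    pmf = hypergeom.pmf(support, r1 + r2, k, r1)
    observed = pmf[support == table.a][0]
    return float(pmf[pmf <= observed * (1 + 1e-7)].sum())


class TestFisherExact:
    def test_htv_specific_pattern(self):
        # present in both of 2 vent genomes, absent from all 14 others
        assert fisher_exact_2x2(ContingencyTable2x2(2, 0, 0, 14)) == pytest.approx(
            1 / 120
        )

    def test_absent_everywhere_is_uninformative(self):
        assert fisher_exact_2x2(ContingencyTable2x2(0, 2, 0, 14)) == 1.0

    def test_balanced_table(self):
        assert fisher_exact_2x2(ContingencyTable2x2(1, 1, 7, 7)) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 1, 1, 1)

    def test_matches_enumeration_oracle_all_margins(self):
        # exhaustive over every table with both group sizes <= 20
        for r1 in range(1, 21):
            for r2 in range(1, 21):
                for k in range(r1 + r2 + 1):
                    for a in range(max(0, k - r2), min(r1, k) + 1):
                        table = ContingencyTable2x2(a, r1 - a, k - a, r2 - (k - a))
                        assert fisher_exact_2x2(table) == pytest.approx(
                            enumeration_fisher(table), rel=1e-9
                        ), (r1, r2, k, a)

    def test_matches_scipy_on_sample(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, size=4)
            table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            if table.n_htv == 0 or table.n_nonhtv == 0:
                continue
            expected = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-6)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_unchanged(self):
        assert bh_adjust([0.5]) == [0.5]

    def test_worked_example_with_distinct_q(self):
        # m=4: sorted q = (4*.01/1, 4*.04/2, ...) with step-up minima
        assert bh_adjust([0.04, 0.01, 0.3, 1.0]) == pytest.approx(
            [0.08, 0.04, 0.4, 1.0]
        )

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.random(500)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p.tolist()) == pytest.approx(expected.tolist())

    def test_dominates_p_and_preserves_ranks(self):
        rng = np.random.default_rng(3)
        p = rng.random(100)
        q = np.array(bh_adjust(p.tolist()))
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEnvironmentAssociation:
    def test_planted_cluster_detected(self):
        meta = make_metadata(16, 2)
        rows = {"planted": [1, 1] + [0] * 14, "background": [1] * 10 + [0] * 6}
        matrix = pd.DataFrame.from_dict(
            rows, orient="index", columns=meta.genome_ids
        ).astype(bool)
        results = {r.cluster_id: r for r in environment_association(matrix, meta)}
        planted = results["planted"]
        assert planted.significant
        assert planted.direction == Environment.HTV
        assert planted.p == pytest.approx(1 / 120)

    def test_core_clusters_excluded(self):
        meta = make_metadata(16, 2)
        matrix = pd.DataFrame.from_dict(
            {"core": [1] * 16, "acc": [1, 0] * 8}, orient="index",
            columns=meta.genome_ids,
        ).astype(bool)
        results = environment_association(matrix, meta)
        assert {r.cluster_id for r in results} == {"acc"}

    def test_recovers_planted_associations_exactly(self, study_bundle):
        matrix, _, meta, truth = study_bundle
        results = environment_association(matrix, meta, alpha=0.05)
        htv = {r.cluster_id for r in results if r.direction == Environment.HTV}
        non = {r.cluster_id for r in results if r.direction == Environment.NONHTV}
        assert htv == truth.planted_htv
        assert non == truth.planted_nonhtv
        assert len(htv) == 57 and len(non) == 82

    def test_significant_count_invariant_under_column_permutation(
        self, small_bundle
    ):
        matrix, _, meta, _ = small_bundle
        results = environment_association(matrix, meta)
        n_sig = sum(r.significant for r in results)
        rng = np.random.default_rng(6)
        shuffled = matrix[list(rng.permutation(matrix.columns))]
        results2 = environment_association(shuffled, meta)
        assert sum(r.significant for r in results2) == n_sig

    def test_attainable_patterns_with_2v14_design(self):
        # enumerate every presence pattern: which are callable at 0.05?
        significant = set()
        for a in range(3):
            for c in range(15):
                if (a + c) in (0, 16):
                    continue
                p = fisher_exact_2x2(ContingencyTable2x2(a, 2 - a, c, 14 - c))
                if is_below_alpha(p, 0.05):
                    significant.add((a, c))
        htv_calls = {(a, c) for a, c in significant if a / 2 > c / 14}
        non_calls = {(a, c) for a, c in significant if c / 14 > a / 2}
        assert htv_calls == {(2, 0), (2, 1)}
        assert non_calls == {(0, 13), (0, 14)}

    def test_empty_group_rejected(self):
        meta = make_metadata(4, 0)
        matrix = pd.DataFrame.from_dict(
            {"c1": [1, 0, 1, 0]}, orient="index", columns=meta.genome_ids
        ).astype(bool)
        with pytest.raises(ValueError):
            environment_association(matrix, meta)

    def test_invalid_alpha_rejected(self, small_bundle):
        matrix, _, meta, _ = small_bundle
        with pytest.raises(ValueError):
            environment_association(matrix, meta, alpha=-1.0)
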