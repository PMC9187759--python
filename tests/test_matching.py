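import numpy as np
import pandas as pd
import pytest

from tnbcstrat import (
    ClinicalTable,
    ExpressionMatrix,
    cross_correlate,
    generate_cohort,
    generate_duplicate,
    match_samples,
    normalize_expression,
    verify_clinical,
)


def _matrix(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(arr.shape[0])],
            columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
        ),
        stage="normalized",
    )


@pytest.fixture
def random_matrix(rng):
    return _matrix(rng.standard_normal((200, 8)))


class TestCrossCorrelate:
    def test_self_correlation_diagonal_is_one(self, random_matrix):
        tab = cross_correlate(random_matrix, random_matrix)
        assert np.allclose(np.diag(tab.to_numpy()), 1.0, atol=1e-12)

    def test_permuted_copy_puts_one_at_permuted_entry(self, rng, random_matrix):
        perm = rng.permutation(8)
        b = _matrix(random_matrix.values.to_numpy()[:, perm], prefix="t")
        tab = cross_correlate(random_matrix, b)
        for target_pos, source_pos in enumerate(perm):
            assert np.isclose(tab.iloc[source_pos, target_pos], 1.0, atol=1e-12)

    def test_noisy_permutation_recovered_by_argmax(self, rng):
        a = _matrix(rng.standard_normal((200, 8)))
        perm = rng.permutation(8)
        noisy = a.values.to_numpy()[:, perm] + rng.normal(0, 0.3, (200, 8))
        b = _matrix(noisy, prefix="t")
        tab = cross_correlate(a, b)
        # exhaustive argmax over the 8x8 table recovers the permutation
        for target_pos, source_pos in enumerate(perm):
            assert tab.iloc[:, target_pos].idxmax() == a.sample_ids[source_pos]

    def test_too_few_shared_genes_is_error(self, rng):
        a = _matrix(rng.standard_normal((10, 3)))
        with pytest.raises(ValueError, match="shared genes"):
            cross_correlate(a, a, min_shared_genes=30)

    def test_invariant_under_common_gene_reordering(self, rng, random_matrix):
        b = _matrix(rng.standard_normal((200, 5)), prefix="t")
        tab1 = cross_correlate(random_matrix, b)
        order = rng.permutation(200)
        a2 = ExpressionMatrix(random_matrix.values.iloc[order], stage="normalized")
        b2 = ExpressionMatrix(b.values.iloc[order], stage="normalized")
        tab2 = cross_correlate(a2, b2)
        assert np.allclose(tab1.to_numpy(), tab2.to_numpy(), atol=1e-12)

    def test_zero_variance_sample_set_missing_with_warning(self, rng):
        a = _matrix(rng.standard_normal((50, 3)))
        vals = a.values.copy()
        vals["s1"] = 2.5
        b = ExpressionMatrix(vals, stage="normalized")
        with pytest.warns(UserWarning, match="zero-variance"):
            tab = cross_correlate(a, b)
        assert tab["s1"].isna().all()


class TestMatchSamples:
    def _table(self, rows, cols=3):
        return pd.DataFrame(
            rows, index=[f"q{i}" for i in range(len(rows))],
            columns=[f"t{j}" for j in range(cols)],
        )

    def test_clear_margin_reliable(self):
        res = match_samples(self._table([[0.95, 0.40, 0.38]]), margin_min=0.1)
        row = res.table.loc["q0"]
        assert row["best_match"] == "t0"
        assert np.isclose(row["margin"], 0.55)
        assert row["reliable"] and not row["excluded"]

    def test_narrow_margin_unreliable(self):
        res = match_samples(self._table([[0.60, 0.58, 0.10]]), margin_min=0.1)
        row = res.table.loc["q0"]
        assert not row["reliable"]
        assert row["excluded"] and row["exclusion_reason"] == "low margin"

    def test_collision_flagged_not_excluded(self):
        res = match_samples(
            self._table([[0.9, 0.2, 0.1], [0.95, 0.3, 0.2]]), margin_min=0.1
        )
        assert res.table["collision"].all()
        assert not res.table["excluded"].any()

    def test_fully_missing_row_is_unmatched(self):
        tab = self._table([[np.nan, np.nan, np.nan], [0.9, 0.1, 0.0]])
        res = match_samples(tab)
        assert res.table.loc["q0", "exclusion_reason"] == "unmatched"
        assert res.table.loc["q1", "reliable"]


class TestVerifyClinical:
    def _clin(self, ids, ages, sizes):
        return ClinicalTable(
            pd.DataFrame({"age": ages, "tumor_size": sizes}, index=ids)
        )

    def _matches(self):
        tab = pd.DataFrame(
            [[0.9, 0.1, 0.0]], index=["q0"], columns=["t0", "t1", "t2"]
        )
        return match_samples(tab)

    def test_agreeing_fields_pass(self):
        res = verify_clinical(
            self._matches(),
            self._clin(["q0"], [54], [2.1]),
            self._clin(["t0", "t1", "t2"], [54, 1, 1], [2.1, 1, 1]),
        )
        assert res.table.loc["q0", "clinical_ok"] == True  # noqa: E712
        assert not res.table.loc["q0", "excluded"]

    def test_age_disagreement_excludes(self):
        res = verify_clinical(
            self._matches(),
            self._clin(["q0"], [54], [2.1]),
            self._clin(["t0", "t1", "t2"], [71, 1, 1], [2.1, 1, 1]),
            age_tol=1.0,
        )
        row = res.table.loc["q0"]
        assert row["clinical_ok"] == False  # noqa: E712
        assert row["excluded"] and row["exclusion_reason"] == "clinical disagreement"

    def test_missing_fields_skipped(self):
        res = verify_clinical(
            self._matches(),
            self._clin(["q0"], [54], [np.nan]),
            self._clin(["t0", "t1", "t2"], [54, 1, 1], [np.nan, 1, 1]),
        )
        assert res.table.loc["q0", "clinical_ok"] == True  # noqa: E712

    def test_all_fields_missing_leaves_clinical_ok_missing(self):
        res = verify_clinical(
            self._matches(),
            self._clin(["q0"], [np.nan], [np.nan]),
            self._clin(["t0", "t1", "t2"], [np.nan, 1, 1], [np.nan, 1, 1]),
        )
        assert pd.isna(res.table.loc["q0", "clinical_ok"])


class TestEndToEndRecovery:
    def test_noiseless_duplicate_recovers_permutation_with_unit_correlation(self):
        matrix, clin, _ = generate_cohort(
            n_samples=12, n_background_genes=100, seed=5
        )
        dup = generate_duplicate(matrix, clin, noise_sd=0.0, permute_seed=6)
        tab = cross_correlate(
            normalize_expression(matrix), normalize_expression(dup.matrix)
        )
        res = match_samples(tab)
        for q, t in res.matched_pairs():
            assert dup.mapping[t] == q
        assert np.allclose(res.table["best_correlation"], 1.0, atol=1e-10)

    def test_noisy_recovery_across_seeds(self):
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            matrix, clin, _ = generate_cohort(
                n_samples=20, n_background_genes=200 - 180, seed=100 + seed
            )
            dup = generate_duplicate(
                matrix, clin, noise_sd=0.5, permute_seed=200 + seed
            )
            tab = cross_correlate(
                normalize_expression(matrix), normalize_expression(dup.matrix)
            )
            res = match_samples(tab)
            ok = all(dup.mapping[t] == q for q, t in res.matched_pairs())
            hits += ok and len(res.matched_pairs()) == 20
        assert hits == n_seeds
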