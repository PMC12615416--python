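"""Bulk DE stage: TPM arithmetic, filtering rules, NB Wald calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modscore import (
    BulkSimSpec,
    CountMatrix,
    DEGCallParams,
    call_degs,
    compute_tpm,
    nb_wald_test,
    overexpression_fold,
    prefilter_genes,
    simulate_bulk,
)


def _matrix(counts: dict, lengths, condition):
    df = pd.DataFrame(counts)
    return CountMatrix(
        counts=df,
        gene_lengths=pd.Series(lengths, index=df.index),
        condition=pd.Series(condition, index=df.columns),
    )


class TestTpm:
    def test_two_gene_hand_oracle(self):
        m = _matrix(
            {"s1": [10, 10]}, [1000, 2000], {"s1": "control"}
        )
        tpm = compute_tpm(m)
        assert tpm["s1"].tolist() == pytest.approx([666666.6667, 333333.3333], abs=0.01)

    def test_single_gene_forced_to_million(self):
        m = _matrix({"s1": [7]}, [123], {"s1": "control"})
        assert compute_tpm(m)["s1"].iloc[0] == pytest.approx(1e6)

    def test_uniform_counts_and_lengths_give_uniform_tpm(self):
        m = _matrix(
            {"s1": [5, 5, 5, 5]}, [800] * 4, {"s1": "control"}
        )
        assert compute_tpm(m)["s1"].tolist() == pytest.approx([250000.0] * 4)

    def test_columns_sum_to_million(self, tiny_counts):
        tpm = compute_tpm(tiny_counts)
        assert tpm.sum(axis=0).tolist() == pytest.approx([1e6] * 4)

    def test_all_zero_sample_errors(self):
        m = _matrix({"s1": [0, 0]}, [100, 100], {"s1": "control"})
        with pytest.raises(ValueError):
            compute_tpm(m)


class TestOverexpressionFold:
    def test_identical_groups_fold_one(self, tiny_counts):
        tpm = compute_tpm(tiny_counts)
        tpm.loc["gA"] = 16.36
        assert overexpression_fold(tpm, tiny_counts.condition, "gA") == pytest.approx(1.0)

    def test_reported_baseline_arithmetic(self, tiny_counts):
        # control mean 16.36, treated mean 1357.88 -> ~83-fold (direct division)
        tpm = compute_tpm(tiny_counts)
        tpm.loc["gA", ["c1", "c2"]] = 16.36
        tpm.loc["gA", ["t1", "t2"]] = 1357.88
        fold = overexpression_fold(tpm, tiny_counts.condition, "gA")
        assert fold == pytest.approx(83.0, abs=0.01)

    def test_planted_overexpression_recovered(self):
        # single planted gene so the library composition shifts only ~5%;
        # average the fold over seeds because one fold carries ~11% CV from
        # NB dispersion at n = 4
        folds = []
        for seed in range(8):
            spec = BulkSimSpec(
                n_genes=2000,
                planted_effects={"g00000": float(np.log2(100))},
                gene_lengths=[1000] * 2000,
                seed=seed,
            )
            m, _ = simulate_bulk(spec)
            folds.append(overexpression_fold(compute_tpm(m), m.condition, "g00000"))
        # TPM folds run slightly below count folds because the overexpressed
        # gene inflates the treated libraries' normalization denominator
        assert np.mean(folds) == pytest.approx(100.0, rel=0.15)

    def test_zero_control_mean_errors(self, tiny_counts):
        tpm = compute_tpm(tiny_counts)
        tpm.loc["gA", ["c1", "c2"]] = 0.0
        with pytest.raises(ZeroDivisionError):
            overexpression_fold(tpm, tiny_counts.condition, "gA")


class TestPrefilter:
    @pytest.mark.parametrize(
        "row, kept",
        [
            ([12, 11, 10, 10, 0, 0, 0, 0], True),  # 4 samples >= 10
            ([9, 9, 9, 9, 9, 9, 9, 9], False),  # none reach 10
            ([10, 10, 10, 0, 0, 0, 0, 0], False),  # only 3 qualify
        ],
    )
    def test_rule_on_examples(self, row, kept):
        cols = [f"s{i}" for i in range(8)]
        m = _matrix(
            {c: [v] for c, v in zip(cols, row)},
            [1000],
            {c: ("control" if i < 4 else "treated") for i, c in enumerate(cols)},
        )
        retained = prefilter_genes(m)
        assert (len(retained) == 1) is kept

    def test_min_samples_exceeding_n_samples_errors(self, tiny_counts):
        with pytest.raises(ValueError):
            prefilter_genes(tiny_counts, min_samples=10)

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 30, size=(500, 8)),
            index=[f"g{i}" for i in range(500)],
            columns=[f"s{i}" for i in range(8)],
        )
        m = CountMatrix(
            counts=counts,
            gene_lengths=pd.Series(1000, index=counts.index),
            condition=pd.Series(
                ["control"] * 4 + ["treated"] * 4, index=counts.columns
            ),
        )
        got = set(prefilter_genes(m))
        expected = {
            g
            for g, row in counts.iterrows()
            if sum(v >= 10 for v in row) >= 4
        }
        assert got == expected


class TestNbWald:
    def test_identical_groups_null_result(self):
        vals = [100, 105, 95, 100]
        m = _matrix(
            {f"s{i}": [v, 50] for i, v in enumerate(vals + vals)},
            [1000, 1000],
            {f"s{i}": ("control" if i < 4 else "treated") for i in range(8)},
        )
        res = nb_wald_test(m)
        assert res["log2fc"].tolist() == pytest.approx([0.0, 0.0], abs=1e-12)
        assert res["pvalue"].tolist() == pytest.approx([1.0, 1.0])

    def test_null_type_one_error_calibrated(self, null_bulk_de):
        frac = (null_bulk_de["pvalue"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_planted_effect_recovered_with_small_bias(self):
        effects = {f"g{i:05d}": 2.0 for i in range(200)}
        m, _ = simulate_bulk(BulkSimSpec(n_genes=2000, planted_effects=effects, seed=5))
        res = nb_wald_test(m)
        bias = res["log2fc"].iloc[:200].mean() - 2.0
        assert abs(bias) < 0.2

    def test_swapping_condition_labels_negates_log2fc(self, tiny_counts):
        res = nb_wald_test(tiny_counts)
        flipped = CountMatrix(
            counts=tiny_counts.counts,
            gene_lengths=tiny_counts.gene_lengths,
            condition=tiny_counts.condition.map(
                {"control": "treated", "treated": "control"}
            ),
        )
        res_f = nb_wald_test(flipped)
        assert np.allclose(res_f["log2fc"], -res["log2fc"])
        assert np.allclose(res_f["pvalue"], res["pvalue"])

    def test_scale_invariance_of_log2fc(self):
        m, _ = simulate_bulk(BulkSimSpec(n_genes=300, baseline_mean=200, seed=8))
        res = nb_wald_test(m)
        scaled_counts = m.counts.copy()
        scaled_counts["control_1"] = (scaled_counts["control_1"] * 3).astype(int)
        m2 = CountMatrix(
            counts=scaled_counts,
            gene_lengths=m.gene_lengths,
            condition=m.condition,
        )
        res2 = nb_wald_test(m2)
        high = res["base_mean"] >= 50
        assert np.abs(res2["log2fc"][high] - res["log2fc"][high]).max() < 0.05

    def test_bh_monotone_and_padj_at_least_p(self, null_bulk_de):
        t = null_bulk_de.sort_values("pvalue")
        assert (t["padj"] >= t["pvalue"] - 1e-12).all()
        assert (np.diff(t["padj"]) >= -1e-12).all()


class TestCallDegs:
    def _table(self, rows):
        return pd.DataFrame(
            rows, index=[f"g{i}" for i in range(len(rows))]
        ).assign(tested=True)

    def test_strict_boundary_semantics(self):
        t = self._table(
            [
                {"log2fc": 1.6, "padj": 0.049},  # called, up
                {"log2fc": -1.6, "padj": 0.01},  # called, down
                {"log2fc": 3.0, "padj": 0.05},  # padj not strictly below
                {"log2fc": 1.5, "padj": 0.001},  # |lfc| not strictly above
            ]
        )
        degs = call_degs(t, DEGCallParams())
        assert list(degs.index) == ["g0", "g1"]
        assert degs["direction"].tolist() == [1, -1]

    def test_matches_brute_force_comprehension(self):
        rng = np.random.default_rng(3)
        t = self._table(
            [
                {"log2fc": float(lfc), "padj": float(p)}
                for lfc, p in zip(
                    rng.normal(0, 2, 500), rng.uniform(0, 0.12, 500)
                )
            ]
        )
        params = DEGCallParams()
        degs = call_degs(t, params)
        expected = [
            g
            for g, row in t.iterrows()
            if row["padj"] < params.padj_cut and abs(row["log2fc"]) > params.lfc_cut
        ]
        assert list(degs.index) == expected

    @given(
        padj=st.floats(0, 1, allow_nan=False),
        lfc=st.floats(-6, 6, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_call_rule_is_the_predicate(self, padj, lfc):
        t = self._table([{"log2fc": lfc, "padj": padj}])
        called = len(call_degs(t, DEGCallParams())) == 1
        assert called == (padj < 0.05 and abs(lfc) > 1.5)

    def test_stringent_profile(self):
        t = self._table(
            [
                {"log2fc": 2.0, "padj": 1e-11},
                {"log2fc": 2.0, "padj": 1e-9},
            ]
        )
        degs = call_degs(t, DEGCallParams.stringent())
        assert list(degs.index) == ["g0"]
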