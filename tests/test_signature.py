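"""Normalization, DEG filtering, metric correlation and signature assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermaquant import signature, synthetic


class TestNormalizeCounts:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        _, sf = signature.normalize_counts(counts)
        assert np.allclose(sf, 1.0)

    def test_pure_depth_effect(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        norm, sf = signature.normalize_counts(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        assert np.allclose(norm["a"], norm["b"])

    def test_matches_bruteforce_median_of_ratios(self):
        """Independent re-derivation of the size factors on a random matrix."""
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.negative_binomial(10, 0.1, size=(50, 6)) + 1,
            columns=[f"s{i}" for i in range(6)],
        )
        _, sf = signature.normalize_counts(counts)
        # brute force: per-gene geometric mean, per-sample median of ratios
        expected = []
        logs = np.log(counts.to_numpy(dtype=float))
        geo = np.exp(logs.mean(axis=1))
        for j in range(counts.shape[1]):
            expected.append(np.median(counts.to_numpy()[:, j] / geo))
        assert np.allclose(sf.to_numpy(), expected)

    def test_no_universally_positive_gene_errors(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            signature.normalize_counts(counts)


class TestBHAdjust:
    def test_textbook_step_up_example(self):
        out = signature.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_all_ones(self):
        assert signature.bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(signature.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            signature.bh_adjust([0.5, 1.5])

    def test_matches_bruteforce_and_statsmodels(self):
        """Step-up definition re-derived by brute force; statsmodels agrees."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            got = signature.bh_adjust(p)
            m = len(p)
            brute = np.empty(m)
            order = np.argsort(p)
            for rank_pos, idx in enumerate(order):
                candidates = [
                    p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
                ]
                brute[idx] = min(1.0, min(candidates))
            assert np.allclose(got, brute, atol=1e-12)
            assert np.allclose(got, multipletests(p, method="fdr_bh")[1], atol=1e-12)


class TestCallDEGs:
    def test_toy_matrix_exactly_planted_genes_pass(self, toy_deg_matrix):
        table = signature.call_degs(toy_deg_matrix, ("ctrl", "treat"))
        assert set(table.index[table["passed"]]) == {"g_up", "g_down"}

    def test_boundary_gene_at_three_fails_strict_count_filter(self, toy_deg_matrix):
        table = signature.call_degs(toy_deg_matrix, ("ctrl", "treat"))
        row = table.loc["g_boundary"]
        assert row["mean_norm_count"] == pytest.approx(3.0)
        assert abs(row["log2fc"]) > np.log2(1.5)  # fails only the count clause
        assert not row["passed"]

    def test_flat_gene_zero_fold_change(self, toy_deg_matrix):
        table = signature.call_degs(toy_deg_matrix, ("ctrl", "treat"))
        assert table.loc["g_flat1", "log2fc"] == pytest.approx(0.0, abs=1e-9)
        assert table.loc["g_flat1", "p"] == 1.0

    def test_human_preset_raises_count_threshold(self, toy_deg_matrix):
        table = signature.call_degs(
            toy_deg_matrix, ("ctrl", "treat"), crit=signature.HUMAN_CRITERIA
        )
        # both planted genes still clear mean normalized count 250 > 4
        assert set(table.index[table["passed"]]) == {"g_up", "g_down"}

    def test_degenerate_group_size_rejected(self, toy_deg_matrix):
        m = signature.CountMatrix(
            counts=toy_deg_matrix.counts,
            groups=pd.Series(
                ["ctrl"] * 5 + ["treat"], index=toy_deg_matrix.counts.columns
            ),
        )
        with pytest.raises(ValueError):
            signature.call_degs(m, ("ctrl", "treat"))

    def test_null_calibration(self):
        """No planted genes, no group effect: pass fraction stays below α."""
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(12)]
        metrics = pd.DataFrame({"m": rng.normal(size=12)}, index=samples)
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=samples)
        fractions = []
        for rep in range(20):
            spec = synthetic.SignatureSpec(n_genes=500)
            m, _, _ = synthetic.generate_counts(spec, metrics, groups, seed=rep)
            table = signature.call_degs(m, ("a", "b"))
            fractions.append(table["passed"].mean())
        assert np.mean(fractions) <= 0.05 + 0.01


class TestCorrelateToMetric:
    def test_proportional_gene_r2_one(self):
        metric = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        norm = pd.DataFrame(
            {"a": [2.0], "b": [4.0], "c": [6.0], "d": [8.0]}, index=["g"]
        )
        res = signature.correlate_to_metric(norm, metric, scale="linear")
        assert res.loc["g", "r2"] == pytest.approx(1.0)
        assert res.loc["g", "sign"] == 1

    def test_constant_gene_r2_zero(self):
        metric = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        norm = pd.DataFrame({s: [5.0] for s in "abcd"}, index=["g"])
        res = signature.correlate_to_metric(norm, metric)
        assert res.loc["g", "r2"] == 0.0

    def test_constant_metric_rejected(self):
        metric = pd.Series([1.0] * 4, index=list("abcd"))
        norm = pd.DataFrame({s: [5.0, 1.0] for s in "abcd"}, index=["g", "h"])
        with pytest.raises(ValueError):
            signature.correlate_to_metric(norm, metric)

    def test_planted_gene_r2_recovered(self, cohort_count_matrix):
        matrix, metrics, truth = cohort_count_matrix
        norm, _ = signature.normalize_counts(matrix)
        res = signature.correlate_to_metric(norm, metrics["alignment"])
        assert res.loc[truth["gene"], "r2"].median() == pytest.approx(0.8, abs=0.1)


class TestBuildSignatures:
    @staticmethod
    def _signature_inputs(matrix, metrics):
        norm, _ = signature.normalize_counts(matrix)
        degs = signature.call_degs_pooled(matrix, control_group="saline")
        corr = {
            m: signature.correlate_to_metric(norm, metrics[m])
            for m in ("alignment", "thickness")
        }
        return corr, degs["passed"]

    def test_empty_deg_set_empty_signatures(self, cohort_count_matrix):
        matrix, metrics, _ = cohort_count_matrix
        corr, deg_pass = self._signature_inputs(matrix, metrics)
        none_pass = pd.Series(False, index=deg_pass.index)
        sigs = signature.build_signatures(
            corr, none_pass, {"alignment": 0.4, "thickness": 0.7}
        )
        assert all(len(s.genes) == 0 for s in sigs.values())

    def test_planted_alignment_genes_recovered(self, cohort_count_matrix):
        """Sensitivity and specificity ≥0.9 for the alignment signature."""
        matrix, metrics, truth = cohort_count_matrix
        corr, deg_pass = self._signature_inputs(matrix, metrics)
        sigs = signature.build_signatures(
            corr, deg_pass, {"alignment": 0.4, "thickness": 0.7}
        )
        hits = sigs["alignment"].genes
        planted = set(truth["gene"])
        background = set(matrix.genes) - planted
        sensitivity = len(hits & planted) / len(planted)
        specificity = 1.0 - len(hits & background) / len(background)
        assert sensitivity >= 0.9
        assert specificity >= 0.9

    def test_monotone_in_cutoff(self, cohort_count_matrix):
        matrix, metrics, _ = cohort_count_matrix
        corr, deg_pass = self._signature_inputs(matrix, metrics)
        sizes = [
            len(
                signature.build_signatures(corr, deg_pass, {"alignment": c})[
                    "alignment"
                ].genes
            )
            for c in (0.2, 0.4, 0.6, 0.8)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_unique_sets_pairwise_disjoint(self, cohort_count_matrix):
        matrix, metrics, _ = cohort_count_matrix
        corr, deg_pass = self._signature_inputs(matrix, metrics)
        sigs = signature.build_signatures(
            corr, deg_pass, {"alignment": 0.4, "thickness": 0.4}
        )
        uniq = [s.unique_genes for s in sigs.values()]
        assert uniq[0].isdisjoint(uniq[1])
        union_all = set().union(*(s.genes for s in sigs.values()))
        assert set().union(*uniq) <= union_all

    def test_unknown_metric_threshold_rejected(self, cohort_count_matrix):
        matrix, metrics, _ = cohort_count_matrix
        corr, deg_pass = self._signature_inputs(matrix, metrics)
        with pytest.raises(ValueError, match="unknown"):
            signature.build_signatures(corr, deg_pass, {"bogus": 0.4})


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30),
)
def test_bh_monotone_and_bounded(pvals):
    """BH output is within [min(p), 1] and preserves the p-value ordering."""
    adj = signature.bh_adjust(pvals)
    assert np.all(adj <= 1.0)
    assert np.all(adj >= np.asarray(pvals) - 1e-15)
    order = np.argsort(pvals, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)
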