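"""State calling, Welch tests, BH FDR, top-K selection, clustering order."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methtopo as mt
from methtopo.core import MethtopoError, MethylationMatrix, SampleSheet


def make_matrix(data, scale="M"):
    return MethylationMatrix(pd.DataFrame(data, dtype=float), scale=scale)


def make_sheet(groups):
    df = pd.DataFrame(
        {"group": groups, "platform": "A450K"},
        index=pd.Index([f"s{i}" for i in range(len(groups))], name="sample_id"),
    )
    return SampleSheet(df)


class TestGroupMeanM:
    def test_single_sample_group_is_identity(self):
        m = make_matrix({"s0": [1.0, -3.0]})
        sheet = make_sheet(["g"])
        pd.testing.assert_series_equal(
            mt.group_mean_m(m, sheet, "g"), m.values["s0"], check_names=False
        )

    def test_two_sample_mean(self):
        m = make_matrix({"s0": [1.0], "s1": [3.0]})
        assert mt.group_mean_m(m, make_sheet(["g", "g"]), "g").iloc[0] == 2.0

    def test_matches_direct_mean_oracle_with_missing_values(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(size=(30, 6))
        arr[rng.random(arr.shape) < 0.1] = np.nan
        m = make_matrix({f"s{i}": arr[:, i] for i in range(6)})
        got = mt.group_mean_m(m, make_sheet(["g"] * 6), "g").to_numpy()
        expected = np.nanmean(arr, axis=1)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_empty_group_rejected(self):
        m = make_matrix({"s0": [1.0]})
        with pytest.raises(MethtopoError):
            mt.group_mean_m(m, make_sheet(["g"]), "other")


class TestCallStates:
    @pytest.mark.parametrize(
        "mean, state", [(2.0, "hyper"), (0.0, "neither"), (-2.0, "hypo"),
                        (2.5, "hyper"), (-1.99, "neither")]
    )
    def test_boundaries_inclusive(self, mean, state):
        calls = mt.call_states(pd.Series({"p": mean}))
        assert calls.states["p"] == state

    def test_partition_and_sign_symmetry(self):
        rng = np.random.default_rng(2)
        means = pd.Series(rng.normal(scale=3, size=500),
                          index=[f"p{i}" for i in range(500)])
        calls = mt.call_states(means)
        flipped = mt.call_states(-means)
        assert calls.hyper_probes == flipped.hypo_probes
        assert calls.hypo_probes == flipped.hyper_probes
        n = (len(calls.hyper_probes) + len(calls.hypo_probes)
             + len(calls.probes_in_state("neither")))
        assert n == 500

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(MethtopoError):
            mt.call_states(pd.Series([0.0]), hyper_min=-2, hypo_max=2)


class TestWelch:
    def test_identical_groups_give_t_zero(self):
        m = make_matrix({f"s{i}": [v] for i, v in enumerate([1, 2, 3, 1, 2, 3])})
        res = mt.welch_t_per_probe(m, make_sheet(["a"] * 3 + ["b"] * 3), "a", "b")
        assert res["t"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_scipy_closed_form(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(size=(25, 11))
        arr[:, 5:] += 0.4
        m = make_matrix({f"s{i}": arr[:, i] for i in range(11)})
        res = mt.welch_t_per_probe(m, make_sheet(["a"] * 5 + ["b"] * 6), "a", "b")
        t, p = stats.ttest_ind(arr[:, :5], arr[:, 5:], axis=1, equal_var=False)
        np.testing.assert_allclose(res["t"], t, atol=1e-12)
        np.testing.assert_allclose(res["p"], p, atol=1e-12)

    def test_zero_variance_equal_means_flagged_p_one(self):
        m = make_matrix({f"s{i}": [5.0] for i in range(6)})
        res = mt.welch_t_per_probe(m, make_sheet(["a"] * 3 + ["b"] * 3), "a", "b")
        assert res["degenerate"].iloc[0]
        assert res["p"].iloc[0] == 1.0

    def test_null_type_one_error_within_binomial_ci(self):
        """Under a global null the Welch test rejects at ~alpha."""
        rng = np.random.default_rng(12)
        n_probes, n = 2000, 10
        arr = rng.normal(size=(n_probes, 2 * n))
        m = make_matrix({f"s{i}": arr[:, i] for i in range(2 * n)})
        res = mt.welch_t_per_probe(m, make_sheet(["a"] * n + ["b"] * n), "a", "b")
        rate = float((res["p"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / n_probes)
        assert abs(rate - 0.05) < 2.576 * se
        # and essentially nothing survives FDR control
        q = mt.bh_fdr(res["p"].to_numpy())
        assert (q < 0.05).mean() <= 0.05 + 3 * se


class TestBHFDR:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            mt.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_all_ones(self):
        assert (mt.bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_empty(self):
        assert mt.bh_fdr([]).size == 0

    def test_matches_brute_force_definition(self):
        """q_(i) = min_{j >= i} min(1, m p_(j) / j) on random inputs."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 60))
            m = len(p)
            order = np.argsort(p, kind="mergesort")
            brute = np.empty(m)
            sorted_p = p[order]
            for rank in range(m):
                brute[order[rank]] = min(
                    min(1.0, m * sorted_p[j] / (j + 1)) for j in range(rank, m)
                )
            np.testing.assert_allclose(mt.bh_fdr(p), brute, atol=1e-12)


class TestTopK:
    @staticmethod
    def frame(qs, deltas, ids=None):
        ids = ids or [f"p{i}" for i in range(len(qs))]
        return pd.DataFrame({"q": qs, "delta_m": deltas}, index=ids)

    def test_full_list_when_k_equals_total(self):
        res = self.frame([0.2, 0.1], [1, 1])
        assert set(mt.top_k_probes(res, 2)) == {"p0", "p1"}

    def test_smaller_q_leads(self):
        res = self.frame([0.02, 0.01], [1, 1])
        assert mt.top_k_probes(res, 1) == ["p1"]

    def test_tie_break_by_effect_then_id(self):
        res = self.frame([0.01, 0.01, 0.01], [1.0, -2.0, 1.0], ["b", "c", "a"])
        assert mt.top_k_probes(res, 3) == ["c", "a", "b"]

    def test_heavy_ties_match_documented_oracle(self):
        rng = np.random.default_rng(13)
        n = 200
        res = self.frame(
            rng.choice([0.01, 0.02, 0.03], size=n),
            rng.choice([-2.0, -1.0, 1.0, 2.0], size=n),
        )
        oracle = sorted(res.index, key=lambda i: (res.loc[i, "q"],
                                                  -abs(res.loc[i, "delta_m"]), i))
        assert mt.top_k_probes(res, n) == oracle

    def test_invalid_k_rejected(self):
        res = self.frame([0.1], [1])
        with pytest.raises(MethtopoError):
            mt.top_k_probes(res, 0)
        with pytest.raises(MethtopoError):
            mt.top_k_probes(res, 2)


class TestHierarchicalOrder:
    def test_metric_forcing_on_1d_toy(self):
        """Samples at 0 and 1 merge before 10 joins: the pair stays adjacent."""
        m = make_matrix({"a": [0.0], "b": [1.0], "c": [10.0]})
        sample_order, _ = mt.hierarchical_order(m)
        assert {sample_order[0], sample_order[1]} == {"a", "b"} or (
            {sample_order[1], sample_order[2]} == {"a", "b"}
        )

    def test_duplicate_samples_adjacent(self):
        rng = np.random.default_rng(14)
        base = rng.normal(size=8)
        m = make_matrix({"dup1": base, "dup2": base, "other": base + 5,
                         "far": base - 7})
        sample_order, _ = mt.hierarchical_order(m)
        i, j = sample_order.index("dup1"), sample_order.index("dup2")
        assert abs(i - j) == 1

    def test_planted_clusters_contiguous(self):
        rng = np.random.default_rng(15)
        left = rng.normal(0, 0.2, size=(30, 4))
        right = rng.normal(4, 0.2, size=(30, 4))
        cols = {f"L{i}": left[:, i] for i in range(4)}
        cols |= {f"R{i}": right[:, i] for i in range(4)}
        m = make_matrix(cols)
        sample_order, _ = mt.hierarchical_order(m)
        labels = [s[0] for s in sample_order]
        assert labels == sorted(labels) or labels == sorted(labels, reverse=True)

    def test_constant_matrix_warns_and_is_deterministic(self):
        m = make_matrix({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        with pytest.warns(UserWarning):
            first = mt.hierarchical_order(m)
        with pytest.warns(UserWarning):
            second = mt.hierarchical_order(m)
        assert first == second


class TestRegionDirectionCounts:
    def test_multi_membership_counted_in_each_region(self, manifest_factory):
        manifest = manifest_factory(
            [("p1", "chr1", 10, ["gene_body", "enhancer"], [], ["A450K"]),
             ("p2", "chr1", 20, ["promoter"], [], ["A450K"])]
        )
        states = pd.Series({"p1": "hyper", "p2": "hypo"})
        counts, _ = mt.region_direction_counts(states, manifest)
        assert counts.loc["gene_body", "hyper"] == 1
        assert counts.loc["enhancer", "hyper"] == 1
        assert counts.loc["promoter", "hypo"] == 1

    def test_empty_significant_set_gives_zero_table(self, manifest_factory):
        manifest = manifest_factory([("p1", "chr1", 10, ["promoter"], [], ["A450K"])])
        counts, _ = mt.region_direction_counts(pd.Series(dtype=object), manifest)
        assert (counts.to_numpy() == 0).all()

    def test_planted_direction_ordering(self, study, result):
        """Hyper counts rank gene body/enhancer above promoter; hypo reverses."""
        universe = result.universe
        all_states = pd.concat(
            [c.states for c in result.state_calls.values()], axis=1
        ).mode(axis=1)[0]
        counts, _ = mt.region_direction_counts(all_states, universe)
        assert counts.loc["gene_body", "hyper"] > counts.loc["promoter", "hyper"]
        assert counts.loc["enhancer", "hyper"] > counts.loc["promoter", "hyper"]
        assert counts.loc["promoter", "hypo"] > counts.loc["gene_body", "hypo"]
        assert counts.loc["promoter", "hypo"] > counts.loc["enhancer", "hypo"]
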