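import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from antigenome import differential as df
from antigenome import profiles as pf


def brute_force_bh(p):
    """Step-up BH by direct definition: q_i = min over j with p_j >= p_i of p_j*m/rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        q[idx] = min(running_min, 1.0)
    return q


class TestKwTest:
    def test_hand_computed_two_groups(self):
        h, p = df.kw_test([np.array([1, 2, 3]), np.array([4, 5, 6])])
        assert h == pytest.approx(12 / 42 * 13.5)  # 3.857...

    def test_identical_groups_null(self):
        h, p = df.kw_test([np.ones(4), np.ones(4)])
        assert h == 0.0
        assert p == 1.0

    def test_matches_wilcoxon_normal_approx(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, size=25)
            b = rng.normal(0.3, 1, size=25)
            _, p_kw = df.kw_test([a, b])
            z = sps.ranksums(a, b).statistic
            p_z = 2 * sps.norm.sf(abs(z))
            assert abs(p_kw - p_z) < 0.01

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            df.kw_test([np.array([1, 2, 3])])

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            df.kw_test([np.array([1.0]), np.array([])])


class TestBhFdr:
    def test_uniform_ladder(self):
        q = df.bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(q, 0.05)

    def test_single_p(self):
        assert df.bh_fdr([0.123]) == pytest.approx([0.123])

    def test_all_ones(self):
        assert (df.bh_fdr(np.ones(10)) == 1.0).all()

    def test_q_at_least_p(self, rng):
        p = rng.random(500)
        q = df.bh_fdr(p)
        assert (q >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            df.bh_fdr([0.5, 1.5])

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 80)))
            assert np.allclose(df.bh_fdr(p), brute_force_bh(p))

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_brute_force_property(self, p):
        assert np.allclose(df.bh_fdr(p), brute_force_bh(p))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(300)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(df.bh_fdr(p), expected)


class TestDifferentialSelection:
    def test_planted_antigens_flagged(self, sim_bundle):
        meta = sim_bundle["meta"]
        serum = meta[~meta["is_control"]]
        case = list(serum[(serum["group"].isin(["PBO-A", "PBO-NA"]))
                          & (serum["month"] == 0)]["sample_id"])
        control = list(serum[(serum["group"] == "HC") & (serum["month"] == 0)]["sample_id"])
        result = df.differential_selection(
            sim_bundle["norm"].log2, sim_bundle["calls"], meta, case, control
        )
        planted = sim_bundle["truth"].planted_antigens()
        hits = df.case_hits(result)
        assert len(planted & hits) >= 0.5 * len(planted)

    def test_result_invariants(self, sim_bundle):
        meta = sim_bundle["meta"]
        serum = meta[~meta["is_control"]]
        case = list(serum[(serum["group"] == "PBO-A") & (serum["month"] == 0)]["sample_id"])
        control = list(serum[(serum["group"] == "HC") & (serum["month"] == 0)]["sample_id"])
        result = df.differential_selection(
            sim_bundle["norm"].log2, sim_bundle["calls"], meta, case, control
        )
        assert (result["q"] >= result["p"] - 1e-12).all()
        assert result["q"].between(0, 1).all()
        assert (result["case_prevalence"] >= 0.01).all()
        assert set(result["direction"]) <= {df.CASE_ENRICHED, df.CONTROL_ENRICHED}

    def test_empty_groups_error(self, sim_bundle):
        with pytest.raises(ValueError):
            df.differential_selection(
                sim_bundle["norm"].log2, sim_bundle["calls"], sim_bundle["meta"],
                [], ["x"],
            )


class TestSummaries:
    @staticmethod
    def _table(n_case, n_control, n_null=10):
        rows = []
        for i in range(n_case):
            rows.append((f"c{i}", df.CASE_ENRICHED, True))
        for i in range(n_control):
            rows.append((f"k{i}", df.CONTROL_ENRICHED, True))
        for i in range(n_null):
            rows.append((f"n{i}", df.CASE_ENRICHED, False))
        table = pd.DataFrame(rows, columns=["antigen", "direction", "significant"])
        return table.set_index("antigen")

    def test_headline_totals(self):
        summary = df.summarize_significant(self._table(541, 322))
        assert summary == {"case_enriched": 541, "control_enriched": 322, "total": 863}

    def test_case_hits_excludes_control_direction(self):
        hits = df.case_hits(self._table(3, 2))
        assert hits == {"c0", "c1", "c2"}


class TestReproducibilityPartition:
    def test_headline_worked_example(self):
        shared = {f"s{i}" for i in range(335)}
        set1 = shared | {f"a{i}" for i in range(206)}
        set2 = shared | {f"b{i}" for i in range(270)}
        assert len(set1) == 541 and len(set2) == 605
        partition = df.reproducibility_partition(set1, set2)
        assert len(partition["unique_to_1"]) == 206
        assert len(partition["shared"]) == 335
        assert len(partition["unique_to_2"]) == 270

    def test_identical_sets(self):
        partition = df.reproducibility_partition({"a", "b"}, {"a", "b"})
        assert partition["unique_to_1"] == set()
        assert partition["unique_to_2"] == set()

    def test_disjoint_sets(self):
        partition = df.reproducibility_partition({"a"}, {"b"})
        assert partition["shared"] == set()


class TestSplitCohort:
    def test_stratified_even_split(self):
        donors = pd.Series(
            ["g1"] * 10 + ["g2"] * 8, index=[f"d{i}" for i in range(18)]
        )
        assignment = df.split_cohort(donors, seed=3)
        table = pd.Series(assignment)
        for group in ("g1", "g2"):
            members = table[donors.loc[table.index] == group]
            assert abs((members == 1).sum() - (members == 2).sum()) <= 1

    def test_odd_subgroup_extra_to_set1(self):
        donors = pd.Series(["g"] * 5, index=[f"d{i}" for i in range(5)])
        assignment = df.split_cohort(donors, seed=1)
        counts = pd.Series(assignment).value_counts()
        assert counts[1] == 3 and counts[2] == 2

    def test_seed_determinism(self):
        donors = pd.Series(["g1"] * 6 + ["g2"] * 6, index=[f"d{i}" for i in range(12)])
        assert df.split_cohort(donors, seed=9) == df.split_cohort(donors, seed=9)

    def test_too_small_subgroup(self):
        donors = pd.Series(["g1", "g2"], index=["d0", "d1"])
        with pytest.raises(ValueError):
            df.split_cohort(donors, seed=0)


class TestPrevalenceFilter:
    def test_zero_threshold_identity(self):
        prevalence = pd.Series({"a": 0.5, "b": 0.01})
        assert df.prevalence_filter({"a", "b"}, prevalence, 0.0) == {"a", "b"}

    def test_impossible_threshold_empty(self):
        prevalence = pd.Series({"a": 0.5})
        assert df.prevalence_filter({"a"}, prevalence, 1.01) == set()

    def test_monotone_nesting(self, rng):
        prevalence = pd.Series(rng.random(100), index=[f"a{i}" for i in range(100)])
        hits = set(prevalence.index)
        loose = df.prevalence_filter(hits, prevalence, 0.1)
        tight = df.prevalence_filter(hits, prevalence, 0.3)
        assert tight <= loose


class TestSubgroupOverlap:
    def test_headline_two_set_example(self):
        shared = {f"s{i}" for i in range(171)}
        rnf_a = shared | {f"a{i}" for i in range(91)}
        rnf_na = shared | {f"b{i}" for i in range(46)}
        assert len(rnf_a) == 262 and len(rnf_na) == 217
        partition = df.subgroup_overlap({"RNF-A": rnf_a, "RNF-NA": rnf_na})
        assert len(partition.unique_to("RNF-A")) == 91
        assert len(partition.unique_to("RNF-NA")) == 46

    def test_four_identical_sets(self):
        s = {"a", "b", "c"}
        partition = df.subgroup_overlap({k: set(s) for k in "wxyz"})
        assert partition.shared_by_all() == s
        assert partition.union_size() == 3

    def test_matches_brute_force(self, rng):
        universe = [f"x{i}" for i in range(40)]
        sets = {
            name: {u for u in universe if rng.random() < 0.5} for name in "abcd"
        }
        partition = df.subgroup_overlap(sets)
        for key, count in partition.region_counts.items():
            brute = [
                u
                for u in set().union(*sets.values())
                if {n for n in sets if u in sets[n]} == set(key)
            ]
            assert count == len(brute)

    def test_too_many_sets(self):
        with pytest.raises(ValueError):
            df.subgroup_overlap({str(i): {i} for i in range(5)})


class TestRankBias:
    def test_top_ten_of_hundred(self):
        representation = pd.Series(
            np.arange(100, 0, -1), index=[f"a{i}" for i in range(100)], dtype=float
        )
        hits = {f"a{i}" for i in range(10)}
        report = df.rank_bias_diagnostic(hits, representation)
        assert report["median_rank"] == 5.5

    def test_single_hit(self):
        representation = pd.Series({"a": 3.0, "b": 2.0, "c": 1.0})
        report = df.rank_bias_diagnostic({"b"}, representation)
        assert report["median_rank"] == 2.0

    def test_uniform_hits_centered(self, rng):
        n = 10_000
        representation = pd.Series(
            rng.random(n), index=[f"a{i}" for i in range(n)]
        )
        hits = set(rng.choice(representation.index, size=100, replace=False))
        report = df.rank_bias_diagnostic(hits, representation)
        # sample median of m uniform ranks: SE ~ 1.25 * (N/sqrt(12)) / sqrt(m)
        se = 1.2533 * (n / np.sqrt(12)) / np.sqrt(100)
        assert abs(report["median_rank"] - (n + 1) / 2) <= 3 * se

    def test_missing_hit_errors(self):
        representation = pd.Series({"a": 1.0, "b": 2.0, "c": 0.5})
        with pytest.raises(KeyError):
            df.rank_bias_diagnostic({"z"}, representation)


class TestLongitudinal:
    @staticmethod
    def _meta(n_donors, months, group="G"):
        rows = []
        for d in range(n_donors):
            for m in months:
                rows.append(
                    {
                        "sample_id": f"d{d}_m{m}",
                        "donor_id": f"d{d}",
                        "group": group,
                        "month": m,
                        "batch": "B1",
                        "is_control": False,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_time_points_nothing_significant(self, rng):
        meta = self._meta(10, [0, 24])
        base = pd.DataFrame(
            rng.lognormal(3, 1, size=(50, 10)),
            index=[f"a{i}" for i in range(50)],
            columns=[f"d{d}_m0" for d in range(10)],
        )
        log2 = pd.concat(
            [base, base.rename(columns=lambda c: c.replace("m0", "m24"))], axis=1
        )
        results, r2 = df.longitudinal_paired(log2, meta, "G", [(0, 24)])
        assert not results[(0, 24)]["significant"].any()
        assert np.allclose(r2["r2"], 1.0)

    def test_planted_rise_detected(self, rng):
        n_donors, n_antigens = 30, 60
        meta = self._meta(n_donors, [0, 24])
        values0 = rng.lognormal(3, 0.3, size=(n_antigens, n_donors))
        values24 = values0.copy()
        affected = list(range(8))
        values24[affected] *= 4  # uniform 4-fold rise at month 24
        values24 *= np.exp(rng.normal(0, 0.05, size=values24.shape))
        log2 = pd.DataFrame(
            np.column_stack([np.log2(values0 + 1), np.log2(values24 + 1)]),
            index=[f"a{i}" for i in range(n_antigens)],
            columns=[f"d{d}_m0" for d in range(n_donors)]
            + [f"d{d}_m24" for d in range(n_donors)],
        )
        results, _ = df.longitudinal_paired(log2, meta, "G", [(0, 24)])
        table = results[(0, 24)]
        assert table.iloc[affected]["significant"].all()

    def test_unpaired_donor_excluded_with_warning(self, rng):
        meta = self._meta(6, [0, 24])
        meta = meta[meta["sample_id"] != "d5_m24"]
        log2 = pd.DataFrame(
            rng.lognormal(3, 1, size=(20, len(meta))),
            index=[f"a{i}" for i in range(20)],
            columns=list(meta["sample_id"]),
        )
        with pytest.warns(UserWarning, match="unpaired"):
            results, r2 = df.longitudinal_paired(log2, meta, "G", [(0, 24)])
        assert set(r2["donor_id"]) == {f"d{d}" for d in range(5)}

    def test_too_few_pairs_error(self, rng):
        meta = self._meta(3, [0, 24])
        log2 = pd.DataFrame(
            rng.lognormal(3, 1, size=(10, len(meta))),
            index=[f"a{i}" for i in range(10)],
            columns=list(meta["sample_id"]),
        )
        with pytest.raises(ValueError, match=">=5"):
            df.longitudinal_paired(log2, meta, "G", [(0, 24)])
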