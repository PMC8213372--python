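import numpy as np
import pandas as pd
import pytest
from scipy import stats

from charmod.counting import SampleTable
from charmod.differential import (
    bh_adjust,
    condition_mean_rows,
    differential_analysis,
    estimate_dispersion,
    estimate_size_factors,
    kmeans_modules,
    moderate_dispersion,
    row_normalize,
    select_differential_union,
)
from charmod.differential import test_pairwise as nb_pairwise_test
from charmod.simulate import SimulationParams, simulate_dataset


def two_group_samples(n_a, n_b, cond_a="baseline", cond_b="art_1yr"):
    rows = [
        {"sample_id": f"a{i}", "condition": cond_a, "subject_id": f"sa{i}"}
        for i in range(n_a)
    ] + [
        {"sample_id": f"b{i}", "condition": cond_b, "subject_id": f"sb{i}"}
        for i in range(n_b)
    ]
    return SampleTable(pd.DataFrame(rows))


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        sf = estimate_size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_sqrt2_split(self):
        counts = pd.DataFrame({"A": [10, 20, 40], "B": [20, 40, 80]})
        sf = estimate_size_factors(counts)
        assert sf["A"] == pytest.approx(1 / np.sqrt(2))
        assert sf["B"] == pytest.approx(np.sqrt(2))

    def test_matches_literal_median_of_ratios(self, rng):
        counts = pd.DataFrame(
            rng.negative_binomial(10, 0.3, size=(200, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        sf = estimate_size_factors(counts)
        # independent literal re-implementation
        mat = counts.to_numpy(float)
        keep = (mat > 0).all(axis=1)
        ref = np.exp(np.mean(np.log(mat[keep]), axis=1))
        factors = np.array(
            [np.median(mat[keep, j] / ref) for j in range(mat.shape[1])]
        )
        factors /= np.exp(np.mean(np.log(factors)))
        assert np.allclose(sf.to_numpy(), factors)

    def test_geometric_mean_one(self, rng):
        counts = pd.DataFrame(
            rng.poisson(30, size=(100, 5)), columns=list("abcde")
        )
        sf = estimate_size_factors(counts)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0, abs=1e-6)

    def test_no_all_positive_row_errors(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError, match="filter"):
            estimate_size_factors(counts)

    def test_agrees_with_deseq2_reference_implementation(self, rng):
        # independent cross-check against pydeseq2's median-of-ratios
        # (compared after rescaling both to geometric mean 1)
        from pydeseq2.dds import DeseqDataSet

        counts = pd.DataFrame(
            rng.negative_binomial(10, 0.3, size=(100, 8)),
            columns=[f"s{i}" for i in range(8)],
        )
        ours = estimate_size_factors(counts)
        dds = DeseqDataSet(
            counts=counts.T,
            metadata=pd.DataFrame(
                {"condition": ["A"] * 4 + ["B"] * 4}, index=counts.columns
            ),
            design="~condition",
            quiet=True,
        )
        dds.fit_size_factors()
        ref = np.asarray(dds.obs["size_factors"], dtype=float)
        ref = ref / np.exp(np.mean(np.log(ref)))
        assert np.allclose(ours.to_numpy(), ref, rtol=1e-6)


class TestDispersion:
    def test_constant_counts_hit_floor(self):
        counts = pd.DataFrame(
            {f"s{i}": [50, 100] for i in range(6)},
        )
        samples = two_group_samples(3, 3)
        samples.df["sample_id"] = counts.columns
        samples = SampleTable(samples.df)
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersion(counts, sf, samples, dispersion_floor=1e-8)
        assert np.allclose(disp, 1e-8)

    def test_poisson_counts_mostly_floored(self, rng):
        # under Poisson truth the MoM numerator is negative about half the
        # time, so a large share of regions land on the floor and the
        # typical estimate is near zero
        n = 20
        counts = pd.DataFrame(
            rng.poisson(100, size=(500, n)), columns=[f"s{i}" for i in range(n)]
        )
        samples = SampleTable(
            pd.DataFrame(
                {
                    "sample_id": counts.columns,
                    "condition": ["baseline"] * n,
                    "subject_id": counts.columns,
                }
            )
        )
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersion(counts, sf, samples)
        assert (disp <= 1e-8).mean() > 0.4
        assert np.median(disp) < 0.05

    def test_nb_dispersion_recovered_at_n50(self, rng):
        n = 50
        alpha = 0.5
        mu = 100.0
        counts = pd.DataFrame(
            rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu), size=(300, n)),
            columns=[f"s{i}" for i in range(n)],
        )
        samples = SampleTable(
            pd.DataFrame(
                {
                    "sample_id": counts.columns,
                    "condition": ["baseline"] * n,
                    "subject_id": counts.columns,
                }
            )
        )
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersion(counts, sf, samples)
        assert 0.35 <= np.median(disp) <= 0.65


class TestBH:
    def test_step_up_hand_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_matches_brute_force_min_over_tail(self, rng):
        p = rng.random(1000)
        q = bh_adjust(p)
        order = np.argsort(p)
        m = len(p)
        brute = np.empty(m)
        sorted_p = p[order]
        for i in range(m):
            brute[i] = min(
                min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
            )
        expected = np.empty(m)
        expected[order] = brute
        assert np.allclose(q, expected)

    def test_nan_excluded_from_family(self):
        q = bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(q[1])
        # m = 2, not 3
        assert q[0] == pytest.approx(0.02)

    def test_never_more_discoveries_than_raw(self, rng):
        p = rng.random(500) ** 2
        q = bh_adjust(p)
        assert (q < 0.05).sum() <= (p < 0.05).sum()


class TestPairwiseWald:
    def test_identical_groups_zero_lfc_p_one(self):
        counts = pd.DataFrame(
            {f"{g}{i}": [30, 55, 80] for g in "ab" for i in range(3)}
        )
        samples = two_group_samples(3, 3)
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.1, index=counts.index)
        res = nb_pairwise_test(counts, sf, disp, samples, ("baseline", "art_1yr"))
        assert np.allclose(res["log2_fold_change"], 0.0)
        assert np.allclose(res["wald_statistic"], 0.0)
        assert np.allclose(res["p_value"], 1.0)

    def test_normalization_equivariance(self, rng):
        # rescaling one sample's counts and its size factor by c leaves the
        # estimand unchanged; for a count likelihood the statistics match
        # approximately (the rescaled sample carries c times the Fisher
        # information), so equality is asserted to a few percent
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.2, size=(100, 8)) + 1,
            columns=[f"s{i}" for i in range(8)],
        )
        samples = two_group_samples(4, 4)
        samples.df["sample_id"] = counts.columns
        samples = SampleTable(samples.df)
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.2, index=counts.index)
        base = nb_pairwise_test(counts, sf, disp, samples, ("baseline", "art_1yr"))
        scaled = counts.copy()
        scaled["s0"] = (scaled["s0"] * 3).astype(int)
        sf2 = sf.copy()
        sf2["s0"] = 3.0
        res = nb_pairwise_test(scaled, sf2, disp, samples, ("baseline", "art_1yr"))
        assert np.allclose(
            base["log2_fold_change"], res["log2_fold_change"], atol=0.1
        )
        assert np.allclose(
            base["wald_statistic"], res["wald_statistic"], atol=0.15
        )

    def test_requires_two_replicates(self):
        counts = pd.DataFrame({"a0": [5], "b0": [5]})
        samples = two_group_samples(1, 1)
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.1, index=counts.index)
        with pytest.raises(ValueError, match=">= 2 samples"):
            nb_pairwise_test(counts, sf, disp, samples, ("baseline", "art_1yr"))

    def test_null_p_values_calibrated_and_uniform(self):
        fracs, ks_stats = [], []
        for seed in (11, 12, 13):
            p = SimulationParams(
                n_regions=2000,
                n_per_condition=5,
                alpha=0.2,
                depth=50,
                module_proportions={},
                se_gene_count=0,
                conditions=("baseline", "art_1yr"),
            )
            ds = simulate_dataset(p, seed=seed)
            results, _ = differential_analysis(
                ds["counts"], ds["samples"], conditions=("baseline", "art_1yr")
            )
            pv = results[("baseline", "art_1yr")]["p_value"].dropna().to_numpy()
            fracs.append((pv < 0.05).mean())
            ks_stats.append(stats.kstest(pv, "uniform").statistic)
        assert all(0.03 <= f <= 0.07 for f in fracs)
        assert all(k < 0.05 for k in ks_stats)

    def test_planted_effect_sensitivity_and_fdr(self):
        p = SimulationParams(
            n_regions=2000,
            n_per_condition=5,
            alpha=0.2,
            depth=50,
            module_proportions={"B": 0.10},
            se_gene_count=0,
            conditions=("baseline", "art_1yr"),
            lfc=2.0,
        )
        ds = simulate_dataset(p, seed=1)
        results, _ = differential_analysis(
            ds["counts"], ds["samples"], conditions=("baseline", "art_1yr")
        )
        q = results[("baseline", "art_1yr")]["q_value"]
        truth = np.array(ds["truth"].module_labels) == "B"
        called = (q < 0.05).fillna(False).to_numpy()
        assert called[truth].mean() >= 0.8
        assert (called & ~truth).sum() / max(called.sum(), 1) <= 0.10


class TestUnion:
    def test_single_significant_comparison_included(self):
        df1 = pd.DataFrame(
            {"q_value": [0.01, 0.5]}, index=["r1", "r2"]
        )
        df2 = pd.DataFrame(
            {"q_value": [0.9, 0.9]}, index=["r1", "r2"]
        )
        union = select_differential_union({("a", "b"): df1, ("a", "c"): df2}, 0.05)
        assert union == ["r1"]

    def test_empty_union_and_clustering_refusal(self):
        df = pd.DataFrame({"q_value": [0.9]}, index=["r1"])
        assert select_differential_union({("a", "b"): df}, 0.05) == []
        with pytest.raises(ValueError, match="regions"):
            kmeans_modules(pd.DataFrame(np.zeros((0, 4))), k=4)

    def test_union_recall_and_fdr_on_planted_truth(self):
        ds = simulate_dataset(seed=5)
        truth = ds["truth"]
        pairwise, _ = differential_analysis(
            ds["counts"],
            ds["samples"],
            conditions=("naive", "baseline", "art_1yr", "untreated_1yr"),
        )
        union = select_differential_union(pairwise, 0.05)
        lab = np.array(truth.module_labels)
        called = np.isin(np.array(truth.region_ids()), union)
        true_diff = lab != "background"
        assert called[true_diff].mean() >= 0.8
        assert (called & ~true_diff).sum() / called.sum() <= 0.10


class TestConditionMeans:
    def test_single_sample_equals_transformed_values(self):
        counts = pd.DataFrame({"s1": [3, 7]}, index=["r1", "r2"])
        samples = SampleTable(
            pd.DataFrame(
                {"sample_id": ["s1"], "condition": ["baseline"], "subject_id": ["x"]}
            )
        )
        sf = pd.Series([2.0], index=["s1"])
        out = condition_mean_rows(counts, sf, samples, ["r1", "r2"])
        assert np.allclose(out["baseline"], np.log2(counts["s1"] / 2.0 + 1))

    def test_matches_direct_mean_oracle(self, rng):
        counts = pd.DataFrame(
            rng.poisson(40, size=(50, 4)), columns=["a0", "a1", "b0", "b1"]
        )
        counts.index = [f"r{i}" for i in range(50)]
        samples = two_group_samples(2, 2)
        sf = estimate_size_factors(counts)
        out = condition_mean_rows(counts, sf, samples, list(counts.index))
        t = np.log2(counts / sf + 1)
        assert np.allclose(out["baseline"], t[["a0", "a1"]].mean(axis=1))
        assert np.allclose(out["art_1yr"], t[["b0", "b1"]].mean(axis=1))

    def test_condition_without_samples_errors(self):
        counts = pd.DataFrame({"a0": [1], "a1": [2]}, index=["r1"])
        samples = two_group_samples(2, 0)
        sf = pd.Series(1.0, index=counts.columns)
        with pytest.raises(ValueError, match="art_1yr"):
            condition_mean_rows(
                counts, sf, samples, ["r1"], conditions=("baseline", "art_1yr")
            )


class TestRowNormalize:
    def test_hand_z_score(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"], columns=list("abc"))
        z, flagged = row_normalize(m)
        assert np.allclose(z.loc["r"], [-1.2247, 0, 1.2247], atol=1e-4)
        assert flagged == []

    def test_constant_row_flagged_zero(self):
        m = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]], index=["r1", "r2"])
        z, flagged = row_normalize(m)
        assert np.allclose(z.loc["r1"], 0.0)
        assert flagged == ["r1"]

    def test_rows_have_zero_mean_unit_sd(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 4)))
        z, _ = row_normalize(m)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=0), 1.0)


class TestKmeansModules:
    def test_two_separated_patterns_perfect_partition(self, rng):
        a = rng.normal(0, 0.2, size=(40, 4)) + np.array([3, 0, 0, 0])
        b = rng.normal(0, 0.2, size=(60, 4)) + np.array([0, 0, 3, 0])
        m = pd.DataFrame(np.vstack([a, b]))
        out = kmeans_modules(m, k=2, seed=0)
        labels = out.labels.to_numpy()
        assert len(set(labels[:40])) == 1 and len(set(labels[40:])) == 1
        assert labels[0] != labels[-1]
        # labels ordered by descending size: the 60-row cluster is 'A'
        assert labels[-1] == "A"

    def test_deterministic_given_seed(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 4)))
        l1 = kmeans_modules(m, k=3, seed=7).labels
        l2 = kmeans_modules(m, k=3, seed=7).labels
        pd.testing.assert_series_equal(l1, l2)

    def test_k_below_two_rejected(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError):
            kmeans_modules(m, k=1, seed=0)

    def test_four_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        ds = simulate_dataset(seed=6)
        truth = ds["truth"]
        conds = ("naive", "baseline", "art_1yr", "untreated_1yr")
        pairwise, sf = differential_analysis(
            ds["counts"], ds["samples"], conditions=conds
        )
        union = select_differential_union(pairwise, 0.05)
        means = condition_mean_rows(
            ds["counts"], sf, ds["samples"], union, conditions=conds
        )
        normed, _ = row_normalize(means)
        modules = kmeans_modules(normed, k=4, seed=0)
        id2lab = dict(zip(truth.region_ids(), truth.module_labels))
        true_labels = np.array([id2lab[r] for r in union])
        planted = true_labels != "background"
        ari = adjusted_rand_score(
            true_labels[planted], modules.labels.to_numpy()[planted]
        )
        assert ari >= 0.9


def test_moderate_dispersion_shrinks_toward_median():
    disp = pd.Series([0.01, 0.2, 1.0])
    moderated, dof = moderate_dispersion(disp, residual_dof=8, prior_dof=10)
    assert dof == 18
    med = 0.2
    assert np.allclose(moderated, (8 * disp + 10 * med) / 18)
    assert abs(moderated.iloc[0] - med) < abs(disp.iloc[0] - med)
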