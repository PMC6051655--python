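import numpy as np
import pandas as pd
import pytest

from retrotime import (
    NormalizationResult,
    TimecourseConfig,
    adjust_and_select,
    cluster_profiles,
    fit_global_nb,
    make_design,
    run_timecourse,
    select_and_cluster,
    stepwise_select,
)

from conftest import nb_counts


@pytest.fixture(scope="module")
def design(study_samples):
    return make_design(study_samples, degree=2)


def unit_norm(samples, lib=100_000, d=0.1):
    return NormalizationResult(
        factors=pd.Series(1.0, index=samples),
        library_sizes=pd.Series(lib, index=samples),
        dispersion=d, samples=list(samples))


class TestDesign:
    def test_study_design_shape(self, design):
        """Controls 6/30/120 h + starved 6/15/30/72/120 h, degree 2:
        8 rows x 6 columns."""
        assert design.matrix.shape == (8, 6)
        assert design.term_names == [
            "intercept", "time^1", "time^2", "starved",
            "starved:time^1", "starved:time^2"]

    def test_study_design_full_rank(self, design):
        assert np.linalg.matrix_rank(design.matrix) == design.matrix.shape[1]

    def test_degree1_two_by_two_full_rank(self):
        from retrotime import SampleSheet
        frame = pd.DataFrame(
            {"series": ["control", "control", "starved", "starved"],
             "time_h": [6.0, 30.0, 6.0, 30.0]},
            index=["c6", "c30", "s6", "s30"])
        d = make_design(SampleSheet(frame), degree=1)
        assert d.matrix.shape == (4, 4)
        assert np.linalg.matrix_rank(d.matrix) == 4

    def test_missing_series_errors(self):
        from retrotime import SampleSheet
        frame = pd.DataFrame({"series": ["control"] * 3,
                              "time_h": [6.0, 30.0, 120.0]},
                             index=list("abc"))
        with pytest.raises(ValueError, match="starved"):
            make_design(SampleSheet(frame), degree=2)


class TestGlobalFit:
    def test_null_p_values_roughly_uniform(self, design):
        rng = np.random.default_rng(10)
        offsets = np.zeros(8)
        n = 2000
        hits = 0
        for _ in range(n):
            y = nb_counts(rng, np.full(8, 100.0), 0.1)
            res = fit_global_nb(y, design, offsets, theta=10.0)
            hits += res["p_global"] <= 0.05
        assert 0.03 <= hits / n <= 0.08

    def test_r2_zero_when_counts_equal_intercept_fit(self, design):
        y = np.full(8, 50)
        res = fit_global_nb(y, design, np.zeros(8), theta=10.0)
        assert res["r2"] == pytest.approx(0.0, abs=1e-8)

    def test_planted_rise_detected(self, design, study_samples):
        """Starved series rising 8-fold by 72-120 h at d=0.1 yields a
        strongly significant global fit."""
        rng = np.random.default_rng(11)
        t = study_samples.frame["time_h"].to_numpy()
        starved = (study_samples.frame["series"] == "starved").to_numpy()
        mu = 100 * 2.0 ** (np.where(starved, 3.0 * t / 120.0, 0.0))
        hits = 0
        for _ in range(20):
            y = nb_counts(rng, mu, 0.1)
            res = fit_global_nb(y, design, np.zeros(8), theta=10.0)
            hits += res["p_global"] < 1e-3
        assert hits >= 18


class TestStepwise:
    def test_strong_interaction_retained(self, design, study_samples):
        rng = np.random.default_rng(12)
        t = study_samples.frame["time_h"].to_numpy()
        starved = (study_samples.frame["series"] == "starved").to_numpy()
        mu = 100 * 2.0 ** (starved * 3.0 * t / 120.0)
        recovered = 0
        for _ in range(20):
            y = nb_counts(rng, mu, 0.05)
            terms, r2 = stepwise_select(y, design, np.zeros(8), theta=20.0)
            if any(t.startswith("starved") for t in terms) and r2 > 0.5:
                recovered += 1
        assert recovered >= 16

    def test_pure_noise_mostly_empty(self, design):
        rng = np.random.default_rng(13)
        empty = 0
        for _ in range(50):
            y = nb_counts(rng, np.full(8, 100.0), 0.1)
            terms, _ = stepwise_select(y, design, np.zeros(8), theta=10.0)
            empty += not terms
        assert empty >= 35  # majority behaviour under the null

    def test_alpha_one_retains_everything(self, design):
        y = np.arange(1, 9) * 10
        terms, _ = stepwise_select(y, design, np.zeros(8), theta=10.0,
                                   alpha_step=1.0)
        assert set(terms) == set(design.term_names) - {"intercept"}


class TestSelection:
    def test_bh_matches_sort_based_oracle(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(size=500)
        table = pd.DataFrame({"p_global": p, "r2": 1.0})
        out = adjust_and_select(table, TimecourseConfig(Q=0.1))
        # brute-force BH: sort, scale by m/rank, enforce monotonicity from
        # the largest p down
        order = np.argsort(p)
        m = len(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        assert np.allclose(out["p_adj"].to_numpy(), expected, atol=1e-12)

    def test_monotone_in_thresholds(self, small_dataset, small_norm):
        result = run_timecourse(small_dataset.counts, small_dataset.samples,
                                small_norm, TimecourseConfig(), cluster=False)
        base = result.table
        loose_q = adjust_and_select(base, TimecourseConfig(Q=0.05))
        loose_r2 = adjust_and_select(base, TimecourseConfig(r2_min=0.5))
        assert set(base.index[base.selected]) <= \
            set(loose_q.index[loose_q.selected])
        assert set(base.index[base.selected]) <= \
            set(loose_r2.index[loose_r2.selected])

    def test_selected_iff_thresholds_met(self, small_dataset, small_norm):
        result = run_timecourse(small_dataset.counts, small_dataset.samples,
                                small_norm, cluster=False)
        t = result.table.dropna(subset=["p_adj"])
        expected = (t["p_adj"] <= 0.01) & (t["r2"] >= 0.7)
        assert (t["selected"] == expected).all()


class TestClustering:
    def test_archetype_recovery(self, small_dataset, small_norm):
        """Planted archetypes co-cluster: adjusted Rand >= 0.8 at k=4."""
        from sklearn.metrics import adjusted_rand_score
        from retrotime import rpkm

        truth = small_dataset.truth
        planted = truth[truth["archetype"].isin(
            ["progressive_up", "early_up", "late_down", "progressive_down"])]
        profiles = rpkm(small_dataset.counts, small_norm).loc[planted.index]
        labels, _ = cluster_profiles(profiles, small_dataset.samples, k=4)
        ari = adjusted_rand_score(planted["archetype"], labels)
        assert ari >= 0.8

    def test_up_clusters_labelled_first(self, small_dataset, small_norm):
        from retrotime import rpkm
        truth = small_dataset.truth
        planted = truth[truth["archetype"].isin(
            ["progressive_up", "progressive_down"])]
        profiles = rpkm(small_dataset.counts, small_norm).loc[planted.index]
        labels, _ = cluster_profiles(profiles, small_dataset.samples, k=2)
        up_mean = labels[planted["archetype"] == "progressive_up"].mean()
        down_mean = labels[planted["archetype"] == "progressive_down"].mean()
        assert up_mean < down_mean  # cluster 1 = rising late in starvation

    def test_single_feature_single_cluster(self, small_dataset, small_norm, study_samples):
        from retrotime import rpkm
        profiles = rpkm(small_dataset.counts, small_norm).iloc[:1]
        labels, _ = cluster_profiles(profiles, small_dataset.samples, k=1)
        assert list(labels) == [1]

    def test_k_exceeding_features_errors(self, small_dataset, small_norm):
        from retrotime import rpkm
        profiles = rpkm(small_dataset.counts, small_norm).iloc[:3]
        with pytest.raises(ValueError, match="exceeds"):
            cluster_profiles(profiles, small_dataset.samples, k=5)

    def test_partition_invariant_to_feature_order(self, small_dataset, small_norm):
        from retrotime import rpkm
        truth = small_dataset.truth
        planted = truth[truth["archetype"] != "null"]
        profiles = rpkm(small_dataset.counts, small_norm).loc[planted.index]
        labels, _ = cluster_profiles(profiles, small_dataset.samples, k=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(profiles))
        labels_perm, _ = cluster_profiles(profiles.iloc[perm],
                                          small_dataset.samples, k=4)
        assert (labels_perm.reindex(labels.index) == labels).all()


def test_config_validation():
    with pytest.raises(ValueError):
        TimecourseConfig(Q=0.0)
    with pytest.raises(ValueError):
        TimecourseConfig(r2_min=1.5)
    with pytest.raises(ValueError):
        TimecourseConfig(degree=0)
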