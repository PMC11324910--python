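import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from metaferm import patterns
from metaferm.io import SampleMeta
from metaferm.patterns import (
    DbscanSelection,
    GenusFilterParams,
    classify_patterns,
    dbscan_patterns,
    genus_profiles,
    kmeans_stability,
    row_normalize,
    select_genera,
    tau_index,
)
from metaferm.simulate import planted_pattern_profiles, planted_profile_matrix


def _samples(conditions=("BLANK", "IMMP94"), times=(0, 24, 48), replicates=2):
    out = []
    for c in conditions:
        for t in times:
            for r in range(1, replicates + 1):
                out.append(SampleMeta(f"{c}_t{t}_r{r}", c, float(t), r, "A"))
    return out


class TestSelectGenera:
    def _counts(self, rows, samples):
        return pd.DataFrame(
            rows, columns=[s.sample_id for s in samples],
        )

    def test_average_count_threshold_is_inclusive(self):
        samples = _samples()
        counts = pd.DataFrame(
            np.full((3, len(samples)), 10),
            index=["a1", "a2", "a3"],
            columns=[s.sample_id for s in samples],
        )
        labels = {"a1": "A", "a2": "A", "a3": "A"}
        assert select_genera(counts, labels, samples) == ["A"]

    def test_rare_genus_everywhere_is_dropped(self):
        samples = _samples()
        n = len(samples)
        big = np.full((4, n), 500)
        small = np.full((1, n), 2)  # 0.1% of reads, avg count 2
        counts = pd.DataFrame(
            np.vstack([big, small]),
            index=["b1", "b2", "b3", "b4", "r1"],
            columns=[s.sample_id for s in samples],
        )
        labels = {g: ("Big" if g.startswith("b") else "Rare") for g in counts.index}
        assert select_genera(counts, labels, samples) == ["Big"]

    def test_condition_share_rescues_locally_dominant_genus(self):
        samples = _samples()
        n = len(samples)
        big = np.full((4, n), 500)
        focal = np.full((1, n), 2.0)
        blank_cols = [i for i, s in enumerate(samples) if s.condition == "BLANK"]
        focal[0, blank_cols] = 31  # ~1.5% of reads in BLANK only
        counts = pd.DataFrame(
            np.vstack([big, focal]).astype(int),
            index=["b1", "b2", "b3", "b4", "f1"],
            columns=[s.sample_id for s in samples],
        )
        labels = {g: ("Big" if g.startswith("b") else "Focal") for g in counts.index}
        assert select_genera(counts, labels, samples) == ["Big", "Focal"]


class TestGenusProfiles:
    def test_single_genus_gives_all_ones(self):
        samples = _samples()
        counts = pd.DataFrame(
            np.arange(1, len(samples) + 1)[None, :].repeat(2, axis=0),
            index=["g1", "g2"],
            columns=[s.sample_id for s in samples],
        )
        prof = genus_profiles(counts, {"g1": "A", "g2": "A"}, ["A"])
        assert np.allclose(prof.to_numpy(), 1.0)

    def test_equal_genera_split_evenly_and_columns_sum_to_one(self):
        samples = _samples()
        counts = pd.DataFrame(
            np.full((2, len(samples)), 7),
            index=["g1", "g2"],
            columns=[s.sample_id for s in samples],
        )
        prof = genus_profiles(counts, {"g1": "A", "g2": "B"}, ["A", "B"])
        assert np.allclose(prof.to_numpy(), 0.5)
        assert np.allclose(prof.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_sample_is_an_error(self):
        samples = _samples()
        arr = np.full((2, len(samples)), 3)
        arr[:, 0] = 0
        counts = pd.DataFrame(
            arr, index=["g1", "g2"], columns=[s.sample_id for s in samples]
        )
        with pytest.raises(ValueError):
            genus_profiles(counts, {"g1": "A", "g2": "B"}, ["A", "B"])


class TestRowNormalize:
    def test_row_shares(self):
        df = pd.DataFrame([[2, 2, 0, 0]], index=["g"])
        norm, dropped = row_normalize(df)
        assert np.allclose(norm.loc["g"], [0.5, 0.5, 0, 0])
        assert dropped == []

    def test_zero_rows_removed_and_reported(self):
        df = pd.DataFrame([[1, 1], [0, 0]], index=["a", "z"])
        norm, dropped = row_normalize(df)
        assert list(norm.index) == ["a"] and dropped == ["z"]

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            row_normalize(pd.DataFrame([[1, -1]]))


def oracle_tau(labels, D):
    """Brute-force double loop over all (within, between) pair comparisons."""
    n = len(labels)
    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (within if labels[i] == labels[j] else between).append(D[i, j])
    conc = disc = 0
    for w in within:
        for b in between:
            if w < b:
                conc += 1
            elif w > b:
                disc += 1
    return (conc - disc) / (len(within) * len(between))


class TestTauIndex:
    def test_perfect_separation_gives_one(self):
        X = np.vstack([np.zeros((3, 2)), np.ones((3, 2)) * 10])
        X += np.arange(6)[:, None] * 0.01
        labels = [0, 0, 0, 1, 1, 1]
        from scipy.spatial.distance import squareform

        assert tau_index(labels, squareform(pdist(X))) == 1.0

    def test_all_tied_distances_give_zero(self):
        D = np.ones((4, 4)) - np.eye(4)
        assert tau_index([0, 0, 1, 1], D) == 0.0

    def test_single_cluster_is_undefined(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError):
            tau_index([0, 0, 0], D)

    def test_matches_bruteforce_oracle(self, rng):
        from scipy.spatial.distance import squareform

        for _ in range(50):
            n = int(rng.integers(4, 31))
            X = rng.normal(size=(n, 3))
            labels = rng.integers(0, int(rng.integers(2, 5)), size=n)
            if len(np.unique(labels)) < 2:
                labels[0] = labels[0] + 1
            D = squareform(pdist(X))
            assert tau_index(labels, D) == pytest.approx(oracle_tau(labels, D), abs=1e-12)

    def test_permutation_null_is_centred_on_zero(self, rng):
        from scipy.spatial.distance import squareform

        X = rng.normal(size=(20, 3))
        D = squareform(pdist(X))
        taus = []
        for _ in range(200):
            labels = rng.permutation([0] * 10 + [1] * 10)
            taus.append(tau_index(labels, D))
        assert abs(np.mean(taus)) < 0.05


class TestKmeansStability:
    def test_same_seed_gives_identical_report(self):
        X, _ = planted_profile_matrix(seed=1)
        a = kmeans_stability(X, k_range=range(1, 8), n_restarts=10, seed=2)
        b = kmeans_stability(X, k_range=range(1, 8), n_restarts=10, seed=2)
        assert a.chosen_k == b.chosen_k
        assert a.final_partition.equals(b.final_partition)
        assert a.support_per_k.equals(b.support_per_k)

    def test_k_beyond_row_count_is_skipped(self):
        X, _ = planted_profile_matrix(rows_per_cluster=2, seed=0)  # 8 rows
        rep = kmeans_stability(X, k_range=range(1, 21), n_restarts=5, seed=0)
        assert rep.skipped_k == list(range(9, 21))

    def test_identical_rows_choose_two_with_degenerate_guard(self):
        X = pd.DataFrame(np.ones((5, 6)))
        rep = kmeans_stability(X, k_range=range(1, 7), n_restarts=10, seed=0)
        assert rep.chosen_k == 2
        assert rep.n_degenerate_runs > 0

    def test_well_separated_planted_groups_are_recovered(self):
        X, labels = planted_profile_matrix(seed=13)
        rep = kmeans_stability(X, seed=13)
        assert rep.chosen_k == 4
        assert adjusted_rand_score(labels, rep.final_partition) >= 0.9

    def test_support_of_planted_k_beats_neighbours(self):
        X, _ = planted_profile_matrix(seed=17)
        rep = kmeans_stability(X, seed=17)
        s = rep.support_per_k
        assert s[4] >= s[3] and s[4] >= s[5]

    def test_clustergram_sizes_are_consistent(self):
        X, _ = planted_profile_matrix(seed=3)
        rep = kmeans_stability(X, k_range=range(1, 7), n_restarts=10, seed=3)
        for k, grp in rep.clustergram.groupby("k"):
            assert grp["size"].sum() == X.shape[0]
            assert len(grp) == k

    def test_fast_ari_matches_sklearn(self, rng):
        for _ in range(100):
            a = rng.integers(0, 5, 30)
            b = rng.integers(0, 4, 30)
            assert patterns.adjusted_rand(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )


class TestDbscanPatterns:
    def test_identical_genes_form_single_cluster_without_noise(self):
        X = pd.DataFrame(np.tile([0.25, 0.25, 0.25, 0.25], (6, 1)))
        res = dbscan_patterns(X)
        assert (res.labels == 0).all()

    def test_fewer_genes_than_minpts_are_all_noise(self):
        X = pd.DataFrame(np.eye(2))
        res = dbscan_patterns(X, DbscanSelection(minpts=3))
        assert (res.labels == -1).all()

    def test_row_order_invariance(self):
        X, _, _ = planted_pattern_profiles(genes_per_pattern=15, seed=6)
        res = dbscan_patterns(X)
        perm = X.sample(frac=1.0, random_state=1)
        res_perm = dbscan_patterns(perm)
        joined = pd.DataFrame(
            {"a": res.labels, "b": res_perm.labels.reindex(res.labels.index)}
        )
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_planted_patterns_recovered(self):
        X, labels, _ = planted_pattern_profiles(seed=4)
        res = dbscan_patterns(X)
        core = res.labels >= 0
        assert core.mean() >= 0.9
        assert (
            adjusted_rand_score(
                np.asarray(labels)[core.to_numpy()], res.labels[core]
            )
            >= 0.95
        )

    def test_override_epsilon_is_honoured(self):
        X, _, _ = planted_pattern_profiles(genes_per_pattern=10, seed=2)
        res = dbscan_patterns(X, DbscanSelection(override_epsilon=0.45))
        assert res.chosen_epsilon == 0.45


class TestClassifyPatterns:
    def test_hand_profiles_hit_all_three_classes(self):
        samples = _samples()
        ids = [s.sample_id for s in samples]
        t0 = np.array([1.0 if s.time_h == 0 else 0 for s in samples])
        ctrl = np.array(
            [1.0 if (s.condition == "BLANK" and s.time_h == 48) else 0 for s in samples]
        )
        up = np.array([s.time_h for s in samples], dtype=float)
        X = pd.DataFrame(
            [t0 / t0.sum(), ctrl / ctrl.sum(), up / up.sum()],
            index=["a", "b", "c"], columns=ids,
        )
        clusters = pd.Series([0, 1, 2], index=X.index)
        got = {a.gene_id: a.pattern for a in classify_patterns(X, samples, clusters)}
        assert got == {"a": "T0_ONLY", "b": "CONTROL_LATE", "c": "UP_LATE"}

    def test_uniform_shares_with_many_cells_are_other(self):
        samples = _samples(conditions=("BLANK", "IMMP27", "IMMP94", "IMMP96"),
                           times=(0, 6, 12, 24, 48))
        ids = [s.sample_id for s in samples]
        X = pd.DataFrame(
            [np.full(len(ids), 1.0 / len(ids))], index=["u"], columns=ids
        )
        clusters = pd.Series([0], index=X.index)
        (a,) = classify_patterns(X, samples, clusters)
        assert a.pattern == "OTHER"  # 20 cells: uniform share < theta everywhere

    def test_noise_genes_carry_no_pattern(self):
        samples = _samples()
        ids = [s.sample_id for s in samples]
        X = pd.DataFrame(
            np.full((2, len(ids)), 1.0 / len(ids)), index=["a", "b"], columns=ids
        )
        clusters = pd.Series([-1, -1], index=X.index)
        for a in classify_patterns(X, samples, clusters):
            assert a.is_noise and a.pattern is None

    def test_cluster_label_is_majority_vote(self):
        samples = _samples()
        ids = [s.sample_id for s in samples]
        t0 = np.array([1.0 if s.time_h == 0 else 0 for s in samples])
        up = np.array([s.time_h for s in samples], dtype=float)
        rows = [t0 / t0.sum(), t0 / t0.sum(), up / up.sum()]
        X = pd.DataFrame(rows, index=["a", "b", "c"], columns=ids)
        clusters = pd.Series([0, 0, 0], index=X.index)
        got = {a.gene_id: a.pattern for a in classify_patterns(X, samples, clusters)}
        assert set(got.values()) == {"T0_ONLY"}

    def test_missing_t0_columns_rejected(self):
        samples = _samples(times=(24, 48))
        ids = [s.sample_id for s in samples]
        X = pd.DataFrame(np.full((1, len(ids)), 1 / len(ids)), index=["a"], columns=ids)
        with pytest.raises(ValueError, match="t0"):
            classify_patterns(X, samples, pd.Series([0], index=X.index))
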