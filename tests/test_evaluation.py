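import numpy as np
import pytest
from itertools import combinations

import cmimpute as cm


def _grid(combos, means, probe_ids=None):
    means = np.asarray(means, float)
    probe_ids = probe_ids or [f"p{j}" for j in range(means.shape[1])]
    return cm.CombinationGrid(combos, means, probe_ids)


def _random_combo_dataset(rng, n_species=3, n_tissues=3, n_per=2, n_probes=5,
                          drop=0):
    species, tissue, rows, ids = [], [], [], []
    combos = [(s, t) for s in range(n_species) for t in range(n_tissues)]
    if drop:
        keep = rng.choice(len(combos), size=len(combos) - drop, replace=False)
        combos = [combos[i] for i in sorted(keep)]
    for s, t in combos:
        for i in range(n_per):
            species.append(f"s{s}")
            tissue.append(f"t{t}")
            rows.append(rng.uniform(0.05, 0.95, size=n_probes))
            ids.append(f"s{s}_t{t}_{i}")
    return cm.MethylationDataset(np.array(rows), ids, species, tissue,
                                 [f"p{j}" for j in range(n_probes)])


class TestSamplewiseMetrics:
    def test_identity_gives_perfect_scores(self):
        g = _grid([("a", "x"), ("b", "x")], [[0.1, 0.5, 0.9], [0.2, 0.3, 0.4]])
        df = cm.samplewise_metrics(g, g)
        np.testing.assert_allclose(df["pearson"], 1.0)
        assert (df["mse"] == 0.0).all()

    def test_antisymmetry(self):
        obs = _grid([("a", "x")], [[0.1, 0.5, 0.9]])
        imp = _grid([("a", "x")], [[0.9, 0.5, 0.1]])
        df = cm.samplewise_metrics(imp, obs)
        assert df["pearson"].iloc[0] == pytest.approx(-1.0)

    def test_worked_three_probe_mse(self):
        obs = _grid([("a", "x")], [[0.2, 0.4, 0.9]])
        imp = _grid([("a", "x")], [[0.1, 0.5, 0.9]])
        df = cm.samplewise_metrics(imp, obs)
        assert df["mse"].iloc[0] == pytest.approx((0.01 + 0.01 + 0.0) / 3)

    def test_constant_vector_reported_missing(self):
        obs = _grid([("a", "x")], [[0.3, 0.3, 0.3]])
        imp = _grid([("a", "x")], [[0.1, 0.2, 0.3]])
        df = cm.samplewise_metrics(imp, obs)
        assert np.isnan(df["pearson"].iloc[0])
        assert not np.isnan(df["mse"].iloc[0])

    def test_mismatched_combos_error(self):
        a = _grid([("a", "x")], [[0.1, 0.2]])
        b = _grid([("b", "x")], [[0.1, 0.2]])
        with pytest.raises(ValueError):
            cm.samplewise_metrics(a, b)


class TestProbewiseMetrics:
    def test_identity(self):
        g = _grid([("a", "x"), ("b", "x"), ("c", "x")],
                  [[0.1, 0.9], [0.5, 0.2], [0.8, 0.4]])
        df = cm.probewise_metrics(g, g)
        np.testing.assert_allclose(df["pearson"], 1.0)

    def test_constant_probe_missing(self):
        obs = _grid([("a", "x"), ("b", "x")], [[0.3, 0.1], [0.3, 0.9]])
        imp = _grid([("a", "x"), ("b", "x")], [[0.2, 0.2], [0.4, 0.8]])
        df = cm.probewise_metrics(imp, obs)
        assert np.isnan(df["pearson"].iloc[0])
        assert df["pearson"].iloc[1] == pytest.approx(1.0)

    def test_four_combo_worked_correlation(self):
        obs_col = np.array([0.1, 0.4, 0.6, 0.9])
        imp_col = np.array([0.2, 0.3, 0.7, 0.8])
        obs = _grid([("a", "x"), ("b", "x"), ("c", "x"), ("d", "x")],
                    obs_col[:, None])
        imp = _grid(list(obs.combos), imp_col[:, None])
        df = cm.probewise_metrics(imp, obs)
        expected = np.corrcoef(imp_col, obs_col)[0, 1]
        assert df["pearson"].iloc[0] == pytest.approx(expected)

    def test_transpose_consistency_with_samplewise(self):
        """Probe-wise on transposed grids equals sample-wise on the originals."""
        rng = np.random.default_rng(3)
        combos = [(f"s{i}", "x") for i in range(4)]
        obs = _grid(combos, rng.random((4, 6)))
        imp = _grid(combos, rng.random((4, 6)))
        sw = cm.samplewise_metrics(imp, obs)
        obs_t = _grid([(f"p{j}", "y") for j in range(6)], obs.means.T,
                      [c[0] for c in combos])
        imp_t = _grid([(f"p{j}", "y") for j in range(6)], imp.means.T,
                      [c[0] for c in combos])
        pw_t = cm.probewise_metrics(imp_t, obs_t)
        np.testing.assert_allclose(sw["pearson"].to_numpy(), pw_t["pearson"].to_numpy())
        np.testing.assert_allclose(sw["mse"].to_numpy(), pw_t["mse"].to_numpy())


class TestProbeVariances:
    def test_identical_means_give_zero(self):
        rng = np.random.default_rng(0)
        row = rng.random(4)
        beta = np.vstack([row] * 4)
        ds = cm.MethylationDataset(beta, list("abcd"), ["s1", "s1", "s2", "s2"],
                                   ["t1", "t2", "t1", "t2"],
                                   [f"p{j}" for j in range(4)])
        pv = cm.probe_variances(ds)
        np.testing.assert_allclose(pv.inter_combination, 0.0, atol=1e-15)
        np.testing.assert_allclose(pv.mean_inter_tissue, 0.0, atol=1e-15)
        np.testing.assert_allclose(pv.mean_inter_species, 0.0, atol=1e-15)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_nested_loop_oracle(self, seed):
        """All three procedures equal explicit nested loops over combination
        means: population variance across combos, across tissues averaged over
        multi-tissue species, and across species averaged over multi-species
        tissues."""
        rng = np.random.default_rng(seed)
        ds = _random_combo_dataset(rng, drop=rng.integers(0, 3))
        pv = cm.probe_variances(ds)
        grid = cm.observed_grid(ds)
        mean_of = {c: grid.means[i] for i, c in enumerate(grid.combos)}

        def pop_var(rows):
            arr = np.stack(rows)
            mu = arr.sum(axis=0) / len(arr)
            return ((arr - mu) ** 2).sum(axis=0) / len(arr)

        np.testing.assert_allclose(
            pv.inter_combination, pop_var(list(mean_of.values())), atol=1e-12
        )
        species = sorted({s for s, _ in grid.combos})
        per_species = []
        for s in species:
            rows = [mean_of[c] for c in grid.combos if c[0] == s]
            if len(rows) > 1:
                per_species.append(pop_var(rows))
        np.testing.assert_allclose(
            pv.mean_inter_tissue, np.sum(per_species, axis=0) / len(per_species),
            atol=1e-12,
        )
        tissues = sorted({t for _, t in grid.combos})
        per_tissue = []
        for t in tissues:
            rows = [mean_of[c] for c in grid.combos if c[1] == t]
            if len(rows) > 1:
                per_tissue.append(pop_var(rows))
        np.testing.assert_allclose(
            pv.mean_inter_species, np.sum(per_tissue, axis=0) / len(per_tissue),
            atol=1e-12,
        )

    def test_single_tissue_species_contributes_nothing(self):
        beta = np.array([[0.2], [0.8], [0.4], [0.6], [0.5]])
        ds = cm.MethylationDataset(
            beta, list("abcde"),
            ["s1", "s1", "s2", "s2", "s3"],
            ["t1", "t2", "t1", "t2", "t1"],
            ["p0"],
        )
        pv = cm.probe_variances(ds)
        # oracle: only s1 and s2 have >1 tissue
        v1 = np.var([0.2, 0.8])
        v2 = np.var([0.4, 0.6])
        assert pv.mean_inter_tissue[0] == pytest.approx((v1 + v2) / 2)

    def test_additive_decomposition_on_crossed_grid(self):
        """With a fully crossed grid and additive combo means, the
        inter-combination variance splits exactly into the mean inter-tissue
        plus mean inter-species variances."""
        rng = np.random.default_rng(7)
        n_s, n_t, m = 4, 3, 6
        a = rng.normal(size=(n_s, m))
        b = rng.normal(size=(n_t, m))
        rows, species, tissue, ids = [], [], [], []
        for i in range(n_s):
            for j in range(n_t):
                rows.append(0.5 + 0.1 * (a[i] + b[j]))
                species.append(f"s{i}")
                tissue.append(f"t{j}")
                ids.append(f"{i}_{j}")
        beta = np.clip(np.array(rows), 0, 1)
        ds = cm.MethylationDataset(beta, ids, species, tissue,
                                   [f"p{j}" for j in range(m)])
        pv = cm.probe_variances(ds)
        np.testing.assert_allclose(
            pv.inter_combination, pv.mean_inter_tissue + pv.mean_inter_species,
            atol=1e-12,
        )

    def test_undefined_inter_tissue_errors(self):
        ds = cm.MethylationDataset(
            np.array([[0.1], [0.9]]), ["a", "b"], ["s1", "s2"], ["t1", "t1"],
            ["p0"],
        )
        with pytest.raises(ValueError, match="inter-tissue"):
            cm.probe_variances(ds)


class TestQuartileSummary:
    def test_equal_split_of_eight(self):
        metric = np.arange(8, dtype=float)
        variances = np.arange(8, dtype=float)
        df = cm.quartile_summary(metric, variances)
        assert df["n_probes"].tolist() == [2, 2, 2, 2]

    def test_monotone_metric_gives_monotone_quartiles(self):
        rng = np.random.default_rng(1)
        variances = rng.random(40)
        metric = 2.0 * variances + 1.0
        df = cm.quartile_summary(metric, variances)
        assert df["mean_metric"].is_monotonic_increasing

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_sort_and_slice_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(8, 30))
        metric = rng.normal(size=m)
        metric[rng.random(m) < 0.1] = np.nan
        variances = rng.random(m)
        df = cm.quartile_summary(metric, variances)
        order = np.argsort(variances, kind="stable")
        chunks = np.array_split(order, 4)
        for q, idx in enumerate(chunks, start=1):
            expected = np.nanmean(metric[idx])
            got = df.loc[q, "mean_metric"]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)


class TestIndividualVariability:
    def test_identical_duplicates_give_one(self):
        rng = np.random.default_rng(2)
        row = rng.random(5)
        ds = cm.MethylationDataset(np.vstack([row, row]), ["a", "b"],
                                   ["s", "s"], ["t", "t"],
                                   [f"p{j}" for j in range(5)])
        series, overall = cm.individual_variability(ds)
        assert overall == pytest.approx(1.0)

    def test_single_individual_combo_excluded(self, tiny_dataset):
        series, overall = cm.individual_variability(tiny_dataset)
        assert set(series.index) == {"cat|blood"}

    def test_three_individuals_match_enumeration(self):
        rng = np.random.default_rng(4)
        beta = rng.random((3, 6))
        ds = cm.MethylationDataset(beta, list("abc"), ["s"] * 3, ["t"] * 3,
                                   [f"p{j}" for j in range(6)])
        series, overall = cm.individual_variability(ds)
        expected = np.mean(
            [np.corrcoef(beta[i], beta[j])[0, 1]
             for i, j in combinations(range(3), 2)]
        )
        assert overall == pytest.approx(expected)


def _auc_oracle(scores, labels):
    """Exhaustive pair-counting AUC with ties credited 0.5."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestSignalAUC:
    def test_perfect_separation(self):
        # two species x two tissues; same-species rows identical
        means = np.array([[0.1, 0.2, 0.9], [0.1, 0.2, 0.9],
                          [0.9, 0.8, 0.1], [0.9, 0.8, 0.1]])
        g = _grid([("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")], means)
        assert cm.signal_auc(g, "species") == 1.0

    def test_pure_ties_give_half(self):
        rng = np.random.default_rng(0)
        row = rng.random(4)
        means = np.vstack([row] * 4) + np.outer([0, 1, 2, 3], np.zeros(4))
        # all rows identical -> all pairwise correlations equal (nan actually)
        g = _grid([("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")], means)
        assert cm.signal_auc(g, "species") == 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        combos = [("a", "x"), ("a", "y"), ("b", "x"), ("b", "z"), ("c", "y")]
        g = _grid(combos, rng.random((5, 7)))
        means = g.means
        for mode, which in (("species", 0), ("tissue", 1)):
            scores, labels = [], []
            for i, j in combinations(range(5), 2):
                scores.append(np.corrcoef(means[i], means[j])[0, 1])
                labels.append(combos[i][which] == combos[j][which])
            assert cm.signal_auc(g, mode) == pytest.approx(
                _auc_oracle(scores, labels), abs=1e-12
            )

    def test_invariant_to_monotone_transform_of_scores(self):
        """Rank-based AUC depends only on the score ordering, checked by
        comparing against the oracle on raw and squashed scores."""
        rng = np.random.default_rng(9)
        combos = [("a", "x"), ("a", "y"), ("b", "x"), ("b", "y"), ("c", "x")]
        g = _grid(combos, rng.random((5, 6)))
        scores, labels = [], []
        for i, j in combinations(range(5), 2):
            scores.append(np.corrcoef(g.means[i], g.means[j])[0, 1])
            labels.append(combos[i][0] == combos[j][0])
        raw = _auc_oracle(scores, labels)
        squashed = _auc_oracle(list(np.tanh(5 * np.asarray(scores))), labels)
        assert cm.signal_auc(g, "species") == pytest.approx(raw) == pytest.approx(squashed)

    def test_no_positive_pairs_errors(self):
        g = _grid([("a", "x"), ("b", "y")], np.random.default_rng(0).random((2, 3)))
        with pytest.raises(ValueError):
            cm.signal_auc(g, "species")


class TestRemoveSpeciesSignal:
    def test_species_baseline_grid_maps_to_zero(self, tiny_dataset):
        grid = cm.mean_baseline_grid(
            tiny_dataset, [("cat", "blood"), ("dog", "blood")], "species"
        )
        delta = cm.remove_species_signal(grid, tiny_dataset)
        np.testing.assert_allclose(delta.means, 0.0, atol=1e-15)

    def test_matches_direct_subtraction(self, tiny_dataset):
        grid = cm.observed_grid(tiny_dataset)
        delta = cm.remove_species_signal(grid, tiny_dataset)
        for i, (s, _t) in enumerate(grid.combos):
            np.testing.assert_allclose(
                delta.means[i], grid.means[i] - cm.species_baseline(tiny_dataset, s)
            )
        assert (delta.means >= -1).all() and (delta.means <= 1).all()


class TestPairedComparison:
    def test_equal_vectors_undefined_test(self):
        frac, p = cm.paired_comparison([0.5, 0.6], [0.5, 0.6])
        assert frac == 0.0
        assert np.isnan(p)

    def test_six_all_positive_exact_p(self):
        a = np.array([0.2, 0.3, 0.4, 0.5, 0.6, 0.7])
        b = a - 0.05
        frac, p = cm.paired_comparison(a, b)
        assert frac == 1.0
        assert p == pytest.approx(2 / 64, abs=1e-12)

    def test_matches_sign_flip_enumeration(self):
        """Exact two-sided p equals full enumeration of sign patterns."""
        rng = np.random.default_rng(8)
        d = rng.normal(size=10)
        frac, p = cm.paired_comparison(d, np.zeros(10))
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = ranks[d > 0].sum()
        n = len(d)
        mid = ranks.sum() / 2
        count = 0
        for mask in range(2 ** n):
            bits = [(mask >> i) & 1 for i in range(n)]
            w = sum(r for r, b in zip(ranks, bits) if b)
            if abs(w - mid) >= abs(w_obs - mid) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 2 ** n, abs=1e-10)

    def test_large_n_normal_approximation_close_to_enumeration(self):
        rng = np.random.default_rng(12)
        a = rng.random(50)
        b = a + rng.normal(0, 0.05, size=50)
        _frac, p = cm.paired_comparison(a, b)
        assert 0 <= p <= 1
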