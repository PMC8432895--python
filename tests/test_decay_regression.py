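"""Decay regression: pair dataset construction, OLS oracle equivalence,
degrees of freedom, permutation behavior."""

import numpy as np
import pandas as pd
import pytest

from synteny_decay.decay_regression import (
    SyntenyDecayModel,
    build_pair_dataset,
    compare_models,
    subset_excluding,
)


def square(vals, taxa):
    return pd.DataFrame(vals, index=taxa, columns=taxa)


def random_matrices(rng, orders, d_scale=0.5):
    """Random symmetric GOC-like (positive) and distance matrices plus an
    order map; ``orders`` maps order name -> taxon count."""
    taxa, omap = [], {}
    for o, n in orders.items():
        for k in range(n):
            t = f"{o}_{k}"
            taxa.append(t)
            omap[t] = o
    n = len(taxa)
    g = rng.uniform(0.05, 1.0, size=(n, n))
    g = (g + g.T) / 2
    np.fill_diagonal(g, 1.0)
    d = rng.uniform(0.05, d_scale, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return square(g, taxa), square(d, taxa), omap


def pairs_from_model(rng, order_params, n_per_order, sigma=0.1, d_lo=0.02, d_hi=0.6):
    """Tidy pair table generated from y = exp(a + b d) * lognoise."""
    rows = []
    for o, (a, b) in order_params.items():
        d = rng.uniform(d_lo, d_hi, size=n_per_order)
        y = np.exp(a + b * d + rng.normal(0, sigma, size=n_per_order))
        for di, yi in zip(d, y):
            rows.append(("x", "y", o, di, yi))
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "order", "d", "y"])


class TestPairDataset:
    def test_two_orders_of_two(self):
        rng = np.random.default_rng(0)
        G, D, omap = random_matrices(rng, {"O1": 2, "O2": 2})
        pairs = build_pair_dataset(G, D, omap, min_taxa_per_order=2)
        assert len(pairs) == 2  # one within-order pair each

    def test_large_order_pair_count(self):
        # an order of 79 taxa contributes C(79,2) = 3081 pairs
        rng = np.random.default_rng(1)
        G, D, omap = random_matrices(rng, {"Lepidoptera": 79})
        pairs = build_pair_dataset(G, D, omap)
        assert len(pairs) == 3081

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        G, D, omap = random_matrices(rng, {"A": 5, "B": 4, "C": 6})
        pairs = build_pair_dataset(G, D, omap, min_taxa_per_order=2)
        taxa = list(G.index)
        expected = set()
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j and omap[a] == omap[b]:
                    expected.add((a, b, omap[a], D.iat[i, j], G.iat[i, j]))
        got = set(map(tuple, pairs.itertuples(index=False)))
        assert got == expected

    def test_small_orders_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        G, D, omap = random_matrices(rng, {"Big": 6, "Tiny": 2})
        with pytest.warns(UserWarning, match="Tiny"):
            pairs = build_pair_dataset(G, D, omap, min_taxa_per_order=4)
        assert set(pairs["order"]) == {"Big"}

    def test_taxon_mismatch_raises(self):
        rng = np.random.default_rng(4)
        G, D, omap = random_matrices(rng, {"A": 4})
        D2 = D.iloc[:3, :3]
        with pytest.raises(ValueError, match="differ"):
            build_pair_dataset(G, D2, omap)

    def test_unclassified_taxon_raises(self):
        rng = np.random.default_rng(5)
        G, D, omap = random_matrices(rng, {"A": 4})
        del omap["A_0"]
        with pytest.raises(ValueError, match="classification"):
            build_pair_dataset(G, D, omap)


class TestSubsetExcluding:
    def test_removal_counts(self):
        rng = np.random.default_rng(6)
        pairs = pairs_from_model(rng, {"A": (1, -2), "B": (1, -2)}, 10)
        sub = subset_excluding(pairs, "A")
        assert len(sub) == 10
        assert set(sub["order"]) == {"B"}

    def test_unknown_order_raises(self):
        rng = np.random.default_rng(7)
        pairs = pairs_from_model(rng, {"A": (1, -2)}, 5)
        with pytest.raises(KeyError):
            subset_excluding(pairs, "Nope")

    def test_partition(self):
        rng = np.random.default_rng(8)
        pairs = pairs_from_model(rng, {"A": (1, -2), "B": (0, -1), "C": (2, -3)}, 7)
        removed = [
            pairs[pairs["order"] == o] for o in ("A", "B", "C")
        ]
        assert sum(len(r) for r in removed) == len(pairs)


class TestFit:
    def test_noiseless_exponential_recovery(self):
        d = np.linspace(0.05, 1.0, 40)
        y = np.exp(2 - 3 * d)
        pairs = pd.DataFrame({"order": "O", "d": d, "y": y})
        res = SyntenyDecayModel(pairs, form="exponential").fit()
        assert res.params.loc["O", "slope"] == pytest.approx(-3.0, abs=1e-10)
        assert res.params.loc["O", "intercept"] == pytest.approx(2.0, abs=1e-10)
        assert res.rss == pytest.approx(0.0, abs=1e-10)
        assert res.F > 1e8  # RSS ~ 0

    @pytest.mark.parametrize("form", ["linear", "exponential", "power"])
    def test_matches_statsmodels_oracle(self, form):
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        for _ in range(5):
            pairs = pairs_from_model(
                rng, {"A": (1.0, -2.0), "B": (0.5, -4.0)}, 30, sigma=0.2
            )
            res = SyntenyDecayModel(pairs, form=form).fit()
            d, y = pairs["d"].to_numpy(), pairs["y"].to_numpy()
            if form == "linear":
                x, z = d, y
            elif form == "exponential":
                x, z = d, np.log(y)
            else:
                x, z = np.log(d), np.log(y)
            X = []
            orders = sorted(pairs["order"].unique())
            for o in orders:
                ind = (pairs["order"] == o).to_numpy().astype(float)
                X.append(ind)
                X.append(ind * x)
            fit = sm.OLS(z, np.column_stack(X)).fit()
            for i, o in enumerate(orders):
                assert res.params.loc[o, "intercept"] == pytest.approx(
                    fit.params[2 * i], rel=1e-8
                )
                assert res.params.loc[o, "slope"] == pytest.approx(
                    fit.params[2 * i + 1], rel=1e-8
                )
            assert res.rss == pytest.approx(float(fit.ssr), rel=1e-8)
            # F against intercept-only on the same response scale
            assert res.F == pytest.approx(
                float(fit.fvalue), rel=1e-8
            )

    @pytest.mark.parametrize("m", [2, 3, 4, 5, 6])
    def test_df_identities(self, m):
        rng = np.random.default_rng(m)
        params = {f"O{i}": (1.0, -2.0) for i in range(m)}
        pairs = pairs_from_model(rng, params, 12)
        res = SyntenyDecayModel(pairs, form="exponential").fit()
        n = len(pairs)
        assert res.df_model == 2 * m - 1
        assert res.df_resid == n - 2 * m
        assert res.df_model + res.df_resid + 1 == n

    def test_published_df_structure(self):
        """With five orders and 3,600 pairs the by-order design has
        (9, 3590) df; excluding the largest order (3,081 pairs) leaves four
        orders on 519 pairs with interaction df (3, 511)."""
        rng = np.random.default_rng(99)
        sizes = {"Lepidoptera": 3081, "A": 150, "B": 150, "C": 120, "D": 99}
        pairs = pd.concat(
            [
                pairs_from_model(rng, {o: (1.0, -2.0)}, n)
                for o, n in sizes.items()
            ],
            ignore_index=True,
        )
        assert len(pairs) == 3600
        res = SyntenyDecayModel(pairs, form="exponential").fit()
        assert (res.df_model, res.df_resid) == (9, 3590)
        sub = subset_excluding(pairs, "Lepidoptera")
        assert len(sub) == 519
        res2 = SyntenyDecayModel(sub, form="exponential").fit()
        m = 4
        q, df_full = m - 1, len(sub) - 2 * m
        assert (q, df_full) == (3, 511)

    def test_nonpositive_y_under_log_raises_above_threshold(self):
        d = np.linspace(0.1, 1, 50)
        y = np.exp(-d)
        y[:3] = 0.0  # 6% nonpositive
        pairs = pd.DataFrame({"order": "O", "d": d, "y": y})
        with pytest.raises(ValueError, match="nonpositive"):
            SyntenyDecayModel(pairs, form="exponential").fit()
        res = SyntenyDecayModel(
            pairs, form="exponential", nonpositive="force"
        ).fit()
        assert res.n_dropped == 3
        assert res.n == 47

    def test_predict_on_original_scale(self):
        d = np.linspace(0.05, 1.0, 30)
        y = np.exp(1.5 - 2.5 * d)
        pairs = pd.DataFrame({"order": "O", "d": d, "y": y})
        res = SyntenyDecayModel(pairs, form="exponential").fit()
        assert np.allclose(res.predict(d, order="O"), y, rtol=1e-8)


class TestPermutation:
    def test_reproducible_and_bounded(self):
        rng = np.random.default_rng(20)
        G, D, omap = random_matrices(rng, {"A": 8, "B": 8})
        m = SyntenyDecayModel.from_matrices(G, D, omap, form="exponential")
        r1 = m.permutation_test(n_perm=99, seed=123)
        r2 = m.permutation_test(n_perm=99, seed=123)
        assert np.array_equal(r1.null_F, r2.null_F)
        assert r1.p == r2.p
        assert r1.p >= 1 / 100

    def test_strong_signal_minimal_p(self):
        """Cleanly separated signal: observed F exceeds every permuted F."""
        rng = np.random.default_rng(21)
        tree_taxa = {"A": 20, "B": 20}
        from synteny_decay.synthetic_data import random_clade_tree
        from synteny_decay.phylo_distance import patristic_matrix

        tree, omap = random_clade_tree(tree_taxa, seed=21)
        D = patristic_matrix(tree)
        taxa = list(D.index)
        n = len(taxa)
        g = np.exp(1 - 5 * D.values + rng.normal(0, 0.05, size=(n, n)))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 1.0)
        G = square(g, taxa)
        m = SyntenyDecayModel.from_matrices(G, D, omap, form="exponential")
        r = m.permutation_test(n_perm=999, seed=7)
        assert r.p == pytest.approx(1 / 1000)

    def test_requires_matrix_context(self):
        pairs = pd.DataFrame(
            {"order": ["O"] * 10, "d": np.linspace(0.1, 1, 10), "y": np.exp(-np.linspace(0.1, 1, 10))}
        )
        m = SyntenyDecayModel(pairs)
        with pytest.raises(ValueError, match="from_matrices"):
            m.permutation_test(n_perm=9, seed=0)

    def test_single_order_interaction_raises(self):
        rng = np.random.default_rng(23)
        G, D, omap = random_matrices(rng, {"A": 6})
        m = SyntenyDecayModel.from_matrices(G, D, omap)
        with pytest.raises(ValueError, match="2 orders"):
            m.interaction_test(n_perm=9, seed=0)

    def test_nperm_validation(self):
        rng = np.random.default_rng(24)
        G, D, omap = random_matrices(rng, {"A": 5, "B": 5})
        m = SyntenyDecayModel.from_matrices(G, D, omap)
        with pytest.raises(ValueError, match="n_perm"):
            m.permutation_test(n_perm=0, seed=1)


class TestCompareModels:
    def test_exponential_data_ranked_first(self):
        rng = np.random.default_rng(30)
        from synteny_decay.synthetic_data import random_clade_tree
        from synteny_decay.phylo_distance import patristic_matrix

        tree, omap = random_clade_tree({"A": 15, "B": 15}, seed=30)
        D = patristic_matrix(tree)
        taxa = list(D.index)
        n = len(taxa)
        g = np.exp(0.5 - 4 * D.values + rng.normal(0, 0.1, size=(n, n)))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 1.0)
        report = compare_models(square(g, taxa), D, omap, n_perm=49, seed=2)
        assert report.iloc[0]["form"] == "exponential"
        assert list(report["rank"]) == [1, 2, 3]
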