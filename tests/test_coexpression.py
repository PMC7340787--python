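"""Network core: adjacency, scale-free fit, TOM, cut, eigengenes, traits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from coexppi.coexpression import (
    CoexpressionNetwork,
    ModuleAssignment,
    choose_power,
    cluster_and_cut,
    module_eigengenes,
    module_trait_correlation,
    scale_free_fit,
    select_critical_module,
    soft_adjacency,
    tom_similarity,
)
from coexppi.synthetic import SyntheticDesign, generate_expression, generate_traits
from coexppi.utils import CoexppiError


def _pair_matrix(cor, n_samples=200, seed=0):
    """Two genes with (approximately exact) correlation ``cor``."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_samples)
    y = rng.standard_normal(n_samples)
    # orthogonalize then mix for an exact sample correlation
    x = (x - x.mean()) / x.std()
    y = y - y.mean()
    y -= x * (x @ y) / (x @ x)
    y /= y.std()
    z = cor * x + np.sqrt(1 - cor**2) * y
    return pd.DataFrame([x, z], index=["a", "b"])


class TestSoftAdjacency:
    @pytest.mark.parametrize(
        "cor,power,mode,expected",
        [
            (0.5, 5, "unsigned", 0.5**5),
            (0.5, 1, "unsigned", 0.5),
            (-0.5, 5, "unsigned", 0.5**5),
            (-0.5, 5, "signed", 0.25**5),
        ],
    )
    def test_known_correlations(self, cor, power, mode, expected):
        m = _pair_matrix(cor)
        adj = soft_adjacency(m, power, mode=mode)
        assert adj[0, 1] == pytest.approx(expected, abs=1e-12)
        assert adj[0, 0] == adj[1, 1] == 1.0

    def test_constant_gene_named_in_error(self):
        m = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4]], index=["flat", "ok"])
        with pytest.raises(CoexppiError, match="flat"):
            soft_adjacency(m, 2)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(min_value=1, max_value=10), st.integers(min_value=0, max_value=99))
    def test_raising_power_weakly_decreases_entries(self, power, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.standard_normal((6, 30)))
        a1 = soft_adjacency(m, power)
        a2 = soft_adjacency(m, power + 1)
        assert (a2 <= a1 + 1e-12).all()


def _block_adjacency(sizes, z=0.5):
    """Disconnected equal-weight cliques whose binned log-log degree points
    are exactly collinear with slope -1 (k_m = z / c_m)."""
    n = sum(sizes)
    adj = np.zeros((n, n))
    start = 0
    for c in sizes:
        w = (z / c) / (c - 1)
        adj[start:start + c, start:start + c] = w
        start += c
    np.fill_diagonal(adj, 1.0)
    return adj


class TestScaleFreeFit:
    def test_collinear_negative_slope_gives_signed_r2_one(self):
        fit = scale_free_fit(_block_adjacency([32, 16, 8, 4]), n_bins=10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)
        assert fit.slope < 0

    def test_regular_graph_flagged_zero(self):
        adj = np.full((12, 12), 0.3)
        np.fill_diagonal(adj, 1.0)
        fit = scale_free_fit(adj)
        assert fit.degenerate and fit.r_squared == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_least_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        adj = rng.uniform(0, 1, (40, 40)) ** 3
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 1.0)
        fit = scale_free_fit(adj, n_bins=10)

        # oracle: same binning, closed-form least squares
        k = adj.sum(axis=0) - 1.0
        edges = np.linspace(k.min(), k.max(), 11)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        xs, ys = [], []
        for b in range(10):
            mask = which == b
            if mask.any() and k[mask].mean() > 0:
                xs.append(np.log10(k[mask].mean()))
                ys.append(np.log10(mask.sum() / 40))
        xs, ys = np.array(xs), np.array(ys)
        slope = ((xs - xs.mean()) * (ys - ys.mean())).sum() / ((xs - xs.mean()) ** 2).sum()
        r2 = np.corrcoef(xs, ys)[0, 1] ** 2
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.r_squared == pytest.approx(-np.sign(slope) * r2, abs=1e-10)


class TestChoosePower:
    def test_first_exceedance_and_fallback(self, small_world):
        _, expr, _ = small_world
        power, table = choose_power(expr, candidates=range(1, 9), threshold=0.9)
        above = table[table.r_squared > 0.9]
        if len(above):
            assert power == int(above.power.iloc[0])
        else:
            assert power == int(table.loc[table.r_squared.idxmax(), "power"])

    def test_fallback_warns_when_nothing_qualifies(self, small_world):
        _, expr, _ = small_world
        with pytest.warns(UserWarning, match="argmax"):
            choose_power(expr, candidates=[1], threshold=0.999)


class TestTOM:
    def test_complete_graph_overlap_is_one(self):
        adj = np.ones((3, 3))
        assert np.allclose(tom_similarity(adj), 1.0)

    def test_zero_offdiagonal_gives_zero_overlap(self):
        tom = tom_similarity(np.eye(4))
        assert np.allclose(tom, np.eye(4))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_triple_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        adj = rng.uniform(0, 1, (n, n))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 1.0)
        tom = tom_similarity(adj)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l_ij = sum(adj[i, u] * adj[u, j] for u in range(n) if u not in (i, j))
                k_i = sum(adj[i, u] for u in range(n) if u != i)
                k_j = sum(adj[j, u] for u in range(n) if u != j)
                expected = (l_ij + adj[i, j]) / (min(k_i, k_j) + 1 - adj[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=9999))
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 15))
        adj = rng.uniform(0, 1, (n, n))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 1.0)
        tom = tom_similarity(adj)
        assert np.allclose(tom, tom.T, atol=1e-10)
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()
        assert np.allclose(np.diag(tom), 1.0)


class TestClusterAndCut:
    def test_noiseless_planted_blocks_recovered_exactly(self):
        design = SyntheticDesign(
            n_genes=50, n_samples=60, module_sizes=(20, 20), background_genes=10,
            factor_loading_range=(1.0, 1.0), seed=3,
        )
        expr, truth = generate_expression(design)
        tom = tom_similarity(soft_adjacency(expr, 5))
        assignment = cluster_and_cut(tom, expr, min_module_size=10)
        truth_labels = [truth.module_of_gene.get(g, "grey") for g in expr.index]
        assert len(assignment) == 2
        assert adjusted_rand_score(truth_labels, assignment.labels.tolist()) == 1.0

    def test_iid_noise_yields_no_modules(self, noise_matrix):
        tom = tom_similarity(soft_adjacency(noise_matrix, 5))
        assignment = cluster_and_cut(tom, noise_matrix, min_module_size=10)
        assert len(assignment) == 0
        assert (assignment.labels == "grey").all()

    def test_fewer_genes_than_min_size_all_grey(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.standard_normal((5, 20)), index=list("abcde"))
        tom = tom_similarity(soft_adjacency(m, 2))
        with pytest.warns(UserWarning, match="grey"):
            assignment = cluster_and_cut(tom, m, min_module_size=10)
        assert (assignment.labels == "grey").all()

    def test_labels_are_size_ordered_colors(self, small_world):
        _, expr, _ = small_world
        tom = tom_similarity(soft_adjacency(expr, 5))
        assignment = cluster_and_cut(tom, expr)
        sizes = assignment.sizes().drop("grey", errors="ignore")
        assert list(assignment.modules[:3]) == ["turquoise", "blue", "brown"]
        ordered = [sizes[m] for m in assignment.modules]
        assert ordered == sorted(ordered, reverse=True)


class TestEigengenes:
    def test_identical_genes_give_common_profile(self):
        rng = np.random.default_rng(1)
        profile = rng.standard_normal(40)
        m = pd.DataFrame([profile * 2, profile * 3, profile * 0.5],
                         index=["a", "b", "c"])
        assignment = ModuleAssignment(pd.Series("blue", index=m.index))
        me = module_eigengenes(m, assignment)
        eig = me.eigengenes["blue"].to_numpy()
        std_profile = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(eig, std_profile, atol=1e-10)
        assert me.variance_explained["blue"] == pytest.approx(1.0)

    def test_noiseless_factor_module_recovers_factor(self):
        design = SyntheticDesign(
            n_genes=22, n_samples=50, module_sizes=(20,), background_genes=2,
            factor_loading_range=(1.0, 1.0), seed=5,
        )
        expr, truth = generate_expression(design)
        genes = [g for g, m in truth.module_of_gene.items() if m == "M1"]
        assignment = ModuleAssignment(
            pd.Series({g: ("m" if g in genes else "grey") for g in expr.index})
        )
        me = module_eigengenes(expr, assignment)
        cor = np.corrcoef(me.eigengenes["m"], truth.factor_matrix.iloc[0])[0, 1]
        assert abs(cor) == pytest.approx(1.0, abs=1e-10)

    def test_two_orthogonal_halves_split_variance(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        u, v = np.sin(t), np.cos(t)
        m = pd.DataFrame([u, u, u, v, v, v], index=list("abcdef"))
        assignment = ModuleAssignment(pd.Series("m", index=m.index))
        me = module_eigengenes(m, assignment)
        assert me.variance_explained["m"] == pytest.approx(0.5, abs=1e-10)

    def test_constant_gene_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        profile = rng.standard_normal(30)
        m = pd.DataFrame([profile, profile, np.ones(30)], index=["a", "b", "flat"])
        assignment = ModuleAssignment(pd.Series("m", index=m.index))
        with pytest.warns(UserWarning, match="flat"):
            me = module_eigengenes(m, assignment)
        assert me.variance_explained["m"] == pytest.approx(1.0)


class TestModuleTrait:
    def _stats(self, eig_values, trait_values):
        samples = [f"s{i}" for i in range(len(eig_values))]
        from coexppi.coexpression import ModuleEigengenes

        eig = ModuleEigengenes(
            eigengenes=pd.DataFrame({"m": eig_values}, index=samples),
            variance_explained=pd.Series({"m": 0.5}),
        )
        traits = pd.DataFrame({"t": trait_values}, index=samples)
        return module_trait_correlation(eig, traits)

    def test_identical_eigengene_and_trait(self):
        vals = np.arange(10.0)
        stats = self._stats(vals, vals)
        assert stats.correlation.loc["m", "t"] == pytest.approx(1.0)
        assert stats.p_value.loc["m", "t"] < 1e-12

    def test_orthogonal_eigengene_and_trait(self):
        t = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        stats = self._stats(np.sin(t), np.cos(t))
        assert stats.correlation.loc["m", "t"] == pytest.approx(0.0, abs=1e-12)
        assert stats.p_value.loc["m", "t"] == pytest.approx(1.0, abs=1e-6)

    def test_zero_variance_trait_flagged(self):
        stats = self._stats(np.arange(8.0), np.ones(8))
        assert stats.flagged_traits == ["t"]
        assert stats.correlation.loc["m", "t"] == 0.0
        assert stats.p_value.loc["m", "t"] == 1.0

    def test_gs_and_mm_equal_one_for_self(self):
        """A gene identical to the trait has GS 1; a gene tracking its own
        eigengene exactly has MM 1."""
        rng = np.random.default_rng(3)
        profile = rng.standard_normal(50)
        expr = pd.DataFrame(
            [profile, profile * 1.5], index=["a", "b"],
            columns=[f"s{i}" for i in range(50)],
        )
        assignment = ModuleAssignment(pd.Series("m", index=expr.index))
        me = module_eigengenes(expr, assignment)
        traits = pd.DataFrame({"t": profile}, index=expr.columns)
        stats = module_trait_correlation(me, traits, matrix=expr, assignment=assignment)
        assert stats.gene_significance.loc["a", "t"] == pytest.approx(1.0)
        assert stats.module_membership["a"] == pytest.approx(1.0)


class TestSelectCritical:
    def _stats(self, rs, ps, sizes=None):
        from coexppi.coexpression import ModuleTraitStats

        idx = list(rs)
        return ModuleTraitStats(
            correlation=pd.DataFrame({"t": pd.Series(rs)}),
            p_value=pd.DataFrame({"t": pd.Series(ps)}),
            module_sizes=pd.Series(sizes) if sizes else None,
        )

    def test_largest_significant_correlation_wins(self):
        stats = self._stats({"green": 0.32, "blue": 0.1}, {"green": 1e-4, "blue": 0.3})
        assert select_critical_module(stats, "t") == "green"

    def test_tie_breaks_smaller_p_then_larger_module(self):
        stats = self._stats(
            {"a": 0.5, "b": 0.5}, {"a": 0.01, "b": 0.001}, sizes={"a": 10, "b": 10}
        )
        assert select_critical_module(stats, "t") == "b"
        stats = self._stats(
            {"a": 0.5, "b": -0.5}, {"a": 0.01, "b": 0.01}, sizes={"a": 10, "b": 30}
        )
        assert select_critical_module(stats, "t") == "b"

    def test_nothing_significant_raises_with_best(self):
        stats = self._stats({"a": 0.2, "b": 0.1}, {"a": 0.2, "b": 0.5})
        with pytest.raises(CoexppiError, match="best candidate a"):
            select_critical_module(stats, "t")


class TestModelFacade:
    def test_fit_produces_summary_and_critical_module(self, small_design):
        expr, truth = generate_expression(small_design)
        traits = generate_traits(small_design, truth)
        model = CoexpressionNetwork(expr, traits)
        results = model.fit(powers=range(1, 7))
        text = results.summary()
        assert "soft power" in text and "turquoise" in text
        critical = results.critical_module("recurrence", alpha=0.05)
        # the planted trait module is the largest -> "turquoise"
        members = set(results.modules.members(critical))
        planted = {g for g, m in truth.module_of_gene.items() if m == "M1"}
        assert len(members & planted) / len(planted) > 0.8
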