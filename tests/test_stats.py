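"""Screen statistics: normalization, energy distance, DE, scores."""

import numpy as np
import pandas as pd
import pytest

from merscreen import stats as st


@pytest.fixture(scope="module")
def null_population():
    """600 cells over 40 genes from one distribution; first 200 controls."""
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.poisson(6.0, size=(600, 40)), columns=[f"g{i}" for i in range(40)]
    )
    ctrl = np.zeros(600, dtype=bool)
    ctrl[:200] = True
    return counts, ctrl


class TestNormalization:
    def test_tp10k_arithmetic(self):
        counts = pd.DataFrame([[2, 3, 5]], columns=list("abc"))
        layer = st.tp10k_log(counts)
        expected = np.log1p(np.array([2000.0, 3000.0, 5000.0]))
        assert np.allclose(layer.to_numpy()[0], expected)

    def test_zero_total_cell_rejected(self):
        counts = pd.DataFrame([[0, 0], [1, 2]], columns=list("ab"))
        with pytest.raises(ValueError, match="zero total"):
            st.tp10k_log(counts)

    def test_control_z_mean_zero_sd_one_within_batch(self, null_population):
        counts, ctrl = null_population
        batch = pd.Series(["b1", "b2"] * 300, index=counts.index)
        layers = st.normalize_and_zscore(counts, ctrl, batch=batch)
        for b in ("b1", "b2"):
            zc = layers.z[(batch == b).to_numpy() & ctrl]
            assert np.allclose(zc.mean(axis=0), 0, atol=1e-10)
            assert np.allclose(zc.std(axis=0, ddof=0), 1, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, null_population):
        counts, ctrl = null_population
        rng = np.random.default_rng(1)
        cov = pd.DataFrame(
            {"area": rng.normal(100, 10, len(counts)),
             "n_mol": counts.sum(axis=1).astype(float)},
            index=counts.index,
        )
        layers = st.normalize_and_zscore(counts, ctrl, covariates=cov)
        resid = layers.residual.to_numpy()
        centered = cov.to_numpy() - cov.to_numpy().mean(axis=0)
        inner = centered.T @ resid
        assert np.abs(inner).max() < 1e-6

    def test_zero_variance_gene_excluded_and_logged(self, null_population):
        counts, ctrl = null_population
        counts = counts.copy()
        counts["flat"] = 0  # silent in controls -> zero variance there
        counts.loc[~ctrl, "flat"] = 5
        with pytest.warns(UserWarning, match="zero-variance"):
            layers = st.normalize_and_zscore(counts, ctrl)
        assert "flat" in layers.excluded_genes
        assert "flat" not in layers.z.columns


class TestEnergyDistance:
    def test_identical_point_sets_give_zero(self):
        X = np.random.default_rng(2).normal(size=(25, 4))
        assert st.energy_distance(X, X) == pytest.approx(0.0, abs=1e-12)

    def test_singleton_pair_matches_formula(self):
        # two single cells at (0,0) and (3,4): E = 2 d(x, y)
        assert st.energy_distance([[0, 0]], [[3, 4]], "sqeuclidean") == 50.0
        assert st.energy_distance([[0, 0]], [[3, 4]], "euclidean") == 10.0

    def test_sqeuclidean_equals_twice_mean_shift(self):
        rng = np.random.default_rng(3)
        X, Y = rng.normal(size=(200, 3)), rng.normal(size=(300, 3)) + [1, 0, 0]
        e = st.energy_distance(X, Y, "sqeuclidean")
        shift = X.mean(0) - Y.mean(0)
        assert e == pytest.approx(2 * (shift @ shift), rel=1e-9)

    def test_null_groups_not_significant(self, null_population):
        counts, ctrl = null_population
        labels = pd.Series(
            ["control"] * 200 + [f"null_{i//40}" for i in range(400)],
            index=counts.index,
        )
        layers = st.normalize_and_zscore(counts, ctrl)
        cfg = st.StatsConfig(n_permutations=300, seed=4)
        res = st.energy_distance_test(layers.tp10k_log, labels, "control", cfg)
        assert res["significant"].sum() == 0
        assert (res["statistic"] >= -1e-9).all()

    def test_shifted_group_detected(self, null_population):
        counts, ctrl = null_population
        counts = counts.copy()
        labels = pd.Series(["control"] * 200 + ["shifted"] * 100 + ["null"] * 300,
                           index=counts.index)
        counts.iloc[200:300, :10] += 4  # strong shift on 10 genes
        layers = st.normalize_and_zscore(counts, ctrl)
        cfg = st.StatsConfig(n_permutations=300, seed=5)
        res = st.energy_distance_test(layers.tp10k_log, labels, "control", cfg)
        res = res.set_index("group")
        assert res.loc["shifted", "significant"]
        assert not res.loc["null", "significant"]

    def test_permutation_p_superuniform_under_null(self, null_population):
        """Repeated null draws: P(p <= a) <= a + slack for small a."""
        counts, ctrl = null_population
        layers = st.normalize_and_zscore(counts, ctrl)
        rng = np.random.default_rng(6)
        ps = []
        for rep in range(30):
            idx = rng.permutation(600)
            labels = pd.Series("rest", index=counts.index)
            labels.iloc[idx[:100]] = "grp"
            labels.iloc[idx[100:400]] = "control"
            cfg = st.StatsConfig(n_permutations=99, seed=rep)
            res = st.energy_distance_test(
                layers.tp10k_log[labels != "rest"],
                labels[labels != "rest"],
                "control",
                cfg,
            )
            ps.append(res["p"].iloc[0])
        ps = np.array(ps)
        for a in (0.1, 0.25, 0.5):
            assert (ps <= a).mean() <= a + 0.15

    def test_group_of_one_rejected(self, null_population):
        counts, ctrl = null_population
        labels = pd.Series("control", index=counts.index)
        labels.iloc[-1] = "lonely"
        layers = st.normalize_and_zscore(counts, ctrl)
        with pytest.raises(ValueError, match="fewer than 2"):
            st.energy_distance_test(layers.tp10k_log, labels, "control")


class TestDifferentialExpression:
    def test_group_identical_to_control_nothing_significant(self, null_population):
        counts, ctrl = null_population
        layers = st.normalize_and_zscore(counts, ctrl)
        res = st.differential_expression(layers.tp10k_log, ctrl, ctrl)
        assert res["significant"].sum() == 0
        assert np.allclose(res["log2fc"], 0)

    def test_planted_two_fold_change_detected(self):
        rng = np.random.default_rng(7)
        base = rng.poisson(10.0, size=(400, 30))
        counts = pd.DataFrame(base, columns=[f"g{i}" for i in range(30)])
        counts.iloc[:200, 0] = rng.poisson(20.0, 200)  # 2x on g0 in the group
        layers = st.tp10k_log(counts)
        group = np.arange(400) < 200
        res = st.differential_expression(layers, group, ~group).set_index("gene")
        assert res.loc["g0", "significant"]
        assert res.loc["g0", "log2fc"] > 0.5

    def test_null_fdr_controlled(self):
        rng = np.random.default_rng(8)
        fracs = []
        for rep in range(10):
            counts = pd.DataFrame(
                rng.poisson(8.0, size=(300, 50)), columns=[f"g{i}" for i in range(50)]
            )
            layers = st.tp10k_log(counts)
            group = np.arange(300) < 150
            res = st.differential_expression(layers, group, ~group)
            fracs.append(res["significant"].mean())
        assert np.mean(fracs) <= 0.05

    def test_depletion_log2fc_recovery(self, panel_library):
        """Planted depletion factor recovered as pseudobulk log2FC within
        +/- 0.15 at n = 500 cells per arm."""
        from merscreen import simulate as sim

        panel, library = panel_library
        depl = library.entries[
            (~library.entries.is_control)
            & (library.entries.template == "depletion")
        ]
        baselines = panel.genes.set_index("name")["baseline"]
        best = int(np.argmax(baselines.loc[depl["target_gene"]].to_numpy()))
        guide = depl.iloc[best]["guide"]
        target = library.row(guide)["target_gene"]
        screen = sim.simulate_tissue(library, n_cells=1000, moi=0.3, seed=30)
        screen.cells["guides"] = [(guide,) if i < 500 else () for i in range(1000)]
        counts = sim.simulate_counts(screen, panel, seed=31)
        layers = st.tp10k_log(counts)
        group = np.arange(1000) < 500
        res = st.differential_expression(layers, group, ~group).set_index("gene")
        assert res.loc[target, "log2fc"] == pytest.approx(np.log2(0.2), abs=0.15)


class TestPseudobulk:
    def test_self_correlation_is_one(self, null_population):
        counts, ctrl = null_population
        labels = pd.Series(["control"] * 200 + ["a"] * 200 + ["b"] * 200,
                           index=counts.index)
        layers = st.normalize_and_zscore(counts, ctrl)
        profiles, corr = st.pseudobulk_profiles(
            layers.z, labels, "control", top_n=30,
            expression_layer=layers.tp10k_log,
        )
        assert np.allclose(np.diag(corr), 1.0)
        assert profiles.shape == (2, 30)

    def test_support_restricted_to_top_n(self, null_population):
        counts, ctrl = null_population
        labels = pd.Series(["control"] * 200 + ["a"] * 400, index=counts.index)
        layers = st.normalize_and_zscore(counts, ctrl)
        profiles, _ = st.pseudobulk_profiles(layers.z, labels, "control", top_n=12)
        assert profiles.shape[1] == 12

    def test_shared_effect_template_correlates_more_than_controls(self):
        rng = np.random.default_rng(9)
        n_genes = 40
        base = rng.poisson(8.0, size=(800, n_genes)).astype(float)
        counts = pd.DataFrame(base, columns=[f"g{i}" for i in range(n_genes)])
        labels = pd.Series(
            ["control"] * 400 + ["gA_1"] * 100 + ["gA_2"] * 100
            + ["ctrlA"] * 100 + ["ctrlB"] * 100,
            index=counts.index,
        )
        # two guides share the same planted effect; pseudo-controls do not
        effect_rows = (labels == "gA_1") | (labels == "gA_2")
        counts.loc[effect_rows, [f"g{i}" for i in range(8)]] *= 2
        layers = st.normalize_and_zscore(counts, labels == "control")
        _, corr = st.pseudobulk_profiles(
            layers.z, labels, "control", top_n=30,
            expression_layer=layers.tp10k_log,
        )
        assert corr.loc["gA_1", "gA_2"] > corr.loc["ctrlA", "ctrlB"]

    def test_top_n_larger_than_panel_rejected(self, null_population):
        counts, ctrl = null_population
        labels = pd.Series(["control"] * 200 + ["a"] * 400, index=counts.index)
        layers = st.normalize_and_zscore(counts, ctrl)
        with pytest.raises(ValueError):
            st.pseudobulk_profiles(layers.z, labels, "control", top_n=10_000)


class TestGeneSetScore:
    def test_control_guide_scores_near_zero(self, null_population):
        counts, ctrl = null_population
        labels = pd.Series(["control"] * 200 + ["pseudo"] * 400, index=counts.index)
        layers = st.normalize_and_zscore(counts, ctrl)
        res = st.gene_set_score(layers.z, [f"g{i}" for i in range(5)], labels, "control")
        assert abs(res.set_index("guide").loc["pseudo", "score"]) < 0.2
        assert not res.set_index("guide").loc["pseudo", "significant"]

    def test_planted_one_z_induction_recovered(self, null_population):
        counts, ctrl = null_population
        labels = pd.Series(["control"] * 200 + ["induced"] * 400, index=counts.index)
        layers = st.normalize_and_zscore(counts, ctrl)
        z = layers.z.copy()
        gene_set = [f"g{i}" for i in range(6)]
        z.loc[(labels == "induced").to_numpy(), gene_set] += 1.0
        res = st.gene_set_score(z, gene_set, labels, "control").set_index("guide")
        assert res.loc["induced", "score"] == pytest.approx(1.0, abs=0.15)
        assert res.loc["induced", "significant"]

    def test_missing_genes_listed(self, null_population):
        counts, ctrl = null_population
        labels = pd.Series(["control"] * 200 + ["a"] * 400, index=counts.index)
        layers = st.normalize_and_zscore(counts, ctrl)
        with pytest.raises(ValueError, match="nope"):
            st.gene_set_score(layers.z, ["nope"], labels, "control")


class TestZonationScore:
    @staticmethod
    def _marker_z(fill):
        markers = st.ZonationMarkers()
        cols = list(markers.periportal) + list(markers.pericentral)
        z = pd.DataFrame(0.0, index=[0], columns=cols + ["other"])
        for c, v in fill.items():
            z[c] = v
        return z

    def test_periportal_sum_positive_seven(self):
        markers = st.ZonationMarkers()
        z = self._marker_z({c: 1.0 for c in markers.periportal})
        assert st.zonation_score(z).iloc[0] == 7.0

    def test_pericentral_sum_negative_sixteen(self):
        markers = st.ZonationMarkers()
        z = self._marker_z({c: 1.0 for c in markers.pericentral})
        assert st.zonation_score(z).iloc[0] == -16.0

    def test_split_mode_returns_partial_sums(self):
        markers = st.ZonationMarkers()
        z = self._marker_z({markers.periportal[0]: 2.0, markers.pericentral[0]: 3.0})
        parts = st.zonation_score(z, split=True)
        assert parts.loc[0, "periportal"] == 2.0
        assert parts.loc[0, "pericentral"] == 3.0

    def test_control_population_mean_near_zero(self, panel_library):
        from merscreen import simulate as sim

        panel, library = panel_library
        screen = sim.simulate_tissue(library, n_cells=2000, moi=0.3, seed=32)
        counts = sim.simulate_counts(screen, panel, seed=33)
        ctrl = (screen.cells["guides"].map(len) == 0).to_numpy()
        layers = st.normalize_and_zscore(counts, ctrl)
        score = st.zonation_score(layers.z)
        assert abs(score[ctrl].mean()) < 0.1

    def test_monotone_in_planted_delta_z(self, panel_library):
        """Mean zonation score of carrier cells increases with delta_z."""
        from merscreen import simulate as sim

        panel, library = panel_library
        means = []
        for dz in (-0.3, 0.0, 0.3):
            lib = library.entries.copy()
            lib.loc[lib.index[0], ["template", "delta_z"]] = ["zonal", dz]
            libx = sim.PerturbationLibrary(lib, stress_set=library.stress_set)
            guide = lib["guide"].iloc[0]
            screen = sim.simulate_tissue(libx, n_cells=2000, moi=0.3, seed=34)
            screen.cells["guides"] = [
                (guide,) if i < 1000 else () for i in range(2000)
            ]
            counts = sim.simulate_counts(screen, panel, seed=35)
            ctrl = np.arange(2000) >= 1000
            layers = st.normalize_and_zscore(counts, ctrl)
            means.append(st.zonation_score(layers.z)[:1000].mean())
        assert means[0] < means[1] < means[2]


class TestIntensityEffects:
    @staticmethod
    def _intensity_data(shift=0.0):
        rng = np.random.default_rng(10)
        channels = ["anti_Gapdh", "anti_Perilipin", "polyA"]
        intens = pd.DataFrame(
            rng.normal(100, 10, size=(600, 3)), columns=channels
        )
        labels = pd.Series(["control"] * 300 + ["sgX"] * 300)
        samples = pd.Series(["s1", "s2"] * 300)
        intens.loc[(labels == "sgX").to_numpy(), "anti_Gapdh"] += shift * 10
        return intens, labels, samples

    def test_planted_negative_shift_detected(self):
        intens, labels, samples = self._intensity_data(shift=-1.0)
        res = st.intensity_effects(intens, labels, "control", samples)
        res = res.set_index(["guide", "channel"])
        hit = res.loc[("sgX", "anti_Gapdh")]
        assert hit["mean_z"] == pytest.approx(-1.0, abs=0.2)
        assert hit["significant"]

    def test_control_like_guide_no_significant_channels(self):
        intens, labels, samples = self._intensity_data(shift=0.0)
        res = st.intensity_effects(intens, labels, "control", samples)
        assert res["significant"].sum() == 0

    def test_control_z_mean_zero_per_sample(self):
        intens, labels, samples = self._intensity_data(shift=0.5)
        ctrl = labels == "control"
        for s in ("s1", "s2"):
            sub = intens[(samples == s).to_numpy() & ctrl.to_numpy()]
            z = (sub - sub.mean()) / sub.std(ddof=0)
            assert np.allclose(z.mean(), 0, atol=1e-10)
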