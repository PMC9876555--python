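"""Mass-fraction normalization, scaling statistics, hit calling,
power-analysis threshold, phospho adjustment, correlations, and
cell-area statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cellscaling as cs

LINES = [f"L{i:02d}" for i in range(1, 12)]


def _panel(areas):
    return pd.DataFrame({"line_id": LINES[: len(areas)],
                         "mean_area_um2": areas})


@pytest.fixture()
def panel_areas():
    # five small, six large around a 900 split
    return np.array([400, 500, 600, 700, 800, 1000, 1100,
                     1200, 1300, 1400, 1500], dtype=float)


class TestNormalization:
    def test_single_feature_all_hundred(self):
        # a lone feature is the whole sample: every mass fraction is 1
        raw = pd.DataFrame([[2.0, 4.0, 6.0]], index=["f1"],
                           columns=["a", "b", "c"])
        out = cs.normalize_mass_fraction(raw)
        np.testing.assert_allclose(out.loc["f1"], [100.0, 100.0, 100.0])

    def test_row_rescale(self):
        # equal column sums: normalization reduces to the mean-100 rescale
        raw = pd.DataFrame([[2.0, 4.0, 6.0], [6.0, 4.0, 2.0]],
                           index=["f1", "f2"], columns=["a", "b", "c"])
        out = cs.normalize_mass_fraction(raw)
        np.testing.assert_allclose(out.loc["f1"], [50.0, 100.0, 150.0])

    def test_proportional_columns_equal_fractions(self):
        raw = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 6.0]},
                           index=["f1", "f2"])
        frac = raw / raw.sum()
        assert (frac["a"] == frac["b"]).all()
        out = cs.normalize_mass_fraction(raw)
        np.testing.assert_allclose(out["a"], out["b"])

    def test_planted_fractions_recovered(self, rng):
        fractions = rng.dirichlet(np.ones(30))
        scales = rng.uniform(1e5, 1e7, 8)
        raw = pd.DataFrame(np.outer(fractions, scales),
                           index=[f"f{i}" for i in range(30)],
                           columns=[f"s{i}" for i in range(8)])
        recovered = raw / raw.sum()
        np.testing.assert_allclose(recovered.to_numpy(),
                                   np.tile(fractions[:, None], 8), atol=1e-9)

    def test_idempotent_under_equal_column_sums(self, rng):
        """Re-normalizing changes nothing when the sample columns carry
        equal total signal (the only regime where the two-step procedure
        can be an exact projection; with unequal totals the column
        division re-tilts rows)."""
        row = rng.uniform(1, 10, 6)
        raw = pd.DataFrame([np.roll(row, i) for i in range(6)])  # circulant
        once = cs.normalize_mass_fraction(raw)
        twice = cs.normalize_mass_fraction(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(),
                                   atol=1e-9)

    def test_approximately_idempotent_in_general(self, rng):
        raw = pd.DataFrame(rng.uniform(1, 10, (200, 5)))
        once = cs.normalize_mass_fraction(raw)
        twice = cs.normalize_mass_fraction(once)
        assert np.abs(twice.to_numpy() / once.to_numpy() - 1).max() < 0.05

    def test_all_zero_row_dropped_with_warning(self):
        raw = pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["f1", "f2"])
        with pytest.warns(UserWarning, match="dropped"):
            out = cs.normalize_mass_fraction(raw)
        assert list(out.index) == ["f1"]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cs.normalize_mass_fraction(pd.DataFrame([[-1.0, 2.0]]))

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError, match="column"):
            cs.normalize_mass_fraction(pd.DataFrame([[1.0, 0.0]]))

    def test_missing_values_masked_mean(self):
        raw = pd.DataFrame([[10.0, np.nan, 20.0], [10.0, 30.0, 20.0]],
                           index=["f1", "f2"], columns=["a", "b", "c"])
        out = cs.normalize_mass_fraction(raw)
        assert np.isnan(out.loc["f1", "b"])
        # hand check: fractions of f1 are 0.5 (a), 0.5 (c); observed-line
        # mean is 0.5, so both observed cells rescale to exactly 100
        np.testing.assert_allclose(out.loc["f1", ["a", "c"]], [100.0, 100.0])
        # f2: fractions 0.5, 1.0, 0.5 -> mean 2/3 -> [75, 150, 75]
        np.testing.assert_allclose(out.loc["f2"], [75.0, 150.0, 75.0])

    def test_transformer_wrapper(self, rng):
        raw = pd.DataFrame(rng.uniform(1, 5, (10, 4)))
        out = cs.MassFractionScaler().fit_transform(raw)
        np.testing.assert_allclose(out.mean(axis=1), 100.0, rtol=1e-9)


class TestSizeScalingStats:
    def test_perfect_correlate(self, panel_areas):
        matrix = pd.DataFrame([panel_areas], index=["f1"],
                              columns=LINES)
        stats = cs.size_scaling_stats(matrix, _panel(panel_areas))
        assert stats.loc["f1", "R"] == pytest.approx(1.0)

    def test_constant_feature(self, panel_areas):
        matrix = pd.DataFrame([np.full(11, 100.0)], index=["f1"],
                              columns=LINES)
        stats = cs.size_scaling_stats(matrix, _panel(panel_areas))
        assert stats.loc["f1", "Fc"] == pytest.approx(1.0)
        assert np.isnan(stats.loc["f1", "R"])

    def test_planted_fold_change(self, panel_areas, rng):
        split = panel_areas.mean()
        prof = np.where(panel_areas > split, 200.0, 100.0)
        noisy = prof * rng.lognormal(0, 0.05, 11)
        matrix = pd.DataFrame([noisy], index=["f1"], columns=LINES)
        stats = cs.size_scaling_stats(matrix, _panel(panel_areas))
        assert stats.loc["f1", "Fc"] == pytest.approx(2.0, rel=0.1)

    def test_group_size_precondition(self):
        areas = np.array([100.0, 200, 300, 2000, 2100, 2200, 2300, 2400])
        # only 3 small lines after the split
        matrix = pd.DataFrame(np.ones((2, 8)) * 100,
                              columns=LINES[:8])
        with pytest.raises(ValueError, match="4 lines"):
            cs.size_scaling_stats(matrix, _panel(areas))


class TestHitCalling:
    def _stats(self, rows):
        return pd.DataFrame(rows, columns=["R", "p", "Fc"]).assign(
            n_large=5, n_small=6)

    def test_boundary_is_strict(self):
        stats = self._stats([[0.9, 0.001, 1.5]])
        assert not cs.call_scaling_hits(stats)["hit"].iloc[0]

    def test_requires_correlation(self):
        stats = self._stats([[-0.3, 0.4, 2.0]])
        assert not cs.call_scaling_hits(stats)["hit"].iloc[0]

    def test_direction(self):
        stats = self._stats([[0.9, 0.001, 2.0], [-0.9, 0.001, 0.5]])
        out = cs.call_scaling_hits(stats)
        assert out["hit"].all()
        assert list(out["direction"]) == ["super", "sub"]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            cs.call_scaling_hits(self._stats([[0.9, 0.01, 2.0]]), fc_lo=1.2)

    def test_planted_sensitivity_and_fpr(self, panel, omics):
        """Default synthetic panel: sensitivity >= 0.9 at effect size 2,
        false-positive rate <= 0.05 among nulls."""
        matrix = cs.normalize_mass_fraction(omics["peptides"])
        stats = cs.size_scaling_stats(matrix, panel.table.reset_index())
        hits = cs.call_scaling_hits(stats)
        planted = omics["truth"]["scaling"] != "null"
        called = hits["hit"]
        sensitivity = (called & planted).sum() / planted.sum()
        fpr = (called & ~planted).sum() / (~planted).sum()
        assert sensitivity >= 0.9
        assert fpr <= 0.05

    def test_null_panel_fpr(self, panel):
        """10,000 null features at noise CV 0.2: empirical FPR <= 0.05."""
        spec = cs.OmicsSpec(n_features=10_000, fraction_sub=0.0,
                            fraction_super=0.0, rng_seed=21)
        nulls = cs.make_omics(spec, panel)
        matrix = cs.normalize_mass_fraction(nulls["peptides"])
        stats = cs.size_scaling_stats(matrix, panel.table.reset_index())
        hits = cs.call_scaling_hits(stats)
        assert hits["hit"].mean() <= 0.05


class TestMinDetectableFc:
    def test_reference_value(self):
        assert round(cs.min_detectable_fc(), 1) == 1.5

    def test_fc_algebra(self):
        # d = 40 about a centre of 100 gives 120/80 = 1.5 exactly
        d = 40.0
        assert (100 + d / 2) / (100 - d / 2) == pytest.approx(1.5)

    def test_monotonicity(self):
        base = cs.min_detectable_fc()
        assert cs.min_detectable_fc(n1=50, n2=60) < base
        assert cs.min_detectable_fc(sd=40.0) > base
        assert cs.min_detectable_fc(power=0.99) > base
        assert cs.min_detectable_fc(power=0.5, n1=50_000, n2=60_000) < 1.01

    def test_undefined_when_difference_too_large(self):
        with pytest.raises(ValueError, match="Fc"):
            cs.min_detectable_fc(sd=200.0, n1=2, n2=2)


class TestPhosphoAdjustment:
    def _mats(self):
        pep = pd.DataFrame([[100.0, 200.0, 300.0]], index=["p1"],
                           columns=["a", "b", "c"])
        return pep

    def test_proportional_gives_constant(self):
        pep = self._mats()
        ph = pd.DataFrame([[10.0, 20.0, 30.0]], index=["s1"],
                          columns=["a", "b", "c"])
        adj = cs.adjusted_phospho_abundance(
            ph, pep, pd.Series({"s1": "p1"}))
        np.testing.assert_allclose(adj.loc["s1"], 100.0)

    def test_isolates_phospho_signal(self):
        pep = pd.DataFrame([[100.0, 100.0, 100.0, 100.0]], index=["p1"],
                           columns=list("abcd"))
        ph = pd.DataFrame([[10.0, 10.0, 20.0, 20.0]], index=["s1"],
                          columns=list("abcd"))
        adj = cs.adjusted_phospho_abundance(ph, pep, pd.Series({"s1": "p1"}))
        ratio = adj.loc["s1", "c"] / adj.loc["s1", "a"]
        assert ratio == pytest.approx(2.0)

    def test_line_permutation_equivariance(self):
        pep = self._mats()
        ph = pd.DataFrame([[10.0, 40.0, 90.0]], index=["s1"],
                          columns=["a", "b", "c"])
        adj = cs.adjusted_phospho_abundance(ph, pep, pd.Series({"s1": "p1"}))
        perm = ["c", "a", "b"]
        adj_perm = cs.adjusted_phospho_abundance(
            ph[perm], pep[perm], pd.Series({"s1": "p1"}))
        np.testing.assert_allclose(adj_perm.to_numpy(),
                                   adj[perm].to_numpy())

    def test_zero_parent_becomes_missing(self):
        pep = pd.DataFrame([[0.0, 200.0, 300.0]], index=["p1"],
                           columns=["a", "b", "c"])
        ph = pd.DataFrame([[10.0, 20.0, 30.0]], index=["s1"],
                          columns=["a", "b", "c"])
        adj = cs.adjusted_phospho_abundance(ph, pep, pd.Series({"s1": "p1"}))
        assert np.isnan(adj.loc["s1", "a"])

    def test_unmapped_site_rejected(self):
        pep = self._mats()
        ph = pd.DataFrame([[1.0, 2.0, 3.0]], index=["s9"],
                          columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="parent"):
            cs.adjusted_phospho_abundance(ph, pep, pd.Series({"s1": "p1"}))


class TestRatioCovariates:
    def test_proportional_feature(self, rng):
        lines = LINES[:8]
        num = 100 * rng.uniform(0.5, 2.0, 8)
        den = np.full(8, 100.0)
        matrix = pd.DataFrame(
            [num, den, 3.0 * num / den], columns=lines,
            index=["numf", "denf", "target"])
        out = cs.ratio_covariates(matrix, ["numf"], ["denf"])
        assert out.loc["target", "R"] == pytest.approx(1.0)

    def test_identical_sets_degenerate(self, rng):
        lines = LINES[:8]
        matrix = pd.DataFrame(rng.uniform(50, 150, (3, 8)), columns=lines,
                              index=["f1", "f2", "f3"])
        out = cs.ratio_covariates(matrix, ["f1", "f2", "f3"],
                                  ["f1", "f2", "f3"])
        assert out["R"].isna().all()

    def test_planted_covariate_is_top_hit(self, rng):
        lines = LINES[:10]
        ratio_driver = rng.uniform(0.5, 2.0, 10)
        rows = {"num": 100 * ratio_driver, "den": np.full(10, 100.0)}
        for i in range(30):
            rows[f"null{i}"] = 100 * rng.lognormal(0, 0.2, 10)
        rows["cov"] = 100 * ratio_driver * rng.lognormal(0, 0.02, 10)
        matrix = pd.DataFrame(rows).T
        matrix.columns = lines
        out = cs.ratio_covariates(matrix, ["num"], ["den"])
        others = out.drop(index=["num", "cov"])
        assert out.loc["cov", "R"] > others["R"].abs().max()

    def test_empty_sets_rejected(self, rng):
        matrix = pd.DataFrame(rng.uniform(1, 2, (2, 5)))
        with pytest.raises(ValueError):
            cs.ratio_covariates(matrix, [], [0])


class TestMrnaProteinCorrelations:
    def test_identical_matrices_per_line(self, panel_areas, rng):
        genes = [f"g{i}" for i in range(50)]
        prot = pd.DataFrame(rng.lognormal(4, 0.5, (50, 11)), index=genes,
                            columns=LINES)
        out = cs.mrna_protein_correlations(prot, prot, _panel(panel_areas),
                                           mode="per_line")
        np.testing.assert_allclose(out["R"], 1.0)

    def test_independent_matrices_near_zero(self, panel_areas, rng):
        genes = [f"g{i}" for i in range(1000)]
        rna = pd.DataFrame(rng.lognormal(4, 0.5, (1000, 11)), index=genes,
                           columns=LINES)
        prot = pd.DataFrame(rng.lognormal(4, 0.5, (1000, 11)), index=genes,
                            columns=LINES)
        out = cs.mrna_protein_correlations(rna, prot, _panel(panel_areas),
                                           mode="per_line")
        assert np.abs(out["R"]).max() < 0.1

    def test_coupling_mixture_recovered(self, panel, omics):
        """Per-gene coefficient histogram reproduces the generator's
        (uncoupled, positive, negative) proportions within 5 points."""
        pep = cs.normalize_mass_fraction(omics["peptides"])
        out = cs.mrna_protein_correlations(
            omics["transcripts"], pep, panel.table.reset_index(),
            mode="per_gene", subset="all")
        frac_pos = ((out["R"] > 0.55) & (out["p"] < 0.05)).mean()
        frac_neg = ((out["R"] < -0.55) & (out["p"] < 0.05)).mean()
        assert frac_pos == pytest.approx(0.30, abs=0.05)
        assert frac_neg == pytest.approx(0.10, abs=0.05)

    def test_subset_thresholds(self, panel_areas, rng):
        genes = [f"g{i}" for i in range(30)]
        mat = pd.DataFrame(rng.lognormal(4, 0.5, (30, 11)), index=genes,
                           columns=LINES)
        small = cs.mrna_protein_correlations(mat, mat, _panel(panel_areas),
                                             mode="per_gene", subset="small")
        assert (small["n_lines"] == 5).all()
        with pytest.raises(ValueError, match="3 lines"):
            few = _panel(np.array([100.0, 200, 2000, 2100, 2200, 2300]))
            cs.mrna_protein_correlations(
                mat[LINES[:6]], mat[LINES[:6]], few,
                mode="per_gene", subset="small")


class TestAreaStats:
    def test_constant_areas(self):
        areas = {"L1": np.full(200, 5.0)}
        summary, transformed, _ = cs.area_distribution_stats(areas)
        assert summary.loc["L1", "variance"] == 0.0
        assert summary.loc["L1", "cv"] == 0.0
        assert np.isnan(summary.loc["L1", "skew"])

    def test_acosh_boundary(self):
        areas = {"L1": np.concatenate([[1.0], np.full(199, 3.0)])}
        _, transformed, _ = cs.area_distribution_stats(areas)
        assert transformed["L1"][0] == 0.0

    def test_subunit_area_rejected(self):
        areas = {"L1": np.concatenate([np.full(150, 5.0), [0.5]])}
        with pytest.raises(ValueError, match="L1"):
            cs.area_distribution_stats(areas)

    def test_mean_variance_scaling(self, rng):
        """Lines generated with jointly scaled location/width show the
        linear mean-variance relation of the measured panel."""
        scales = np.array([300, 500, 800, 1200, 1800], dtype=float)
        areas = {f"L{i}": s * rng.lognormal(0, 0.45, 3000)
                 for i, s in enumerate(scales)}
        summary, _, flags = cs.area_distribution_stats(areas)
        r, _ = sps.pearsonr(summary["mean"], np.sqrt(summary["variance"]))
        assert r > 0.9
        assert "bartlett_p" in flags and "anova_p" in flags


class TestEffectSizeMatrix:
    def test_self_comparison(self, rng):
        areas = {"L1": rng.uniform(1, 2, 20), "L2": rng.uniform(1, 2, 20)}
        result = cs.effect_size_matrix(areas, n_classes=2)
        assert result.cl_matrix.loc["L1", "L1"] == 0.5

    def test_disjoint_samples(self):
        areas = {"A": np.array([1.0, 2.0]), "B": np.array([10.0, 11.0])}
        result = cs.effect_size_matrix(areas, n_classes=2)
        assert result.cl_matrix.loc["A", "B"] == 0.0
        assert result.cl_matrix.loc["B", "A"] == 1.0

    def test_interleaved_samples(self):
        areas = {"A": np.array([1.0, 3.0]), "B": np.array([2.0, 4.0])}
        result = cs.effect_size_matrix(areas, n_classes=2)
        assert result.cl_matrix.loc["B", "A"] == 0.75

    def test_matches_brute_force(self, rng):
        """CL from the rank-sum statistic equals direct pair counting
        (ties half-weighted) on 200 random small samples."""
        for _ in range(200):
            n1, n2 = rng.integers(2, 13, size=2)
            a = rng.integers(0, 8, n1).astype(float)
            b = rng.integers(0, 8, n2).astype(float)
            result = cs.effect_size_matrix({"A": a, "B": b}, n_classes=2)
            wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            assert result.cl_matrix.loc["A", "B"] == pytest.approx(
                wins / (n1 * n2))

    def test_three_classes_ordered_by_size(self, rng):
        areas = {}
        for i, scale in enumerate([100, 110, 500, 520, 2000, 2100]):
            areas[f"L{i}"] = scale * rng.lognormal(0, 0.2, 300)
        result = cs.effect_size_matrix(areas)
        assert set(result.classes) == {1, 2, 3}
        means = {line: areas[line].mean() for line in areas}
        by_class = pd.Series(means).groupby(result.classes).mean()
        assert by_class.is_monotonic_increasing

    def test_single_line_degenerate(self, rng):
        result = cs.effect_size_matrix({"L1": rng.uniform(1, 2, 50)})
        assert result.cl_matrix.shape == (1, 1)
        assert result.classes.loc["L1"] == 1
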