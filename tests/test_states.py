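"""Normalization, clustering, neuron classes and proportion models."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from snstates import (
    ProportionModelSpec,
    classify_neuron_states,
    compute_proportions,
    embed_and_cluster,
    fit_proportion_model,
    meta_analyze_proportions,
    normalize_counts,
)


class TestNormalizeCounts:
    def test_poisson_gene_residuals_standardized(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(5.0, size=(10_000, 30))
        res = normalize_counts(X)
        assert abs(res[:, 0].mean()) < 0.1
        assert abs(res[:, 0].var() - 1.0) < 0.1

    def test_doubling_depth_leaves_residuals_nearly_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(rng.gamma(2.0, 5.0 / 2.0, size=(2000, 40)))
        r1 = normalize_counts(X)
        r2 = normalize_counts(2 * X)
        # doubling counts genuinely halves the relative Poisson noise, so
        # the moment dispersion shifts slightly; residuals stay aligned
        corr = np.corrcoef(r1.ravel(), r2.ravel())[0, 1]
        assert corr > 0.999

    def test_fixed_dispersion_residuals_exactly_depth_invariant(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(3.0, size=(500, 20))
        r1 = normalize_counts(X, dispersion=0.1, clip=1e9)
        r2 = normalize_counts(2 * X, dispersion=0.1, clip=1e9)
        mu1 = np.outer(X.sum(1), X.sum(0) / X.sum())
        # same relative model: residuals scale by sqrt((mu+a mu^2)/(2mu+4a mu^2))
        scale = np.sqrt((2 * mu1 + 0.1 * 4 * mu1**2) / (mu1 + 0.1 * mu1**2))
        assert np.allclose(r2 * scale, 2 * r1, atol=1e-8)

    def test_all_zero_gene_gets_zero_residuals(self):
        X = np.zeros((10, 3))
        X[:, 0] = 1
        res = normalize_counts(X)
        assert np.all(res[:, 1] == 0)


class TestEmbedAndCluster:
    def test_well_separated_states_recovered(self, state_cohort):
        cm, _, truth = state_cohort
        res = normalize_counts(cm)
        labels, _ = embed_and_cluster(res, n_components=10, k=3, seed=0)
        assert adjusted_rand_score(truth.nuclei.cell_state, labels) >= 0.95

    def test_k_one_gives_single_cluster(self, small_cohort):
        cm, _, _ = small_cohort
        labels, _ = embed_and_cluster(normalize_counts(cm), k=1)
        assert len(np.unique(labels)) == 1

    def test_same_seed_identical_labels(self, state_cohort):
        cm, _, _ = state_cohort
        res = normalize_counts(cm)
        a, _ = embed_and_cluster(res, k=3, seed=7)
        b, _ = embed_and_cluster(res, k=3, seed=7)
        assert np.array_equal(a, b)


class TestClassifyNeuronStates:
    def _expr(self, slc, gad):
        return np.column_stack([slc, gad, np.ones_like(slc)])

    def test_marker_dominance_assigns_class(self):
        expr = self._expr(np.r_[np.full(50, 10.0), np.zeros(50)],
                          np.r_[np.zeros(50), np.full(50, 10.0)])
        clusters = np.r_[np.zeros(50, int), np.ones(50, int)]
        samples = np.tile([0, 1], 50)
        out = classify_neuron_states(expr, ["SLC17A7", "GAD1", "X"], clusters, samples)
        assert out == {0: "EN", 1: "IN"}

    def test_exact_tie_is_ambiguous(self):
        expr = self._expr(np.full(20, 3.0), np.full(20, 3.0))
        out = classify_neuron_states(
            expr, ["SLC17A7", "GAD1", "X"], np.zeros(20, int), np.zeros(20, int)
        )
        assert out == {0: "ambiguous"}


class TestComputeProportions:
    def _meta(self, n_state, n_total, threshold_type="microglia"):
        rows = []
        for i in range(n_total):
            rows.append(
                {
                    "barcode": f"b{i}",
                    "subject_id": "S1",
                    "cell_type": threshold_type,
                    "cell_state": "mic.0" if i < n_state else "mic.1",
                }
            )
        return pd.DataFrame(rows)

    def test_quarter_proportion_and_cuberoot(self):
        props = compute_proportions(self._meta(50, 200))
        row = props[props.cell_state == "mic.0"].iloc[0]
        assert row.proportion == pytest.approx(0.25)
        assert row.cuberoot_proportion == pytest.approx(0.62996, abs=1e-5)

    def test_inclusion_is_strictly_greater_than_threshold(self):
        assert len(compute_proportions(self._meta(10, 55))) > 0  # 55 > 50
        assert len(compute_proportions(self._meta(10, 50))) == 0  # 50 is excluded

    def test_proportions_sum_to_one_per_subject(self, small_cohort):
        _, meta, _ = small_cohort
        props = compute_proportions(meta, min_nuclei=50)
        sums = props.groupby(["subject_id", "cell_type"]).proportion.sum()
        assert np.allclose(sums, 1.0)

    def test_row_count_matches_included_subjects(self, small_cohort):
        _, meta, _ = small_cohort
        props = compute_proportions(meta, min_nuclei=50)
        included = props.groupby(["subject_id", "cell_type"]).size()
        states_per = meta.groupby(["subject_id", "cell_type"]).cell_state.nunique()
        for key, n in included.items():
            assert n == states_per[key]


def _subject_table(values, predictor="group"):
    rows = []
    for i, v in enumerate(values):
        rows.append({"subject_id": f"S{i}", predictor: v, "sex": "F"})
    return pd.DataFrame(rows)


def _prop_table(cuberoots):
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(len(cuberoots))],
            "cell_type": "microglia",
            "cell_state": "mic.0",
            "n_state_nuclei": 10,
            "n_celltype_nuclei": 100,
            "proportion": np.asarray(cuberoots) ** 3,
            "cuberoot_proportion": cuberoots,
        }
    )


class TestFitProportionModel:
    def test_zero_noise_shift_recovered_exactly(self):
        group = [0, 0, 0, 1, 1, 1]
        cuberoot = [0.5, 0.5, 0.5, 0.6, 0.6, 0.6]
        fits = fit_proportion_model(
            _prop_table(cuberoot), _subject_table(group), ProportionModelSpec("group", ())
        )
        assert fits.coef.iloc[0] == pytest.approx(0.1, abs=1e-12)
        assert fits.p.iloc[0] < 1e-6

    def test_additive_dose_coding_recovers_slope(self):
        rng = np.random.default_rng(0)
        dose = np.repeat([0, 1, 2], 8)
        cuberoot = 0.4 + 0.05 * dose + rng.normal(0, 0.01, len(dose))
        fits = fit_proportion_model(
            _prop_table(cuberoot), _subject_table(dose, "dose"), ProportionModelSpec("dose", ())
        )
        assert fits.coef.iloc[0] == pytest.approx(0.05, abs=0.01)

    def test_cube_root_transform_is_actually_applied(self):
        # concavity of the cube root reverses this group contrast:
        # raw means 0.365 vs 0.216, cube-root means 0.5 vs 0.6
        props = _prop_table([0.1, 0.9, 0.6, 0.6])
        group = [0, 0, 1, 1]
        fits = fit_proportion_model(
            props, _subject_table(group), ProportionModelSpec("group", ())
        )
        import statsmodels.api as sm

        raw = sm.OLS(props.proportion, sm.add_constant(np.array(group, float))).fit()
        assert np.sign(fits.coef.iloc[0]) == 1.0
        assert np.sign(raw.params.iloc[1]) == -1.0

    def test_rank_deficient_design_names_aliased_terms(self):
        subj = _subject_table([0, 0, 1, 1])
        subj["copy"] = subj["group"]
        with pytest.raises(ValueError, match="aliased"):
            fit_proportion_model(
                _prop_table([0.4, 0.5, 0.5, 0.6]),
                subj,
                ProportionModelSpec("group", ("copy",)),
            )

    def test_subject_filter_restricts_cohort(self):
        subj = _subject_table([0, 0, 1, 1, 0, 1])
        subj["status"] = ["sAD"] * 4 + ["other"] * 2
        fits = fit_proportion_model(
            _prop_table([0.4, 0.45, 0.5, 0.55, 0.9, 0.1]),
            subj,
            ProportionModelSpec("group", (), subject_filter="status == 'sAD'"),
        )
        assert fits.n_subjects.iloc[0] == 4


class TestMetaAnalysis:
    def test_two_identical_z2_results_combine_to_2_83(self):
        from scipy import stats

        p = 2 * stats.norm.sf(2.0)
        z, p_comb = meta_analyze_proportions([(0.5, p, 10), (0.5, p, 10)])
        assert z == pytest.approx(2 * np.sqrt(2), abs=1e-9)
        assert p_comb < p

    def test_opposite_effects_cancel(self):
        z, p = meta_analyze_proportions([(0.5, 0.01, 10), (-0.5, 0.01, 10)])
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_null_inputs_stay_null(self):
        z, p = meta_analyze_proportions([(0.0, 0.5, 10), (0.0, 0.5, 10)])
        assert z == 0.0 and p == 1.0
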