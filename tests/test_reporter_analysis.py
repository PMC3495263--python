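"""Reporter selection, reporter SVD patterns, correlation, stepwise F-test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chromowave as cw
from chromowave import ComputationError, InputError


@pytest.fixture
def reference():
    return pd.DataFrame(
        {
            "gene_symbol": ["gA", "gB", "gC", "gD"],
            "cell_type": ["neuron", "neuron", "neuron", "astrocyte"],
            "fold_change": [25.0, 30.0, 15.0, 40.0],
            "chromosome": ["1", "X", "2", "3"],
        }
    )


class TestSelectReporters:
    def test_filter_rules(self, reference, small_study):
        ann = small_study.annotation.copy()
        ann.loc[ann.index[0], "gene_symbol"] = "gA"
        study = cw.ExpressionStudy(
            small_study.matrix, small_study.detection, ann, small_study.samples
        )
        rset = cw.select_reporters(reference, study, "neuron")
        # gB is on X, gC is only 15-fold: both excluded
        assert set(rset.genes) == {"gA", "gB", "gC"} - {"gB", "gC"}
        assert rset.probes == [ann.index[0]]

    def test_fold_exactly_20_excluded(self, reference, small_study):
        ref = reference.assign(fold_change=[20.0, 30.0, 15.0, 40.0])
        ann = small_study.annotation.copy()
        ann.loc[ann.index[0], "gene_symbol"] = "gA"
        study = cw.ExpressionStudy(
            small_study.matrix, small_study.detection, ann, small_study.samples
        )
        with pytest.raises(ComputationError, match="no reporters"):
            cw.select_reporters(ref, study, "neuron")

    def test_gene_with_multiple_probes_attaches_all(self, reference, small_study):
        ann = small_study.annotation.copy()
        three = ann.index[:3]
        ann.loc[three, "gene_symbol"] = "gA"
        study = cw.ExpressionStudy(
            small_study.matrix, small_study.detection, ann, small_study.samples
        )
        rset = cw.select_reporters(reference, study, "neuron")
        assert sorted(rset.probes) == sorted(three)

    def test_missing_columns_rejected(self, small_study):
        with pytest.raises(InputError, match="missing columns"):
            cw.select_reporters(pd.DataFrame({"gene_symbol": []}), small_study, "neuron")

    def test_synthetic_reference_round_trip(self, small_study, small_profiles):
        rset = cw.select_reporters(small_profiles.reference, small_study, "neuron")
        assert set(rset.genes) == set(small_profiles.reporters["neuron"])


class TestReporterPattern:
    def _study_from_matrix(self, mat: np.ndarray, genes=None):
        n, m = mat.shape
        probes = [f"p{i}" for i in range(n)]
        ann = pd.DataFrame(
            {
                "gene_symbol": genes or [f"g{i}" for i in range(n)],
                "chromosome": "1",
                "start_bp": np.arange(1, n + 1),
                "is_escape": False,
            },
            index=pd.Index(probes, name="probe_id"),
        )
        meta = pd.DataFrame(
            {"group": "control", "sex": "M", "age": 70},
            index=pd.Index([f"s{j}" for j in range(m)], name="sample_id"),
        )
        mat_df = pd.DataFrame(mat, index=probes, columns=meta.index)
        det = pd.DataFrame(True, index=probes, columns=meta.index)
        return cw.ExpressionStudy(mat_df, det, ann, meta, scale="log2")

    def _reporter_set(self, study):
        return cw.ReporterGeneSet(
            cell_type="neuron",
            genes={g: 25.0 for g in study.annotation.gene_symbol},
            probes=list(study.annotation.index),
        )

    def test_rank_one_gives_centered_profile(self):
        v = np.array([1.0, 3.0, 2.0, 5.0])
        scales = np.array([1.0, 2.0, 0.5])
        study = self._study_from_matrix(np.outer(scales, v))  # probes x samples
        loadings = cw.reporter_pattern(study, self._reporter_set(study))
        centered = v - v.mean()
        # loadings proportional to the centered sample profile, positively oriented
        ratio = loadings / centered
        assert np.allclose(ratio, ratio[0])
        assert np.corrcoef(loadings, v)[0, 1] > 0

    def test_identical_samples_get_equal_loadings(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=6)
        other = rng.normal(size=6)
        mat = np.column_stack([col, col, other])
        loadings = cw.reporter_pattern(
            self._study_from_matrix(mat), self._reporter_set(self._study_from_matrix(mat))
        )
        assert loadings[0] == pytest.approx(loadings[1], abs=1e-10)

    def test_tracks_true_neuron_fraction_on_synthetic_cohort(self, default_runs):
        rs = [
            abs(
                cw.correlate_loadings(
                    run.neuronal_loadings, run.study.samples.frac_neuron.to_numpy()
                ).r
            )
            for run in default_runs
        ]
        assert min(rs) >= 0.9

    def test_linear_study_rejected(self, small_study, small_profiles):
        rset = cw.select_reporters(small_profiles.reference, small_study, "neuron")
        with pytest.raises(InputError):
            cw.reporter_pattern(small_study, rset)


class TestCorrelate:
    def test_perfect_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = cw.correlate_loadings(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-6
        assert res.n == 4

    def test_anticorrelation(self):
        x = np.array([1.0, 2.0, 5.0])
        assert cw.correlate_loadings(x, -x).r == pytest.approx(-1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert cw.correlate_loadings(x, y).r == cw.correlate_loadings(y, x).r

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=15), rng.normal(size=15)
        res = cw.correlate_loadings(x, y)
        ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    @pytest.mark.parametrize(
        "x,y",
        [
            (np.ones(5), np.arange(5.0)),
            (np.arange(3.0), np.arange(3.0) * 0 + 2),
        ],
    )
    def test_zero_variance_rejected(self, x, y):
        with pytest.raises(ComputationError):
            cw.correlate_loadings(x, y)

    def test_short_vectors_rejected(self):
        with pytest.raises(InputError):
            cw.correlate_loadings(np.arange(2.0), np.arange(2.0))


class TestStepwise:
    def test_exact_base_fit_adds_nothing(self):
        # type-I control: y determined by x1 alone
        count = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x1 = rng.normal(size=20)
            x2 = rng.normal(size=20)
            res = cw.stepwise_add(3.0 * x1 + 1.0, x1, x2)
            count += not res.added_is_significant
        assert count >= 19

    def test_perfect_fit_by_added_predictor(self):
        rng = np.random.default_rng(3)
        x2 = rng.normal(size=10)
        x1 = rng.normal(size=10)
        res = cw.stepwise_add(x2, x1, x2)
        assert res.added_is_significant
        assert res.partial_p < 1e-6

    def test_minimal_n_returns_finite_f(self):
        rng = np.random.default_rng(4)
        y, x1, x2 = rng.normal(size=(3, 4))
        res = cw.stepwise_add(y, x1, x2)
        assert np.isfinite(res.partial_F)
        assert 0 <= res.partial_p <= 1

    def test_collinear_predictors_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ComputationError, match="collinear"):
            cw.stepwise_add(x**2, x, 2 * x + 1)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(6, 30))
            x1, x2 = rng.normal(size=(2, n))
            y = 0.5 * x1 + rng.normal(size=n)
            res = cw.stepwise_add(y, x1, x2)
            # brute-force normal equations
            for design, attr in [(np.column_stack([np.ones(n), x1]), "rss1"),
                                 (np.column_stack([np.ones(n), x1, x2]), "rss2")]:
                beta = np.linalg.solve(design.T @ design, design.T @ y)
                rss = np.sum((y - design @ beta) ** 2)
                if attr == "rss1":
                    rss1 = rss
                else:
                    rss2 = rss
            f_oracle = ((rss1 - rss2) / 1) / (rss2 / (n - 3))
            assert res.partial_F == pytest.approx(f_oracle, abs=1e-8, rel=1e-8)


class TestEndToEndAssociation:
    def test_neuronal_correlation_band(self, default_runs):
        rs = [abs(run.r_neuronal) for run in default_runs]
        assert min(rs) >= 0.75
        assert np.median(rs) >= 0.9

    def test_astro_correlation_weaker_when_independent(self, independent_astro_runs):
        weaker = sum(
            abs(run.r_astro) < abs(run.r_neuronal) for run in independent_astro_runs
        )
        assert weaker == len(independent_astro_runs)

    def test_astro_adds_no_information_when_independent(self, independent_astro_runs):
        nonsig = 0
        for run in independent_astro_runs:
            res = cw.stepwise_add(
                run.result.case_loadings, run.neuronal_loadings, run.astro_loadings
            )
            nonsig += not res.added_is_significant
        assert nonsig >= 9
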