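"""Comparison methods: regression by exhaustive CV, ML baseline, Inferelator rule."""

import numpy as np
import pandas as pd
import pytest

from tftarget.baselines import (
    MLBaseline,
    MLBaselineConfig,
    inferelator_combine,
    inferelator_single_score,
    regression_rank_genes,
    regression_select,
)
from tftarget.data import ExpressionSet


class TestInferelator:
    @pytest.mark.parametrize(
        "b1,b2,b3,expected",
        [(0.2, 0.5, 0.1, 0.2), (0.0, 0.7, 0.4, 0.4), (0.0, 0.0, 0.0, 0.0),
         (-0.6, 0.5, -0.1, 0.5)],
    )
    def test_pair_formula(self, b1, b2, b3, expected):
        assert inferelator_combine(b1, b2, b3) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            inferelator_combine(np.nan, 1.0, 1.0)

    def test_single_score_max_over_terms(self):
        table = pd.DataFrame(
            {"gene": ["g1"] * 3, "term": ["A", "B", "A:B"],
             "beta": [0.2, -0.9, 0.5]}
        )
        assert inferelator_single_score(table, "g1", "A") == pytest.approx(0.5)
        assert inferelator_single_score(table, "g1", "B") == pytest.approx(0.9)
        assert inferelator_single_score(table, "g1", "C") == 0.0

    def test_pair_score_from_table(self):
        from tftarget.baselines import inferelator_pair_score

        table = pd.DataFrame(
            {"gene": ["g1"] * 3, "term": ["A", "B", "B:A"],
             "beta": [0.2, -0.9, 0.1]}
        )
        # max(|0.1|, min(|0.2|, |-0.9|)) = 0.2; interaction matched either order
        assert inferelator_pair_score(table, "g1", "A", "B") == pytest.approx(0.2)
        assert inferelator_pair_score(table, "g1", "A", "C") == 0.0


class TestRegressionSelect:
    def test_exact_linear_recovery(self):
        t = np.arange(12.0)
        F = np.column_stack([np.sin(t / 3) + 1.5, np.cos(t / 2) + 1.5, t / 6])
        y = 2.0 * F[:, 0] + 1.0
        model = regression_select(y, F)
        assert model.active == (0,)
        assert model.cv_mse == pytest.approx(0.0, abs=1e-16)
        assert model.weights[0] == pytest.approx(2.0)
        assert model.bias == pytest.approx(1.0)

    def test_constant_gene_selects_null(self):
        t = np.arange(10.0)
        F = np.column_stack([np.sin(t), np.cos(t)])
        model = regression_select(np.full(10, 3.0), F)
        assert model.active == ()

    def test_random_genes_prefer_null_overall(self, rng):
        t = np.arange(10.0)
        F = np.column_stack([np.sin(t / 2) + 2, np.cos(t / 3) + 2])
        n_null = 0
        n_genes = 300
        for _ in range(n_genes):
            y = rng.normal(1.0, 0.5, t.size)
            if regression_select(y, F).active == ():
                n_null += 1
        # CV punishes spurious regressors: null chosen far above 1/4 of the time
        assert n_null / n_genes > 2 / 4

    def test_invariant_to_tf_order(self, rng):
        t = np.arange(12.0)
        F = np.column_stack([np.sin(t / 3) + 2, np.cos(t / 2) + 2, t / 6 + 1])
        y = 1.5 * F[:, 2] + rng.normal(0, 0.05, t.size)
        m1 = regression_select(y, F)
        m2 = regression_select(y, F[:, ::-1])
        assert m1.cv_mse == pytest.approx(m2.cv_mse)
        assert np.allclose(sorted(m1.weights), sorted(m2.weights), atol=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            regression_select([1.0, 2.0], np.ones((2, 1)))


def _tiny_dataset(seed=0, n_genes=3):
    """1-TF synthetic set generated directly from the ODE model."""
    from tftarget.ode import (
        FunctionOnGrid, KineticParams, ProteinParams, ResponseWeights,
        solve_transcription, solve_translation,
    )

    rng = np.random.default_rng(seed)
    times = np.array([0.0, 1.0, 2.0, 3.0, 5.0, 7.0, 9.0, 11.0])
    grid = np.union1d(np.linspace(0, 11, 80), times)
    fv = 0.2 + 2.5 * np.exp(-0.5 * ((grid - 4) / 2.0) ** 2)
    f = FunctionOnGrid(grid, fv)
    p = solve_translation(f, ProteinParams(delta=1.0, p0=fv[0]))
    rows = []
    truth = {}
    for j in range(n_genes):
        kp = KineticParams(b=0.2, s=1.5, d=0.8, a=0.4)
        rw = ResponseWeights(w=np.array([1.0]), w0=-0.3)
        m = solve_transcription([p], rw, kp, times)
        noisy = m + rng.normal(0, 0.05, times.size)
        rows.append(pd.DataFrame({
            "gene": f"g{j}", "condition": "c1", "replicate": "r1",
            "time": times, "value": np.maximum(noisy, 0), "variance": 0.0025,
        }))
        truth[f"g{j}"] = m
    rows.append(pd.DataFrame({
        "gene": "TF1", "condition": "c1", "replicate": "r1",
        "time": times, "value": f(times), "variance": 0.0025,
    }))
    return ExpressionSet(pd.concat(rows, ignore_index=True)), truth


class TestMLBaseline:
    def test_nested_structures_and_optimality(self):
        data, truth = _tiny_dataset(seed=1, n_genes=1)
        ml = MLBaseline(data, ["TF1"], MLBaselineConfig(n_restarts=3, maxiter=150, grid_size=80))
        ll, flags = ml.fit_gene(data.series("g0"), seed=0)
        # nesting: the regulated model includes the null as a special case
        assert ll[1] >= ll[0] - 1e-6
        assert not flags.any()

    def test_noise_free_fit_beats_generating_parameters(self):
        from tftarget.ode import (
            FunctionOnGrid, KineticParams, ProteinParams, ResponseWeights,
            solve_transcription, solve_translation,
        )

        times = np.array([0.0, 1.0, 2.0, 3.0, 5.0, 7.0, 9.0, 11.0])
        grid = np.union1d(np.linspace(0, 11, 80), times)
        fv = 0.2 + 2.5 * np.exp(-0.5 * ((grid - 4) / 2.0) ** 2)
        p = solve_translation(FunctionOnGrid(grid, fv), ProteinParams(1.0, p0=fv[0]))
        kp = KineticParams(b=0.2, s=1.5, d=0.8, a=0.4)
        m = solve_transcription([p], ResponseWeights(np.array([1.0]), -0.3), kp, times)
        frame = pd.concat([
            pd.DataFrame({"gene": "g0", "condition": "c1", "replicate": "r1",
                          "time": times, "value": m, "variance": 0.0025}),
            pd.DataFrame({"gene": "TF1", "condition": "c1", "replicate": "r1",
                          "time": times, "value": np.interp(times, grid, fv),
                          "variance": 0.0025}),
        ], ignore_index=True)
        data = ExpressionSet(frame)
        ml = MLBaseline(data, ["TF1"], MLBaselineConfig(n_restarts=4, maxiter=200, grid_size=80))
        ll, _ = ml.fit_gene(data.series("g0"), seed=0)
        # log-lik at the generating parameters (noise-free residuals ~ 0)
        var = np.full(times.size, 0.0025)
        ll_truth = -0.5 * np.sum(np.log(2 * np.pi * var))
        assert ll[1] >= ll_truth - 1.0

    def test_activation_only_keeps_weights_nonnegative(self):
        data, _ = _tiny_dataset(seed=2, n_genes=1)
        cfg = MLBaselineConfig(n_restarts=2, maxiter=60, grid_size=60, activation_only=True)
        ml = MLBaseline(data, ["TF1"], cfg)
        table = ml.score_genes(data, genes=["g0"], seed=0)
        assert set(table.frame.columns) >= {"logev_0", "logev_1", "map_structure"}


class TestRegressionRanking:
    def test_ranking_ascending_in_cv_mse(self, small_benchmark):
        data = small_benchmark.expression
        genes = small_benchmark.test_genes[:8]
        ranked = regression_rank_genes(data, ["ANT", "BEE", "CAR"], genes)
        assert list(ranked["cv_mse"]) == sorted(ranked["cv_mse"])
        assert set(ranked["gene"]) == set(genes)
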