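"""Training-phase MCMC: correctness, reproducibility and robustification."""

import numpy as np
import pandas as pd
import pytest

from tftarget.data import ExpressionSet, TrainingNetwork
from tftarget.model import TFActivityModel
from tftarget.ode import (
    FunctionOnGrid,
    KineticParams,
    ProteinParams,
    ResponseWeights,
    solve_transcription,
    solve_translation,
)
from tftarget.training import (
    TrainingConfig,
    corrupt_training_links,
    robust_filter,
    run_training,
)

TIMES = np.array([0.0, 2.0, 5.0, 9.0])


def _one_tf_dataset(gene_params, noise_sd=0.05, seed=0, extra_driver=None,
                    times=TIMES):
    """Tiny 1-TF dataset generated straight from the ODE model.

    ``gene_params``: list of (w, w0, KineticParams).  ``extra_driver`` maps
    gene index -> additive unmodelled signal at the observation times.
    """
    rng = np.random.default_rng(seed)
    grid = np.union1d(np.linspace(times[0], times[-1], 60), times)
    fv = 0.3 + 2.0 * np.exp(-0.5 * ((grid - 3.5) / 1.8) ** 2)
    f = FunctionOnGrid(grid, fv)
    p = solve_translation(f, ProteinParams(delta=1.0, p0=fv[0]))
    rows = []
    for j, (w, w0, kp) in enumerate(gene_params):
        m = solve_transcription([p], ResponseWeights(np.array([w]), w0), kp, times)
        if extra_driver and j in extra_driver:
            m = m + extra_driver[j]
        y = np.maximum(m + noise_sd * rng.standard_normal(m.shape), 0.0)
        rows.append(pd.DataFrame({
            "gene": f"g{j}", "condition": "c1", "replicate": "r1",
            "time": times, "value": y, "variance": noise_sd**2,
        }))
    rows.append(pd.DataFrame({
        "gene": "TF1", "condition": "c1", "replicate": "r1",
        "time": times, "value": np.maximum(
            f(times) + noise_sd * rng.standard_normal(times.shape), 0.0),
        "variance": noise_sd**2,
    }))
    data = ExpressionSet(pd.concat(rows, ignore_index=True))
    net = TrainingNetwork(pd.DataFrame(
        {"TF1": [1] * len(gene_params)},
        index=[f"g{j}" for j in range(len(gene_params))],
    ))
    return data, net, grid, p


class TestBasics:
    def test_chain_reproducibility(self):
        data, net, *_ = _one_tf_dataset(
            [(1.0, -0.2, KineticParams(b=0.2, s=1.2, d=0.7, a=0.3))] * 3
        )
        cfg = TrainingConfig(iterations=150, burn_in=100, n_store=50, grid_size=25)
        a = run_training(data, net, cfg, seed=5)
        b = run_training(data, net, cfg, seed=5)
        assert np.array_equal(a.delta_samples, b.delta_samples)
        key = ("c1", "r1")
        assert np.array_equal(a.activity_samples[key], b.activity_samples[key])

    def test_masked_weights_stay_zero(self):
        data, _, _, _ = _one_tf_dataset(
            [(1.0, 0.0, KineticParams(b=0.2, s=1.0, d=0.8, a=0.3))] * 3
        )
        # add a second TF column that regulates nothing
        frame = data.frame
        tf2 = frame[frame["gene"] == "TF1"].copy()
        tf2["gene"] = "TF2"
        data = ExpressionSet(pd.concat([frame, tf2], ignore_index=True))
        net = TrainingNetwork(pd.DataFrame(
            {"TF1": [1, 1, 1], "TF2": [0, 0, 0]}, index=["g0", "g1", "g2"]
        ))
        cfg = TrainingConfig(iterations=200, burn_in=150, n_store=60, grid_size=25)
        post = run_training(data, net, cfg, seed=2)
        assert np.all(post.gene_samples["w"][:, :, 1] == 0.0)
        assert np.any(post.gene_samples["w"][:, :, 0] != 0.0)

    def test_empty_training_set_rejected(self):
        data, net, *_ = _one_tf_dataset(
            [(1.0, 0.0, KineticParams(b=0.2, s=1.0, d=0.8, a=0.3))]
        )
        empty = TrainingNetwork(net.frame.iloc[:0])
        with pytest.raises(ValueError):
            run_training(data, empty, TrainingConfig(iterations=10, burn_in=10))

    def test_save_load_round_trip(self, tmp_path):
        data, net, *_ = _one_tf_dataset(
            [(1.0, 0.0, KineticParams(b=0.2, s=1.0, d=0.8, a=0.3))] * 2
        )
        cfg = TrainingConfig(iterations=80, burn_in=60, n_store=40, grid_size=25)
        post = run_training(data, net, cfg, seed=1)
        path = tmp_path / "posterior.npz"
        post.save(path)
        from tftarget.training import TrainingResults

        back = TrainingResults.load(path)
        assert back.tf_names == post.tf_names
        key = ("c1", "r1")
        assert np.allclose(back.activity_samples[key], post.activity_samples[key])
        assert np.allclose(back.delta_samples, post.delta_samples)


class TestCorruptLinks:
    def test_module_level_alias(self):
        net = TrainingNetwork(pd.DataFrame({"T": [1, 0, 1]}, index=list("abc")))
        assert np.array_equal(corrupt_training_links(net, 0.0, 1).X, net.X)
        assert np.array_equal(corrupt_training_links(net, 1.0, 1).X, 1 - net.X)


class TestRobustFilter:
    def _run_adaptive(self, extra=None, seed=0):
        kp = KineticParams(b=0.2, s=1.2, d=0.7, a=0.3)
        params = [(1.0, -0.2, kp)] * 6
        data, net, *_ = _one_tf_dataset(
            params, noise_sd=0.05, seed=seed, extra_driver=extra,
            times=np.array([0.0, 1.0, 2.0, 3.5, 5.0, 7.0, 9.0, 11.0]),
        )
        cfg = TrainingConfig(iterations=600, burn_in=600, n_store=200,
                             grid_size=30, use_adaptive=True)
        return run_training(data, net, cfg, seed=seed)

    def test_threshold_edges(self):
        post = self._run_adaptive()
        assert robust_filter(post, np.inf) == [f"g{j}" for j in range(6)]
        with pytest.raises(ValueError):
            robust_filter(post, -1.0)

    def test_confounded_gene_excluded(self):
        # gene 5 carries a large unmodelled late pulse the TF cannot explain
        t = np.array([0.0, 1.0, 2.0, 3.5, 5.0, 7.0, 9.0, 11.0])
        pulse = 2.5 * np.exp(-0.5 * ((t - 9.0) / 1.2) ** 2)
        post = self._run_adaptive(extra={5: pulse}, seed=3)
        kept = robust_filter(post, 0.01)
        assert "g5" not in kept
        av = post.adaptive_var_samples.mean(axis=0)
        # the confounded gene needs far more extra variance than the others
        assert av[5] > 5 * np.median(av[:5])
        assert len(kept) >= 2

    def test_requires_adaptive_posterior(self):
        data, net, *_ = _one_tf_dataset(
            [(1.0, 0.0, KineticParams(b=0.2, s=1.0, d=0.8, a=0.3))] * 2
        )
        post = run_training(
            data, net, TrainingConfig(iterations=50, burn_in=40, grid_size=25), seed=0
        )
        with pytest.raises(ValueError):
            robust_filter(post, 0.01)


class TestPosteriorCorrectness:
    """MCMC marginals vs a brute-force quadrature posterior.

    Two genes, one TF, four time points; the latent TF function, weights and
    all other parameters are pinned so the free parameters are each gene's
    (b, d).  The exact posterior then factorises over genes and is computable
    by 2-d quadrature.
    """

    def test_bd_moments_match_quadrature(self):
        kp = KineticParams(b=0.25, s=1.2, d=0.7, a=0.4)
        data, net, grid, p_true = _one_tf_dataset(
            [(1.0, -0.2, kp)] * 2, noise_sd=0.08, seed=4
        )
        fixed = ("f", "hypers", "delta", "p0", "s", "a", "w", "w0")
        init = {
            "delta": [1.0],
            "s": np.full(2, kp.s), "a": np.full(2, kp.a),
            "w": np.ones((2, 1)), "w0": np.full(2, -0.2),
        }
        cfg = TrainingConfig(iterations=4000, burn_in=1000, n_store=4000,
                             grid_size=60, fixed=fixed, init=init)
        post = run_training(data, net, cfg, seed=6)
        b_mcmc = post.gene_samples["b"]
        d_mcmc = post.gene_samples["d"]

        # quadrature oracle on the identical pinned model
        key = ("c1", "r1")
        grid_t = post.grids[key]
        f_obs = data.series("TF1")[key]
        fv = np.interp(grid_t, f_obs[0], f_obs[1])
        p = solve_translation(
            FunctionOnGrid(grid_t, fv), ProteinParams(delta=1.0, p0=max(f_obs[1][0], 1e-2))
        )
        lb = np.linspace(np.log(0.02), np.log(3.0), 140)
        ld = np.linspace(np.log(0.05), np.log(8.0), 140)
        for j in range(2):
            t, y, var = data.series(f"g{j}")[key]
            loglik = np.empty((lb.size, ld.size))
            for q, ldv in enumerate(ld):
                for r, lbv in enumerate(lb):
                    kp_try = KineticParams(b=np.exp(lbv), s=kp.s, d=np.exp(ldv), a=kp.a)
                    m = solve_transcription(
                        [p], ResponseWeights(np.array([1.0]), -0.2), kp_try, t
                    )
                    loglik[r, q] = -0.5 * np.sum((y - m) ** 2 / var)
            logprior = (
                -0.5 * (lb[:, None] / 1.5) ** 2 - 0.5 * (ld[None, :] / 1.5) ** 2
            )
            w = np.exp(loglik + logprior - (loglik + logprior).max())
            w /= w.sum()
            eb = np.sum(w * np.exp(lb)[:, None])
            ed = np.sum(w * np.exp(ld)[None, :])
            sdb = np.sqrt(np.sum(w * (np.exp(lb)[:, None] - eb) ** 2))
            sdd = np.sqrt(np.sum(w * (np.exp(ld)[None, :] - ed) ** 2))
            assert b_mcmc[:, j].mean() == pytest.approx(eb, abs=0.25 * sdb + 0.02)
            assert d_mcmc[:, j].mean() == pytest.approx(ed, abs=0.25 * sdd + 0.02)


class TestModelSurface:
    def test_fit_robust_two_stage(self):
        kp = KineticParams(b=0.2, s=1.2, d=0.7, a=0.3)
        t = np.array([0.0, 1.0, 2.0, 3.5, 5.0, 7.0, 9.0, 11.0])
        pulse = 2.5 * np.exp(-0.5 * ((t - 9.0) / 1.2) ** 2)
        data, net, *_ = _one_tf_dataset(
            [(1.0, -0.2, kp)] * 5, noise_sd=0.05, seed=3,
            extra_driver={4: pulse}, times=t,
        )
        cfg = TrainingConfig(iterations=500, burn_in=500, n_store=150, grid_size=30)
        model = TFActivityModel(data, net, cfg)
        post, retained = model.fit_robust(seed=1)
        assert "g4" not in retained
        assert post.gene_ids == retained
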