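"""Shared test fixtures: toy posteriors, an independent evidence oracle and
the scaled-down benchmark experiment used for ordering checks."""

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from tftarget.ode import (
    FunctionOnGrid,
    KineticParams,
    ProteinParams,
    ResponseWeights,
    solve_transcription,
    solve_translation,
)
from tftarget.training import TrainingConfig, TrainingResults

KEY = ("c1", "r1")
TOY_TIMES = np.array([0.0, 1.0, 2.0, 3.0, 5.0, 7.0, 9.0, 11.0, 14.0, 18.0])


def toy_activities(n_tf=2, grid_n=60):
    """Smooth, well-separated TF activity functions on a dense grid."""
    grid = np.union1d(np.linspace(0.0, 18.0, grid_n), TOY_TIMES)
    shapes = [(2.5, 5.0, 2.0, 0.2), (2.0, 12.0, 2.5, 0.15), (1.5, 8.0, 4.0, 0.3)]
    ps = []
    for amp, centre, width, base in shapes[:n_tf]:
        fv = base + amp * np.exp(-0.5 * ((grid - centre) / width) ** 2)
        p = solve_translation(FunctionOnGrid(grid, fv), ProteinParams(1.0, p0=fv[0]))
        ps.append(p.values)
    return grid, np.array(ps)


def toy_posterior(n_tf=2, grid_n=60, n_samples=1, jitter=0.0, seed=0):
    """A minimal TrainingResults carrying fixed TF activities.

    With ``n_samples=1`` and no jitter the prediction phase scores genes
    against known activities, which makes low-dimensional oracles feasible.
    """
    grid, P = toy_activities(n_tf, grid_n)
    rng = np.random.default_rng(seed)
    samples = np.array(
        [P * np.exp(jitter * rng.standard_normal(P.shape)) for _ in range(n_samples)]
    )
    tf_names = [f"TF{i + 1}" for i in range(n_tf)]
    S = n_samples
    return TrainingResults(
        tf_names=tf_names,
        gene_ids=[],
        keys=[KEY],
        grids={KEY: grid},
        activity_samples={KEY: samples},
        f_samples={KEY: samples.copy()},
        delta_samples=np.ones((S, n_tf)),
        p0_samples={KEY: np.ones((S, n_tf))},
        hyper_samples=np.ones((S, n_tf, 2)),
        gene_samples={},
        adaptive_var_samples=None,
        acceptance={},
        config=TrainingConfig(),
        seed=seed,
    )


def toy_gene_series(posterior, w, w0, kp: KineticParams, noise_sd=0.08, seed=0):
    """Observations of one gene generated from the toy activities."""
    grid = posterior.grids[KEY]
    P = posterior.activity_samples[KEY][0]
    ps = [FunctionOnGrid(grid, row) for row in P]
    m = solve_transcription(ps, ResponseWeights(np.asarray(w, float), w0), kp, TOY_TIMES)
    rng = np.random.default_rng(seed)
    y = np.maximum(m + noise_sd * rng.standard_normal(m.shape), 0.0)
    var = np.full_like(y, noise_sd**2)
    return {KEY: (TOY_TIMES, y, var)}


# ---------------------------------------------------------------------------
# independent evidence oracle: defensive importance sampling
# ---------------------------------------------------------------------------


def _oracle_loglik(phi, active, n_tf, ps, times, y, var):
    """Likelihood from the public ODE solver (independent of the fast path)."""
    b, d, a = np.exp(phi[0]), np.exp(phi[1]), np.exp(phi[2])
    w = np.zeros(n_tf)
    if active.size:
        s = np.exp(phi[3])
        w0 = phi[4]
        w[active] = phi[5 : 5 + active.size]
    else:
        s, w0 = 0.0, 0.0
    kp = KineticParams(b=b, s=s, d=d, a=a)
    m = solve_transcription(ps, ResponseWeights(w, w0), kp, times)
    r = y - m
    return -0.5 * np.sum(np.log(2 * np.pi * var) + r * r / var)


def _oracle_logprior(phi, active, kinetic_sd=1.5, weight_sd=2.0):
    sds = [kinetic_sd] * 3
    if active.size:
        sds += [kinetic_sd, weight_sd] + [weight_sd] * active.size
    sds = np.array(sds)
    z = phi / sds
    return float(np.sum(-0.5 * z * z - np.log(sds) - 0.5 * np.log(2 * np.pi)))


def _fd_hessian(f, x, eps=1e-4):
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps * eps)
    return H


def is_evidence_oracle(posterior, series, x, n_draws=40_000, seed=0,
                       sample_index=0):
    """Defensive importance-sampling estimate of log p(y | x).

    Proposal: 50/50 mixture of the prior and a Laplace approximation at the
    posterior mode (located by direct optimisation of the exact log
    posterior).  Returns (log_evidence, Monte-Carlo standard error in nats).
    """
    grid = posterior.grids[KEY]
    P = posterior.activity_samples[KEY][sample_index]
    ps = [FunctionOnGrid(grid, row) for row in P]
    n_tf = P.shape[0]
    t, y, var = series[KEY]
    active = np.flatnonzero(np.asarray(x) == 1)
    dim = 3 if active.size == 0 else 5 + active.size

    def logpost(phi):
        return _oracle_loglik(phi, active, n_tf, ps, t, y, var) + _oracle_logprior(phi, active)

    x0 = np.zeros(dim)
    x0[0] = np.log(max(np.median(y) * 0.5, 1e-2))
    x0[1] = np.log(0.6)
    x0[2] = np.log(max(y[0], 1e-2))
    best = None
    for trial in range(4):
        start = x0 + (0.7 * trial) * np.random.default_rng(seed + trial).standard_normal(dim)
        res = minimize(lambda p: -logpost(p), start, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
        res = minimize(lambda p: -logpost(p), res.x, method="BFGS",
                       options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    mode = best.x
    H = _fd_hessian(lambda p: -logpost(p), mode)
    # regularise to a valid covariance
    vals, vecs = np.linalg.eigh(H)
    vals = np.maximum(vals, 1e-3)
    base_cov = (vecs / vals) @ vecs.T

    from scipy.special import gammaln

    df = 4.0
    comps = []  # (weight, chol, logdet) of multivariate-t components
    for weight, infl in ((0.45, 3.0), (0.25, 12.0)):
        cov = base_cov * infl
        chol = np.linalg.cholesky(cov)
        _, logdet = np.linalg.slogdet(cov)
        comps.append((weight, chol, logdet))
    prior_weight = 0.30
    prior_sds = np.array([1.5] * 3 + ([1.5, 2.0] + [2.0] * active.size if active.size else []))

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_draws, [c[0] for c in comps] + [prior_weight])
    blocks = []
    for (w_, chol, _), n_c in zip(comps, counts[:2]):
        z = rng.standard_normal((n_c, dim))
        u = rng.chisquare(df, n_c) / df
        blocks.append(mode + (z / np.sqrt(u)[:, None]) @ chol.T)
    blocks.append(rng.standard_normal((counts[2], dim)) * prior_sds)
    draws = np.vstack(blocks)

    def _logpdf_t(phi_batch, chol, logdet):
        diff = phi_batch - mode
        sol = np.linalg.solve(chol, diff.T).T
        quad = np.sum(sol * sol, axis=1)
        return (
            gammaln((df + dim) / 2.0) - gammaln(df / 2.0)
            - 0.5 * dim * np.log(df * np.pi) - 0.5 * logdet
            - 0.5 * (df + dim) * np.log1p(quad / df)
        )

    def log_q(phi_batch):
        zp = phi_batch / prior_sds
        lq_prior = np.sum(-0.5 * zp * zp - np.log(prior_sds) - 0.5 * np.log(2 * np.pi), axis=1)
        parts = [lq_prior + np.log(prior_weight)]
        for w_, chol, logdet in comps:
            parts.append(_logpdf_t(phi_batch, chol, logdet) + np.log(w_))
        return logsumexp(np.vstack(parts), axis=0)

    lw = np.empty(n_draws)
    for k in range(n_draws):
        lw[k] = logpost(draws[k])
    lw -= log_q(draws)
    log_ev = logsumexp(lw) - np.log(n_draws)
    # MC standard error via normalised weights
    wts = np.exp(lw - lw.max())
    ess = wts.sum() ** 2 / np.sum(wts**2)
    se = np.sqrt(np.var(wts / wts.mean()) / n_draws)
    return float(log_ev), float(se), float(ess)


# ---------------------------------------------------------------------------
# scaled-down benchmark experiment (training + prediction + baselines)
# ---------------------------------------------------------------------------


def run_benchmark_experiment(
    seed,
    conditions=(1, 2),
    n_train=15,
    n_test=80,
    grid_size=50,
    train_iters=5000,
    train_burn=4000,
    with_ml=False,
):
    """Generate a benchmark, train, predict and compute single-link AUCs.

    Returns a dict with per-TF AUCs of the Bayesian method (and optionally
    the ML baseline), plus the mean posterior variance of the TF activities.
    """
    from tftarget.baselines import MLBaseline, MLBaselineConfig
    from tftarget.evaluation import roc
    from tftarget.model import TFActivityModel
    from tftarget.predict import PredictionConfig, StructureScorer
    from tftarget.synthetic import SyntheticConfig, generate_benchmark
    from tftarget.training import TrainingConfig

    cfg = SyntheticConfig(
        n_genes=n_train + n_test, n_train=n_train, conditions=(1, 2),
        grid_size=grid_size,
    )
    ds = generate_benchmark(cfg, seed=seed)
    # one dataset per seed; experiments differ in which conditions they see
    from tftarget.data import ExpressionSet

    conds = [f"c{c}" for c in conditions]
    expression = ExpressionSet(
        ds.expression.frame[ds.expression.frame["condition"].isin(conds)]
    )
    tcfg = TrainingConfig(
        iterations=train_iters, burn_in=train_burn, n_store=200, grid_size=grid_size,
    )
    posterior = TFActivityModel(expression, ds.corrupted_network, tcfg).fit(seed=seed)
    pcfg = PredictionConfig(
        n_activity_samples=3, chain_iterations=230, chain_burn_in=120,
        mode_search_iters=25,
    )
    scorer = StructureScorer(posterior, pcfg)
    table = scorer.score_genes(expression, genes=ds.test_genes, seed=seed)
    truth = ds.truth.structures.loc[ds.test_genes]
    marg = table.single_marginals().loc[ds.test_genes]

    out = {"seed": seed, "conditions": tuple(conditions), "auc": {}, "table": table,
           "dataset": ds, "posterior": posterior}
    for tf in ("ANT", "BEE", "CAR"):
        _, _, auc = roc(marg[tf].to_numpy(), truth[tf].to_numpy())
        out["auc"][tf] = auc
    _, _, auc_all = roc(marg.to_numpy().ravel(), truth.to_numpy().ravel())
    out["auc"]["all"] = auc_all
    out["activity_var"] = float(
        np.mean([posterior.activity_samples[k].var(axis=0).mean()
                 for k in posterior.keys])
    )
    if with_ml:
        mlcfg = MLBaselineConfig(n_restarts=2, maxiter=60, grid_size=grid_size)
        ml = MLBaseline.from_training(expression, ds.corrupted_network, mlcfg, seed=seed)
        ml_table = ml.score_genes(expression, genes=ds.test_genes, seed=seed)
        ml_marg = ml_table.single_marginals().loc[ds.test_genes]
        out["ml_auc"] = {}
        for tf in ("ANT", "BEE", "CAR"):
            _, _, auc = roc(ml_marg[tf].to_numpy(), truth[tf].to_numpy())
            out["ml_auc"][tf] = auc
        _, _, auc_all = roc(ml_marg.to_numpy().ravel(), truth.to_numpy().ravel())
        out["ml_auc"]["all"] = auc_all
    return out
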