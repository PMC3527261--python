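"""Training phase: joint MCMC over latent TF activities and ODE parameters.

Given a small set of training genes whose regulating TFs are (approximately)
known, the sampler infers, per experimental condition/replicate:

* the latent TF mRNA functions f_i(t) under whitened squared-exponential GP
  priors (elliptical slice sampling),
* the protein activities p_i(t) = translation-ODE response of f_i,

and, shared across conditions:

* protein degradation rates delta_i and GP hyperparameters,
* per-gene kinetics (b, d, s, a) and response weights (w, w0) with weights
  clamped to zero wherever the training network says the link is absent,
* optional per-gene adaptive noise variances used to robustify training
  against genes the TF set cannot explain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky

from .data import ExpressionSet, TrainingNetwork
from .gp import GPHyperparams, gp_cov
from .ode import POSITIVITY_FLOOR

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "TrainingResults",
    "run_training",
    "robust_filter",
    "corrupt_training_links",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class TrainingConfig:
    """MCMC settings and priors for the training phase."""

    iterations: int = 30_000
    burn_in: int = 20_000
    n_store: int = 500
    grid_size: int = 100
    activation_only: bool = False
    use_adaptive: bool = False
    adaptive_threshold: float = 0.01
    log_every: int = 0
    #: log-normal prior sd on positive scalars (b, s, d, a, delta, p0)
    kinetic_prior_sd: float = 1.5
    #: normal prior sd on response weights and bias
    weight_prior_sd: float = 2.0
    #: mean of the exponential prior on adaptive variances
    adaptive_prior_mean: float = 0.05
    #: log-normal prior sd on GP hyperparameters
    hyper_prior_sd: float = 1.0
    #: names of blocks to hold fixed at their initial values (for testing /
    #: restricted fits): subset of {"f", "hypers", "delta", "p0"} plus any of
    #: the per-gene parameters {"b", "d", "s", "a", "w", "w0"}
    fixed: tuple = ()
    #: optional overrides of initial values, e.g. {"delta": [...], "s": [...]}
    init: dict = field(default_factory=dict)


def corrupt_training_links(X: TrainingNetwork, rate: float, seed) -> TrainingNetwork:
    """Flip each training-network link independently with the given rate."""
    return X.corrupt(rate, seed)


def robust_filter(posterior: "TrainingResults", threshold: float = 0.01):
    """Training genes whose posterior-mean adaptive variance is acceptable.

    Genes needing extra noise beyond the measurement model are poorly
    explained by the modelled TFs (e.g. driven by a confounder) and are
    dropped before the final, non-adaptive training run.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if posterior.adaptive_var_samples is None:
        raise ValueError("posterior was not trained with use_adaptive=True")
    mean_av = posterior.adaptive_var_samples.mean(axis=0)
    return [g for g, v in zip(posterior.gene_ids, mean_av) if v <= threshold]


@dataclass
class TrainingResults:
    """Posterior samples from the training phase.

    Activity samples are stored per condition key on that key's dense grid;
    kinetics, weights and degradation rates are shared across keys.
    """

    tf_names: list
    gene_ids: list
    keys: list
    grids: dict                      # key -> (N,) times
    activity_samples: dict           # key -> (S, I, N) protein activities
    f_samples: dict                  # key -> (S, I, N) TF mRNA functions
    delta_samples: np.ndarray        # (S, I)
    p0_samples: dict                 # key -> (S, I)
    hyper_samples: np.ndarray        # (S, I, 2): variance, lengthscale
    gene_samples: dict               # name -> (S, J) or (S, J, I) for "w"
    adaptive_var_samples: np.ndarray | None
    acceptance: dict
    config: TrainingConfig
    seed: int

    @property
    def n_samples(self):
        return self.delta_samples.shape[0]

    def delta_summary(self):
        """Posterior median and central 95% interval of each delta_i."""
        import pandas as pd

        q = np.quantile(self.delta_samples, [0.025, 0.5, 0.975], axis=0)
        return pd.DataFrame(
            {"q2.5": q[0], "median": q[1], "q97.5": q[2]}, index=self.tf_names
        )

    def activity_mean(self, key):
        return self.activity_samples[key].mean(axis=0)

    def summary(self):
        """Human-readable report of the fit."""
        import pandas as pd

        lines = ["Training-phase posterior summary", "=" * 34]
        lines.append(f"TFs: {', '.join(self.tf_names)}")
        lines.append(f"training genes: {len(self.gene_ids)}")
        lines.append(f"conditions/replicates: {len(self.keys)}")
        lines.append(f"stored samples: {self.n_samples}")
        lines.append("")
        lines.append("Protein degradation rates (1/h):")
        lines.append(self.delta_summary().round(3).to_string())
        hyp = np.median(self.hyper_samples, axis=0)
        lines.append("")
        lines.append("GP hyperparameters (posterior medians):")
        lines.append(
            pd.DataFrame(
                {"variance": hyp[:, 0], "lengthscale": hyp[:, 1]}, index=self.tf_names
            ).round(3).to_string()
        )
        if self.adaptive_var_samples is not None:
            av = self.adaptive_var_samples.mean(axis=0)
            lines.append("")
            lines.append(
                "adaptive variances (posterior means): "
                + ", ".join(f"{g}={v:.4f}" for g, v in zip(self.gene_ids, av))
            )
        for name, rate in sorted(self.acceptance.items()):
            lines.append(f"acceptance[{name}] = {rate:.3f}")
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------

    def save(self, path):
        """Archive the posterior as a portable .npz with a JSON manifest."""
        import json

        payload = {
            "delta_samples": self.delta_samples,
            "hyper_samples": self.hyper_samples,
        }
        for k, key in enumerate(self.keys):
            payload[f"grid_{k}"] = self.grids[key]
            payload[f"activity_{k}"] = self.activity_samples[key]
            payload[f"f_{k}"] = self.f_samples[key]
            payload[f"p0_{k}"] = self.p0_samples[key]
        for name, arr in self.gene_samples.items():
            payload[f"gene_{name}"] = arr
        if self.adaptive_var_samples is not None:
            payload["adaptive_var"] = self.adaptive_var_samples
        manifest = {
            "tf_names": self.tf_names,
            "gene_ids": self.gene_ids,
            "keys": [list(k) for k in self.keys],
            "gene_sample_names": list(self.gene_samples),
            "has_adaptive": self.adaptive_var_samples is not None,
            "acceptance": self.acceptance,
            "seed": self.seed,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
                if k != "init"
            },
        }
        payload["manifest"] = np.frombuffer(
            json.dumps(manifest).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path):
        import json

        with np.load(path) as z:
            manifest = json.loads(z["manifest"].tobytes().decode())
            keys = [tuple(k) for k in manifest["keys"]]
            cfg = dict(manifest["config"])
            cfg["fixed"] = tuple(cfg.get("fixed", ()))
            return cls(
                tf_names=manifest["tf_names"],
                gene_ids=manifest["gene_ids"],
                keys=keys,
                grids={key: z[f"grid_{k}"] for k, key in enumerate(keys)},
                activity_samples={key: z[f"activity_{k}"] for k, key in enumerate(keys)},
                f_samples={key: z[f"f_{k}"] for k, key in enumerate(keys)},
                delta_samples=z["delta_samples"],
                p0_samples={key: z[f"p0_{k}"] for k, key in enumerate(keys)},
                hyper_samples=z["hyper_samples"],
                gene_samples={
                    name: z[f"gene_{name}"] for name in manifest["gene_sample_names"]
                },
                adaptive_var_samples=z["adaptive_var"] if manifest["has_adaptive"] else None,
                acceptance=manifest["acceptance"],
                config=TrainingConfig(**cfg),
                seed=manifest["seed"],
            )


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------


class _Condition:
    """Per-(condition, replicate) observation layout and likelihood caches."""

    def __init__(self, key, grid, tf_obs, gene_obs_idx, gene_y, gene_var):
        self.key = key
        self.grid = grid                    # (N,)
        self.trel = grid - grid[0]
        self.tf_obs = tf_obs                # per TF: (idx, y, var) or None
        self.obs_idx = gene_obs_idx         # (K,)
        self.y = gene_y                     # (J, K)
        self.var = gene_var                 # (J, K)
        n = grid.size
        h = np.diff(grid)
        left = np.concatenate(([0.0], h / 2.0))
        right = np.concatenate((h / 2.0, [0.0]))
        k = np.arange(n)
        w = np.where(k[None, :] < k[:, None], left + right, 0.0)
        np.fill_diagonal(w, left)
        self.quad_w_full = w                              # (N, N)
        self.lag_full = np.maximum(grid[:, None] - grid[None, :], 0.0)
        self.quad_w = w[gene_obs_idx]                     # (K, N)
        self.lag = self.lag_full[gene_obs_idx]            # (K, N)
        self.t_obs = self.trel[gene_obs_idx]               # (K,)
        # mutable caches, filled by the sampler
        self.chol = None      # per TF (N, N)
        self.f = None         # (I, N)
        self.p = None         # (I, N)
        self.logp = None      # (I, N)
        self.g = None         # (J, N)
        self.E = None         # (J, K, N) decay-weighted quadrature operator
        self.m = None         # (J, K)
        self.gene_ll = None   # (J,)
        self.tf_ll = None     # (I,)


class _Sampler:
    TARGET_ACC = 0.25

    def __init__(self, data: ExpressionSet, network: TrainingNetwork,
                 config: TrainingConfig, seed: int):
        self.config = config
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.tf_names = network.tf_names
        self.gene_ids = [g for g in network.genes]
        missing = [g for g in self.gene_ids if g not in data]
        if missing:
            raise ValueError(f"training genes without expression data: {missing}")
        if not self.gene_ids:
            raise ValueError("empty training set")
        for tf in self.tf_names:
            if tf not in data:
                raise ValueError(f"no mRNA series for TF {tf!r}")
        self.X = network.X.astype(bool)            # (J, I)
        self.J, self.I = self.X.shape
        self._build_conditions(data)
        self._init_state()

    # -- layout --------------------------------------------------------------

    def _build_conditions(self, data):
        keys = data.keys
        self.conds = []
        for key in keys:
            # rectangular gene observation block for this key
            times = None
            ys, vs = [], []
            for g in self.gene_ids:
                ser = data.series(g)
                if key not in ser:
                    raise ValueError(f"gene {g!r} missing series {key}")
                t, y, v = ser[key]
                if t.size < 3:
                    raise ValueError(f"gene {g!r} has fewer than 3 time points")
                if times is None:
                    times = t
                elif t.shape != times.shape or not np.allclose(t, times):
                    raise ValueError("all training genes must share time points")
                ys.append(y)
                vs.append(v)
            all_times = [times]
            tf_raw = []
            for tf in self.tf_names:
                t, y, v = data.series(tf)[key]
                tf_raw.append((t, y, v))
                all_times.append(t)
            lo = min(t[0] for t in all_times)
            hi = max(t[-1] for t in all_times)
            grid = np.linspace(lo, hi, self.config.grid_size)
            grid = np.union1d(grid, np.concatenate(all_times))
            gene_idx = np.searchsorted(grid, times)
            tf_obs = []
            for t, y, v in tf_raw:
                tf_obs.append((np.searchsorted(grid, t), y, v))
            self.conds.append(
                _Condition(key, grid, tf_obs, gene_idx, np.vstack(ys), np.vstack(vs))
            )

    # -- state ---------------------------------------------------------------

    def _init_state(self):
        cfg = self.config
        init = cfg.init
        I, J = self.I, self.J
        # GP hyperparameters (shared across conditions)
        self.log_hyp = np.empty((I, 2))
        self.f_mean = []  # per condition: (I,) constant GP means
        for c in self.conds:
            self.f_mean.append(np.array([np.mean(o[1]) for o in c.tf_obs]))
        span = np.mean([c.grid[-1] - c.grid[0] for c in self.conds])
        for i in range(I):
            v = np.mean([np.var(c.tf_obs[i][1]) for c in self.conds]) + 1e-3
            self.log_hyp[i] = [np.log(v), np.log(span / 4.0)]
        if "hypers" in init:
            self.log_hyp = np.log(np.asarray(init["hypers"], float))
        self.hyper_prior_mu = self.log_hyp.copy()

        self.log_delta = np.log(np.asarray(init.get("delta", np.ones(I)), float))
        self.log_p0 = []
        for c, fm in zip(self.conds, self.f_mean):
            p0 = np.array(
                [max(c.tf_obs[i][1][0], 1e-2) / np.exp(self.log_delta[i]) for i in range(I)]
            )
            self.log_p0.append(np.log(p0))
        if "p0" in init:
            self.log_p0 = [np.log(np.asarray(v, float)) for v in init["p0"]]

        # whitened latent functions, initialised from interpolated TF data
        self.nu = []
        for c, fm in zip(self.conds, self.f_mean):
            self._refresh_chol(c)
            nus = []
            for i in range(I):
                idx, y, _ = c.tf_obs[i]
                f0 = np.interp(c.grid, c.grid[idx], y) - fm[i]
                from scipy.linalg import solve_triangular

                nus.append(solve_triangular(c.chol[i], f0, lower=True))
            self.nu.append(np.array(nus))

        # gene-level parameters
        y_all = np.concatenate([c.y for c in self.conds], axis=1)
        d0 = np.full(J, 0.6)
        b0 = np.maximum(y_all.min(axis=1), 0.02) * d0
        a0 = np.maximum(y_all[:, 0], 0.02)
        s0 = np.maximum(y_all.max(axis=1) * d0 - b0, 0.05) * 2.0
        self.theta = {
            "b": np.log(np.asarray(init.get("b", b0), float)),
            "d": np.log(np.asarray(init.get("d", d0), float)),
            "s": np.log(np.asarray(init.get("s", s0), float)),
            "a": np.log(np.asarray(init.get("a", a0), float)),
        }
        self.w0 = np.asarray(init.get("w0", np.zeros(J)), float).copy()
        w_init = np.where(self.X, 0.5, 0.0)
        if "w" in init:
            w_init = np.asarray(init["w"], float) * self.X
        if cfg.activation_only:
            self.log_w = np.where(self.X, np.log(np.maximum(w_init, 0.05)), -np.inf)
        self.w = np.where(self.X, np.maximum(w_init, 0.05) if cfg.activation_only else w_init, 0.0)
        self.log_av = np.full(J, np.log(0.01))
        self.use_adaptive = cfg.use_adaptive

        # adaptive proposal scales
        self.scales = {
            "gene_kinetics": np.full(J, 0.08),
            "gene_weights": np.full(J, 0.08),
            "gene_all": np.full(J, 0.05),
            "delta": np.full(I, 0.15),
            "p0": np.full((len(self.conds), I), 0.3),
            "hyp": np.full(I, 0.2),
            "av": np.full(J, 0.5),
        }
        self.acc = {k: np.zeros_like(v) for k, v in self.scales.items()}
        self.tries = {k: np.zeros_like(v) for k, v in self.scales.items()}
        self.ess_evals = 0.0
        self.ess_calls = 0.0

        for ci, c in enumerate(self.conds):
            self._refresh_f(ci)
            for i in range(I):
                self._refresh_p(ci, i)
            self._refresh_genes(ci, rebuild_E=True)
            c.tf_ll = np.array([self._tf_ll(c, i) for i in range(I)])

    # -- cache refresh -------------------------------------------------------

    def _refresh_chol(self, c: _Condition):
        c.chol = [
            cholesky(
                gp_cov(c.grid, GPHyperparams(np.exp(h[0]), np.exp(h[1]))), lower=True
            )
            for h in self.log_hyp
        ]

    def _refresh_f(self, ci):
        c = self.conds[ci]
        fm = self.f_mean[ci]
        c.f = np.array(
            [fm[i] + c.chol[i] @ self.nu[ci][i] for i in range(self.I)]
        )

    def _refresh_p(self, ci, i):
        c = self.conds[ci]
        if c.p is None:
            c.p = np.empty((self.I, c.grid.size))
            c.logp = np.empty_like(c.p)
        c.p[i] = np.maximum(
            self._translate(c, c.f[i], np.exp(self.log_delta[i]),
                            np.exp(self.log_p0[ci][i])),
            0.0,
        )
        c.logp[i] = np.log(np.maximum(c.p[i], POSITIVITY_FLOOR))

    @staticmethod
    def _translate(c, f, delta, p0):
        """Trapezoid solution of the translation ODE via the decay operator."""
        C = np.exp(-delta * c.lag_full) * c.quad_w_full
        return p0 * np.exp(-delta * c.trel) + C @ np.maximum(f, 0.0)

    def _build_E(self, c: _Condition, d):
        return np.exp(-d[:, None, None] * c.lag[None]) * c.quad_w[None]

    def _gene_m(self, c, E, g, b, d, s, a):
        decay = np.exp(-d[:, None] * c.t_obs[None, :])           # (J, K)
        integral = np.einsum("jkn,jn->jk", E, g)
        return a[:, None] * decay + (b / d)[:, None] * (1.0 - decay) + s[:, None] * integral

    def _total_var(self, c):
        if self.use_adaptive:
            return c.var + np.exp(self.log_av)[:, None]
        return c.var

    def _gene_ll_from_m(self, c, m, var=None):
        var = self._total_var(c) if var is None else var
        r = c.y - m
        return -0.5 * np.sum(np.log(_TWO_PI * var) + r * r / var, axis=1)

    def _refresh_genes(self, ci, rebuild_E=False):
        c = self.conds[ci]
        b, d, s, a = (np.exp(self.theta[k]) for k in ("b", "d", "s", "a"))
        if rebuild_E or c.E is None:
            c.E = self._build_E(c, d)
        c.g = self._g_from_logp(c.logp)
        c.m = self._gene_m(c, c.E, c.g, b, d, s, a)
        c.gene_ll = self._gene_ll_from_m(c, c.m)

    def _g_from_logp(self, logp, w=None, w0=None):
        w = self.w if w is None else w
        w0 = self.w0 if w0 is None else w0
        z = w0[:, None] + w @ logp
        return 0.5 * (1.0 + np.tanh(0.5 * z))

    def _tf_ll(self, c, i):
        idx, y, v = c.tf_obs[i]
        r = y - c.f[i][idx]
        return float(-0.5 * np.sum(np.log(_TWO_PI * v) + r * r / v))

    # -- priors --------------------------------------------------------------

    def _kin_prior(self, logx):
        sd = self.config.kinetic_prior_sd
        return -0.5 * logx * logx / (sd * sd)

    def _weight_prior(self, w, log_w=None):
        sd = self.config.weight_prior_sd
        if self.config.activation_only:
            # half-normal on w >= 0, sampled as log w (includes Jacobian)
            return -0.5 * w * w / (sd * sd) + (log_w if log_w is not None else np.log(w))
        return -0.5 * w * w / (sd * sd)

    def _av_prior(self, log_av):
        av = np.exp(log_av)
        return -av / self.config.adaptive_prior_mean + log_av

    def _hyper_prior(self, i, log_hyp_i):
        sd = self.config.hyper_prior_sd
        r = log_hyp_i - self.hyper_prior_mu[i]
        return -0.5 * np.sum(r * r) / (sd * sd)

    # -- update blocks -------------------------------------------------------

    def _ess_update_f(self, ci, i):
        """Elliptical slice update of the whitened latent function (c, i)."""
        c = self.conds[ci]
        fm = self.f_mean[ci][i]
        genes = np.flatnonzero(self.w[:, i] != 0.0)
        b, d, s, a = (np.exp(self.theta[k]) for k in ("b", "d", "s", "a"))

        def loglik(nu_prop):
            f = fm + c.chol[i] @ nu_prop
            p = self._translate(c, f, np.exp(self.log_delta[i]),
                                np.exp(self.log_p0[ci][i]))
            logp = c.logp.copy()
            logp[i] = np.log(np.maximum(p, POSITIVITY_FLOOR))
            idx, y, v = c.tf_obs[i]
            r = y - f[idx]
            ll = -0.5 * np.sum(np.log(_TWO_PI * v) + r * r / v)
            if genes.size:
                g = self._g_from_logp(logp, self.w[genes], self.w0[genes])
                m = self._gene_m(c, c.E[genes], g, b[genes], d[genes], s[genes], a[genes])
                var = self._total_var(c)[genes]
                ll += -0.5 * np.sum(np.log(_TWO_PI * var) + (c.y[genes] - m) ** 2 / var)
            return ll

        nu = self.nu[ci][i]
        cur = c.tf_ll[i] + (c.gene_ll[genes].sum() if genes.size else 0.0)
        v = self.rng.standard_normal(nu.shape)
        thresh = cur + np.log(self.rng.random())
        theta = self.rng.uniform(0.0, _TWO_PI)
        lo, hi = theta - _TWO_PI, theta
        self.ess_calls += 1
        while True:
            self.ess_evals += 1
            prop = nu * np.cos(theta) + v * np.sin(theta)
            ll = loglik(prop)
            if ll > thresh:
                break
            if theta < 0:
                lo = theta
            else:
                hi = theta
            theta = self.rng.uniform(lo, hi)
        self.nu[ci][i] = prop
        self._refresh_f(ci)
        self._refresh_p(ci, i)
        self._refresh_genes(ci)
        c.tf_ll[i] = self._tf_ll(c, i)

    def _update_genes(self, block="all"):
        """Random-walk update of each gene's kinetics and/or weights."""
        cfg = self.config
        fixed = set(cfg.fixed)
        if block == "kinetics":
            fixed |= {"w", "w0"}
        elif block == "weights":
            fixed |= {"b", "d", "s", "a"}
        J = self.J
        step = self.scales[f"gene_{block}"]
        prop = {
            k: (v if k in fixed else v + step * self.rng.standard_normal(J))
            for k, v in self.theta.items()
        }
        w0_p = self.w0 if "w0" in fixed else self.w0 + step * self.rng.standard_normal(J)
        if "w" in fixed:
            log_w_p = self.log_w if cfg.activation_only else None
            w_p = self.w
        elif cfg.activation_only:
            log_w_p = np.where(
                self.X, self.log_w + step[:, None] * self.rng.standard_normal((J, self.I)), -np.inf
            )
            w_p = np.where(self.X, np.exp(log_w_p), 0.0)
        else:
            log_w_p = None
            w_p = np.where(
                self.X, self.w + step[:, None] * self.rng.standard_normal((J, self.I)), 0.0
            )

        logr = np.zeros(J)
        for k in ("b", "d", "s", "a"):
            logr += self._kin_prior(prop[k]) - self._kin_prior(self.theta[k])
        sd = cfg.weight_prior_sd
        logr += -0.5 * (w0_p**2 - self.w0**2) / (sd * sd)
        if cfg.activation_only:
            pw = np.where(self.X, self._weight_prior(w_p, log_w_p), 0.0)
            cw = np.where(self.X, self._weight_prior(self.w, self.log_w), 0.0)
            logr += (pw - cw).sum(axis=1)
        else:
            logr += (
                np.where(self.X, self._weight_prior(w_p) - self._weight_prior(self.w), 0.0)
            ).sum(axis=1)

        b, d, s, a = (np.exp(prop[k]) for k in ("b", "d", "s", "a"))
        new_E, new_m, new_ll = [], [], []
        cur_ll = np.zeros(J)
        for c in self.conds:
            E = self._build_E(c, d)
            g = self._g_from_logp(c.logp, w_p, w0_p)
            m = self._gene_m(c, E, g, b, d, s, a)
            new_E.append(E)
            new_m.append(m)
            new_ll.append(self._gene_ll_from_m(c, m))
            cur_ll += c.gene_ll
        logr += sum(new_ll) - cur_ll

        accept = np.log(self.rng.random(J)) < logr
        self.tries[f"gene_{block}"] += 1
        self.acc[f"gene_{block}"] += accept
        if np.any(accept):
            for k in ("b", "d", "s", "a"):
                self.theta[k][accept] = prop[k][accept]
            self.w0[accept] = w0_p[accept]
            self.w[accept] = w_p[accept]
            if cfg.activation_only:
                self.log_w[accept] = log_w_p[accept]
            for c, E, m, ll in zip(self.conds, new_E, new_m, new_ll):
                c.E[accept] = E[accept]
                c.m[accept] = m[accept]
                c.gene_ll[accept] = ll[accept]
                # g depends on weights; refresh rows
                c.g[accept] = self._g_from_logp(c.logp, self.w[accept], self.w0[accept])

    def _update_delta(self, i):
        """Update log delta_i jointly with a compensating shift of the w0_j.

        Changing delta_i rescales p_i, which every regulated gene would have
        to absorb through its bias; shifting each w0_j by
        w_ji * (change in mean log p_i) removes that ridge.  The shift is a
        deterministic unit-Jacobian bijection, so plain MH acceptance applies.
        """
        prop = self.log_delta[i] + self.scales["delta"][i] * self.rng.standard_normal()
        logr = self._kin_prior(prop) - self._kin_prior(self.log_delta[i])
        old = self.log_delta[i]
        old_w0 = self.w0.copy()
        # mixture kernel: half the moves carry the compensating w0 shift
        # (fast along the scale ridge), half are plain (anchored by the data)
        compensate = "w0" not in self.config.fixed and self.rng.random() < 0.5
        mean_logp_old = np.mean([c.logp[i].mean() for c in self.conds])
        self.log_delta[i] = prop
        snapshots = []
        for ci, c in enumerate(self.conds):
            snapshots.append((c.p[i].copy(), c.logp[i].copy(), c.g.copy(), c.m.copy(), c.gene_ll.copy()))
            self._refresh_p(ci, i)
        mean_logp_new = np.mean([c.logp[i].mean() for c in self.conds])
        if compensate:
            self.w0 = old_w0 + self.w[:, i] * (mean_logp_old - mean_logp_new)
        sd = self.config.weight_prior_sd
        logr += np.sum(-0.5 * (self.w0**2 - old_w0**2) / (sd * sd))
        for ci, c in enumerate(self.conds):
            self._refresh_genes(ci)
            logr += c.gene_ll.sum() - snapshots[ci][4].sum()
        self.tries["delta"][i] += 1
        if np.log(self.rng.random()) < logr:
            self.acc["delta"][i] += 1
        else:
            self.log_delta[i] = old
            self.w0 = old_w0
            for c, (p, logp, g, m, ll) in zip(self.conds, snapshots):
                c.p[i], c.logp[i], c.g, c.m, c.gene_ll = p, logp, g, m, ll

    def _update_p0(self, ci, i):
        c = self.conds[ci]
        prop = self.log_p0[ci][i] + self.scales["p0"][ci, i] * self.rng.standard_normal()
        logr = self._kin_prior(prop) - self._kin_prior(self.log_p0[ci][i])
        old = self.log_p0[ci][i]
        snap = (c.p[i].copy(), c.logp[i].copy(), c.g.copy(), c.m.copy(), c.gene_ll.copy())
        self.log_p0[ci][i] = prop
        self._refresh_p(ci, i)
        self._refresh_genes(ci)
        logr += c.gene_ll.sum() - snap[4].sum()
        self.tries["p0"][ci, i] += 1
        if np.log(self.rng.random()) < logr:
            self.acc["p0"][ci, i] += 1
        else:
            self.log_p0[ci][i] = old
            c.p[i], c.logp[i], c.g, c.m, c.gene_ll = snap

    def _update_hyper(self, i):
        prop = self.log_hyp[i] + self.scales["hyp"][i] * self.rng.standard_normal(2)
        logr = self._hyper_prior(i, prop) - self._hyper_prior(i, self.log_hyp[i])
        old_hyp = self.log_hyp[i].copy()
        old_state = []
        for c in self.conds:
            old_state.append(
                (c.chol[i], c.f[i].copy(), c.p[i].copy(), c.logp[i].copy(),
                 c.g.copy(), c.m.copy(), c.gene_ll.copy(), c.tf_ll[i])
            )
        self.log_hyp[i] = prop
        try:
            for ci, c in enumerate(self.conds):
                c.chol[i] = cholesky(
                    gp_cov(c.grid, GPHyperparams(np.exp(prop[0]), np.exp(prop[1]))),
                    lower=True,
                )
                c.f[i] = self.f_mean[ci][i] + c.chol[i] @ self.nu[ci][i]
                self._refresh_p(ci, i)
                self._refresh_genes(ci)
                new_tf = self._tf_ll(c, i)
                logr += (c.gene_ll.sum() - old_state[ci][6].sum()) + (new_tf - old_state[ci][7])
                c.tf_ll[i] = new_tf
        except np.linalg.LinAlgError:
            logr = -np.inf
        self.tries["hyp"][i] += 1
        if np.log(self.rng.random()) < logr:
            self.acc["hyp"][i] += 1
        else:
            self.log_hyp[i] = old_hyp
            for c, st in zip(self.conds, old_state):
                c.chol[i], c.f[i], c.p[i], c.logp[i], c.g, c.m, c.gene_ll, c.tf_ll[i] = st

    def _update_av(self):
        prop = self.log_av + self.scales["av"] * self.rng.standard_normal(self.J)
        logr = self._av_prior(prop) - self._av_prior(self.log_av)
        new_ll = []
        cur = np.zeros(self.J)
        for c in self.conds:
            var = c.var + np.exp(prop)[:, None]
            new_ll.append(self._gene_ll_from_m(c, c.m, var))
            cur += c.gene_ll
        logr += sum(new_ll) - cur
        accept = np.log(self.rng.random(self.J)) < logr
        self.tries["av"] += 1
        self.acc["av"] += accept
        if np.any(accept):
            self.log_av[accept] = prop[accept]
            for c, ll in zip(self.conds, new_ll):
                c.gene_ll[accept] = ll[accept]

    # -- adaptation & main loop ---------------------------------------------

    def _adapt(self, it):
        gamma = 2.0 / np.sqrt(1.0 + it / 10.0)
        for name in self.scales:
            tries = np.maximum(self.tries[name], 1)
            rate = self.acc[name] / tries
            self.scales[name] *= np.exp(gamma * (rate - self.TARGET_ACC))
            np.clip(self.scales[name], 1e-3, 5.0, out=self.scales[name])
            self.acc[name][...] = 0
            self.tries[name][...] = 0

    def run(self):
        cfg = self.config
        fixed = set(cfg.fixed)
        total = cfg.burn_in + cfg.iterations
        n_store = min(cfg.n_store, cfg.iterations)
        store_at = set(
            (cfg.burn_in + np.unique(
                np.linspace(0, cfg.iterations - 1, n_store).astype(int))).tolist()
        )
        S = len(store_at)
        stored = {
            "activity": {c.key: np.empty((S, self.I, c.grid.size)) for c in self.conds},
            "f": {c.key: np.empty((S, self.I, c.grid.size)) for c in self.conds},
            "delta": np.empty((S, self.I)),
            "p0": {c.key: np.empty((S, self.I)) for c in self.conds},
            "hyp": np.empty((S, self.I, 2)),
            "gene": {
                "b": np.empty((S, self.J)), "d": np.empty((S, self.J)),
                "s": np.empty((S, self.J)), "a": np.empty((S, self.J)),
                "w": np.empty((S, self.J, self.I)), "w0": np.empty((S, self.J)),
            },
            "av": np.empty((S, self.J)) if self.use_adaptive else None,
        }
        s_out = 0
        adapt_every = 50
        for it in range(total):
            if "f" not in fixed:
                for ci in range(len(self.conds)):
                    for i in range(self.I):
                        self._ess_update_f(ci, i)
            if not {"b", "d", "s", "a", "w", "w0"} <= fixed:
                self._update_genes("kinetics")
                self._update_genes("weights")
                self._update_genes("all")
            if "delta" not in fixed:
                for i in range(self.I):
                    self._update_delta(i)
            if "p0" not in fixed:
                for ci in range(len(self.conds)):
                    for i in range(self.I):
                        self._update_p0(ci, i)
            if "hypers" not in fixed:
                for i in range(self.I):
                    self._update_hyper(i)
            if self.use_adaptive:
                self._update_av()
            if it < cfg.burn_in and (it + 1) % adapt_every == 0:
                self._adapt(it)
            if cfg.log_every and (it + 1) % cfg.log_every == 0:
                ll = sum(c.gene_ll.sum() + c.tf_ll.sum() for c in self.conds)
                logger.info("iter %d/%d loglik %.2f", it + 1, total, ll)
            if it in store_at:
                for c in self.conds:
                    stored["activity"][c.key][s_out] = c.p
                    stored["f"][c.key][s_out] = c.f
                for ci, c in enumerate(self.conds):
                    stored["p0"][c.key][s_out] = np.exp(self.log_p0[ci])
                stored["delta"][s_out] = np.exp(self.log_delta)
                stored["hyp"][s_out] = np.exp(self.log_hyp)
                for k in ("b", "d", "s", "a"):
                    stored["gene"][k][s_out] = np.exp(self.theta[k])
                stored["gene"]["w"][s_out] = self.w
                stored["gene"]["w0"][s_out] = self.w0
                if self.use_adaptive:
                    stored["av"][s_out] = np.exp(self.log_av)
                s_out += 1

        acceptance = {}
        for name in self.scales:
            tr = self.tries[name].sum()
            acceptance[name] = float(self.acc[name].sum() / tr) if tr else float("nan")
        acceptance["ess_evals_per_call"] = float(
            self.ess_evals / max(self.ess_calls, 1.0)
        )
        return TrainingResults(
            tf_names=self.tf_names,
            gene_ids=self.gene_ids,
            keys=[c.key for c in self.conds],
            grids={c.key: c.grid for c in self.conds},
            activity_samples=stored["activity"],
            f_samples=stored["f"],
            delta_samples=stored["delta"],
            p0_samples=stored["p0"],
            hyper_samples=stored["hyp"],
            gene_samples=stored["gene"],
            adaptive_var_samples=stored["av"],
            acceptance=acceptance,
            config=self.config,
            seed=self.seed,
        )


def run_training(
    data: ExpressionSet,
    network: TrainingNetwork,
    config: TrainingConfig | None = None,
    seed: int = 0,
) -> TrainingResults:
    """Run the training-phase MCMC and return the posterior. Deterministic
    given the seed."""
    config = config or TrainingConfig()
    return _Sampler(data, network, config, seed).run()
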