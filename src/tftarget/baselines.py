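"""Comparison methods: maximum-likelihood scoring, sparse regression by
exhaustive cross-validation, and the Inferelator rank-combination rule."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import ExpressionSet
from .predict import ModelScoreTable, all_structures
from .ode import POSITIVITY_FLOOR

__all__ = [
    "MLBaselineConfig",
    "MLBaseline",
    "RegressionModel",
    "regression_select",
    "regression_rank_genes",
    "inferelator_combine",
    "inferelator_single_score",
]

_TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# maximum-likelihood baseline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MLBaselineConfig:
    """Optimizer settings for the point-estimate baseline."""

    n_restarts: int = 10
    maxiter: int = 200
    grid_size: int = 60
    activation_only: bool = False
    restart_spread: float = 1.0
    bound: float = 12.0


class MLBaseline:
    """Point-estimate counterpart of the Bayesian pipeline.

    TF activities are not inferred: each protein function is the
    deterministic translation-ODE response of a piecewise-linear
    interpolation of the observed TF mRNA, with the protein degradation rate
    included in the per-gene optimisation.  Structures are compared by
    maximised log-likelihood in place of Bayesian evidence; rankings are then
    produced exactly as in the Bayesian case.
    """

    def __init__(self, data: ExpressionSet, tf_names, config: MLBaselineConfig | None = None,
                 deltas=None):
        self.config = config or MLBaselineConfig()
        self.tf_names = list(tf_names)
        self.I = len(self.tf_names)
        self.structures = all_structures(self.I)
        self.deltas = None if deltas is None else np.asarray(deltas, float)
        self._prepare(data)
        if self.deltas is not None:
            # deltas fixed (estimated in a training pass): protein log-activity
            # is a constant of the optimisation, computed once per key
            self._logp_fixed = {
                key: np.vstack(
                    [self._protein(key, i, self.deltas[i]) for i in range(self.I)]
                )
                for key in self.keys
            }

    def _prepare(self, data):
        self.keys = data.keys
        self.f_grid = {}
        self.grids = {}
        for key in self.keys:
            tf_times, tf_vals = [], []
            for tf in self.tf_names:
                if tf not in data:
                    raise ValueError(f"no mRNA series for TF {tf!r}")
                t, y, _ = data.series(tf)[key]
                tf_times.append(t)
                tf_vals.append(y)
            lo = min(t[0] for t in tf_times)
            hi = max(t[-1] for t in tf_times)
            grid = np.linspace(lo, hi, self.config.grid_size)
            grid = np.union1d(grid, np.concatenate(tf_times))
            self.grids[key] = grid
            self.f_grid[key] = np.vstack(
                [np.interp(grid, t, np.maximum(y, 0.0)) for t, y in zip(tf_times, tf_vals)]
            )
            # full-grid trapezoid decay-operator pieces, built once per key
            n = grid.size
            h = np.diff(grid)
            left = np.concatenate(([0.0], h / 2.0))
            right = np.concatenate((h / 2.0, [0.0]))
            kk = np.arange(n)
            w = np.where(kk[None, :] < kk[:, None], left + right, 0.0)
            np.fill_diagonal(w, left)
            self._qw = getattr(self, "_qw", {})
            self._qw[key] = w
            self._lag = getattr(self, "_lag", {})
            self._lag[key] = np.maximum(grid[:, None] - grid[None, :], 0.0)

    # -- likelihood ----------------------------------------------------------

    def _protein(self, key, i, delta):
        grid = self.grids[key]
        f = self.f_grid[key][i]
        C = np.exp(-delta * self._lag[key]) * self._qw[key]
        # quasi-steady-state initial protein level f(0)/delta
        p = (f[0] / delta) * np.exp(-delta * (grid - grid[0])) + C @ f
        return np.log(np.maximum(p, POSITIVITY_FLOOR))

    def _neg_loglik(self, phi, active, obs):
        cfg = self.config
        k = active.size
        fixed = self.deltas is not None
        b, d, a = np.exp(phi[0]), np.exp(phi[1]), np.exp(phi[2])
        if k:
            s = np.exp(phi[3])
            w0 = phi[4]
            w = np.exp(phi[5 : 5 + k]) if cfg.activation_only else phi[5 : 5 + k]
            deltas = self.deltas[active] if fixed else np.exp(phi[5 + k : 5 + 2 * k])
        ll = 0.0
        for key, t_obs, idx, y, var in obs:
            decay = np.exp(-d * t_obs)
            m = a * decay + (b / d) * (1.0 - decay)
            if k:
                if fixed:
                    logp = self._logp_fixed[key][active]
                else:
                    logp = np.vstack(
                        [self._protein(key, i, deltas[r]) for r, i in enumerate(active)]
                    )
                g = 0.5 * (1.0 + np.tanh(0.5 * (w0 + w @ logp)))
                E = np.exp(-d * self._lag[key][idx]) * self._qw[key][idx]
                m = m + s * (E @ g)
            r_ = y - m
            ll += -0.5 * np.sum(np.log(_TWO_PI * var) + r_ * r_ / var)
        return -ll

    def _obs_layout(self, series):
        obs = []
        for key, (t, y, v) in series.items():
            grid = self.grids[key]
            idx = np.clip(np.searchsorted(grid, t), 0, grid.size - 1)
            if not np.allclose(grid[idx], t, atol=1e-9):
                raise ValueError("observation times must lie on the TF grid")
            obs.append((key, t - grid[0], idx, np.asarray(y, float), np.asarray(v, float)))
        return obs

    def fit_gene(self, series, seed=0):
        """Maximised log-likelihood for every structure of one gene.

        Returns (log-likelihoods, flags); a flag marks structures where no
        optimizer start converged (the best end point is still reported).
        """
        cfg = self.config
        obs = self._obs_layout(series)
        rng = np.random.default_rng(seed)
        y0 = np.concatenate([o[3] for o in obs])
        n_struct = len(self.structures)
        loglik = np.full(n_struct, -np.inf)
        flags = np.zeros(n_struct, dtype=bool)
        best_phi = [None] * n_struct
        order = np.argsort(self.structures.sum(axis=1), kind="mergesort")
        for r in order:
            x = self.structures[r]
            active = np.flatnonzero(x == 1)
            k = active.size
            free_delta = self.deltas is None
            dim = 3 if k == 0 else (5 + 2 * k if free_delta else 5 + k)
            base = np.zeros(dim)
            base[0] = np.log(max(np.median(y0) * 0.5, 1e-2))
            base[1] = np.log(0.6)
            base[2] = np.log(max(y0[0], 1e-2))
            if k:
                base[3] = np.log(max(y0.max() - y0.min(), 0.1))
                base[5 : 5 + k] = np.log(0.5) if cfg.activation_only else 0.5
                if free_delta:
                    base[5 + k :] = 0.0  # log delta = 0 -> delta = 1/h
            starts = [base]
            # warm starts embedding the best fit of each nested sub-structure
            for rr in range(n_struct):
                sub = self.structures[rr]
                if best_phi[rr] is None or not np.all(sub <= x) or sub.sum() != k - 1:
                    continue
                emb = base.copy()
                phi_s = best_phi[rr]
                emb[:3] = phi_s[:3]
                if sub.sum() == 0:
                    emb[3] = np.log(1e-3)
                    emb[4] = 0.0
                else:
                    emb[3] = phi_s[3]
                    emb[4] = phi_s[4]
                sub_active = np.flatnonzero(sub == 1)
                for rpos, i in enumerate(active):
                    if i in sub_active:
                        spos = int(np.flatnonzero(sub_active == i)[0])
                        emb[5 + rpos] = phi_s[5 + spos]
                        if free_delta:
                            emb[5 + k + rpos] = phi_s[5 + sub.sum() + spos]
                    else:
                        emb[5 + rpos] = np.log(1e-3) if cfg.activation_only else 0.0
                starts.append(emb)
            for _ in range(cfg.n_restarts):
                starts.append(base + cfg.restart_spread * rng.standard_normal(dim))
            best, best_val, any_ok = None, np.inf, False
            bounds = [(-cfg.bound, cfg.bound)] * dim
            for x0 in starts:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = minimize(
                        self._neg_loglik, np.clip(x0, -cfg.bound, cfg.bound),
                        args=(active, obs), method="L-BFGS-B",
                        bounds=bounds, options={"maxiter": cfg.maxiter},
                    )
                any_ok = any_ok or bool(res.success)
                if res.fun < best_val:
                    best_val, best = res.fun, res.x
            loglik[r] = -best_val
            best_phi[r] = best
            flags[r] = not any_ok
        return loglik, flags

    @classmethod
    def from_training(cls, data: ExpressionSet, network, config=None, seed=0):
        """Point-estimate training pass: fix the protein decay rates.

        Mirrors the two-phase design: each training gene (known structure) is
        fitted with its own free decay rates for the active TFs, and the
        per-TF median over training genes becomes the fixed delta used for
        genome-wide prediction.
        """
        import zlib

        free = cls(data, network.tf_names, config)
        collected = {i: [] for i in range(free.I)}
        for gene in network.genes:
            x = network.structure(gene)
            active = np.flatnonzero(x == 1)
            if active.size == 0:
                continue
            gene_seed = np.random.SeedSequence(
                [int(seed), zlib.crc32(str(gene).encode())]
            ).generate_state(1)[0]
            ll, _ = free._fit_single_structure(data.series(gene), active, gene_seed)
            phi = ll[1]
            k = active.size
            for r, i in enumerate(active):
                collected[i].append(float(np.exp(phi[5 + k + r])))
        deltas = np.array(
            [np.median(collected[i]) if collected[i] else 1.0 for i in range(free.I)]
        )
        return cls(data, network.tf_names, config, deltas=deltas)

    def _fit_single_structure(self, series, active, seed):
        """Multi-start fit of one structure; returns ((loglik, phi), flag)."""
        cfg = self.config
        obs = self._obs_layout(series)
        rng = np.random.default_rng(seed)
        y0 = np.concatenate([o[3] for o in obs])
        k = active.size
        free_delta = self.deltas is None
        dim = 3 if k == 0 else (5 + 2 * k if free_delta else 5 + k)
        base = np.zeros(dim)
        base[0] = np.log(max(np.median(y0) * 0.5, 1e-2))
        base[1] = np.log(0.6)
        base[2] = np.log(max(y0[0], 1e-2))
        if k:
            base[3] = np.log(max(y0.max() - y0.min(), 0.1))
            base[5 : 5 + k] = np.log(0.5) if cfg.activation_only else 0.5
        starts = [base] + [
            base + cfg.restart_spread * rng.standard_normal(dim)
            for _ in range(cfg.n_restarts)
        ]
        best, best_val, any_ok = None, np.inf, False
        bounds = [(-cfg.bound, cfg.bound)] * dim
        for x0 in starts:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = minimize(self._neg_loglik, np.clip(x0, -cfg.bound, cfg.bound),
                               args=(active, obs), method="L-BFGS-B",
                               bounds=bounds, options={"maxiter": cfg.maxiter})
            any_ok = any_ok or bool(res.success)
            if res.fun < best_val:
                best_val, best = res.fun, res.x
        return (-best_val, best), (not any_ok)

    def score_genes(self, data, genes=None, seed=0) -> ModelScoreTable:
        """Pseudo-posterior table from maximised likelihoods (softmax)."""
        import zlib

        genes = list(genes if genes is not None else data.genes)
        rows = []
        for g in genes:
            gene_seed = np.random.SeedSequence(
                [int(seed), zlib.crc32(str(g).encode())]
            ).generate_state(1)[0]
            ll, _ = self.fit_gene(data.series(g), seed=gene_seed)
            rows.append(ll)
        return ModelScoreTable.from_log_evidences(genes, np.vstack(rows), self.tf_names)


# ---------------------------------------------------------------------------
# exhaustive-CV linear regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionModel:
    """Selected linear model m_j ~ sum_i w_i f_i + w0 for one gene."""

    active: tuple
    weights: np.ndarray
    bias: float
    cv_mse: float


def _loo_mse(Xd, y):
    """Exact leave-one-out MSE of OLS via the hat matrix."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    G = np.linalg.pinv(Xd.T @ Xd)
    h = np.einsum("ij,jk,ik->i", Xd, G, Xd)
    denom = 1.0 - h
    if np.any(denom < 1e-8):
        return np.inf, beta
    return float(np.mean((resid / denom) ** 2)), beta


def regression_select(gene_values, tf_values) -> RegressionModel:
    """Best of all 2^I linear TF-mRNA regressions by leave-one-out CV.

    ``gene_values``: (n,) target mRNA observations; ``tf_values``: (n, I)
    TF mRNA at the same points.  Folds are single time points, so with 12
    observations this is 12-fold CV.  Degenerate designs (e.g. constant TF
    columns making a fold unsolvable) are dropped with a warning.
    """
    y = np.asarray(gene_values, float)
    F = np.asarray(tf_values, float)
    n, I = F.shape
    if n < 3:
        raise ValueError("need at least 3 time points")
    best = None
    for mask in all_structures(I):
        active = tuple(np.flatnonzero(mask == 1))
        Xd = np.column_stack([F[:, list(active)], np.ones(n)])
        mse, beta = _loo_mse(Xd, y)
        if not np.isfinite(mse):
            warnings.warn(f"dropping degenerate regression model {active}")
            continue
        if best is None or mse < best.cv_mse or (
            mse == best.cv_mse and len(active) < len(best.active)
        ):
            w = np.zeros(I)
            w[list(active)] = beta[:-1]
            best = RegressionModel(active=active, weights=w, bias=float(beta[-1]), cv_mse=mse)
    if best is None:
        raise ValueError("all regression models degenerate")
    return best


def regression_rank_genes(data: ExpressionSet, tf_names, genes=None) -> pd.DataFrame:
    """Per-gene best regression model, ranked by CV-MSE ascending."""
    genes = list(genes if genes is not None else (g for g in data.genes if g not in tf_names))
    tf_series = {tf: data.series(tf) for tf in tf_names}
    rows = []
    for g in genes:
        ser = data.series(g)
        y, F = [], []
        for key, (t, v, _) in ser.items():
            y.append(v)
            F.append(np.column_stack([tf_series[tf][key][1] for tf in tf_names]))
        model = regression_select(np.concatenate(y), np.vstack(F))
        rows.append(
            {
                "gene": g,
                "structure": "".join(
                    "1" if i in model.active else "0" for i in range(len(tf_names))
                ),
                "cv_mse": model.cv_mse,
                "bias": model.bias,
                **{f"w_{tf}": model.weights[i] for i, tf in enumerate(tf_names)},
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["cv_mse", "gene"], kind="mergesort")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Inferelator rank combination
# ---------------------------------------------------------------------------


def inferelator_combine(beta1, beta2, beta3) -> float:
    """Pair score from component weights: max(|b3|, min(|b1|, |b2|))."""
    for b in (beta1, beta2, beta3):
        if not np.isfinite(b):
            raise ValueError("betas must be finite")
    return float(max(abs(beta3), min(abs(beta1), abs(beta2))))


def inferelator_pair_score(weight_table: pd.DataFrame, gene, tf1, tf2) -> float:
    """Pair score for a gene from a weight table with interaction terms.

    beta1/beta2 are the solo weights of the two TFs (0 if absent), beta3 the
    weight of their interaction term ("TF1:TF2" in either order).
    """
    sub = weight_table[weight_table["gene"] == gene]

    def beta_of(term_set):
        hit = sub[sub["term"].apply(lambda t: set(t.split(":")) == term_set)]
        return float(hit["beta"].iloc[0]) if not hit.empty else 0.0

    b1 = beta_of({tf1})
    b2 = beta_of({tf2})
    b3 = beta_of({tf1, tf2})
    return inferelator_combine(b1, b2, b3)


def inferelator_single_score(weight_table: pd.DataFrame, gene, tf) -> float:
    """Single-TF score: max |beta| over terms mentioning the TF.

    ``weight_table`` columns: gene, term, beta; interaction terms are
    written "TF1:TF2".
    """
    sub = weight_table[weight_table["gene"] == gene]
    hits = sub[sub["term"].str.split(":").apply(lambda parts: tf in parts)]
    if hits.empty:
        return 0.0
    return float(hits["beta"].abs().max())
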