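"""Prediction phase: genome-wide Bayesian scoring of regulation structures.

For each test gene the marginal likelihood p(y | x, training data) of every
structure vector x in {0,1}^I is approximated while holding the TF-activity
posterior from the training phase fixed.  Per activity sample a short MCMC
explores the gene's kinetic and response parameters, and the evidence is
recovered from Chib's identity

    log p(y) = log p(y | phi) + log p(phi) - log p(phi | y)

evaluated at the posterior mean phi with the posterior ordinate estimated by
a Gaussian fit to the chain; evidences are then averaged over activity
samples in log space.  Posterior probabilities over structures, MAP
structures and single/pair link marginals follow by direct enumeration.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .ode import POSITIVITY_FLOOR
from .training import TrainingResults

__all__ = [
    "PredictionConfig",
    "StructureScorer",
    "ModelScoreTable",
    "all_structures",
    "structure_label",
    "bernoulli_structure_prior",
    "posterior_over_structures",
    "map_structure",
    "marginal_link_prob",
    "pair_marginal",
    "restricted_posterior",
]

_TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# posterior calculus over the discrete structure space
# ---------------------------------------------------------------------------


def all_structures(I: int) -> np.ndarray:
    """All 2^I binary structure vectors, in binary counting order."""
    n = 1 << I
    out = np.zeros((n, I), dtype=int)
    for i in range(I):
        out[:, i] = (np.arange(n) >> (I - 1 - i)) & 1
    return out


def structure_label(x) -> str:
    return "".join(str(int(v)) for v in x)


def bernoulli_structure_prior(link_prob, I) -> np.ndarray:
    """Structure prior with independent per-link inclusion probabilities.

    ``link_prob`` may be a scalar or a length-I vector; 0.5 everywhere
    reproduces the uniform prior over structures.
    """
    p = np.broadcast_to(np.asarray(link_prob, float), (I,))
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("link probabilities must be in [0, 1]")
    structures = all_structures(I)
    prior = np.prod(np.where(structures == 1, p, 1.0 - p), axis=1)
    return prior


def posterior_over_structures(log_evidences, prior=None) -> np.ndarray:
    """Softmax of log-evidence + log-prior over all structures (sums to 1)."""
    le = np.asarray(log_evidences, float)
    if np.all(np.isneginf(le)):
        raise ValueError("all structures have zero evidence")
    if np.any(np.isnan(le)):
        raise ValueError("non-finite log-evidences")
    if prior is not None:
        prior = np.asarray(prior, float)
        if np.any(prior < 0) or not np.isclose(prior.sum(), 1.0):
            raise ValueError("structure prior must be a probability vector")
        with np.errstate(divide="ignore"):
            le = le + np.log(prior)
    le = le - logsumexp(le)
    return np.exp(le)


def map_structure(posteriors, structures=None) -> np.ndarray:
    """Most probable structure; ties go to fewer links, then lexicographic."""
    post = np.asarray(posteriors, float)
    if structures is None:
        I = int(round(np.log2(post.size)))
        structures = all_structures(I)
    structures = np.asarray(structures)
    order = np.lexsort(
        (list(map(structure_label, structures)), structures.sum(axis=1), -post)
    )
    return structures[order[0]]


def marginal_link_prob(posteriors, i, structures=None) -> float:
    """Posterior probability that TF i regulates the gene (sum over x_i=1)."""
    post = np.asarray(posteriors, float)
    if structures is None:
        structures = all_structures(int(round(np.log2(post.size))))
    structures = np.asarray(structures)
    if not 0 <= i < structures.shape[1]:
        raise IndexError("TF index out of range")
    return float(post[structures[:, i] == 1].sum())


def pair_marginal(posteriors, i, j, structures=None) -> float:
    post = np.asarray(posteriors, float)
    if structures is None:
        structures = all_structures(int(round(np.log2(post.size))))
    structures = np.asarray(structures)
    I = structures.shape[1]
    if not (0 <= i < I and 0 <= j < I):
        raise IndexError("TF index out of range")
    mask = (structures[:, i] == 1) & (structures[:, j] == 1)
    return float(post[mask].sum())


def restricted_posterior(log_evidences, active_set, structures=None) -> np.ndarray:
    """Posterior over a restricted model set.

    For a single TF {i} the set is {TF-only, null} ("Posterior-2"); for a
    pair {i, j} it is {pair, i alone, j alone, null} ("Posterior-4").  The
    first entry is the probability of the full active-set model.
    """
    active_set = sorted(set(active_set))
    if not active_set:
        raise ValueError("active set must be non-empty")
    le = np.asarray(log_evidences, float)
    if structures is None:
        structures = all_structures(int(round(np.log2(le.size))))
    structures = np.asarray(structures)
    I = structures.shape[1]

    def idx_of(active):
        x = np.zeros(I, dtype=int)
        x[list(active)] = 1
        return int(np.flatnonzero((structures == x).all(axis=1))[0])

    if len(active_set) == 1:
        members = [active_set, []]
    elif len(active_set) == 2:
        i, j = active_set
        members = [[i, j], [i], [j], []]
    else:
        raise ValueError("restricted posteriors support single TFs and pairs")
    sub = le[[idx_of(m) for m in members]]
    return np.exp(sub - logsumexp(sub))


# ---------------------------------------------------------------------------
# evidence approximation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionConfig:
    """Settings of the per-gene evidence approximation."""

    #: TF-activity posterior samples to average over (evenly spaced through
    #: the stored samples); ignored when plug_in is set
    n_activity_samples: int = 10
    #: use the posterior-mean activity instead of averaging over samples
    plug_in: bool = False
    chain_iterations: int = 500
    chain_burn_in: int = 250
    #: independent chains per structure; log-evidences are averaged to tame
    #: ordinate-estimation noise
    n_chains: int = 1
    #: Nelder-Mead iterations (per dimension) of the chain-start mode search
    mode_search_iters: int = 200
    kinetic_prior_sd: float = 1.5
    weight_prior_sd: float = 2.0
    activation_only: bool = False
    #: add a per-gene adaptive noise variance to the likelihood (robust fit)
    use_adaptive: bool = False
    adaptive_prior_mean: float = 0.05


class _KeyContext:
    """Precomputed quadrature and activity pieces for one condition key."""

    def __init__(self, grid, logp_samples, obs_times, obs_values, obs_vars):
        self.grid = grid
        self.logp_samples = logp_samples          # (S_used, I, N)
        self.y = np.asarray(obs_values, float)
        self.var = np.asarray(obs_vars, float)
        t = np.asarray(obs_times, float)
        idx = np.searchsorted(grid, t)
        idx = np.clip(idx, 0, grid.size - 1)
        if not np.allclose(grid[idx], t, atol=1e-9):
            raise ValueError("test-gene observation times must lie on the grid")
        n = grid.size
        h = np.diff(grid)
        left = np.concatenate(([0.0], h / 2.0))
        right = np.concatenate((h / 2.0, [0.0]))
        k = np.arange(n)
        w = np.where(k[None, :] < k[:, None], left + right, 0.0)
        np.fill_diagonal(w, left)
        self.quad_w = w[idx]                                     # (K, N)
        self.lag = np.maximum(grid[idx][:, None] - grid[None, :], 0.0)
        self.neg_lag = -self.lag
        self.t_obs = grid[idx] - grid[0]
        self.neg_t_obs = -self.t_obs
        self.inv_var = 1.0 / self.var
        self.log_var_const = float(-0.5 * np.sum(np.log(_TWO_PI * self.var)))


class _GeneEvidence:
    """Likelihood, prior and chain for one gene x one structure."""

    def __init__(self, contexts, active, config: PredictionConfig):
        self.ctx = contexts
        self.active = np.asarray(active, dtype=int)
        self.cfg = config
        self.k = self.active.size
        # transformed parameter layout:
        #   [log b, log d, log a]                      (null model)
        #   [log b, log d, log a, log s, w0, w_1..w_k] (regulated models)
        self.dim = 3 if self.k == 0 else 5 + self.k
        if config.use_adaptive:
            self.dim += 1
        y0 = np.concatenate([c.y for c in contexts])
        self.init = np.zeros(self.dim)
        self.init[0] = np.log(max(np.median(y0) * 0.5, 1e-2))
        self.init[1] = np.log(0.6)
        self.init[2] = np.log(max(y0[0], 1e-2))
        if self.k:
            self.init[3] = np.log(max(y0.max() - y0.min(), 0.1))
            if config.activation_only:
                self.init[5 : 5 + self.k] = np.log(0.5)
        if config.use_adaptive:
            self.init[-1] = np.log(0.01)
        # prior sds of the coordinates with plain normal priors in phi-space:
        # log-kinetics (log-normal priors) and, unless activation-only,
        # weights/bias (normal priors)
        ks, ws = config.kinetic_prior_sd, config.weight_prior_sd
        sds = [ks, ks, ks]
        if self.k:
            sds += [ks, ws]
            if not config.activation_only:
                sds += [ws] * self.k
        self._norm_n = len(sds)
        self._norm_sd = np.array(sds)
        self._prior_const = float(
            np.sum(-np.log(self._norm_sd) - 0.5 * np.log(_TWO_PI))
        )

    def log_prior(self, phi):
        cfg = self.cfg
        z = phi[: self._norm_n] / self._norm_sd
        lp = self._prior_const - 0.5 * float(z @ z)
        if self.k and cfg.activation_only:
            # half-normal prior on w >= 0 with log-space Jacobian
            ws = cfg.weight_prior_sd
            u = phi[5 : 5 + self.k]
            w = np.exp(u)
            lp += float(
                np.sum(
                    np.log(2.0) - 0.5 * np.log(_TWO_PI) - np.log(ws)
                    - 0.5 * w * w / (ws * ws) + u
                )
            )
        if cfg.use_adaptive:
            av = np.exp(phi[-1])
            lp += -np.log(cfg.adaptive_prior_mean) - av / cfg.adaptive_prior_mean + phi[-1]
        return lp

    def log_lik(self, phi, sample_index):
        cfg = self.cfg
        b, d, a = np.exp(phi[0]), np.exp(phi[1]), np.exp(phi[2])
        if self.k:
            s = np.exp(phi[3])
            w0 = phi[4]
            w = np.exp(phi[5 : 5 + self.k]) if cfg.activation_only else phi[5 : 5 + self.k]
        adaptive = cfg.use_adaptive
        av = np.exp(phi[-1]) if adaptive else 0.0
        ll = 0.0
        for c in self.ctx:
            decay = np.exp(d * c.neg_t_obs)
            m = a * decay + (b / d) * (1.0 - decay)
            if self.k:
                logp = c.logp_samples[sample_index][self.active]
                g = 0.5 * (1.0 + np.tanh(0.5 * (w0 + w @ logp)))
                E = np.exp(d * c.neg_lag) * c.quad_w
                m += s * (E @ g)
            r = c.y - m
            if adaptive:
                var = c.var + av
                ll += -0.5 * float(np.sum(np.log(_TWO_PI * var) + r * r / var))
            else:
                ll += c.log_var_const - 0.5 * float(r @ (r * c.inv_var))
        return ll

    def _posterior_mode(self, sample_index):
        """Cheap mode search used to start the chain in the typical set.

        The mode found for the first activity sample warm-starts the search
        for the others (activity samples differ only slightly).
        """
        from scipy.optimize import minimize

        def negpost(phi):
            return -(self.log_lik(phi, sample_index) + self.log_prior(phi))

        cached = getattr(self, "_mode_cache", None)
        start = self.init if cached is None else cached
        iters = self.cfg.mode_search_iters * self.dim
        if cached is not None:
            iters = max(iters // 4, 10 * self.dim)
        res = minimize(negpost, start, method="Nelder-Mead",
                       options={"maxiter": iters, "xatol": 1e-4, "fatol": 1e-6})
        if np.isfinite(res.fun):
            self._mode_cache = res.x
            return res.x
        return np.array(start, copy=True)

    def chib_evidence(self, sample_index, rng):
        """Chib-style log-evidence for one TF-activity sample.

        Runs an adaptive random-walk Metropolis chain, picks the
        highest-posterior visited point phi*, and applies Chib's identity
        log p(y) = log p(y|phi*) + log p(phi*) - log p(phi*|y) with the
        posterior ordinate estimated from the chain by the Chib-Jeliazkov
        construction for Metropolis kernels.
        """
        cfg = self.cfg
        d = self.dim
        phi = self._posterior_mode(sample_index)
        cur = self.log_lik(phi, sample_index) + self.log_prior(phi)
        n_keep = cfg.chain_iterations
        burn = cfg.chain_burn_in
        half = burn // 2
        # phase 1: isotropic proposals, scale adapted to ~25% acceptance
        scale = 0.15
        warm = np.empty((half, d))
        acc = 0
        for it in range(half):
            prop = phi + scale * rng.standard_normal(d)
            new = self.log_lik(prop, sample_index) + self.log_prior(prop)
            if np.log(rng.random()) < new - cur:
                phi, cur = prop, new
                acc += 1
            if (it + 1) % 25 == 0:
                scale *= np.exp((acc / (it + 1) - 0.25) / np.sqrt(1.0 + it / 25.0))
                scale = float(np.clip(scale, 1e-3, 2.0))
            warm[it] = phi
        # phase 2 onwards: multivariate proposals shaped by the warm-up
        # covariance (adaptive-Metropolis style), frozen before sampling so
        # the kernel in the ordinate estimate matches the chain exactly
        cov = np.atleast_2d(np.cov(warm.T)) + 1e-8 * np.eye(d)
        L = np.linalg.cholesky(cov)
        gscale = 2.38 / np.sqrt(d)
        acc = 0
        for it in range(burn - half):
            prop = phi + gscale * (L @ rng.standard_normal(d))
            new = self.log_lik(prop, sample_index) + self.log_prior(prop)
            if np.log(rng.random()) < new - cur:
                phi, cur = prop, new
                acc += 1
            if (it + 1) % 25 == 0:
                gscale *= np.exp((acc / (it + 1) - 0.25) / np.sqrt(1.0 + it / 25.0))
                gscale = float(np.clip(gscale, 1e-3, 5.0))
        chain = np.empty((n_keep, d))
        chain_lp = np.empty(n_keep)
        for it in range(n_keep):
            prop = phi + gscale * (L @ rng.standard_normal(d))
            new = self.log_lik(prop, sample_index) + self.log_prior(prop)
            if np.log(rng.random()) < new - cur:
                phi, cur = prop, new
            chain[it] = phi
            chain_lp[it] = cur
        best = int(np.argmax(chain_lp))
        phi_star, lp_star = chain[best], chain_lp[best]
        # posterior ordinate at phi* by the Chib-Jeliazkov identity:
        # numerator E_post[alpha(phi -> phi*) q(phi*|phi)], denominator
        # E_{q(.|phi*)}[alpha(phi* -> psi)]
        Ls = gscale * L
        sol = np.linalg.solve(Ls, (chain - phi_star).T)
        log_q = (
            -0.5 * np.sum(sol * sol, axis=0)
            - np.sum(np.log(np.diag(Ls)))
            - 0.5 * d * np.log(_TWO_PI)
        )
        log_num = logsumexp(np.minimum(0.0, lp_star - chain_lp) + log_q) - np.log(n_keep)
        n_den = max(60, n_keep // 4)
        psi = phi_star + rng.standard_normal((n_den, d)) @ Ls.T
        lp_psi = np.array(
            [self.log_lik(p, sample_index) + self.log_prior(p) for p in psi]
        )
        log_den = logsumexp(np.minimum(0.0, lp_psi - lp_star)) - np.log(n_den)
        return lp_star - (log_num - log_den)


class StructureScorer:
    """Scores regulation structures for test genes against a trained posterior."""

    def __init__(self, posterior: TrainingResults, config: PredictionConfig | None = None):
        self.posterior = posterior
        self.config = config or PredictionConfig()
        self.tf_names = posterior.tf_names
        self.I = len(self.tf_names)
        self.structures = all_structures(self.I)
        self._prepare_activity()

    def _prepare_activity(self):
        cfg = self.config
        post = self.posterior
        S = post.n_samples
        if cfg.plug_in:
            self._logp = {
                key: np.log(
                    np.maximum(post.activity_samples[key].mean(axis=0), POSITIVITY_FLOOR)
                )[None]
                for key in post.keys
            }
            self.n_samples_used = 1
        else:
            take = np.unique(np.linspace(0, S - 1, min(cfg.n_activity_samples, S)).astype(int))
            self._logp = {
                key: np.log(np.maximum(post.activity_samples[key][take], POSITIVITY_FLOOR))
                for key in post.keys
            }
            self.n_samples_used = take.size

    def _contexts(self, series):
        ctx = []
        for key, (t, y, v) in series.items():
            if key not in self.posterior.grids:
                raise KeyError(f"series key {key} absent from the training posterior")
            if len(t) < 2:
                raise ValueError("need at least 2 time points to score a gene")
            ctx.append(
                _KeyContext(self.posterior.grids[key], self._logp[key], t, y, v)
            )
        if not ctx:
            raise ValueError("gene has no observations in the trained conditions")
        return ctx

    def score_structure(self, series, x, seed=0) -> float:
        """Log-evidence of one structure for one gene's series dict."""
        ctx = self._contexts(series)
        active = np.flatnonzero(np.asarray(x) == 1)
        ev = _GeneEvidence(ctx, active, self.config)
        rng = np.random.default_rng(seed)
        evs = [self._structure_evidence(ev, s, rng) for s in range(self.n_samples_used)]
        return float(logsumexp(evs) - np.log(self.n_samples_used))

    def _structure_evidence(self, ev, sample_index, rng):
        reps = [
            ev.chib_evidence(sample_index, rng) for _ in range(self.config.n_chains)
        ]
        return float(np.mean(reps))

    def score_gene(self, series, seed=0) -> np.ndarray:
        """Log-evidences of all 2^I structures for one gene."""
        ctx = self._contexts(series)
        rng = np.random.default_rng(seed)
        out = np.empty(len(self.structures))
        for r, x in enumerate(self.structures):
            ev = _GeneEvidence(ctx, np.flatnonzero(x == 1), self.config)
            evs = [self._structure_evidence(ev, s, rng) for s in range(self.n_samples_used)]
            out[r] = logsumexp(evs) - np.log(self.n_samples_used)
        return out

    def score_genes(self, data, genes=None, prior=None, seed=0, n_jobs=1) -> "ModelScoreTable":
        """Score many genes; embarrassingly parallel and order-invariant.

        Each gene's RNG stream is derived from the base seed and a hash of
        the gene id, so results do not depend on gene order or job count.
        """
        genes = list(genes if genes is not None else data.genes)
        series_by_gene = {g: data.series(g) for g in genes}

        def one(gene):
            gene_seed = np.random.SeedSequence(
                [int(seed), zlib.crc32(str(gene).encode())]
            ).generate_state(1)[0]
            return self.score_gene(series_by_gene[gene], seed=gene_seed)

        if n_jobs != 1:
            from joblib import Parallel, delayed

            rows = Parallel(n_jobs=n_jobs)(delayed(one)(g) for g in genes)
        else:
            rows = [one(g) for g in genes]
        return ModelScoreTable.from_log_evidences(
            genes, np.vstack(rows), self.tf_names, prior=prior
        )


# ---------------------------------------------------------------------------
# result table
# ---------------------------------------------------------------------------


class ModelScoreTable:
    """Per-gene structure scores, posteriors, MAP calls and link marginals."""

    def __init__(self, frame: pd.DataFrame, tf_names):
        self.frame = frame
        self.tf_names = list(tf_names)
        self.structures = all_structures(len(self.tf_names))

    @classmethod
    def from_log_evidences(cls, genes, log_ev, tf_names, prior=None):
        tf_names = list(tf_names)
        structures = all_structures(len(tf_names))
        labels = [structure_label(x) for x in structures]
        rows = []
        for g, le in zip(genes, log_ev):
            post = posterior_over_structures(le, prior)
            row = {"gene": g}
            row.update({f"logev_{l}": v for l, v in zip(labels, le)})
            row.update({f"post_{l}": v for l, v in zip(labels, post)})
            xmap = map_structure(post, structures)
            row["map_structure"] = structure_label(xmap)
            row["map_prob"] = float(post[labels.index(structure_label(xmap))])
            for i, tf in enumerate(tf_names):
                row[f"marg_{tf}"] = marginal_link_prob(post, i, structures)
            for i in range(len(tf_names)):
                for j in range(i + 1, len(tf_names)):
                    row[f"pair_{tf_names[i]}+{tf_names[j]}"] = pair_marginal(
                        post, i, j, structures
                    )
            rows.append(row)
        return cls(pd.DataFrame(rows), tf_names)

    @property
    def genes(self):
        return list(self.frame["gene"])

    def posteriors(self, gene) -> np.ndarray:
        row = self.frame.loc[self.frame["gene"] == gene].iloc[0]
        labels = [structure_label(x) for x in self.structures]
        return np.array([row[f"post_{l}"] for l in labels])

    def single_marginals(self) -> pd.DataFrame:
        cols = {tf: self.frame[f"marg_{tf}"].to_numpy() for tf in self.tf_names}
        return pd.DataFrame(cols, index=self.frame["gene"])

    def pair_marginals(self) -> pd.DataFrame:
        cols = {}
        for i in range(len(self.tf_names)):
            for j in range(i + 1, len(self.tf_names)):
                name = f"{self.tf_names[i]}+{self.tf_names[j]}"
                cols[name] = self.frame[f"pair_{name}"].to_numpy()
        return pd.DataFrame(cols, index=self.frame["gene"])

    def ranked_links(self, mode="single") -> pd.DataFrame:
        """All (gene, link) scores sorted decreasing; ties broken by gene id."""
        marg = self.single_marginals() if mode == "single" else self.pair_marginals()
        long = marg.reset_index().melt(
            id_vars="gene", var_name="link", value_name="score"
        )
        return long.sort_values(
            ["score", "gene", "link"], ascending=[False, True, True], kind="mergesort"
        ).reset_index(drop=True)

    def ranked_map(self) -> pd.DataFrame:
        """Genes ranked by the posterior probability of their MAP structure."""
        sub = self.frame[["gene", "map_structure", "map_prob"]].copy()
        return sub.sort_values(
            ["map_prob", "gene"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
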