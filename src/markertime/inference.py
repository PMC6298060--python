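"""Posterior inference: adaptive MCMC, mean-field variational Bayes, summaries.

Two backends produce the same :class:`PosteriorSamples` contract:

* ``fit_mcmc`` — adaptive Metropolis-within-Gibbs on the unconstrained
  parameterization.  Because the likelihood factorizes over cells given the
  gene parameters (and over genes given the pseudotimes), proposals for all
  pseudotimes, and for all per-gene parameter triplets, are made and
  accepted/rejected in parallel, which keeps a pure-numpy sampler fast.
* ``fit_vi`` — stochastic gradient variational inference with a mean-field
  Gaussian family on the unconstrained space, reparameterized gradients from
  the model's analytic gradient, and Adam updates.  Draws returned are
  samples from the fitted approximation.

Both are deterministic given a seed.  Pseudotimes are initialized from the
first principal component of the expression matrix rescaled into (0, 1),
which keeps chains from straddling the two reflection-symmetric posterior
modes (the model is invariant under t -> 1 - t with k -> -k, times -> 1 - time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._engine import ModelEngine
from .model import SWITCH, PriorSettings, resolve_behaviours
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PosteriorSamples",
    "FitSummary",
    "fit_mcmc",
    "fit_vi",
    "summarize_fit",
    "align_direction",
    "fitted_curve",
    "hpd_interval",
]


@dataclass
class PosteriorSamples:
    """Posterior (or variational) draws, grouped by chain.

    Array shapes: ``t`` is (chains, draws, N); ``eta``, ``shape``, ``time``
    are (chains, draws, G); ``beta0``, ``beta1``, ``phi`` are (chains, draws).
    ``shape``/``time`` hold k/t0 for switch genes and b/p for transient ones.
    """

    t: np.ndarray
    eta: np.ndarray
    shape: np.ndarray
    time: np.ndarray
    beta0: np.ndarray
    beta1: np.ndarray
    phi: np.ndarray
    cell_ids: tuple
    gene_ids: tuple
    behaviours: np.ndarray
    seed: int | None = None
    method: str = ""
    config: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.t.ndim != 3:
            raise ValueError("draws must be (chains, draws, N)")
        if self.n_draws < 1:
            raise ValueError("need at least one draw")
        if np.any(self.t < 0) or np.any(self.t >= 1):
            raise ValueError("pseudotime draws must lie in [0, 1)")
        if np.any(self.eta <= 0) or np.any(self.phi < 0):
            raise ValueError("draws violate parameter support")

    @property
    def n_chains(self):
        return self.t.shape[0]

    @property
    def n_draws(self):
        return self.t.shape[1]

    @property
    def n_cells(self):
        return self.t.shape[2]

    @property
    def n_genes(self):
        return self.eta.shape[2]

    def flat(self, name):
        """Draws of one parameter with chains stacked: (chains*draws, ...)."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def pseudotime_mean(self):
        return self.flat("t").mean(axis=0)

    def gene_index(self, gene):
        try:
            return list(self.gene_ids).index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def reflected(self):
        """Mirror the trajectory: t -> 1-t, times -> 1-time, k -> -k."""
        sw = self.behaviours == SWITCH
        shape = self.shape.copy()
        shape[:, :, sw] = -shape[:, :, sw]
        return replace(
            self, t=1.0 - self.t, time=1.0 - self.time, shape=shape,
        )

    def to_arviz(self):
        import arviz as az

        return az.from_dict(posterior=dict(
            t=self.t, eta=self.eta, shape=self.shape, time=self.time,
            beta0=self.beta0, beta1=self.beta1, phi=self.phi,
        ))

    def save(self, path):
        """Write draws + metadata to a compressed archive."""
        import json

        from . import __version__

        meta = dict(
            cell_ids=list(self.cell_ids), gene_ids=list(self.gene_ids),
            behaviours=[str(b) for b in self.behaviours],
            seed=self.seed, method=self.method, config=self.config,
            version=__version__,
        )
        np.savez_compressed(
            path, t=self.t, eta=self.eta, shape=self.shape, time=self.time,
            beta0=self.beta0, beta1=self.beta1, phi=self.phi,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path):
        import json

        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            return cls(
                t=z["t"], eta=z["eta"], shape=z["shape"], time=z["time"],
                beta0=z["beta0"], beta1=z["beta1"], phi=z["phi"],
                cell_ids=tuple(meta["cell_ids"]),
                gene_ids=tuple(meta["gene_ids"]),
                behaviours=np.array(meta["behaviours"], dtype=object),
                seed=meta.get("seed"), method=meta.get("method", ""),
                config=meta.get("config", {}),
            )


@dataclass
class FitSummary:
    """Point estimates, credible intervals and convergence diagnostics."""

    pseudotime: pd.DataFrame   # cell_id, mean, lower, upper
    parameters: pd.DataFrame   # parameter, gene_id, mean, lower, upper, rhat, ess
    level: float = 0.95


# ---------------------------------------------------------------------------
# shared setup

def _as_matrix(Y):
    if isinstance(Y, ExpressionMatrix):
        return Y.values, Y.cell_ids, Y.gene_ids
    Y = np.asarray(Y, float)
    n, g = Y.shape
    return (
        Y,
        tuple(f"cell_{i}" for i in range(n)),
        tuple(f"gene_{j}" for j in range(g)),
    )


def _pca_pseudotime_init(values):
    """First principal component rescaled into [0.05, 0.95]."""
    X = values - values.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    pc1 = X @ vt[0]
    lo, hi = pc1.min(), pc1.max()
    if hi - lo < 1e-12:
        return np.full(len(pc1), 0.5)
    return 0.05 + 0.9 * (pc1 - lo) / (hi - lo)


def _initial_vector(engine, values, priors):
    t0 = _pca_pseudotime_init(values)
    G = engine.G
    eta = np.ones(G)          # half-peak is ~1 after size-factor normalization
    shape = np.where(engine.sw, 0.0, engine.shape_loc)
    time = np.full(G, 0.5)
    return engine.pack(t0, eta, shape, time, 0.0, 0.0, 1.0)


def _package_draws(engine, draws_by_chain, cell_ids, gene_ids, seed, method,
                   config, diagnostics):
    """Stack per-chain (S, D) unconstrained draws into PosteriorSamples."""
    fields = dict(t=[], eta=[], shape=[], time=[], beta0=[], beta1=[], phi=[])
    for Z in draws_by_chain:
        c = engine.unpack_batch(Z)
        for k in fields:
            fields[k].append(c[k])
    return PosteriorSamples(
        **{k: np.stack(v) for k, v in fields.items()},
        cell_ids=tuple(cell_ids), gene_ids=tuple(gene_ids),
        behaviours=engine.behaviours.copy(),
        seed=seed, method=method, config=config, diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# MCMC backend

def fit_mcmc(Y, behaviours, priors=None, *, chains=2, warmup=1000, iters=1000,
             seed=0, prior_only=False, thin=1, init="pca"):
    """Adaptive Metropolis-within-Gibbs sampling of the joint posterior.

    Per iteration, three blocks are updated: all pseudotimes (independent
    per-cell accept/reject), all per-gene parameter triplets (independent
    per-gene accept/reject), and the shared noise parameters.  Proposal
    scales adapt during warmup toward standard acceptance targets.

    Set ``prior_only=True`` to sample from the prior alone (used to validate
    the sampler against known prior moments).  ``init`` is either ``"pca"``
    (pseudotimes from the first principal component) or an unconstrained
    parameter vector, e.g. the variational mean from a :func:`fit_vi` run
    (``fit.diagnostics["q_mean"]``) for a warm start; chains beyond the
    first are jittered around it.
    """
    if iters < 1:
        raise ValueError("need at least one post-warmup iteration")
    values, cell_ids, gene_ids = _as_matrix(Y)
    priors = priors or PriorSettings()
    engine = ModelEngine(values, gene_ids, behaviours, priors)
    rng = np.random.default_rng(seed)
    N, G = engine.N, engine.G
    like = not prior_only

    def loglik_cells(c):
        if not like:
            return np.zeros(N)
        return engine.loglik_matrix(c).sum(axis=1)

    if isinstance(init, str):
        if init != "pca":
            raise ValueError(f"unknown init {init!r}")
        z_init = _initial_vector(engine, values, priors)
    else:
        z_init = np.asarray(init, float)
        if z_init.shape != (engine.D,):
            raise ValueError(
                f"init vector has shape {z_init.shape}, expected ({engine.D},)"
            )

    draws_by_chain, accept_stats = [], []
    for chain in range(chains):
        z = z_init.copy()
        if chain > 0:
            z = z + 0.1 * rng.standard_normal(z.shape)
        c = engine.unpack(z)
        L = engine.loglik_matrix(c) if like else np.zeros((N, G))
        per_cell, per_gene, lp_noise = engine.prior_terms(c)
        scale_t = np.full(N, 0.5)
        scale_g = np.full(G, 0.2)
        scale_n = 0.1
        acc_t = acc_g = acc_n = 0.0
        kept = []
        total = warmup + iters * thin
        # adaptive per-gene 3x3 (and noise 3x3) proposal covariance, learned
        # from warmup history: (eta, shape, time) are strongly correlated a
        # posteriori and isotropic proposals mix poorly
        cov_start = min(300, warmup // 2)
        mean_g = np.zeros((G, 3)); M2_g = np.zeros((G, 3, 3)); n_hist = 0
        mean_n = np.zeros(3); M2_n = np.zeros((3, 3))
        chol_g = np.tile(np.eye(3), (G, 1, 1))
        chol_n = np.eye(3)
        for it in range(total):
            # --- pseudotime block: parallel per-cell Metropolis
            u = z[:N]
            u_prop = u + scale_t * rng.standard_normal(N)
            z_prop = z.copy()
            z_prop[:N] = u_prop
            c_prop = engine.unpack(z_prop)
            L_prop = engine.loglik_matrix(c_prop) if like else L
            pc_prop = engine.prior_terms(c_prop)[0]
            logr = (pc_prop + L_prop.sum(axis=1)) - (per_cell + L.sum(axis=1))
            acc = np.log(rng.random(N)) < logr
            z[:N] = np.where(acc, u_prop, u)
            c = engine.unpack(z)
            L[acc] = L_prop[acc]
            per_cell = np.where(acc, pc_prop, per_cell)

            # --- gene block: parallel per-gene Metropolis on (eta, shape, time)
            zg = z[N:N + 3 * G].reshape(3, G)
            step = np.einsum("gij,gj->ig", chol_g, rng.standard_normal((G, 3)))
            zg_prop = zg + scale_g * step
            z_prop = z.copy()
            z_prop[N:N + 3 * G] = zg_prop.ravel()
            c_prop = engine.unpack(z_prop)
            L_prop = engine.loglik_matrix(c_prop) if like else L
            pg_prop = engine.prior_terms(c_prop)[1]
            logr = (pg_prop + L_prop.sum(axis=0)) - (per_gene + L.sum(axis=0))
            accg = np.log(rng.random(G)) < logr
            zg_new = np.where(accg, zg_prop, zg)
            z[N:N + 3 * G] = zg_new.ravel()
            c = engine.unpack(z)
            L[:, accg] = L_prop[:, accg]
            per_gene = np.where(accg, pg_prop, per_gene)

            # --- noise block: joint Metropolis on (beta0, beta1, log phi)
            z_prop = z.copy()
            z_prop[-3:] = z[-3:] + scale_n * (chol_n @ rng.standard_normal(3))
            c_prop = engine.unpack(z_prop)
            L_prop = engine.loglik_matrix(c_prop) if like else L
            ln_prop = engine.prior_terms(c_prop)[2]
            logr = (ln_prop + L_prop.sum()) - (lp_noise + L.sum())
            accn = np.log(rng.random()) < logr
            if accn:
                z = z_prop
                c = c_prop
                L = L_prop
                lp_noise = ln_prop

            if it < warmup:
                # Robbins-Monro adaptation toward target acceptance rates
                gam = (it + 1) ** -0.6
                scale_t *= np.exp(gam * (acc.astype(float) - 0.44))
                scale_g *= np.exp(gam * (accg.astype(float) - 0.3))
                scale_n *= np.exp(gam * (float(accn) - 0.3))
                # running covariance of the gene / noise blocks (Welford)
                n_hist += 1
                cur_g = z[N:N + 3 * G].reshape(3, G).T          # (G, 3)
                d1 = cur_g - mean_g
                mean_g += d1 / n_hist
                M2_g += np.einsum("gi,gj->gij", d1, cur_g - mean_g)
                d1n = z[-3:] - mean_n
                mean_n += d1n / n_hist
                M2_n += np.outer(d1n, z[-3:] - mean_n)
                if it >= cov_start and (it + 1) % 50 == 0 and n_hist > 10:
                    cov = M2_g / (n_hist - 1) + 1e-6 * np.eye(3)
                    chol_new = np.linalg.cholesky(cov)
                    # normalize so scale_g keeps its meaning across updates
                    norm = np.cbrt(np.abs(np.linalg.det(chol_new)))
                    chol_g = chol_new / norm[:, None, None]
                    covn = M2_n / (n_hist - 1) + 1e-6 * np.eye(3)
                    chol_n = np.linalg.cholesky(covn)
                    chol_n = chol_n / np.cbrt(abs(np.linalg.det(chol_n)))
            else:
                acc_t += acc.mean()
                acc_g += accg.mean()
                acc_n += float(accn)
                if (it - warmup) % thin == 0:
                    kept.append(z.copy())
        draws_by_chain.append(np.array(kept))
        denom = max(iters * thin, 1)
        accept_stats.append(dict(
            t=acc_t / denom, genes=acc_g / denom, noise=acc_n / denom,
        ))
    config = dict(chains=chains, warmup=warmup, iters=iters, seed=seed,
                  prior_only=prior_only, thin=thin)
    samples = _package_draws(
        engine, draws_by_chain, cell_ids, gene_ids, seed, "mcmc", config,
        dict(acceptance=accept_stats),
    )
    if like and chains > 1:
        samples = _align_chains(samples)
    return samples


def _align_chains(samples: PosteriorSamples) -> PosteriorSamples:
    """Reflect chains that sit in the mirrored posterior mode.

    The posterior is exactly symmetric under t -> 1 - t (with the induced
    gene-parameter changes), so chains may individually land in either mode;
    pooling them unaligned would average the two mirror images away.  Each
    chain whose mean pseudotime profile anti-correlates with chain 0's is
    reflected — a relabeling that leaves every draw's posterior density
    unchanged.
    """
    ref = samples.t[0].mean(axis=0)
    flip = np.zeros(samples.n_chains, dtype=bool)
    for c in range(1, samples.n_chains):
        r = np.corrcoef(ref, samples.t[c].mean(axis=0))[0, 1]
        flip[c] = np.isfinite(r) and r < 0
    if not flip.any():
        return samples
    mirrored = samples.reflected()
    pick = lambda a, b: np.where(flip[:, None, None] if a.ndim == 3 else  # noqa: E731
                                 flip[:, None], b, a)
    return replace(
        samples,
        t=pick(samples.t, mirrored.t),
        time=pick(samples.time, mirrored.time),
        shape=pick(samples.shape, mirrored.shape),
    )


# ---------------------------------------------------------------------------
# VI backend

def fit_vi(Y, behaviours, priors=None, *, steps=3000, lr=0.01, mc_samples=1,
           n_draws=1000, seed=0, monitor_window=25):
    """Stochastic gradient variational inference (mean-field Gaussian).

    Maximizes the ELBO with reparameterized gradients and Adam; the fitted
    approximation is then sampled ``n_draws`` times to produce draws under
    the same contract as :func:`fit_mcmc` (one "chain").

    Raises ``RuntimeError`` if the ELBO estimate is non-finite for a full
    monitoring window of consecutive steps.
    """
    if steps < 1:
        raise ValueError("need at least one optimization step")
    values, cell_ids, gene_ids = _as_matrix(Y)
    priors = priors or PriorSettings()
    engine = ModelEngine(values, gene_ids, behaviours, priors)
    rng = np.random.default_rng(seed)
    D = engine.D

    m = _initial_vector(engine, values, priors)
    log_s = np.full(D, -2.0)
    # Adam state
    mom_m = np.zeros(D); vel_m = np.zeros(D)
    mom_s = np.zeros(D); vel_s = np.zeros(D)
    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    elbo_trace = np.empty(steps)
    bad_run = 0
    half_log_2pie = 0.5 * (1.0 + np.log(2.0 * np.pi))
    for step in range(steps):
        s = np.exp(log_s)
        g_m = np.zeros(D)
        g_ls = np.zeros(D)
        val_acc = 0.0
        ok = True
        for _ in range(mc_samples):
            xi = rng.standard_normal(D)
            zdraw = m + s * xi
            val, grad = engine.log_density_and_grad(zdraw)
            if not (np.isfinite(val) and np.all(np.isfinite(grad))):
                ok = False
                break
            g_m += grad
            g_ls += grad * s * xi
            val_acc += val
        entropy = D * half_log_2pie + log_s.sum()
        if ok:
            elbo = val_acc / mc_samples + entropy
            g_m /= mc_samples
            g_ls = g_ls / mc_samples + 1.0  # entropy gradient wrt log s
            bad_run = 0
        else:
            elbo = -np.inf
            bad_run += 1
            if bad_run >= monitor_window:
                raise RuntimeError(
                    f"ELBO non-finite for {monitor_window} consecutive steps; "
                    "check input scaling and priors"
                )
            elbo_trace[step] = elbo
            continue
        elbo_trace[step] = elbo
        # Adam ascent
        tstep = step + 1
        mom_m = b1 * mom_m + (1 - b1) * g_m
        vel_m = b2 * vel_m + (1 - b2) * g_m ** 2
        m = m + lr * (mom_m / (1 - b1 ** tstep)) / (
            np.sqrt(vel_m / (1 - b2 ** tstep)) + adam_eps
        )
        mom_s = b1 * mom_s + (1 - b1) * g_ls
        vel_s = b2 * vel_s + (1 - b2) * g_ls ** 2
        log_s = log_s + lr * (mom_s / (1 - b1 ** tstep)) / (
            np.sqrt(vel_s / (1 - b2 ** tstep)) + adam_eps
        )

    Z = m + np.exp(log_s) * rng.standard_normal((n_draws, D))
    config = dict(steps=steps, lr=lr, mc_samples=mc_samples,
                  n_draws=n_draws, seed=seed)
    samples = _package_draws(
        engine, [Z], cell_ids, gene_ids, seed, "vi", config,
        dict(elbo_trace=elbo_trace, q_mean=m, q_log_sd=log_s),
    )
    return samples


# ---------------------------------------------------------------------------
# summaries

def hpd_interval(draws, level=0.95):
    """Highest-posterior-density interval of a 1-D sample (shortest interval)."""
    x = np.sort(np.asarray(draws, float).ravel())
    n = len(x)
    if n == 1:
        return x[0], x[0]
    m = max(1, int(np.ceil(level * n)))
    if m >= n:
        return x[0], x[-1]
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return x[i], x[i + m]


def _interval(draws, level, kind):
    if kind == "hpd":
        return hpd_interval(draws, level)
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(draws, lo)), float(np.quantile(draws, 1.0 - lo)))


def summarize_fit(samples: PosteriorSamples, level=0.95, interval="hpd") -> FitSummary:
    """Posterior means, credible intervals, and R-hat / ESS diagnostics.

    Intervals are highest-posterior-density by default (equal-tailed via
    ``interval="central"``); R-hat and effective sample size are reported
    when at least two chains are available.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("credible level must lie in (0, 1)")
    if samples.n_draws < 2:
        raise ValueError("need at least 2 draws for intervals")
    import arviz as az

    t_flat = samples.flat("t")
    rows = []
    for i, cid in enumerate(samples.cell_ids):
        lo, hi = _interval(t_flat[:, i], level, interval)
        rows.append(dict(cell_id=cid, mean=t_flat[:, i].mean(), lower=lo, upper=hi))
    pseudotime = pd.DataFrame(rows)

    multi = samples.n_chains >= 2
    prows = []

    def add_param(name, arr, gene_id=None):
        flat = arr.reshape(-1)
        lo, hi = _interval(flat, level, interval)
        rhat = ess = np.nan
        if multi:
            rhat = float(az.rhat(arr))
            ess = float(az.ess(arr))
        prows.append(dict(parameter=name, gene_id=gene_id, mean=flat.mean(),
                          lower=lo, upper=hi, rhat=rhat, ess=ess))

    sw = samples.behaviours == SWITCH
    for j, gid in enumerate(samples.gene_ids):
        add_param("eta", samples.eta[:, :, j], gid)
        add_param("k" if sw[j] else "b", samples.shape[:, :, j], gid)
        add_param("t0" if sw[j] else "p", samples.time[:, :, j], gid)
    for name in ("beta0", "beta1", "phi"):
        add_param(name, getattr(samples, name))
    return FitSummary(pseudotime=pseudotime, parameters=pd.DataFrame(prows),
                      level=level)


def align_direction(samples: PosteriorSamples, anchor="none", priors=None):
    """Resolve the trajectory-direction non-identifiability.

    The posterior is invariant under the reflection t -> 1 - t (with
    k -> -k and switch/peak times mirrored), so the direction must be fixed
    by convention.  ``anchor`` is one of:

    * ``"none"`` — return the samples unchanged;
    * ``"prior_switch_times"`` — reflect if the posterior-mean regulation
      times are anti-correlated with the prior time locations (requires
      informative, non-constant prior locations);
    * ``"reference_cell:<id>"`` — reflect if the named cell (expected at the
      start of the trajectory) has posterior-mean pseudotime above 0.5.
    """
    if anchor == "none":
        return samples
    if anchor == "prior_switch_times":
        priors = priors or PriorSettings()
        _, _, time_loc, _, _ = priors.resolved(samples.gene_ids, samples.behaviours)
        post_mean = samples.flat("time").mean(axis=0)
        if np.std(time_loc) < 1e-12:
            logger.warning(
                "prior switch-time locations are constant; direction left unchanged"
            )
            return samples
        r = np.corrcoef(time_loc, post_mean)[0, 1]
        return samples.reflected() if r < 0 else samples
    if anchor.startswith("reference_cell:"):
        cid = anchor.split(":", 1)[1]
        try:
            i = list(samples.cell_ids).index(cid)
        except ValueError:
            raise ValueError(f"unknown reference cell {cid!r}") from None
        return samples.reflected() if samples.pseudotime_mean[i] > 0.5 else samples
    raise ValueError(f"unknown anchor {anchor!r}")


def fitted_curve(samples: PosteriorSamples, gene, grid, level=0.95,
                 interval="hpd"):
    """Posterior mean and credible band of a gene's mean function on a grid."""
    from .model import sigmoid_mean, transient_mean

    grid = np.asarray(grid, float)
    if np.any(grid < 0) or np.any(grid >= 1):
        raise ValueError("grid values must lie in [0, 1)")
    j = samples.gene_index(gene)
    eta = samples.flat("eta")[:, j][:, None]
    shape = samples.flat("shape")[:, j][:, None]
    time = samples.flat("time")[:, j][:, None]
    if samples.behaviours[j] == SWITCH:
        curves = sigmoid_mean(grid[None, :], eta, shape, time)
    else:
        curves = transient_mean(grid[None, :], eta, shape, time)
    lo = np.empty(len(grid)); hi = np.empty(len(grid))
    for i in range(len(grid)):
        lo[i], hi[i] = _interval(curves[:, i], level, interval)
    return pd.DataFrame(dict(t=grid, mean=curves.mean(axis=0), lower=lo, upper=hi))
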