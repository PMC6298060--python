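"""Generative model: mean functions, dropout, noise model, priors.

Each gene g is declared a priori as *switch-like* or *transient* and its
mean expression along pseudotime t in [0, 1) is

    switch:    mu(t) = 2 * eta_g / (1 + exp(-k_g * (t - t0_g)))
    transient: mu(t) = 2 * eta_g * exp(-lam * b_g * (t - p_g)**2),  lam = 10

so eta_g is the half-peak expression (exactly mu(t0) for switch genes and
half the peak mu(p) for transient ones), k_g the activation strength and
direction, t0_g the switch time, p_g the peak time and b_g the bandwidth.

Observations follow a zero-inflated, dispersed Student-t model: with
pi_ng = logit^-1(beta0 + beta1 * mu_ng) the dropout probability,

    p(y | pi, mu, sigma2) = pi * delta_0(y) + (1 - pi) * T_nu(y | mu, sigma2)

where T_nu is a location-scale Student-t (sigma2 is the squared scale, not
the variance) and sigma2 = (1 + phi) * mu + eps with dispersion phi and a
small variance floor eps = 0.01.  The Bernoulli dropout indicator is
marginalized analytically, which keeps the target differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, gammaln
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm, truncnorm

__all__ = [
    "LAMBDA_TRANSIENT",
    "SigmoidGeneParams",
    "TransientGeneParams",
    "NoiseParams",
    "PriorSettings",
    "ModelParameters",
    "resolve_behaviours",
    "sigmoid_mean",
    "transient_mean",
    "dropout_probability",
    "observation_variance",
    "log_obs_density",
    "log_prior",
    "log_joint",
]

#: fixed transient-bandwidth scale constant
LAMBDA_TRANSIENT = 10.0

SWITCH = "switch"
TRANSIENT = "transient"


def resolve_behaviours(gene_ids, behaviours) -> np.ndarray:
    """Return an array of per-gene behaviour strings aligned with gene_ids.

    ``behaviours`` may be a mapping gene -> behaviour or a sequence in gene
    order.  Every gene must be assigned exactly one of {"switch", "transient"}.
    """
    gene_ids = list(gene_ids)
    if isinstance(behaviours, dict):
        missing = [g for g in gene_ids if g not in behaviours]
        if missing:
            raise ValueError(f"no behaviour declared for gene(s): {missing}")
        beh = [behaviours[g] for g in gene_ids]
    else:
        beh = list(behaviours)
        if len(beh) != len(gene_ids):
            raise ValueError(
                f"{len(beh)} behaviours for {len(gene_ids)} genes"
            )
    beh = np.array([str(b).lower() for b in beh], dtype=object)
    bad = set(beh) - {SWITCH, TRANSIENT}
    if bad:
        raise ValueError(
            f"unknown behaviour(s) {sorted(bad)}; expected 'switch' or 'transient'"
        )
    return beh


# ---------------------------------------------------------------------------
# parameter containers

@dataclass(frozen=True)
class SigmoidGeneParams:
    """Switch-like gene: half-peak eta > 0, strength k, switch time t0 in [0,1)."""

    eta: float
    k: float
    t0: float

    def mean(self, t):
        return sigmoid_mean(t, self.eta, self.k, self.t0)


@dataclass(frozen=True)
class TransientGeneParams:
    """Transient gene: half-peak eta > 0, bandwidth b >= 0, peak time p in [0,1)."""

    eta: float
    b: float
    p: float
    lam: float = LAMBDA_TRANSIENT

    def mean(self, t):
        return transient_mean(t, self.eta, self.b, self.p, self.lam)


@dataclass(frozen=True)
class NoiseParams:
    """Dropout regression coefficients, dispersion and Student-t constants."""

    beta0: float
    beta1: float
    phi: float
    eps: float = 0.01
    nu: float = 10.0


@dataclass(frozen=True)
class PriorSettings:
    """Hyperparameters of the hierarchical prior.

    Precisions parameterize Normal/TruncNorm widths as variance = 1/tau.
    Defaults are weakly informative on the scale induced by the half-peak-1
    normalization.  Per-gene overrides (keyed by gene id) may set any of
    mu_k, tau_k, mu_t, tau_t, mu_p, tau_p, mu_b, tau_b.
    """

    delta: float = 2.0          # eta ~ Gamma(delta/2, rate 1/2)
    mu_k: float = 0.0           # switch strength prior location
    # On the half-peak-1 scale a gene switching over a fifth of the
    # trajectory has |k| ~ 20, so a weak strength prior needs sd ~ 10.
    tau_k: float = 0.01         # switch strength prior precision
    mu_t: float = 0.5           # switch time prior location
    tau_t: float = 1.0
    mu_p: float = 0.5           # peak time prior location
    tau_p: float = 1.0
    mu_b: float = 5.0           # bandwidth prior location, TruncNorm[0, inf)
    tau_b: float = 0.04         # bandwidth prior precision (variance 25)
    alpha_phi: float = 2.0      # dispersion phi ~ Gamma(alpha_phi, beta_phi)
    beta_phi: float = 2.0
    beta_var: float = 0.1       # beta0, beta1 ~ Normal(0, beta_var) [variance]
    t_loc: float = 0.5          # pseudotime prior TruncNorm[0,1)(t_loc, t_var)
    t_var: float = 1.0
    nu: float = 10.0            # Student-t degrees of freedom (fixed)
    eps: float = 0.01           # variance floor (fixed)
    gamma_rate_parameterization: bool = True  # Gamma(shape, rate) convention
    per_gene: dict = field(default_factory=dict)

    def _gene(self, gene_id, key, default):
        return self.per_gene.get(gene_id, {}).get(key, default)

    def resolved(self, gene_ids, behaviours):
        """Per-gene prior location/precision arrays for the shape and time params.

        For switch genes the "shape" parameter is k and the "time" parameter
        is t0; for transient genes they are b and p respectively.
        """
        behaviours = resolve_behaviours(gene_ids, behaviours)
        shape_loc, shape_prec, time_loc, time_prec = [], [], [], []
        for gid, beh in zip(gene_ids, behaviours):
            if beh == SWITCH:
                shape_loc.append(self._gene(gid, "mu_k", self.mu_k))
                shape_prec.append(self._gene(gid, "tau_k", self.tau_k))
                time_loc.append(self._gene(gid, "mu_t", self.mu_t))
                time_prec.append(self._gene(gid, "tau_t", self.tau_t))
            else:
                shape_loc.append(self._gene(gid, "mu_b", self.mu_b))
                shape_prec.append(self._gene(gid, "tau_b", self.tau_b))
                time_loc.append(self._gene(gid, "mu_p", self.mu_p))
                time_prec.append(self._gene(gid, "tau_p", self.tau_p))
        return (
            np.asarray(shape_loc, float),
            np.asarray(shape_prec, float),
            np.asarray(time_loc, float),
            np.asarray(time_prec, float),
            behaviours,
        )


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter state: pseudotimes plus per-gene and noise parameters.

    ``shape`` holds k for switch genes and b for transient genes; ``time``
    holds t0 for switch genes and p for transient genes, aligned with the
    behaviour declaration the model is evaluated under.
    """

    t: np.ndarray        # (N,) pseudotimes in [0, 1)
    eta: np.ndarray      # (G,) half-peak expression > 0
    shape: np.ndarray    # (G,) k (switch) or b (transient)
    time: np.ndarray     # (G,) t0 (switch) or p (transient), in [0, 1)
    noise: NoiseParams

    def replace(self, **kw):
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# mean functions and noise model

def sigmoid_mean(t, eta, k, t0):
    """Sigmoidal mean 2*eta / (1 + exp(-k*(t - t0))); equals eta at t = t0."""
    t = np.asarray(t, dtype=float)
    return 2.0 * np.asarray(eta) * expit(np.asarray(k) * (t - np.asarray(t0)))


def transient_mean(t, eta, b, p, lam=LAMBDA_TRANSIENT):
    """Gaussian-shaped mean 2*eta*exp(-lam*b*(t - p)^2); peaks at 2*eta at t = p."""
    t = np.asarray(t, dtype=float)
    return 2.0 * np.asarray(eta) * np.exp(-lam * np.asarray(b) * (t - np.asarray(p)) ** 2)


def dropout_probability(mu, beta0, beta1):
    """Dropout probability logit^-1(beta0 + beta1 * mu)."""
    return expit(beta0 + beta1 * np.asarray(mu, dtype=float))


def observation_variance(mu, phi, eps=0.01):
    """Mean-variance relation sigma2 = (1 + phi) * mu + eps."""
    return (1.0 + phi) * np.asarray(mu, dtype=float) + eps


def _t_logpdf(y, mu, sigma2, nu):
    """Location-scale Student-t log density with squared scale sigma2."""
    z2 = (y - mu) ** 2 / sigma2
    return (
        gammaln((nu + 1.0) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * np.log(np.pi * nu * sigma2)
        - (nu + 1.0) / 2.0 * np.log1p(z2 / nu)
    )


def log_obs_density(y, mu, pi, sigma2, nu):
    """Zero-inflated Student-t log density, vectorized.

    Exact zeros are scored as log(pi + (1 - pi) * T_nu(0 | mu, sigma2)) —
    the point mass plus the continuous component's density at zero —
    and positives as log(1 - pi) + log T_nu(y | mu, sigma2).
    """
    y = np.asarray(y, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("dropout probability must lie in [0, 1]")
    mu, sigma2 = np.broadcast_arrays(
        np.asarray(mu, float), np.asarray(sigma2, float)
    )[0], np.asarray(sigma2, float)
    logt = _t_logpdf(y, mu, sigma2, nu)
    with np.errstate(divide="ignore"):
        zero_branch = np.log(pi + (1.0 - pi) * np.exp(_t_logpdf(0.0, mu, sigma2, nu)))
        pos_branch = np.log1p(-pi) + logt
    return np.where(y == 0.0, zero_branch, pos_branch)


# ---------------------------------------------------------------------------
# priors and joint density

def _log_truncnorm(x, loc, var, lower, upper):
    sd = np.sqrt(var)
    a, b = (lower - loc) / sd, (upper - loc) / sd
    return truncnorm.logpdf(x, a, b, loc=loc, scale=sd)


def log_prior(params: ModelParameters, priors: PriorSettings, gene_ids, behaviours):
    """Sum of all prior log densities, including truncation normalizers.

    Returns -inf (never raises) when any parameter lies outside its support.
    """
    shape_loc, shape_prec, time_loc, time_prec, beh = priors.resolved(
        gene_ids, behaviours
    )
    t = np.asarray(params.t, float)
    eta = np.asarray(params.eta, float)
    shape = np.asarray(params.shape, float)
    time = np.asarray(params.time, float)
    sw = beh == SWITCH

    if (
        np.any(t < 0) or np.any(t >= 1)
        or np.any(eta <= 0)
        or np.any(time < 0) or np.any(time >= 1)
        or np.any(shape[~sw] < 0)
        or params.noise.phi < 0
    ):
        return -np.inf

    lp = 0.0
    # pseudotimes ~ TruncNorm[0,1)
    lp += _log_truncnorm(t, priors.t_loc, priors.t_var, 0.0, 1.0).sum()
    # eta ~ Gamma(delta/2, rate 1/2)
    if priors.gamma_rate_parameterization:
        lp += gamma_dist.logpdf(eta, priors.delta / 2.0, scale=2.0).sum()
    else:
        lp += gamma_dist.logpdf(eta, priors.delta / 2.0, scale=0.5).sum()
    # switch: k ~ Normal(mu_k, 1/tau_k); time t0 ~ TruncNorm[0,1)
    if np.any(sw):
        lp += norm.logpdf(
            shape[sw], loc=shape_loc[sw], scale=np.sqrt(1.0 / shape_prec[sw])
        ).sum()
    # transient: b ~ TruncNorm[0,inf)
    if np.any(~sw):
        lp += _log_truncnorm(
            shape[~sw], shape_loc[~sw], 1.0 / shape_prec[~sw], 0.0, np.inf
        ).sum()
    # switch/peak times ~ TruncNorm[0,1)
    lp += _log_truncnorm(time, time_loc, 1.0 / time_prec, 0.0, 1.0).sum()
    # dropout coefficients and dispersion
    sd_b = np.sqrt(priors.beta_var)
    lp += norm.logpdf(params.noise.beta0, scale=sd_b)
    lp += norm.logpdf(params.noise.beta1, scale=sd_b)
    lp += gamma_dist.logpdf(
        params.noise.phi, priors.alpha_phi, scale=1.0 / priors.beta_phi
    )
    return float(lp)


def mean_matrix(t, eta, shape, time, behaviours):
    """(N, G) mean expression for every cell and gene."""
    beh = np.asarray(behaviours, dtype=object)
    sw = beh == SWITCH
    t = np.asarray(t, float)[:, None]
    mu = np.empty((t.shape[0], len(eta)))
    if np.any(sw):
        mu[:, sw] = sigmoid_mean(t, eta[sw], shape[sw], time[sw])
    if np.any(~sw):
        mu[:, ~sw] = transient_mean(t, eta[~sw], shape[~sw], time[~sw])
    return mu


def log_joint(Y, params: ModelParameters, priors: PriorSettings, gene_ids,
              behaviours):
    """Log of prior times likelihood: the (unnormalized) posterior density.

    ``Y`` is the normalized (N, G) expression matrix or an ExpressionMatrix.
    """
    values = getattr(Y, "values", Y)
    values = np.asarray(values, float)
    n, g = values.shape
    if params.t.shape != (n,) or params.eta.shape != (g,):
        raise ValueError(
            f"shape mismatch: data is {n}x{g} but parameters are for "
            f"{params.t.shape[0]} cells and {params.eta.shape[0]} genes"
        )
    lp = log_prior(params, priors, gene_ids, behaviours)
    if not np.isfinite(lp):
        return -np.inf
    beh = resolve_behaviours(gene_ids, behaviours)
    mu = mean_matrix(params.t, params.eta, params.shape, params.time, beh)
    pi = dropout_probability(mu, params.noise.beta0, params.noise.beta1)
    sigma2 = observation_variance(mu, params.noise.phi, params.noise.eps)
    ll = log_obs_density(values, mu, pi, sigma2, params.noise.nu)
    return float(lp + ll.sum())
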