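"""Bayesian estimation of the TIHLBW parameters.

Independent gamma priors on each of (lam, alpha, beta, delta), a
Metropolis-within-Gibbs sampler (component-wise Gaussian random walk on
log-parameters, proposal scales adapted toward ~0.3 acceptance during burn-in
and frozen afterwards so the retained chain satisfies detailed balance), the
posterior-mean point estimate that is Bayes under squared error loss (SELF),
and the Heidelberger-Welch stationarity/half-width diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_toeplitz

from .family import ModelParams, tihlbw_params
from .mle import fit_mle, loglik

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorSample",
    "HWResult",
    "log_prior",
    "log_posterior",
    "elicit_priors",
    "sample_posterior",
    "hw_diagnostic",
]

_PARAM_LABELS = ("lambda", "alpha", "beta", "delta")


@dataclass(frozen=True)
class PriorSpec:
    """Independent gamma priors: rate a_i, shape b_i, prior mean b_i / a_i."""

    a: tuple
    b: tuple

    def __post_init__(self):
        a = tuple(float(v) for v in self.a)
        b = tuple(float(v) for v in self.b)
        if len(a) != 4 or len(b) != 4:
            raise ValueError("PriorSpec takes 4 rates and 4 shapes")
        if not all(v > 0 for v in a + b):
            raise ValueError("all hyperparameters must be positive")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def mean(self) -> np.ndarray:
        return np.array(self.b) / np.array(self.a)

    @property
    def variance(self) -> np.ndarray:
        return np.array(self.b) / np.array(self.a) ** 2


@dataclass(frozen=True)
class McmcConfig:
    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 1
    proposal_sd: tuple = (0.3, 0.3, 0.3, 0.3)
    seed: int = 0
    n_chains: int = 1
    adapt_interval: int = 100
    target_accept: float = 0.3

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if len(self.proposal_sd) != 4 or any(s <= 0 for s in self.proposal_sd):
            raise ValueError("proposal_sd must be 4 positive scales")


@dataclass
class PosteriorSample:
    draws: np.ndarray  # (n_retained, 4), strictly positive
    acceptance_rate: np.ndarray  # per parameter, post burn-in
    self_estimate: np.ndarray  # posterior means (SELF point estimates)
    posterior_sd: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    chains: list = field(default_factory=list)  # per-chain draw arrays

    @property
    def param_labels(self):
        return _PARAM_LABELS

    def to_dict(self) -> dict:
        return {
            "self_estimate": dict(zip(_PARAM_LABELS, map(float, self.self_estimate))),
            "posterior_sd": dict(zip(_PARAM_LABELS, map(float, self.posterior_sd))),
            "acceptance_rate": dict(zip(_PARAM_LABELS, map(float, self.acceptance_rate))),
            "n_draws": int(self.draws.shape[0]),
            "diagnostics": {
                k: {kk: (bool(vv) if isinstance(vv, (bool, np.bool_)) else float(vv))
                    for kk, vv in v.items()}
                for k, v in self.diagnostics.items()
            },
        }


def _theta_of(params: ModelParams) -> np.ndarray:
    if params.baseline.name != "weibull":
        raise ValueError("Bayesian estimation is implemented for the TIHLBW model")
    return params.values


def log_prior(params: ModelParams, prior: PriorSpec) -> float:
    """Gamma prior log kernel sum_i [(b_i - 1) log theta_i - a_i theta_i]."""
    theta = _theta_of(params)
    if np.any(theta <= 0):
        return -np.inf
    a = np.array(prior.a)
    b = np.array(prior.b)
    return float(np.sum((b - 1.0) * np.log(theta) - a * theta))


def log_posterior(params: ModelParams, data, prior: PriorSpec) -> float:
    """Joint posterior log kernel: log-likelihood plus gamma prior kernel."""
    lp = log_prior(params, prior)
    if not np.isfinite(lp):
        return -np.inf
    ll = loglik(params, data)
    return ll + lp if np.isfinite(ll) else -np.inf


def elicit_priors(truth: ModelParams, concentration: float) -> PriorSpec:
    """Informative priors whose means equal the assumed true parameters.

    With rate a_i = concentration and shape b_i = concentration * theta_i the
    gamma prior mean is theta_i and the variance theta_i / concentration, so
    larger concentration means tighter priors at the same centre.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    theta = _theta_of(truth)
    return PriorSpec(a=(concentration,) * 4, b=tuple(concentration * theta))


def _run_chain(data, prior, config, rng, theta0):
    y = np.log(theta0)
    sd = np.array(config.proposal_sd, dtype=float)

    def lp_y(yv):
        # posterior of y = log theta includes the Jacobian prod theta_i
        theta = np.exp(yv)
        return log_posterior(tihlbw_params(*theta), data, prior) + float(np.sum(yv))

    cur = lp_y(y)
    if not np.isfinite(cur):
        raise ValueError(
            "initial point has non-finite posterior; supply a different start "
            "(default is the MLE)"
        )
    keep = []
    acc = np.zeros(4)
    n_post = 0
    acc_window = np.zeros(4)
    for it in range(config.n_iter):
        in_burn = it < config.burn_in
        for j in (0, 1, 2, 3):  # sweep order lam, alpha, beta, delta
            prop = y.copy()
            prop[j] += rng.normal(0.0, sd[j])
            new = lp_y(prop)
            if np.log(rng.random()) < new - cur:
                y, cur = prop, new
                acc_window[j] += 1
                if not in_burn:
                    acc[j] += 1
        if in_burn and (it + 1) % config.adapt_interval == 0:
            rate = acc_window / config.adapt_interval
            sd *= np.exp((rate - config.target_accept))
            sd = np.clip(sd, 1e-3, 10.0)
            acc_window[:] = 0.0
        if not in_burn:
            n_post += 1
            if (it - config.burn_in) % config.thin == 0:
                keep.append(np.exp(y))
    return np.array(keep), acc / max(n_post, 1)


def sample_posterior(data, prior: PriorSpec, config: McmcConfig = McmcConfig(),
                     start: ModelParams | None = None) -> PosteriorSample:
    """Metropolis-within-Gibbs posterior sampling for the TIHLBW model.

    The chain starts at the MLE unless ``start`` is given.  With
    ``config.n_chains > 1`` the chains are concatenated for the point
    summaries and kept separately in ``chains`` for diagnostics.
    """
    data = np.asarray(data, dtype=float).ravel()
    if start is None:
        start = fit_mle(data, "tihlbw", n_starts=8, seed=config.seed,
                        compute_se=False).params_hat
    theta0 = _theta_of(start)
    ss = np.random.SeedSequence(config.seed)
    chains = []
    rates = []
    for child in ss.spawn(config.n_chains):
        draws, rate = _run_chain(data, prior, config, np.random.default_rng(child), theta0)
        chains.append(draws)
        rates.append(rate)
    draws = np.vstack(chains)
    diagnostics = {}
    for j, name in enumerate(_PARAM_LABELS):
        hw = hw_diagnostic(chains[0][:, j])
        diagnostics[name] = {
            "stationarity_passed": hw.stationarity_passed,
            "halfwidth_passed": hw.halfwidth_passed,
            "cvm_statistic": hw.cvm_statistic,
            "halfwidth_ratio": hw.halfwidth_ratio,
        }
    return PosteriorSample(
        draws=draws,
        acceptance_rate=np.mean(rates, axis=0),
        self_estimate=draws.mean(axis=0),
        posterior_sd=draws.std(axis=0, ddof=1),
        diagnostics=diagnostics,
        chains=chains,
    )


# ---------------------------------------------------------------------------
# Heidelberger-Welch diagnostic
# ---------------------------------------------------------------------------


@dataclass
class HWResult:
    stationarity_passed: bool
    halfwidth_passed: bool
    cvm_statistic: float
    halfwidth_ratio: float
    start_fraction: float


# asymptotic 5% critical value of the Cramer-von Mises limit distribution
_CVM_CRIT_5PCT = 0.46136


def _spectrum0_ar(x):
    """Spectral density of x at frequency zero via an AIC-selected AR fit."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    v0 = float(np.dot(xc, xc)) / n
    if v0 == 0.0:
        return 0.0
    max_order = int(min(20, n // 10))
    # autocovariances
    gamma = np.array([np.dot(xc[: n - k], xc[k:]) / n for k in range(max_order + 1)])
    best_s0, best_aic = v0, n * np.log(v0)  # AR(0)
    for p in range(1, max_order + 1):
        try:
            phi = solve_toeplitz(gamma[:p], gamma[1 : p + 1])
        except np.linalg.LinAlgError:
            break
        sigma2 = gamma[0] - float(np.dot(phi, gamma[1 : p + 1]))
        if sigma2 <= 0:
            continue
        aic = n * np.log(sigma2) + 2.0 * p
        if aic < best_aic:
            denom = (1.0 - float(np.sum(phi))) ** 2
            if denom > 1e-12:
                best_aic, best_s0 = aic, sigma2 / denom
    return best_s0


def hw_diagnostic(chain, eps: float = 0.1, pvalue: float = 0.05) -> HWResult:
    """Heidelberger-Welch stationarity and half-width test for one chain.

    Stationarity: the Cramér-von Mises statistic of the standardized
    Brownian-bridge transform of the cumulative sums is compared with its
    asymptotic 5% critical value; on failure the first 10% of the chain is
    discarded and the test repeated, up to half the chain.  Half-width: the
    asymptotic 95% half-width of the mean (from the spectral density at zero)
    must be within ``eps`` of the mean's magnitude.  A constant chain passes
    both stages trivially (its Brownian bridge is identically zero).
    """
    x = np.asarray(chain, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("Heidelberger-Welch needs a chain of length >= 100")
    if pvalue != 0.05:
        raise NotImplementedError("only the 5% nominal level is tabulated")

    n_total = x.size
    stationarity = False
    cvm = np.inf
    frac = 0.0
    for k in range(6):  # trim 0%, 10%, ..., 50%
        frac = 0.1 * k
        seg = x[int(frac * n_total):]
        n = seg.size
        s0 = _spectrum0_ar(seg)
        if s0 == 0.0:  # constant chain
            stationarity, cvm = True, 0.0
            break
        csum = np.cumsum(seg)
        t = np.arange(1, n + 1) / n
        bridge = (csum - t * csum[-1]) / np.sqrt(n * s0)
        cvm = float(np.mean(bridge**2))
        if cvm <= _CVM_CRIT_5PCT:
            stationarity = True
            break

    seg = x[int(frac * n_total):]
    mean = seg.mean()
    s0 = _spectrum0_ar(seg)
    halfwidth = 1.96 * np.sqrt(s0 / seg.size)
    ratio = halfwidth / abs(mean) if mean != 0 else (0.0 if halfwidth == 0 else np.inf)
    return HWResult(
        stationarity_passed=bool(stationarity),
        halfwidth_passed=bool(stationarity and ratio <= eps),
        cvm_statistic=cvm,
        halfwidth_ratio=float(ratio),
        start_fraction=frac,
    )
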