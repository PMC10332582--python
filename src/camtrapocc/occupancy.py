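"""Single-season, single-species site-occupancy models with imperfect
detection.

The hierarchy is the standard zero-inflated Bernoulli pair

    z_i ~ Bernoulli(psi_i)                    (site occupancy / habitat use)
    y_ij | z_i ~ Bernoulli(z_i * p_ij)        (detection / intensity of use)

with logit-linear covariate submodels logit(psi_i) = x_i' beta and
logit(p_ij) = w_ij' alpha.  Because camera stations are typically far
smaller than a felid home range, psi is interpreted as habitat use and p as
intensity of use; fit reports carry those labels.

Two engines share one marginal (z-integrated) likelihood: a multi-start
quasi-Newton maximum-likelihood fit, and an adaptive random-walk Metropolis
sampler with weakly-informative Normal(0, 2.5) priors on the coefficients
of scaled covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .covariates import DesignMatrices
from .survey import DetectionHistory

ETA_CLIP = 35.0          # |logit| bound before exponentiation
BOUNDARY_PROB = 0.9999   # fitted probability beyond which we warn

INTERPRETATION = {"psi": "habitat use", "p": "intensity of use"}


@dataclass
class OccuModelSpec:
    """Term lists for the psi and p submodels, plus a display label."""

    psi_terms: list = field(default_factory=list)
    p_terms: list = field(default_factory=list)
    label: str = ""

    def __post_init__(self):
        if not self.label:
            p = "+".join(self.p_terms) or "."
            s = "+".join(self.psi_terms) or "."
            self.label = f"p({p})psi({s})"


@dataclass
class OccuParams:
    """Logit-scale coefficients: beta for occupancy, alpha for detection."""

    beta: np.ndarray
    alpha: np.ndarray

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if not (np.isfinite(self.beta).all() and np.isfinite(self.alpha).all()):
            raise ValueError("coefficients must be finite")

    def pack(self) -> np.ndarray:
        return np.concatenate([self.beta, self.alpha])


def site_likelihood(y_row, psi, p) -> float:
    """Marginal likelihood of one site's detection history.

    ``y_row`` holds {0, 1, nan}; ``psi`` is the site's occupancy
    probability; ``p`` is a scalar or per-occasion detection probability.
    Missing occasions contribute nothing.  Computed in log space with a
    log-sum-exp for the all-zero branch.
    """
    y = np.asarray(y_row, dtype=float)
    obs = ~np.isnan(y)
    if not obs.any():
        raise ValueError("site has no observed occasions")
    p = np.broadcast_to(np.asarray(p, dtype=float), y.shape)
    yo, po = y[obs], p[obs]
    cond = float(np.sum(yo * np.log(po) + (1 - yo) * np.log1p(-po)))
    if (yo == 1).any():
        return float(np.exp(np.log(psi) + cond))
    return float(np.exp(np.logaddexp(np.log(psi) + cond, np.log1p(-psi))))


def _probs(beta, alpha, X, W):
    psi = expit(np.clip(X @ beta, -ETA_CLIP, ETA_CLIP))
    p = expit(np.clip(W @ alpha, -ETA_CLIP, ETA_CLIP))
    return psi, p


def pointwise_loglik(beta, alpha, X, W, yf, obs, never):
    """Per-site marginal log-likelihood, vectorised over sites.

    ``yf`` is the history with NaN filled as 0, ``obs`` the surveyed mask,
    ``never`` flags sites with no detection on any surveyed occasion.
    """
    psi, p = _probs(beta, alpha, X, W)
    with np.errstate(divide="ignore"):
        cond = np.where(obs, yf * np.log(p) + (1 - yf) * np.log1p(-p), 0.0).sum(axis=1)
    det_branch = np.log(psi) + cond
    return np.where(never, np.logaddexp(det_branch, np.log1p(-psi)), det_branch)


def _nll_and_grad(theta, kpsi, X, W, yf, obs, never):
    beta, alpha = theta[:kpsi], theta[kpsi:]
    psi, p = _probs(beta, alpha, X, W)
    cond = np.where(obs, yf * np.log(p) + (1 - yf) * np.log1p(-p), 0.0).sum(axis=1)
    det_branch = np.log(psi) + cond
    ll = np.where(never, np.logaddexp(det_branch, np.log1p(-psi)), det_branch)
    # P(z=1 | y): 1 for detected sites, posterior ratio otherwise
    c = np.where(never, np.exp(det_branch - ll), 1.0)
    g_beta = X.T @ (c - psi)
    resid = np.where(obs, yf - p, 0.0) * c[:, None]
    g_alpha = np.einsum("ij,ijk->k", resid, W)
    return -ll.sum(), -np.concatenate([g_beta, g_alpha])


def _prepare(data: DetectionHistory):
    y = data.matrix
    obs = ~np.isnan(y)
    if not obs.any(axis=1).all():
        raise ValueError("some site has no observed occasions")
    yf = np.nan_to_num(y)
    never = ~((yf == 1) & obs).any(axis=1)
    return yf, obs, never


def _naive_rates(yf, obs, never):
    naive_psi = float(np.clip((~never).mean(), 0.05, 0.95))
    det_sites = ~never
    if det_sites.any():
        naive_p = float(yf[det_sites][obs[det_sites]].mean())
    else:
        naive_p = 0.5
    return naive_psi, float(np.clip(naive_p, 0.05, 0.95))


MULTISTART_OFFSETS = [(0.0, 0.0), (1.0, 1.0), (1.0, -1.0), (-1.0, 1.0), (-1.0, -1.0)]


def _numeric_hessian(fun, theta, eps=1e-5):
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += eps
        tm[j] -= eps
        _, gp = fun(tp)
        _, gm = fun(tm)
        H[:, j] = (gp - gm) / (2 * eps)
    return 0.5 * (H + H.T)


@dataclass
class OccuFitML:
    """Maximum-likelihood occupancy fit."""

    spec: OccuModelSpec
    params: OccuParams
    cov: np.ndarray                 # joint (beta, alpha) covariance
    loglik: float
    aicc: float
    pointwise: np.ndarray           # per-site log-likelihood at the MLE
    converged: bool
    boundary_warning: bool
    n_sites: int
    n_params: int
    designs: DesignMatrices
    data: DetectionHistory

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    def coef_table(self) -> pd.DataFrame:
        names = ([f"psi:{n}" for n in self.designs.psi_names]
                 + [f"p:{n}" for n in self.designs.p_names])
        est = self.params.pack()
        se = self.se
        return pd.DataFrame({
            "term": names, "estimate": est, "se": se,
            "lo95": est - 1.959963984540054 * se,
            "hi95": est + 1.959963984540054 * se,
        })

    def to_report(self) -> dict:
        return {
            "model": self.spec.label,
            "engine": "ml",
            "interpretation": dict(INTERPRETATION),
            "coefficients": self.coef_table().to_dict(orient="records"),
            "loglik": self.loglik,
            "aicc": self.aicc,
            "n_sites": self.n_sites,
            "n_params": self.n_params,
            "converged": self.converged,
            "boundary_warning": self.boundary_warning,
        }


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_ml(data: DetectionHistory, designs: DesignMatrices,
           spec: OccuModelSpec | None = None) -> OccuFitML:
    """Fit the occupancy model by maximum likelihood.

    Quasi-Newton (BFGS, analytic gradient) from 5 deterministic starts:
    intercepts at the logit of the naive occupancy and detection rates with
    offsets (0,0), (+1,+1), (+1,-1), (-1,+1), (-1,-1); slopes start at 0.
    """
    if spec is None:
        spec = OccuModelSpec(label="custom")
    yf, obs, never = _prepare(data)
    if never.all():
        raise ValueError("no detections at all: psi and p are not jointly identifiable")
    X, W = designs.X, designs.W
    kpsi, kp = X.shape[1], W.shape[2]
    naive_psi, naive_p = _naive_rates(yf, obs, never)

    fun = lambda th: _nll_and_grad(th, kpsi, X, W, yf, obs, never)
    best = None
    for dpsi, dp in MULTISTART_OFFSETS:
        theta0 = np.zeros(kpsi + kp)
        theta0[0] = logit(naive_psi) + dpsi
        theta0[kpsi] = logit(naive_p) + dp
        res = minimize(fun, theta0, jac=True, method="BFGS",
                       options={"gtol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    theta = best.x
    nll, grad = fun(theta)
    converged = bool(np.linalg.norm(grad) < 1e-5)
    H = _numeric_hessian(fun, theta)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((len(theta), len(theta)), np.nan)
    psi, p = _probs(theta[:kpsi], theta[kpsi:], X, W)
    boundary = bool((psi > BOUNDARY_PROB).any() or (p[obs] > BOUNDARY_PROB).any())
    if boundary:
        warnings.warn("fitted probabilities at the boundary (psi or p > 0.9999)",
                      stacklevel=2)
    params = OccuParams(theta[:kpsi], theta[kpsi:])
    pw = pointwise_loglik(params.beta, params.alpha, X, W, yf, obs, never)
    n, k = data.n_sites, kpsi + kp
    return OccuFitML(spec=spec, params=params, cov=cov, loglik=float(-nll),
                     aicc=aicc(-nll, k, n) if n > k + 1 else np.nan,
                     pointwise=pw, converged=converged,
                     boundary_warning=boundary, n_sites=n, n_params=k,
                     designs=designs, data=data)


def conditional_occupancy(fit, data: DetectionHistory | None = None) -> np.ndarray:
    """Posterior probability of occupancy given each site's history,
    Pr(z_i = 1 | y_i): exactly 1 for sites with a detection, Bayes-rule
    ratio psi * prod(1-p) / L for never-detected sites.

    For a Bayesian fit, averaged over posterior draws.
    """
    if data is None:
        data = fit.data
    yf, obs, never = _prepare(data)
    X, W = fit.designs.X, fit.designs.W
    if isinstance(fit, OccuFitBayes):
        draws = fit.flat_draws()
        out = np.zeros(data.n_sites)
        for theta in draws:
            beta, alpha = theta[:X.shape[1]], theta[X.shape[1]:]
            psi, p = _probs(beta, alpha, X, W)
            ll = pointwise_loglik(beta, alpha, X, W, yf, obs, never)
            cond = np.where(obs, np.log1p(-p), 0.0).sum(axis=1)
            c = np.where(never, np.exp(np.log(psi) + cond - ll), 1.0)
            out += c
        return out / len(draws)
    beta, alpha = fit.params.beta, fit.params.alpha
    psi, p = _probs(beta, alpha, X, W)
    ll = pointwise_loglik(beta, alpha, X, W, yf, obs, never)
    cond = np.where(obs, np.log1p(-p), 0.0).sum(axis=1)
    return np.where(never, np.exp(np.log(psi) + cond - ll), 1.0)


def compute_rhat(draws: np.ndarray, split: bool = True) -> np.ndarray:
    """Gelman-Rubin potential scale reduction factor, per parameter.

    ``draws`` has shape (chains, iterations) or (chains, iterations,
    parameters).  With ``split=True`` each chain is halved first.  The
    statistic is clipped below at 1 (values < 1 are estimation noise).
    """
    d = np.asarray(draws, dtype=float)
    scalar = d.ndim == 2
    if scalar:
        d = d[:, :, None]
    m, n, k = d.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    if split:
        half = n // 2
        d = np.concatenate([d[:, :half], d[:, half:2 * half]], axis=0)
        m, n = 2 * m, half
    if n < 2:
        raise ValueError("need at least 4 draws per chain")
    means = d.mean(axis=1)                         # (m, k)
    W = d.var(axis=1, ddof=1).mean(axis=0)         # (k,)
    if np.all(W == 0):
        raise ValueError("zero within-chain variance everywhere")
    B = n * means.var(axis=0, ddof=1)
    vhat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(np.maximum(vhat / W, 1.0))
    return float(rhat[0]) if scalar else rhat


@dataclass
class OccuFitBayes:
    """Posterior sample from the adaptive random-walk Metropolis engine."""

    spec: OccuModelSpec
    draws: np.ndarray               # chains x iterations x parameters
    rhat: np.ndarray
    summary: pd.DataFrame           # mean, sd, 2.5/97.5% equal-tailed CI
    pointwise_draws: np.ndarray     # draws x sites log-likelihood
    elpd_loo: float
    elpd_loo_se: float
    pareto_k: np.ndarray
    seed: int
    accept_rate: float
    convergence_warning: bool
    designs: DesignMatrices
    data: DetectionHistory

    def flat_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_report(self) -> dict:
        return {
            "model": self.spec.label,
            "engine": "bayes",
            "interpretation": dict(INTERPRETATION),
            "coefficients": self.summary.to_dict(orient="records"),
            "elpd_loo": self.elpd_loo,
            "elpd_loo_se": self.elpd_loo_se,
            "rhat": list(map(float, np.atleast_1d(self.rhat))),
            "convergence_warning": self.convergence_warning,
            "seed": self.seed,
            "accept_rate": self.accept_rate,
        }


def fit_bayes(data: DetectionHistory, designs: DesignMatrices,
              spec: OccuModelSpec | None = None, chains: int = 3,
              iterations: int = 30000, burn_fraction: float = 0.5,
              seed: int = 0, prior_sd: float = 2.5,
              pointwise_thin: int = 1) -> OccuFitBayes:
    """Sample the posterior with adaptive random-walk Metropolis.

    Priors are Normal(0, ``prior_sd``) on every coefficient (uninformative
    on the scale of z-scored covariates).  The joint proposal scale adapts
    toward a 0.234 acceptance rate during burn-in, then freezes.  The first
    ``burn_fraction`` of each chain is discarded.  A non-fatal warning is
    attached when any split R-hat >= 1.1.
    """
    if spec is None:
        spec = OccuModelSpec(label="custom")
    yf, obs, never = _prepare(data)
    X, W = designs.X, designs.W
    kpsi, kp = X.shape[1], W.shape[2]
    k = kpsi + kp

    try:
        ml = fit_ml(data, designs, spec)
        theta_center = ml.params.pack()
        step0 = np.sqrt(np.clip(np.diag(ml.cov), 1e-4, 4.0))
    except Exception:
        theta_center = np.zeros(k)
        step0 = np.full(k, 0.3)

    def log_post(theta):
        ll = pointwise_loglik(theta[:kpsi], theta[kpsi:], X, W, yf, obs, never).sum()
        return ll - 0.5 * np.sum((theta / prior_sd) ** 2)

    burn = int(iterations * burn_fraction)
    keep = iterations - burn
    all_draws = np.empty((chains, keep, k))
    n_acc_total = 0
    ss = np.random.SeedSequence([int(seed), 0x0CCA])
    for c, child in enumerate(ss.spawn(chains)):
        rng = np.random.default_rng(child)
        theta = theta_center + 0.1 * rng.standard_normal(k)
        lp = log_post(theta)
        log_scale = np.log(2.38 / np.sqrt(k))
        batch_acc, batch_n, batch_idx = 0, 0, 0
        for it in range(iterations):
            prop = theta + np.exp(log_scale) * step0 * rng.standard_normal(k)
            lp_prop = log_post(prop)
            if np.log(rng.random()) < lp_prop - lp:
                theta, lp = prop, lp_prop
                batch_acc += 1
                if it >= burn:
                    n_acc_total += 1
            batch_n += 1
            if it < burn and batch_n == 50:
                batch_idx += 1
                rate = batch_acc / batch_n
                log_scale += (rate - 0.234) / np.sqrt(batch_idx)
                batch_acc, batch_n = 0, 0
            if it >= burn:
                all_draws[c, it - burn] = theta

    rhat = compute_rhat(all_draws)
    conv_warn = bool(np.any(rhat >= 1.1))
    if conv_warn:
        warnings.warn("R-hat >= 1.1 for some parameter; chains may not have mixed",
                      stacklevel=2)
    flat = all_draws.reshape(-1, k)
    names = ([f"psi:{n}" for n in designs.psi_names]
             + [f"p:{n}" for n in designs.p_names])
    summary = pd.DataFrame({
        "term": names,
        "mean": flat.mean(axis=0),
        "sd": flat.std(axis=0, ddof=1),
        "lo95": np.quantile(flat, 0.025, axis=0),
        "hi95": np.quantile(flat, 0.975, axis=0),
        "rhat": np.atleast_1d(rhat),
    })

    sub = flat[::pointwise_thin]
    pw = np.empty((len(sub), data.n_sites))
    chunk = max(1, 2_000_000 // max(1, data.n_sites * data.n_occasions))
    for s0 in range(0, len(sub), chunk):
        for si, theta in enumerate(sub[s0:s0 + chunk]):
            pw[s0 + si] = pointwise_loglik(theta[:kpsi], theta[kpsi:],
                                           X, W, yf, obs, never)
    from .selection import psis_loo
    loo = psis_loo(pw)

    return OccuFitBayes(spec=spec, draws=all_draws, rhat=np.atleast_1d(rhat),
                        summary=summary, pointwise_draws=pw,
                        elpd_loo=loo["elpd"], elpd_loo_se=loo["se"],
                        pareto_k=loo["pareto_k"], seed=int(seed),
                        accept_rate=n_acc_total / max(1, chains * keep),
                        convergence_warning=conv_warn, designs=designs,
                        data=data)


def predict_response(fit, target: str, grid: dict,
                     level: float = 0.95) -> pd.DataFrame:
    """Predicted psi or p along a covariate grid, other terms held at 0
    (the scaled mean) or their reference level.

    ``grid`` maps a base term name to its values (numeric array, or level
    strings for a categorical).  ML fits get delta-method intervals on the
    link scale back-transformed; Bayesian fits get equal-tailed posterior
    quantiles.
    """
    if target not in ("psi", "p"):
        raise ValueError("target must be 'psi' or 'p'")
    designs = fit.designs
    names = designs.psi_names if target == "psi" else designs.p_names
    terms_in_model = set()
    for nm in names[1:]:
        base = nm[:-2] if nm.endswith("^2") else nm.split("[")[0]
        terms_in_model.add(base)
    for term in grid:
        if term not in terms_in_model:
            raise ValueError(f"term {term!r} not in the fitted {target} submodel")

    lengths = {len(np.atleast_1d(v)) for v in grid.values()}
    if len(lengths) > 1:
        raise ValueError("grid values must share a length")
    m = lengths.pop() if lengths else 1

    G = np.zeros((m, len(names)))
    G[:, 0] = 1.0
    for jcol, nm in enumerate(names[1:], start=1):
        if nm.endswith("^2"):
            base = nm[:-2]
            if base in grid:
                G[:, jcol] = np.atleast_1d(grid[base]).astype(float) ** 2
        elif "[" in nm:
            base, lev = nm.split("[")
            lev = lev.rstrip("]")
            if base in grid:
                vals = np.atleast_1d(grid[base])
                G[:, jcol] = (vals.astype(str) == lev).astype(float)
        elif nm in grid:
            G[:, jcol] = np.atleast_1d(grid[nm]).astype(float)

    kpsi = designs.X.shape[1]
    zq = 1.959963984540054 * (level / 0.95) if level == 0.95 else None
    if isinstance(fit, OccuFitBayes):
        flat = fit.flat_draws()
        block = flat[:, :kpsi] if target == "psi" else flat[:, kpsi:]
        eta = block @ G.T
        prob = expit(np.clip(eta, -ETA_CLIP, ETA_CLIP))
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        return pd.DataFrame({
            "fit": prob.mean(axis=0),
            "lo": np.quantile(prob, lo, axis=0),
            "hi": np.quantile(prob, hi, axis=0),
        })
    from scipy.stats import norm
    z = norm.ppf(1 - (1 - level) / 2)
    coefs = fit.params.beta if target == "psi" else fit.params.alpha
    cov = (fit.cov[:kpsi, :kpsi] if target == "psi"
           else fit.cov[kpsi:, kpsi:])
    eta = G @ coefs
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", G, cov, G), 0, None))
    return pd.DataFrame({
        "fit": expit(eta),
        "lo": expit(eta - z * se),
        "hi": expit(eta + z * se),
    })
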