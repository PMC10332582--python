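"""Model selection (AICc and PSIS-LOO elpd pathways), the p-first
sequential submodeling strategy, and MacKenzie-Bailey goodness of fit.

Two ranking currencies coexist, mirroring the two fitting engines: AICc
with Akaike weights for maximum-likelihood fits (co-occurrence stage), and
the expected log pointwise predictive density (elpd) estimated by
Pareto-smoothed importance-sampling leave-one-out cross-validation for
Bayesian fits.  Absolute fit is assessed with the MacKenzie-Bailey chi^2
statistic referenced against parametric-bootstrap or posterior-predictive
replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from . import occupancy as occ
from .covariates import build_design
from .survey import DetectionHistory


def aicc_table(fits, labels=None) -> pd.DataFrame:
    """Rank ML fits by AICc (shared dataset assumed).

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); Akaike weights are
    exp(-delta/2) renormalised; rows with delta < 2 are flagged as the
    retained (competitive) set.
    """
    rows = []
    for i, fit in enumerate(fits):
        k = getattr(fit, "n_params", None) or fit.k
        n = getattr(fit, "n_sites", None) or fit.data.n_sites
        label = labels[i] if labels else getattr(fit.spec, "label", f"m{i}")
        rows.append({"model": label, "k": k,
                     "aicc": occ.aicc(fit.loglik, k, n), "loglik": fit.loglik})
    df = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    df["delta"] = df["aicc"] - df["aicc"].iloc[0]
    w = np.exp(-df["delta"] / 2)
    df["weight"] = w / w.sum()
    df["retained"] = df["delta"] < 2.0
    return df


def psis_loo(pointwise_draws: np.ndarray) -> dict:
    """PSIS-LOO from a draws x sites pointwise log-likelihood matrix.

    Raw importance ratios are reciprocal pointwise likelihoods; the largest
    weights are generalised-Pareto smoothed (arviz), and sites with shape
    k-hat > 0.7 are flagged as unreliable.
    """
    import arviz as az
    ll = np.asarray(pointwise_draws, dtype=float)   # (S, n)
    log_ratios = -ll.T                              # (n, S)
    lw, khat = az.psislw(log_ratios)
    lw = np.asarray(lw)
    khat = np.asarray(khat)
    elpd_i = logsumexp(lw + ll.T, axis=1)           # lw normalised per site
    n = ll.shape[1]
    lpd_i = logsumexp(ll, axis=0) - np.log(ll.shape[0])
    return {
        "elpd": float(elpd_i.sum()),
        "se": float(np.sqrt(n * np.var(elpd_i, ddof=1))) if n > 1 else 0.0,
        "pointwise": elpd_i,
        "lpd": float(lpd_i.sum()),
        "p_loo": float(lpd_i.sum() - elpd_i.sum()),
        "pareto_k": khat,
        "n_high_k": int((khat > 0.7).sum()),
    }


def elpd_compare(fits, labels=None) -> pd.DataFrame:
    """Rank Bayesian fits by PSIS-LOO elpd.

    delta is each model's elpd minus the best model's; its SE is
    sqrt(n * var(pointwise differences)).  A row is flagged "less_support"
    when |delta| exceeds its SE.  Weights are exp-renormalised elpd
    (pseudo-BMA).
    """
    loos = []
    for fit in fits:
        loos.append(psis_loo(fit.pointwise_draws))
    ns = {len(l["pointwise"]) for l in loos}
    if len(ns) > 1:
        raise ValueError("fits do not share a site set")
    n = ns.pop()
    elpds = np.array([l["elpd"] for l in loos])
    best = int(np.argmax(elpds))
    rows = []
    for i, (fit, loo) in enumerate(zip(fits, loos)):
        diff = loo["pointwise"] - loos[best]["pointwise"]
        delta = float(diff.sum())
        se_delta = float(np.sqrt(n * np.var(diff, ddof=1))) if i != best else 0.0
        label = labels[i] if labels else getattr(fit.spec, "label", f"m{i}")
        rows.append({"model": label, "elpd": loo["elpd"], "se": loo["se"],
                     "p_loo": loo["p_loo"], "delta": delta,
                     "se_delta": se_delta,
                     "less_support": bool(abs(delta) > se_delta) if i != best else False,
                     "n_high_k": loo["n_high_k"]})
    df = pd.DataFrame(rows).sort_values("elpd", ascending=False,
                                        kind="mergesort").reset_index(drop=True)
    w = np.exp(df["elpd"] - df["elpd"].max())
    df["weight"] = w / w.sum()
    return df


@dataclass
class PFirstResult:
    """Staged selection tables and the winning model specification."""

    stage1: pd.DataFrame
    stage2: pd.DataFrame
    final_spec: occ.OccuModelSpec
    final_fit: object


def _as_term_list(cand):
    return list(cand) if isinstance(cand, (list, tuple)) else [cand]


def p_first_selection(data: DetectionHistory, table: pd.DataFrame,
                      p_candidates, psi_candidates, engine: str = "ml",
                      seed: int = 0, **bayes_kwargs) -> PFirstResult:
    """Sequential-by-selection submodeling, p first.

    Stage 1 ranks p(term)psi(.) models (plus the null) while holding psi
    constant; stage 2 fixes the stage-1 winner's detection structure and
    ranks psi(term) models (plus the null).  Ranking is AICc for the ML
    engine and PSIS-LOO elpd for the Bayesian engine.
    """
    if engine not in ("ml", "bayes"):
        raise ValueError("engine must be 'ml' or 'bayes'")
    if not p_candidates and not psi_candidates:
        warnings.warn("no candidate terms; returning the null model only",
                      stacklevel=2)

    def fit_one(psi_terms, p_terms, chain_seed):
        spec = occ.OccuModelSpec(psi_terms=psi_terms, p_terms=p_terms)
        designs = build_design(table, psi_terms, p_terms,
                               n_occasions=data.n_occasions, effort=data.effort)
        if engine == "ml":
            return occ.fit_ml(data, designs, spec)
        return occ.fit_bayes(data, designs, spec, seed=chain_seed, **bayes_kwargs)

    def rank(fits):
        if engine == "ml":
            df = aicc_table(fits)
            return df, df["model"].iloc[0]
        df = elpd_compare(fits)
        return df, df["model"].iloc[0]

    stage1_specs = [[]] + [_as_term_list(c) for c in p_candidates]
    fits1 = [fit_one([], p_terms, seed + 101 + i)
             for i, p_terms in enumerate(stage1_specs)]
    table1, winner1 = rank(fits1)
    best_p = next(f.spec.p_terms for f in fits1 if f.spec.label == winner1)

    stage2_specs = [[]] + [_as_term_list(c) for c in psi_candidates]
    fits2 = [fit_one(psi_terms, best_p, seed + 201 + i)
             for i, psi_terms in enumerate(stage2_specs)]
    table2, winner2 = rank(fits2)
    final_fit = next(f for f in fits2 if f.spec.label == winner2)
    return PFirstResult(stage1=table1, stage2=table2,
                        final_spec=final_fit.spec, final_fit=final_fit)


# ---------------------------------------------------------------------------
# MacKenzie-Bailey goodness of fit


def mb_statistic(fit, data: DetectionHistory | None = None,
                 params: occ.OccuParams | None = None) -> float:
    """MacKenzie-Bailey chi^2 for a single-species fit.

    Sites are grouped into cohorts sharing a missingness pattern; within a
    cohort, the expected count of each *observed* unique history h is
    E_h = sum_i Pr(h | theta, x_i), and one pooled never-observed cell per
    cohort carries O = 0, E = N_cohort - sum_h E_h.  chi^2 sums
    (O-E)^2 / E over all cells.
    """
    if data is None:
        data = fit.data
    if params is None:
        params = fit.params
    X, W = fit.designs.X, fit.designs.W
    psi, p = occ._probs(params.beta, params.alpha, X, W)
    y = data.matrix
    obsmask = ~np.isnan(y)

    chisq = 0.0
    patterns = {}
    for i in range(data.n_sites):
        patterns.setdefault(tuple(obsmask[i]), []).append(i)
    for pat, sites in patterns.items():
        pat = np.array(pat)
        hist_counts = {}
        for i in sites:
            h = tuple(y[i, pat].astype(int))
            hist_counts[h] = hist_counts.get(h, 0) + 1
        E_sum = 0.0
        for h, O in hist_counts.items():
            hv = np.array(h, dtype=float)
            ph = p[np.ix_(sites, np.flatnonzero(pat))]
            cond = (hv * np.log(ph) + (1 - hv) * np.log1p(-ph)).sum(axis=1)
            probs = psi[sites] * np.exp(cond)
            if not hv.any():
                probs = probs + (1 - psi[sites])
            E = float(probs.sum())
            chisq += (O - E) ** 2 / E
            E_sum += E
        E_pool = max(len(sites) - E_sum, 0.0)
        chisq += E_pool  # (0 - E)^2 / E
    return float(chisq)


def zero_proportion(data: DetectionHistory) -> float:
    """Proportion of surveyed cells with no detection (optional GOF
    discrepancy variant)."""
    obsmask = ~np.isnan(data.matrix)
    return float((data.matrix[obsmask] == 0).mean())


@dataclass
class GofResult:
    """Observed discrepancy and its reference p-value."""

    statistic: float
    p_value: float
    p_lower: float          # other tail; small values flag underdispersion
    n_replicates: int
    seed: int
    mode: str               # "bootstrap" | "posterior"

    def to_report(self) -> dict:
        return {"statistic": self.statistic, "p_value": self.p_value,
                "p_lower": self.p_lower, "n_replicates": self.n_replicates,
                "seed": self.seed, "mode": self.mode}


def _simulate_history(psi, p, obsmask, rng) -> np.ndarray:
    z = rng.random(len(psi)) < psi
    yy = (rng.random(p.shape) < p) & z[:, None]
    return np.where(obsmask, yy.astype(float), np.nan)


def _refit_statistic(fit, new_matrix, statistic):
    """Refit the model on a simulated matrix, starting at the observed
    fit's estimates (speed/stability), and return the discrepancy."""
    data = DetectionHistory(fit.data.species, fit.data.station_ids,
                            new_matrix, fit.data.effort)
    yf, obsmask, never = occ._prepare(data)
    if never.all():
        raise ValueError("simulated dataset has no detections")
    X, W = fit.designs.X, fit.designs.W
    kpsi = X.shape[1]
    fun = lambda th: occ._nll_and_grad(th, kpsi, X, W, yf, obsmask, never)
    res = minimize(fun, fit.params.pack(), jac=True, method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 300})
    params = occ.OccuParams(res.x[:kpsi], res.x[kpsi:])
    if statistic == "zeros":
        return zero_proportion(data)
    return mb_statistic(fit, data, params)


def gof_bootstrap(fit, n_sims: int = 1000, seed: int = 0,
                  statistic: str = "chisq") -> GofResult:
    """Parametric-bootstrap MacKenzie-Bailey test for an ML fit.

    Datasets are simulated at the MLE with the observed missingness,
    refitted, and their chi^2 recomputed; p is the proportion of simulated
    statistics >= the observed one.
    """
    obs_stat = (mb_statistic(fit) if statistic == "chisq"
                else zero_proportion(fit.data))
    X, W = fit.designs.X, fit.designs.W
    psi, p = occ._probs(fit.params.beta, fit.params.alpha, X, W)
    obsmask = ~np.isnan(fit.data.matrix)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x60F]))
    sims, failures = [], 0
    for _ in range(n_sims):
        ysim = _simulate_history(psi, p, obsmask, rng)
        try:
            sims.append(_refit_statistic(fit, ysim, statistic))
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
    if failures > 0.1 * n_sims:
        raise RuntimeError(f"{failures}/{n_sims} bootstrap refits failed")
    sims = np.asarray(sims)
    return GofResult(statistic=float(obs_stat),
                     p_value=float((sims >= obs_stat).mean()),
                     p_lower=float((sims <= obs_stat).mean()),
                     n_replicates=len(sims), seed=int(seed), mode="bootstrap")


def gof_posterior_predictive(fit, n_draws_used: int = 500, seed: int = 0,
                             statistic: str = "chisq") -> GofResult:
    """Posterior-predictive MacKenzie-Bailey check for a Bayesian fit.

    For each sampled posterior draw, a replicate dataset is simulated and
    the discrepancy computed for both the replicate and the observed data
    at that draw's parameters; the Bayesian P value is the proportion of
    draws whose replicate discrepancy exceeds the observed one
    (P > 0.05 indicates acceptable fit).
    """
    flat = fit.flat_draws()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x99]))
    idx = rng.choice(len(flat), size=min(n_draws_used, len(flat)), replace=False)
    X, W = fit.designs.X, fit.designs.W
    kpsi = X.shape[1]
    obsmask = ~np.isnan(fit.data.matrix)
    exceed = 0
    below = 0
    for s in idx:
        theta = flat[s]
        params = occ.OccuParams(theta[:kpsi], theta[kpsi:])
        psi, p = occ._probs(params.beta, params.alpha, X, W)
        if statistic == "zeros":
            obs_stat = zero_proportion(fit.data)
        else:
            obs_stat = mb_statistic(fit, fit.data, params)
        ysim = _simulate_history(psi, p, obsmask, rng)
        sim_data = DetectionHistory(fit.data.species, fit.data.station_ids,
                                    ysim, fit.data.effort)
        if statistic == "zeros":
            rep_stat = zero_proportion(sim_data)
        else:
            rep_stat = mb_statistic(fit, sim_data, params)
        if rep_stat > obs_stat:
            exceed += 1
        if rep_stat < obs_stat:
            below += 1
    n = len(idx)
    mean_params = occ.OccuParams(flat[:, :kpsi].mean(axis=0),
                                 flat[:, kpsi:].mean(axis=0))
    return GofResult(statistic=float(mb_statistic(fit, fit.data, mean_params)
                                     if statistic == "chisq"
                                     else zero_proportion(fit.data)),
                     p_value=exceed / n, p_lower=below / n,
                     n_replicates=n, seed=int(seed), mode="posterior")
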