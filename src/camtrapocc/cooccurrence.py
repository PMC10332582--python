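"""Two-species conditional co-occurrence models (psiBa parameterization).

An asymmetric model for a dominant species A and a subordinate species B.
The eight parameters are

    psiA   occupancy of A
    psiBA  occupancy of B given A present
    psiBa  occupancy of B given A absent
    pA     detection of A where B is absent (A-only sites)
    pB     detection of B where A is absent (B-only sites)
    rA     detection of A where both are present
    rBA    detection of B where both are present, on occasions where A
           was detected
    rBa    detection of B where both are present, on occasions where A
           was not detected

Nested variants alias parameters: psiBA = psiBa (occupancy independence)
and pA = rA, pB = rBA = rBa (detection independence), giving models with
4, 5, 7 and 8 parameters.  Derived summaries are the species interaction
factor (SIF) and the detection interaction factor (DIF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .occupancy import ETA_CLIP, MULTISTART_OFFSETS, aicc, _numeric_hessian
from .survey import DetectionHistory

PARAM_NAMES = ["psiA", "psiBA", "psiBa", "pA", "pB", "rA", "rBA", "rBa"]
REPORT_KEYS = ["ΨA", "ΨBA", "ΨBa", "pA", "pB", "rA", "rBA", "rBa"]


@dataclass
class CoOccData:
    """Paired histories on identical station order, occasions and
    missingness."""

    history_A: DetectionHistory
    history_B: DetectionHistory

    def __post_init__(self):
        a, b = self.history_A, self.history_B
        if a.matrix.shape != b.matrix.shape:
            raise ValueError("paired histories must share shape")
        if a.station_ids != b.station_ids:
            raise ValueError("paired histories must share station order")
        if not np.array_equal(np.isnan(a.matrix), np.isnan(b.matrix)):
            raise ValueError("paired histories must share missingness")

    @property
    def n_sites(self) -> int:
        return self.history_A.n_sites


@dataclass
class CoOccModelSpec:
    """Variant flags and optional covariates on the subordinate species'
    occupancy (psiBA / psiBa share the covariate slopes)."""

    psi_conditional: bool = True
    det_conditional: bool = True
    covariate_names: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return (1 + (2 if self.psi_conditional else 1)
                + (5 if self.det_conditional else 2)
                + len(self.covariate_names))

    @property
    def label(self) -> str:
        psi = "psiBA!=psiBa" if self.psi_conditional else "psiBA=psiBa"
        det = "pA!=rA,pB!=rBA!=rBa" if self.det_conditional else "pA=rA,pB=rBA=rBa"
        cov = f"+{'+'.join(self.covariate_names)}" if self.covariate_names else ""
        return f"{psi};{det}{cov}"


def enumerate_variants(covariate_names: list | None = None) -> list:
    """The 2x2 grid of occupancy/detection conditioning (k = 4, 5, 7, 8),
    plus covariate-augmented copies when covariates are named."""
    base = [CoOccModelSpec(psi_conditional=pc, det_conditional=dc)
            for pc in (False, True) for dc in (False, True)]
    base.sort(key=lambda s: s.n_params)
    if covariate_names:
        base = base + [CoOccModelSpec(s.psi_conditional, s.det_conditional,
                                      list(covariate_names)) for s in base]
    return base


@dataclass
class CoOccParams:
    """The eight parameters on the probability scale.  psiBA / psiBa may be
    per-site arrays when covariates enter."""

    psiA: float
    psiBA: float | np.ndarray
    psiBa: float | np.ndarray
    pA: float
    pB: float
    rA: float
    rBA: float
    rBa: float

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in PARAM_NAMES}


def species_interaction_factor(psiA, psiBA, psiBa) -> float:
    """SIF Phi = psi_AB / (psi_A * psi_B): the ratio of joint occupancy to
    the product of the marginals.  Phi = 1 means the species occur
    independently; Phi > 1 aggregation; Phi < 1 avoidance."""
    if psiA <= 0:
        raise ValueError("species_interaction_factor undefined for psiA = 0")
    marg_B = psiA * psiBA + (1 - psiA) * psiBa
    if marg_B <= 0:
        raise ValueError("subordinate species has zero marginal occupancy")
    return float((psiA * psiBA) / (psiA * marg_B))


def detection_interaction_factor(rA, rBA, rBa) -> float:
    """DIF delta = rBA / (rA * rBa); delta != 1 indicates conditional
    codetectability of the pair."""
    if rA * rBa == 0:
        raise ValueError("detection_interaction_factor undefined for zero denominator")
    return float(rBA / (rA * rBa))


def _site_logliks(params: CoOccParams, yA, yB, obs):
    """Vectorised per-site log-likelihood of the four-latent-state mixture."""
    yAf, yBf = np.nan_to_num(yA), np.nan_to_num(yB)
    neverA = ~((yAf == 1) & obs).any(axis=1)
    neverB = ~((yBf == 1) & obs).any(axis=1)

    def occ_sum(y, p):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = y * np.log(p) + (1 - y) * np.log1p(-p)
        return np.where(obs, t, 0.0).sum(axis=1)

    lA_r = occ_sum(yAf, params.rA)
    lA_p = occ_sum(yAf, params.pA)
    lB_p = occ_sum(yBf, params.pB)
    rB = np.where(yAf == 1, params.rBA, params.rBa)
    lB_both = occ_sum(yBf, rB)

    psiA = params.psiA
    lpsiBA = np.log(np.broadcast_to(params.psiBA, neverA.shape))
    l1mBA = np.log1p(-np.broadcast_to(params.psiBA, neverA.shape))
    lpsiBa = np.log(np.broadcast_to(params.psiBa, neverA.shape))
    l1mBa = np.log1p(-np.broadcast_to(params.psiBa, neverA.shape))

    neg_inf = -np.inf
    s_both = np.log(psiA) + lpsiBA + lA_r + lB_both
    s_aonly = np.where(neverB, np.log(psiA) + l1mBA + lA_p, neg_inf)
    s_bonly = np.where(neverA, np.log1p(-psiA) + lpsiBa + lB_p, neg_inf)
    s_none = np.where(neverA & neverB, np.log1p(-psiA) + l1mBa, neg_inf)
    stacked = np.stack([s_both, s_aonly, s_bonly, s_none])
    mx = stacked.max(axis=0)
    return mx + np.log(np.exp(stacked - mx).sum(axis=0))


def cooc_site_likelihood(yA_row, yB_row, params: CoOccParams) -> float:
    """Marginal likelihood of one site's paired history, summing the four
    latent states (both, A-only, B-only, neither).  In the both-present
    state, B's detection on occasion j uses rBA if A was detected on j and
    rBa otherwise."""
    yA = np.atleast_2d(np.asarray(yA_row, dtype=float))
    yB = np.atleast_2d(np.asarray(yB_row, dtype=float))
    if not np.array_equal(np.isnan(yA), np.isnan(yB)):
        raise ValueError("paired rows must share missingness")
    obs = ~np.isnan(yA)
    if not obs.any():
        raise ValueError("site has no observed occasions")
    return float(np.exp(_site_logliks(params, yA, yB, obs)[0]))


def _unpack(theta, spec: CoOccModelSpec, Xcov=None):
    """Map the unconstrained parameter vector to probability-scale
    CoOccParams, honouring the spec's aliasing."""
    i = 0
    l_psiA = theta[i]; i += 1
    l_BA = theta[i]; i += 1
    l_Ba = theta[i] if spec.psi_conditional else l_BA
    if spec.psi_conditional:
        i += 1
    ncov = len(spec.covariate_names)
    if ncov:
        slopes = theta[i:i + ncov]
        i += ncov
        shift = Xcov @ slopes
        eta_BA, eta_Ba = l_BA + shift, l_Ba + shift
    else:
        eta_BA, eta_Ba = l_BA, l_Ba
    l_pA = theta[i]; i += 1
    l_pB = theta[i]; i += 1
    if spec.det_conditional:
        l_rA, l_rBA, l_rBa = theta[i], theta[i + 1], theta[i + 2]
        i += 3
    else:
        l_rA, l_rBA, l_rBa = l_pA, l_pB, l_pB
    c = lambda v: expit(np.clip(v, -ETA_CLIP, ETA_CLIP))
    return CoOccParams(psiA=c(l_psiA), psiBA=c(eta_BA), psiBa=c(eta_Ba),
                       pA=c(l_pA), pB=c(l_pB), rA=c(l_rA),
                       rBA=c(l_rBA), rBa=c(l_rBa))


@dataclass
class CoOccFit:
    """Fitted co-occurrence model: probability-scale estimates with SEs,
    the interaction factors, and selection quantities."""

    spec: CoOccModelSpec
    estimates: dict                 # probability scale, aliased params equal
    ses: dict
    loglik: float
    aicc: float
    k: int
    phi: float
    delta: float | None
    theta: np.ndarray
    cov: np.ndarray
    data: CoOccData
    converged: bool
    covariates: np.ndarray | None = None

    def to_report(self) -> dict:
        ests = {rk: float(np.mean(self.estimates[pn]))
                for rk, pn in zip(REPORT_KEYS, PARAM_NAMES)}
        return {
            "model": self.spec.label,
            "parameters": ests,
            "ses": {rk: float(np.mean(self.ses[pn]))
                    for rk, pn in zip(REPORT_KEYS, PARAM_NAMES)},
            "loglik": self.loglik,
            "aicc": self.aicc,
            "k": self.k,
            "SIF": self.phi,
            "DIF": self.delta,
        }


def fit_cooc(data: CoOccData, spec: CoOccModelSpec | None = None,
             covariates: np.ndarray | None = None) -> CoOccFit:
    """Maximum-likelihood fit of a psiBa-parameterization variant.

    Parameters are logit-transformed; optimisation is BFGS from the same
    deterministic multi-start scheme as the single-species engine.  AICc
    uses n = number of sites.  Phi is computed from the estimates; delta
    only for detection-conditional variants.
    """
    if spec is None:
        spec = CoOccModelSpec()
    yA, yB = data.history_A.matrix, data.history_B.matrix
    obs = ~np.isnan(yA)
    for h, which in ((data.history_A, "A"), (data.history_B, "B")):
        if h.n_detections() == 0:
            raise ValueError(f"species {which} ({h.species or which!r}) has no detections")
    Xcov = None
    if spec.covariate_names:
        if covariates is None:
            raise ValueError("spec names covariates but none were passed")
        Xcov = np.asarray(covariates, dtype=float)
        if Xcov.ndim == 1:
            Xcov = Xcov[:, None]
        if Xcov.shape[1] != len(spec.covariate_names):
            raise ValueError("covariate matrix width does not match spec")

    yAf, yBf = np.nan_to_num(yA), np.nan_to_num(yB)
    naive_A = float(np.clip(((yAf == 1) & obs).any(axis=1).mean(), 0.05, 0.95))
    naive_B = float(np.clip(((yBf == 1) & obs).any(axis=1).mean(), 0.05, 0.95))
    naive_pA = float(np.clip(yAf[obs].mean() / max(naive_A, 0.05), 0.02, 0.9))
    naive_pB = float(np.clip(yBf[obs].mean() / max(naive_B, 0.05), 0.02, 0.9))

    k = spec.n_params
    ncov = len(spec.covariate_names)

    def start_vector(dpsi, dp):
        th = []
        th.append(logit(naive_A) + dpsi)
        th.append(logit(naive_B) + dpsi)
        if spec.psi_conditional:
            th.append(logit(naive_B) + dpsi)
        th.extend([0.0] * ncov)
        th.append(logit(naive_pA) + dp)
        th.append(logit(naive_pB) + dp)
        if spec.det_conditional:
            th.extend([logit(naive_pA) + dp, logit(naive_pB) + dp,
                       logit(naive_pB) + dp])
        return np.array(th)

    def nll(theta):
        params = _unpack(theta, spec, Xcov)
        return -_site_logliks(params, yA, yB, obs).sum()

    best = None
    for dpsi, dp in MULTISTART_OFFSETS:
        res = minimize(nll, start_vector(dpsi, dp), method="BFGS",
                       options={"gtol": 1e-6, "maxiter": 1000})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    theta = best.x
    loglik = float(-best.fun)

    eps = 1e-5

    def grad(th):
        g = np.empty_like(th)
        for j in range(len(th)):
            tp, tm = th.copy(), th.copy()
            tp[j] += eps
            tm[j] -= eps
            g[j] = (nll(tp) - nll(tm)) / (2 * eps)
        return None, g

    H = _numeric_hessian(grad, theta, eps=1e-4)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    se_theta = np.sqrt(np.clip(np.diag(cov), 0, None))

    params = _unpack(theta, spec, Xcov)
    est = params.as_dict()

    # delta-method SEs on the probability scale; aliased parameters share SEs
    idx = _theta_index(spec)
    ses = {}
    for pn in PARAM_NAMES:
        j = idx[pn]
        prob = np.mean(est[pn])
        ses[pn] = se_theta[j] * prob * (1 - prob)

    phi = species_interaction_factor(float(params.psiA),
                                     float(np.mean(params.psiBA)),
                                     float(np.mean(params.psiBa)))
    delta = (detection_interaction_factor(params.rA, params.rBA, params.rBa)
             if spec.det_conditional else None)
    n = data.n_sites
    return CoOccFit(spec=spec, estimates=est, ses=ses, loglik=loglik,
                    aicc=aicc(loglik, k, n) if n > k + 1 else np.nan, k=k,
                    phi=phi, delta=delta, theta=theta, cov=cov, data=data,
                    converged=bool(best.success or np.linalg.norm(best.jac) < 1e-3),
                    covariates=Xcov)


def _theta_index(spec: CoOccModelSpec) -> dict:
    """Position of each (possibly aliased) parameter in the theta vector."""
    i = 0
    idx = {"psiA": i}; i += 1
    idx["psiBA"] = i; i += 1
    idx["psiBa"] = i if spec.psi_conditional else idx["psiBA"]
    if spec.psi_conditional:
        i += 1
    i += len(spec.covariate_names)
    idx["pA"] = i; i += 1
    idx["pB"] = i; i += 1
    if spec.det_conditional:
        idx["rA"], idx["rBA"], idx["rBa"] = i, i + 1, i + 2
    else:
        idx["rA"], idx["rBA"], idx["rBa"] = idx["pA"], idx["pB"], idx["pB"]
    return idx


def simulate_pair_matrices(params: CoOccParams, obs: np.ndarray,
                           rng: np.random.Generator):
    """Draw paired detection matrices given the latent four-state
    distribution and the rBA/rBa same-occasion conditioning.  ``obs`` is
    the surveyed-cell mask; unsurveyed cells come back NaN."""
    n, J = obs.shape
    zA = rng.random(n) < params.psiA
    psiBA = np.broadcast_to(params.psiBA, (n,))
    psiBa = np.broadcast_to(params.psiBa, (n,))
    zB = np.where(zA, rng.random(n) < psiBA, rng.random(n) < psiBa)

    pA_eff = np.where(zA & zB, params.rA, params.pA)
    yA = (rng.random((n, J)) < pA_eff[:, None]) & zA[:, None]
    both = (zA & zB)[:, None]
    rB = np.where(yA, params.rBA, params.rBa)
    pB_eff = np.where(both, rB, params.pB)
    yB = (rng.random((n, J)) < pB_eff) & zB[:, None]

    yA = np.where(obs, yA.astype(float), np.nan)
    yB = np.where(obs, yB.astype(float), np.nan)
    return yA, yB, zA, zB


def bootstrap_interaction_factors(fit: CoOccFit, n_boot: int = 500,
                                  seed: int = 0) -> dict:
    """Parametric-bootstrap percentile intervals for the SIF (and DIF when
    the variant is detection-conditional).  Ratio statistics have skewed
    sampling distributions, so the bootstrap replaces the delta method."""
    obs = ~np.isnan(fit.data.history_A.matrix)
    params = _unpack(fit.theta, fit.spec, fit.covariates)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB007]))
    phis, deltas = [], []
    failures = 0
    for _ in range(n_boot):
        yA, yB, _, _ = simulate_pair_matrices(params, obs, rng)
        effort = np.where(obs, fit.data.history_A.effort, 0)
        try:
            hA = DetectionHistory("A", fit.data.history_A.station_ids, yA, effort)
            hB = DetectionHistory("B", fit.data.history_B.station_ids, yB, effort)
            bfit = fit_cooc(CoOccData(hA, hB), fit.spec,
                            covariates=fit.covariates)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        phis.append(bfit.phi)
        if bfit.delta is not None:
            deltas.append(bfit.delta)
    if failures > 0.5 * n_boot:
        warnings.warn(f"{failures}/{n_boot} bootstrap refits failed", stacklevel=2)
    out = {"phi": fit.phi,
           "phi_ci": (float(np.percentile(phis, 2.5)),
                      float(np.percentile(phis, 97.5))),
           "n_boot": len(phis), "seed": int(seed)}
    if deltas:
        out["delta"] = fit.delta
        out["delta_ci"] = (float(np.percentile(deltas, 2.5)),
                           float(np.percentile(deltas, 97.5)))
    return out
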