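"""Occupancy residuals and spatial autocorrelation diagnostics.

Residuals for the occupancy component are the difference between the
site's conditional occupancy (given its detection history) and its
modelled occupancy probability.  Global structure is tested with Moran's I
under row-standardised inverse-distance weights; scale-dependence is
inspected with a distance-binned correlogram against a permutation
envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .occupancy import OccuFitBayes, _prepare, _probs, conditional_occupancy

EARTH_RADIUS_M = 6_371_000.0


def haversine_matrix(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix in metres from lon/lat degrees."""
    lam, phi = np.deg2rad(lon), np.deg2rad(lat)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (np.sin(dphi / 2) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2)
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def distance_matrix(x: np.ndarray, y: np.ndarray,
                    coord_system: str = "planar") -> np.ndarray:
    """Pairwise station distances in metres (Euclidean for planar
    coordinates, haversine for lon/lat)."""
    if coord_system == "lonlat":
        return haversine_matrix(np.asarray(x, float), np.asarray(y, float))
    pts = np.column_stack([x, y]).astype(float)
    return squareform(pdist(pts))


def inverse_distance_weights(dist: np.ndarray) -> np.ndarray:
    """Row-standardised 1/d weights with zero diagonal; duplicate
    coordinates (zero off-diagonal distance) are rejected."""
    d = np.asarray(dist, dtype=float)
    off = ~np.eye(len(d), dtype=bool)
    if (d[off] == 0).any():
        raise ValueError("duplicate coordinates produce infinite weights")
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    return w / w.sum(axis=1, keepdims=True)


def occupancy_residuals(fit, data=None) -> np.ndarray:
    """Per-site occupancy residuals.

    ML: Pr(z_i = 1 | history) - psi_hat_i.  Bayes: the mean over posterior
    draws of z_i^(s) - psi_i^(s), with z sampled from its conditional given
    the history (seeded from the fit's own seed).
    """
    if data is None:
        data = fit.data
    if isinstance(fit, OccuFitBayes):
        yf, obs, never = _prepare(data)
        X, W = fit.designs.X, fit.designs.W
        kpsi = X.shape[1]
        rng = np.random.default_rng(np.random.SeedSequence([fit.seed, 0x2E5]))
        flat = fit.flat_draws()
        total = np.zeros(data.n_sites)
        for theta in flat:
            psi, p = _probs(theta[:kpsi], theta[kpsi:], X, W)
            cond = np.where(obs, np.log1p(-p), 0.0).sum(axis=1)
            num = psi * np.exp(cond)
            c = np.where(never, num / (num + 1 - psi), 1.0)
            z = (rng.random(data.n_sites) < c).astype(float)
            total += z - psi
        return total / len(flat)
    psi, _ = _probs(fit.params.beta, fit.params.alpha,
                    fit.designs.X, fit.designs.W)
    return conditional_occupancy(fit, data) - psi


@dataclass
class MoranResult:
    I: float
    expectation: float      # -1/(n-1)
    variance: float         # normal approximation
    z: float
    p_value: float          # two-sided
    n: int


def morans_i(residuals: np.ndarray, weights: np.ndarray) -> MoranResult:
    """Global Moran's I with normal-approximation inference.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    """
    x = np.asarray(residuals, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 sites")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("constant residuals: Moran's I undefined")
    S0 = w.sum()
    I = (n / S0) * float(xc @ w @ xc) / denom
    E = -1.0 / (n - 1)
    S1 = 0.5 * ((w + w.T) ** 2).sum()
    S2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    var = ((n * n * S1 - n * S2 + 3 * S0 * S0)
           / ((n * n - 1) * S0 * S0)) - E * E
    z = (I - E) / np.sqrt(var)
    from scipy.stats import norm
    p = 2 * norm.sf(abs(z))
    return MoranResult(I=float(I), expectation=E, variance=float(var),
                       z=float(z), p_value=float(p), n=n)


@dataclass
class Correlogram:
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    I: np.ndarray
    env_lo: np.ndarray
    env_hi: np.ndarray
    n_pairs: np.ndarray
    reliable: np.ndarray    # bins with >= 20 pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers, "I": self.I,
                             "lo": self.env_lo, "hi": self.env_hi,
                             "n_pairs": self.n_pairs,
                             "reliable": self.reliable})


def distance_correlogram(residuals: np.ndarray, coords: np.ndarray,
                         coord_system: str = "planar", n_bins: int = 8,
                         n_perms: int = 999, seed: int = 0) -> Correlogram:
    """Distance-binned Moran's I correlogram with a permutation envelope.

    Bins hold roughly equal numbers of site pairs; within a bin the
    weights are binary membership indicators.  The 2.5/97.5% envelope
    comes from shuffling residuals over sites.
    """
    x = np.asarray(residuals, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 sites for a correlogram")
    coords = np.asarray(coords, dtype=float)
    dist = distance_matrix(coords[:, 0], coords[:, 1], coord_system)
    iu = np.triu_indices(n, k=1)
    dvals = dist[iu]
    if dvals.max() == 0:
        raise ValueError("all sites share one location")
    edges = np.quantile(dvals, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = 0.0, dvals.max() + 1e-9
    edges = np.unique(edges)
    nb = len(edges) - 1

    xc = x - x.mean()
    denom = float(xc @ xc)
    bin_idx = np.searchsorted(edges, dvals, side="right") - 1
    bin_idx = np.clip(bin_idx, 0, nb - 1)
    n_pairs = np.bincount(bin_idx, minlength=nb)

    def bin_I(values):
        vc = values - values.mean()
        d = float(vc @ vc)
        prod = vc[iu[0]] * vc[iu[1]]
        sums = np.bincount(bin_idx, weights=prod, minlength=nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (n / (2 * n_pairs)) * (2 * sums) / d

    I_obs = bin_I(x)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0E]))
    perms = np.empty((n_perms, nb))
    for k in range(n_perms):
        perms[k] = bin_I(rng.permutation(x))
    lo = np.nanpercentile(perms, 2.5, axis=0)
    hi = np.nanpercentile(perms, 97.5, axis=0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Correlogram(bin_edges=edges, bin_centers=centers, I=I_obs,
                       env_lo=lo, env_hi=hi, n_pairs=n_pairs,
                       reliable=n_pairs >= 20)
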