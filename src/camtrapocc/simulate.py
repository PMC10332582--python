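"""Synthetic camera-trap data generators.

The generators invert the occupancy hierarchy (draw z, then y given z) so
that every downstream stage — history construction, fitting, selection,
GOF, spatial diagnostics, co-occurrence — can be exercised and validated
against known truth without any field data.  The study-design preset
mirrors a three-reserve cloud-forest survey: 58 stations, ~130 ± 24 day
deployments collapsed to 7-day occasions (19 max), null-model habitat use
0.68 and weekly detectability 0.15.

A deterministic survey fixture reproducing the printed per-reserve effort,
detection counts and camera-array MCP areas of that survey is also
provided (synthetic stand-in: the study deposited no raw data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cooccurrence import CoOccData, CoOccParams, simulate_pair_matrices
from .covariates import DesignMatrices, build_design
from .survey import DetectionHistory


@dataclass
class SimScenario:
    """Generative truth for a single- or paired-species simulation."""

    n_sites: int = 58
    n_occasions: int = 19
    occasion_days: int = 7
    psi: float | None = 0.68            # scalar truth, or use beta/alpha
    p: float | None = 0.15
    beta: np.ndarray | None = None      # logit-scale occupancy coefficients
    alpha: np.ndarray | None = None
    psi_terms: list = field(default_factory=list)
    p_terms: list = field(default_factory=list)
    n_categorical_levels: int = 2       # for a "cat" detection covariate
    missing_rate: float = 0.0           # random mid-survey gap probability
    deployment_mean: float | None = None   # days; None = full grid
    deployment_sd: float = 24.0
    cooc: dict | None = None            # psiA..rBa for paired scenarios
    extra_covariates: list = field(default_factory=list)  # inert columns
    seed: int = 0

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), salt]))


def _covariate_table(scenario: SimScenario, rng) -> pd.DataFrame:
    """Standard-normal numeric covariates plus a two-level categorical,
    covering every term the scenario's submodels name."""
    n = scenario.n_sites
    cols = {"station_id": [f"S{i + 1:03d}" for i in range(n)]}
    needed = set()
    for t in (scenario.psi_terms + scenario.p_terms
              + list(scenario.extra_covariates)):
        if t == "effort":
            continue
        needed.add(t[:-2] if t.endswith("^2") else t)
    for name in sorted(needed):
        if name == "cat":
            levels = [chr(ord("a") + k) for k in range(scenario.n_categorical_levels)]
            cols[name] = [levels[i % len(levels)] for i in range(n)]
        else:
            cols[name] = rng.standard_normal(n)
    return pd.DataFrame(cols)


def _effort_matrix(scenario: SimScenario, rng) -> np.ndarray:
    """Per-cell effort: trailing truncation from truncated-normal
    deployment lengths plus optional random mid-survey gaps."""
    n, J, od = scenario.n_sites, scenario.n_occasions, scenario.occasion_days
    effort = np.full((n, J), od, dtype=int)
    if scenario.deployment_mean is not None:
        days = rng.normal(scenario.deployment_mean, scenario.deployment_sd, n)
        days = np.clip(np.round(days), 30, J * od).astype(int)
        for i, d in enumerate(days):
            full, rem = divmod(int(d), od)
            effort[i, :] = 0
            effort[i, :full] = od
            if full < J and rem:
                effort[i, full] = rem
    if scenario.missing_rate > 0:
        gaps = rng.random((n, J)) < scenario.missing_rate
        active = effort > 0
        # never blank a site's every occasion
        for i in range(n):
            if (gaps[i] & active[i]).sum() >= active[i].sum():
                gaps[i, np.flatnonzero(active[i])[0]] = False
        effort[gaps] = 0
    return effort


def _design_for(scenario: SimScenario, table: pd.DataFrame,
                effort: np.ndarray) -> DesignMatrices:
    return build_design(table, scenario.psi_terms, scenario.p_terms,
                        n_occasions=scenario.n_occasions, effort=effort)


def simulate_single(scenario: SimScenario):
    """Draw one single-species dataset.

    Returns (DetectionHistory, covariate table, truth record).  Truth holds
    the realised z vector and the generating parameters for recovery tests.
    """
    rng = scenario.rng(0x51)
    table = _covariate_table(scenario, rng)
    effort = _effort_matrix(scenario, rng)
    obs = effort > 0
    designs = _design_for(scenario, table, effort)

    if scenario.beta is not None:
        beta = np.atleast_1d(np.asarray(scenario.beta, float))
        psi = expit(designs.X @ beta)
    else:
        beta = np.array([logit(scenario.psi)])
        psi = np.full(scenario.n_sites, scenario.psi)
    if scenario.alpha is not None:
        alpha = np.atleast_1d(np.asarray(scenario.alpha, float))
        p = expit(designs.W @ alpha)
    else:
        alpha = np.array([logit(scenario.p)])
        p = np.full((scenario.n_sites, scenario.n_occasions), scenario.p)

    z = rng.random(scenario.n_sites) < psi
    y = (rng.random(p.shape) < p) & z[:, None]
    matrix = np.where(obs, y.astype(float), np.nan)
    history = DetectionHistory(species="simulated",
                               station_ids=list(table["station_id"]),
                               matrix=matrix, effort=effort,
                               occasion_days=scenario.occasion_days)
    truth = {"beta": beta, "alpha": alpha, "psi": psi, "p": p, "z": z,
             "seed": scenario.seed}
    return history, table, truth


def simulate_cooc(scenario: SimScenario):
    """Draw one paired-species dataset under the psiBa parameterization.

    The joint latent state comes from the four-cell distribution
    (psiA*psiBA, psiA*(1-psiBA), (1-psiA)*psiBa, (1-psiA)*(1-psiBa)); B's
    occasion-level detection switches between rBA and rBa with A's
    same-occasion detection.
    """
    if scenario.cooc is None:
        raise ValueError("scenario.cooc must supply the paired truth")
    rng = scenario.rng(0xC0)
    effort = _effort_matrix(scenario, rng)
    obs = effort > 0
    params = CoOccParams(**scenario.cooc)
    yA, yB, zA, zB = simulate_pair_matrices(params, obs, rng)
    ids = [f"S{i + 1:03d}" for i in range(scenario.n_sites)]
    hA = DetectionHistory("species_A", ids, yA, effort,
                          occasion_days=scenario.occasion_days)
    hB = DetectionHistory("species_B", ids, yB, effort,
                          occasion_days=scenario.occasion_days)
    truth = {"params": params, "zA": zA, "zB": zB, "seed": scenario.seed}
    return CoOccData(history_A=hA, history_B=hB), truth


def scenario_middle_cauca(seed: int = 0) -> SimScenario:
    """The study-design preset: 58 stations, 19 weekly occasions, habitat
    use 0.68, weekly detectability 0.15, deployment lengths
    Normal(130, 24) truncated at 30 days (trailing missingness)."""
    return SimScenario(n_sites=58, n_occasions=19, occasion_days=7,
                       psi=0.68, p=0.15, deployment_mean=130.0,
                       deployment_sd=24.0, seed=seed)


# ---------------------------------------------------------------------------
# Deterministic survey fixture reproducing the printed survey totals
# (synthetic stand-in for the undeposited field data).

_BLOCKS = [
    # block_id, n_stations, effort (trap-nights), mcp_km2 (rect width m x height m)
    ("MPNR", 19, 4518, (5000.0, 5314.0)),     # 26.57 km^2
    ("CSJIMD", 19, 2829, (5000.0, 5298.0)),   # 26.49 km^2
    ("CSCD", 20, 3342, (5000.0, 4204.0)),     # 21.02 km^2
]

# species label -> per-block (daily count, 7-day occasion count)
_SPECIES_COUNTS = {
    "tiger_cat": [(109, 70), (56, 46), (16, 13)],
    "tayra": [(89, 63), (52, 41), (17, 14)],
    "killers": [(54, 46), (17, 16), (12, 11)],
    "prey": [(532, 184), (215, 119), (218, 120)],
}


def survey_fixture():
    """Deterministic stations + independence-filtered records whose survey
    summary reproduces the printed per-reserve trap-nights, 7-day and daily
    independent detection counts, and camera-array MCP areas.

    Station layouts are rectangles of the printed MCP area with cameras on
    the corners, so the convex hull is exact.  Detections are laid out one
    per 7-day occasion first (occasion counts), then extra records are
    added on further days of already-detected occasions (daily counts).
    """
    station_rows, record_rows = [], []
    x_offset = 0.0
    for b, (block, n_st, eff, (wx, wy)) in enumerate(_BLOCKS):
        base_days, rem = divmod(eff, n_st)
        act = pd.Timestamp("2021-01-01")
        per_station_days = [base_days + (1 if i < rem else 0) for i in range(n_st)]
        for i, days in enumerate(per_station_days):
            gx = i % 5
            gy = i // 5
            # pin the first four stations to the rectangle corners
            corner = [(0, 0), (wx, 0), (0, wy), (wx, wy)]
            if i < 4:
                x, y = corner[i]
            else:
                x = (gx + 0.5) * wx / 5
                y = (gy + 0.5) * wy / 4
            station_rows.append({
                "station_id": f"{block}-{i + 1:02d}",
                "x": x + x_offset, "y": y, "coord_system": "planar",
                "activation_date": act,
                "retrieval_date": act + pd.Timedelta(days=days - 1),
                "pir_delay_class": "<=0.6s" if i % 2 == 0 else ">0.6s",
                "block_id": block,
            })
        x_offset += 60_000.0

        for species, counts in _SPECIES_COUNTS.items():
            daily, weekly = counts[b]
            slots = []   # (station index, occasion index) with capacity
            for i, days in enumerate(per_station_days):
                for j in range(int(np.ceil(days / 7))):
                    slots.append((i, j, days))
            placed = []
            for w in range(weekly):
                i, j, days = slots[w]
                placed.append((i, j, days, 0))
            extra = daily - weekly
            depth = 1
            while extra > 0:
                for w in range(weekly):
                    if extra == 0:
                        break
                    i, j, days = slots[w]
                    if j * 7 + depth < days and depth < 7:
                        placed.append((i, j, days, depth))
                        extra -= 1
                depth += 1
                if depth >= 7:
                    raise RuntimeError("fixture cannot place all daily detections")
            for i, j, days, d in placed:
                record_rows.append({
                    "station_id": f"{block}-{i + 1:02d}",
                    "species": species,
                    "timestamp": act + pd.Timedelta(days=j * 7 + d, hours=12),
                })
    stations = pd.DataFrame(station_rows)
    records = pd.DataFrame(record_rows)
    records["timestamp"] = pd.to_datetime(records["timestamp"])
    return records, stations
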