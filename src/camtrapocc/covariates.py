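"""Covariate standardisation, collinearity screening, landscape PCA and
design-matrix assembly for the occupancy (ψ) and detection (p) submodels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def zscore(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Standardise the named numeric columns to mean 0, sample SD 1
    ((x - mean) / SD, ddof=1).  Missing cells propagate; a constant column
    is an error."""
    out = table.copy()
    for col in columns:
        x = pd.to_numeric(out[col])
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} is constant; cannot z-scale")
        out[col] = (x - x.mean()) / sd
    return out


def correlation_screen(table: pd.DataFrame, threshold: float = 0.65,
                       columns: list[str] | None = None) -> pd.DataFrame:
    """Flag covariate pairs with |Pearson r| strictly above ``threshold``.

    Uses pairwise-complete rows; pairs with fewer than 3 complete rows are
    reported as not evaluable.  Returns a frame with columns
    (var1, var2, r, flagged, evaluable); r is rounded to 2 decimals.
    """
    if columns is None:
        columns = [c for c in table.columns
                   if pd.api.types.is_numeric_dtype(table[c])]
    if len(columns) < 2:
        raise ValueError("need at least 2 numeric columns to screen")
    rows = []
    for a_i, a in enumerate(columns):
        for b in columns[a_i + 1:]:
            sub = table[[a, b]].dropna()
            if len(sub) < 3:
                rows.append({"var1": a, "var2": b, "r": np.nan,
                             "flagged": False, "evaluable": False})
                continue
            r = float(np.corrcoef(sub[a], sub[b])[0, 1])
            rows.append({"var1": a, "var2": b, "r": round(r, 2),
                         "flagged": bool(abs(r) > threshold),
                         "evaluable": True})
    return pd.DataFrame(rows)


@dataclass
class PcaSummary:
    """Correlation-matrix PCA of landscape metrics.

    Components with eigenvalue > 1 are retained (Kaiser rule).  The sign of
    PC1 is fixed so that the first metric's ("forest amount" style) loading
    is negative: negative scores then read as a gradient of increasing
    forest amount and cohesion.
    """

    eigenvalues: np.ndarray          # descending
    loadings: np.ndarray             # metrics x components, unit-norm columns
    scores: np.ndarray               # stations x retained components
    scores_all: np.ndarray           # stations x all components
    n_retained: int
    metric_names: list[str]


def pca_landscape(table: pd.DataFrame,
                  columns: list[str] | None = None) -> PcaSummary:
    """PCA of landscape metrics on the correlation matrix, summarising
    correlated metrics into a composite landscape-structure covariate."""
    if columns is None:
        columns = list(table.columns)
    if len(columns) < 2:
        raise ValueError("need at least 2 metric columns")
    X = table[columns].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing cells not allowed in landscape PCA")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = columns[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"metric {bad!r} is constant")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    if evecs[0, 0] > 0:   # anchor PC1 sign to the forest-amount metric
        evecs[:, 0] = -evecs[:, 0]
    n_keep = int((evals > 1.0).sum())
    scores_all = Z @ evecs
    return PcaSummary(eigenvalues=evals, loadings=evecs,
                      scores=scores_all[:, :n_keep], scores_all=scores_all,
                      n_retained=n_keep, metric_names=list(columns))


@dataclass
class DesignMatrices:
    """Design matrices for the logit-linear ψ and p submodels.

    ``X`` (sites × k_ψ) enters logit(ψ_i) = x_i·β; ``W`` (sites × occasions
    × k_p) enters logit(p_ij) = w_ij·α.  First column of each is the
    intercept.  Quadratic terms ("name^2") square the already-scaled base
    column; categoricals are dummy-coded against the alphabetically first
    level; the occasion-level term "effort" draws from the effort matrix,
    z-scaled across all surveyed cells.
    """

    X: np.ndarray
    W: np.ndarray
    psi_names: list[str]
    p_names: list[str]
    reference_levels: dict[str, str]


def _term_columns(table: pd.DataFrame, term: str,
                  reference_levels: dict[str, str]):
    """Expand one term into (column array list, name list)."""
    if term.endswith("^2"):
        base = term[:-2]
        if base not in table.columns:
            raise ValueError(f"unknown term {base!r}")
        if not pd.api.types.is_numeric_dtype(table[base]):
            raise ValueError(f"quadratic term on categorical {base!r}")
        col = table[base].to_numpy(dtype=float) ** 2
        return [col], [term]
    if term not in table.columns:
        raise ValueError(f"unknown term {term!r}")
    s = table[term]
    if pd.api.types.is_numeric_dtype(s):
        return [s.to_numpy(dtype=float)], [term]
    levels = sorted(map(str, s.unique()))
    ref = levels[0]
    reference_levels[term] = ref
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((s.astype(str) == lev).to_numpy(dtype=float))
        names.append(f"{term}[{lev}]")
    return cols, names


def build_design(table: pd.DataFrame, psi_terms: list[str],
                 p_terms: list[str], n_occasions: int | None = None,
                 effort: np.ndarray | None = None) -> DesignMatrices:
    """Assemble X (ψ) and W (p) with intercepts from a station-keyed
    covariate table.  Site-level p-terms are broadcast across occasions."""
    n = len(table)
    refs: dict[str, str] = {}

    X_cols, X_names = [np.ones(n)], ["(Intercept)"]
    for term in psi_terms:
        cols, names = _term_columns(table, term, refs)
        X_cols.extend(cols)
        X_names.extend(names)
    X = np.column_stack(X_cols)

    if n_occasions is None:
        n_occasions = effort.shape[1] if effort is not None else 1
    J = n_occasions
    W_cols, W_names = [np.ones((n, J))], ["(Intercept)"]
    for term in p_terms:
        if term == "effort":
            if effort is None:
                raise ValueError("term 'effort' requires an effort matrix")
            e = effort.astype(float)
            obs = e > 0
            mu, sd = e[obs].mean(), e[obs].std(ddof=1)
            if sd == 0:
                scaled = np.zeros_like(e)
            else:
                scaled = (e - mu) / sd
            W_cols.append(scaled)
            W_names.append("effort")
            continue
        cols, names = _term_columns(table, term, refs)
        for c, nm in zip(cols, names):
            W_cols.append(np.repeat(c[:, None], J, axis=1))
            W_names.append(nm)
    W = np.stack(W_cols, axis=2)
    return DesignMatrices(X=X, W=W, psi_names=X_names, p_names=W_names,
                          reference_levels=refs)
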