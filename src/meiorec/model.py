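"""Joint-site feature matrix, PCA and forward-selection linear models.

Chromatin variables are summarised at joint PRDM9–DSB sites at two scales —
the local value at the site bin and the mean over a ±250-kb window (the
"500-kb average") — standardized, and reduced by PCA.  DSB activity at
PRDM9 sites and crossover likelihood at DSB sites are then modelled by
ordinary least squares with forward selection: at each step the candidate
with the smallest entry p-value joins the model if it passes the
Bonferroni-corrected threshold ``alpha / n_candidates``.  Adjustment
covariates (binding score, fractional chromosomal position) compete in the
selection like every other candidate rather than being forced in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .binning import BinnedTrack
from .recombination import SiteSet


@dataclass
class FeatureMatrix:
    """Standardized site-by-feature matrix with row/column metadata."""

    X: np.ndarray                 # (n_sites, n_cols), column mean 0 / sd 1
    columns: list[str]
    rows: pd.DataFrame            # bin_id + response/adjustment scores per kept site
    n_dropped_rows: int
    dropped_columns: list[str]


@dataclass
class PcaResult:
    loadings: np.ndarray          # (n_components, n_cols), orthonormal rows
    explained_variance_ratio: np.ndarray
    scores: np.ndarray            # (n_sites, n_components)
    columns: list[str]


@dataclass
class ModelFit:
    """Forward-selected OLS fit with its naive baseline."""

    response: str
    selected: list[str]           # in selection order
    coef: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    r2: float
    naive_r2: float
    naive_predictors: list[str]
    threshold: float
    n_obs: int


def standardize(X: np.ndarray) -> np.ndarray:
    """Column-wise zero-mean unit-sd scaling (idempotent)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def build_feature_matrix(
    joint_sites: SiteSet,
    variables: dict[str, BinnedTrack],
    bins,
    window_bins: int = 50,
) -> FeatureMatrix:
    """Two columns per variable: local value at the site bin and the mean
    over the site ± ``window_bins`` bins (501 kb by default at 5-kb bins),
    computed ignoring missing bins and clipped at chromosome ends.  Rows
    with any missing feature are dropped (counted); zero-variance columns
    are dropped with a warning before scaling."""
    ids = joint_sites.bin_ids
    cols, names = [], []
    for name, track in variables.items():
        v = track.values
        local = v[ids]
        win = np.empty(len(ids))
        for k, b in enumerate(ids):
            chrom = joint_sites.table["chrom"].iloc[k]
            sl = bins.chrom_slice(chrom)
            lo = max(sl.start, b - window_bins)
            hi = min(sl.stop, b + window_bins + 1)
            w = v[lo:hi]
            good = np.isfinite(w)
            win[k] = w[good].mean() if good.any() else np.nan
        cols += [local, win]
        names += [f"{name}_local", f"{name}_win"]
    X = np.column_stack(cols)
    keep_rows = np.isfinite(X).all(axis=1)
    n_dropped = int((~keep_rows).sum())
    X = X[keep_rows]
    if X.shape[0] == 0:
        raise ValueError("all rows dropped: every site has a missing feature")
    sd = X.std(axis=0)
    dropped_cols = [n for n, s in zip(names, sd) if s == 0]
    if dropped_cols:
        warnings.warn(f"dropping zero-variance feature columns: {dropped_cols}")
    keep_cols = sd > 0
    X = standardize(X[:, keep_cols])
    return FeatureMatrix(
        X=X,
        columns=[n for n, k in zip(names, keep_cols) if k],
        rows=joint_sites.table[keep_rows].reset_index(drop=True),
        n_dropped_rows=n_dropped,
        dropped_columns=dropped_cols,
    )


def run_pca(fm: FeatureMatrix, n_components: int = 4) -> PcaResult:
    """PCA of the standardized feature matrix (SVD via scikit-learn).

    Sign convention: each loading vector is oriented so its
    largest-magnitude element is positive.
    """
    if fm.X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    if fm.X.shape[0] < fm.X.shape[1]:
        warnings.warn("fewer sites than feature columns; PCA may be unstable")
    n_components = min(n_components, *fm.X.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(fm.X)
    loadings = pca.components_.copy()
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return PcaResult(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=scores,
        columns=fm.columns,
    )


def forward_select_ols(
    response: np.ndarray,
    candidates: dict[str, np.ndarray],
    alpha_base: float = 0.001,
    naive_predictors: list[str] | None = None,
    response_name: str = "y",
    max_condition: float = 1e10,
) -> ModelFit:
    """Forward stepwise OLS under a Bonferroni entry threshold.

    Starting from an intercept-only model, each step fits the current model
    plus each remaining candidate and admits the one with the smallest entry
    p-value, provided ``p < alpha_base / n`` with ``n`` the total number of
    candidates; selection stops otherwise.  Ill-conditioned candidate
    additions (condition number > ``max_condition``) are skipped with a
    warning.  Ties in p-value resolve to the lexicographically smaller
    candidate name.
    """
    y = np.asarray(response, dtype=float)
    names = sorted(candidates)
    n_cand = len(names)
    threshold = alpha_base / n_cand
    selected: list[str] = []
    remaining = list(names)
    while remaining:
        best_name, best_p = None, np.inf
        for name in remaining:
            Xtry = np.column_stack(
                [candidates[c] for c in selected] + [candidates[name]]
            )
            Xtry = sm.add_constant(Xtry, has_constant="add")
            if np.linalg.cond(Xtry) > max_condition:
                warnings.warn(f"candidate {name!r} is collinear with the model; skipped")
                continue
            fit = sm.OLS(y, Xtry).fit()
            p = fit.pvalues[-1]
            if p < best_p:
                best_name, best_p = name, p
        if best_name is None or best_p >= threshold:
            break
        selected.append(best_name)
        remaining.remove(best_name)

    def _fit(pred_names):
        if pred_names:
            X = sm.add_constant(
                np.column_stack([candidates[c] for c in pred_names]), has_constant="add"
            )
        else:
            X = np.ones((len(y), 1))
        return sm.OLS(y, X).fit()

    final = _fit(selected)
    naive_predictors = [p for p in (naive_predictors or []) if p in candidates]
    naive = _fit(naive_predictors)
    coef = dict(zip(["const"] + selected, final.params))
    tv = dict(zip(["const"] + selected, final.tvalues))
    pv = dict(zip(["const"] + selected, final.pvalues))
    return ModelFit(
        response=response_name,
        selected=selected,
        coef=coef,
        tvalues=tv,
        pvalues=pv,
        r2=float(final.rsquared) if selected else 0.0,
        naive_r2=float(naive.rsquared) if naive_predictors else 0.0,
        naive_predictors=naive_predictors,
        threshold=threshold,
        n_obs=len(y),
    )


def fit_recombination_models(
    fm: FeatureMatrix,
    pca: PcaResult,
    prdm9_mask: np.ndarray,
    dsb_mask: np.ndarray,
    alpha_base: float = 0.001,
) -> dict[str, ModelFit]:
    """The three site-level models.

    * ``dsb``: DMC1 score at PRDM9 sites ~ PCs + PRDM9 score + position;
      naive baseline = PRDM9 score only.
    * ``crossover``: crossover score at DSB sites ~ PCs + DMC1 score +
      position; naive baseline = DMC1 score + position.
    * ``prdm9_to_crossover``: crossover score at PRDM9 sites ~ PCs + PRDM9
      score + position; naive baseline = PRDM9 score + position.

    ``prdm9_mask`` / ``dsb_mask`` are boolean row selectors over ``fm.rows``.
    """
    rows = fm.rows

    def _candidates(mask, score_col):
        cand = {
            f"PC{i+1}": pca.scores[mask, i] for i in range(pca.scores.shape[1])
        }
        cand[score_col] = rows[score_col].to_numpy(dtype=float)[mask]
        cand["position"] = rows["position"].to_numpy(dtype=float)[mask]
        return cand

    out = {}
    out["dsb"] = forward_select_ols(
        rows["dmc1"].to_numpy(dtype=float)[prdm9_mask],
        _candidates(prdm9_mask, "prdm9"),
        alpha_base=alpha_base,
        naive_predictors=["prdm9"],
        response_name="dmc1",
    )
    out["crossover"] = forward_select_ols(
        rows["crossover"].to_numpy(dtype=float)[dsb_mask],
        _candidates(dsb_mask, "dmc1"),
        alpha_base=alpha_base,
        naive_predictors=["dmc1", "position"],
        response_name="crossover",
    )
    out["prdm9_to_crossover"] = forward_select_ols(
        rows["crossover"].to_numpy(dtype=float)[prdm9_mask],
        _candidates(prdm9_mask, "prdm9"),
        alpha_base=alpha_base,
        naive_predictors=["prdm9", "position"],
        response_name="crossover",
    )
    return out
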