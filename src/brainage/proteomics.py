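"""Label-free proteomics downstream of the peptide intensity table.

Pipeline: log2 transform and quantile normalisation of peptide
intensities; left-censored (below-detection) entries imputed with a
censored-normal accelerated-failure-time model; Tukey median polish to
summarise peptides to proteins; complete-case filtering; moderated-t
differential abundance (delegating to the expression machinery); and
Spearman mRNA-protein correlation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm, spearmanr

from .de import DEResult, fit_moderated

__all__ = [
    "peptide_matrix",
    "normalize_peptides",
    "impute_censored",
    "median_polish",
    "median_polish_summarize",
    "filter_complete",
    "differential_abundance",
    "mrna_protein_correlation",
]


def peptide_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Long peptide table -> wide peptide x sample matrix (NaN = censored).

    Expects columns ``peptide_id, protein_id, sample_id, intensity``.
    Returns the matrix and the peptide -> protein map.
    """
    required = {"peptide_id", "protein_id", "sample_id", "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    if table.duplicated(subset=["peptide_id", "sample_id"]).any():
        raise ValueError("duplicate (peptide, sample) entries")
    wide = table.pivot(index="peptide_id", columns="sample_id",
                       values="intensity")
    prot = table.drop_duplicates("peptide_id").set_index("peptide_id")[
        "protein_id"].loc[wide.index]
    return wide, prot


def normalize_peptides(mat: pd.DataFrame, log_transform: bool = True
                       ) -> pd.DataFrame:
    """log2 transform and quantile-normalise peptide intensities.

    Quantile normalisation forces every sample's observed values onto the
    common distribution of per-rank means (ties averaged); censored (NaN)
    entries are excluded from the reference distribution and stay missing.
    """
    if mat.shape[1] < 2:
        raise ValueError("quantile normalisation needs >= 2 samples")
    zero_obs = mat.notna().sum(axis=0) == 0
    if zero_obs.any():
        raise ValueError(
            f"samples with zero observed peptides: {list(mat.columns[zero_obs])}")
    x = mat.to_numpy(dtype=float)
    if log_transform:
        if np.nanmin(x) <= 0:
            raise ValueError("intensities must be positive before log2")
        x = np.log2(x)
    n, m = x.shape
    # mean of sorted observed values at a common quantile grid
    grid = np.linspace(0.0, 1.0, n)
    ref = np.zeros(n)
    for j in range(m):
        col = np.sort(x[~np.isnan(x[:, j]), j])
        q = np.linspace(0.0, 1.0, col.size) if col.size > 1 else np.array([0.5])
        ref += np.interp(grid, q, col)
    ref /= m
    out = np.full_like(x, np.nan)
    for j in range(m):
        obs = ~np.isnan(x[:, j])
        col = x[obs, j]
        ranks = pd.Series(col).rank(method="average").to_numpy()  # 1..k, ties avg
        k = col.size
        q = (ranks - 1) / (k - 1) if k > 1 else np.array([0.5])
        out[obs, j] = np.interp(q, grid, ref)
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)


def _censored_normal_mle(obs: np.ndarray, cens_limits: np.ndarray
                         ) -> tuple[float, float]:
    """MLE of (mu, sigma) from observed values plus left-censoring limits."""
    mu0 = obs.mean() if obs.size else cens_limits.mean()
    sd0 = max(obs.std(ddof=0), 0.1) if obs.size > 1 else 1.0

    def nll(par: np.ndarray) -> float:
        mu, log_sd = par
        sd = np.exp(log_sd)
        val = -np.sum(norm.logpdf(obs, mu, sd))
        if cens_limits.size:
            val -= np.sum(norm.logcdf(cens_limits, mu, sd))
        return val

    res = minimize(nll, np.array([mu0, np.log(sd0)]), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 500})
    mu, sd = res.x[0], float(np.exp(res.x[1]))
    return float(mu), sd


def impute_censored(mat: pd.DataFrame) -> pd.DataFrame:
    """Impute left-censored peptide entries with an AFT-style model.

    Intensities being already on the log scale, the accelerated failure
    time model with normal errors reduces to a per-peptide censored-normal
    regression: censored entries are left-censored at their sample's
    minimum observed intensity (the detection limit proxy); the imputed
    value is the model's conditional expectation below the censor point,
    hence never exceeds it. Peptides censored in every sample are dropped
    with a warning.
    """
    x = mat.to_numpy(dtype=float).copy()
    det_limit = np.nanmin(x, axis=0)  # per-sample minimum observed
    all_missing = np.isnan(x).all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} peptides censored everywhere",
            stacklevel=2)
        mat = mat.loc[~all_missing]
        x = x[~all_missing]
    for i in range(x.shape[0]):
        miss = np.isnan(x[i])
        if not miss.any():
            continue
        obs = x[i, ~miss]
        limits = det_limit[miss]
        mu, sd = _censored_normal_mle(obs, limits)
        a = (limits - mu) / sd
        # E[Y | Y < limit] for a normal, guarded against tiny tail mass
        dens = np.exp(norm.logpdf(a) - np.clip(norm.logcdf(a), -700, 0))
        imput = mu - sd * dens
        x[i, miss] = np.minimum(imput, limits)
    return pd.DataFrame(x, index=mat.index, columns=mat.columns)


def median_polish(mat: np.ndarray, tol: float = 1e-4, max_iter: int = 10
                  ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey's two-way median polish (NaN-aware).

    Returns ``(overall, row_effects, col_effects, residuals)`` from
    alternating row and column median sweeps, stopped when the change in
    the total absolute residual falls below ``tol`` (relative) or after
    ``max_iter`` iterations.
    """
    r = np.array(mat, dtype=float)
    n_row, n_col = r.shape
    overall = 0.0
    row_eff = np.zeros(n_row)
    col_eff = np.zeros(n_col)
    last = np.nansum(np.abs(r))
    for _ in range(max_iter):
        rm = np.nanmedian(r, axis=1)
        rm[np.isnan(rm)] = 0.0
        r -= rm[:, None]
        row_eff += rm
        delta = np.nanmedian(col_eff)
        col_eff -= delta
        overall += delta
        cm = np.nanmedian(r, axis=0)
        cm[np.isnan(cm)] = 0.0
        r -= cm[None, :]
        col_eff += cm
        delta = np.nanmedian(row_eff)
        row_eff -= delta
        overall += delta
        total = np.nansum(np.abs(r))
        if last == 0 or abs(last - total) < tol * max(last, 1e-12):
            break
        last = total
    return overall, row_eff, col_eff, r


def median_polish_summarize(mat: pd.DataFrame, peptide_to_protein: pd.Series
                            ) -> pd.DataFrame:
    """Summarise peptide intensities to protein level by median polish.

    Protein abundance per sample = overall effect + column (sample)
    effects; peptide-specific offsets are absorbed by the row effects.
    Samples where every peptide of a protein is missing stay missing.
    """
    rows = {}
    for protein, peps in peptide_to_protein.groupby(peptide_to_protein):
        sub = mat.loc[peps.index]
        overall, _, col_eff, _ = median_polish(sub.to_numpy())
        profile = overall + col_eff
        all_na = sub.isna().all(axis=0).to_numpy()
        profile[all_na] = np.nan
        rows[protein] = profile
    return pd.DataFrame(rows, index=mat.columns).T


def filter_complete(proteins: pd.DataFrame) -> pd.DataFrame:
    """Keep proteins quantified in every sample (complete cases)."""
    return proteins.loc[proteins.notna().all(axis=1)]


def differential_abundance(proteins: pd.DataFrame, design: pd.DataFrame,
                           contrasts: dict[str, np.ndarray]) -> DEResult:
    """Moderated-t differential abundance on protein log2 intensities."""
    return fit_moderated(proteins, design, contrasts)


def mrna_protein_correlation(mrna: pd.Series, protein: pd.Series,
                             idmap: pd.DataFrame | None = None
                             ) -> tuple[float, int]:
    """Spearman correlation between matched mRNA and protein quantities.

    ``idmap`` (gene_id, protein_id) links the two id spaces; identity when
    omitted. Returns ``(r_s, n_pairs)``; fewer than 3 matched pairs yields
    NaN with a warning.
    """
    if idmap is None:
        shared = mrna.index.intersection(protein.index)
        x, y = mrna.loc[shared], protein.loc[shared]
    else:
        gcol, pcol = idmap.columns[:2]
        pairs = idmap[idmap[gcol].isin(mrna.index)
                      & idmap[pcol].isin(protein.index)]
        x = mrna.loc[pairs[gcol]].to_numpy()
        y = protein.loc[pairs[pcol]].to_numpy()
    n = len(x)
    if n < 3:
        warnings.warn("fewer than 3 matched mRNA-protein pairs", stacklevel=2)
        return float("nan"), n
    r_s = spearmanr(x, y).statistic
    return float(r_s), n
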