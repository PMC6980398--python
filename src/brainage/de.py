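"""Differential expression core: CPM filtering, TMM normalisation, RUV batch
factors, and empirical-Bayes moderated t-tests.

The workflow mirrors the standard bulk RNA-seq pipeline for a 2x2
(age x genotype) design with three replicates per condition:

1. keep genes above a CPM threshold in enough libraries,
2. compute trimmed-mean-of-M-values (TMM) scale factors,
3. estimate one factor of unwanted variation from replicate-group-centred
   log-CPM (RUVs-style),
4. fit per-gene linear models on log-CPM with the RUV factor as a covariate
   and shrink residual variances towards a common prior before t-testing
   the four pairwise contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

__all__ = [
    "CONTRASTS",
    "StudyDesign",
    "ModeratedFitParams",
    "DEResult",
    "filter_by_cpm",
    "cpm",
    "logcpm",
    "tmm_factors",
    "ruv_factors",
    "condition_design",
    "fit_moderated",
    "bh_adjust",
    "celltype_marker_profile",
]

#: The four pairwise comparisons of the 2x2 design, as (test, reference)
#: condition labels. Conditions are "<age>_<genotype>".
CONTRASTS: dict[str, tuple[str, str]] = {
    "youngHet_vs_youngWt": ("young_het", "young_wt"),
    "agedHet_vs_agedWt": ("aged_het", "aged_wt"),
    "agedWt_vs_youngWt": ("aged_wt", "young_wt"),
    "agedHet_vs_youngHet": ("aged_het", "young_het"),
}


@dataclass
class StudyDesign:
    """Per-sample factors for the 2x2 age x genotype design.

    ``meta`` is indexed by sample id with columns ``genotype`` (wt/het),
    ``age`` (young/aged) and ``batch`` (replicate group identifier).
    """

    meta: pd.DataFrame
    contrasts: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(CONTRASTS))

    def __post_init__(self) -> None:
        required = {"genotype", "age", "batch"}
        missing = required - set(self.meta.columns)
        if missing:
            raise ValueError(f"design metadata missing columns: {sorted(missing)}")
        bad_gt = set(self.meta["genotype"]) - {"wt", "het"}
        bad_age = set(self.meta["age"]) - {"young", "aged"}
        if bad_gt or bad_age:
            raise ValueError(
                f"unknown factor levels: genotype={bad_gt or '{}'} age={bad_age or '{}'}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.meta.index

    @property
    def condition(self) -> pd.Series:
        """Condition label ``<age>_<genotype>`` per sample."""
        return self.meta["age"].str.cat(self.meta["genotype"], sep="_")


@dataclass
class ModeratedFitParams:
    """Empirical-Bayes variance moderation parameters.

    ``prior_df`` may be ``numpy.inf`` when the residual variances are
    homogeneous enough that the moment estimator degenerates.
    """

    prior_df: float
    prior_var: float
    residual_df: float
    posterior_var: pd.Series

    @property
    def total_df(self) -> float:
        return self.prior_df + self.residual_df


@dataclass
class DEResult:
    """Per-contrast moderated differential expression tables.

    Each table is indexed by gene id with columns
    ``logFC, t, p, FDR, AveExpr``.
    """

    tables: dict[str, pd.DataFrame]
    params: ModeratedFitParams | None = None

    def __getitem__(self, contrast: str) -> pd.DataFrame:
        try:
            return self.tables[contrast]
        except KeyError:
            raise KeyError(
                f"contrast {contrast!r} not in DE result; "
                f"available: {sorted(self.tables)}") from None

    def contrast_names(self) -> list[str]:
        return list(self.tables)


# ---------------------------------------------------------------------------
# CPM filtering and transforms
# ---------------------------------------------------------------------------

def _check_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("duplicate gene or sample identifiers in count matrix")
    vals = counts.to_numpy()
    if not np.all(np.isfinite(vals)) or (vals < 0).any():
        raise ValueError("counts must be finite and non-negative")


def cpm(counts: pd.DataFrame, lib_size: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on raw (or supplied effective) library sizes."""
    if lib_size is None:
        lib_size = counts.sum(axis=0)
    return counts * 1e6 / lib_size


def logcpm(counts: pd.DataFrame, lib_size: pd.Series | None = None,
           prior_count: float = 0.5) -> pd.DataFrame:
    """log2 CPM with a small prior count keeping zeros finite.

    ``lib_size`` may carry TMM-effective library sizes; by default raw
    column sums are used.
    """
    if lib_size is None:
        lib_size = counts.sum(axis=0)
    return np.log2((counts + prior_count) * 1e6 / (lib_size + 2 * prior_count))


def filter_by_cpm(counts: pd.DataFrame, min_cpm: float = 1.5,
                  min_samples: int = 6) -> pd.DataFrame:
    """Keep genes with CPM strictly above ``min_cpm`` in >= ``min_samples``
    libraries (CPM computed on raw library sizes). Gene order preserved."""
    _check_counts(counts)
    if min_samples > counts.shape[1]:
        raise ValueError("min_samples exceeds number of samples")
    keep = (cpm(counts) > min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("CPM filter removed every gene", stacklevel=2)
    return counts.loc[keep]


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              log_ratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference.

    Returns the scale factor (2**trimmed-mean-of-M). Genes with a zero in
    either sample drop out of the M/A computation; weights are inverse
    asymptotic binomial variances.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2
        v = (n_obs - obs) / n_obs / obs + (n_ref - ref) / n_ref / ref
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0:
        raise ValueError("sample shares no positive genes with the reference")
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    # ranks, 1-based, average ties (matches R's rank())
    rank_r = pd.Series(log_r).rank().to_numpy()
    rank_e = pd.Series(abs_e).rank().to_numpy()
    keep = ((rank_r >= lo_l) & (rank_r <= hi_l)
            & (rank_e >= lo_s) & (rank_e <= hi_s))
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, ref_sample: str | None = None) -> pd.Series:
    """TMM normalisation factors, one per sample, log-sum zero.

    The reference sample (when not given) is the one whose 75th-percentile
    CPM is closest to the mean of those quantiles. M-values are trimmed by
    30%, A-values by 5%, and the trimmed mean is precision-weighted.
    """
    _check_counts(counts)
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    x = counts.to_numpy(dtype=float)
    if ref_sample is None:
        f75 = np.quantile(x, 0.75, axis=0) / lib.to_numpy()
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_sample)
    ref = x[:, ref_idx]
    n_ref = lib.iloc[ref_idx]
    factors = np.array([
        _tmm_pair(x[:, j], ref, lib.iloc[j], n_ref) for j in range(x.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# RUVs-style unwanted variation
# ---------------------------------------------------------------------------

def ruv_factors(logexpr: pd.DataFrame, replicate_groups: pd.Series,
                k: int = 1) -> pd.DataFrame:
    """Estimate k factors of unwanted variation from replicate groups.

    Expression is centred within each replicate group (samples sharing the
    same biology), removing the biological signal; the leading left-singular
    directions of the centred sample x gene matrix capture whatever
    systematic variation remains (batch). Columns of the returned ``W``
    (samples x k) are unit-norm, mutually orthogonal, first element of each
    column non-negative.
    """
    groups = replicate_groups.loc[logexpr.columns]
    counts = groups.value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise ValueError(f"replicate groups with fewer than 2 samples: {small}")
    y = logexpr.to_numpy(dtype=float).T  # samples x genes
    yc = y.copy()
    for g in counts.index:
        rows = (groups == g).to_numpy()
        yc[rows] -= yc[rows].mean(axis=0, keepdims=True)
    rank = np.linalg.matrix_rank(yc)
    if k >= rank + 1 or k >= y.shape[0]:
        raise ValueError(f"k={k} >= rank of group-centred matrix ({rank})")
    u, _, _ = np.linalg.svd(yc, full_matrices=False)
    w = u[:, :k].copy()
    for j in range(k):
        if w[0, j] < 0:
            w[:, j] = -w[:, j]
    return pd.DataFrame(w, index=logexpr.columns,
                        columns=[f"W{i + 1}" for i in range(k)])


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated linear model
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled F-distribution to sample variances.

    Returns ``(s0_sq, d0)`` — the prior variance and prior degrees of
    freedom — by matching the mean and variance of ``log(s2)`` against the
    digamma/trigamma moments of a log-F. ``d0`` above 1e6 is reported as
    infinity (variances effectively homogeneous).
    """
    s2 = np.asarray(s2, dtype=float)
    med = np.median(s2)
    if med == 0:
        med = 1.0
    s2 = np.maximum(s2, 1e-5 * med)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        if d0 > 1e6:
            d0 = np.inf
            s0_sq = float(np.exp(e_mean))
        else:
            s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(s2.mean())
    return s0_sq, d0


def squeeze_var(s2: np.ndarray, df: float, s0_sq: float, d0: float) -> np.ndarray:
    """Posterior variances shrinking ``s2`` towards the prior ``s0_sq``."""
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, float), s0_sq)
    return (d0 * s0_sq + df * s2) / (d0 + df)


def condition_design(design: StudyDesign,
                     ruv: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cell-means design matrix: one indicator column per condition, plus
    optional RUV covariate columns."""
    cond = design.condition
    levels = ["young_wt", "young_het", "aged_wt", "aged_het"]
    levels = [lv for lv in levels if lv in set(cond)]
    X = pd.DataFrame(
        {lv: (cond == lv).astype(float) for lv in levels}, index=cond.index)
    if ruv is not None:
        X = pd.concat([X, ruv.loc[X.index]], axis=1)
    return X


def contrast_vector(X: pd.DataFrame, test: str, ref: str) -> np.ndarray:
    c = np.zeros(X.shape[1])
    c[X.columns.get_loc(test)] = 1.0
    c[X.columns.get_loc(ref)] = -1.0
    return c


def fit_moderated(logexpr: pd.DataFrame, X: pd.DataFrame,
                  contrasts: dict[str, np.ndarray],
                  prior: tuple[float, float] | None = None) -> DEResult:
    """Per-gene least squares with empirical-Bayes variance moderation.

    ``X`` is the samples x p design; ``contrasts`` maps names to p-vectors.
    ``prior`` optionally fixes ``(s0_sq, d0)`` — used by tests probing the
    d0 -> 0 and d0 -> inf limits.

    Raises if the design is not full column rank (aliased columns listed).
    """
    if isinstance(X, pd.DataFrame):
        if set(X.index) != set(logexpr.columns):
            raise ValueError("design rows do not match expression samples")
        X = X.loc[logexpr.columns]
    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    if np.linalg.matrix_rank(Xm) < p:
        # name aliased columns: those whose removal restores full rank
        aliased = [c for i, c in enumerate(X.columns)
                   if np.linalg.matrix_rank(np.delete(Xm, i, axis=1))
                   == np.linalg.matrix_rank(Xm)]
        raise ValueError(f"design matrix is singular; aliased columns: {aliased}")
    d_res = n - p
    if d_res < 1:
        raise ValueError("no residual degrees of freedom")
    Y = logexpr.to_numpy(dtype=float)  # genes x n
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    beta = Y @ Xm @ xtx_inv.T  # genes x p
    resid = Y - beta @ Xm.T
    s2 = (resid ** 2).sum(axis=1) / d_res
    if prior is None:
        s0_sq, d0 = fit_f_dist(s2, d_res)
    else:
        s0_sq, d0 = prior
    s2_post = squeeze_var(s2, d_res, s0_sq, d0)
    # with an infinite prior the t reference caps at the pooled df
    df_total = min(d0 + d_res, Y.shape[0] * d_res)
    ave_expr = Y.mean(axis=1)
    tables = {}
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        lfc = beta @ c
        v_c = float(c @ xtx_inv @ c)
        tstat = lfc / np.sqrt(s2_post * v_c)
        pval = 2.0 * t_dist.sf(np.abs(tstat), df_total)
        tables[name] = pd.DataFrame(
            {"logFC": lfc, "t": tstat, "p": pval,
             "FDR": bh_adjust(pval), "AveExpr": ave_expr},
            index=logexpr.index)
    params = ModeratedFitParams(
        prior_df=d0, prior_var=s0_sq, residual_df=d_res,
        posterior_var=pd.Series(s2_post, index=logexpr.index))
    return DEResult(tables=tables, params=params)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")[::-1]  # descending
    ranked = p[order] * m / np.arange(m, 0, -1)
    adj = np.minimum.accumulate(ranked)
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Cell-type marker QC
# ---------------------------------------------------------------------------

def celltype_marker_profile(logexpr: pd.DataFrame,
                            marker_sets: dict[str, list[str]]
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean log-expression of each cell type's marker genes per sample.

    Returns ``(profile, coverage)``: the celltype x sample mean matrix and a
    table of markers found vs requested. Cell types with zero markers in
    the matrix are flagged absent (NaN row), not fatal.
    """
    rows, cov = {}, {}
    for ct, markers in marker_sets.items():
        present = [g for g in markers if g in logexpr.index]
        cov[ct] = {"n_requested": len(markers), "n_found": len(present)}
        if not present:
            warnings.warn(f"no markers found for cell type {ct!r}", stacklevel=2)
            rows[ct] = pd.Series(np.nan, index=logexpr.columns)
        else:
            rows[ct] = logexpr.loc[present].mean(axis=0)
    if all(v["n_found"] == 0 for v in cov.values()):
        raise ValueError("no marker genes from any set present in the matrix")
    return pd.DataFrame(rows).T, pd.DataFrame(cov).T
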