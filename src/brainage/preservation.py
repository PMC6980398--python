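"""Permutation-based cross-network module preservation.

A module defined in a reference co-expression network is evaluated in a
test network through two families of statistics:

density (how co-expressed the module's genes remain in the test network):
  - mean intra-module correlation,
  - mean intra-module signed adjacency,
  - proportion of variance explained by the module eigengene;

connectivity (whether the module's internal topology is conserved):
  - correlation of intramodular connectivity vectors (cor.kIM),
  - correlation of gene-eigengene correlations (cor.kME),
  - correlation of the off-diagonal correlation entries (cor.cor).

The null distribution permutes gene-module assignments in the test network
(module sizes preserved); ``Z = (obs - mean_perm)/sd_perm`` per statistic,
``Z_density``/``Z_connectivity`` are medians within each family and
``Z_summary`` their mean. Z-summary below 2 indicates no evidence of
preservation, 2-10 weak-to-moderate, above 10 strong.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import signed_adjacency

__all__ = [
    "PreservationResult",
    "observed_stats",
    "zsummary",
    "random_module_baseline",
    "classify_zsummary",
]

_DENSITY = ("mean_cor", "mean_adj", "prop_var_explained")
_CONNECTIVITY = ("cor_kim", "cor_kme", "cor_cor")
STATS = _DENSITY + _CONNECTIVITY


def classify_zsummary(z: float) -> str:
    if not np.isfinite(z):
        return "undefined"
    if z < 2:
        return "none"
    if z <= 10:
        return "weak-moderate"
    return "strong"


@dataclass
class PreservationResult:
    """Per-module observed statistics, permutation nulls and Z scores."""

    observed: pd.DataFrame
    perm_mean: pd.DataFrame
    perm_sd: pd.DataFrame
    z: pd.DataFrame
    summary: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.summary is None:
            zd = self.z[list(_DENSITY)].median(axis=1)
            zc = self.z[list(_CONNECTIVITY)].median(axis=1)
            zs = (zd + zc) / 2.0
            self.summary = pd.DataFrame({
                "n_genes": self.observed["n_genes"].astype(int),
                "Z_density": zd,
                "Z_connectivity": zc,
                "Z_summary": zs,
                "classification": zs.map(classify_zsummary),
            })


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _safe_cor(u: np.ndarray, v: np.ndarray) -> float:
    if u.size < 2 or np.std(u) == 0 or np.std(v) == 0:
        return np.nan
    return float(np.corrcoef(u, v)[0, 1])


def _module_stats(x_ref: np.ndarray, x_test: np.ndarray, beta: float) -> dict:
    """All six statistics for one module; ``x_*`` are genes x samples slices
    of the (matched) reference and test expression."""
    m = x_ref.shape[0]
    zr = _standardize(x_ref)
    zt = _standardize(x_test)
    cr = np.clip(zr @ zr.T / x_ref.shape[1], -1.0, 1.0)
    ct = np.clip(zt @ zt.T / x_test.shape[1], -1.0, 1.0)
    off = ~np.eye(m, dtype=bool)
    at = ((1.0 + ct) / 2.0) ** beta
    ar = ((1.0 + cr) / 2.0) ** beta

    def _kme(z: np.ndarray) -> tuple[np.ndarray, float]:
        # gene-eigengene correlations, eigengene sign-aligned with the
        # module mean profile so kME signs are comparable across networks
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0] if np.dot(vt[0], z.mean(axis=0)) >= 0 else -vt[0]
        eig = eig - eig.mean()
        norm = np.linalg.norm(eig)
        if norm == 0:
            return np.full(z.shape[0], np.nan), np.nan
        kme = (z @ eig) / (np.sqrt(z.shape[1]) * norm)
        return kme, float(s[0] ** 2 / np.sum(s ** 2))

    kme_t, prop_var = _kme(zt)
    kme_r, _ = _kme(zr)

    iu = np.triu_indices(m, k=1)
    return {
        "n_genes": m,
        "mean_cor": float(ct[off].mean()),
        "mean_adj": float(at[off].mean()),
        "prop_var_explained": prop_var,
        "cor_kim": _safe_cor(ar[off].reshape(m, m - 1).sum(axis=1),
                             at[off].reshape(m, m - 1).sum(axis=1)),
        "cor_kme": _safe_cor(kme_r, kme_t),
        "cor_cor": _safe_cor(cr[iu], ct[iu]),
    }


def _match_orthologs(expr_ref: pd.DataFrame, expr_test: pd.DataFrame,
                     ortho: pd.DataFrame | None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align the two expression matrices gene-for-gene via the ortholog map
    (identity map when ``ortho`` is None); one-to-one, first match wins."""
    if ortho is None:
        shared = expr_ref.index.intersection(expr_test.index)
        return expr_ref.loc[shared], expr_test.loc[shared]
    src, tgt = ortho.columns[:2]
    pairs = ortho.drop_duplicates(subset=src).drop_duplicates(subset=tgt)
    pairs = pairs[pairs[src].isin(expr_ref.index)
                  & pairs[tgt].isin(expr_test.index)]
    ref = expr_ref.loc[pairs[src]]
    test = expr_test.loc[pairs[tgt]]
    test.index = ref.index  # matched ortholog positions share ref ids
    return ref, test


def observed_stats(expr_ref: pd.DataFrame, expr_test: pd.DataFrame,
                   labels_ref: pd.Series, ortho: pd.DataFrame | None = None,
                   beta: float = 14.0) -> pd.DataFrame:
    """Observed preservation statistics for each reference module.

    Modules with fewer than 3 genes surviving the ortholog match are
    reported with NaN statistics and ``testable = False``.
    """
    ref, test = _match_orthologs(expr_ref, expr_test, ortho)
    rows = {}
    for module in sorted(set(labels_ref) - {0}):
        genes = labels_ref.index[labels_ref == module].intersection(ref.index)
        if len(genes) < 3:
            rows[module] = dict.fromkeys(("n_genes",) + STATS, np.nan)
            rows[module]["n_genes"] = len(genes)
            rows[module]["testable"] = False
            continue
        stats = _module_stats(ref.loc[genes].to_numpy(dtype=float),
                              test.loc[genes].to_numpy(dtype=float), beta)
        stats["testable"] = True
        rows[module] = stats
    return pd.DataFrame(rows).T


def zsummary(expr_ref: pd.DataFrame, expr_test: pd.DataFrame,
             labels_ref: pd.Series, ortho: pd.DataFrame | None = None,
             n_perm: int = 200, seed: int | None = None,
             beta: float = 14.0,
             rng: np.random.Generator | None = None) -> PreservationResult:
    """Permutation Z-summary preservation of reference modules in a test
    network. Gene-module assignments are permuted in the test network
    (module sizes preserved; marginal network structure untouched)."""
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a usable null")
    if rng is None:
        rng = np.random.default_rng(seed)
    ref, test = _match_orthologs(expr_ref, expr_test, ortho)
    obs = observed_stats(expr_ref, expr_test, labels_ref, ortho, beta)
    testable = [m for m in obs.index if obs.loc[m, "testable"]]

    x_ref = {m: ref.loc[labels_ref.index[labels_ref == m]
                        .intersection(ref.index)].to_numpy(dtype=float)
             for m in testable}
    test_arr = test.to_numpy(dtype=float)
    n_genes_total = test_arr.shape[0]

    perm_stats = {m: [] for m in testable}
    for _ in range(n_perm):
        perm = rng.permutation(n_genes_total)
        start = 0
        for m in testable:
            size = x_ref[m].shape[0]
            take = perm[start:start + size]
            start += size
            perm_stats[m].append(
                _module_stats(x_ref[m], test_arr[take], beta))

    stat_cols = list(STATS)
    perm_mean = pd.DataFrame(index=obs.index, columns=stat_cols, dtype=float)
    perm_sd = pd.DataFrame(index=obs.index, columns=stat_cols, dtype=float)
    z = pd.DataFrame(index=obs.index, columns=stat_cols, dtype=float)
    for m in testable:
        arr = pd.DataFrame(perm_stats[m])[stat_cols].to_numpy(dtype=float)
        mu = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0, ddof=1)
        perm_mean.loc[m] = mu
        perm_sd.loc[m] = sd
        with np.errstate(divide="ignore", invalid="ignore"):
            zm = (obs.loc[m, stat_cols].to_numpy(dtype=float) - mu) / sd
        zm[~np.isfinite(zm)] = np.nan
        z.loc[m] = zm
    return PreservationResult(observed=obs, perm_mean=perm_mean,
                              perm_sd=perm_sd, z=z)


def random_module_baseline(expr_ref: pd.DataFrame, expr_test: pd.DataFrame,
                           ortho: pd.DataFrame | None = None,
                           size: int = 1000, n_perm: int = 200,
                           seed: int | None = None, beta: float = 14.0
                           ) -> PreservationResult:
    """Preservation of a pseudo-module of uniformly sampled genes.

    The expected outcome between unrelated networks is no preservation
    (Z-summary < 2); this calibrates the Z scale.
    """
    rng = np.random.default_rng(seed)
    ref, _ = _match_orthologs(expr_ref, expr_test, ortho)
    if size > len(ref.index):
        raise ValueError(f"random module size {size} exceeds the "
                         f"{len(ref.index)}-gene shared universe")
    genes = ref.index[rng.choice(len(ref.index), size=size, replace=False)]
    labels = pd.Series(0, index=ref.index, name="module")
    labels.loc[genes] = 1
    return zsummary(expr_ref, expr_test, labels, ortho,
                    n_perm=n_perm, beta=beta, rng=rng)
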