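"""Signed weighted co-expression networks.

Adjacency is the signed transform ``((1 + cor)/2)**beta`` of the Pearson
correlation (beta = 14 by default, chosen for approximate scale-freeness in
brain expression data), smoothed by the topological overlap measure (TOM).
Modules are branches of the average-linkage dendrogram of 1 - TOM, detected
by a documented dynamic-hybrid variant (size, core-scatter and PAM
assignment stages) and summarised by their eigengenes (first principal
components), which are then correlated with binary trait indicators using
a hybrid Pearson/biweight-midcorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact
from scipy.stats import t as t_dist

__all__ = [
    "NetworkParams",
    "ModuleAssignment",
    "signed_adjacency",
    "connectivity",
    "connectivity_filter",
    "topological_overlap",
    "cut_modules",
    "module_eigengene",
    "bicor",
    "hybrid_correlation",
    "module_trait_correlation",
    "module_overlap",
]


@dataclass(frozen=True)
class NetworkParams:
    soft_power: float = 14.0
    min_module_size: int = 40
    deep_split: int = 1
    pam_max_distance: float = 0.90
    connectivity_filter_percentile: float = 10.0

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not (0 <= self.connectivity_filter_percentile < 100):
            raise ValueError("percentile must lie in [0, 100)")
        if not (0 < self.pam_max_distance <= 1):
            raise ValueError("pam_max_distance must lie in (0, 1]")


@dataclass
class ModuleAssignment:
    """Gene -> module labels (0 = unassigned/grey), dendrogram, eigengenes."""

    labels: pd.Series
    linkage_matrix: np.ndarray | None = None
    eigengenes: pd.DataFrame | None = None
    variance_explained: pd.Series | None = None

    def module_sizes(self) -> pd.Series:
        return self.labels[self.labels != 0].value_counts().sort_index()

    def genes_in(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]


# ---------------------------------------------------------------------------
# Adjacency / connectivity / TOM
# ---------------------------------------------------------------------------

def _corr(expr: pd.DataFrame) -> np.ndarray:
    """Pearson correlation between genes (rows of ``expr``)."""
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[sd == 0].tolist()
        raise ValueError(f"constant-expression genes have undefined "
                         f"correlations: {bad[:10]}")
    c = np.corrcoef(x)
    return np.clip(c, -1.0, 1.0)


def signed_adjacency(expr: pd.DataFrame, beta: float = 14.0) -> pd.DataFrame:
    """Signed adjacency ``a_ij = ((1 + cor_ij)/2)**beta``, unit diagonal."""
    a = ((1.0 + _corr(expr)) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Whole-network connectivity k_i = sum of off-diagonal adjacencies."""
    a = adj.to_numpy()
    return pd.Series(a.sum(axis=1) - np.diag(a), index=adj.index, name="k")


def connectivity_filter(expr: pd.DataFrame, params: NetworkParams = NetworkParams(),
                        expr_other: pd.DataFrame | None = None) -> pd.DataFrame:
    """Drop low-connectivity genes (noise reduction before module detection).

    Keeps genes whose signed-network connectivity is at or above the given
    percentile (midpoint-interpolated), so an all-tied network loses no
    genes. When a second dataset is
    supplied the criterion is applied in both and genes must pass in each.
    Constant genes are dropped with a warning beforehand.
    """
    sd = expr.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"dropping {(sd == 0).sum()} constant-expression genes",
                      stacklevel=2)
        expr = expr.loc[sd > 0]
    keep = expr.index
    for e in ([expr] if expr_other is None else
              [expr, expr_other.loc[expr_other.index.intersection(keep)]]):
        k = connectivity(signed_adjacency(e.loc[e.index.intersection(keep)],
                                          params.soft_power))
        thr = np.percentile(k.to_numpy(), params.connectivity_filter_percentile,
                            method="midpoint")
        keep = keep.intersection(k.index[k >= thr])
    return expr.loc[expr.index.intersection(keep)]


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_u a_iu a_uj`` over u != i, j. Diagonal 1, symmetric,
    bounded in [0, 1].
    """
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # noqa: E741 - shared-neighbour term, standard notation
    num = l + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore"):
        tom = num / den
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.index)


# ---------------------------------------------------------------------------
# Dynamic-hybrid module detection
# ---------------------------------------------------------------------------

#: deepSplit -> maximum core scatter (as a fraction of the cut height);
#: lower values demand tighter branches (standard hybrid tree-cut mapping).
_MAX_CORE_SCATTER = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91, 4: 0.95}


def cut_modules(dissim: pd.DataFrame,
                params: NetworkParams = NetworkParams()) -> ModuleAssignment:
    """Detect modules on a dissimilarity (typically 1 - TOM).

    A documented dynamic-hybrid variant, not an exact port of the reference
    tree cutter: (1) average-linkage dendrogram; (2) every dendrogram
    branch of at least ``min_module_size`` genes whose core scatter (mean
    pairwise dissimilarity of the tighter half of the branch) stays below
    the deepSplit-dependent bound is a module candidate, and the lowest
    candidate branches (no accepted descendant) become module cores;
    (3) a PAM-like stage assigns leftover genes to the nearest module
    medoid iff that distance <= ``pam_max_distance``.
    Modules are numbered by decreasing size; label 0 is unassigned (grey).
    """
    d = dissim.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("dissimilarity must be square and symmetric")
    genes = dissim.index
    n = len(genes)
    if n < params.min_module_size:
        warnings.warn("fewer genes than min_module_size; all unassigned",
                      stacklevel=2)
        return ModuleAssignment(labels=pd.Series(0, index=genes))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    cut_height = 0.99 * Z[-1, 2]
    max_scatter = _MAX_CORE_SCATTER[int(np.clip(params.deep_split, 0, 4))]

    # leaves of every internal node, nodes indexed n..2n-2 in merge order
    leaves: list[np.ndarray | None] = [np.array([i]) for i in range(n)]
    for a, b in Z[:, :2].astype(int):
        leaves.append(np.concatenate([leaves[a], leaves[b]]))

    def _core_scatter(members: np.ndarray) -> float:
        sub = d[np.ix_(members, members)]
        mean_d = sub.sum(axis=1) / (members.size - 1)
        core = members[np.argsort(mean_d, kind="mergesort")[
            :max(2, members.size // 2)]]
        core_sub = d[np.ix_(core, core)]
        return core_sub.sum() / (core.size * (core.size - 1))

    # lowest tight branches: merge order is non-decreasing in height, so a
    # node whose children were already accepted is skipped
    has_accepted = np.zeros(2 * n - 1, dtype=bool)
    modules: list[np.ndarray] = []
    for i, (a, b) in enumerate(Z[:, :2].astype(int)):
        node = n + i
        if has_accepted[a] or has_accepted[b]:
            has_accepted[node] = True
            continue
        members = leaves[node]
        if members.size < params.min_module_size:
            continue
        if Z[i, 2] > cut_height:
            continue
        if _core_scatter(members) <= max_scatter * cut_height:
            modules.append(members)
            has_accepted[node] = True

    labels = np.zeros(n, dtype=int)
    modules.sort(key=lambda m: -m.size)
    medoids = []
    for i, members in enumerate(modules, start=1):
        labels[members] = i
        sub = d[np.ix_(members, members)]
        medoids.append(members[int(np.argmin(sub.sum(axis=1)))])

    # PAM stage: adopt unassigned genes close enough to a module medoid —
    # within the hard cap and within 1.25x the module core's own radius,
    # so diffuse genes cannot latch onto a tight module
    if medoids:
        radius = np.array([
            min(params.pam_max_distance,
                1.25 * np.percentile(d[members, med], 95))
            for members, med in zip(modules, medoids)])
        unassigned = np.where(labels == 0)[0]
        if unassigned.size:
            dist_to_med = d[np.ix_(unassigned, np.array(medoids))]
            best = np.argmin(dist_to_med, axis=1)
            best_d = dist_to_med[np.arange(unassigned.size), best]
            adopt = best_d <= radius[best]
            labels[unassigned[adopt]] = best[adopt] + 1

    # renumber by final size, largest first
    final = np.zeros(n, dtype=int)
    sizes = pd.Series(labels[labels != 0]).value_counts()
    for new, old in enumerate(sizes.sort_values(ascending=False).index, start=1):
        final[labels == old] = new
    return ModuleAssignment(labels=pd.Series(final, index=genes, name="module"),
                            linkage_matrix=Z)


# ---------------------------------------------------------------------------
# Eigengenes and trait correlation
# ---------------------------------------------------------------------------

def module_eigengene(expr: pd.DataFrame, labels: pd.Series
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component of each module's standardised expression.

    Returns ``(eigengenes, variance_explained)``; eigengenes are unit-norm
    sample-length vectors, sign-aligned so their correlation with the
    module's mean expression profile is non-negative.
    """
    if expr.shape[1] < 2:
        raise ValueError("eigengenes require at least 2 samples")
    eigs, varexp = {}, {}
    for module in sorted(set(labels) - {0}):
        genes = labels.index[labels == module]
        if len(genes) < 2:
            raise ValueError(f"module {module} has fewer than 2 genes")
        x = expr.loc[genes].to_numpy(dtype=float)
        x = (x - x.mean(axis=1, keepdims=True))
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = x / sd
        _, s, vt = np.linalg.svd(x, full_matrices=False)
        eig = vt[0]
        if np.dot(eig, x.mean(axis=0)) < 0:
            eig = -eig
        eigs[f"ME{module}"] = eig
        varexp[f"ME{module}"] = float(s[0] ** 2 / np.sum(s ** 2))
    return (pd.DataFrame(eigs, index=expr.columns),
            pd.Series(varexp, name="variance_explained"))


def _bicor_weights(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Tukey biweights around the median; flags degenerate (MAD 0 or
    few-distinct-values) vectors for the Pearson fallback."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0 or np.unique(x).size <= 3:
        return np.ones_like(x), True
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u ** 2) ** 2
    w[np.abs(u) >= 1] = 0.0
    return w, False


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation (median/MAD-weighted robust correlation)."""
    return hybrid_correlation(x, y, robust_x=True, robust_y=True)


def hybrid_correlation(x: np.ndarray, y: np.ndarray,
                       robust_x: bool = True, robust_y: bool = True) -> float:
    """Hybrid Pearson-robust correlation.

    Each side uses biweight midcovariance terms unless it is degenerate for
    the robust weighting (binary traits, zero MAD), in which case that side
    falls back to Pearson centring — the 'hybrid' in hybrid-robust
    correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    wx, degen_x = _bicor_weights(x) if robust_x else (np.ones_like(x), True)
    wy, degen_y = _bicor_weights(y) if robust_y else (np.ones_like(y), True)
    xc = x - (np.mean(x) if degen_x else np.median(x))
    yc = y - (np.mean(y) if degen_y else np.median(y))
    if degen_x:
        wx = np.ones_like(x)
    if degen_y:
        wy = np.ones_like(y)
    xt = xc * wx
    yt = yc * wy
    denom = np.sqrt(np.sum(xt ** 2)) * np.sqrt(np.sum(yt ** 2))
    if denom == 0:
        return float("nan")
    return float(np.clip(np.sum(xt * yt) / denom, -1.0, 1.0))


def module_trait_correlation(eigengenes: pd.DataFrame,
                             traits: pd.DataFrame) -> pd.DataFrame:
    """Hybrid-robust correlation of each eigengene with each binary trait.

    Returns a long table (module, trait, cor, p) with unadjusted Student
    t p-values on n - 2 df. Constant traits are flagged with NaN.
    """
    n = len(eigengenes)
    if n < 3:
        raise ValueError("need at least 3 samples for trait correlation")
    bad = [c for c in traits.columns
           if not set(pd.unique(traits[c].dropna())) <= {0, 1}]
    if bad:
        raise ValueError(f"traits must be binary 0/1 indicators: {bad}")
    rows = []
    for me in eigengenes.columns:
        for trait in traits.columns:
            t_vals = traits[trait].to_numpy(dtype=float)
            if np.unique(t_vals).size < 2:
                rows.append((me, trait, np.nan, np.nan))
                continue
            r = hybrid_correlation(eigengenes[me].to_numpy(), t_vals)
            r_clip = min(abs(r), 1 - 1e-12)
            tstat = r_clip * np.sqrt((n - 2) / (1 - r_clip ** 2))
            p = 2.0 * t_dist.sf(tstat, n - 2)
            rows.append((me, trait, r, p))
    return pd.DataFrame(rows, columns=["module", "trait", "cor", "p"])


# ---------------------------------------------------------------------------
# Cross-network module overlap
# ---------------------------------------------------------------------------

def module_overlap(labels_a: pd.Series, labels_b: pd.Series,
                   ortho: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Cross-tabulate module co-membership over orthologs.

    ``ortho`` maps network-A gene ids to network-B gene ids (two columns).
    Returns ``(contingency, fisher_p, sankey)`` where ``sankey`` is a
    node/link structure ready for serialisation; link weights sum to the
    number of shared ortholog pairs.
    """
    src, tgt = ortho.columns[:2]
    pairs = ortho[ortho[src].isin(labels_a.index) & ortho[tgt].isin(labels_b.index)]
    if len(pairs) == 0:
        raise ValueError("no ortholog pairs shared between the two networks")
    la = labels_a.loc[pairs[src]].to_numpy()
    lb = labels_b.loc[pairs[tgt]].to_numpy()
    tab = pd.crosstab(pd.Series(la, name="module_a"),
                      pd.Series(lb, name="module_b"))
    total = tab.to_numpy().sum()
    fisher = pd.DataFrame(np.nan, index=tab.index, columns=tab.columns)
    for i in tab.index:
        for j in tab.columns:
            k = tab.loc[i, j]
            row = tab.loc[i].sum()
            col = tab[j].sum()
            table = [[k, row - k], [col - k, total - row - col + k]]
            fisher.loc[i, j] = fisher_exact(table, alternative="greater")[1]
    nodes = ([{"name": f"A{m}"} for m in tab.index]
             + [{"name": f"B{m}"} for m in tab.columns])
    links = [{"source": f"A{i}", "target": f"B{j}",
              "value": int(tab.loc[i, j])}
             for i in tab.index for j in tab.columns if tab.loc[i, j] > 0]
    return tab, fisher, {"nodes": nodes, "links": links}
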