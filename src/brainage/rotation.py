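"""Self-contained rotation gene-set testing (ROAST) and its fast analytic
approximation (FRY).

Both tests work in the "effects" coordinate system: for each gene the data
are projected through the QR decomposition of the design (with the contrast
of interest rotated into the last coefficient), leaving a vector of
``1 + d`` coordinates — the contrast effect plus ``d`` residual effects —
whose direction is uniform on the sphere under the null hypothesis.

ROAST draws random unit vectors (rotations), recomputes a moderated
z-statistic per gene per rotation, and compares rotated set statistics with
the observed ones; with B rotations p-values have granularity 1/(B+1)
(directional p-values pool the +/- rotation means, granularity 1/(2B+1)).
FRY replaces the rotations with the exact null distribution of the
set-mean statistic under an equal-correlation assumption.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import chi2
from scipy.stats import t as t_dist

from .de import bh_adjust, fit_f_dist, squeeze_var

__all__ = [
    "map_orthologs",
    "lm_effects",
    "roast_test",
    "fry_test",
]

SQRT2 = float(np.sqrt(2.0))


# ---------------------------------------------------------------------------
# Gene-set plumbing
# ---------------------------------------------------------------------------

def map_orthologs(sets: dict[str, list[str]],
                  ortho: pd.DataFrame) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Translate gene-set members through a (many-to-many) ortholog map.

    ``ortho`` has two columns: source id, target id. Each source id is
    replaced by all of its targets, de-duplicated with order preserved;
    sets losing every member are dropped with a warning. Returns the mapped
    collection and a per-set mapping report.
    """
    if len(ortho) == 0:
        raise ValueError("ortholog map is empty")
    src, tgt = ortho.columns[:2]
    lut: dict[str, list[str]] = {}
    for s, t in zip(ortho[src], ortho[tgt]):
        lut.setdefault(s, []).append(t)
    mapped: dict[str, list[str]] = {}
    report = {}
    for name, members in sets.items():
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        out: list[str] = []
        seen = set()
        n_hit = 0
        for g in members:
            targets = lut.get(g)
            if targets:
                n_hit += 1
                for t in targets:
                    if t not in seen:
                        seen.add(t)
                        out.append(t)
        report[name] = {"n_input": len(members), "n_mapped_input": n_hit,
                        "n_output": len(out)}
        if out:
            mapped[name] = out
        else:
            warnings.warn(f"gene set {name!r} lost all members in mapping",
                          stacklevel=2)
    return mapped, pd.DataFrame(report).T


# ---------------------------------------------------------------------------
# Effects coordinates
# ---------------------------------------------------------------------------

def _contrast_last_basis(c: np.ndarray) -> np.ndarray:
    """Orthonormal p x p basis whose last column is c/||c||."""
    p = c.size
    u = c / np.linalg.norm(c)
    # complete to a basis via QR of [u | I], keep orthogonal complement
    q, _ = np.linalg.qr(np.column_stack([u, np.eye(p)]), mode="reduced")
    # q[:,0] is +-u; ensure exact alignment and put it last
    if np.dot(q[:, 0], u) < 0:
        q[:, 0] = -q[:, 0]
    return np.column_stack([q[:, 1:p], q[:, 0]])


def lm_effects(expr: pd.DataFrame, design: pd.DataFrame | np.ndarray,
               contrast: np.ndarray) -> pd.DataFrame:
    """Project each gene into (contrast effect, d residual effects).

    Returns a genes x (1 + d) frame; column 0 carries the signed contrast
    effect, the remainder are residual-space coordinates. ``contrast`` is a
    vector over design columns.
    """
    if isinstance(design, pd.DataFrame):
        if set(design.index) != set(expr.columns):
            raise ValueError("design rows do not match expression samples")
        design = design.loc[expr.columns]
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    c = np.asarray(contrast, dtype=float)
    if c.size != p:
        raise ValueError("contrast length must match design columns")
    if not np.any(c):
        raise ValueError("contrast is all zero")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design must be full column rank")
    if n <= p:
        raise ValueError("no residual degrees of freedom")
    Xp = X @ _contrast_last_basis(c)
    q, r = np.linalg.qr(Xp, mode="complete")
    eff = expr.to_numpy(dtype=float) @ q  # genes x n
    eff = eff[:, p - 1:]
    if r[p - 1, p - 1] < 0:
        eff[:, 0] = -eff[:, 0]
    cols = ["contrast"] + [f"res{i}" for i in range(1, n - p + 1)]
    return pd.DataFrame(eff, index=expr.index, columns=cols)


def _zscore_t(x: np.ndarray, df: float) -> np.ndarray:
    """Bailey's closed-form normalising transformation of a t-statistic."""
    if np.isinf(df):
        return np.asarray(x, dtype=float)
    df = min(df, 1e4)
    return (((df + 0.125) / (df + 1.125))
            * np.sqrt((df + 19.0 / 12.0) * np.log1p(x * x / (df + 1.0 / 12.0)))
            * np.sign(x))


def _subset_effects(effects: pd.DataFrame, members: list[str]) -> np.ndarray:
    idx = effects.index.get_indexer([g for g in members if g in effects.index])
    return effects.to_numpy()[idx[idx >= 0]]


# ---------------------------------------------------------------------------
# ROAST
# ---------------------------------------------------------------------------

def roast_test(expr: pd.DataFrame, design: pd.DataFrame | np.ndarray,
               contrast: np.ndarray, sets: dict[str, list[str]],
               n_rot: int = 9999, seed: int | None = None,
               set_stat: str = "mean", rng: np.random.Generator | None = None
               ) -> pd.DataFrame:
    """Rotation gene-set test with the 'mean' set statistic.

    One stream of rotations is shared by all sets within the comparison so
    that set p-values are comparable. Per set the result carries
    ``p_up, p_down, p_mixed, FDR_mixed, prop_up, prop_down,
    n_genes_in_data``; directional p-values have granularity 1/(2B+1),
    mixed 1/(B+1). ``prop_up``/``prop_down`` count genes whose moderated z
    exceeds +/- sqrt(2).
    """
    if set_stat != "mean":
        raise NotImplementedError("only the 'mean' set statistic is provided")
    if rng is None:
        rng = np.random.default_rng(seed)
    effects = lm_effects(expr, design, contrast)
    E = effects.to_numpy()
    d = E.shape[1] - 1
    s2 = (E[:, 1:] ** 2).mean(axis=1)
    s0_sq, d0 = fit_f_dist(s2, d)
    s2_post = squeeze_var(s2, d, s0_sq, d0)
    df_total = d0 + d
    z_obs = _zscore_t(E[:, 0] / np.sqrt(s2_post), df_total)

    memberships: dict[str, np.ndarray] = {}
    untestable = []
    for name, members in sets.items():
        idx = effects.index.get_indexer(members)
        idx = idx[idx >= 0]
        if idx.size == 0:
            untestable.append(name)
        else:
            memberships[name] = np.unique(idx)
    if untestable:
        warnings.warn(f"sets absent from the data: {untestable}", stacklevel=2)

    obs_up = {n: z_obs[i].mean() for n, i in memberships.items()}
    obs_mixed = {n: np.abs(z_obs[i]).mean() for n, i in memberships.items()}
    count_up = dict.fromkeys(memberships, 0)
    count_down = dict.fromkeys(memberships, 0)
    count_mixed = dict.fromkeys(memberships, 0)

    row_ss = (E ** 2).sum(axis=1)
    chunk = max(1, min(n_rot, int(5e6 // max(E.shape[0], 1))))
    done = 0
    while done < n_rot:
        b = min(chunk, n_rot - done)
        r = rng.standard_normal((b, d + 1))
        r /= np.linalg.norm(r, axis=1, keepdims=True)
        sig = E @ r.T  # genes x b rotated contrast effects
        s2r = (row_ss[:, None] - sig ** 2) / d
        if np.isfinite(d0):
            s2r = (d0 * s0_sq + d * s2r) / df_total
        else:
            s2r = np.full_like(s2r, s0_sq)
        zr = _zscore_t(sig / np.sqrt(s2r), df_total)
        for name, idx in memberships.items():
            m = zr[idx].mean(axis=0)
            count_up[name] += int((m > obs_up[name]).sum()
                                  + (-m > obs_up[name]).sum())
            count_down[name] += int((m > -obs_up[name]).sum()
                                    + (-m > -obs_up[name]).sum())
            count_mixed[name] += int(
                (np.abs(zr[idx]).mean(axis=0) > obs_mixed[name]).sum())
        done += b

    rows = {}
    for name, idx in memberships.items():
        z = z_obs[idx]
        rows[name] = {
            "p_up": (count_up[name] + 1) / (2 * n_rot + 1),
            "p_down": (count_down[name] + 1) / (2 * n_rot + 1),
            "p_mixed": (count_mixed[name] + 1) / (n_rot + 1),
            "prop_up": float((z > SQRT2).mean()),
            "prop_down": float((z < -SQRT2).mean()),
            "n_genes_in_data": int(idx.size),
        }
    for name in untestable:
        rows[name] = {"p_up": np.nan, "p_down": np.nan, "p_mixed": np.nan,
                      "prop_up": np.nan, "prop_down": np.nan,
                      "n_genes_in_data": 0}
    out = pd.DataFrame(rows).T
    tested = out["n_genes_in_data"] > 0
    out["FDR_mixed"] = np.nan
    if tested.any():
        out.loc[tested, "FDR_mixed"] = bh_adjust(
            out.loc[tested, "p_mixed"].to_numpy())
    out["n_genes_in_data"] = out["n_genes_in_data"].astype(int)
    return out.loc[list(sets)]


# ---------------------------------------------------------------------------
# FRY
# ---------------------------------------------------------------------------

def _expected_max_u2(d1: int, n_nodes: int = 128) -> float:
    """E[max of d1 squared coordinates of a random unit vector], by
    Gauss-Legendre quadrature of the order statistic integral."""
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    u = (nodes + 1.0) / 2.0
    w = weights / 2.0
    d = d1 - 1
    return float(np.sum(d1 * u ** d * chi2.ppf(u, df=1) * w))


def fry_test(expr: pd.DataFrame, design: pd.DataFrame | np.ndarray,
             contrast: np.ndarray, sets: dict[str, list[str]]) -> pd.DataFrame:
    """Fast analytic rotation gene-set test.

    Genes are standardised by posterior residual SDs estimated robustly
    (leaving out each gene's largest squared coordinate, bias-corrected by
    the expected maximum under rotation). For each set the mean effects
    vector is treated as a single pseudo-gene: its t-statistic on the
    residual df gives directional p-values (the set-mean statistic's exact
    null under equal correlation); the mixed p-value comes from a beta
    approximation to the rotated quadratic form using the set's singular
    value spectrum. Single-gene sets reduce to the gene's moderated t-test.
    """
    effects = lm_effects(expr, design, contrast)
    E = effects.to_numpy()
    d1 = E.shape[1]
    d = d1 - 1
    # robust residual variance: drop the largest squared coordinate
    e_u2max = _expected_max_u2(d1)
    u2max = (E ** 2).max(axis=1)
    s2_robust = ((E ** 2).sum(axis=1) - u2max) / (d1 - e_u2max)
    s2 = (E[:, 1:] ** 2).mean(axis=1)
    s0_sq, d0 = fit_f_dist(s2, d)
    s2_robust = squeeze_var(s2_robust, 0.92 * d, s0_sq, d0)
    Es = E / np.sqrt(s2_robust)[:, None]

    rows = {}
    untestable = []
    for name, members in sets.items():
        idx = effects.index.get_indexer(members)
        idx = np.unique(idx[idx >= 0])
        if idx.size == 0:
            untestable.append(name)
            rows[name] = {"p_up": np.nan, "p_down": np.nan, "p_mixed": np.nan,
                          "prop_up": np.nan, "prop_down": np.nan,
                          "n_genes_in_data": 0}
            continue
        S = Es[idx]
        mean_vec = S.mean(axis=0)
        if idx.size == 1:
            # single-gene set: exactly the gene's moderated t-test
            s2_post1 = squeeze_var(s2[idx], d, s0_sq, d0)[0]
            t_set = E[idx[0], 0] / np.sqrt(s2_post1)
            p_two = 2.0 * t_dist.sf(abs(t_set), d0 + d)
        else:
            t_set = mean_vec[0] / np.sqrt(np.mean(mean_vec[1:] ** 2))
            p_two = 2.0 * t_dist.sf(abs(t_set), d)
        p_up = p_two / 2.0 if t_set > 0 else 1.0 - p_two / 2.0
        p_down = 1.0 - p_up
        if idx.size > 1:
            sv = np.linalg.svd(S, compute_uv=False)
            A = sv ** 2
            if A[0] - A[-1] < 1e-12:  # isotropic set: exact beta(1/2, d/2)
                f_obs = (S[:, 0] ** 2).sum() / A.sum()
                p_mixed = float(beta_dist.sf(f_obs, 0.5, d / 2.0))
            else:
                beta_mean = 1.0 / d1
                beta_var = d / d1 / d1 / (d1 / 2.0 + 1.0)
                f_obs = ((S[:, 0] ** 2).sum() - A[-1]) / (A[0] - A[-1])
                frb_mean = (A.sum() * beta_mean - A[-1]) / (A[0] - A[-1])
                cov = np.full((A.size, A.size), -beta_var / d)
                np.fill_diagonal(cov, beta_var)
                frb_var = float(A @ cov @ A) / (A[0] - A[-1]) ** 2
                apb = frb_mean * (1.0 - frb_mean) / frb_var - 1.0
                alpha = apb * frb_mean
                p_mixed = float(
                    beta_dist.sf(f_obs, max(alpha, 1e-12),
                                 max(apb - alpha, 1e-12)))
        else:
            p_mixed = p_two
        # proportions from the moderated z of member genes (shared with ROAST)
        s2_post = squeeze_var(s2[idx], d, s0_sq, d0)
        z = _zscore_t(E[idx, 0] / np.sqrt(s2_post), d0 + d)
        rows[name] = {"p_up": p_up, "p_down": p_down, "p_mixed": p_mixed,
                      "prop_up": float((z > SQRT2).mean()),
                      "prop_down": float((z < -SQRT2).mean()),
                      "n_genes_in_data": int(idx.size)}
    if untestable:
        warnings.warn(f"sets absent from the data: {untestable}", stacklevel=2)
    out = pd.DataFrame(rows).T
    tested = out["n_genes_in_data"] > 0
    out["FDR_mixed"] = np.nan
    if tested.any():
        out.loc[tested, "FDR_mixed"] = bh_adjust(
            out.loc[tested, "p_mixed"].to_numpy())
    out["n_genes_in_data"] = out["n_genes_in_data"].astype(int)
    return out.loc[list(sets)]
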