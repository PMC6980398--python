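"""Shared fixtures: a small synthetic study run once per session through
the differential-expression front end, reused by the pattern, gene-set and
proteomics tests."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from brainage import de
from brainage.simulate import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def study():
    """Default synthetic study with planted patterns, DE already fitted."""
    warnings.filterwarnings("ignore")
    cfg = SimConfig(seed=0)
    counts, design, truth = simulate_counts(cfg)
    kept = de.filter_by_cpm(counts, 1.5, 6)
    factors = de.tmm_factors(kept)
    logexpr = de.logcpm(kept, lib_size=kept.sum(axis=0) * factors)
    ruv = de.ruv_factors(logexpr, design.condition, k=1)
    X = de.condition_design(design, ruv)
    contrasts = {name: de.contrast_vector(X, a, b)
                 for name, (a, b) in design.contrasts.items()}
    result = de.fit_moderated(logexpr, X, contrasts)
    return {"config": cfg, "counts": counts, "design": design,
            "truth": truth, "logexpr": logexpr, "X": X,
            "contrasts": contrasts, "de": result}


@pytest.fixture(scope="session")
def null_study():
    """Same design with every planted effect set to zero."""
    warnings.filterwarnings("ignore")
    cfg = SimConfig(seed=42, n_genes=2000, pattern_counts={}, effect_size=0.0)
    counts, design, truth = simulate_counts(cfg)
    kept = de.filter_by_cpm(counts, 1.5, 6)
    logexpr = de.logcpm(kept, lib_size=kept.sum(axis=0) * de.tmm_factors(kept))
    ruv = de.ruv_factors(logexpr, design.condition, k=1)
    X = de.condition_design(design, ruv)
    contrasts = {name: de.contrast_vector(X, a, b)
                 for name, (a, b) in design.contrasts.items()}
    result = de.fit_moderated(logexpr, X, contrasts)
    return {"config": cfg, "design": design, "logexpr": logexpr,
            "X": X, "contrasts": contrasts, "de": result}


def make_de_result(rows: dict[str, dict[str, tuple[float, float, float]]]
                   ) -> de.DEResult:
    """Hand-built DEResult from {contrast: {gene: (logFC, p, FDR)}}."""
    tables = {}
    genes = sorted({g for tab in rows.values() for g in tab})
    for contrast, tab in rows.items():
        data = {g: tab.get(g, (0.0, 1.0, 1.0)) for g in genes}
        df = pd.DataFrame.from_dict(data, orient="index",
                                    columns=["logFC", "p", "FDR"])
        df["t"] = np.sign(df["logFC"]) * 1.0
        df["AveExpr"] = 0.0
        tables[contrast] = df
    return de.DEResult(tables=tables)
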