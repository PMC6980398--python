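"""Age x genotype expression-pattern taxonomy.

Genes are classified by how their mutant-vs-wild-type fold change behaves
across young and aged brains:

- ``inverted`` — the het-vs-wt fold change flips sign between young and
  aged animals (significant in one age, nominally significant in the other);
- ``inappropriately_down`` — down-regulated both during mutant aging and in
  aged mutants relative to aged wild types;
- ``failure_up`` / ``failure_down`` — genes that move during normal (wild
  type) aging but fail to move the same way in aged mutants;
- the concordance fraction and the aging signature quantify how much mutant
  expression change recapitulates normal aging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .de import DEResult

__all__ = [
    "PatternThresholds",
    "classify_inverted",
    "classify_failure_and_inappropriate",
    "assign_patterns",
    "concordance_fraction",
    "aging_signature",
    "cluster_fc_profiles",
]

C_YOUNG = "youngHet_vs_youngWt"
C_AGED = "agedHet_vs_agedWt"
C_WT_AGING = "agedWt_vs_youngWt"
C_HET_AGING = "agedHet_vs_youngHet"


@dataclass(frozen=True)
class PatternThresholds:
    fdr_primary: float = 0.05
    p_secondary_unadjusted: float = 0.05
    display_abs_log2fc: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.fdr_primary <= 1 and 0 < self.p_secondary_unadjusted <= 1):
            raise ValueError("significance thresholds must lie in (0, 1]")
        if self.display_abs_log2fc <= 0:
            raise ValueError("display_abs_log2fc must be positive")


def _table(de: DEResult, contrast: str) -> pd.DataFrame:
    return de[contrast]


def classify_inverted(de: DEResult,
                      th: PatternThresholds = PatternThresholds()) -> pd.Index:
    """Genes whose het-vs-wt fold change flips sign between ages.

    Requires FDR < ``fdr_primary`` in one of the two het-vs-wt contrasts and
    unadjusted p < ``p_secondary_unadjusted`` in the other (either
    orientation). A fold change of exactly 0 has no sign and never flips.
    """
    young, aged = _table(de, C_YOUNG), _table(de, C_AGED)
    sy, sa = np.sign(young["logFC"]), np.sign(aged["logFC"])
    flip = (sy != sa) & (sy != 0) & (sa != 0)
    sig = (((young["FDR"] < th.fdr_primary)
            & (aged["p"] < th.p_secondary_unadjusted))
           | ((aged["FDR"] < th.fdr_primary)
              & (young["p"] < th.p_secondary_unadjusted)))
    return young.index[flip & sig]


def classify_failure_and_inappropriate(
        de: DEResult, th: PatternThresholds = PatternThresholds()
) -> dict[str, pd.Index]:
    """The inappropriately-down and failure-to-regulate gene sets.

    - ``inappropriately_down``: significantly down in both mutant aging and
      aged het-vs-wt;
    - ``failure_up``: significantly up during wild-type aging but not
      significantly up in aged het-vs-wt (i.e. failing the FDR+sign
      criterion, not necessarily moving oppositely);
    - ``failure_down``: mirrored.
    """
    aged = _table(de, C_AGED)
    het_aging = _table(de, C_HET_AGING)
    wt_aging = _table(de, C_WT_AGING)
    fdr = th.fdr_primary

    sig_dn_aged = (aged["FDR"] < fdr) & (aged["logFC"] < 0)
    sig_up_aged = (aged["FDR"] < fdr) & (aged["logFC"] > 0)

    inapp_down = (het_aging["FDR"] < fdr) & (het_aging["logFC"] < 0) & sig_dn_aged
    fail_up = (wt_aging["FDR"] < fdr) & (wt_aging["logFC"] > 0) & ~sig_up_aged
    fail_down = (wt_aging["FDR"] < fdr) & (wt_aging["logFC"] < 0) & ~sig_dn_aged
    return {
        "inappropriately_down": aged.index[inapp_down],
        "failure_up": aged.index[fail_up],
        "failure_down": aged.index[fail_down],
    }


#: Precedence when a gene satisfies several pattern predicates.
PRECEDENCE = ("inverted", "inappropriately_down", "failure_up", "failure_down")


def assign_patterns(de: DEResult,
                    th: PatternThresholds = PatternThresholds()
                    ) -> tuple[pd.Series, dict[str, pd.Index]]:
    """Unique pattern label per gene by precedence, plus the raw sets.

    Group definitions overlap; precedence (inverted > inappropriately_down >
    failure groups) yields a partition. Returns ``(labels, raw_sets)`` where
    ``labels`` maps every gene to a pattern or ``"none"``.
    """
    raw = {"inverted": classify_inverted(de, th)}
    raw.update(classify_failure_and_inappropriate(de, th))
    universe = _table(de, C_AGED).index
    labels = pd.Series("none", index=universe, name="pattern")
    for name in reversed(PRECEDENCE):
        labels.loc[raw[name]] = name
    return labels, raw


def concordance_fraction(de: DEResult, contrast_a: str, contrast_b: str,
                         th: PatternThresholds = PatternThresholds()
                         ) -> tuple[float, int, int]:
    """Fraction of genes DE in contrast A whose fold change keeps its sign
    in contrast B. Returns ``(fraction, numerator, denominator)``;
    the fraction is NaN when no gene is DE in A."""
    a, b = _table(de, contrast_a), _table(de, contrast_b)
    de_a = a.index[a["FDR"] < th.fdr_primary]
    denom = len(de_a)
    if denom == 0:
        return float("nan"), 0, 0
    sa = np.sign(a.loc[de_a, "logFC"])
    sb = np.sign(b.loc[de_a, "logFC"])
    num = int(((sa == sb) & (sa != 0)).sum())
    return num / denom, num, denom


def aging_signature(de: DEResult,
                    th: PatternThresholds = PatternThresholds()) -> pd.Index:
    """Genes DE during both wild-type and mutant aging with concordant
    fold-change signs — the shared aging signature."""
    wt, het = _table(de, C_WT_AGING), _table(de, C_HET_AGING)
    both = ((wt["FDR"] < th.fdr_primary) & (het["FDR"] < th.fdr_primary))
    sw, sh = np.sign(wt["logFC"]), np.sign(het["logFC"])
    return wt.index[both & (sw == sh) & (sw != 0)]


def cluster_fc_profiles(genes: pd.Index, de: DEResult, n_clusters: int = 4,
                        th: PatternThresholds = PatternThresholds()
                        ) -> pd.DataFrame:
    """Display clustering of per-gene fold-change profiles.

    Genes passing the display filter (|log2FC| > ``display_abs_log2fc`` in at
    least one contrast) are clustered on their 4-vector of fold changes
    (Euclidean distance, complete linkage), with deterministic leaf order.
    Returns a frame with per-contrast logFC, cluster label and display rank.
    """
    contrasts = [C_YOUNG, C_AGED, C_WT_AGING, C_HET_AGING]
    fc = pd.DataFrame({c: _table(de, c).loc[genes, "logFC"] for c in contrasts})
    fc = fc.loc[fc.abs().max(axis=1) > th.display_abs_log2fc]
    out = fc.copy()
    if len(fc) == 0:
        out["cluster"], out["order"] = [], []
        return out
    if len(fc) == 1:
        out["cluster"], out["order"] = 1, 0
        return out
    Z = linkage(fc.to_numpy(), method="complete", metric="euclidean")
    k = min(n_clusters, len(fc))
    out["cluster"] = fcluster(Z, t=k, criterion="maxclust")
    order = leaves_list(Z)
    rank = np.empty(len(fc), dtype=int)
    rank[order] = np.arange(len(fc))
    out["order"] = rank
    return out.sort_values("order")
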