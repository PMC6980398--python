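"""Promoter extraction, PWM scanning and over-representation analysis.

Promoters are windows around annotated transcription start sites (default
1500 bp upstream, 200 bp downstream, strand-aware). Motifs are scanned as
log-odds scores of a position probability matrix against a background base
composition (uniform 0.25 by default) on both strands; a position is a hit
when its score reaches a fraction (default 90%) of the motif's maximum
attainable score. Enrichment of motifs or annotation terms in a gene list
is a one-sided hypergeometric test over a stated background universe with
Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "PWM",
    "extract_promoters",
    "scan_pwm",
    "motif_hit_genes",
    "overrepresentation_test",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position probability matrix with a fraction-of-maximum threshold.

    ``matrix`` is width x 4 (A, C, G, T) of per-position probabilities;
    ``threshold`` is the fraction of the maximum log-odds score required
    for a hit (the "90% match" convention), or an absolute log-odds score
    when ``threshold_is_fraction`` is False.
    """

    motif_id: str
    matrix: np.ndarray
    threshold: float = 0.90
    threshold_is_fraction: bool = True
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4 (A,C,G,T)")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")
        if self.threshold_is_fraction and not (0 < self.threshold <= 1):
            raise ValueError("fractional threshold must lie in (0, 1]")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, pseudo: float = 1e-4) -> np.ndarray:
        """Per-position log2-odds vs the background composition."""
        p = np.clip(self.matrix, pseudo, None)
        return np.log2(p / self.background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def score_cutoff(self) -> float:
        if self.threshold_is_fraction:
            return self.threshold * self.max_score()
        return self.threshold

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id + "_rc", self.matrix[::-1, ::-1],
                   self.threshold, self.threshold_is_fraction,
                   self.background[::-1].copy())


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------

def extract_promoters(tss: pd.DataFrame, genome: dict[str, str],
                      upstream: int = 1500, downstream: int = 200
                      ) -> tuple[dict[str, str], pd.DataFrame]:
    """Strand-aware promoter windows around transcription start sites.

    ``tss`` carries BED-style records (columns ``chrom, start, end, name,
    score, strand``; 0-based half-open, the TSS is ``start`` on + and
    ``end - 1`` on -). For + strand genes the window is
    ``[TSS - upstream, TSS + downstream)``; for - strand the mirrored
    window is extracted and reverse-complemented, so position 0 of every
    returned sequence is the most-upstream base. Windows truncated at
    contig edges are flagged; TSSs on missing contigs are skipped with a
    warning. Returns ``(sequences, provenance)``.
    """
    seqs: dict[str, str] = {}
    prov = []
    for rec in tss.itertuples(index=False):
        chrom, name, strand = str(rec.chrom), str(rec.name), str(rec.strand)
        if chrom not in genome:
            warnings.warn(f"TSS for {name} on missing contig {chrom}; skipped",
                          stacklevel=2)
            continue
        contig = genome[chrom]
        if strand == "+":
            pos = int(rec.start)
            lo, hi = pos - upstream, pos + downstream
        else:
            pos = int(rec.end) - 1
            lo, hi = pos - downstream + 1, pos + upstream + 1
        truncated = lo < 0 or hi > len(contig)
        seq = contig[max(lo, 0):min(hi, len(contig))].upper()
        if strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        if pos < 0 or pos >= len(contig):
            warnings.warn(f"TSS for {name} off contig {chrom}; skipped",
                          stacklevel=2)
            continue
        seqs[name] = seq
        prov.append((name, chrom, strand, max(lo, 0), min(hi, len(contig)),
                     truncated))
    return seqs, pd.DataFrame(
        prov, columns=["gene", "chrom", "strand", "start", "end", "truncated"])


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    """Sequence -> index array; N (or any other symbol) -> 4."""
    lut = np.full(128, 4, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_one(idx: np.ndarray, lo_matrix: np.ndarray) -> np.ndarray:
    """Sliding log-odds scores; N bases contribute 0 (background odds)."""
    w = lo_matrix.shape[0]
    n = idx.size - w + 1
    if n <= 0:
        return np.empty(0)
    padded = np.hstack([lo_matrix, np.zeros((w, 1))])  # column 4 = N -> 0
    scores = np.zeros(n)
    for j in range(w):
        scores += padded[j, idx[j:j + n]]
    return scores


def scan_pwm(promoters: dict[str, str], pwm: PWM) -> pd.DataFrame:
    """Scan every promoter on both strands.

    Returns a hit table (gene, position, strand, score); positions are
    0-based offsets of the match start on the promoter's forward
    coordinates for both strands. Promoters shorter than the motif yield
    no hits.
    """
    cutoff = pwm.score_cutoff()
    lo_fwd = pwm.log_odds()
    lo_rev = pwm.reverse_complement().log_odds()
    rows = []
    for gene, seq in promoters.items():
        idx = _encode(seq)
        for strand, lo in (("+", lo_fwd), ("-", lo_rev)):
            scores = _scan_one(idx, lo)
            for pos in np.flatnonzero(scores >= cutoff - 1e-12):
                rows.append((gene, int(pos), strand, float(scores[pos])))
    return pd.DataFrame(rows, columns=["gene", "position", "strand", "score"])


def motif_hit_genes(promoters: dict[str, str], pwm: PWM) -> set[str]:
    """Genes with at least one hit (enrichment counts genes, not hits)."""
    hits = scan_pwm(promoters, pwm)
    return set(hits["gene"])


# ---------------------------------------------------------------------------
# Over-representation
# ---------------------------------------------------------------------------

def overrepresentation_test(target: set[str], background: set[str],
                            annotation: dict[str, set[str]]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with Bonferroni.

    ``target`` must be a subset of ``background``; terms are restricted to
    the background universe before testing. Returns a per-term table
    (overlap, target_size, term_size, background_size, p, p_bonferroni)
    sorted by p.
    """
    stray = set(target) - set(background)
    if stray:
        raise ValueError(
            f"target genes outside the background universe: {sorted(stray)[:10]}")
    n_bg = len(background)
    n_target = len(target)
    rows = {}
    for term, members in annotation.items():
        in_bg = set(members) & set(background)
        k = len(in_bg & set(target))
        p = float(hypergeom.sf(k - 1, n_bg, len(in_bg), n_target))
        rows[term] = {"overlap": k, "target_size": n_target,
                      "term_size": len(in_bg), "background_size": n_bg,
                      "p": p}
    out = pd.DataFrame(rows).T
    out["p_bonferroni"] = np.minimum(out["p"] * len(annotation), 1.0)
    for c in ("overlap", "target_size", "term_size", "background_size"):
        out[c] = out[c].astype(int)
    return out.sort_values("p")
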