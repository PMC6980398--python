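"""Synthetic study generator.

Generates complete synthetic studies carrying the statistical structure
the analysis stages assume: negative-binomial RNA-seq counts for a 2x2
(young/aged x wt/het) design with three replicates per condition and a
rank-1 batch effect; correlated gene blocks (modules) replicated with
varying fidelity in a second species; motif-annotated promoters; and
peptide tables with left-censoring. Truth labels are emitted alongside the
data and are never consumed by analysis stages.

Planted expression patterns (log2 condition offsets of size ``effect_size``
relative to the wild-type baseline):

===============  ========  ========  ========  ========
pattern          young_wt  young_het aged_wt   aged_het
===============  ========  ========  ========  ========
inverted         0         +e        0         -e
accel_aging      0         +e        +e        +e
fail_up          0         0         +e        0
fail_down        0         0         -e        0
inapprop_down    0         0         0         -e
aging_only       0         0         +-e       +-e
null             0         0         0         0
===============  ========  ========  ========  ========

(accelerated-aging genes carry the aging offset already in young mutants;
failure genes move during wild-type aging only; aging-only genes move the
same way in both genotypes, sign random per gene.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import StudyDesign
from .enrichment import PWM

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "PATTERNS",
    "simulate_counts",
    "simulate_module_expression",
    "simulate_promoters",
    "simulate_peptides",
]

PATTERNS = ("inverted", "accel_aging", "fail_up", "fail_down",
            "inapprop_down", "aging_only", "null")
CONDITIONS = ("young_wt", "young_het", "aged_wt", "aged_het")


@dataclass
class SimConfig:
    """Study-level simulation parameters.

    Defaults mirror the study design the analysis targets: a 2x2 design
    with three biological replicates per condition, a common NB dispersion
    of 0.1 (typical bulk brain RNA-seq), and a single rank-1 batch factor
    aligned with replicate index.
    """

    n_genes: int = 2000
    n_reps_per_condition: int = 3
    pattern_counts: dict[str, int] = field(default_factory=lambda: {
        "inverted": 80, "accel_aging": 80, "fail_up": 80, "fail_down": 40,
        "inapprop_down": 60, "aging_only": 120})
    effect_size: float = 2.0
    dispersion: float = 0.1
    lib_size_range: tuple[int, int] = (8_000_000, 12_000_000)
    batch_effect_sd: float = 0.3
    n_modules: int = 5
    module_size_range: tuple[int, int] = (40, 60)
    module_cor: float = 0.8
    preserved_fraction: float = 0.6
    motif_library: list[str] = field(default_factory=lambda: ["GRE"])
    motif_target_fraction: float = 0.6
    protein_rho: float = 0.4
    censor_quantile: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.pattern_counts) - set(PATTERNS)
        if unknown:
            raise ValueError(f"unknown pattern labels: {sorted(unknown)}")
        if sum(self.pattern_counts.values()) > self.n_genes:
            raise ValueError("sum of pattern_counts exceeds n_genes")
        if not 0 < self.module_cor < 1:
            raise ValueError("module_cor must lie in (0, 1)")
        if not -1 <= self.protein_rho <= 1:
            raise ValueError("protein_rho must lie in [-1, 1]")
        for name in ("n_genes", "n_reps_per_condition", "n_modules"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible per-component substream of the seed."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _stream_key(stream)]))


def _stream_key(s: str) -> int:
    # stable FNV-1a hash so substreams don't depend on PYTHONHASHSEED
    h = 2166136261
    for ch in s.encode():
        h = (h ^ ch) * 16777619 % (2 ** 32)
    return h % (2 ** 31)


@dataclass
class PlantedTruth:
    """Ground truth emitted next to the data, never fed to analysis."""

    pattern: pd.Series | None = None
    condition_log2_offset: pd.DataFrame | None = None
    baseline_log2: pd.Series | None = None
    library_sizes: pd.Series | None = None
    modules: dict[str, pd.Series] = field(default_factory=dict)
    module_preserved: pd.Series | None = None
    motif_flags: pd.DataFrame | None = None
    motif_positions: pd.DataFrame | None = None
    protein_profile: pd.DataFrame | None = None
    batch: pd.Series | None = None


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _pattern_offsets(cfg: SimConfig, rng: np.random.Generator
                     ) -> tuple[pd.Series, pd.DataFrame]:
    genes = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    labels = pd.Series("null", index=genes, name="pattern")
    pos = 0
    for pat in PATTERNS:
        k = cfg.pattern_counts.get(pat, 0)
        if pat == "null":
            continue
        labels.iloc[pos:pos + k] = pat
        pos += k
    e = cfg.effect_size
    off = pd.DataFrame(0.0, index=genes, columns=list(CONDITIONS))
    for g in labels.index:
        pat = labels.loc[g]
        if pat == "inverted":
            off.loc[g, ["young_het", "aged_het"]] = (e, -e)
        elif pat == "accel_aging":
            off.loc[g, ["young_het", "aged_wt", "aged_het"]] = (e, e, e)
        elif pat == "fail_up":
            off.loc[g, "aged_wt"] = e
        elif pat == "fail_down":
            off.loc[g, "aged_wt"] = -e
        elif pat == "inapprop_down":
            off.loc[g, "aged_het"] = -e
        elif pat == "aging_only":
            s = e if rng.random() < 0.5 else -e
            off.loc[g, ["aged_wt", "aged_het"]] = (s, s)
    return labels, off


def simulate_counts(cfg: SimConfig
                    ) -> tuple[pd.DataFrame, StudyDesign, PlantedTruth]:
    """Negative-binomial count matrix for the 2x2 design.

    Counts ~ NB(mean = lib_j * q_gc, var = mu + phi mu^2) where log2 q_gc
    sums a gene baseline, the pattern offset of the gene's condition, and a
    rank-1 batch term (batch scalar x gene loading) shared by all samples
    of a replicate batch. Library sizes are uniform in ``lib_size_range``.
    """
    rng = cfg.rng("counts")
    labels, off = _pattern_offsets(cfg, rng)
    genes = labels.index
    n_rep = cfg.n_reps_per_condition
    samples, cond_of, batch_of = [], [], []
    for cond in CONDITIONS:
        for r in range(n_rep):
            samples.append(f"{cond}_r{r + 1}")
            cond_of.append(cond)
            batch_of.append(f"b{r + 1}")
    meta = pd.DataFrame({
        "genotype": [c.split("_")[1] for c in cond_of],
        "age": [c.split("_")[0] for c in cond_of],
        "batch": batch_of,
    }, index=pd.Index(samples, name="sample_id"))
    design = StudyDesign(meta=meta)

    # baseline abundances: broad log-normal, normalised to proportions
    base = rng.normal(loc=4.0, scale=2.0, size=cfg.n_genes)  # log2 scale
    batch_scalar = rng.normal(0.0, cfg.batch_effect_sd, size=n_rep)
    gene_loading = rng.normal(0.0, 1.0, size=cfg.n_genes)
    lib = rng.integers(cfg.lib_size_range[0], cfg.lib_size_range[1] + 1,
                       size=len(samples)).astype(float)

    log2q = np.empty((cfg.n_genes, len(samples)))
    for j, (cond, b) in enumerate(zip(cond_of, batch_of)):
        r = int(b[1:]) - 1
        log2q[:, j] = (base + off[cond].to_numpy()
                       + batch_scalar[r] * gene_loading)
    q = 2.0 ** log2q
    q /= q.sum(axis=0, keepdims=True)
    mu = q * lib[None, :]
    phi = cfg.dispersion
    if phi > 0:
        n_param = 1.0 / phi
        counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = PlantedTruth(pattern=labels, condition_log2_offset=off,
                         baseline_log2=pd.Series(base, index=genes,
                                                 name="baseline_log2"),
                         library_sizes=pd.Series(lib, index=samples,
                                                 name="lib_size"),
                         batch=pd.Series(batch_of, index=meta.index,
                                         name="batch"))
    return counts_df, design, truth


# ---------------------------------------------------------------------------
# Module expression (two species)
# ---------------------------------------------------------------------------

def simulate_module_expression(cfg: SimConfig, n_samples: int = 12,
                               n_samples_b: int | None = None,
                               unpreserved: str = "independent"
                               ) -> tuple[pd.DataFrame, pd.DataFrame,
                                          pd.DataFrame, PlantedTruth]:
    """Gaussian expression with planted co-expression modules in two species.

    Each module's genes load on a latent per-sample factor with loading
    ``sqrt(v_i)`` and noise ``sqrt(1 - v_i)``, so the correlation of two
    module genes is ``sqrt(v_i v_j) ~ module_cor``; per-gene loadings vary
    mildly around the target so intramodular connectivity has structure to
    preserve. A ``preserved_fraction`` of modules reuse the same loadings
    in species B (new latent factor realisation, same topology). The rest
    depend on ``unpreserved``: ``"independent"`` (default) keeps them
    coherent modules in B but on independent factors with re-drawn
    loadings (connectivity topology lost, density kept);
    ``"noise"`` dissolves them into unstructured noise in B (both density
    and connectivity lost — the null that permutation preservation tests
    probe). The ortholog map links gene ids one-to-one.
    """
    if unpreserved not in ("independent", "noise"):
        raise ValueError("unpreserved must be 'independent' or 'noise'")
    if cfg.n_modules * max(cfg.module_size_range) > cfg.n_genes:
        raise ValueError("modules cannot cover more genes than n_genes")
    rng = cfg.rng("modules")
    if n_samples_b is None:
        n_samples_b = n_samples
    sizes = rng.integers(cfg.module_size_range[0],
                         cfg.module_size_range[1] + 1, size=cfg.n_modules)
    genes_a = pd.Index([f"a{i:05d}" for i in range(cfg.n_genes)])
    genes_b = pd.Index([f"b{i:05d}" for i in range(cfg.n_genes)])
    labels = np.zeros(cfg.n_genes, dtype=int)
    # membership scattered over gene ids so independent simulations do not
    # share modular positions
    order = rng.permutation(cfg.n_genes)
    pos = 0
    for m, size in enumerate(sizes, start=1):
        labels[order[pos:pos + size]] = m
        pos += size

    v = np.zeros(cfg.n_genes)
    in_mod = labels > 0
    v[in_mod] = np.clip(
        cfg.module_cor + rng.uniform(-0.1, 0.1, size=in_mod.sum()),
        0.05, 0.98)
    n_preserved = int(round(cfg.preserved_fraction * cfg.n_modules))
    preserved = np.zeros(cfg.n_modules + 1, dtype=bool)
    preserved[1:n_preserved + 1] = True

    def _expr(n_s: int, loadings: np.ndarray, gen: np.random.Generator
              ) -> np.ndarray:
        factors = gen.standard_normal((cfg.n_modules + 1, n_s))
        # standardise each factor realisation so the realised within-module
        # correlation tracks the loading target even at few samples
        factors = (factors - factors.mean(axis=1, keepdims=True))
        factors /= factors.std(axis=1, keepdims=True)
        x = gen.standard_normal((cfg.n_genes, n_s))
        for m in range(1, cfg.n_modules + 1):
            sel = labels == m
            x[sel] = (np.sqrt(loadings[sel])[:, None] * factors[m]
                      + np.sqrt(1.0 - loadings[sel])[:, None] * x[sel])
        return x

    expr_a = _expr(n_samples, v, rng)
    v_b = v.copy()
    redraw = in_mod & ~preserved[labels]
    if unpreserved == "noise":
        v_b[redraw] = 0.0
    else:
        v_b[redraw] = np.clip(
            cfg.module_cor + rng.uniform(-0.1, 0.1, size=redraw.sum()),
            0.05, 0.98)
    expr_b = _expr(n_samples_b, v_b, rng)

    ea = pd.DataFrame(expr_a, index=genes_a,
                      columns=[f"sA{j + 1}" for j in range(n_samples)])
    eb = pd.DataFrame(expr_b, index=genes_b,
                      columns=[f"sB{j + 1}" for j in range(n_samples_b)])
    ortho = pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b})
    truth = PlantedTruth(
        modules={"a": pd.Series(labels, index=genes_a, name="module"),
                 "b": pd.Series(labels, index=genes_b, name="module")},
        module_preserved=pd.Series(preserved[1:],
                                   index=range(1, cfg.n_modules + 1),
                                   name="preserved"))
    return ea, eb, ortho, truth


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def simulate_promoters(flagged_genes: pd.Series, pwms: list[PWM],
                       all_genes: list[str] | None = None,
                       length: int = 1700, seed: int = 0,
                       base_probs: tuple[float, float, float, float]
                       = (0.25, 0.25, 0.25, 0.25),
                       sample_occurrence: bool = False
                       ) -> tuple[dict[str, str], pd.DataFrame]:
    """Random promoters with motif occurrences planted in flagged genes.

    ``flagged_genes`` maps gene id -> motif id (or '' / NaN for none).
    Background bases are i.i.d. with ``base_probs``; each flagged gene gets
    one occurrence of its motif consensus (so every planted occurrence
    scores at the motif's maximum and truth recovery is well-defined) at a
    uniform position on a uniform strand; ``sample_occurrence=True``
    samples the occurrence from the PWM columns instead. Returns
    ``(sequences, insertions)`` where insertions records gene, motif,
    position and strand.
    """
    rng = np.random.default_rng(seed)
    pwm_by_id = {p.motif_id: p for p in pwms}
    for p in pwms:
        if p.width > length:
            raise ValueError(f"PWM {p.motif_id} wider than promoter length")
    genes = list(all_genes) if all_genes is not None else list(flagged_genes.index)
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    rows = []
    for g in genes:
        seq = rng.choice(bases, size=length, p=base_probs)
        motif_id = flagged_genes.get(g, "")
        if isinstance(motif_id, str) and motif_id:
            pwm = pwm_by_id[motif_id]
            if sample_occurrence:
                occ = np.array([bases[rng.choice(4, p=row / row.sum())]
                                for row in pwm.matrix])
            else:
                occ = np.array(list(pwm.consensus()))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                occ = np.array([comp[b] for b in occ[::-1]])
            start = int(rng.integers(0, length - pwm.width + 1))
            seq[start:start + pwm.width] = occ
            rows.append((g, motif_id, start, strand))
        seqs[g] = "".join(seq)
    ins = pd.DataFrame(rows, columns=["gene", "motif", "position", "strand"])
    return seqs, ins


# ---------------------------------------------------------------------------
# Peptides
# ---------------------------------------------------------------------------

def simulate_peptides(mrna_profile: pd.DataFrame, cfg: SimConfig,
                      n_peptides_per_protein: tuple[int, int] = (2, 6),
                      base_intensity: float = 20.0, noise_sd: float = 0.3,
                      protein_scale: float = 4.0
                      ) -> tuple[pd.DataFrame, PlantedTruth]:
    """Peptide intensity table coupled to mRNA profiles with left-censoring.

    Protein log2 abundance is Gaussian-copula coupled to the mRNA level
    **across genes**: within each sample the mRNA values are converted to
    normal scores z, and protein = rho' z + sqrt(1 - rho'^2) eta with a
    per-gene (translation-efficiency-like) offset eta and the loading
    rho' = 2 sin(pi rho / 6) — the exact bivariate-normal inversion giving
    gene-wise Spearman correlation ``protein_rho``. Peptide log2 intensity
    = protein + peptide offset + error; entries below the
    ``censor_quantile`` of the global intensity distribution are reported
    missing (left-censored). Returns the long table (intensities on the
    raw, linear scale) and the protein-level truth.
    """
    from scipy.stats import norm as _norm

    rng = cfg.rng("peptides")
    rho_pearson = 2.0 * np.sin(np.pi * cfg.protein_rho / 6.0)
    prof = mrna_profile.to_numpy(dtype=float)
    n_g = prof.shape[0]
    # normal scores across genes, per sample
    ranks = prof.argsort(axis=0).argsort(axis=0) + 1.0
    z = _norm.ppf((ranks - 0.5) / n_g)
    genes = mrna_profile.index
    eta = rng.standard_normal((n_g, 1))
    # protein_scale sets the log2 dynamic range of protein abundances
    # (proteomes span far more than transcript noise), keeping peptide
    # offsets comparatively small after summarisation
    protein = protein_scale * (
        rho_pearson * z + np.sqrt(max(0.0, 1.0 - rho_pearson ** 2)) * eta)
    protein_ids = pd.Index([f"prot_{g}" for g in genes])
    samples = list(mrna_profile.columns)

    rows = []
    for i, pid in enumerate(protein_ids):
        n_pep = int(rng.integers(n_peptides_per_protein[0],
                                 n_peptides_per_protein[1] + 1))
        for p in range(n_pep):
            offset = rng.normal(0.0, 2.0)
            err = rng.normal(0.0, noise_sd, size=len(samples))
            log2_int = base_intensity + protein[i] + offset + err
            for j, s in enumerate(samples):
                rows.append((f"{pid}_pep{p + 1}", pid, s, log2_int[j]))
    table = pd.DataFrame(rows, columns=["peptide_id", "protein_id",
                                        "sample_id", "intensity"])
    if cfg.censor_quantile > 0:
        cut = table["intensity"].quantile(cfg.censor_quantile)
        table.loc[table["intensity"] < cut, "intensity"] = np.nan
    table["intensity"] = 2.0 ** table["intensity"]
    truth = PlantedTruth(protein_profile=pd.DataFrame(
        protein, index=protein_ids, columns=samples))
    return table, truth
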