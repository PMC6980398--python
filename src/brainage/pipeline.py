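"""End-to-end orchestration of the synthetic-study analysis.

``run_pipeline`` executes the stages in dependency order — simulate (or
ingest) counts, differential expression, pattern classification, gene-set
testing, network construction, module preservation, promoter motif
enrichment and proteomics — writing per-stage artefacts plus a
machine-readable ``summary.json`` that twins the study's headline numbers
(DE counts per contrast, pattern-group sizes, significant gene sets,
module counts, preserved modules, enriched motifs, differentially
abundant proteins, mRNA-protein correlation).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import de, enrichment, network, patterns, preservation, proteomics, rotation
from .simulate import (SimConfig, simulate_counts, simulate_module_expression,
                       simulate_peptides, simulate_promoters)

__all__ = ["default_config", "validate_config", "run_pipeline", "gre_pwm"]


def gre_pwm(threshold: float = 0.90) -> enrichment.PWM:
    """A glucocorticoid-receptor-element-like palindromic motif
    (AGAACAnnnTGTTCT) as a probability matrix, 85% consensus weight."""
    consensus = "AGAACANNNTGTTCT"
    rows = []
    for b in consensus:
        if b == "N":
            rows.append([0.25] * 4)
        else:
            row = [0.05] * 4
            row["ACGT".index(b)] = 0.85
            rows.append(row)
    return enrichment.PWM("GRE", np.array(rows), threshold)


def default_config(seed: int = 0) -> dict[str, Any]:
    """Full default configuration; every study constant surfaced here."""
    return {
        "seed": seed,
        "simulate": dataclasses.asdict(SimConfig(seed=seed)),
        "de": {"min_cpm": 1.5, "min_samples": 6, "ruv_k": 1},
        "patterns": {"fdr_primary": 0.05, "p_secondary_unadjusted": 0.05,
                     "display_abs_log2fc": 0.5},
        "gst": {"method": "fry", "n_rot": 9999, "n_random_sets": 20,
                "set_size": 30},
        "network": {"soft_power": 14.0, "min_module_size": 40,
                    "deep_split": 1, "pam_max_distance": 0.90,
                    "connectivity_filter_percentile": 10.0},
        "preservation": {"n_perm": 200, "random_module_size": 1000},
        "enrichment": {"upstream": 1500, "downstream": 200,
                       "motif_threshold": 0.90, "promoter_length": 1700},
        "proteomics": {"n_proteins": 300},
        "stages": {"de": True, "patterns": True, "gst": True,
                   "network": True, "preservation": True,
                   "enrichment": True, "proteomics": True},
    }


def validate_config(config: dict[str, Any]) -> list[str]:
    """Itemised validation messages; empty list means valid."""
    errors: list[str] = []
    if "seed" not in config:
        errors.append("missing 'seed'")
    for key in ("counts_path", "metadata_path"):
        if key in config and not Path(config[key]).exists():
            errors.append(f"{key} does not exist: {config[key]}")
    pat = config.get("patterns", {})
    for k in ("fdr_primary", "p_secondary_unadjusted"):
        v = pat.get(k, 0.05)
        if not 0 < v <= 1:
            errors.append(f"patterns.{k} must lie in (0, 1], got {v}")
    if pat.get("display_abs_log2fc", 0.5) <= 0:
        errors.append("patterns.display_abs_log2fc must be positive")
    net = config.get("network", {})
    if net.get("soft_power", 14) < 1:
        errors.append("network.soft_power must be >= 1")
    if not 0 < net.get("pam_max_distance", 0.9) <= 1:
        errors.append("network.pam_max_distance must lie in (0, 1]")
    if config.get("gst", {}).get("n_rot", 9999) < 1:
        errors.append("gst.n_rot must be positive")
    if config.get("preservation", {}).get("n_perm", 200) < 20:
        errors.append("preservation.n_perm must be >= 20")
    if "simulate" in config and config["simulate"] is not None:
        try:
            sim = {k: v for k, v in config["simulate"].items()}
            sim["pattern_counts"] = dict(sim.get("pattern_counts", {}))
            SimConfig(**sim)
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate: {exc}")
    return errors


def _config_hash(config: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Execute the enabled stages; artefacts land under ``out_dir``.

    Returns the summary dict (also written to ``summary.json`` alongside
    provenance: config hash and seed).
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", {})
    seed = int(config["seed"])
    summary: dict[str, Any] = {"provenance": {
        "config_hash": _config_hash(config), "seed": seed}}

    # ------------------------------------------------------------- inputs
    sim_cfg_dict = dict(config.get("simulate") or {})
    sim_cfg_dict["seed"] = seed
    sim_cfg = SimConfig(**sim_cfg_dict)
    if "counts_path" in config:
        counts = pd.read_csv(config["counts_path"], sep="\t", index_col=0)
        meta = pd.read_csv(config["metadata_path"], sep="\t", index_col=0)
        design = de.StudyDesign(meta=meta)
        truth = None
    else:
        counts, design, truth = simulate_counts(sim_cfg)
        (out / "sim").mkdir(exist_ok=True)
        counts.to_csv(out / "sim" / "counts.tsv", sep="\t")
        design.meta.to_csv(out / "sim" / "metadata.tsv", sep="\t")
        truth.pattern.to_csv(out / "sim" / "truth_patterns.tsv", sep="\t")

    # ----------------------------------------------------------------- DE
    de_result = None
    logexpr = None
    if stages.get("de", True):
        p = config.get("de", {})
        kept = de.filter_by_cpm(counts, p.get("min_cpm", 1.5),
                                min(p.get("min_samples", 6), counts.shape[1]))
        factors = de.tmm_factors(kept)
        eff_lib = kept.sum(axis=0) * factors
        logexpr = de.logcpm(kept, lib_size=eff_lib)
        ruv = de.ruv_factors(logexpr, design.condition, k=p.get("ruv_k", 1))
        X = de.condition_design(design, ruv)
        contrasts = {name: de.contrast_vector(X, a, b)
                     for name, (a, b) in design.contrasts.items()}
        de_result = de.fit_moderated(logexpr, X, contrasts)
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        for name, tab in de_result.tables.items():
            tab.to_csv(de_dir / f"{name}.tsv", sep="\t")
        summary["de_counts"] = {
            name: int((tab["FDR"] < 0.05).sum())
            for name, tab in de_result.tables.items()}

    # ----------------------------------------------------------- patterns
    if stages.get("patterns", True) and de_result is not None:
        th = patterns.PatternThresholds(**config.get("patterns", {}))
        labels, raw = patterns.assign_patterns(de_result, th)
        frac, num, den = patterns.concordance_fraction(
            de_result, patterns.C_YOUNG, patterns.C_WT_AGING, th)
        signature = patterns.aging_signature(de_result, th)
        pat_dir = out / "patterns"
        pat_dir.mkdir(exist_ok=True)
        labels.to_csv(pat_dir / "labels.tsv", sep="\t")
        clusters = patterns.cluster_fc_profiles(
            labels.index[labels != "none"], de_result, th=th)
        clusters.to_csv(pat_dir / "display_clusters.tsv", sep="\t")
        summary["pattern_groups"] = {
            k: int(len(v)) for k, v in raw.items()}
        summary["pattern_partition"] = {
            k: int(n) for k, n in labels.value_counts().items()}
        summary["concordance"] = {"fraction": None if np.isnan(frac) else
                                  round(float(frac), 4),
                                  "numerator": num, "denominator": den}
        summary["aging_signature_n"] = int(len(signature))

    # ---------------------------------------------------------------- GST
    if stages.get("gst", True) and de_result is not None and truth is not None:
        g = config.get("gst", {})
        rng = np.random.default_rng(seed + 1)
        sets: dict[str, list[str]] = {}
        for pat in ("inverted", "accel_aging", "aging_only"):
            members = [x for x in truth.pattern.index[truth.pattern == pat]
                       if x in logexpr.index]
            if members:
                sets[f"planted_{pat}"] = members
        universe = list(logexpr.index)
        for i in range(g.get("n_random_sets", 20)):
            sets[f"random{i:02d}"] = list(
                rng.choice(universe, size=g.get("set_size", 30), replace=False))
        X = de.condition_design(design, de.ruv_factors(
            logexpr, design.condition, k=config.get("de", {}).get("ruv_k", 1)))
        gst_dir = out / "gst"
        gst_dir.mkdir(exist_ok=True)
        n_sig = {}
        for name, (a, b) in design.contrasts.items():
            c = de.contrast_vector(X, a, b)
            if g.get("method", "fry") == "fry":
                res = rotation.fry_test(logexpr, X, c, sets)
            else:
                res = rotation.roast_test(logexpr, X, c, sets,
                                          n_rot=g.get("n_rot", 9999),
                                          seed=seed + 2)
            res.to_csv(gst_dir / f"{name}.tsv", sep="\t")
            n_sig[name] = int((res["FDR_mixed"] < 0.05).sum())
        summary["significant_gene_sets"] = n_sig

    # ------------------------------------------------------------ network
    labels_a = None
    expr_a = expr_b = ortho = None
    if stages.get("network", True):
        params = network.NetworkParams(**config.get("network", {}))
        expr_a, expr_b, ortho, net_truth = simulate_module_expression(sim_cfg)
        filtered = network.connectivity_filter(expr_a, params)
        adj = network.signed_adjacency(filtered, params.soft_power)
        tom = network.topological_overlap(adj)
        assignment = network.cut_modules(1.0 - tom, params)
        labels_a = assignment.labels
        net_dir = out / "network"
        net_dir.mkdir(exist_ok=True)
        labels_a.to_csv(net_dir / "modules.tsv", sep="\t")
        if (labels_a != 0).any():
            eigs, varexp = network.module_eigengene(filtered, labels_a)
            eigs.to_csv(net_dir / "eigengenes.tsv", sep="\t")
        summary["n_modules"] = int(labels_a.max())
        summary["n_unassigned_genes"] = int((labels_a == 0).sum())

    # ------------------------------------------------------- preservation
    if stages.get("preservation", True) and labels_a is not None \
            and (labels_a != 0).any():
        p = config.get("preservation", {})
        pres = preservation.zsummary(
            expr_a, expr_b, labels_a, ortho,
            n_perm=p.get("n_perm", 200), seed=seed + 3)
        pres_dir = out / "preservation"
        pres_dir.mkdir(exist_ok=True)
        pres.summary.to_csv(pres_dir / "zsummary.tsv", sep="\t")
        size = min(p.get("random_module_size", 1000), len(ortho) // 2)
        # negative control: an independently simulated network (no shared
        # structure at all) stands in for the unrelated-test-network case
        indep_cfg = dataclasses.replace(sim_cfg, seed=seed + 101)
        expr_indep = simulate_module_expression(indep_cfg)[0]
        baseline = preservation.random_module_baseline(
            expr_a, expr_indep, None, size=size,
            n_perm=p.get("n_perm", 200), seed=seed + 4)
        baseline.summary.to_csv(pres_dir / "random_baseline.tsv", sep="\t")
        summary["preserved_modules"] = {
            str(m): row["classification"]
            for m, row in pres.summary.iterrows()}
        summary["random_module_zsummary"] = round(
            float(baseline.summary["Z_summary"].iloc[0]), 4)

    # --------------------------------------------------------- enrichment
    if stages.get("enrichment", True) and truth is not None:
        e = config.get("enrichment", {})
        pwm = gre_pwm(e.get("motif_threshold", 0.90))
        rng = np.random.default_rng(seed + 5)
        inv = truth.pattern.index[truth.pattern == "inverted"]
        n_flag = int(round(sim_cfg.motif_target_fraction * len(inv)))
        flagged = pd.Series("", index=truth.pattern.index)
        if n_flag:
            flagged.loc[rng.choice(inv, size=n_flag, replace=False)] = "GRE"
        promoters, _ = simulate_promoters(
            flagged, [pwm], length=e.get("promoter_length", 1700),
            seed=seed + 6)
        hit_genes = enrichment.motif_hit_genes(promoters, pwm)
        background = set(truth.pattern.index)
        res = enrichment.overrepresentation_test(
            set(inv), background, {"GRE": hit_genes})
        enr_dir = out / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        res.to_csv(enr_dir / "motif_enrichment.tsv", sep="\t")
        summary["enriched_motifs"] = {
            m: round(float(r["p_bonferroni"]), 6)
            for m, r in res.iterrows() if r["p_bonferroni"] < 0.05}

    # --------------------------------------------------------- proteomics
    if stages.get("proteomics", True) and logexpr is not None:
        n_prot = config.get("proteomics", {}).get("n_proteins", 300)
        mrna = logexpr.iloc[:n_prot]
        table, _ = simulate_peptides(mrna, sim_cfg)
        mat, pep2prot = proteomics.peptide_matrix(table)
        normed = proteomics.normalize_peptides(mat)
        completed = proteomics.impute_censored(normed)
        pep2prot = pep2prot.loc[completed.index]
        prots = proteomics.filter_complete(
            proteomics.median_polish_summarize(completed, pep2prot))
        Xp = de.condition_design(design)
        contrasts = {name: de.contrast_vector(Xp, a, b)
                     for name, (a, b) in design.contrasts.items()}
        da = proteomics.differential_abundance(prots, Xp, contrasts)
        prot_dir = out / "proteomics"
        prot_dir.mkdir(exist_ok=True)
        prots.to_csv(prot_dir / "proteins.tsv", sep="\t")
        for name, tab in da.tables.items():
            tab.to_csv(prot_dir / f"da_{name}.tsv", sep="\t")
        gene_of = pd.Series({p: p.replace("prot_", "")
                             for p in prots.index})
        idmap = pd.DataFrame({"gene_id": gene_of.values,
                              "protein_id": gene_of.index})
        r_s, n_pairs = proteomics.mrna_protein_correlation(
            mrna.mean(axis=1), prots.mean(axis=1), idmap)
        summary["da_counts"] = {name: int((tab["FDR"] < 0.05).sum())
                                for name, tab in da.tables.items()}
        summary["mrna_protein_spearman"] = {"r_s": round(r_s, 4),
                                            "n_pairs": n_pairs}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
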