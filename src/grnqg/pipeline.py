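"""End-to-end orchestration of the synthetic benchmark and its report.

A :class:`RunConfig` (JSON/YAML-friendly flat blocks) drives the stages

    simulate -> gwas -> qtl -> phylo -> reciprocity -> report

in dependency order. Every stochastic stage draws its seed from a named
substream of the global seed (SHA-256 of the stage name folded into the
seed), so toggling one stage never perturbs another; all intermediate
artifacts are files in the documented formats and the machine-readable
report records each stage's inputs digest, parameters (including every
default that papers over an unstated choice: prune window, FDR estimator,
MAF cutoff) and headline statistics. Re-running an identical config
reproduces identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from . import dataio, mmgwas, phylosig, qtlmap, reciprocity, simdata
from .errors import ConfigurationError, DataError

__all__ = ["RunConfig", "RunReport", "run_pipeline", "compare_phenotype_groups",
           "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    h = hashlib.sha256(stage.encode()).digest()
    return (int(global_seed) ^ int.from_bytes(h[:4], "little")) % (2**31 - 1)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "grnqg_run"
    stages: dict[str, bool] = field(default_factory=lambda: {
        "simulate": True, "gwas": True, "qtl": True, "phylo": True,
        "reciprocity": True,
    })
    simulate: dict[str, Any] = field(default_factory=dict)
    gwas: dict[str, Any] = field(default_factory=dict)
    qtl: dict[str, Any] = field(default_factory=dict)
    phylo: dict[str, Any] = field(default_factory=dict)
    reciprocity: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                import yaml

                raw = yaml.safe_load(fh)
            else:
                raw = json.load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError("config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps({"seed": self.seed, "stages": self.stages,
                           "warnings": self.warnings}, indent=2, sort_keys=True,
                          default=_jsonable)
        if path:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def _digest(*paths: str) -> str:
    h = hashlib.sha256()
    for p in paths:
        with open(p, "rb") as fh:
            h.update(fh.read())
    return h.hexdigest()[:16]


_SIM_DEFAULTS = dict(
    # isolate panel emulating a differentiated multi-population wild panel
    n_strains=96, n_subpopulations=3, fst=0.15, markers_per_chromosome=60,
    chromosomes=[["I", 50.0], ["II", 50.0], ["III", 50.0], ["IV", 50.0],
                 ["V", 50.0], ["X", 50.0]],
    sample_missing_rate=0.02, genotyping_error_rate=0.001,
    # RILs
    n_rils=95, selfing_generations=10,
    # architecture: one shared QTL with opposing effects plus one private QTL
    # per trait, a polygenic background and binomial scoring of >= 500
    # embryos in two replicates
    baseline_liability=[-0.8, 1.5],
    qtls=[["II", 25.0, 0.45, -0.45], ["IV", 20.0, 0.5, 0.0],
          ["I", 30.0, 0.0, -0.5]],
    polygenic_loci=50, polygenic_sd=0.3, strain_noise_sd=0.25,
    embryos_per_replicate=500, replicates=2,
)


def _simulate_stage(cfg: RunConfig, out: str, report: RunReport) -> dict:
    p = {**_SIM_DEFAULTS, **cfg.simulate}
    seed = stage_seed(cfg.seed, "simulate")
    sim_cfg = simdata.SimulationConfig(
        seed=seed, n_strains=int(p["n_strains"]),
        chromosomes=tuple((str(c), float(l)) for c, l in p["chromosomes"]),
        markers_per_chromosome=int(p["markers_per_chromosome"]),
        n_subpopulations=int(p["n_subpopulations"]), fst=float(p["fst"]),
        sample_missing_rate=float(p["sample_missing_rate"]),
        genotyping_error_rate=float(p["genotyping_error_rate"]),
    )
    panel, panel_map, labels = simdata.simulate_isolate_panel(sim_cfg)
    arch = simdata.TraitArchitecture(
        baseline_liability=tuple(p["baseline_liability"]),
        qtls=tuple(simdata.QtlEffect(str(c), float(pos), float(e1), float(e2))
                   for c, pos, e1, e2 in p["qtls"]),
        polygenic_background=(int(p["polygenic_loci"]), float(p["polygenic_sd"])),
        embryos_per_replicate=int(p["embryos_per_replicate"]),
        replicates=int(p["replicates"]),
        strain_noise_sd=float(p["strain_noise_sd"]),
    )
    panel_pheno = simdata.simulate_phenotypes(
        panel, panel_map, arch, seed=stage_seed(cfg.seed, "panel-pheno"))

    m = len(panel_map.marker_ids)
    parent_a = np.zeros(m, dtype=np.int8)
    parent_b = np.ones(m, dtype=np.int8)
    rils = simdata.simulate_ril_population(
        parent_a, parent_b, panel_map, int(p["n_rils"]),
        int(p["selfing_generations"]), seed=stage_seed(cfg.seed, "rils"))
    ril_pheno = simdata.simulate_phenotypes(
        rils, panel_map, arch, seed=stage_seed(cfg.seed, "ril-pheno"))

    dataio.write_012_trio(os.path.join(out, "panel"), panel, panel_map)
    dataio.write_012_trio(os.path.join(out, "rils"), rils, panel_map)
    dataio.write_marker_map(os.path.join(out, "markers.tsv"), panel_map)
    dataio.write_phenotypes_csv(os.path.join(out, "panel_phenotypes.csv"), panel_pheno)
    dataio.write_phenotypes_csv(os.path.join(out, "ril_phenotypes.csv"), ril_pheno)

    report.stages["simulate"] = {
        "parameters": p, "seed": seed,
        "digest": _digest(os.path.join(out, "panel.012"),
                          os.path.join(out, "rils.012"),
                          os.path.join(out, "panel_phenotypes.csv"),
                          os.path.join(out, "ril_phenotypes.csv")),
        "n_strains": panel.n_strains, "n_rils": rils.n_strains, "n_markers": m,
    }
    return {"panel": panel, "panel_map": panel_map, "panel_pheno": panel_pheno,
            "rils": rils, "ril_pheno": ril_pheno, "arch": arch,
            "subpop_labels": labels}


def _gwas_stage(cfg: RunConfig, out: str, report: RunReport, data: dict) -> None:
    p = {"trait": "trait1", "min_maf": 0.05, "permutations": 200, "alpha": 0.05,
         **cfg.gwas}
    panel, panel_map, pheno = data["panel"], data["panel_map"], data["panel_pheno"]
    y = pheno.trait_vector(p["trait"], panel.strain_ids).to_numpy(float)
    K = mmgwas.ibs_kinship(panel)
    scan = mmgwas.emma_scan(y, panel, K, min_maf=float(p["min_maf"]),
                            marker_map=panel_map)
    fdr = mmgwas.permutation_fdr(scan, y, panel, K,
                                 n_permutations=int(p["permutations"]),
                                 seed=stage_seed(cfg.seed, "gwas-perm"),
                                 alpha=float(p["alpha"]))
    table = scan.table.copy()
    table["fdr"] = fdr.marker_fdr.reindex(table.index)
    path = os.path.join(out, "gwas_scan.tsv")
    table.to_csv(path, sep="\t")
    top = scan.tested.sort_values("p").head(5)
    report.stages["gwas"] = {
        "parameters": p, "digest": _digest(path),
        "fdr_estimator": "permutation ratio (step-up monotonised)",
        "maxstat_p_threshold": fdr.maxstat_p_threshold,
        "n_tested": int(scan.table["tested"].sum()),
        "top_markers": [
            {"marker": mid, "minus_log10_p": float(r["minus_log10_p"]),
             "fdr": float(table.at[mid, "fdr"])}
            for mid, r in top.iterrows()
        ],
    }


def _qtl_stage(cfg: RunConfig, out: str, report: RunReport, data: dict) -> None:
    p = {"traits": ["trait1", "trait2"], "step": 1.0, "error_rate": 1e-4,
         "permutations": 200, "alpha": 0.05, "drop": 1.5, **cfg.qtl}
    rils, panel_map, pheno = data["rils"], data["panel_map"], data["ril_pheno"]
    cross = qtlmap.CrossPopulation(rils, panel_map)
    summary = {}
    for trait in p["traits"]:
        y = pheno.trait_vector(trait, rils.strain_ids)
        curve = qtlmap.scanone_em(cross, y, step_cM=float(p["step"]),
                                  error_rate=float(p["error_rate"]))
        thr = qtlmap.permutation_threshold(
            cross, y, n_permutations=int(p["permutations"]),
            alpha=float(p["alpha"]), seed=stage_seed(cfg.seed, f"qtl-{trait}"),
            step_cM=float(p["step"]), error_rate=float(p["error_rate"]))
        path = os.path.join(out, f"qtl_{trait}.tsv")
        curve.frame.to_csv(path, sep="\t", index=False)
        peaks = []
        for chrom in panel_map.chromosomes():
            peak = qtlmap.lod_support_interval(curve, chrom, float(p["drop"]), thr)
            if peak.has_peak and peak.peak_lod >= thr:
                peaks.append({"chrom": chrom, "peak_cM": peak.peak_cM,
                              "lod": peak.peak_lod,
                              "interval_cM": [peak.interval_lo_cM,
                                              peak.interval_hi_cM]})
        summary[trait] = {"max_lod": curve.max_lod, "threshold": thr,
                          "significant_peaks": peaks, "curve_digest": _digest(path)}
    report.stages["qtl"] = {"parameters": p, "traits": summary}


def _phylo_stage(cfg: RunConfig, out: str, report: RunReport, data: dict) -> None:
    p = {"trait": "trait1", "outgroup": None, **cfg.phylo}
    panel, pheno = data["panel"], data["panel_pheno"]
    dm = phylosig.snp_distance(panel)
    tree = phylosig.neighbor_joining(dm)
    if p["outgroup"]:
        phylosig.root_at_outgroup(tree, p["outgroup"])
    path = os.path.join(out, "panel_nj.nwk")
    dataio.write_newick(path, tree)
    tips = pheno.trait_vector(p["trait"], panel.strain_ids)
    fit = phylosig.pagel_lambda(tree, tips)
    report.stages["phylo"] = {
        "parameters": p, "digest": _digest(path),
        "lambda_hat": fit.lambda_hat, "lrt": fit.lrt, "p_value": fit.p_value,
    }


def _reciprocity_stage(cfg: RunConfig, out: str, report: RunReport, data: dict) -> None:
    p = {"trait1": "trait1", "trait2": "trait2", "window": 50, "step": 5,
         "r2": 0.8, "zcut": 1.96, "min_class": 3, **cfg.reciprocity}
    rils, panel_map, pheno = data["rils"], data["panel_map"], data["ril_pheno"]
    table, rep = reciprocity.reciprocity_analysis(
        rils, panel_map, pheno, p["trait1"], p["trait2"],
        window_size=int(p["window"]), step=int(p["step"]),
        r2_threshold=float(p["r2"]), z_cutoff=float(p["zcut"]),
        min_class_size=int(p["min_class"]))
    path = os.path.join(out, "allelic_effects.tsv")
    table.frame.to_csv(path, sep="\t")
    report.stages["reciprocity"] = {
        "parameters": p, "digest": _digest(path),
        "genome_wide_r": rep.genome_wide_r, "genome_wide_p": rep.genome_wide_p,
        "n_markers": rep.n_markers,
        "per_chromosome": rep.per_chromosome.to_dict(orient="records"),
        "strain_spearman_rho": rep.strain_spearman_rho,
        "strain_spearman_p": rep.strain_spearman_p,
        "stage_counts": rep.stage_counts,
    }


_STAGE_ORDER = ["simulate", "gwas", "qtl", "phylo", "reciprocity"]
_STAGE_FUNCS = {"gwas": _gwas_stage, "qtl": _qtl_stage, "phylo": _phylo_stage,
                "reciprocity": _reciprocity_stage}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order; analysis stages
    require the simulate stage (or previously simulated artifacts in
    ``out_dir``)."""
    report = RunReport(seed=config.seed)
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    data: dict | None = None
    if config.stages.get("simulate", True):
        data = _simulate_stage(config, out, report)
    for name in _STAGE_ORDER[1:]:
        if not config.stages.get(name, True):
            continue
        if data is None:
            data = _load_artifacts(out)
        try:
            _STAGE_FUNCS[name](config, out, report, data)
        except (DataError, ConfigurationError) as exc:
            report.stages[name] = {"error": str(exc)}
            report.warnings.append(f"stage {name} failed: {exc}")
    report.to_json(os.path.join(out, "report.json"))
    return report


def _load_artifacts(out: str) -> dict:
    panel_path = os.path.join(out, "panel.012")
    if not os.path.exists(panel_path):
        raise ConfigurationError(
            f"stage requires simulated inputs but {panel_path} is missing "
            "(enable the simulate stage or point out_dir at a previous run)")
    panel, _ = dataio.read_012_trio(os.path.join(out, "panel"))
    rils, _ = dataio.read_012_trio(os.path.join(out, "rils"))
    panel_map = dataio.read_marker_map(os.path.join(out, "markers.tsv"))
    return {
        "panel": panel, "panel_map": panel_map, "rils": rils,
        "panel_pheno": dataio.read_phenotypes_csv(
            os.path.join(out, "panel_phenotypes.csv")),
        "ril_pheno": dataio.read_phenotypes_csv(
            os.path.join(out, "ril_phenotypes.csv")),
    }


def compare_phenotype_groups(counts: list[list[int]] | None = None,
                             groups: tuple | None = None) -> dict:
    """Reporting-stage hypothesis tests, delegated to scipy.

    ``counts``: 2x2 table -> two-sided Fisher exact (odds ratio + p).
    ``groups``: (sample1, sample2) -> two-sided Welch t test.
    """
    out: dict = {}
    if counts is not None:
        tbl = np.asarray(counts)
        if tbl.shape != (2, 2) or (tbl < 0).any():
            raise DataError("Fisher test needs a nonnegative 2x2 table")
        orr, p = stats.fisher_exact(tbl, alternative="two-sided")
        out["fisher"] = {"odds_ratio": float(orr), "p": float(p)}
    if groups is not None:
        a, b = (np.asarray(g, float) for g in groups)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        out["t_test"] = {"t": float(t), "p": float(p), "welch": True}
    if not out:
        raise ConfigurationError("provide counts and/or groups")
    return out
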