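"""End-to-end orchestration of the integrative pipeline.

Stage order: simulate (optional) -> expression meta-analysis -> compendium
scan -> stratified genetics -> compound search -> tissue profile.  Each
stage reads its inputs from disk (so the pipeline exercises the same file
formats a real analysis would), writes its tables under the output
directory, and contributes to a JSON run manifest recording versions, seed,
thresholds and input hashes.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import admeta
from admeta import io
from admeta.compounds import collapse_compounds, compound_scan
from admeta.expression import intersect_and_confirm, map_to_genes, presence_filter, run_de, select_compartment
from admeta.genetics import (
    CANONICAL_STRATA,
    LENIENT_P,
    LENIENT_WINDOW,
    STRICT_P,
    STRICT_WINDOW,
    genotype_propensity,
    region_scan,
    replication_filter,
)
from admeta.scan import scan_compendium
from admeta.synthetic import (
    SimulationConfig,
    gene_regions,
    simulate_compound_profiles,
    simulate_expression_studies,
    simulate_genotype_studies,
    simulate_sample_compendium,
    simulate_tissue_matrix,
)
from admeta.tissue import brain_specificity_summary, correlation_cluster, scale_matrix

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "expression", "scan", "genetics", "compounds", "tissue")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs: paths, thresholds, stage toggles."""

    data_dir: Path
    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # expression
    de_alpha: float = 0.05
    holdout_study: int | None = -1  # last study confirms; None -> no holdout
    excluded_compartments: tuple[str, ...] = ()
    moderated: bool = False
    # scan
    scan_alpha: float = 0.05
    scan_min_m: int = 15
    scan_gene: str = "NEUROD6"
    scan_attribute: str = "gender"
    # genetics
    window: int = STRICT_WINDOW
    p_threshold: float = STRICT_P
    lenient_window: int = LENIENT_WINDOW
    lenient_p: float = LENIENT_P
    replication_min_studies: int = 2
    # compounds
    compound_alpha: float = 0.05
    compound_gene: str = "NEUROD6"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    dry_run: bool = False

    def __post_init__(self) -> None:
        problems = []
        for name in ("de_alpha", "scan_alpha", "compound_alpha", "p_threshold", "lenient_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                problems.append(f"{name} must be in (0, 1), got {v}")
        for name in ("window", "lenient_window"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            problems.append(f"unknown stages: {sorted(unknown)}")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))
        self.data_dir = Path(self.data_dir)
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", {})
        raw.update(overrides)
        for key in ("stages", "excluded_compartments"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "seed" in raw and "seed" not in sim:
            sim["seed"] = raw["seed"]
        for key in ("planted_down_genes", "compartments", "planted_compounds",
                    "maf_range", "cell_lines"):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(sim[key])
        return cls(simulation=SimulationConfig(**sim), **raw)


def _configure_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = "%(asctime)s\t%(name)s\t%(levelname)s\t%(message)s"
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    handlers.append(logging.FileHandler(out_dir / "run.log"))
    logging.basicConfig(level=logging.INFO, format=fmt, handlers=handlers, force=True)


# --------------------------------------------------------------- stages

def stage_simulate(cfg: PipelineConfig) -> dict:
    sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
    data = cfg.data_dir
    for study in simulate_expression_studies(sim):
        io.write_expression_study(study, data / "expression" / study.name)
    io.write_compendium(simulate_sample_compendium(sim), data / "compendium")
    for study in simulate_genotype_studies(sim):
        io.write_genotype_study(study, data / "genotypes" / study.name)
    io.write_regions_bed(gene_regions(sim), data / "regions.bed")
    io.write_profiles(simulate_compound_profiles(sim), data / "profiles")
    matrix, flags = simulate_tissue_matrix(sim)
    io.write_tissue_matrix(matrix, flags, data / "tissue")
    return {"n_expression_studies": sim.n_studies, "n_snp_studies": sim.n_snp_studies,
            "seed": cfg.seed}


def stage_expression(cfg: PipelineConfig) -> dict:
    root = cfg.data_dir / "expression"
    study_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    gene_sets, qc_reports = [], {}
    out = cfg.out_dir / "expression"
    out.mkdir(parents=True, exist_ok=True)
    for sd in study_dirs:
        study = io.read_expression_study(sd)
        by_comp = {
            comp: run_de(study, study.group_contrast(comp), alpha=cfg.de_alpha,
                         moderated=cfg.moderated)
            for comp in study.samples["compartment"].unique()
        }
        label, qc = select_compartment(
            by_comp, study.is_control_probe,
            exclude=set(cfg.excluded_compartments), alpha=cfg.de_alpha,
        )
        qc_reports[study.name] = qc
        if label is None:
            logger.warning("study %s: all compartments failed QC; skipped", study.name)
            continue
        de = presence_filter(by_comp[label], study.pa_calls, study.group_contrast(label))
        de.table.to_csv(out / f"{study.name}_de.tsv", sep="\t")
        gene_sets.append(map_to_genes(de, study.probe_map))
    holdout = cfg.holdout_study
    if holdout is not None and holdout < 0:
        holdout += len(gene_sets)
    down_lists = [gs.down for gs in gene_sets]
    intersection, confirmed = intersect_and_confirm(down_lists, holdout=holdout)
    pd.Series(sorted(intersection), name="gene").to_csv(out / "intersection_down.tsv",
                                                        sep="\t", index=False)
    pd.Series(sorted(confirmed), name="gene").to_csv(out / "confirmed_down.tsv",
                                                     sep="\t", index=False)
    io.write_manifest(qc_reports, out / "qc_report.json")
    return {"n_studies": len(gene_sets), "n_intersection_down": len(intersection),
            "n_confirmed_down": len(confirmed), "confirmed_down": sorted(confirmed)}


def stage_scan(cfg: PipelineConfig) -> dict:
    compendium = io.read_compendium(cfg.data_dir / "compendium")
    out = cfg.out_dir / "scan"
    out.mkdir(parents=True, exist_ok=True)
    table = scan_compendium(
        compendium, cfg.scan_gene, cfg.scan_attribute,
        alpha=cfg.scan_alpha, min_m=cfg.scan_min_m,
    )
    table.to_csv(out / "attribute_enrichment.tsv", sep="\t", index=False)
    from admeta.scan import scan_dataset

    per_sample = []
    for ds in compendium.datasets:
        res = scan_dataset(ds, cfg.scan_gene, alpha=cfg.scan_alpha)
        if res is not None:
            per_sample.append(res.assign(dataset=ds.name))
    if per_sample:
        pd.concat(per_sample).to_csv(out / "sample_scan.tsv", sep="\t")
    ok = table[table["status"] == "ok"]
    best = ok.iloc[0].to_dict() if len(ok) else None
    return {"n_rows": int(len(table)), "top": best}


def stage_genetics(cfg: PipelineConfig) -> dict:
    root = cfg.data_dir / "genotypes"
    study_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    regions = io.read_regions_bed(cfg.data_dir / "regions.bed", window=cfg.window)
    out = cfg.out_dir / "genetics"
    out.mkdir(parents=True, exist_ok=True)
    best_tables = {}
    studies = {}
    for sd in study_dirs:
        study = io.read_genotype_study(sd)
        studies[study.name] = study
        rows, best = region_scan(study, regions, strata=CANONICAL_STRATA,
                                 p_threshold=cfg.p_threshold)
        rows.to_csv(out / f"{study.name}_association.tsv", sep="\t", index=False)
        best_tables[study.name] = best
    replication = replication_filter(best_tables, p_threshold=cfg.p_threshold,
                                     min_studies=cfg.replication_min_studies)
    replication.to_csv(out / "replication.tsv", sep="\t", index=False)
    flagged = replication[replication["flagged"]]

    # propensity tables for the best SNP of each flagged gene-stratum pair
    prop_rows = []
    for _, row in flagged.iterrows():
        for study_name, study in studies.items():
            region = next((r for r in regions if r.gene == row["gene"]), None)
            if region is None:
                continue
            from admeta.genetics import StratumSpec, stratify, window_select

            spec = next(s for s in CANONICAL_STRATA if s.label == row["stratum"])
            sub = stratify(study, spec)
            status = sub.subjects["status"] == "case"
            if not status.any() or status.all():
                continue
            snp_ids = window_select(region, sub.snps)
            for snp in snp_ids:
                prop = genotype_propensity(sub.genotypes.loc[snp], status)
                prop.insert(0, "snp_id", snp)
                prop.insert(0, "stratum", row["stratum"])
                prop.insert(0, "gene", row["gene"])
                prop.insert(0, "study", study_name)
                prop_rows.append(prop)
    if prop_rows:
        pd.concat(prop_rows, ignore_index=True).to_csv(out / "propensity.tsv",
                                                       sep="\t", index=False)
    io.write_manifest(
        {"p_threshold": cfg.p_threshold, "window": cfg.window,
         "min_studies": cfg.replication_min_studies},
        out / "thresholds.json",
    )
    return {
        "n_flagged": int(len(flagged)),
        "flagged": flagged[["gene", "stratum"]].to_dict("records"),
    }


def stage_compounds(cfg: PipelineConfig) -> dict:
    profiles = io.read_profiles(cfg.data_dir / "profiles")
    out = cfg.out_dir / "compounds"
    out.mkdir(parents=True, exist_ok=True)
    sig = compound_scan(profiles, cfg.compound_gene, alpha=cfg.compound_alpha)
    sig.to_csv(out / "significant_profiles.tsv", sep="\t", index=False)
    unique = collapse_compounds(sig)
    unique.to_csv(out / "unique_compounds.tsv", sep="\t", index=False)
    return {"n_significant_profiles": int(len(sig)),
            "n_unique_compounds": int(len(unique)),
            "compounds": unique["compound"].tolist()}


def stage_tissue(cfg: PipelineConfig) -> dict:
    matrix, flags = io.read_tissue_matrix(cfg.data_dir / "tissue")
    out = cfg.out_dir / "tissue"
    out.mkdir(parents=True, exist_ok=True)
    scaled = scale_matrix(matrix)
    scaled.to_csv(out / "scaled.tsv", sep="\t", float_format="%.6g")
    _, leaves = correlation_cluster(scaled)
    pd.Series(leaves, name="gene").to_csv(out / "leaf_order.tsv", sep="\t", index=False)
    scores = brain_specificity_summary(scaled, flags)
    scores.to_csv(out / "brain_specificity.tsv", sep="\t")
    return {"n_genes": int(len(scores)),
            "top_gene": scores.index[0],
            "mean_specificity": float(scores.mean())}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "expression": stage_expression,
    "scan": stage_scan,
    "genetics": stage_genetics,
    "compounds": stage_compounds,
    "tissue": stage_tissue,
}

_STAGE_INPUTS = {
    "expression": ("expression",),
    "scan": ("compendium",),
    "genetics": ("genotypes", "regions.bed"),
    "compounds": ("profiles",),
    "tissue": ("tissue",),
}


def validate_inputs(cfg: PipelineConfig) -> list[str]:
    """Enumerate every missing input for the requested stages."""
    problems = []
    for stage in cfg.stages:
        if stage == "simulate":
            continue
        if "simulate" in cfg.stages:
            continue  # simulate will create them
        for rel in _STAGE_INPUTS.get(stage, ()):
            path = cfg.data_dir / rel
            if not path.exists():
                problems.append(f"stage {stage}: missing input {path}")
    return problems


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in order and write the run manifest.

    Returns the manifest dict; raises on the first stage error after logging
    it, leaving partial outputs and the manifest-so-far on disk.  With
    ``dry_run`` set, inputs are validated and nothing is written.
    """
    _configure_logging(cfg.out_dir)
    problems = validate_inputs(cfg)
    if problems:
        raise FileNotFoundError("; ".join(problems))
    if cfg.dry_run:
        logger.info("dry run: inputs validated, nothing written")
        return {"dry_run": True, "stages": list(cfg.stages)}
    manifest: dict = {
        "package_version": admeta.__version__,
        "seed": cfg.seed,
        "thresholds": {
            "de_alpha": cfg.de_alpha, "scan_alpha": cfg.scan_alpha,
            "scan_min_m": cfg.scan_min_m, "window": cfg.window,
            "p_threshold": cfg.p_threshold,
            "replication_min_studies": cfg.replication_min_studies,
            "compound_alpha": cfg.compound_alpha,
        },
        "stages": {},
        "skipped": [s for s in ALL_STAGES if s not in cfg.stages],
    }
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.time()
        logger.info("stage %s: starting", stage)
        try:
            result = _STAGE_FUNCS[stage](cfg)
        except Exception:
            logger.exception("stage %s failed", stage)
            manifest["stages"][stage] = {"status": "error"}
            io.write_manifest(manifest, cfg.out_dir / "manifest.json")
            raise
        manifest["stages"][stage] = {"status": "ok", "seconds": round(time.time() - t0, 2),
                                     "result": result}
        logger.info("stage %s: done in %.1fs", stage, time.time() - t0)
    manifest["input_hashes"] = {
        str(p.relative_to(cfg.data_dir)): io.file_sha256(p)
        for p in sorted(cfg.data_dir.rglob("*"))
        if p.is_file()
    }
    io.write_manifest(manifest, cfg.out_dir / "manifest.json")
    return manifest
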