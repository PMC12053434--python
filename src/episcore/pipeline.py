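"""End-to-end orchestration: deconvolve -> model -> associate -> survive.

Stages hand off flat files (TSV/BED) so each is independently testable and
replaceable.  Every run writes a machine-readable ``summary.json`` with the
headline quantities and a ``manifest.json`` recording input hashes, the
parameters and seed actually used, and output hashes; a rerun with the same
config is bit-identical for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import build_design, fit_sitewise_models, methylation_expression_correlation, select_trait_associated_sites
from .deconvolution import MethylDeconvolver, compute_cell_pcs
from .io import (
    ValidationError,
    join_metadata,
    parse_site_key,
    read_methylation_matrix,
    read_sample_metadata,
    write_methylation_matrix,
    write_regions_bed,
    write_sample_metadata,
)
from .mmlr import encode_traits, loocv_episcores
from .outcomes import build_survival_table, fit_cox, moderation_analysis, plot_km_by_score
from .simulate import (
    SimulationConfig,
    ReferencePanel,
    make_site_gene_mapping,
    simulate_cohort,
    simulate_expression,
    simulate_reference_panel,
    simulate_survival,
)

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "make_demo",
           "write_reference_panel", "read_reference_panel"]

log = logging.getLogger("episcore")


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


@dataclass
class PipelineConfig:
    """Paths, stage toggles, and stage parameters for one pipeline run."""

    matrix: str = ""
    metadata: str = ""
    panel: str = ""
    expression: str = ""
    site_gene_mapping: str = ""
    out_dir: str = "episcore_run"

    run_deconvolve: bool = True
    run_mmlr: bool = True
    run_associate: bool = True
    run_survive: bool = True
    run_moderate: bool = True
    run_expression: bool = False

    dmr_min_length_bp: int = 500
    dmr_delta_threshold: float = -0.30
    dmr_fdr: float = 0.05
    dmr_gap_bp: int = 300
    n_cell_pcs: int = 3
    traits: tuple = ("age", "sex", "cmv", "atg", "transplant", "infection_risk")
    use_cell_pcs: bool = True
    use_ancestry_pcs: bool = True
    add_intercept: bool = True
    group_by_subject: bool = True
    association_trait: str = "atg"
    association_alpha: float = 0.05
    association_direction: str = "positive"
    cox_covariate: str = "epi_infection_risk"
    cmv_positive_only: bool = True
    survival_use_sample: str = "pre"
    moderators: tuple = ("transplant", "atg")
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for stage, path, name in (
            (True, self.matrix, "matrix"),
            (True, self.metadata, "metadata"),
            (self.run_deconvolve, self.panel, "panel"),
            (self.run_expression, self.expression, "expression"),
        ):
            if stage and (not path or not Path(path).exists()):
                raise ConfigError(f"required input {name!r} missing or not found: {path!r}")
        if self.run_mmlr and self.use_cell_pcs and not self.run_deconvolve:
            raise ConfigError("MMLR requests cell PCs but deconvolution stage is disabled")
        if not (0 < self.association_alpha <= 1):
            raise ConfigError("association_alpha must be in (0, 1]")
        if self.dmr_delta_threshold >= 0:
            raise ConfigError("dmr_delta_threshold must be negative (hypomethylation)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("traits", "moderators"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


# --------------------------------------------------------------------------
# reference panel round-trip (TSV, columns "celltype|replicate")
# --------------------------------------------------------------------------

def write_reference_panel(panel: ReferencePanel, path) -> None:
    flat = panel.profiles.copy()
    flat.columns = [f"{ct}|{rep}" for ct, rep in flat.columns]
    flat.index.name = "site"
    flat.to_csv(path, sep="\t", float_format="%.6f")


def read_reference_panel(path) -> ReferencePanel:
    flat = pd.read_csv(path, sep="\t", index_col=0)
    pairs = [tuple(c.split("|", 1)) for c in flat.columns]
    if any(len(p) != 2 for p in pairs):
        raise ValidationError("panel columns must be named 'celltype|replicate'")
    flat.columns = pd.MultiIndex.from_tuples(pairs, names=["celltype", "replicate"])
    base = flat.T.groupby(level=0).mean().T
    return ReferencePanel(profiles=flat, base_profiles=base)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _sites_to_regions(sites: list[str]) -> pd.DataFrame:
    rows = []
    for s in sites:
        chrom, pos = parse_site_key(s)
        rows.append((chrom, pos - 1, pos, s, 0.0))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "score"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the summary."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = {}
    for name in ("matrix", "metadata", "panel", "expression", "site_gene_mapping"):
        p = getattr(config, name)
        if p and Path(p).exists():
            inputs[name] = _sha256(Path(p))

    log.info("[load] matrix=%s metadata=%s", config.matrix, config.metadata)
    matrix = read_methylation_matrix(config.matrix)
    metadata = read_sample_metadata(config.metadata)
    meta_aligned = join_metadata(matrix, metadata)

    summary: dict = {"seed": config.seed, "n_sites": int(matrix.shape[0]),
                     "n_samples": int(matrix.shape[1])}
    cell_pcs = None

    if config.run_deconvolve:
        log.info("[deconvolve] calling markers (min %d bp, delta <= %.2f, FDR %.2f)",
                 config.dmr_min_length_bp, config.dmr_delta_threshold, config.dmr_fdr)
        panel = read_reference_panel(config.panel)
        dec = MethylDeconvolver(
            min_length_bp=config.dmr_min_length_bp,
            delta_threshold=config.dmr_delta_threshold,
            fdr=config.dmr_fdr, gap_bp=config.dmr_gap_bp,
        ).fit(panel)
        fractions = dec.transform(matrix.T)
        fractions.to_csv(out / "cell_fractions.tsv", sep="\t", float_format="%.6f")
        regions = dec.markers_.regions.rename(columns={"celltype": "label", "delta": "score"})
        write_regions_bed(regions[["chrom", "start", "end", "label", "score"]],
                          out / "marker_regions.bed")
        cell_pcs = compute_cell_pcs(fractions, config.n_cell_pcs)
        cell_pcs.to_csv(out / "cell_pcs.tsv", sep="\t", float_format="%.6f")
        summary["n_marker_regions"] = int(len(dec.markers_.regions))
        summary["n_marker_sites"] = int(len(dec.markers_.all_sites()))

    T = encode_traits(meta_aligned, cell_pcs=cell_pcs if config.use_cell_pcs else None,
                      traits=config.traits,
                      include_ancestry_pcs=config.use_ancestry_pcs,
                      add_intercept=config.add_intercept)

    panel_scores = None
    if config.run_mmlr:
        groups = meta_aligned["subject_id"] if config.group_by_subject else None
        log.info("[mmlr] LOOCV over %d samples (%d traits)%s", T.shape[0], T.shape[1],
                 " grouped by subject" if groups is not None else "")
        panel_scores = loocv_episcores(T, matrix, groups=groups)
        panel_scores.scores.to_csv(out / "episcores.tsv", sep="\t", float_format="%.6f")
        for trait, auc in panel_scores.auc.items():
            summary[f"epi_{trait}_auc"] = round(float(auc), 6)
        for trait, rho in panel_scores.correlation.items():
            summary[f"epi_{trait}_spearman"] = round(float(rho), 6)

    if config.run_associate:
        log.info("[associate] site-wise OLS, trait=%s alpha=%.3g direction=%s",
                 config.association_trait, config.association_alpha,
                 config.association_direction)
        design = build_design(T)  # adds an intercept only if T lacks one
        result = fit_sitewise_models(matrix, design)
        result.to_long().to_csv(out / "association.tsv", sep="\t", index=False,
                                float_format="%.6g")
        from .association import plot_manhattan
        ax = plot_manhattan(result, config.association_trait, config.association_alpha)
        ax.figure.savefig(out / "manhattan.png", dpi=100)
        sites = select_trait_associated_sites(
            result, config.association_trait, config.association_alpha,
            config.association_direction,
        )
        pd.Series(sites, name="site").to_csv(out / "associated_sites.tsv",
                                             sep="\t", index=False)
        if sites:
            write_regions_bed(_sites_to_regions(sites), out / "associated_sites.bed")
        summary[f"n_{config.association_trait}_associated_sites"] = len(sites)

    if config.run_survive:
        if panel_scores is None:
            raise ConfigError("survival stage requires the MMLR stage")
        log.info("[survive] Cox PH on %s (CMV filter=%s)", config.cox_covariate,
                 config.cmv_positive_only)
        table = build_survival_table(meta_aligned, panel_scores,
                                     cmv_filter=config.cmv_positive_only,
                                     use_sample=config.survival_use_sample)
        write_sample_metadata(table, out / "survival_table.tsv")
        fit = fit_cox(table, [config.cox_covariate])
        fit.summary.to_csv(out / "cox_fit.tsv", sep="\t", float_format="%.6g")
        row = fit.summary.loc[config.cox_covariate]
        summary["cox_hr"] = round(float(row["hr"]), 6)
        summary["cox_ci"] = [round(float(row["ci_lower"]), 6),
                             round(float(row["ci_upper"]), 6)]
        summary["cox_p"] = round(float(row["p"]), 6)
        summary["cox_score_sd"] = round(float(fit.score_sd[config.cox_covariate]), 6)
        _, km_p, km_ax = plot_km_by_score(table, config.cox_covariate, split="median")
        km_ax.figure.savefig(out / "km_curves.png", dpi=100)
        summary["km_logrank_p"] = round(float(km_p), 6)

    if config.run_moderate:
        if panel_scores is None or "age" not in panel_scores.scores.columns:
            raise ConfigError("moderation stage requires MMLR with the age trait")
        rows = []
        for moderator in config.moderators:
            if moderator not in T.columns:
                raise ConfigError(f"moderator {moderator!r} not among encoded traits")
            fit = moderation_analysis(panel_scores.scores["age"].to_numpy(),
                                      meta_aligned["age"].to_numpy(),
                                      T[moderator].to_numpy())
            rows.append({"moderator": moderator,
                         "interaction": float(fit.coef["age:moderator"]),
                         "interaction_p": fit.interaction_p,
                         "slope0": fit.slope_moderator0,
                         "slope1": fit.slope_moderator1})
            summary[f"moderation_{moderator}_p"] = round(fit.interaction_p, 6)
        pd.DataFrame(rows).to_csv(out / "moderation.tsv", sep="\t", index=False,
                                  float_format="%.6g")

    if config.run_expression:
        expr = pd.read_csv(config.expression, sep="\t", index_col=0)
        with open(config.site_gene_mapping) as fh:
            mapping = dict(line.strip().split("\t") for line in fh if line.strip())
        table = methylation_expression_correlation(matrix, expr, mapping)
        table.to_csv(out / "expression_correlation.tsv", sep="\t", index=False,
                     float_format="%.6g")
        summary["n_expression_pairs_passing"] = int(table["passes"].sum())

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()},
        "input_hashes": inputs,
        # determinism contract covers the text artifacts; figures are display
        "output_hashes": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.suffix in (".tsv", ".bed", ".json")
            and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    log.info("[done] summary written to %s", out / "summary.json")
    return summary


def make_demo(seed: int, out_dir, n_subjects: int = 90, n_sites: int = 8000,
              n_celltypes: int = 6) -> Path:
    """Emit a ready-to-run synthetic cohort and its pipeline config.

    Defaults echo the emulated study scale: six reference cell types, 90
    subjects with paired pre/post samples, an 8,000-site panel.  Returns the
    path to the written config YAML.
    """
    out = Path(out_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    sim = SimulationConfig(seed=seed, n_subjects=n_subjects, n_sites=n_sites,
                           n_celltypes=n_celltypes)
    panel, true_dmrs = simulate_reference_panel(sim)
    matrix, metadata, truth = simulate_cohort(sim, panel)
    metadata = simulate_survival(metadata, truth, sim)
    mapping = make_site_gene_mapping(truth, trait="atg", n_sites=30)
    expr = simulate_expression(matrix, mapping, sim)

    write_methylation_matrix(matrix, out / "inputs" / "matrix.tsv")
    write_sample_metadata(metadata, out / "inputs" / "metadata.tsv")
    write_reference_panel(panel, out / "inputs" / "panel.tsv")
    write_regions_bed(true_dmrs, out / "inputs" / "true_dmrs.bed")
    expr.to_csv(out / "inputs" / "expression.tsv", sep="\t", float_format="%.6f")
    with open(out / "inputs" / "site_gene_mapping.tsv", "w") as fh:
        for site, gene in mapping.items():
            fh.write(f"{site}\t{gene}\n")
    # ground-truth sidecars for recovery checks
    truth.cell_fractions.to_csv(out / "inputs" / "true_fractions.tsv", sep="\t",
                                float_format="%.6f")
    pd.concat(truth.effect_sites, names=["trait", "site"]).rename("effect").to_csv(
        out / "inputs" / "true_effect_sites.tsv", sep="\t")

    cfg = PipelineConfig(
        matrix=str(out / "inputs" / "matrix.tsv"),
        metadata=str(out / "inputs" / "metadata.tsv"),
        panel=str(out / "inputs" / "panel.tsv"),
        expression=str(out / "inputs" / "expression.tsv"),
        site_gene_mapping=str(out / "inputs" / "site_gene_mapping.tsv"),
        out_dir=str(out / "run"),
        run_expression=True,
        seed=seed,
    )
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    return cfg_path
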