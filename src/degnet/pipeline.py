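"""End-to-end orchestration: data -> DE -> meta -> network -> rescue -> motif -> survival.

A run is driven by one :class:`RunConfig` (loadable from YAML). In simulate
mode every input is drawn by the synthetic module from the run seed; in
file mode the same stages run on user-supplied matrices, prior, promoters,
PFM, annotation and survival records. Identical config + seed produces a
byte-identical machine-readable run report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import call_degs, de_test
from .errors import ConfigError, PipelineError
from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    TFPrior,
    read_expression_matrix,
    read_gmt,
    read_pfm,
    read_promoters,
    read_survival_table,
    read_tf_prior,
    write_de_results,
    write_expression_matrix,
    write_gmt,
    write_pfm,
    write_promoters,
    write_sites_bed,
    write_sites_table,
    write_tf_prior,
)
from .meta import run_meta_contrast
from .motif import default_cebpb_pfm, design_motif_mutants, pfm_to_pwm, rank_genes_by_motif, scan_promoter
from .regulatory import build_rescue_network, build_tf_network, classify_rescue, rank_tfs
from .survival import SurvivalRecord, km_estimate, logrank_test, stratify_by_median
from .synthetic import (
    SimulationConfig,
    generate_annotation,
    generate_cohorts,
    generate_knockdown,
    generate_promoters,
    generate_survival,
    generate_tf_prior,
    split_by_cohort,
)

_INPUT_KEYS = (
    "cohorts",
    "metadata",
    "knockdown",
    "knockdown_metadata",
    "tf_prior",
    "promoters",
    "pfm",
    "annotation",
    "survival",
)


@dataclass
class RunConfig:
    """One pipeline run: either a simulation block or explicit input paths."""

    outdir: str = "degnet_run"
    seed: int = 0
    lfc_min: float = 0.5
    alpha: float = 0.05
    rel_threshold: float = 0.85
    mode: str | None = None  # nb_wald / welch_log / None (auto)
    simulate: dict | None = None  # SimulationConfig overrides
    inputs: dict | None = None  # paths keyed by _INPUT_KEYS

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'simulate' and 'inputs' must be given")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.lfc_min < 0:
            raise ConfigError("lfc_min must be non-negative")
        if not 0 < self.rel_threshold <= 1:
            raise ConfigError("rel_threshold must lie in (0, 1]")
        if self.inputs is not None:
            unknown = set(self.inputs) - set(_INPUT_KEYS)
            if unknown:
                raise ConfigError(f"unknown input keys {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def simulation_config(self) -> SimulationConfig:
        block = dict(self.simulate or {})
        block.setdefault("seed", self.seed)
        try:
            return SimulationConfig(**block)
        except TypeError as exc:
            raise ConfigError(f"bad simulation block: {exc}") from None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order and write the run report.

    Returns the report dict; all intermediate tables are written under
    ``config.outdir``. Any stage error aborts with the stage name; a FAILED
    marker file records the stage for partial runs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "lfc_min": config.lfc_min,
            "alpha": config.alpha,
            "rel_threshold": config.rel_threshold,
        },
        "stages": {},
        "files": {},
    }
    stage = "init"
    try:
        # ---- inputs -------------------------------------------------------
        stage = "inputs"
        if config.simulate is not None:
            sim = config.simulation_config()
            matrix, metadata, truth = generate_cohorts(sim)
            kd_matrix, kd_metadata = generate_knockdown(sim, truth)
            prior = generate_tf_prior(sim, truth)
            pfm = default_cebpb_pfm()
            annotation = generate_annotation(sim, truth)
            report["stages"]["inputs"] = {"source": "simulate", "n_genes": matrix.n_genes}
        else:
            paths = config.inputs or {}
            cohort_paths = paths.get("cohorts") or {}
            if not cohort_paths:
                raise ConfigError("inputs.cohorts must map cohort name -> matrix path")
            value_kind = "counts" if (config.mode or "nb_wald") == "nb_wald" else "continuous"
            cohort_matrices = {
                name: read_expression_matrix(p, value_kind) for name, p in cohort_paths.items()
            }
            metadata = pd.read_csv(paths["metadata"], sep="\t")
            matrix = None
            kd_matrix = kd_metadata = None
            if "knockdown" in paths:
                kd_matrix = read_expression_matrix(paths["knockdown"], value_kind)
                kd_metadata = pd.read_csv(paths["knockdown_metadata"], sep="\t")
            prior = read_tf_prior(paths["tf_prior"]) if "tf_prior" in paths else None
            pfm = read_pfm(paths["pfm"]) if "pfm" in paths else default_cebpb_pfm()
            annotation = read_gmt(paths["annotation"]) if "annotation" in paths else None
            truth = None
            sim = None
            report["stages"]["inputs"] = {"source": "files", "cohorts": sorted(cohort_paths)}

        if config.simulate is not None:
            cohort_matrices = split_by_cohort(matrix, metadata)
            # persist the simulated inputs so subcommand runs can reproduce the chain
            write_expression_matrix(matrix, outdir / "cohorts.tsv")
            metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
            write_expression_matrix(kd_matrix, outdir / "knockdown.tsv")
            kd_metadata.to_csv(outdir / "knockdown_metadata.tsv", sep="\t", index=False)
            write_tf_prior(prior, outdir / "tf_prior.tsv")
            write_pfm(pfm, outdir / "pfm.txt")
            write_gmt(annotation, outdir / "annotation.gmt")

        # ---- per-cohort + meta DE ----------------------------------------
        stage = "meta"
        meta_report = run_meta_contrast(
            cohort_matrices,
            metadata,
            contrast=("healthy", "tumor"),
            mode=config.mode,
            lfc_min=config.lfc_min,
            alpha=config.alpha,
        )
        for cohort, res in meta_report.per_study_results.items():
            write_de_results(res, outdir / f"de_{cohort}.tsv")
        write_de_results(meta_report.meta_results, outdir / "de_meta.tsv")
        deg_counts = {
            cohort: {"up": len(s.up), "down": len(s.down)} for cohort, s in meta_report.per_study.items()
        }
        deg_counts["meta"] = {"up": len(meta_report.meta.up), "down": len(meta_report.meta.down)}
        report["stages"]["meta"] = {
            "deg_counts": deg_counts,
            "venn": meta_report.venn,
            "common_up": len(meta_report.common_up),
            "common_down": len(meta_report.common_down),
        }
        (outdir / "meta_report.json").write_text(
            json.dumps(
                {
                    "venn": meta_report.venn,
                    "common_up": sorted(meta_report.common_up),
                    "common_down": sorted(meta_report.common_down),
                },
                indent=2,
                sort_keys=True,
            )
        )

        # ---- TF network ---------------------------------------------------
        hub = None
        if prior is not None:
            stage = "network"
            network = build_tf_network(meta_report, prior, tf_universe=prior.tfs)
            ranking = rank_tfs(network)
            hub = ranking[0][0] if ranking else None
            with (outdir / "network_edges.tsv").open("w") as fh:
                fh.write("tf\ttarget\n")
                for tf, target in sorted(network.edges):
                    fh.write(f"{tf}\t{target}\n")
            (outdir / "network_summary.json").write_text(
                json.dumps(
                    {"hub_tf": hub, "out_degrees": {tf: d for tf, d in ranking}},
                    indent=2,
                    sort_keys=True,
                )
            )
            report["stages"]["network"] = {
                "n_edges": len(network.edges),
                "n_nodes": len(network.nodes),
                "hub_tf": hub,
                "hub_out_degree": ranking[0][1] if ranking else 0,
            }

        # ---- knockdown DE + rescue ---------------------------------------
        rescue = None
        if kd_matrix is not None:
            stage = "rescue"
            kd_results = de_test(
                kd_matrix, kd_metadata, contrast=("control", "perturbed"), mode=config.mode
            )
            write_de_results(kd_results, outdir / "de_knockdown.tsv")
            kd_sets = call_degs(kd_results, config.lfc_min, config.alpha)
            rescue = classify_rescue(
                meta_report.meta_results, kd_results, config.lfc_min, config.alpha
            )
            rescue.to_csv(outdir / "rescue_table.tsv", sep="\t", index=False, float_format="%.6g")
            class_counts = rescue["rescue_class"].value_counts().to_dict()
            report["stages"]["rescue"] = {
                "kd_up": len(kd_sets.up),
                "kd_down": len(kd_sets.down),
                "class_counts": {k: int(v) for k, v in sorted(class_counts.items())},
            }
            if annotation is not None:
                edges, colors, enrichment = build_rescue_network(rescue, annotation, config.alpha)
                with (outdir / "rescue_network.tsv").open("w") as fh:
                    fh.write("gene\tterm_id\tterm_color\n")
                    for gene, term in edges:
                        fh.write(f"{gene}\t{term}\t{colors[term]}\n")
                if len(enrichment):
                    enrichment.to_csv(
                        outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
                    )
                report["stages"]["rescue"]["n_enriched_terms"] = len(colors)

        # ---- motif scan ---------------------------------------------------
        stage = "motif"
        if config.simulate is not None:
            motif_genes = sorted(
                set(meta_report.common_up | meta_report.common_down)
                | set(truth.motif_offsets_by_gene)
            )
            promoters = generate_promoters(sim, truth, pfm, genes=motif_genes)
            write_promoters(promoters, outdir / "promoters.fa")
        elif config.inputs and "promoters" in (config.inputs or {}):
            promoters = read_promoters(config.inputs["promoters"])
        else:
            promoters = None
        if promoters:
            pwm = pfm_to_pwm(pfm)
            ranking_table = rank_genes_by_motif(promoters, pwm, config.rel_threshold)
            ranking_table.to_csv(
                outdir / "gene_ranking.tsv", sep="\t", index=False, float_format="%.6g"
            )
            all_sites = []
            for gene, seq in promoters.items():
                all_sites.extend(scan_promoter(seq, pwm, config.rel_threshold, gene=gene))
            write_sites_bed(all_sites, outdir / "motif_sites.bed", promoter_length=len(next(iter(promoters.values()))))
            write_sites_table(all_sites, outdir / "motif_sites.tsv")
            top_gene = str(ranking_table.iloc[0]["gene"]) if len(ranking_table) else None
            mutant_info = None
            if top_gene:
                top_sites = [s for s in all_sites if s.gene == top_gene]
                if top_sites:
                    mutant_seq, subs = design_motif_mutants(
                        promoters[top_gene], top_sites, pwm, rel_threshold=config.rel_threshold
                    )
                    write_promoters({f"{top_gene}_mutant": mutant_seq}, outdir / "mutant_promoter.fa")
                    with (outdir / "mutant_substitutions.tsv").open("w") as fh:
                        fh.write("tss_position\tref\talt\n")
                        for pos, ref, alt in subs:
                            fh.write(f"{pos}\t{ref}\t{alt}\n")
                    residual = scan_promoter(mutant_seq, pwm, config.rel_threshold, gene=top_gene)
                    mutant_info = {"n_substitutions": len(subs), "residual_sites": len(residual)}
            report["stages"]["motif"] = {
                "n_genes_scanned": len(promoters),
                "n_sites": len(all_sites),
                "top_gene": top_gene,
                "top_gene_sites": int(
                    ranking_table.iloc[0]["site_count"]) if len(ranking_table) else 0,
                "mutant": mutant_info,
            }

        # ---- survival -----------------------------------------------------
        stage = "survival"
        records = None
        if config.simulate is not None and truth is not None and truth.survival_gene:
            tumor_ids = metadata.loc[metadata["group"] == "tumor", "sample_id"]
            expr = matrix.data.loc[truth.survival_gene, list(tumor_ids)]
            records = generate_survival(sim, truth, expr)
            with (outdir / "survival.tsv").open("w") as fh:
                fh.write("sample_id\ttime\tevent\texpression\n")
                for r, e in zip(records, expr):
                    fh.write(f"{r.sample_id}\t{r.time:.6g}\t{r.event}\t{e:.6g}\n")
        elif config.inputs and "survival" in (config.inputs or {}):
            table = read_survival_table(config.inputs["survival"])
            strata = stratify_by_median(pd.Series(table["expression"].to_numpy(), index=table["sample_id"]))
            records = [
                SurvivalRecord(str(r.sample_id), float(r.time), int(r.event), strata[r.sample_id])
                for r in table.itertuples()
            ]
        if records is not None:
            chi2, p = logrank_test(records)
            high = [r for r in records if r.stratum == "high"]
            low = [r for r in records if r.stratum == "low"]
            km_high, km_low = km_estimate(high), km_estimate(low)
            with (outdir / "survival_km.tsv").open("w") as fh:
                fh.write("stratum\ttime\tsurvival\tat_risk\tevents\n")
                for label, curve in (("high", km_high), ("low", km_low)):
                    for t, s, n, d in zip(curve.event_times, curve.survival, curve.at_risk, curve.n_events):
                        fh.write(f"{label}\t{t:.6g}\t{s:.6g}\t{n}\t{d}\n")
            (outdir / "survival_test.json").write_text(
                json.dumps(
                    {"chi_square": chi2, "p": p, "n_high": len(high), "n_low": len(low)},
                    indent=2,
                    sort_keys=True,
                )
            )
            report["stages"]["survival"] = {
                "chi_square": round(chi2, 10),
                "p": round(p, 12),
                "n_high": len(high),
                "n_low": len(low),
            }
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "run_report.json":
            report["files"][p.name] = _sha256(p)
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
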