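"""End-to-end orchestration: normalize -> test -> classify -> group -> report.

:func:`run_pipeline` drives one or two species through the whole analysis
and writes every result table plus a run manifest; identical inputs and
configuration reproduce the outputs byte for byte.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import ClassThresholds, class_tally, classify_all
from .conserve import conserved_dynamics, map_orthologs
from .dlt import detect_dlts
from .dynamics import abundance_analysis
from .io import read_config, read_counts, read_sample_sheet, write_tsv
from .normalize import normalize, size_factors, replicate_percentages, stage_profiles
from .simulate import SectionCountMatrix
from .temporal import TemporalThresholds, assign_temporal_groups, cluster_profiles
from .normalize import PCT_COLUMNS

log = logging.getLogger("tomoloc")


@dataclass
class PipelineConfig:
    counts: str
    sample_sheet: str
    stage_order: list[str]
    output_dir: str
    counts2: str | None = None
    sample_sheet2: str | None = None
    stage_order2: list[str] | None = None
    ortholog_map: str | None = None
    symbols: str | None = None
    symbols2: str | None = None
    padj_threshold: float = 0.1
    count_threshold: float = 20.0
    min_fold: float = 1.5
    abundance_min_fold: float = 1.5
    class_thresholds: dict = field(default_factory=dict)
    cluster_verification: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.padj_threshold <= 1:
            raise ValueError("padj_threshold must lie in [0, 1]")
        if self.count_threshold < 0:
            raise ValueError("count_threshold must be >= 0")
        if self.min_fold <= 1 or self.abundance_min_fold <= 1:
            raise ValueError("fold thresholds must exceed 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**read_config(path))


def _read_symbols(path, genes: pd.Index) -> pd.Series:
    if path is None:
        return pd.Series(genes, index=genes, name="symbol")
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index("gene_id")["symbol"].reindex(genes)


def _analyze_species(
    scm: SectionCountMatrix, cfg: PipelineConfig, outdir: Path, tag: str
) -> dict:
    """Full single-species analysis; writes TSVs under ``outdir``."""
    out: dict = {}
    factors = size_factors(scm.counts)
    write_tsv(factors.rename("factor").rename_axis("sample_id").reset_index(),
              outdir / f"{tag}size_factors.tsv")
    norm = normalize(scm.counts, factors)
    profiles = stage_profiles(norm, scm.samples)
    rep_pcts = replicate_percentages(norm, scm.samples)
    write_tsv(profiles, outdir / f"{tag}profiles.tsv")
    out["size_factors"], out["profiles"] = factors, profiles

    stages = [s for s in scm.stage_order if s in set(scm.samples["stage"])]
    dlt_tables = {}
    for stage in stages:
        res = detect_dlts(
            scm, "within_stage", stage=stage,
            padj_threshold=cfg.padj_threshold, count_threshold=cfg.count_threshold,
            precomputed_factors=factors,
        )
        dlt_tables[f"within_stage_{stage}"] = res
        write_tsv(res, outdir / f"{tag}dlt_within_stage_{stage}.tsv")
    if len(stages) >= 2:
        for design in ("profile_across_stages", "magnitude_across_stages",
                       "total_between_stages"):
            res = detect_dlts(
                scm, design,
                padj_threshold=cfg.padj_threshold, count_threshold=cfg.count_threshold,
                precomputed_factors=factors,
            )
            dlt_tables[design] = res
            write_tsv(res, outdir / f"{tag}dlt_{design}.tsv")
    out["dlt"] = dlt_tables

    ct = ClassThresholds(**cfg.class_thresholds) if cfg.class_thresholds else ClassThresholds()
    # classify the stage profiles of each stage's DLTs
    per_stage = []
    for stage in stages:
        flagged = dlt_tables[f"within_stage_{stage}"].query("is_dlt")["gene_id"]
        sub = profiles[(profiles["stage"] == stage) & profiles["gene_id"].isin(flagged)]
        per_stage.append(sub)
    dlt_profiles = pd.concat(per_stage) if per_stage else profiles.iloc[:0]
    classes = classify_all(dlt_profiles, ct)
    write_tsv(classes, outdir / f"{tag}classes.tsv")
    write_tsv(class_tally(classes).reset_index(), outdir / f"{tag}class_summary.tsv")
    out["classes"] = classes

    temporal = None
    if len(stages) >= 2:
        dlt_any = sorted(
            set().union(*(
                set(dlt_tables[f"within_stage_{s}"].query("is_dlt")["gene_id"])
                for s in stages
            ))
        )
        all_classified = classify_all(profiles[profiles["gene_id"].isin(dlt_any)], ct)
        tt = TemporalThresholds(min_fold=cfg.min_fold)
        temporal = assign_temporal_groups(
            all_classified, rep_pcts, dlt_any, scm.stage_order, tt
        )
        write_tsv(temporal, outdir / f"{tag}temporal.tsv")
        out["temporal"] = temporal

        if cfg.cluster_verification and len(temporal.query("group != 'other'")) >= 3:
            keep = temporal.query("group != 'other'")["gene_id"]
            mat = (
                all_classified[all_classified["gene_id"].isin(keep)]
                .pivot_table(index="gene_id", columns="stage", values=PCT_COLUMNS)
                .dropna()
            )
            kmax = min(6, len(mat) - 1)
            if kmax >= 2:
                labels, scores = cluster_profiles(mat.to_numpy(), range(2, kmax + 1))
                report = pd.DataFrame({"gene_id": mat.index, "cluster": labels})
                write_tsv(report, outdir / f"{tag}cluster_report.tsv")
                out["clusters"] = report

        dyn = abundance_analysis(
            scm, min_fold=cfg.abundance_min_fold,
            padj_threshold=cfg.padj_threshold, count_threshold=cfg.count_threshold,
            class_thresholds=ct, profiles=profiles,
            total_test=dlt_tables["total_between_stages"],
        )
        write_tsv(dyn, outdir / f"{tag}dynamics.tsv")
        out["dynamics"] = dyn
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis described by ``cfg``.

    Returns the result bundle (a dict of DataFrames, nested per species
    when two are configured) and writes all declared outputs plus
    ``manifest.json`` under ``cfg.output_dir``.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        sheet = read_sample_sheet(cfg.sample_sheet)
        scm = read_counts(cfg.counts, sheet, cfg.stage_order)
        log.info("species 1: %d genes, %d samples", *scm.counts.shape)
        bundle = {"species1": _analyze_species(scm, cfg, outdir, "")}

        if cfg.counts2 is not None:
            sheet2 = read_sample_sheet(cfg.sample_sheet2)
            scm2 = read_counts(cfg.counts2, sheet2, cfg.stage_order2 or cfg.stage_order)
            log.info("species 2: %d genes, %d samples", *scm2.counts.shape)
            bundle["species2"] = _analyze_species(scm2, cfg, outdir, "species2_")
            t1, t2 = bundle["species1"].get("temporal"), bundle["species2"].get("temporal")
            if t1 is not None and t2 is not None:
                unit_map = (
                    pd.read_csv(cfg.ortholog_map, sep="\t", dtype=str)
                    if cfg.ortholog_map else None
                )
                pairs = map_orthologs(
                    _read_symbols(cfg.symbols, scm.counts.index),
                    _read_symbols(cfg.symbols2, scm2.counts.index),
                    unit_map,
                )
                write_tsv(pairs, outdir / "ortholog_pairs.tsv")
                conserved = conserved_dynamics(
                    t1, t2, pairs,
                    bundle["species1"].get("dynamics"),
                    bundle["species2"].get("dynamics"),
                )
                for name, table in conserved.items():
                    write_tsv(table, outdir / f"conserved_{name}.tsv")
                bundle["conserved"] = conserved
        caught = sorted(str(w.message) for w in wrec)

    manifest = {
        "tomoloc_version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "padj": cfg.padj_threshold,
            "total_count": cfg.count_threshold,
            "min_fold": cfg.min_fold,
            "abundance_min_fold": cfg.abundance_min_fold,
            "class_thresholds": cfg.class_thresholds or "defaults",
        },
        "n_warnings": len(caught),
        "warnings": caught[:50],
        "outputs": sorted(p.name for p in outdir.glob("*.tsv")),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    bundle["manifest"] = manifest
    return bundle
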