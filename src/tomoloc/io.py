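"""TSV file formats and configuration.

All tables are UTF-8 tab-separated files with Unix newlines, a header
line, and "NA" for missing values; counts files carry gene_id as the
first column.  Pipeline configuration is a YAML file mirroring
:class:`tomoloc.pipeline.PipelineConfig`.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import SectionCountMatrix

_TSV_KW = dict(sep="\t", na_rep="NA", lineterminator="\n")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, **_TSV_KW)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "species", "stage", "replicate", "section"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet lacks columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id: {dup}")
    return sheet.set_index("sample_id")


def read_counts(path, sample_sheet: pd.DataFrame, stage_order: list[str]) -> SectionCountMatrix:
    """Read a gene x sample counts TSV, validated against the sample sheet.

    Counts must be integers; duplicate gene ids and samples absent from
    the sheet are errors naming the offender.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ValueError("first column of a counts file must be 'gene_id'")
    df = df.set_index("gene_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene_id: {dup}")
    for col in df.columns:
        if col not in sample_sheet.index:
            raise ValueError(f"sample {col!r} missing from the sample sheet")
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            bad = vals.index[~np.isclose(vals % 1, 0) | vals.isna()]
            if len(bad):
                raise ValueError(
                    f"non-integer count at gene {bad[0]!r}, sample {col!r}"
                )
            df[col] = vals.astype(int)
    samples = sample_sheet.loc[df.columns]
    return SectionCountMatrix(df, samples, stage_order)


def write_dataset(scm: SectionCountMatrix, truth: pd.DataFrame | None, outdir) -> dict[str, Path]:
    """Write a simulated dataset as counts/sample-sheet (and truth) TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "sample_sheet": outdir / "sample_sheet.tsv",
    }
    write_tsv(scm.counts.reset_index(), paths["counts"])
    write_tsv(scm.samples.reset_index(), paths["sample_sheet"])
    if truth is not None:
        paths["ground_truth"] = outdir / "ground_truth.tsv"
        write_tsv(truth.reset_index(), paths["ground_truth"])
    return paths


def read_config(path) -> dict:
    """Load a YAML pipeline configuration into a plain dict."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    return cfg
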