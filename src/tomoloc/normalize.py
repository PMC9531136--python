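"""Median-of-ratios normalization and per-oocyte section percentages.

Size factors follow the median-of-ratios construction: for each sample the
factor is the median, over genes whose counts are nonzero in every sample,
of the ratio of that sample's count to the gene's geometric mean across
samples.  Normalized counts are then summarized per gene and oocyte as the
percentage of the transcript found in each of the five sections.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .simulate import SECTIONS

PCT_COLUMNS = [f"pct_{s}" for s in SECTIONS]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Genes with a zero count in any sample (geometric mean zero) are
    excluded from the median.  Raises if no gene is eligible.
    """
    x = counts.to_numpy(float)
    eligible = (x > 0).all(axis=1)
    if not eligible.any():
        raise ValueError(
            "median-of-ratios: no gene has nonzero counts in every sample"
        )
    logx = np.log(x[eligible])
    log_geomean = logx.mean(axis=1, keepdims=True)
    ratios = np.exp(logx - log_geomean)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="factor")


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover every sample")
    return counts / factors


def _oocyte_groups(samples: pd.DataFrame) -> pd.core.groupby.DataFrameGroupBy:
    return samples.groupby(["species", "stage", "replicate"], sort=False)


def replicate_percentages(
    normalized: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene section percentages for every individual oocyte.

    Returns a long table with one row per (gene, oocyte): species, stage,
    replicate, pct_A..pct_E and the oocyte's total normalized count for the
    gene.  Oocytes in which a gene has zero total are reported with NaN
    percentages (a flagged missing profile, not zeros).  Every oocyte must
    have all five sections.
    """
    out = []
    for (species, stage, rep), grp in _oocyte_groups(samples):
        secs = set(grp["section"])
        if secs != set(SECTIONS):
            missing = sorted(set(SECTIONS) - secs)
            raise ValueError(
                f"oocyte ({species}, {stage}, {rep}) lacks sections {missing}"
            )
        cols = [grp.index[grp["section"] == s][0] for s in SECTIONS]
        sub = normalized[cols].to_numpy(float)
        totals = sub.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * sub / totals[:, None]
        pct[totals == 0] = np.nan
        df = pd.DataFrame(pct, index=normalized.index, columns=PCT_COLUMNS)
        df.insert(0, "species", species)
        df.insert(1, "stage", stage)
        df.insert(2, "replicate", rep)
        df["total"] = totals
        out.append(df)
    res = pd.concat(out)
    res.index.name = "gene_id"
    return res.reset_index()


def stage_profiles(
    normalized: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Stage-level localization profiles: mean of per-oocyte percentages.

    Oocytes with zero total for a gene are excluded from that gene's stage
    mean (with a warning); a gene with no informative oocyte at a stage has
    a NaN profile.  Also reports the mean per-oocyte total normalized count
    ('total', the per-oocyte transcript amount used in DLT thresholds).
    """
    reps = replicate_percentages(normalized, samples)
    n_missing = int(reps[PCT_COLUMNS[0]].isna().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} zero-total gene/oocyte profiles excluded from stage means"
        )
    agg = (
        reps.groupby(["gene_id", "species", "stage"], sort=False)[
            PCT_COLUMNS + ["total"]
        ]
        .mean()
        .reset_index()
    )
    n_reps = (
        reps.dropna(subset=[PCT_COLUMNS[0]])
        .groupby(["gene_id", "species", "stage"], sort=False)
        .size()
        .rename("n_replicates")
    )
    agg = agg.merge(
        n_reps, left_on=["gene_id", "species", "stage"], right_index=True, how="left"
    )
    agg["n_replicates"] = agg["n_replicates"].fillna(0).astype(int)
    return agg
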