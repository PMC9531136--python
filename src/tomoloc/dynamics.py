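"""Total-abundance dynamics: degradation and de novo synthesis.

The total transcript amount of a gene per oocyte (sum of the five
sections' normalized counts) is compared between the earliest and latest
stage with the ``total_between_stages`` LRT; genes with a significant and
at least ``min_fold`` change are labeled degraded (decrease) or de novo
synthesized (increase).  Where the change co-occurs with a profile shift,
a spatial subgroup records how (e.g. animal degradation leaving a vegetal
gradient, uniform degradation without gradient change).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import ClassThresholds, classify_all
from .dlt import detect_dlts
from .normalize import PCT_COLUMNS, normalize, size_factors, stage_profiles
from .simulate import SectionCountMatrix
from .temporal import ANIMAL_CLASSES, VEGETAL_CLASSES

DYNAMICS_LABELS = ("stable", "degraded", "de_novo")
SUBGROUP_LABELS = (
    "animal_degradation_to_vegetal",
    "vegetal_de_novo",
    "uniform_degradation",
    "uniform_synthesis",
    "animal_de_novo",
    "center_degradation",
    "none",
)


def classify_abundance(
    earliest_total: float,
    latest_total: float,
    padj: float,
    min_fold: float = 1.5,
    padj_threshold: float = 0.1,
) -> str:
    """degraded / de_novo / stable from the earliest-vs-latest total fold.

    Requires both significance (padj below threshold) and a fold change of
    at least ``min_fold``; a zero earliest total gets a one-count
    pseudocount in the ratio.
    """
    if min_fold <= 1:
        raise ValueError("min_fold must exceed 1")
    if earliest_total > 0:
        ratio = latest_total / earliest_total
    else:
        ratio = (latest_total + 1.0) / (earliest_total + 1.0)
    if not np.isnan(padj) and padj < padj_threshold:
        if ratio <= 1.0 / min_fold:
            return "degraded"
        if ratio >= min_fold:
            return "de_novo"
    return "stable"


def classify_dynamics_subgroup(
    dynamics: str,
    early_pct: np.ndarray,
    late_pct: np.ndarray,
    late_class: str,
    shift_min_points: float = 10.0,
    uniform_max_points: float = 5.0,
) -> str:
    """Spatial subgroup of an abundance change.

    ``shift_min_points`` is the minimum percentage-point move of a pole
    half (or the central section) that counts as a gradient change;
    ``uniform_max_points`` bounds all per-section moves of a "uniform"
    change.  Stable genes map to "none".
    """
    if dynamics == "stable":
        return "none"
    e = np.asarray(early_pct, float)
    l = np.asarray(late_pct, float)
    if np.isnan(e).any() or np.isnan(l).any():
        return "none"
    delta = l - e
    an_drop = (e[0] + e[1]) - (l[0] + l[1])
    veg_rise = (l[3] + l[4]) - (e[3] + e[4])
    if (
        dynamics == "degraded"
        and an_drop >= shift_min_points
        and late_class in VEGETAL_CLASSES
    ):
        return "animal_degradation_to_vegetal"
    if (
        dynamics == "de_novo"
        and veg_rise >= shift_min_points
        and late_class in VEGETAL_CLASSES
    ):
        return "vegetal_de_novo"
    if dynamics == "de_novo" and late_class in ANIMAL_CLASSES:
        return "animal_de_novo"
    others = np.abs(np.delete(delta, 2))
    if (
        dynamics == "degraded"
        and -delta[2] >= shift_min_points
        and (others <= uniform_max_points).all()
    ):
        return "center_degradation"
    if (np.abs(delta) <= uniform_max_points).all():
        return "uniform_degradation" if dynamics == "degraded" else "uniform_synthesis"
    return "none"


def abundance_analysis(
    scm: SectionCountMatrix,
    min_fold: float = 1.5,
    padj_threshold: float = 0.1,
    count_threshold: float = 20.0,
    class_thresholds: ClassThresholds = ClassThresholds(),
    profiles: pd.DataFrame | None = None,
    total_test: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene abundance dynamics and spatial subgroups across stages.

    Runs the ``total_between_stages`` test (unless a precomputed result is
    supplied), computes per-stage mean oocyte totals, and labels each
    gene's dynamics and subgroup.  Only genes clearing the per-oocyte
    count threshold in at least one stage can be non-stable.
    """
    stage_order = scm.stage_order
    stages_present = [s for s in stage_order if s in set(scm.samples["stage"])]
    if len(stages_present) < 2:
        raise ValueError("abundance dynamics needs >= 2 stages")
    first, last = stages_present[0], stages_present[-1]

    if total_test is None:
        total_test = detect_dlts(
            scm, "total_between_stages",
            padj_threshold=padj_threshold, count_threshold=count_threshold,
        )
    if profiles is None:
        factors = size_factors(scm.counts)
        profiles = stage_profiles(normalize(scm.counts, factors), scm.samples)
    classified = classify_all(profiles, class_thresholds)
    prof = classified.set_index(["gene_id", "stage"])

    # per-stage mean oocyte totals come with the stage profiles
    totals = profiles.pivot_table(index="gene_id", columns="stage", values="total")

    rows = []
    for _, rec in total_test.iterrows():
        gene = rec["gene_id"]
        t_first = float(totals.loc[gene, first])
        t_last = float(totals.loc[gene, last])
        significant = rec["is_dlt"]  # padj and count threshold combined
        dyn = classify_abundance(
            t_first, t_last,
            rec["padj"] if significant else np.nan,
            min_fold, padj_threshold,
        )
        e = prof.loc[(gene, first), PCT_COLUMNS].to_numpy(float)
        l = prof.loc[(gene, last), PCT_COLUMNS].to_numpy(float)
        sub = classify_dynamics_subgroup(
            dyn, e, l, prof.loc[(gene, last), "class_label"]
        )
        rows.append((gene, t_first, t_last, rec["padj"], dyn, sub))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", f"total_{first}", f"total_{last}", "padj", "dynamics", "subgroup",
        ],
    )
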