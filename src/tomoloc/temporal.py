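"""Temporal relocalization groups across ordered oocyte stages.

DLTs whose section profiles change between the earliest and latest stage
are filtered by fold change and replicate reproducibility, then assigned
a named group describing when their animal/vegetal gradient formed:

  early_vegetal / early_animal          gradient already present early and
                                        essentially unchanged (<1.5x)
  late_*_homogeneous                    uniform early profile relocalizing
                                        to a pole late
  late_*_predefined                     a half-formed early gradient that
                                        sharpens late (>=1.2x)
  polar                                 both poles enriched late, hollow
                                        center
  other                                 everything else

Rule-based assignment is the decision path; divisive (DIANA) clustering
of the concatenated stage x section profiles is provided as an
independent verification.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.metrics import silhouette_score

from .normalize import PCT_COLUMNS

VEGETAL_CLASSES = frozenset({"vegetal", "extreme_vegetal"})
ANIMAL_CLASSES = frozenset({"animal", "extreme_animal"})

TEMPORAL_GROUP_LABELS = (
    "early_vegetal",
    "late_vegetal_homogeneous",
    "late_vegetal_predefined",
    "early_animal",
    "late_animal_homogeneous",
    "late_animal_predefined",
    "polar",
    "other",
)


@dataclass(frozen=True)
class TemporalThresholds:
    """Boundaries of the rule-based temporal grouping.

    ``min_fold`` is the stage/section fold-change filter (1.5x; 2x is the
    stricter alternative for very DLT-rich datasets); ``pseudocount`` is
    added to percentages in every fold ratio.  The homogeneous band
    brackets a uniform pole-pair share (40 %), the predefined band a
    half-formed gradient; ``early_max_fold`` / ``predefined_min_fold`` are
    the limited-vs-enhanced pole fold discriminators.
    """

    min_fold: float = 1.5
    pseudocount: float = 1.0
    early_max_fold: float = 1.5
    predefined_min_fold: float = 1.2
    homogeneous_band: tuple[float, float] = (30.0, 45.0)
    predefined_band: tuple[float, float] = (45.0, 60.0)
    polar_half_min_pct: float = 35.0
    polar_center_max_pct: float = 15.0


def stage_fold_change_filter(
    early_pct: np.ndarray,
    late_pct: np.ndarray,
    min_fold: float = 1.5,
    pseudocount: float = 1.0,
) -> tuple[bool, float]:
    """Whether any section changed by >= min_fold between the stages.

    Per-section fold = (late + eps)/(early + eps); a change in either
    direction counts.  Returns (passed, max fold change), the latter
    folded to >= 1.
    """
    if min_fold <= 1:
        raise ValueError("min_fold must exceed 1")
    e = np.asarray(early_pct, float) + pseudocount
    l = np.asarray(late_pct, float) + pseudocount
    folds = l / e
    max_fold = float(np.max(np.maximum(folds, 1.0 / folds)))
    return max_fold >= min_fold, max_fold


def replicate_reproducibility_filter(
    early_mean_pct: np.ndarray, late_replicate_pcts: np.ndarray
) -> bool:
    """Direction of change consistent across the late-stage replicates.

    Finds the maximally changing section (late stage mean vs early stage
    mean) and requires every late-stage replicate to move it in the same
    direction.  With a single late replicate the gene passes with a
    warning (reproducibility cannot be assessed).
    """
    early = np.asarray(early_mean_pct, float)
    late = np.atleast_2d(np.asarray(late_replicate_pcts, float))
    late = late[~np.isnan(late).any(axis=1)]
    if late.shape[0] < 2:
        warnings.warn("single late-stage replicate; reproducibility not assessable")
        return True
    delta_mean = late.mean(axis=0) - early
    sec = int(np.argmax(np.abs(delta_mean)))
    signs = np.sign(late[:, sec] - early[sec])
    ref = np.sign(delta_mean[sec])
    return bool(np.all(signs == ref)) and ref != 0


def _pole_fold(early_half: float, late_half: float, eps: float) -> float:
    return (late_half + eps) / (early_half + eps)


def assign_temporal_group(
    early_pct: np.ndarray,
    late_pct: np.ndarray,
    early_class: str,
    late_class: str,
    passed_filters: bool,
    thresholds: TemporalThresholds = TemporalThresholds(),
) -> str:
    """Named temporal group from the earliest and latest stage profiles.

    Early groups (gradient present at both ends, pole fold < 1.5x) are
    exempt from the fold/reproducibility filters, which change little by
    definition; all late groups and polar require ``passed_filters``.
    """
    t = thresholds
    e = np.asarray(early_pct, float)
    l = np.asarray(late_pct, float)
    veg_e, veg_l = e[3] + e[4], l[3] + l[4]
    an_e, an_l = e[0] + e[1], l[0] + l[1]
    eps = t.pseudocount
    veg_fold = _pole_fold(veg_e, veg_l, eps)
    an_fold = _pole_fold(an_e, an_l, eps)

    if (
        early_class in VEGETAL_CLASSES
        and late_class in VEGETAL_CLASSES
        and veg_fold < t.early_max_fold
    ):
        return "early_vegetal"
    if (
        early_class in ANIMAL_CLASSES
        and late_class in ANIMAL_CLASSES
        and an_fold < t.early_max_fold
    ):
        return "early_animal"
    if not passed_filters:
        return "other"
    if (
        an_l >= t.polar_half_min_pct
        and veg_l >= t.polar_half_min_pct
        and l[2] <= t.polar_center_max_pct
    ):
        return "polar"
    hlo, hhi = t.homogeneous_band
    plo, phi = t.predefined_band
    if early_class == "undefined" and hlo <= veg_e < hhi and late_class in VEGETAL_CLASSES:
        return "late_vegetal_homogeneous"
    if plo <= veg_e < phi and late_class in VEGETAL_CLASSES and veg_fold >= t.predefined_min_fold:
        return "late_vegetal_predefined"
    if early_class == "undefined" and hlo <= an_e < hhi and late_class in ANIMAL_CLASSES:
        return "late_animal_homogeneous"
    if plo <= an_e < phi and late_class in ANIMAL_CLASSES and an_fold >= t.predefined_min_fold:
        return "late_animal_predefined"
    return "other"


def assign_temporal_groups(
    classified_profiles: pd.DataFrame,
    replicate_pcts: pd.DataFrame,
    dlt_genes,
    stage_order: list[str],
    thresholds: TemporalThresholds = TemporalThresholds(),
) -> pd.DataFrame:
    """Assign a temporal group to every DLT gene.

    ``classified_profiles`` is the output of :func:`tomoloc.classify.
    classify_all` on stage profiles, ``replicate_pcts`` the per-oocyte
    percentage table, ``dlt_genes`` the genes flagged as DLTs in at least
    one stage.  Uses the earliest and latest stage present (in
    ``stage_order``) for every gene.
    """
    columns = ["gene_id", "group", "max_section_fold_change", "reproducible"]
    dlt_genes = list(dlt_genes)
    if not dlt_genes:
        return pd.DataFrame(columns=columns)
    stages_present = [s for s in stage_order if s in set(classified_profiles["stage"])]
    if len(stages_present) < 2:
        raise ValueError("temporal grouping needs >= 2 stages")
    first, last = stages_present[0], stages_present[-1]
    prof = classified_profiles.set_index(["gene_id", "stage"])
    late_reps = replicate_pcts[replicate_pcts["stage"] == last].groupby("gene_id")

    rows = []
    for gene in dlt_genes:
        try:
            pe = prof.loc[(gene, first)]
            pl = prof.loc[(gene, last)]
        except KeyError:
            continue
        e = pe[PCT_COLUMNS].to_numpy(float)
        l = pl[PCT_COLUMNS].to_numpy(float)
        if np.isnan(e).any() or np.isnan(l).any():
            rows.append((gene, "other", np.nan, False))
            continue
        passed_fc, max_fold = stage_fold_change_filter(
            e, l, thresholds.min_fold, thresholds.pseudocount
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reproducible = replicate_reproducibility_filter(
                e, late_reps.get_group(gene)[PCT_COLUMNS].to_numpy(float)
            )
        group = assign_temporal_group(
            e, l, pe["class_label"], pl["class_label"],
            passed_fc and reproducible, thresholds,
        )
        rows.append((gene, group, max_fold, reproducible))
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# DIANA divisive clustering (verification path)
# ---------------------------------------------------------------------------

def _split_cluster(D: np.ndarray, members: list[int]) -> tuple[list[int], list[int]]:
    """One DIANA split: seed a splinter from the most dissimilar member,
    then move over points closer (on average) to the splinter."""
    rest = list(members)
    avg = D[np.ix_(rest, rest)].sum(axis=1) / (len(rest) - 1)
    splinter = [rest.pop(int(np.argmax(avg)))]
    moved = True
    while moved and len(rest) > 1:
        moved = False
        d_spl = D[np.ix_(rest, splinter)].mean(axis=1)
        d_rest = D[np.ix_(rest, rest)].sum(axis=1) / (len(rest) - 1)
        gains = d_rest - d_spl
        i = int(np.argmax(gains))
        if gains[i] > 0:
            splinter.append(rest.pop(i))
            moved = True
    return splinter, rest


def diana_labels(D: np.ndarray, k: int) -> np.ndarray:
    """Divisive hierarchical clustering into k clusters.

    Repeatedly splits the cluster with the largest diameter; stops early if
    every remaining cluster has zero diameter.
    """
    n = D.shape[0]
    clusters: list[list[int]] = [list(range(n))]
    while len(clusters) < k:
        diameters = [
            D[np.ix_(c, c)].max() if len(c) > 1 else 0.0 for c in clusters
        ]
        i = int(np.argmax(diameters))
        if diameters[i] <= 0:
            break
        spl, rest = _split_cluster(D, clusters[i])
        clusters[i] = rest
        clusters.append(spl)
    labels = np.empty(n, int)
    for ci, c in enumerate(clusters):
        labels[c] = ci
    return labels


def cluster_profiles(
    profile_matrix: np.ndarray, k_range=range(2, 7)
) -> tuple[np.ndarray, dict[int, float]]:
    """DIANA clustering of concatenated stage x section profile vectors.

    k is chosen within ``k_range`` by maximum mean silhouette (Euclidean).
    All-identical rows are degenerate: returns one cluster with a warning.
    Returns (labels, {k: silhouette}).
    """
    X = np.asarray(profile_matrix, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("clustering needs >= 2 profiles")
    ks = [int(k) for k in k_range]
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    D = squareform(pdist(X))
    if D.max() <= 0:
        warnings.warn("all profiles identical; returning a single cluster")
        return np.zeros(n, int), {}
    scores: dict[int, float] = {}
    best_labels, best_score = None, -np.inf
    for k in ks:
        labels = diana_labels(D, k)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(D, labels, metric="precomputed"))
        if scores[k] > best_score:  # ties keep the smallest k
            best_labels, best_score = labels, scores[k]
    return best_labels, scores
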