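"""Synthetic sectioned-oocyte count data with known ground truth.

Emulates the structure of a TOMO-Seq experiment: each oocyte is cut into
five sections along the animal-vegetal axis (A = extremely animal ...
E = extremely vegetal) and each section is sequenced separately, for
several replicate oocytes at several ordered growth stages.  Every gene
is drawn from a localization *archetype* (its terminal section-fraction
profile), a *temporal group* (how the profile develops across stages) and
an *abundance dynamics* label (how its total amount changes), all of which
are recorded as ground truth so downstream callers can be benchmarked.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SECTIONS: tuple[str, ...] = ("A", "B", "C", "D", "E")

#: Terminal (fully developed) section fractions per localization archetype.
#: vegetal archetypes are the axis mirror of the animal ones.
ARCHETYPE_FRACTIONS: dict[str, tuple[float, ...]] = {
    "extreme_animal": (0.70, 0.15, 0.08, 0.04, 0.03),
    "animal": (0.35, 0.30, 0.15, 0.12, 0.08),
    "central": (0.10, 0.20, 0.40, 0.20, 0.10),
    "vegetal": (0.08, 0.12, 0.15, 0.30, 0.35),
    "extreme_vegetal": (0.03, 0.04, 0.08, 0.15, 0.70),
    "uniform": (0.20, 0.20, 0.20, 0.20, 0.20),
    "polar": (0.35, 0.10, 0.05, 0.10, 0.40),
}

TEMPORAL_GROUPS: tuple[str, ...] = (
    "early_vegetal",
    "late_vegetal_homogeneous",
    "late_vegetal_predefined",
    "early_animal",
    "late_animal_homogeneous",
    "late_animal_predefined",
    "polar",
    "none",
)

ABUNDANCE_DYNAMICS: tuple[str, ...] = ("stable", "degraded", "de_novo")

_UNIFORM = np.full(5, 0.2)


@dataclass(frozen=True)
class GeneBlock:
    """A homogeneous block of simulated genes sharing one ground truth.

    ``start_fractions`` / ``end_fractions`` override the trajectory implied
    by ``archetype`` and ``temporal_group`` (used e.g. to plant abundance
    subgroups whose profile moves between archetypes).
    """

    n: int
    archetype: str
    temporal_group: str = "none"
    dynamics: str = "stable"
    start_fractions: tuple[float, ...] | None = None
    end_fractions: tuple[float, ...] | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPE_FRACTIONS:
            raise ValueError(f"unknown archetype: {self.archetype!r}")
        if self.temporal_group not in TEMPORAL_GROUPS:
            raise ValueError(f"unknown temporal group: {self.temporal_group!r}")
        if self.dynamics not in ABUNDANCE_DYNAMICS:
            raise ValueError(f"unknown abundance dynamics: {self.dynamics!r}")
        if self.n < 1:
            raise ValueError("block size must be >= 1")
        for name in ("start_fractions", "end_fractions"):
            fr = getattr(self, name)
            if fr is not None:
                fr = np.asarray(fr, float)
                if fr.shape != (5,) or (fr <= 0).any() or abs(fr.sum() - 1) > 1e-9:
                    raise ValueError(f"{name} must be 5 positive fractions summing to 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and noise model of a simulated single-species dataset.

    Defaults describe two ordered stages (small -> big oocytes) with three
    replicate oocytes each, deep libraries (8k-30k transcripts per gene per
    oocyte) and a small replicate-to-replicate negative-binomial dispersion,
    so that planted localization trajectories sit clear of the downstream
    classification boundaries.
    """

    blocks: tuple[GeneBlock, ...]
    stages: tuple[str, ...] = ("small", "big")
    replicates_per_stage: int = 3
    sections: tuple[str, ...] = SECTIONS
    base_abundance_range: tuple[float, float] = (8_000.0, 30_000.0)
    dispersion: float = 0.002
    library_size_factor_range: tuple[float, float] = (0.75, 1.3)
    degraded_fold_per_stage: float = 0.5
    de_novo_fold_per_stage: float = 2.0
    species: str = "species1"
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.sections) != SECTIONS:
            raise ValueError(f"sections must be exactly {SECTIONS}")
        if self.replicates_per_stage < 2:
            raise ValueError("replicates_per_stage must be >= 2")
        if len(self.stages) != len(set(self.stages)):
            raise ValueError("stage labels must be unique")
        lo, hi = self.base_abundance_range
        if not (0 < lo <= hi):
            raise ValueError("base_abundance_range must be positive and ordered")
        lo, hi = self.library_size_factor_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_factor_range must be positive and ordered")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.degraded_fold_per_stage <= 0 or self.de_novo_fold_per_stage <= 0:
            raise ValueError("per-stage abundance folds must be positive")
        dynamic = any(
            b.temporal_group != "none" or b.dynamics != "stable" for b in self.blocks
        )
        if dynamic and len(self.stages) < 2:
            raise ValueError("temporal/abundance dynamics require >= 2 stages")
        if len(self.stages) < 1 or not self.blocks:
            raise ValueError("need >= 1 stage and >= 1 gene block")


@dataclass
class SectionCountMatrix:
    """Raw integer counts (genes x samples) with per-sample annotations.

    ``samples`` is indexed by sample_id with columns species, stage,
    replicate, section; ``stage_order`` declares the developmental order
    of the stage labels.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    stage_order: list[str]

    def __post_init__(self) -> None:
        required = {"species", "stage", "replicate", "section"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns do not match sample sheet sample_ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene_id: {dup}")
        unknown = set(self.samples["stage"]) - set(self.stage_order)
        if unknown:
            raise ValueError(f"stages missing from stage_order: {sorted(unknown)}")
        key = self.samples[["species", "stage", "replicate", "section"]]
        if key.duplicated().any():
            raise ValueError("duplicate (species, stage, replicate, section) sample")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index


def profile_fractions(
    archetype: str,
    stage_progress: float,
    temporal_group: str = "none",
    terminal: np.ndarray | None = None,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Section fractions of a gene at a given point of oogenesis.

    ``stage_progress`` maps the ordered stages onto [0, 1].  Late groups
    interpolate linearly from a uniform profile (0.2 per section) at
    progress 0 to the archetype's terminal fractions at progress 1;
    ``*_predefined`` groups start from a half-strength gradient (the
    midpoint of uniform and terminal); early groups and ``none`` hold the
    terminal fractions throughout; the ``polar`` group grows its bipolar
    profile out of a uniform start like the late groups.
    """
    if archetype not in ARCHETYPE_FRACTIONS:
        raise ValueError(f"unknown archetype: {archetype!r}")
    if temporal_group not in TEMPORAL_GROUPS:
        raise ValueError(f"unknown temporal group: {temporal_group!r}")
    if not 0.0 <= stage_progress <= 1.0:
        raise ValueError("stage_progress must lie in [0, 1]")
    end = np.asarray(
        ARCHETYPE_FRACTIONS[archetype] if terminal is None else terminal, float
    )
    if start is not None:
        origin = np.asarray(start, float)
    elif temporal_group in ("early_vegetal", "early_animal", "none"):
        origin = end
    elif temporal_group.endswith("_predefined"):
        origin = 0.5 * (_UNIFORM + end)
    else:  # late homogeneous starts and the polar group grow from uniform
        origin = _UNIFORM
    frac = origin + stage_progress * (end - origin)
    return frac / frac.sum()


def _stage_total_fold(dynamics: str, stage_index: int, config: SimulationConfig) -> float:
    if dynamics == "degraded":
        return config.degraded_fold_per_stage**stage_index
    if dynamics == "de_novo":
        return config.de_novo_fold_per_stage**stage_index
    return 1.0


def generate_dataset(config: SimulationConfig) -> tuple[SectionCountMatrix, pd.DataFrame]:
    """Draw a seeded dataset and its per-gene ground-truth table.

    Counts are negative binomial with mean
    ``total(stage) * fraction(section) * library_size_factor(sample)`` and
    variance ``mu + alpha * mu**2``; the same seed reproduces the dataset
    bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    n_stages = len(config.stages)
    progress = (
        np.zeros(1) if n_stages == 1 else np.arange(n_stages) / (n_stages - 1)
    )

    sample_rows = []
    for stage in config.stages:
        for rep in range(1, config.replicates_per_stage + 1):
            for sec in config.sections:
                sid = f"{config.species}_{stage}_r{rep}_{sec}"
                sample_rows.append((sid, config.species, stage, f"r{rep}", sec))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "species", "stage", "replicate", "section"]
    ).set_index("sample_id")
    lo, hi = config.library_size_factor_range
    lib_factors = rng.uniform(lo, hi, size=len(samples))

    n_genes = sum(b.n for b in config.blocks)
    gene_ids = [f"g{i:05d}" for i in range(1, n_genes + 1)]

    truth_rows = []
    mean_blocks = []
    gi = 0
    for block in config.blocks:
        terminal = (
            None if block.end_fractions is None else np.asarray(block.end_fractions)
        )
        start = (
            None if block.start_fractions is None else np.asarray(block.start_fractions)
        )
        stage_fracs = np.stack(
            [
                profile_fractions(
                    block.archetype, p, block.temporal_group, terminal, start
                )
                for p in progress
            ]
        )  # n_stages x 5
        lo, hi = config.base_abundance_range
        base = rng.uniform(lo, hi, size=block.n)
        folds = np.array(
            [_stage_total_fold(block.dynamics, i, config) for i in range(n_stages)]
        )
        # per-sample expected counts for the block: n x (stages*reps*5)
        sec_idx = {s: i for i, s in enumerate(config.sections)}
        per_sample = np.empty((block.n, len(samples)))
        for j, (sid, row) in enumerate(samples.iterrows()):
            si = config.stages.index(row["stage"])
            per_sample[:, j] = (
                base * folds[si] * stage_fracs[si, sec_idx[row["section"]]] * lib_factors[j]
            )
        if (per_sample <= 0).any():
            raise ValueError("non-positive expected count in simulation")
        mean_blocks.append(per_sample)
        for g in range(block.n):
            row = {
                "gene_id": gene_ids[gi],
                "symbol": gene_ids[gi],
                "archetype": block.archetype,
                "temporal_group": block.temporal_group,
                "dynamics": block.dynamics,
                "label": block.label or block.temporal_group,
            }
            for si, stage in enumerate(config.stages):
                for ci, sec in enumerate(config.sections):
                    row[f"frac_{stage}_{sec}"] = stage_fracs[si, ci]
                row[f"total_{stage}"] = base[g] * folds[si]
            truth_rows.append(row)
            gi += 1

    mu = np.vstack(mean_blocks)
    if config.dispersion > 1e-12:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=samples.index)
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    scm = SectionCountMatrix(counts_df, samples, list(config.stages))
    return scm, truth


# ---------------------------------------------------------------------------
# Benchmark configurations: the study conditions used by the test suite and
# the acceptance analyses.
# ---------------------------------------------------------------------------

def temporal_benchmark_config(
    seed: int = 0, n_per_group: int = 60, n_background: int = 600
) -> SimulationConfig:
    """All seven named temporal groups plus unlocalized background genes.

    The uniform background is the majority of the transcriptome, as in
    real data; this also keeps the median-of-ratios factors anchored to
    non-localized genes instead of absorbing section composition.
    """
    blocks = (
        GeneBlock(n_per_group, "extreme_vegetal", "early_vegetal"),
        GeneBlock(n_per_group, "vegetal", "late_vegetal_homogeneous"),
        GeneBlock(n_per_group, "vegetal", "late_vegetal_predefined"),
        GeneBlock(n_per_group, "extreme_animal", "early_animal"),
        GeneBlock(n_per_group, "animal", "late_animal_homogeneous"),
        GeneBlock(n_per_group, "animal", "late_animal_predefined"),
        GeneBlock(n_per_group, "polar", "polar"),
        GeneBlock(n_background, "uniform", "none"),
    )
    return SimulationConfig(blocks=blocks, seed=seed)


def dynamics_benchmark_config(
    seed: int = 0, n_per_group: int = 50, n_background: int = 400
) -> SimulationConfig:
    """Planted abundance dynamics and their spatial subgroups.

    Folds follow the simulator defaults (x0.5 per stage step for degraded,
    x2 for de novo); profile trajectories are chosen so each subgroup rule
    is satisfied with clear margin.
    """
    uni = (0.2, 0.2, 0.2, 0.2, 0.2)
    blocks = (
        GeneBlock(n_background, "uniform", "none", "stable", label="stable"),
        GeneBlock(n_per_group, "uniform", "none", "degraded",
                  label="uniform_degradation"),
        GeneBlock(n_per_group, "uniform", "none", "de_novo",
                  label="uniform_synthesis"),
        GeneBlock(n_per_group, "vegetal", "none", "degraded",
                  start_fractions=(0.40, 0.30, 0.10, 0.10, 0.10),
                  end_fractions=(0.10, 0.10, 0.10, 0.30, 0.40),
                  label="animal_degradation_to_vegetal"),
        GeneBlock(n_per_group, "vegetal", "none", "de_novo",
                  start_fractions=uni,
                  label="vegetal_de_novo"),
        GeneBlock(n_per_group, "animal", "none", "de_novo",
                  start_fractions=uni,
                  label="animal_de_novo"),
        GeneBlock(n_per_group, "central", "none", "degraded",
                  start_fractions=(0.17, 0.17, 0.32, 0.17, 0.17),
                  end_fractions=uni,
                  label="center_degradation"),
    )
    return SimulationConfig(blocks=blocks, seed=seed)


def null_uniform_config(
    seed: int = 0,
    n_genes: int = 2000,
    total_mean: float = 1000.0,
    dispersion: float = 0.1,
    stages: tuple[str, ...] = ("small",),
    replicates: int = 3,
) -> SimulationConfig:
    """Uniform (no localization) genes for false-positive control.

    The default total of 1000 per oocyte puts 200 expected counts in each
    of the five sections.
    """
    return SimulationConfig(
        blocks=(GeneBlock(n_genes, "uniform"),),
        stages=stages,
        replicates_per_stage=replicates,
        base_abundance_range=(total_mean, total_mean),
        dispersion=dispersion,
        library_size_factor_range=(1.0, 1.0),
        seed=seed,
    )


def power_benchmark_config(
    seed: int = 0,
    n_vegetal: int = 500,
    n_uniform: int = 1500,
    total_mean: float = 1000.0,
    dispersion: float = 0.1,
    replicates: int = 3,
) -> SimulationConfig:
    """Planted steep vegetal genes among a uniform background (one stage)."""
    blocks = (
        GeneBlock(n_vegetal, "vegetal",
                  end_fractions=(0.05, 0.05, 0.10, 0.30, 0.50)),
        GeneBlock(n_uniform, "uniform"),
    )
    return SimulationConfig(
        blocks=blocks,
        stages=("small",),
        replicates_per_stage=replicates,
        base_abundance_range=(total_mean, total_mean),
        dispersion=dispersion,
        library_size_factor_range=(1.0, 1.0),
        seed=seed,
    )


def two_species_benchmark(
    seed: int = 0, n_conserved: int = 100, n_specific: int = 60,
    n_background: int = 400,
) -> tuple[
    tuple[SectionCountMatrix, pd.DataFrame],
    tuple[SectionCountMatrix, pd.DataFrame],
    pd.DataFrame,
]:
    """Two species with planted conserved temporal groups and an ortholog map.

    The conserved genes are split between the three pooled conserved sets
    (early vegetal, late vegetal, animal); half of the conserved pairs share
    a (case-varied) gene symbol, the other half are linked only through an
    orthologous-unit number.  Returns ((scm1, truth1), (scm2, truth2),
    ortholog_map).
    """
    per = n_conserved // 4
    conserved_blocks = (
        GeneBlock(per, "extreme_vegetal", "early_vegetal"),
        GeneBlock(per, "vegetal", "late_vegetal_homogeneous"),
        GeneBlock(per, "animal", "late_animal_homogeneous"),
        GeneBlock(n_conserved - 3 * per, "extreme_animal", "early_animal"),
    )
    specific1 = (GeneBlock(n_specific, "vegetal", "late_vegetal_predefined"),
                 GeneBlock(n_background, "uniform", "none"))
    specific2 = (GeneBlock(n_specific, "polar", "polar"),
                 GeneBlock(n_background, "uniform", "none"))
    cfg1 = SimulationConfig(blocks=conserved_blocks + specific1,
                            species="species1", seed=seed)
    cfg2 = SimulationConfig(blocks=conserved_blocks + specific2,
                            species="species2", seed=seed + 1)
    scm1, truth1 = generate_dataset(cfg1)
    scm2, truth2 = generate_dataset(cfg2)

    # distinct gene ids per species; shared biology via symbols / units
    truth1 = truth1.rename(index=lambda g: "s1_" + g)
    truth2 = truth2.rename(index=lambda g: "s2_" + g)
    scm1.counts.index = truth1.index
    scm2.counts.index = truth2.index

    # default symbols are species-unique; only conserved pairs get shared ones
    sym1 = pd.Series(truth1.index, index=truth1.index)
    sym2 = pd.Series(truth2.index, index=truth2.index)
    unit_rows = []
    for i in range(n_conserved):
        g1, g2 = truth1.index[i], truth2.index[i]
        if i % 2 == 0:  # symbol-matched pair, case differing between species
            sym1.loc[g1] = f"sym{i:04d}"
            sym2.loc[g2] = f"SYM{i:04d}"
        else:  # no shared symbol; linked by an orthologous unit
            sym1.loc[g1] = f"s1only{i:04d}"
            sym2.loc[g2] = f"s2only{i:04d}"
            unit_rows.append((g1, g2, f"OU{i:04d}"))
    truth1["symbol"] = sym1
    truth2["symbol"] = sym2
    ortholog_map = pd.DataFrame(
        unit_rows, columns=["gene_id_species1", "gene_id_species2", "unit_id"]
    )
    return (scm1, truth1), (scm2, truth2), ortholog_map
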