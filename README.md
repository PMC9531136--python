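# tomoloc

Analysis of maternal mRNA localization along the animal–vegetal (A–V) axis
of developing oocytes from TOMO-Seq data: each oocyte is cryosectioned into
five axial sections (A = extremely animal … E = extremely vegetal), each
section is sequenced separately, and the resulting gene × sample count
matrix — for several replicate oocytes at several ordered growth stages —
is analyzed for *where* each transcript sits, *when* its gradient forms,
and *whether* it is degraded or newly synthesized during oogenesis.

The package is aimed at developmental-biology groups working with sectioned
bulk RNA-seq of oocytes or similar axially organized specimens. It starts
from a count matrix (read preprocessing and alignment are out of scope) and
provides:

- **Normalization** — per-sample size factors by the median-of-ratios
  method (`s_j = median_g k_gj / (∏_j' k_gj')^{1/n}` over genes with no
  zeros), and per-oocyte section percentages
  `p_s = 100 · k_s / Σ_{s'∈A..E} k_{s'}`.
- **DLT detection** — per-gene negative-binomial GLMs
  (`log μ = Xβ + log s_j`, `Var = μ + αμ²`) with likelihood-ratio tests of
  nested designs: `~replicate + position` vs `~replicate` (within a stage),
  `~Size + position + Size:position` vs `~Size + position` (profile change
  across stages), `~Size + position` vs `~Size` (magnitude change), and
  `~Size` vs `~1` on per-oocyte totals. A differentially localized
  transcript (DLT) has Benjamini–Hochberg adjusted p < 0.1 and more than
  20 transcripts per oocyte.
- **Profile classification** — extreme animal / animal / central /
  vegetal / extreme vegetal / undefined, by configurable thresholds on the
  section percentages.
- **Temporal grouping** — early vs late vegetal/animal gradient formation
  (with "predefined" subgroups that sharpen a pre-existing weak gradient),
  polar profiles, fold-change (≥1.5× or 2×) and replicate-reproducibility
  filters, plus DIANA divisive clustering as an independent verification.
- **Abundance dynamics** — degraded / de novo synthesized / stable calls
  from the total-count test, with spatial subgroups (e.g. animal
  degradation leaving a vegetal gradient, uniform degradation).
- **Conservation** — two-species ortholog matching (case-insensitive gene
  symbols, then orthologous-unit numbers) and conserved temporal/abundance
  sets, with Z-scored profile matrices for reporting.
- **Synthetic data** — a seeded generator that emulates the sectioned-
  oocyte design with known per-gene localization archetypes, temporal
  groups, and abundance dynamics, so every stage of the pipeline can be
  benchmarked against ground truth.

## Worked example

```python
import tomoloc as tl

# two stages (small -> big), 3 oocytes each, all seven temporal groups
# planted (20 genes per group) on a 200-gene uniform background
cfg = tl.simulate.temporal_benchmark_config(seed=0, n_per_group=20,
                                            n_background=200)
scm, truth = tl.generate_dataset(cfg)

factors = tl.size_factors(scm.counts)
norm = tl.normalize(scm.counts, factors)
profiles = tl.stage_profiles(norm, scm.samples)

dlt_any = set()
for stage in scm.stage_order:
    res = tl.detect_dlts(scm, "within_stage", stage=stage,
                         precomputed_factors=factors)
    print(f"{stage}: {int(res.is_dlt.sum())} DLTs / {len(res)} genes tested")
    dlt_any |= set(res.query("is_dlt").gene_id)

classified = tl.classify_all(profiles[profiles.gene_id.isin(dlt_any)])
reps = tl.replicate_percentages(norm, scm.samples)
assign = tl.assign_temporal_groups(classified, reps, sorted(dlt_any),
                                   scm.stage_order)
print(assign.group.value_counts().to_string())
```

prints

```
small: 97 DLTs / 340 genes tested
big: 170 DLTs / 340 genes tested
group
other                       41
early_vegetal               20
late_vegetal_homogeneous    20
early_animal                20
polar                       20
late_animal_homogeneous     20
late_animal_predefined      19
late_vegetal_predefined     18
```

Reading this: at the small stage only the *early* gradients (and the
half-formed "predefined" ones) are localized, so fewer genes test as DLTs;
by the big stage the late groups have relocalized and 170 genes are DLTs.
The rule-based grouping then recovers the planted temporal groups almost
perfectly — 137 of the 140 planted named-group genes — while the uniform
background lands in `other` (41 genes, including the three filter
near-misses from the predefined groups).

The same analysis is available from the shell:

```sh
tomoloc simulate --preset temporal --seed 0 --out-dir data/
tomoloc run-all --config config.yaml     # full pipeline, writes TSVs + manifest
```

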