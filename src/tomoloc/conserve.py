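"""Cross-species comparison of localization dynamics.

Genes of the two species are paired by case-insensitive gene-symbol
matching first, and through a supplied orthologous-unit table for genes
without a shared symbol.  A pair is conserved for a pooled temporal set
(early vegetal / late vegetal / animal) when both members carry a group
of that set; conserved degradation / de novo sets intersect the
abundance-dynamics labels the same way.  Z-scored profile matrices
support heatmap-style reporting.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: pooled conserved sets over the named temporal groups
CONSERVED_POOLS: dict[str, frozenset[str]] = {
    "early_vegetal": frozenset({"early_vegetal"}),
    "late_vegetal": frozenset({"late_vegetal_homogeneous", "late_vegetal_predefined"}),
    "animal": frozenset(
        {"early_animal", "late_animal_homogeneous", "late_animal_predefined"}
    ),
}


def map_orthologs(
    symbols1: pd.Series,
    symbols2: pd.Series,
    unit_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pair genes across species by symbol, then by orthologous unit.

    ``symbols1``/``symbols2`` map gene_id -> symbol per species (gene ids
    unique).  Symbol matching is case-insensitive and exact; a symbol with
    several partners takes the lexicographically first gene id on each
    side, with a warning.  Remaining genes are paired through ``unit_map``
    (columns gene_id_species1, gene_id_species2, unit_id); each gene joins
    at most one pair.  Returns columns gene_id_species1, gene_id_species2,
    match_type.
    """
    for s, name in ((symbols1, "symbols1"), (symbols2, "symbols2")):
        if s.index.duplicated().any():
            raise ValueError(f"{name} has duplicate gene ids")

    def by_symbol(s: pd.Series) -> dict[str, str]:
        table: dict[str, list[str]] = {}
        for gid, sym in s.items():
            if pd.isna(sym) or sym == "":
                continue
            table.setdefault(str(sym).lower(), []).append(gid)
        out = {}
        for sym, gids in table.items():
            if len(gids) > 1:
                warnings.warn(
                    f"symbol {sym!r} maps to multiple genes; keeping first of {sorted(gids)}"
                )
            out[sym] = min(gids)
        return out

    t1, t2 = by_symbol(symbols1), by_symbol(symbols2)
    pairs = [
        (t1[sym], t2[sym], "symbol") for sym in sorted(set(t1) & set(t2))
    ]
    used1 = {p[0] for p in pairs}
    used2 = {p[1] for p in pairs}
    if unit_map is not None and len(unit_map):
        for _, row in unit_map.sort_values("unit_id").iterrows():
            g1, g2 = row["gene_id_species1"], row["gene_id_species2"]
            if g1 in used1 or g2 in used2:
                continue
            if g1 not in symbols1.index or g2 not in symbols2.index:
                continue
            pairs.append((g1, g2, "orthologous_unit"))
            used1.add(g1)
            used2.add(g2)
    return pd.DataFrame(
        pairs, columns=["gene_id_species1", "gene_id_species2", "match_type"]
    )


def conserved_dynamics(
    assignments1: pd.DataFrame,
    assignments2: pd.DataFrame,
    pairs: pd.DataFrame,
    abundance1: pd.DataFrame | None = None,
    abundance2: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Ortholog pairs with matching pooled temporal (and abundance) labels.

    ``assignments1``/``assignments2`` are temporal-group tables (columns
    gene_id, group).  Returns one pair table per pooled set; with
    abundance tables supplied, also "degraded" and "de_novo" sets.
    The result is symmetric in the two species.
    """
    g1 = assignments1.set_index("gene_id")["group"]
    g2 = assignments2.set_index("gene_id")["group"]
    out: dict[str, pd.DataFrame] = {}
    for pool, members in CONSERVED_POOLS.items():
        rows = [
            (a, b)
            for a, b in zip(pairs["gene_id_species1"], pairs["gene_id_species2"])
            if g1.get(a) in members and g2.get(b) in members
        ]
        out[pool] = pd.DataFrame(rows, columns=["gene_id_species1", "gene_id_species2"])
    if abundance1 is not None and abundance2 is not None:
        d1 = abundance1.set_index("gene_id")["dynamics"]
        d2 = abundance2.set_index("gene_id")["dynamics"]
        for label in ("degraded", "de_novo"):
            rows = [
                (a, b)
                for a, b in zip(pairs["gene_id_species1"], pairs["gene_id_species2"])
                if d1.get(a) == label and d2.get(b) == label
            ]
            out[label] = pd.DataFrame(
                rows, columns=["gene_id_species1", "gene_id_species2"]
            )
    return out


def zscore_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-scores (population standard deviation).

    Standardizes each row (a gene's per-stage section percentages) to mean
    0 and sd 1; zero-variance rows become all zeros with a warning.
    """
    x = values.to_numpy(float)
    if x.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 values per row")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population (n) denominator
    degenerate = (sd == 0).ravel()
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance rows z-scored to zeros")
    sd[sd == 0] = 1.0
    return pd.DataFrame((x - mean) / sd, index=values.index, columns=values.columns)
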