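"""Negative-binomial GLM likelihood-ratio tests for differential localization.

Each gene is modeled with a log-link negative-binomial regression on the
sample annotations (section position, oocyte stage, replicate), with the
log size factor as offset and a per-gene dispersion shared between the
nested full and reduced fits.  Four named designs cover the questions the
pipeline asks:

  within_stage           ~replicate + position      vs  ~replicate
  profile_across_stages  ~Size + position
                          + Size:position           vs  ~Size + position
  magnitude_across_stages ~Size + position          vs  ~Size
  total_between_stages   ~Size                      vs  ~1   (per-oocyte
                          summed normalized counts as input, offset 0)

A differentially localized transcript (DLT) is a gene with adjusted
p-value below 0.1 and more than 20 transcripts per oocyte.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.stats.multitest import multipletests

from .normalize import normalize, size_factors
from .simulate import SECTIONS, SectionCountMatrix

MIN_DISPERSION = 1e-8
MAX_DISPERSION = 10.0


@dataclass(frozen=True)
class DesignSpec:
    """A nested full/reduced model pair over the annotation factors."""

    name: str
    full_terms: tuple[str, ...]
    reduced_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not set(self.reduced_terms) <= set(self.full_terms):
            raise ValueError("reduced terms must be a subset of full terms")

    @property
    def tested_terms(self) -> tuple[str, ...]:
        return tuple(t for t in self.full_terms if t not in self.reduced_terms)


DESIGNS: dict[str, DesignSpec] = {
    "within_stage": DesignSpec(
        "within_stage", ("intercept", "replicate", "position"), ("intercept", "replicate")
    ),
    "profile_across_stages": DesignSpec(
        "profile_across_stages",
        ("intercept", "Size", "position", "Size:position"),
        ("intercept", "Size", "position"),
    ),
    "magnitude_across_stages": DesignSpec(
        "magnitude_across_stages", ("intercept", "Size", "position"), ("intercept", "Size")
    ),
    "total_between_stages": DesignSpec(
        "total_between_stages", ("intercept", "Size"), ("intercept",)
    ),
}


@dataclass
class GeneFitResult:
    """One fitted NB GLM for one gene."""

    gene_id: str
    log_likelihood: float
    coefficients: dict[str, float]
    dispersion: float
    converged: bool
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return len(self.coefficients)


def _factor_columns(
    samples: pd.DataFrame, factor: str, stage_order: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded indicator columns (reference level dropped)."""
    if factor == "position":
        values = samples["section"]
        levels = [s for s in SECTIONS if s in set(values)]
    elif factor == "Size":
        values = samples["stage"]
        levels = [s for s in stage_order if s in set(values)]
    elif factor == "replicate":
        values = samples["replicate"]
        levels = sorted(set(values))
    else:
        raise ValueError(f"unknown design factor: {factor!r}")
    cols = [(values == lev).to_numpy(float) for lev in levels[1:]]
    names = [f"{factor}[{lev}]" for lev in levels[1:]]
    return (np.column_stack(cols) if cols else np.empty((len(samples), 0)), names)


def build_design_matrix(
    samples: pd.DataFrame,
    terms: tuple[str, ...],
    stage_order: list[str],
    tested_terms: tuple[str, ...] = (),
) -> tuple[np.ndarray, list[str]]:
    """Numeric treatment-coded design matrix for the given terms.

    Position levels are ordered A..E and stages follow ``stage_order``, the
    first present level of each being the reference.  Interaction columns
    are elementwise products of the main-effect indicators.  A factor that
    appears among ``tested_terms`` but has fewer than two levels raises;
    aliased (linearly dependent) columns are dropped with a warning.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    if "intercept" in terms:
        blocks.append(np.ones((len(samples), 1)))
        names.append("intercept")
    main: dict[str, tuple[np.ndarray, list[str]]] = {}
    for term in terms:
        if term in ("intercept", "Size:position"):
            continue
        cols, colnames = _factor_columns(samples, term, stage_order)
        main[term] = (cols, colnames)
        if term in tested_terms and cols.shape[1] == 0:
            raise ValueError(f"tested factor {term!r} has a single level")
        blocks.append(cols)
        names.extend(colnames)
    if "Size:position" in terms:
        sz, sz_names = main.get("Size") or _factor_columns(samples, "Size", stage_order)
        po, po_names = main.get("position") or _factor_columns(
            samples, "position", stage_order
        )
        if "Size:position" in tested_terms and (sz.shape[1] == 0 or po.shape[1] == 0):
            raise ValueError("tested factor 'Size:position' has a single level")
        for i, sn in enumerate(sz_names):
            for j, pn in enumerate(po_names):
                blocks.append((sz[:, i] * po[:, j])[:, None])
                names.append(f"{sn}:{pn}")
    X = np.hstack(blocks)
    # drop aliased columns (rank-revealing pivoted QR)
    if X.shape[1] > 1:
        _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        rank = int((diag > diag[0] * 1e-10).sum()) if diag.size else 0
        if rank < X.shape[1]:
            keep = np.sort(piv[:rank])
            dropped = [names[i] for i in sorted(set(range(X.shape[1])) - set(keep))]
            warnings.warn(f"dropping aliased design columns: {dropped}")
            X = X[:, keep]
            names = [names[i] for i in keep]
    return X, names


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Iteratively reweighted least squares for a log-link NB GLM.

    Returns (coefficients, fitted means, converged); convergence is a max
    coefficient change below ``tol``.
    """
    mu = np.maximum(y, 0.5)
    eta = np.log(mu) - offset
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(maxiter):
        mu = np.exp(np.clip(eta + offset, -30, 30))
        w = mu / (1.0 + alpha * mu)
        z = eta + (y - mu) / mu
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
        eta = X @ beta
    mu = np.exp(np.clip(X @ beta + offset, -30, 30))
    return beta, mu, converged


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    r = 1.0 / max(alpha, MIN_DISPERSION)
    return float(stats.nbinom.logpmf(y, r, r / (r + mu)).sum())


def estimate_dispersion(
    y: np.ndarray, X: np.ndarray, size_factors: np.ndarray
) -> float:
    """Per-gene NB dispersion by equating the Pearson statistic to its df.

    Fits a Poisson GLM (the zero-dispersion limit), then solves
    ``sum((y-mu)^2 / (mu + a*mu^2)) = n - p`` for the dispersion ``a`` —
    a method-of-moments estimate whose degrees-of-freedom correction keeps
    the downstream tests calibrated.  Clipped to [1e-8, 10].
    """
    y = np.asarray(y, float)
    n, p = X.shape
    if n - p < 1:
        raise ValueError("dispersion estimation needs >= 1 residual df")
    offset = np.log(size_factors)
    _, mu, _ = _irls(y, X, offset, 0.0)
    if np.all(mu < 1e-10):
        warnings.warn("all fitted means ~0; dispersion floored")
        return MIN_DISPERSION
    mu = np.maximum(mu, 1e-10)

    def pearson_gap(a: float) -> float:
        return float(np.sum((y - mu) ** 2 / (mu + a * mu**2)) - (n - p))

    if pearson_gap(MIN_DISPERSION) <= 0:
        return MIN_DISPERSION
    if pearson_gap(MAX_DISPERSION) >= 0:
        return MAX_DISPERSION
    return float(optimize.brentq(pearson_gap, MIN_DISPERSION, MAX_DISPERSION, xtol=1e-12))


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    size_factors: np.ndarray,
    alpha: float,
    column_names: list[str] | None = None,
    gene_id: str = "",
) -> GeneFitResult:
    """Fit a log-link NB(alpha) regression with log size-factor offset."""
    y = np.asarray(y, float)
    alpha = float(np.clip(alpha, MIN_DISPERSION, MAX_DISPERSION))
    offset = np.log(np.asarray(size_factors, float))
    beta, mu, converged = _irls(y, X, offset, alpha)
    ll = _nb_loglik(y, mu, alpha) if converged else float("nan")
    names = column_names or [f"b{i}" for i in range(X.shape[1])]
    return GeneFitResult(
        gene_id=gene_id,
        log_likelihood=ll,
        coefficients=dict(zip(names, beta)),
        dispersion=alpha,
        converged=bool(converged),
        fitted=mu,
    )


def lrt(full: GeneFitResult, reduced: GeneFitResult) -> tuple[float, float]:
    """Likelihood-ratio test of nested fits: chi-square upper-tail p-value."""
    if not (full.converged and reduced.converged):
        raise ValueError("both fits must have converged")
    if full.dispersion != reduced.dispersion:
        raise ValueError("full and reduced fits must share the dispersion")
    df = full.n_params - reduced.n_params
    if df < 1:
        raise ValueError("LRT needs >= 1 df (full model must be larger)")
    stat = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    return stat, float(stats.chi2.sf(stat, df))


def _oocyte_totals(
    normalized: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-oocyte summed normalized counts and the oocyte-level annotation."""
    key = samples[["species", "stage", "replicate"]].agg("|".join, axis=1)
    normalized = normalized.loc[:, samples.index]
    totals = normalized.T.groupby(key.values, sort=False).sum().T
    ann = (
        samples.assign(_k=key.values)
        .drop_duplicates("_k")
        .set_index("_k")[["species", "stage", "replicate"]]
    )
    ann = ann.loc[totals.columns]
    ann.index.name = "oocyte_id"
    return totals, ann


def detect_dlts(
    scm: SectionCountMatrix,
    design: str = "within_stage",
    stage: str | None = None,
    padj_threshold: float = 0.1,
    count_threshold: float = 20.0,
    p_reference: str = "f",
    precomputed_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Run one design's LRT over all genes and call DLTs.

    Size factors are estimated on the full matrix; the ``within_stage``
    design is then tested on the given stage's samples only, the cross-
    stage designs on all samples, and ``total_between_stages`` on the
    per-oocyte summed normalized counts (rounded, offset 0).  Genes that
    are all-zero in the tested samples are skipped; p-values are adjusted
    with Benjamini-Hochberg across the tested genes.  ``total_count`` is
    the mean per-oocyte normalized transcript amount (for cross-stage
    designs, the maximum of the per-stage means, i.e. the best stage), and
    ``is_dlt`` requires padj < ``padj_threshold`` and
    total_count > ``count_threshold``.

    ``p_reference``: "f" (default) refers the statistic to an
    F(df, n - p_full) distribution, which stays calibrated when the
    per-gene dispersion is itself estimated; "chisq" uses the asymptotic
    chi-square reference.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design: {design!r}")
    if p_reference not in ("f", "chisq"):
        raise ValueError("p_reference must be 'f' or 'chisq'")
    spec = DESIGNS[design]
    factors = size_factors(scm.counts) if precomputed_factors is None else precomputed_factors
    norm = normalize(scm.counts, factors)

    if design == "within_stage":
        if stage is None:
            raise ValueError("within_stage requires a stage")
        mask = scm.samples["stage"] == stage
        if not mask.any():
            raise ValueError(f"no samples at stage {stage!r}")
        samples = scm.samples[mask]
        Y = scm.counts.loc[:, samples.index]
        offs_factors = factors[samples.index].to_numpy()
        totals_scope = samples
    elif design == "total_between_stages":
        totals, ann = _oocyte_totals(norm, scm.samples)
        samples = ann
        Y = totals.round().astype(int)
        offs_factors = np.ones(len(ann))
        totals_scope = scm.samples
    else:
        samples = scm.samples
        Y = scm.counts
        offs_factors = factors.to_numpy()
        totals_scope = scm.samples

    if len(set(samples["stage"])) < 2 and "Size" in spec.tested_terms:
        raise ValueError(f"design {design!r} needs >= 2 stages")
    for term in spec.tested_terms:
        if term == "Size:position":
            continue
        col = {"position": "section", "Size": "stage", "replicate": "replicate"}[term]
        if samples[col].nunique() < 2:
            raise ValueError(f"tested factor {term!r} has a single level")

    Xf, names_f = build_design_matrix(
        samples, spec.full_terms, scm.stage_order, spec.tested_terms
    )
    Xr, names_r = build_design_matrix(samples, spec.reduced_terms, scm.stage_order)
    df_test = Xf.shape[1] - Xr.shape[1]
    if df_test < 1:
        raise ValueError("full model is not larger than reduced after aliasing")
    n, p_full = Xf.shape

    Ynp = Y.to_numpy(float)
    nonzero = Ynp.sum(axis=1) > 0
    n_skipped = int((~nonzero).sum())
    if n_skipped:
        warnings.warn(f"skipping {n_skipped} genes with all-zero counts")

    # per-oocyte normalized totals for the count threshold
    oo_totals, oo_ann = _oocyte_totals(norm, totals_scope)
    if design == "within_stage":
        total_count = oo_totals.mean(axis=1)
    else:
        total_count = (
            oo_totals.T.groupby(oo_ann["stage"].values, sort=False).mean().T.max(axis=1)
        )

    rows = []
    n_nonconv = 0
    for gene, y in zip(Y.index[nonzero], Ynp[nonzero]):
        alpha = estimate_dispersion(y, Xf, offs_factors)
        full = fit_nb_glm(y, Xf, offs_factors, alpha, names_f, gene)
        red = fit_nb_glm(y, Xr, offs_factors, alpha, names_r, gene)
        if not (full.converged and red.converged):
            n_nonconv += 1
            rows.append((gene, np.nan, np.nan, alpha, False))
            continue
        stat = max(0.0, 2.0 * (full.log_likelihood - red.log_likelihood))
        if p_reference == "f" and n > p_full:
            p = float(stats.f.sf(stat / df_test, df_test, n - p_full))
        else:
            p = float(stats.chi2.sf(stat, df_test))
        rows.append((gene, stat, p, alpha, True))
    if n_nonconv:
        warnings.warn(f"{n_nonconv} genes did not converge; excluded from testing")

    res = pd.DataFrame(
        rows, columns=["gene_id", "lrt_statistic", "p_value", "dispersion", "converged"]
    ).set_index("gene_id")
    res.insert(0, "design", design)
    if design == "within_stage":
        res.insert(1, "stage", stage)
    res["df"] = df_test
    res["padj"] = np.nan
    tested = res["p_value"].notna()
    if tested.any():
        res.loc[tested, "padj"] = multipletests(
            res.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    res["total_count"] = total_count.reindex(res.index)
    res["is_dlt"] = (res["padj"] < padj_threshold) & (res["total_count"] > count_threshold)
    return res.reset_index()
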