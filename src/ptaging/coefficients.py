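"""Core coupling statistics between molecular layers.

The protein-to-mRNA (p/m) coefficient is the per-gene, per-animal ratio of
percentile-ranked protein abundance to percentile-ranked mRNA abundance; high
values mean efficient protein output per mRNA unit. The nuclear-to-total
(n/t) coupling is the analogous ratio for the nuclear vs total mRNA
fractions, and the aggregation index is SDS-insoluble protein normalized by
total protein. Each coefficient is standardized per gene across all ages and
replicates (cross-age Z-score); the breadth of the per-age Z distribution
(FWHM of a kernel density estimate, median |Z|) quantifies how tightly the
two layers are coupled at that age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, spearmanr

from .preprocess import percentile_rank
from .types import CoefficientTable, DistributionStats, OmicsMatrix


def _matched_animals(a: OmicsMatrix, b: OmicsMatrix) -> pd.DataFrame:
    """Animals measured exactly once in each layer, with their age.

    Animals present in only one layer are dropped (with a warning); an animal
    measured twice in one layer is an unmatched design and is rejected.
    """
    rows = {}
    for m, tag in ((a, "a"), (b, "b")):
        for s in m.samples:
            key = (s.animal_id, tag)
            if key in rows:
                raise ValueError(
                    f"animal {s.animal_id!r} has multiple samples in one layer; "
                    "matched-design ratios require one sample per animal per layer"
                )
            rows[key] = s
    animals_a = {k[0] for k in rows if k[1] == "a"}
    animals_b = {k[0] for k in rows if k[1] == "b"}
    common = animals_a & animals_b
    dropped = (animals_a | animals_b) - common
    if dropped:
        warnings.warn(f"dropping unmatched animal(s): {sorted(dropped)}", stacklevel=3)
    if not common:
        raise ValueError("no animals matched between layers")
    meta = {}
    for an in common:
        age_a = rows[(an, "a")].age_months
        age_b = rows[(an, "b")].age_months
        if age_a != age_b:
            raise ValueError(f"animal {an!r} has inconsistent ages across layers")
        meta[an] = age_a
    animals = sorted(common)
    return pd.DataFrame({"age_months": [meta[an] for an in animals]},
                        index=pd.Index(animals, name="animal_id"))


def zscore_frame(x: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each row by its own mean and sample sd (ddof=1) over all
    columns. Rows with zero sd map to all-zero Z and are flagged."""
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    constant = list(x.index[(sd == 0) | sd.isna()])
    safe_sd = sd.replace(0, np.nan)
    z = x.sub(mu, axis=0).div(safe_sd, axis=0)
    if constant:
        z.loc[constant] = 0.0
    return z, constant


def zscore_across_ages(t: CoefficientTable) -> CoefficientTable:
    """(Re)compute cross-age Z-scores: z = (x - mu_g) / sigma_g with the mean
    and sd taken over all of the gene's ages and replicates."""
    if t.ratio.shape[1] < 2:
        raise ValueError("need >=2 matched samples per gene to standardize")
    z, constant = zscore_frame(t.ratio)
    return CoefficientTable(t.kind, t.ratio, z, t.meta, constant)


def compute_ratio_coefficient(
    numerator: OmicsMatrix,
    denominator: OmicsMatrix,
    kind: str,
    renormalize: bool = True,
) -> CoefficientTable:
    """Form per-gene per-animal ratios between two matched layers.

    For ``pm`` and ``nt`` the inputs are expected percentile-ranked, so the
    raw ratio is a rank ratio (denominator never zero by construction); the
    ratio matrix is then re-ranked column-wise (the renormalization step)
    unless ``renormalize=False``. For ``aggregation`` the inputs are
    row-median-normalized abundances and the ratio is used as-is (abundance
    ratio semantics). Cross-age Z-scores are attached in all cases.
    """
    if kind not in ("pm", "nt", "aggregation"):
        raise ValueError(f"unknown coefficient kind {kind!r}")
    meta = _matched_animals(numerator, denominator)
    genes = numerator.values.index.intersection(denominator.values.index)
    if genes.empty:
        raise ValueError("no genes shared between the two layers")

    def by_animal(m: OmicsMatrix) -> pd.DataFrame:
        cols = {s.animal_id: m.values.loc[genes, s.sample_id]
                for s in m.samples if s.animal_id in meta.index}
        return pd.DataFrame(cols)[meta.index]

    num = by_animal(numerator)
    den = by_animal(denominator)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    if kind == "aggregation":
        renormalize = False
    if renormalize:
        ranked = percentile_rank(OmicsMatrix(ratio, _meta_to_samples(meta, numerator)))
        ratio = ranked.values
    t = CoefficientTable(kind, ratio, ratio * np.nan, meta, [])
    return zscore_across_ages(t)


def _meta_to_samples(meta: pd.DataFrame, like: OmicsMatrix):
    from .types import SampleMeta

    layer = like.layer
    return [
        SampleMeta(sample_id=an, animal_id=an, age_months=int(age), layer=layer)
        for an, age in meta["age_months"].items()
    ]


# ---------------------------------------------------------------------------
# distribution shape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FwhmResult:
    fwhm: float
    peak_x: float
    n_crossings: int


def fwhm_of_values(x: np.ndarray, grid_points: int = 512) -> FwhmResult:
    """FWHM of a Gaussian KDE (Silverman bandwidth) of ``x``.

    The density is evaluated on a fixed grid spanning the data plus three
    bandwidths; the width is measured between the outermost crossings of half
    the peak density (linear interpolation between grid points). More than
    two crossings indicates multimodality; the outermost pair is still used.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need >=2 distinct finite values for a density estimate")
    kde = gaussian_kde(x, bw_method="silverman")
    bw = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_points)
    dens = kde(grid)
    half = dens.max() / 2.0
    above = dens >= half
    idx = np.flatnonzero(np.diff(above.astype(int)))
    crossings = []
    for i in idx:
        x0, x1 = grid[i], grid[i + 1]
        y0, y1 = dens[i], dens[i + 1]
        crossings.append(x0 + (half - y0) * (x1 - x0) / (y1 - y0))
    if len(crossings) < 2:  # half-max at grid edge; should not occur with 3-bw padding
        raise RuntimeError("could not bracket the half-maximum crossings")
    return FwhmResult(
        fwhm=float(crossings[-1] - crossings[0]),
        peak_x=float(grid[np.argmax(dens)]),
        n_crossings=len(crossings),
    )


def distribution_stats(t: CoefficientTable, age: int, which: str = "mean_z") -> DistributionStats:
    """Breadth of the coefficient Z distribution at one age: FWHM of the KDE
    over per-gene mean Z values (default) or per-gene-per-replicate Z values,
    plus the median absolute Z."""
    if age not in t.ages:
        raise ValueError(f"age {age} not present (have {t.ages})")
    if which == "mean_z":
        z = t.per_age_mean("z")[age].to_numpy()
    elif which == "replicate_z":
        z = t.z[t.animals_for_age(age)].to_numpy().ravel()
    else:
        raise ValueError(f"unknown reduction {which!r}")
    z = z[np.isfinite(z)]
    if z.size < 100:
        warnings.warn(f"only {z.size} genes at age {age}; FWHM may be unstable", stacklevel=2)
    res = fwhm_of_values(z)
    if res.n_crossings > 2:
        warnings.warn(
            f"age {age}: density crosses half-max {res.n_crossings} times "
            "(multimodal); reporting outermost crossings",
            stacklevel=2,
        )
    return DistributionStats(
        age_months=age,
        fwhm=res.fwhm,
        median_abs_z=float(np.median(np.abs(z))),
        n_genes=int(z.size),
        multimodal=res.n_crossings > 2,
    )


# ---------------------------------------------------------------------------
# inter-layer correlation and fold changes
# ---------------------------------------------------------------------------

def interlayer_correlation(a: OmicsMatrix, b: OmicsMatrix) -> pd.DataFrame:
    """Spearman rho between two layers over common genes, one value per
    matched animal. Returns columns animal_id, age_months, rho."""
    meta = _matched_animals(a, b)
    genes = a.values.index.intersection(b.values.index)
    if len(genes) < 3:
        raise ValueError(f"only {len(genes)} common genes; need >=3")
    col_a = {s.animal_id: s.sample_id for s in a.samples}
    col_b = {s.animal_id: s.sample_id for s in b.samples}
    rows = []
    for an, age in meta["age_months"].items():
        x = a.values.loc[genes, col_a[an]]
        y = b.values.loc[genes, col_b[an]]
        ok = x.notna() & y.notna()
        rho = spearmanr(x[ok], y[ok]).statistic
        rows.append({"animal_id": an, "age_months": int(age), "rho": float(rho)})
    return pd.DataFrame(rows)


def correlation_age_medians(corr: pd.DataFrame) -> pd.Series:
    """Median per-animal Spearman rho within each age."""
    return corr.groupby("age_months")["rho"].median()


def coefficient_logfc(t: CoefficientTable, age_b: int, age_a: int) -> pd.DataFrame:
    """Per-gene log2 fold change of the mean coefficient between two ages
    (``age_b`` over ``age_a``), with the percentile-ranked ordering used for
    ranked scatter displays."""
    for age in (age_b, age_a):
        if age not in t.ages:
            raise ValueError(f"age {age} not present (have {t.ages})")
    means = t.per_age_mean("ratio")
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(means[age_b] / means[age_a])
    from scipy.stats import rankdata

    ok = lfc.notna()
    rank = pd.Series(np.nan, index=lfc.index)
    rank[ok] = rankdata(lfc[ok], method="average") / ok.sum()
    return pd.DataFrame({"log2fc": lfc, "percentile": rank})


def trend_zscores(m: OmicsMatrix) -> CoefficientTable:
    """Cross-age Z-scores of column-median-corrected log2 abundances — the
    input to trend classification.

    Per-sample effects (library size, loading) are removed by subtracting
    each column's log2 median; each gene row is then standardized across all
    samples. Quantile normalization is deliberately not applied here: the
    trajectory-shape statistic is invariant to per-gene affine transforms, so
    distribution alignment adds nothing, while its rank mapping censors the
    trajectories of genes at the extremes of the abundance distribution."""
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.log2(m.values)
    vals = vals.replace([-np.inf, np.inf], np.nan)
    vals = vals - vals.median(axis=0)
    return abundance_zscores(m.with_values(vals), log_scale=False)


def abundance_zscores(m: OmicsMatrix, log_scale: bool = True) -> CoefficientTable:
    """Cross-age Z-scores of a single layer's (log2) normalized abundances,
    organised per animal."""
    meta = pd.DataFrame(
        {"age_months": [s.age_months for s in m.samples]},
        index=pd.Index([s.animal_id for s in m.samples], name="animal_id"),
    )
    if meta.index.duplicated().any():
        raise ValueError("multiple samples per animal in one layer")
    vals = m.values.copy()
    vals.columns = meta.index
    if log_scale:
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log2(vals)
        vals = vals.replace([-np.inf, np.inf], np.nan)
    t = CoefficientTable("abundance", vals, vals * np.nan, meta, [])
    return zscore_across_ages(t)
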