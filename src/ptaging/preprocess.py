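"""Filtering and normalization cascade applied per layer.

Default order mirrors the study design: valid-value filter -> contaminant
removal -> (count layers: low-count filter) -> quantile normalization ->
row-wise median normalization -> (for coefficients: percentile rank) ->
standard-error filter. The cascade is order-sensitive; every filter emits a
bookkeeping report.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import FilterReport, FilterStep, GeneSet, OmicsMatrix


def _report(name: str, before: OmicsMatrix, keep_mask: pd.Series) -> tuple[OmicsMatrix, FilterReport]:
    removed = list(before.values.index[~keep_mask])
    out = before.with_values(before.values.loc[keep_mask])
    rep = FilterReport(
        [FilterStep(name, before.values.shape[0], out.values.shape[0], removed)]
    )
    return out, rep


def filter_valid_values(m: OmicsMatrix, min_frac: float = 0.5) -> tuple[OmicsMatrix, FilterReport]:
    """Keep genes with >= ``min_frac`` non-missing replicate values in every
    age group (boundary inclusive). Intended for intensity (protein) layers,
    where missing cells carry MaxQuant not-quantified semantics."""
    if not 0 < min_frac <= 1:
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    for age, n in m.replicates_per_age().items():
        if n == 0:
            raise ValueError(f"no samples at age {age}")
    keep = pd.Series(True, index=m.values.index)
    for age in m.ages:
        cols = m.columns_for_age(age)
        frac = m.values[cols].notna().sum(axis=1) / len(cols)
        keep &= frac >= min_frac
    return _report(f"valid_values(min_frac={min_frac})", m, keep)


def remove_contaminants(m: OmicsMatrix, contaminants: GeneSet | None = None) -> tuple[OmicsMatrix, FilterReport]:
    """Remove listed contaminant genes and any gene flagged '+' in a
    recognised annotation column (Reverse / Potential Contaminant /
    Only Identified by Site). An empty intersection is allowed."""
    drop = set()
    if contaminants is not None:
        drop |= contaminants.intersect(m.values.index)
    if m.flags is not None:
        flagged = (m.flags == "+").any(axis=1)
        drop |= set(m.flags.index[flagged])
    keep = ~m.values.index.isin(drop)
    return _report("contaminants", m, pd.Series(keep, index=m.values.index))


def filter_low_counts(m: OmicsMatrix, min_count: int = 5) -> tuple[OmicsMatrix, FilterReport]:
    """Remove genes whose total read count over all samples is <= ``min_count``
    (inclusive removal: a gene summing to exactly ``min_count`` is dropped)."""
    vals = m.values
    if not np.allclose(vals.fillna(0) % 1, 0):
        warnings.warn("non-integer values in count layer; truncating for the count filter", stacklevel=2)
        vals = np.floor(vals)
    totals = vals.sum(axis=1, skipna=True)
    keep = totals > min_count
    return _report(f"low_counts(total<={min_count})", m, keep)


def quantile_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Force every sample onto a common distribution: the per-rank mean of the
    samples' sorted values. Ties within a sample receive the average of their
    tied ranks' reference values. Missing cells are excluded from rank
    computation and stay missing."""
    vals = m.values
    n_genes, n_samples = vals.shape
    if n_samples < 2:
        warnings.warn("quantile normalization of a single sample is a no-op", stacklevel=2)
        return m.with_values(vals.copy())
    # Reference distribution: mean across samples of each sample's empirical
    # quantile function on a common grid of n_genes points.
    grid = np.linspace(0.0, 1.0, n_genes)
    ref = np.zeros(n_genes)
    for col in vals.columns:
        x = vals[col].dropna().to_numpy()
        if x.size == 0:
            raise ValueError(f"sample {col} has no finite values")
        ref += np.quantile(np.sort(x), grid)
    ref /= n_samples

    out = vals.copy()
    for col in vals.columns:
        x = vals[col]
        ok = x.notna().to_numpy()
        xi = x.to_numpy()[ok]
        mref = ref if xi.size == n_genes else np.interp(
            np.linspace(0.0, 1.0, xi.size), grid, ref
        )
        order = rankdata(xi, method="ordinal") - 1
        mapped = mref[order]
        # ties: average of the tied ranks' reference values
        avg = pd.Series(mapped).groupby(pd.Series(xi)).transform("mean").to_numpy()
        col_out = np.full(n_genes, np.nan)
        col_out[ok] = avg
        out[col] = col_out
    return m.with_values(out)


def median_center_rows(m: OmicsMatrix, mode: str = "divisive") -> OmicsMatrix:
    """Row-wise median normalization. ``divisive`` (abundance scale): each
    gene row is divided by its median, so the output row median is 1.
    ``subtractive`` (log scale): the row median is subtracted (median 0)."""
    med = m.values.median(axis=1, skipna=True)
    if med.isna().any():
        bad = m.values.index[med.isna()].tolist()
        raise ValueError(f"all-missing row(s): {bad[:5]}")
    if mode == "divisive":
        if (med == 0).any():
            raise ValueError("zero row median; cannot divide")
        out = m.values.div(med, axis=0)
    elif mode == "subtractive":
        out = m.values.sub(med, axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return m.with_values(out)


def percentile_rank(m: OmicsMatrix) -> OmicsMatrix:
    """Column-wise percentile rank normalization: value -> rank/n with average
    ranks for ties, computed over the column's non-missing cells. Output lies
    in (0, 1] and is invariant under monotone transforms of a column."""
    out = m.values.copy()
    for col in m.values.columns:
        x = m.values[col]
        ok = x.notna().to_numpy()
        xi = x.to_numpy()[ok]
        if xi.size and np.all(xi == xi[0]):
            warnings.warn(f"sample {col}: all values identical; ranks collapse to the midpoint", stacklevel=2)
        ranks = rankdata(xi, method="average") / xi.size
        col_out = np.full(x.size, np.nan)
        col_out[ok] = ranks
        out[col] = col_out
    return m.with_values(out)


def filter_stderr(
    m: OmicsMatrix,
    threshold: float,
    scope: str = "per_age",
    log_scale: bool = True,
) -> tuple[OmicsMatrix, FilterReport]:
    """Keep genes whose replicate standard error is strictly below
    ``threshold``. Default scope computes the SE within every age group on the
    log2 of the normalized values and requires all ages to pass; ``pooled``
    uses one SE over all samples."""
    m.check_min_replicates(2)
    if log_scale:
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log2(m.values)
        vals = vals.replace([-np.inf, np.inf], np.nan)
    else:
        vals = m.values

    def se(df: pd.DataFrame) -> pd.Series:
        n = df.notna().sum(axis=1)
        return df.std(axis=1, ddof=1) / np.sqrt(n)

    if scope == "per_age":
        keep = pd.Series(True, index=vals.index)
        for age in m.ages:
            keep &= se(vals[m.columns_for_age(age)]) < threshold
    elif scope == "pooled":
        keep = se(vals) < threshold
    else:
        raise ValueError(f"unknown scope {scope!r}")
    keep = keep.fillna(False)
    return _report(f"stderr(<{threshold},{scope})", m, keep)


def preprocess_layer(
    m: OmicsMatrix,
    contaminants: GeneSet | None = None,
    min_valid_frac: float = 0.5,
    min_count: int = 5,
    stderr_threshold: float | None = None,
    stderr_scope: str = "per_age",
) -> tuple[OmicsMatrix, FilterReport]:
    """Run the full per-layer cascade in the canonical order and return the
    normalized matrix (abundance scale, row median 1) plus the filter audit.

    Count layers skip the valid-value rule (counts have no missing cells) and
    apply the low-count rule; intensity layers do the reverse. The stderr
    filter runs last, on the normalized values, when a threshold is given
    (conventionally 0.12 for mRNA and 0.4 for protein layers)."""
    report = FilterReport()
    if m.layer.is_count:
        m, rep = remove_contaminants(m, contaminants)
        report.extend(rep)
        m, rep = filter_low_counts(m, min_count)
        report.extend(rep)
    else:
        m, rep = filter_valid_values(m, min_valid_frac)
        report.extend(rep)
        m, rep = remove_contaminants(m, contaminants)
        report.extend(rep)
    m = quantile_normalize(m)
    med = m.values.median(axis=1, skipna=True)
    if (med <= 0).any():
        # a zero median (possible for sparse count rows) cannot be divided out
        m, rep = _report("nonpositive_median", m, med > 0)
        report.extend(rep)
    m = median_center_rows(m, mode="divisive")
    if stderr_threshold is not None:
        m, rep = filter_stderr(m, stderr_threshold, scope=stderr_scope)
        report.extend(rep)
    return m, report
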