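"""Gene-set group comparisons, percentile grouping, and pipeline orchestration.

Group comparisons treat genes as the pairing unit: each gene contributes one
per-age summary value (mean Z within the age), pairs of ages are compared
with a paired t-test, and the family of the three pairwise contrasts is
corrected with a Tukey studentized-range adjustment (p_adj = P(Q_{k,df} >=
|t|*sqrt(2))), which reduces to the raw paired t at k = 2 and always
satisfies p_adj >= p_raw. By default each gene's per-age values are centered
by the per-age mean over all genes in the table, so a set's comparison
measures its deviation from the transcriptome-wide behaviour rather than any
global shift.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as pio
from .biochem import build_feature_table, correlate_features
from .coefficients import (
    abundance_zscores,
    trend_zscores,
    coefficient_logfc,
    compute_ratio_coefficient,
    correlation_age_medians,
    distribution_stats,
    interlayer_correlation,
)
from .preprocess import filter_low_counts, percentile_rank, preprocess_layer
from .synthetic import SyntheticConfig, default_config, generate_cohort
from .types import CoefficientTable, GeneSet, Layer, OmicsMatrix

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p <= thr:
            return stars
    return "ns"


@dataclass
class PairResult:
    age_a: int
    age_b: int
    mean_diff: float   # mean over genes of (value at age_b - value at age_a)
    t: float
    df: int
    p_raw: float
    p_adj: float
    stars: str
    degenerate: bool = False


@dataclass
class GroupComparison:
    gene_set: str
    n_genes: int
    ages: list[int]
    per_age_means: pd.DataFrame  # genes x ages summary values used
    pairs: list[PairResult] = field(default_factory=list)

    def pair(self, age_b: int, age_a: int) -> PairResult:
        for p in self.pairs:
            if (p.age_b, p.age_a) == (age_b, age_a):
                return p
        raise KeyError(f"no comparison {age_b} vs {age_a}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_set": self.gene_set,
                "age_a": [p.age_a for p in self.pairs],
                "age_b": [p.age_b for p in self.pairs],
                "mean_diff": [p.mean_diff for p in self.pairs],
                "t": [p.t for p in self.pairs],
                "df": [p.df for p in self.pairs],
                "p_raw": [p.p_raw for p in self.pairs],
                "p_adj": [p.p_adj for p in self.pairs],
                "stars": [p.stars for p in self.pairs],
                "degenerate": [p.degenerate for p in self.pairs],
            }
        )


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Paired t-test of y vs x: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1."""
    d = np.asarray(y, float) - np.asarray(x, float)
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero-variance differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def tukey_adjust(t: float, df: int, k_groups: int) -> float:
    """Tukey studentized-range family adjustment of a pairwise t statistic:
    p_adj = P(Q_{k,df} >= |t| * sqrt(2))."""
    q = abs(t) * np.sqrt(2.0)
    return float(stats.studentized_range.sf(q, k_groups, df))


def compare_gene_set_across_ages(
    t: CoefficientTable,
    s: GeneSet,
    value: str = "z",
    center: str = "global_mean",
) -> GroupComparison:
    """Compare a gene set's coefficient across the ages.

    Each member gene contributes its per-age mean value (Z by default); all
    age pairs are tested with a paired t-test and Tukey-adjusted across the
    age family. ``center='global_mean'`` (default) subtracts the per-age
    mean over *all* genes in the table first, isolating set-specific shifts
    from transcriptome-wide ones (the mean, not the median, keeps a random
    set's paired differences centered on zero under skewed Z distributions);
    'global_median' and 'none' are alternatives.
    """
    ages = t.ages
    if len(ages) < 2:
        raise ValueError("need >=2 ages")
    per_age = t.per_age_mean("z" if value == "z" else "ratio")
    if center == "global_mean":
        per_age = per_age - per_age.mean(axis=0)
    elif center == "global_median":
        per_age = per_age - per_age.median(axis=0)
    elif center != "none":
        raise ValueError(f"unknown centering {center!r}")
    members = sorted(s.intersect(per_age.index))
    if len(members) < 3:
        raise ValueError(f"gene set {s.name!r}: only {len(members)} genes present; need >=3")
    vals = per_age.loc[members].dropna()
    comp = GroupComparison(s.name, len(vals), list(ages), vals)
    k = len(ages)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = ages[i], ages[j]
            x, y = vals[a].to_numpy(), vals[b].to_numpy()
            try:
                tstat, df, p_raw = paired_t(x, y)
            except ZeroDivisionError:
                comp.pairs.append(
                    PairResult(a, b, float(np.mean(y - x)), np.nan, len(x) - 1,
                               np.nan, np.nan, "degenerate", degenerate=True)
                )
                continue
            p_adj = tukey_adjust(tstat, df, k)
            comp.pairs.append(
                PairResult(a, b, float(np.mean(y - x)), tstat, df, p_raw, p_adj,
                           significance_stars(p_adj))
            )
    return comp


# ---------------------------------------------------------------------------
# percentile grouping
# ---------------------------------------------------------------------------

def bin_by_percentile(values: pd.Series, cuts: tuple[float, float] = (1 / 3, 2 / 3)) -> pd.Series:
    """Label genes low/medium/high by percentile rank of a statistic with the
    edge semantics low [0, cuts0), medium [cuts0, cuts1], high (cuts1, 1].

    Ranks are span-normalized to [0, 1] (minimum 0, maximum 1, average ranks
    for ties), so default cuts at thirds give balanced bins."""
    v = values.dropna()
    if len(v) < 3:
        raise ValueError("need >=3 genes")
    rank = pd.Series(
        (stats.rankdata(v, method="average") - 1) / (len(v) - 1), index=v.index
    )
    labels = pd.Series("medium", index=v.index)
    labels[rank < cuts[0]] = "low"
    labels[rank > cuts[1]] = "high"
    return labels.reindex(values.index)


def classify_hlm(logfc: pd.Series, lower_q: float = 1 / 3, upper_q: float = 2 / 3) -> pd.Series:
    """Tertile grouping of a log2 fold change into H (increased), L
    (decreased) and M (unchanged). Quantile cut-offs are the default; the
    thresholds used are attached as Series attrs."""
    v = logfc.dropna()
    if len(v) < 3:
        raise ValueError("need >=3 genes")
    lo, hi = v.quantile(lower_q), v.quantile(upper_q)
    labels = pd.Series("M", index=v.index)
    if lo == hi:
        warnings.warn("degenerate fold-change distribution; all genes labelled M", stacklevel=2)
    else:
        labels[v < lo] = "L"
        labels[v > hi] = "H"
    out = labels.reindex(logfc.index)
    out.attrs["cutoffs"] = (float(lo), float(hi))
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict

    def table(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.out_dir / "tables" / f"{name}.tsv", sep="\t", index_col=0)


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _coefficient_stack(
    normalized: dict[Layer, OmicsMatrix],
    counts_raw: dict[Layer, OmicsMatrix],
    nt_min_count: int = 5,
) -> dict[str, CoefficientTable]:
    """Build the three coefficient tables from preprocessed layers."""
    ranked = {lay: percentile_rank(m) for lay, m in normalized.items()}
    out: dict[str, CoefficientTable] = {}
    out["pm"] = compute_ratio_coefficient(
        ranked[Layer.PROTEIN_TOTAL], ranked[Layer.MRNA_TOTAL], "pm"
    )
    # n/t: genes passing the total-layer filters AND a minimum nuclear count
    nuc_kept, _ = filter_low_counts(counts_raw[Layer.MRNA_NUCLEAR], nt_min_count)
    nuc = ranked[Layer.MRNA_NUCLEAR].subset_genes(
        set(nuc_kept.genes) & set(ranked[Layer.MRNA_TOTAL].genes)
    )
    out["nt"] = compute_ratio_coefficient(nuc, ranked[Layer.MRNA_TOTAL], "nt")
    out["aggregation"] = compute_ratio_coefficient(
        normalized[Layer.PROTEIN_INSOLUBLE], normalized[Layer.PROTEIN_TOTAL], "aggregation"
    )
    return out


DEFAULT_THRESHOLDS = {
    "min_valid_frac": 0.5,
    "min_count": 5,
    "stderr_mrna": 0.12,
    "stderr_protein": 0.4,
    "stderr_scope": "per_age",
}


def run_pipeline(
    config: dict | None = None,
    out_dir=None,
    seed: int | None = None,
    make_figures: bool = True,
) -> PipelineResult:
    """Execute the full analysis on a simulated (or on-disk) cohort.

    ``config`` keys: ``synthetic`` (SyntheticConfig overrides) or ``inputs``
    (paths: one TSV per layer plus sample_sheet/fasta/gene_sets/turnover),
    ``thresholds`` (filter settings), ``ages`` contrasts. Writes tables/,
    figures/, reports/ and a manifest.json with SHA-256 checksums of every
    output; identical config and seed give identical checksums.
    """
    config = dict(config or {})
    out = Path(out_dir or "ptaging_run")
    tables = out / "tables"
    figures = out / "figures"
    reports = out / "reports"
    for d in (tables, figures, reports):
        d.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}

    # ---- inputs ----------------------------------------------------------
    if "inputs" in config:
        paths = config["inputs"]
        missing = [k for k in
                   ("mrna_total", "mrna_nuclear", "protein_total", "protein_insoluble")
                   if k not in paths]
        if missing:
            raise ValueError(f"missing input layer(s): {missing}")
        raw = {
            lay: pio.read_matrix(paths[lay.value], paths["sample_sheet"])
            for lay in Layer
        }
        sequences = pio.read_fasta(paths["fasta"]) if "fasta" in paths else {}
        gene_sets = pio.read_gene_sets(paths["gene_sets"]) if "gene_sets" in paths else []
        turnover = pio.read_turnover_table(paths["turnover"]) if "turnover" in paths else None
        truth = None
    else:
        overrides = dict(config.get("synthetic", {}))
        if seed is not None:
            overrides["seed"] = seed
        cohort = generate_cohort(default_config(**overrides))
        raw = cohort.matrices
        sequences, gene_sets, turnover = cohort.sequences, cohort.gene_sets, cohort.turnover
        truth = cohort.truth
    contaminants = pio.default_contaminants()

    # ---- preprocess ------------------------------------------------------
    normalized: dict[Layer, OmicsMatrix] = {}
    for lay, m in raw.items():
        thr = thresholds["stderr_mrna"] if lay.is_count else thresholds["stderr_protein"]
        try:
            nm, rep = preprocess_layer(
                m,
                contaminants=contaminants,
                min_valid_frac=thresholds["min_valid_frac"],
                min_count=thresholds["min_count"],
                stderr_threshold=thr,
                stderr_scope=thresholds["stderr_scope"],
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"preprocess failed for layer {lay.value}: {exc}") from exc
        normalized[lay] = nm
        _write_table(rep.to_frame(), reports / f"filters_{lay.value}.tsv")

    # ---- coefficients ----------------------------------------------------
    coeffs = _coefficient_stack(normalized, raw, thresholds["min_count"])
    dist_rows = []
    for kind, tab in coeffs.items():
        _write_table(tab.ratio, tables / f"{kind}_ratio.tsv")
        _write_table(tab.z, tables / f"{kind}_z.tsv")
        for age in tab.ages:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ds = distribution_stats(tab, age)
            dist_rows.append(
                {"kind": kind, "age_months": age, "fwhm": ds.fwhm,
                 "median_abs_z": ds.median_abs_z, "n_genes": ds.n_genes,
                 "multimodal": ds.multimodal}
            )
    dist_df = pd.DataFrame(dist_rows).set_index(["kind", "age_months"])
    _write_table(dist_df, tables / "distribution_stats.tsv")

    # Spearman between layers is computed on abundances (rank within sample),
    # restricted to filtered genes; row-median centering would strip the
    # cross-gene signal the correlation is about.
    corr = interlayer_correlation(
        raw[Layer.PROTEIN_TOTAL].subset_genes(normalized[Layer.PROTEIN_TOTAL].genes),
        raw[Layer.MRNA_TOTAL].subset_genes(normalized[Layer.MRNA_TOTAL].genes),
    )
    corr["rho_median_age"] = corr["age_months"].map(correlation_age_medians(corr))
    _write_table(corr.set_index("animal_id"), tables / "pm_spearman.tsv")

    # ---- trends ----------------------------------------------------------
    from .trends import classify_genes, summarize_trends

    zm = trend_zscores(
        raw[Layer.MRNA_TOTAL].subset_genes(normalized[Layer.MRNA_TOTAL].genes)
    ).per_age_mean("z")
    zp = trend_zscores(
        raw[Layer.PROTEIN_TOTAL].subset_genes(normalized[Layer.PROTEIN_TOTAL].genes)
    ).per_age_mean("z")
    trend_res = classify_genes(zm, zp)
    _write_table(trend_res.assignments, tables / "trend_assignments.tsv")
    _write_table(summarize_trends(trend_res), tables / "trend_summary.tsv")

    # ---- biochemical features -------------------------------------------
    ages = coeffs["pm"].ages
    lfc = coefficient_logfc(coeffs["pm"], ages[-1], ages[-2])
    _write_table(lfc, tables / "pm_logfc.tsv")
    if sequences:
        costs = pio.read_cost_table(Path(__file__).parent / "data" / "demo_costs.tsv")
        feats = build_feature_table(sequences, costs=costs, turnover=turnover)
        _write_table(feats, tables / "features.tsv")
        fc = correlate_features(feats, lfc["log2fc"])
        _write_table(fc, tables / "feature_correlations.tsv")
        hlm = classify_hlm(lfc["log2fc"])
        _write_table(hlm.to_frame("group"), tables / "hlm_groups.tsv")

    # ---- gene-set comparisons -------------------------------------------
    comp_frames = []
    kind_for_set = {}
    if truth is not None:
        kind_for_set = {
            name: ("nt" if name in truth.config.retention_shift
                   else "aggregation" if name in truth.config.aggregation_shift
                   else "pm")
            for name in (s.name for s in gene_sets)
        }
    for s in gene_sets:
        if s.name == "contaminants":
            continue
        kind = kind_for_set.get(s.name, "pm")
        try:
            comp = compare_gene_set_across_ages(coeffs[kind], s)
        except ValueError:
            continue
        comp_frames.append(comp.to_frame())
    if comp_frames:
        _write_table(
            pd.concat(comp_frames, ignore_index=True), tables / "gene_set_comparisons.tsv"
        )

    # ---- figures ---------------------------------------------------------
    if make_figures:
        _make_figures(coeffs, dist_df, figures)

    # ---- manifest --------------------------------------------------------
    resolved = {
        "thresholds": thresholds,
        "seed": seed,
        "synthetic": config.get("synthetic", {}),
        "inputs": {k: str(v) for k, v in config.get("inputs", {}).items()},
    }
    pio.dump_config(resolved, out / "config_resolved.yaml")
    outputs = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "stages": ["preprocess", "coefficients", "trends", "biochem", "comparisons"],
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(out, manifest)


def _make_figures(coeffs, dist_df: pd.DataFrame, figures: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "ptaging"
    meta = {"Date": None}

    fig, ax = plt.subplots(figsize=(5, 4))
    pm = coeffs["pm"]
    grid = np.linspace(-4, 4, 400)
    for age in pm.ages:
        z = pm.per_age_mean("z")[age].dropna().to_numpy()
        kde = stats.gaussian_kde(z, bw_method="silverman")
        ax.plot(grid, kde(grid), label=f"{age}m")
    ax.set_xlabel("p/m coefficient Z-score")
    ax.set_ylabel("density")
    ax.legend(title="age")
    fig.savefig(figures / "pm_density.svg", metadata=meta)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    sub = dist_df.loc["pm"]
    ax.plot(sub.index, sub["fwhm"], marker="o", label="FWHM")
    ax.plot(sub.index, sub["median_abs_z"], marker="s", label="median |Z|")
    ax.set_xlabel("age (months)")
    ax.set_ylabel("distribution breadth")
    ax.legend()
    fig.savefig(figures / "pm_narrowing.svg", metadata=meta)
    plt.close(fig)


# ---------------------------------------------------------------------------
# planted-truth recovery evaluation
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    flags: pd.DataFrame          # per planted set: contrast, direction, p_adj, recovered
    null_significant: int
    null_total: int
    null_binomial_p: float

    @property
    def all_recovered(self) -> bool:
        return bool(self.flags["recovered"].all())


PLANTED_CONTRASTS = {
    # set name -> (coefficient kind, (age_b, age_a) indices into ages, expected sign)
    "mito_like": ("pm", (-1, -2), -1),
    "syn_like": ("pm", (-2, -3), -1),
    "complexI_like": ("nt", (-1, -2), +1),
    "agg60S_like": ("aggregation", (-1, -2), +1),
}


def evaluate_recovery(
    coeffs: dict[str, CoefficientTable],
    gene_sets: list[GeneSet],
    contrasts: dict | None = None,
    alpha: float = 0.01,
    n_null: int = 20,
    null_alpha: float = 0.05,
    seed: int = 0,
) -> RecoveryReport:
    """Check that each planted gene-set phenotype is flagged with the correct
    direction at Tukey-adjusted ``alpha``, and that permuted null sets of the
    same size are not flagged beyond the expected false-positive count
    (one-sided binomial test at ``null_alpha``)."""
    contrasts = contrasts or PLANTED_CONTRASTS
    sets = {s.name: s for s in gene_sets}
    rows = []
    for name, (kind, (ib, ia), sign) in contrasts.items():
        if name not in sets:
            raise KeyError(f"gene set {name!r} not provided")
        tab = coeffs[kind]
        ages = tab.ages
        comp = compare_gene_set_across_ages(tab, sets[name])
        pair = comp.pair(ages[ib], ages[ia])
        recovered = (pair.p_adj < alpha) and (np.sign(pair.mean_diff) == sign)
        rows.append(
            {
                "gene_set": name,
                "kind": kind,
                "contrast": f"{ages[ib]}m vs {ages[ia]}m",
                "mean_diff": pair.mean_diff,
                "expected_sign": sign,
                "p_adj": pair.p_adj,
                "recovered": recovered,
            }
        )
    flags = pd.DataFrame(rows).set_index("gene_set")

    # permuted null calibration on the p/m late-age contrast
    rng = np.random.default_rng(seed)
    pm = coeffs["pm"]
    planted = set().union(*(s.genes for s in gene_sets))
    pool = [g for g in pm.ratio.index if g not in planted]
    set_size = min(len(next(iter(sets.values())).genes), len(pool))
    ages = pm.ages
    n_sig = 0
    for _ in range(n_null):
        members = rng.choice(pool, size=set_size, replace=False)
        comp = compare_gene_set_across_ages(pm, GeneSet("null", frozenset(members)))
        pair = comp.pair(ages[-1], ages[-2])
        if pair.p_adj < null_alpha:
            n_sig += 1
    binom_p = float(stats.binomtest(n_sig, n_null, null_alpha, alternative="greater").pvalue)
    return RecoveryReport(flags, n_sig, n_null, binom_p)
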