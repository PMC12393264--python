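"""Synthetic four-layer cohorts with planted ground truth.

Generates matched mRNA-total / mRNA-nuclear (counts) and protein-total /
protein-insoluble (intensity) matrices for 3 ages x n replicates, with:

* a trend archetype per gene (the eight idealized mRNA/protein vector pairs,
  imported from :mod:`ptaging.trends` as the single source of truth), scaled
  by ``effect_size`` (log2 units);
* per-gene, per-age translation-efficiency offsets on the protein layer with
  an age-dependent cross-gene dispersion schedule (``pm_dispersion``) — the
  planted analogue of p/m distribution narrowing;
* additive nuclear-retention offsets for named gene sets (``retention_shift``)
  and insolubility offsets for aggregating sets (``aggregation_shift``);
* protein sequences, half-lives and copy numbers for the feature/cost stages.

Replicate values are the latent log2 age mean plus Normal(0, noise_sd),
exponentiated; mRNA layers are additionally scaled to a target library size
and Poisson-sampled into integer counts (deterministic expected counts when
``noise_sd`` is zero, so noiseless recovery is exact). One integer seed
controls the whole cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trends import ARCHETYPE_IDS, build_archetypes
from .types import GeneSet, Layer, OmicsMatrix, SampleMeta, TurnoverTable

# Approximate vertebrate proteome amino-acid frequencies (UniProtKB statistics).
NATURAL_AA_FREQ = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}

#: The seven blood-contaminant genes spiked into synthetic cohorts.
CONTAMINANT_GENES = ("Hbb-b1", "Hbb-b2", "Hbb-y", "Hbb-bh1", "Hbz", "Hbb-bh0", "Alb")


@dataclass
class SyntheticConfig:
    """Study conditions for a simulated cohort. Defaults emulate a three-age
    (6/12/24 months) brain cohort with four animals per age, log-normal
    abundances, an age-narrowing translation-offset dispersion schedule and
    four planted gene-set phenotypes (see ``default_config``)."""

    n_genes: int = 2000
    replicates_per_age: int = 4
    ages: tuple[int, ...] = (6, 12, 24)
    archetype_mix: tuple[float, ...] = (0.125,) * 8
    effect_size: float = 1.0            # log2 amplitude of the archetype trend
    noise_sd: float = 0.1               # log2 replicate noise, all layers
    pm_dispersion: tuple[float, ...] = (1.0, 0.6, 0.4)  # per-age sd of translation offsets
    retention_shift: dict[str, tuple[float, ...]] = field(default_factory=dict)
    pm_set_shift: dict[str, tuple[float, ...]] = field(default_factory=dict)
    aggregation_shift: dict[str, tuple[float, ...]] = field(default_factory=dict)
    set_size: int = 100
    seq_length_range: tuple[int, int] = (100, 1000)
    half_life_lognorm: tuple[float, float] = (4.6, 1.0)  # ln-hours: median ~100 h
    mrna_baseline: tuple[float, float] = (10.0, 1.5)     # log2 counts, mean/sd
    protein_baseline: tuple[float, float] = (20.0, 2.0)  # log2 intensity, mean/sd
    protein_mrna_slope: float = 0.8      # couples protein baseline to mRNA baseline
    protein_baseline_extra_sd: float = 1.5
    library_scale: float = 1000.0        # target mean counts per gene
    insoluble_offset: float = -2.0       # log2 depletion of the insoluble fraction
    positive_charge_coupling: float = 0.0  # log2 offset per sd of (K+R) fraction at oldest age
    include_contaminants: bool = True
    missing_frac: float = 0.0            # MCAR missingness on protein layers
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.archetype_mix) - 1.0) > 1e-9:
            raise ValueError("archetype_mix must sum to 1")
        if any(p < 0 for p in self.archetype_mix):
            raise ValueError("archetype_mix proportions must be non-negative")
        if self.replicates_per_age < 2:
            raise ValueError("need >=2 replicates per age for dispersion statistics")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.seq_length_range[0] < 30:
            raise ValueError("sequence lengths must be >= 30")
        if len(self.pm_dispersion) != len(self.ages):
            raise ValueError("pm_dispersion needs one value per age")
        if self.noise_sd == 0 and self.effect_size == 0:
            warnings.warn("effect_size 0 with noise 0: archetypes are indistinguishable", stacklevel=2)


def default_config(**overrides) -> SyntheticConfig:
    """The default planted-phenotype cohort: a mitochondrial-like set with a
    p/m drop at 24m, a synaptic-like set with a p/m drop from 12m onwards
    (plateau), a complex-I-like set with nuclear retention at 24m, and a
    60S-like aggregating set with an insoluble/total rise at 24m."""
    cfg = SyntheticConfig(
        pm_set_shift={
            "mito_like": (0.0, 0.0, -1.2),
            "syn_like": (0.0, -1.2, -1.2),
        },
        retention_shift={"complexI_like": (0.0, 0.0, 1.2)},
        aggregation_shift={"agg60S_like": (0.0, 0.0, 1.2)},
    )
    return replace(cfg, **overrides)


def trend_config(noise_sd: float = 0.02, n_genes: int = 5000, **overrides) -> SyntheticConfig:
    """Study conditions for trend-archetype recovery: a full-strength trend
    (1.0 log2) in every gene, no translation-offset dispersion and no planted
    gene-set phenotypes, so the archetype is the only age signal."""
    cfg = SyntheticConfig(
        n_genes=n_genes,
        effect_size=1.0,
        noise_sd=noise_sd,
        pm_dispersion=(0.0,) * 3,
    )
    return replace(cfg, **overrides)


def dispersion_config(n_genes: int = 5000, **overrides) -> SyntheticConfig:
    """Study conditions for dispersion-narrowing recovery: the age-narrowing
    translation-offset schedule (1.0, 0.6, 0.4) is the dominant age signal,
    over weak residual trends (0.1 log2) and no planted gene-set phenotypes.
    Strong discordant trends would otherwise add p/m variance at the outer
    ages (their protein-minus-mRNA idealized difference vanishes at the
    middle age) and mask the schedule."""
    cfg = SyntheticConfig(n_genes=n_genes, effect_size=0.1, noise_sd=0.1)
    return replace(cfg, **overrides)


@dataclass
class SyntheticTruth:
    """Planted per-gene parameters for recovery tests."""

    table: pd.DataFrame          # archetype, baselines, per-age offsets, memberships
    sequences: dict[str, str]
    config: SyntheticConfig

    def genes_in_set(self, name: str) -> list[str]:
        col = self.table["gene_sets"].fillna("")
        return list(self.table.index[col.str.split(",").apply(lambda xs: name in xs)])


@dataclass
class Cohort:
    matrices: dict[Layer, OmicsMatrix]
    sequences: dict[str, str]
    gene_sets: list[GeneSet]
    turnover: TurnoverTable
    truth: SyntheticTruth


def generate_sequences(
    n: int,
    length_range: tuple[int, int],
    composition_bias: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    prefix: str = "G",
) -> dict[str, str]:
    """i.i.d. residues from normalized weights; lengths uniform in range."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bias = composition_bias or NATURAL_AA_FREQ
    aas = sorted(bias)
    w = np.array([bias[a] for a in aas], dtype=float)
    if (w < 0).any():
        raise ValueError("composition weights must be >= 0")
    if w.sum() <= 0:
        raise ValueError("all-zero composition weights")
    p = w / w.sum()
    lo, hi = length_range
    out = {}
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        out[f"{prefix}{i + 1:05d}"] = "".join(rng.choice(list(aas), size=length, p=p))
    return out


def _assign_archetypes(n: int, mix: tuple[float, ...], rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of archetype counts, then a shuffle."""
    raw = np.array(mix) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    ids = np.repeat(np.arange(8), counts)
    rng.shuffle(ids)
    return ids


def _sample_ids(cfg: SyntheticConfig, layer: Layer) -> list[SampleMeta]:
    out = []
    for age in cfg.ages:
        for r in range(1, cfg.replicates_per_age + 1):
            animal = f"A{age}m_{r}"
            out.append(
                SampleMeta(
                    sample_id=f"{layer.value}:{animal}",
                    animal_id=animal,
                    age_months=age,
                    layer=layer,
                )
            )
    return out


def generate_cohort(cfg: SyntheticConfig) -> Cohort:
    """Generate the four matched layers plus sequences, gene sets, turnover
    table and ground truth. Identical config and seed give bit-identical
    output."""
    rng = np.random.default_rng(cfg.seed)
    n, ages = cfg.n_genes, cfg.ages
    k = len(ages)
    genes = [f"G{i + 1:05d}" for i in range(n)]

    arch_ids = _assign_archetypes(n, cfg.archetype_mix, rng)
    archetypes = build_archetypes()
    vm = np.array([a.mrna_vector for a in archetypes])
    vp = np.array([a.protein_vector for a in archetypes])
    if k != vm.shape[1]:
        raise ValueError(f"{k} ages but archetype vectors have {vm.shape[1]} points")
    vm_c = vm - vm.mean(axis=1, keepdims=True)
    vp_c = vp - vp.mean(axis=1, keepdims=True)

    base_m = rng.normal(cfg.mrna_baseline[0], cfg.mrna_baseline[1], n)
    base_p = (
        cfg.protein_baseline[0]
        + cfg.protein_mrna_slope * (base_m - cfg.mrna_baseline[0])
        + rng.normal(0.0, cfg.protein_baseline_extra_sd, n)
    )

    # per-gene per-age translation-efficiency offsets (p/m dispersion schedule)
    disp = np.array(cfg.pm_dispersion)
    trans_off = rng.normal(0.0, 1.0, (n, k)) * disp[None, :]

    # gene sets: disjoint random blocks for every named planted set
    set_names = sorted(
        set(cfg.pm_set_shift) | set(cfg.retention_shift) | set(cfg.aggregation_shift)
    )
    pool = rng.permutation(n)
    memberships: dict[str, np.ndarray] = {}
    start = 0
    for name in set_names:
        if start + cfg.set_size > n:
            raise ValueError("not enough genes for the requested planted sets")
        memberships[name] = np.sort(pool[start : start + cfg.set_size])
        start += cfg.set_size

    retention = np.zeros((n, k))
    aggregation = np.zeros((n, k))
    for name, idx in memberships.items():
        if name in cfg.pm_set_shift:
            trans_off[idx] += np.asarray(cfg.pm_set_shift[name])[None, :]
        if name in cfg.retention_shift:
            retention[idx] += np.asarray(cfg.retention_shift[name])[None, :]
        if name in cfg.aggregation_shift:
            aggregation[idx] += np.asarray(cfg.aggregation_shift[name])[None, :]

    sequences = generate_sequences(n, cfg.seq_length_range, seed=rng)
    sequences = dict(zip(genes, sequences.values()))
    if cfg.positive_charge_coupling != 0.0:
        frac_pos = np.array(
            [(s.count("K") + s.count("R")) / len(s) for s in sequences.values()]
        )
        zpos = (frac_pos - frac_pos.mean()) / frac_pos.std()
        trans_off[:, -1] += cfg.positive_charge_coupling * zpos

    # latent log2 age means per layer
    lat_m = base_m[:, None] + cfg.effect_size * vm_c[arch_ids]
    lat_p = base_p[:, None] + cfg.effect_size * vp_c[arch_ids] + trans_off
    lat_nuc = lat_m + retention
    lat_ins = lat_p + cfg.insoluble_offset + aggregation

    half_life = np.exp(rng.normal(cfg.half_life_lognorm[0], cfg.half_life_lognorm[1], n))
    copy_number = 2.0 ** (base_p - base_p.min() + 1.0)

    def replicate_log2(lat: np.ndarray) -> np.ndarray:
        """n x (k * reps) log2 values: age mean + replicate noise."""
        reps = cfg.replicates_per_age
        cols = np.repeat(np.arange(k), reps)
        out = lat[:, cols]
        if cfg.noise_sd > 0:
            out = out + rng.normal(0.0, cfg.noise_sd, out.shape)
        return out

    def count_layer(lat: np.ndarray, layer: Layer, contam_rows: np.ndarray | None) -> OmicsMatrix:
        log2v = replicate_log2(lat)
        if contam_rows is not None:
            log2v = np.vstack([log2v, contam_rows])
        expected = 2.0 ** log2v
        # scale each sample to the target library size
        target = cfg.library_scale * expected.shape[0]
        expected = expected / expected.sum(axis=0, keepdims=True) * target
        counts = rng.poisson(expected) if cfg.noise_sd > 0 else expected
        samples = _sample_ids(cfg, layer)
        index = genes + (list(CONTAMINANT_GENES) if contam_rows is not None else [])
        df = pd.DataFrame(
            counts.astype(float), index=index, columns=[s.sample_id for s in samples]
        )
        return OmicsMatrix(df, samples)

    def intensity_layer(lat: np.ndarray, layer: Layer, contam_rows: np.ndarray | None) -> OmicsMatrix:
        log2v = replicate_log2(lat)
        if contam_rows is not None:
            log2v = np.vstack([log2v, contam_rows])
        vals = 2.0 ** log2v
        if cfg.missing_frac > 0:
            mask = rng.random(vals.shape) < cfg.missing_frac
            vals = np.where(mask, np.nan, vals)
        samples = _sample_ids(cfg, layer)
        index = genes + (list(CONTAMINANT_GENES) if contam_rows is not None else [])
        df = pd.DataFrame(vals, index=index, columns=[s.sample_id for s in samples])
        return OmicsMatrix(df, samples)

    ncols = k * cfg.replicates_per_age
    if cfg.include_contaminants:
        n_con = len(CONTAMINANT_GENES)
        contam = {
            "count": rng.normal(cfg.mrna_baseline[0], 0.5, (n_con, ncols)),
            "intensity": rng.normal(cfg.protein_baseline[0], 0.5, (n_con, ncols)),
        }
    else:
        contam = {"count": None, "intensity": None}

    matrices = {
        Layer.MRNA_TOTAL: count_layer(lat_m, Layer.MRNA_TOTAL, contam["count"]),
        Layer.MRNA_NUCLEAR: count_layer(lat_nuc, Layer.MRNA_NUCLEAR, contam["count"]),
        Layer.PROTEIN_TOTAL: intensity_layer(lat_p, Layer.PROTEIN_TOTAL, contam["intensity"]),
        Layer.PROTEIN_INSOLUBLE: intensity_layer(lat_ins, Layer.PROTEIN_INSOLUBLE, contam["intensity"]),
    }

    member_str = []
    for i in range(n):
        names = [nm for nm, idx in memberships.items() if i in set(idx)]
        member_str.append(",".join(names))
    truth_tbl = pd.DataFrame(
        {
            "archetype": [ARCHETYPE_IDS[a] for a in arch_ids],
            "baseline_log2_mrna": base_m,
            "baseline_log2_protein": base_p,
            **{f"translation_offset_{age}m": trans_off[:, j] for j, age in enumerate(ages)},
            **{f"retention_offset_{age}m": retention[:, j] for j, age in enumerate(ages)},
            **{f"aggregation_offset_{age}m": aggregation[:, j] for j, age in enumerate(ages)},
            "gene_sets": member_str,
            "half_life_h": half_life,
            "copy_number": copy_number,
        },
        index=pd.Index(genes, name="gene"),
    )

    gene_sets = [
        GeneSet(name, frozenset(genes[i] for i in idx)) for name, idx in memberships.items()
    ]
    if cfg.include_contaminants:
        gene_sets.append(GeneSet("contaminants", frozenset(CONTAMINANT_GENES)))
    turnover = TurnoverTable(
        pd.DataFrame(
            {"half_life_h": half_life, "copy_number": copy_number},
            index=pd.Index(genes, name="gene"),
        )
    )
    truth = SyntheticTruth(truth_tbl, sequences, cfg)
    return Cohort(matrices, sequences, gene_sets, turnover, truth)


def write_cohort(cohort: Cohort, out_dir) -> dict[str, str]:
    """Write the cohort in the exact dialects the readers consume; returns a
    {name: path} map. The truth table is written for test harnesses."""
    from pathlib import Path

    from . import io as pio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    samples = []
    for layer, m in cohort.matrices.items():
        p = out / f"{layer.value}.tsv"
        pio.write_matrix(m, p)
        paths[layer.value] = str(p)
        samples.extend(m.samples)
    sheet = out / "samples.tsv"
    pio.write_sample_sheet(samples, sheet)
    paths["sample_sheet"] = str(sheet)
    fasta = out / "sequences.fasta"
    pio.write_fasta(cohort.sequences, fasta)
    paths["fasta"] = str(fasta)
    gmt = out / "gene_sets.gmt"
    pio.write_gene_sets(cohort.gene_sets, gmt)
    paths["gene_sets"] = str(gmt)
    turn = out / "turnover.tsv"
    pio.write_turnover_table(cohort.turnover, turn)
    paths["turnover"] = str(turn)
    truth = out / "truth.tsv"
    cohort.truth.table.to_csv(truth, sep="\t", float_format="%.10g")
    paths["truth"] = str(truth)
    return paths
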