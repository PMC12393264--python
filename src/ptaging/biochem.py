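"""Sequence-derived biochemical features, biosynthetic cost, and protein
turnover energetics.

Features per protein: length, amino-acid composition, charged-residue
fractions, isoelectric point (bisection on a Henderson-Hasselbalch net-charge
model with the EMBOSS pKa set), GRAVY (mean Kyte-Doolittle hydropathy), and
the average biosynthetic cost per residue (avECPA) from a user-supplied cost
table. The turnover cost model prices the maintenance of a protein pool:
a protein of N_aa residues with half-life T turns over at the decay rate
lambda = ln(2)/T, so single-copy cost C_prot = N_aa * ln(2)/T (residues per
hour) and pool cost C_total = C_prot * N_prot. Actual ATP cost is about five
times the residue-turnover rate; that factor is omitted by default and
selectable via ``atp_factor``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .types import STANDARD_AA, CostTable, TurnoverTable

# Kyte & Doolittle (1982) hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# EMBOSS pKa set used for the net-charge model.
PKA_POSITIVE = {"nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


@dataclass(frozen=True)
class Composition:
    length_aa: int            # standard residues counted
    n_nonstandard: int
    frac: dict[str, float]    # per standard residue, sums to 1
    frac_positive: float
    frac_negative: float
    frac_lysine: float


def compute_composition(seq: str, include_histidine: bool = False) -> Composition:
    """Residue fractions and charge-class fractions. Non-standard residues are
    excluded from the denominator and reported in ``n_nonstandard``.
    Positive = K + R (H included only on request; its side chain pKa ~6 leaves
    it mostly neutral at physiological pH); negative = D + E."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = {aa: 0 for aa in STANDARD_AA}
    n_nonstd = 0
    for ch in seq:
        if ch in counts:
            counts[ch] += 1
        else:
            n_nonstd += 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError("sequence contains no standard residues")
    frac = {aa: c / n for aa, c in counts.items()}
    pos = frac["K"] + frac["R"] + (frac["H"] if include_histidine else 0.0)
    return Composition(
        length_aa=n,
        n_nonstandard=n_nonstd,
        frac=frac,
        frac_positive=pos,
        frac_negative=frac["D"] + frac["E"],
        frac_lysine=frac["K"],
    )


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value over standard
    residues (non-standard residues skipped)."""
    vals = [KYTE_DOOLITTLE[ch] for ch in seq.upper() if ch in KYTE_DOOLITTLE]
    if not vals:
        raise ValueError("sequence contains no standard residues")
    return float(np.mean(vals))


def net_charge(seq: str, pH: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH, counting side chains
    of K/R/H (positive), D/E/C/Y (negative) and the two termini."""
    seq = seq.upper()
    counts = {aa: seq.count(aa) for aa in "KRHDECY"}
    charge = 1.0 / (1.0 + 10 ** (pH - PKA_POSITIVE["nterm"]))
    for aa in "KRH":
        charge += counts[aa] / (1.0 + 10 ** (pH - PKA_POSITIVE[aa]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["cterm"] - pH))
    for aa in "DECY":
        charge -= counts[aa] / (1.0 + 10 ** (PKA_NEGATIVE[aa] - pH))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-6) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The net-charge function is strictly decreasing in pH, so the root is
    unique; iteration continues until |net charge| < 1e-4 (and the bracket is
    narrower than ``tol`` pH units)."""
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid)
        if abs(q) < 1e-4 and (hi - lo) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def compute_avecpa(seq: str, costs: CostTable) -> float:
    """Average biosynthetic cost per amino acid: mean of the per-residue cost
    over standard residues (i.e. total chain cost normalized by length).
    Residues absent from the table are excluded."""
    table = costs.cost_per_aa
    vals = [table[ch] for ch in seq.upper() if ch in table]
    if not vals:
        raise ValueError("no costed residues in sequence")
    return float(np.mean(vals))


def compute_cost_model(
    length_aa, half_life_h, copy_number=1.0, atp_factor: float = 1.0
):
    """Turnover cost of one protein species.

    C_prot = N_aa * ln(2)/T_half * atp_factor  (residues, or ATP, per hour)
    C_total = C_prot * N_prot

    Accepts scalars or aligned arrays. Doubling the half-life exactly halves
    both outputs; both are linear in length and copy number.
    """
    length_aa = np.asarray(length_aa, dtype=float)
    half_life_h = np.asarray(half_life_h, dtype=float)
    copy_number = np.asarray(copy_number, dtype=float)
    if np.any(half_life_h <= 0):
        raise ValueError("half-life must be positive")
    if np.any(copy_number <= 0):
        raise ValueError("copy number must be positive")
    c_prot = length_aa * (math.log(2) / half_life_h)
    c_total = c_prot * copy_number
    if atp_factor != 1.0:  # applied last so the factor is exactly multiplicative
        c_prot = c_prot * atp_factor
        c_total = c_total * atp_factor
    if c_prot.ndim == 0:
        return float(c_prot), float(c_total)
    return c_prot, c_total


def build_feature_table(
    sequences: dict[str, str],
    costs: CostTable | None = None,
    turnover: TurnoverTable | None = None,
    disorder: pd.Series | None = None,
    atp_factor: float = 1.0,
    include_histidine: bool = False,
) -> pd.DataFrame:
    """Per-protein feature table: length, residue fractions, charge fractions,
    pI, GRAVY, optional disorder fraction (external predictor output), avECPA
    and cost-model outputs where turnover data is available."""
    rows = {}
    for gene, seq in sequences.items():
        comp = compute_composition(seq, include_histidine=include_histidine)
        row = {
            "length_aa": comp.length_aa,
            "n_nonstandard": comp.n_nonstandard,
            "frac_positive": comp.frac_positive,
            "frac_negative": comp.frac_negative,
            "frac_lysine": comp.frac_lysine,
            "isoelectric_point": isoelectric_point(seq),
            "gravy": gravy(seq),
        }
        for aa in STANDARD_AA:
            row[f"frac_{aa}"] = comp.frac[aa]
        if costs is not None:
            row["avECPA"] = compute_avecpa(seq, costs)
        rows[gene] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene"
    if disorder is not None:
        df["disorder_frac"] = disorder.reindex(df.index)
    if turnover is not None:
        tt = turnover.table.reindex(df.index)
        ok = tt["half_life_h"].notna() & tt["copy_number"].notna()
        c_prot = np.full(len(df), np.nan)
        c_total = np.full(len(df), np.nan)
        if ok.any():
            c_prot[ok.to_numpy()], c_total[ok.to_numpy()] = compute_cost_model(
                df.loc[ok, "length_aa"].to_numpy(),
                tt.loc[ok, "half_life_h"].to_numpy(),
                tt.loc[ok, "copy_number"].to_numpy(),
                atp_factor=atp_factor,
            )
        df["half_life_h"] = tt["half_life_h"]
        df["copy_number"] = tt["copy_number"]
        df["C_prot"] = c_prot
        df["C_total"] = c_total
    return df


def correlate_features(
    features: pd.DataFrame, target: pd.Series, method: str = "spearman"
) -> pd.DataFrame:
    """Rank correlation of every feature column against a per-gene target
    statistic (e.g. the p/m coefficient log2FC between two ages). Positive
    rho means the feature is high where the target is high. Constant features
    have undefined correlation and are reported as missing."""
    if method != "spearman":
        raise ValueError("only Spearman correlation is supported")
    common = features.index.intersection(target.dropna().index)
    if len(common) < 10:
        raise ValueError(f"only {len(common)} common genes; need >=10")
    y = target.loc[common].to_numpy(dtype=float)
    rows = []
    for col in features.columns:
        x = features.loc[common, col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 10 or np.all(x[ok] == x[ok][0]):
            rows.append({"feature": col, "rho": np.nan, "p_value": np.nan, "n": int(ok.sum())})
            continue
        res = spearmanr(x[ok], y[ok])
        rows.append(
            {"feature": col, "rho": float(res.statistic), "p_value": float(res.pvalue), "n": int(ok.sum())}
        )
    return pd.DataFrame(rows).set_index("feature")
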