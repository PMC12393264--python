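"""Eight-archetype temporal classification of matched mRNA/protein trajectories.

Each gene's per-age mean Z profile in the two layers is correlated (Pearson)
with idealized three-point trend vectors — up (0, 0.5, 1), down (1, 0.5, 0),
down-up (1, 0, 1) and up-down (0, 1, 0) — paired into eight archetypes: four
concordant (same shape in mRNA and protein) and four discordant. A gene is
assigned to the archetype with the highest combined correlation (arithmetic
mean of the mRNA and protein correlations). With three time points the
Pearson correlation depends only on the shape of the profile, so the
classification is invariant to per-gene affine transforms of Z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import TrendArchetype

_UP = (0.0, 0.5, 1.0)
_DOWN = (1.0, 0.5, 0.0)
_DOWN_UP = (1.0, 0.0, 1.0)
_UP_DOWN = (0.0, 1.0, 0.0)

ARCHETYPE_IDS = ("i", "ii", "iii", "iv", "v", "vi", "vii", "viii")


def build_archetypes() -> list[TrendArchetype]:
    """The eight idealized (mRNA, protein) trend-vector pairs: i-iv concordant
    (up/up, down/down, down-up/down-up, up-down/up-down), v-viii discordant
    (up/down, down/up, down-up/up-down, up-down/down-up)."""
    pairs = [
        ("i", "up / up", _UP, _UP),
        ("ii", "down / down", _DOWN, _DOWN),
        ("iii", "down-up / down-up", _DOWN_UP, _DOWN_UP),
        ("iv", "up-down / up-down", _UP_DOWN, _UP_DOWN),
        ("v", "up-transcript / down-protein", _UP, _DOWN),
        ("vi", "down-transcript / up-protein", _DOWN, _UP),
        ("vii", "down-up transcript / up-down protein", _DOWN_UP, _UP_DOWN),
        ("viii", "up-down transcript / down-up protein", _UP_DOWN, _DOWN_UP),
    ]
    return [TrendArchetype(i, lab, m, p) for i, lab, m, p in pairs]


def _corr_with_vectors(z: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Pearson r between each row of z (genes x k ages) and each idealized
    vector; rows with zero variance yield NaN."""
    zc = z - z.mean(axis=1, keepdims=True)
    zn = np.linalg.norm(zc, axis=1, keepdims=True)
    vc = vectors - vectors.mean(axis=1, keepdims=True)
    vn = np.linalg.norm(vc, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (zc / zn) @ (vc / vn).T
    return r


@dataclass
class TrendResult:
    assignments: pd.DataFrame  # archetype, r_mrna, r_protein, score, margin, tie
    unclassified: list[str]


def classify_genes(
    z_mrna: pd.DataFrame,
    z_protein: pd.DataFrame,
    archetypes: list[TrendArchetype] | None = None,
    combine: str = "mean",
) -> TrendResult:
    """Assign each gene to the archetype maximising the combined Pearson
    correlation of its per-age mean Z profiles with the idealized vectors.

    ``z_mrna`` and ``z_protein`` are genes x ages frames (same age order).
    ``combine``: 'mean' (default) averages the two per-layer correlations;
    'min' takes the weaker one. Genes with a constant profile in either layer
    have undefined correlation and are left unclassified. Ties go to the
    lowest archetype id and are flagged.
    """
    archetypes = archetypes or build_archetypes()
    k = z_mrna.shape[1]
    if k < 3:
        raise ValueError(f"need >=3 ages, got {k}")
    if list(z_mrna.columns) != list(z_protein.columns):
        raise ValueError("age columns differ between layers")
    if k != len(archetypes[0].mrna_vector):
        raise ValueError(
            f"{k} ages but idealized vectors have {len(archetypes[0].mrna_vector)} points"
        )
    genes = z_mrna.index.intersection(z_protein.index)
    zm = z_mrna.loc[genes].to_numpy(dtype=float)
    zp = z_protein.loc[genes].to_numpy(dtype=float)

    vm = np.array([a.mrna_vector for a in archetypes])
    vp = np.array([a.protein_vector for a in archetypes])
    rm = _corr_with_vectors(zm, vm)
    rp = _corr_with_vectors(zp, vp)
    if combine == "mean":
        score = (rm + rp) / 2.0
    elif combine == "min":
        score = np.minimum(rm, rp)
    else:
        raise ValueError(f"unknown combine rule {combine!r}")

    ok = np.isfinite(score).all(axis=1)
    unclassified = list(genes[~ok])
    rows = []
    ids = [a.id for a in archetypes]
    for gi in np.flatnonzero(ok):
        s = score[gi]
        best = int(np.argmax(s))  # argmax takes the lowest index on ties
        order = np.sort(s)[::-1]
        margin = float(order[0] - order[1])
        rows.append(
            {
                "gene": genes[gi],
                "archetype": ids[best],
                "r_mrna": float(rm[gi, best]),
                "r_protein": float(rp[gi, best]),
                "score": float(s[best]),
                "margin": margin,
                "tie": bool(np.sum(s == s[best]) > 1),
            }
        )
    assignments = pd.DataFrame(
        rows, columns=["gene", "archetype", "r_mrna", "r_protein", "score", "margin", "tie"]
    ).set_index("gene") if rows else pd.DataFrame(
        columns=["archetype", "r_mrna", "r_protein", "score", "margin", "tie"]
    )
    return TrendResult(assignments, unclassified)


def summarize_trends(result: TrendResult) -> pd.DataFrame:
    """Counts and percentages (1 decimal, over classified genes) per archetype."""
    counts = result.assignments["archetype"].value_counts() if len(result.assignments) else pd.Series(dtype=int)
    total = int(counts.sum())
    rows = []
    for aid in ARCHETYPE_IDS:
        n = int(counts.get(aid, 0))
        pct = round(100.0 * n / total, 1) if total else 0.0
        rows.append({"archetype": aid, "n": n, "percent": pct})
    return pd.DataFrame(rows).set_index("archetype")
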