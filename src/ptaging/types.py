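"""Shared domain types for the proteo-transcriptomic aging pipeline.

All downstream stages consume these containers; no stage re-reads raw files.
Abundance matrices are held as pandas DataFrames (genes x samples) together
with per-sample metadata. Gene identifiers are opaque strings; cross-layer
joins are exact string matches (an optional alias map can be applied at read
time for symbol reconciliation).
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
NONSTANDARD_AA = set("BZXUO*")


class Layer(str, enum.Enum):
    """The four measured molecular layers."""

    MRNA_TOTAL = "mrna_total"
    MRNA_NUCLEAR = "mrna_nuclear"
    PROTEIN_TOTAL = "protein_total"
    PROTEIN_INSOLUBLE = "protein_insoluble"

    @property
    def is_count(self) -> bool:
        """Count layers hold integer read counts; zeros are real zeros,
        never missing. Intensity layers may contain missing cells."""
        return self in (Layer.MRNA_TOTAL, Layer.MRNA_NUCLEAR)


@dataclass(frozen=True)
class SampleMeta:
    """One biological sample: a (animal, age, layer) measurement."""

    sample_id: str
    animal_id: str
    age_months: int
    layer: Layer

    def __post_init__(self) -> None:
        if self.age_months <= 0:
            raise ValueError(f"age_months must be positive, got {self.age_months}")


@dataclass
class OmicsMatrix:
    """Gene x sample abundances for a single layer.

    ``values``: DataFrame indexed by gene, columns = sample_id, NaN = missing.
    ``samples``: SampleMeta per column, same order as ``values.columns``.
    ``flags``: optional per-gene annotation columns (e.g. MaxQuant
    "Reverse"/"Potential Contaminant"/"Only Identified by Site" '+' flags).
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.samples) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.samples)} sample records for "
                f"{self.values.shape[1]} value columns"
            )
        ids = [s.sample_id for s in self.samples]
        if ids != list(self.values.columns):
            raise ValueError("sample order does not match value columns")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        layers = {s.layer for s in self.samples}
        if len(layers) > 1:
            raise ValueError(f"mixed layers in one matrix: {sorted(l.value for l in layers)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def layer(self) -> Layer:
        return self.samples[0].layer

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def ages(self) -> list[int]:
        """Distinct ages, ascending."""
        return sorted({s.age_months for s in self.samples})

    def meta_frame(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame indexed by sample_id."""
        return pd.DataFrame(
            {
                "animal_id": [s.animal_id for s in self.samples],
                "age_months": [s.age_months for s in self.samples],
                "layer": [s.layer.value for s in self.samples],
            },
            index=pd.Index([s.sample_id for s in self.samples], name="sample_id"),
        )

    def columns_for_age(self, age: int) -> list[str]:
        return [s.sample_id for s in self.samples if s.age_months == age]

    def replicates_per_age(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for s in self.samples:
            out[s.age_months] = out.get(s.age_months, 0) + 1
        return dict(sorted(out.items()))

    def subset_genes(self, genes) -> "OmicsMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        flags = self.flags.loc[keep] if self.flags is not None else None
        return OmicsMatrix(self.values.loc[keep], list(self.samples), flags)

    def with_values(self, values: pd.DataFrame) -> "OmicsMatrix":
        """Same metadata, new values (genes may be a subset, columns identical)."""
        flags = None
        if self.flags is not None:
            flags = self.flags.loc[self.flags.index.intersection(values.index)]
        return OmicsMatrix(values, list(self.samples), flags)

    def check_min_replicates(self, n: int = 2) -> None:
        for age, k in self.replicates_per_age().items():
            if k < n:
                raise ValueError(
                    f"layer {self.layer.value}: age {age} has {k} replicate(s), "
                    f"need >= {n}"
                )


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def intersect(self, universe) -> frozenset[str]:
        return self.genes & set(universe)


@dataclass(frozen=True)
class CostTable:
    """Per-residue biosynthetic cost (arbitrary energy units)."""

    cost_per_aa: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(STANDARD_AA) - set(self.cost_per_aa)
        if missing:
            raise ValueError(f"cost table missing residues: {sorted(missing)}")
        bad = {a: c for a, c in self.cost_per_aa.items() if c < 0}
        if bad:
            raise ValueError(f"negative costs: {bad}")


@dataclass
class TurnoverTable:
    """Per-gene protein half-life (hours) and copy number (relative scale)."""

    table: pd.DataFrame  # index gene, columns half_life_h, copy_number

    def __post_init__(self) -> None:
        for col in ("half_life_h", "copy_number"):
            if col not in self.table.columns:
                raise ValueError(f"turnover table missing column {col!r}")
            if (self.table[col] <= 0).any():
                bad = self.table.index[self.table[col] <= 0].tolist()
                raise ValueError(f"non-positive {col} for genes {bad[:5]}")


@dataclass
class FilterStep:
    name: str
    genes_in: int
    genes_out: int
    removed: list[str]

    def __post_init__(self) -> None:
        if self.genes_out != self.genes_in - len(self.removed):
            raise ValueError("filter bookkeeping mismatch")


@dataclass
class FilterReport:
    """Audit trail of a filter cascade, in application order."""

    steps: list[FilterStep] = field(default_factory=list)

    def add(self, step: FilterStep) -> None:
        self.steps.append(step)

    def extend(self, other: "FilterReport") -> None:
        self.steps.extend(other.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": [s.name for s in self.steps],
                "genes_in": [s.genes_in for s in self.steps],
                "genes_out": [s.genes_out for s in self.steps],
                "n_removed": [len(s.removed) for s in self.steps],
                "removed": [",".join(s.removed) for s in self.steps],
            }
        )


@dataclass
class CoefficientTable:
    """Per-gene, per-matched-animal ratio coefficients with cross-age Z-scores.

    ``kind``: 'pm' (protein/mRNA), 'nt' (nuclear/total mRNA) or 'aggregation'
    (insoluble/total protein). Columns of ``ratio`` and ``z`` are animal IDs;
    ``meta`` maps each animal to its age.
    """

    kind: str
    ratio: pd.DataFrame
    z: pd.DataFrame
    meta: pd.DataFrame  # index animal_id, column age_months
    constant_genes: list[str] = field(default_factory=list)

    @property
    def ages(self) -> list[int]:
        return sorted(self.meta["age_months"].unique())

    def animals_for_age(self, age: int) -> list[str]:
        return list(self.meta.index[self.meta["age_months"] == age])

    def per_age_mean(self, which: str = "z") -> pd.DataFrame:
        """Per-gene mean of z (or ratio) within each age; columns are ages."""
        mat = self.z if which == "z" else self.ratio
        cols = {age: mat[self.animals_for_age(age)].mean(axis=1) for age in self.ages}
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class DistributionStats:
    """Shape of a coefficient Z distribution at one age."""

    age_months: int
    fwhm: float
    median_abs_z: float
    n_genes: int
    multimodal: bool = False


@dataclass(frozen=True)
class TrendArchetype:
    """One of the eight idealized (mRNA, protein) trajectory pairs."""

    id: str  # roman numeral i..viii
    label: str
    mrna_vector: tuple[float, ...]
    protein_vector: tuple[float, ...]

    def __post_init__(self) -> None:
        for v in (self.mrna_vector, self.protein_vector):
            if len(set(v)) < 2:
                raise ValueError(f"archetype {self.id}: constant idealized vector {v}")


def as_dict(obj) -> dict:
    """Dataclass to plain dict (for manifests / logs)."""
    d = dataclasses.asdict(obj)

    def conv(x):
        if isinstance(x, enum.Enum):
            return x.value
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        if isinstance(x, frozenset):
            return sorted(x)
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [conv(v) for v in x]
        return x

    return conv(d)
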