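"""Readers and writers for the delimited formats the pipeline touches.

Dialects: TSV with UTF-8 and '.' decimal separator; empty cell = missing.
Gene sets in GMT (name, description, tab-separated members); sequences in
FASTA; cost and turnover tables as two/three-column TSV.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    NONSTANDARD_AA,
    CostTable,
    GeneSet,
    Layer,
    OmicsMatrix,
    SampleMeta,
    TurnoverTable,
)

#: Per-gene annotation columns recognised in matrix files ('+' marks removal).
FLAG_COLUMNS = ("Reverse", "Potential Contaminant", "Only Identified by Site")


# ---------------------------------------------------------------------------
# sample sheets and matrices
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "animal_id", "age_months", "layer"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=r.sample_id,
            animal_id=r.animal_id,
            age_months=int(r.age_months),
            layer=Layer(r.layer),
        )
        for r in df.itertuples()
    ]


def write_sample_sheet(samples: list[SampleMeta], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "animal_id": [s.animal_id for s in samples],
            "age_months": [s.age_months for s in samples],
            "layer": [s.layer.value for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_matrix(path, sample_sheet, alias_map: dict[str, str] | None = None) -> OmicsMatrix:
    """Read one layer's gene x sample TSV, joining sample metadata.

    First column holds gene identifiers; remaining columns are sample IDs from
    the sheet, except the recognised MaxQuant-style flag columns which are kept
    as per-gene annotations. Empty cells parse as missing (NaN), never zero.
    ``alias_map`` optionally renames gene identifiers for cross-layer symbol
    reconciliation.
    """
    samples = (
        read_sample_sheet(sample_sheet)
        if not isinstance(sample_sheet, list)
        else sample_sheet
    )
    by_id = {s.sample_id: s for s in samples}
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if alias_map:
        df.index = [alias_map.get(g, g) for g in df.index]
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene ID(s) in {path}: {dups[:5]}")
    flag_cols = [c for c in df.columns if c in FLAG_COLUMNS]
    flags = df[flag_cols].astype("string") if flag_cols else None
    value_cols = [c for c in df.columns if c not in FLAG_COLUMNS]
    unknown = [c for c in value_cols if c not in by_id]
    if unknown:
        raise ValueError(f"unknown sample ID(s) in {path} header: {unknown}")
    values = df[value_cols].astype(float)
    meta = [by_id[c] for c in value_cols]
    layers = {s.layer for s in meta}
    if len(layers) > 1:
        raise ValueError(
            f"{path}: columns span multiple layers {sorted(l.value for l in layers)}"
        )
    return OmicsMatrix(values, meta, flags)


def write_matrix(m: OmicsMatrix, path, float_format: str = "%.10g") -> None:
    """Write values (plus any flag columns) as TSV; missing cells left empty."""
    df = m.values.copy()
    if m.flags is not None:
        df = pd.concat([df, m.flags.reindex(df.index)], axis=1)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=float_format, na_rep="")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, tab-separated
    ``name<TAB>description<TAB>member...``; the description is ignored."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 fields "
                    f"(name, description, >=1 member), got {len(fields)}"
                )
            members = [f for f in fields[2:] if f]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {fields[0]!r} has no members")
            sets.append(GeneSet(fields[0], frozenset(members)))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gene_sets(sets: list[GeneSet], path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            desc = descriptions.get(s.name, "na")
            fh.write("\t".join([s.name, desc, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# sequences (FASTA)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Protein FASTA -> {id: upper-cased sequence}.

    The record ID is the first whitespace-delimited header token. Sequences
    containing non-standard residues (B, Z, X, U, O, *) are retained but a
    warning names them.
    """
    seqs: dict[str, str] = {}
    flagged: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence ID {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for {rec.id!r}")
        if set(seq) & NONSTANDARD_AA:
            flagged.append(rec.id)
        seqs[rec.id] = seq
    if not seqs:
        raise ValueError(f"{path}: no sequences found")
    if flagged:
        warnings.warn(
            f"{len(flagged)} sequence(s) contain non-standard residues "
            f"(e.g. {flagged[:3]}); they are excluded from composition denominators",
            stacklevel=2,
        )
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=g, description="") for g, s in seqs.items()]
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Bio.SeqIO wraps at 60 already


# ---------------------------------------------------------------------------
# cost / turnover tables, config
# ---------------------------------------------------------------------------

def read_cost_table(path) -> CostTable:
    """TSV with columns ``aa`` and ``cost`` covering the 20 standard residues."""
    df = pd.read_csv(path, sep="\t")
    if not {"aa", "cost"} <= set(df.columns):
        raise ValueError(f"{path}: cost table needs columns 'aa' and 'cost'")
    return CostTable({str(a): float(c) for a, c in zip(df["aa"], df["cost"])})


def write_cost_table(t: CostTable, path) -> None:
    pd.DataFrame(
        {"aa": list(t.cost_per_aa), "cost": list(t.cost_per_aa.values())}
    ).to_csv(path, sep="\t", index=False)


def read_turnover_table(path) -> TurnoverTable:
    """TSV with columns ``gene``, ``half_life_h``, ``copy_number``."""
    df = pd.read_csv(path, sep="\t", index_col="gene")
    return TurnoverTable(df[["half_life_h", "copy_number"]].astype(float))


def write_turnover_table(t: TurnoverTable, path) -> None:
    df = t.table.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


def load_config(path) -> dict:
    """YAML config holding thresholds, seeds and paths."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def default_contaminants() -> GeneSet:
    """Blood-contamination gene set shipped with the package (hemoglobin
    subunits and albumin)."""
    path = Path(__file__).parent / "data" / "contaminants.gmt"
    return read_gene_sets(path)[0]
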