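"""Sequence-derived features, biosynthetic cost and turnover energetics.

For each protein: composition, charged fractions, pI, GRAVY, avECPA (mean
per-residue biosynthetic cost), and the turnover cost model
C_prot = N_aa * ln2 / T_half (residues/hour), C_total = C_prot * copies.
"""
from pathlib import Path

import ptaging as pt

seqs = pt.generate_sequences(5, (80, 200), seed=4)
costs = pt.read_cost_table(Path(pt.__file__).parent / "data" / "demo_costs.tsv")
df = pt.build_feature_table(seqs, costs=costs)
cols = ["length_aa", "frac_positive", "isoelectric_point", "gravy", "avECPA"]
print(df[cols].round(3).to_string())

c_prot, c_total = pt.compute_cost_model(length_aa=100, half_life_h=10, copy_number=1e4)
print(f"\n100-residue protein, 10 h half-life: C_prot = {c_prot:.3f} residues/h")
print(f"pool of 1e4 copies: C_total = {c_total:.1f} residues/h (x5 for ATP/h)")
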