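"""Conservation scoring and cross-homolog residue mapping.

Generates an alignment with a known conservation gradient, recovers the
per-column normalized-entropy scores, and maps a residue position across a
synthetic homolog pair that differ by a 7-residue indel — the same operation
used to transfer a disease mutation reported in one species onto another
species' numbering.
"""

import numpy as np

from chokepoint.conservation import align_pair, column_conservation, map_residue
from chokepoint.synthetic import make_msa

target = np.linspace(0, 1, 30)
msa = make_msa(100, target, seed=11)
recovered = column_conservation(msa).scores
r = np.corrcoef(target, recovered)[0, 1]
print(f"conservation recovery over 30 columns, 100 sequences: Pearson r = {r:.3f}")

rng = np.random.default_rng(99)
AA = "ACDEFGHIKLMNPQRSTVWY"
seq_a = "".join(rng.choice(list(AA), 300))
seq_b = seq_a[:100] + seq_a[107:]          # homolog lacking residues 101-107
residue_map = align_pair(seq_a, seq_b)
print(f"position 255 in homolog A maps to {map_residue(residue_map, 255)} in homolog B")
print(f"position  50 in homolog A maps to {map_residue(residue_map, 50)} in homolog B")
print("\nDownstream of the indel every position shifts by 7; the alignment "
      "recovers the correspondence automatically.")
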