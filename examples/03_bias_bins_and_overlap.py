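"""Bin maximum allelic biases and count cross-study overlap.

Three toy genes reported by up to three studies: the per-gene maximum
symmetric bias decides its 10-point bin and whether it clears the 70:30
canonical-imprinting threshold; the membership matrix counts how many
studies each (alias-merged) gene appears in.
"""

import pandas as pd

from poebias.bias import assign_bin, canonical_flag, max_bias
from poebias.overlap import build_membership, overlap_counts

per_tissue_paternal = {
    "Peg3": [96.0, 92.5, 97.0],   # strongly paternal everywhere
    "Herc3": [45.0, 40.7, 29.5],  # maternal (paternal share < 50)
    "Wars": [52.5, 55.1, 53.9],   # weak paternal
}
for gene, values in per_tissue_paternal.items():
    mb = max_bias(values)
    print(f"{gene:6s} max bias {mb.percent_preferred:5.1f}% ({mb.preferred_parent}), "
          f"bin {assign_bin(mb.percent_preferred)}, {canonical_flag(mb.percent_preferred)}")

calls = pd.DataFrame(
    [("Peg3", "A", "brain"), ("Peg3", "B", "brain"), ("Peg3", "C", "liver"),
     ("Herc3", "A", "brain"), ("Herc3", "B", "liver"),
     ("Wars", "C", "brain")],
    columns=["gene_id", "study", "tissue"],
)
matrix = build_membership(calls)
print("\nmembership matrix:\n", matrix.astype(int))
print("genes by number of studies:", overlap_counts(matrix)["degree"])
# Weakly biased genes being seen by a single study is the hallmark of the
# reproducibility problem this toolkit quantifies.
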