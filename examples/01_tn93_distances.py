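"""TN93 distances on an alignment of mixed-length fragments.

Builds a toy alignment in which one record is a 5'-anchored fragment
('?' marks unsequenced positions), computes the pairwise Tamura-Nei
distance matrix under pairwise deletion, and prints it. Distances are in
substitutions per site; the fragment still gets distances because only
the columns it shares with each partner are compared.
"""

import pandas as pd

from codiv import PartialAlignment, distance_matrix

aln = PartialAlignment.from_sequences(
    [
        ("hapA", "ACGTACGTACGTACGTACGTACGTACGTACGT"),
        ("hapB", "ACGTACGTACGTACTTACGTACGTACGAACGT"),  # 2 substitutions
        ("frag", "ACGTACGTACGTACGT????????????????"),  # 5' half only
    ]
)
dm = distance_matrix(aln)
print(pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels).round(4))
print()
print(
    "hapA-hapB compare over all 32 columns; frag only over its first 16,\n"
    "where it is identical to hapA and one transversion away from hapB."
)
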