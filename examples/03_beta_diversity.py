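"""Between-section community structure: Bray-Curtis, PCoA, dendrogram.

Distances are computed on per-section relative abundances (read ratios),
embedded with principal coordinates analysis, and clustered with UPGMA.
"""

from ednadiv import bray_curtis, load_table1_fixture, pcoa, upgma
from ednadiv.beta import nearest_neighbors

matrix, _ = load_table1_fixture()
dist = bray_curtis(matrix, use_relative=True)

res = pcoa(dist)
print("proportion of variation per PCoA axis:",
      [f"{p:.1%}" for p in res.proportions[:4]])
print(f"first three axes together: {res.proportion_explained(3):.2%} "
      f"({res.n_negative} negative eigenvalues reported, not corrected)")
print("\nsection coordinates on the first two axes:")
print(res.coordinates[["PCo1", "PCo2"]].round(3).to_string())

nn = nearest_neighbors(dist)
print("\nnearest neighbor per section:",
      ", ".join(f"{a}-{b}" for a, b in nn.items()))
print("\nUPGMA dendrogram (Newick):")
print(upgma(dist))
print(
    "Sections merging at low heights host similar fish communities; "
    "an axis proportion near two-thirds over three axes means most "
    "between-section structure is low-dimensional."
)
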