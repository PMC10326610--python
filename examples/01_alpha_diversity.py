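"""Per-section alpha diversity of the bundled river survey.

Loads the 97-species x 12-section eDNA count table and prints the five
alpha indices per section: Chao1 (estimated richness), Shannon H
(diversity), Simpson D (concentration: higher = less diverse), Pielou J
(evenness) and Good's coverage (fraction of reads from already-observed
species).
"""

from ednadiv import alpha_frame, load_table1_fixture

matrix, _ = load_table1_fixture()
table = alpha_frame(matrix)

print(table[["s_obs", "chao1", "shannon", "simpson", "pielou", "coverage"]]
      .round(4).to_string())

best = table["shannon"].idxmax()
worst = table["shannon"].idxmin()
print(
    f"\nMost diverse section by Shannon H: {best} "
    f"(H = {table.loc[best, 'shannon']:.3f}); least diverse: {worst} "
    f"(H = {table.loc[worst, 'shannon']:.3f})."
)
print(
    "A large gap between Chao1 and the observed richness S_obs would flag "
    "many undetected rare species; here the two nearly coincide because "
    "sequencing depth is high."
)
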