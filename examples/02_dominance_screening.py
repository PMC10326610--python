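"""McNaughton dominance screening of the bundled river survey.

The dominance index Y_i = (n_i / N) * f_i combines a species' share of
all reads with how many of the 12 sections it occupies; Y > 0.02 flags
species with extremely high relative sequence abundance.
"""

from ednadiv import load_table1_fixture, mcnaughton
from ednadiv.composition import dominance_summary

matrix, records = load_table1_fixture()
names = {r.taxon_id: r.species for r in records}

doms = mcnaughton(matrix, threshold=0.02)
print(f"{'species':<20} {'reads':>9} {'f':>6} {'Y':>11}")
for d in sorted(doms, key=lambda d: -d.y)[:8]:
    print(f"{names[d.taxon_id]:<20} {d.n_i:>9} {d.f_i:>6.3f} {d.y:>11.8f}"
          + ("  << dominant" if d.dominant else ""))

summary = dominance_summary(doms, records, "whole")[0]
print(
    f"\ndominant species: {', '.join(summary.dominant_species)}; "
    f"{summary.n_rheophilic} of {len(summary.dominant)} rheophilic "
    "(flowing-water guild F)"
)
print(
    "A community once dominated by flowing-water specialists now has a "
    f"rheophilic share of only {summary.rheophilic_share:.0%} among its "
    "dominant species — the signature of impoundment."
)
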