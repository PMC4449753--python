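"""Score a handful of species from per-sex motif codes and tabulate
pattern-type frequencies per clade.

Each species is classified from the union of its two sexes' pattern
components: mottling contributes an irregular component, bars/scales/spots a
regular one; both components together make the species bimodal, and a species
patterned in only one sex still counts as patterned.
"""

from plumevo import CharacterMatrix, Motif, SpeciesRecord, bimodal_sex_breakdown, tabulate_frequencies
from plumevo.characters import render_frequency_table

NONE = frozenset([Motif.NONE])
MOTTLE = frozenset([Motif.MOTTLE])
BAR = frozenset([Motif.BAR])
SPOT = frozenset([Motif.SPOT])
MIXED = frozenset([Motif.MOTTLE, Motif.BAR])

records = [
    # taxon, male motifs, female motifs  -> derived state
    SpeciesRecord("anas_one", BAR, MOTTLE),      # regular + irregular across sexes: bimodal
    SpeciesRecord("anas_two", SPOT, NONE),       # patterned in one sex only: regular
    SpeciesRecord("anas_three", NONE, NONE),     # uniform coloration
    SpeciesRecord("tetrao_one", MIXED, MIXED),   # both components in each sex: bimodal
    SpeciesRecord("tetrao_two", MOTTLE, MOTTLE), # irregular
    SpeciesRecord("tetrao_three", BAR, BAR),     # regular
]
for r in records:
    print(f"{r.taxon:14s} male={sorted(m.value for m in r.male)!s:20s} "
          f"female={sorted(m.value for m in r.female)!s:20s} -> {r.state.name}")

clade_map = {r.taxon: ("Demo", "Anatinae" if r.taxon.startswith("anas") else "Tetraoninae", "")
             for r in records}
matrix = CharacterMatrix(records, clade_map=clade_map)

print("\nPer-subfamily percentage of species in each pattern state"
      " (zeros rendered as '-'):")
print(render_frequency_table(tabulate_frequencies(matrix, "subfamily")))

same, one_sex, split = bimodal_sex_breakdown(matrix)
print(f"\nAmong bimodal species: {same:.0%} both sexes bimodal, "
      f"{one_sex:.0%} one sex bimodal, {split:.0%} regular in one sex and "
      f"irregular in the other.")
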