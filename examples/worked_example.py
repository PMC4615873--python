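"""Walk through the canonical path-extension example on a tiny k=4 graph.

The read AAGTCATAA has a sequencing artifact after its solid AAGTC
prefix. Four continuations exist at k-mer AGTC; the corrector prunes the
weak ones and picks the surviving path with the fewest changes.
"""

from readfix import correct_read, fig1_fixture, find_anchor, search_paths, select_path
from readfix.corrector import local_solid_mask, read_threshold

table, read, params = fig1_fixture()

print(f"read: {read.sequence}  (k = {params.k}, alpha = {params.alpha})")
sc = table.successor_counts("AGTC")
print(f"successor counts of AGTC: {sc}")
print(f"  -> t = max = {max(sc.values())}; the read's own continuation "
      f"GTCA has count {table.multiplicity('GTCA')} and is pruned")

h = read_threshold(read, table, params)
mask = local_solid_mask(read.sequence, table, h, params)
anchor = find_anchor(mask)
print(f"read-level threshold h(r) = {h:.1f}; anchor k-mers {anchor} "
      "(the solid AAGT/AGTC stretch)")

candidates = search_paths(read, anchor, "5to3", table, h, params, mask=mask)
print("surviving paths:")
for c in sorted(candidates, key=lambda c: len(c.corrections)):
    print(f"  {c.sequence}  corrections={len(c.corrections)} "
          f"min_count={c.min_multiplicity}")

best = select_path(candidates, read)
result = correct_read(read, table, params)
print(f"selected (minimum change): {best.sequence}")
print(f"corrected read: {result.corrected_sequence}  status={result.status}")
# The two-correction path wins over the four-correction one even though
# the latter runs through slightly higher counts.
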