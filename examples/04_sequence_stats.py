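"""Supermatrix utilities: concatenation, column filtering, G/C content.

Uses the synthetic study bundle's coding fragments to show per-taxon
G/C pooled over fragments, and a toy concatenation + filter.
"""

from phyloarb import (Alignment, FixtureSpec, concatenate, filter_columns,
                      gc_content, make_study_fixture)

bundle = make_study_fixture(FixtureSpec(seed=1))

pooled = {}
for taxon in bundle.tree_uniform.leaf_labels():
    seqs = [a.records[taxon] for a in bundle.fragments if taxon in a.records]
    pooled[taxon] = gc_content(seqs)
lo = min(pooled, key=pooled.get)
hi = max(pooled, key=pooled.get)
print(f"lowest  G/C: {lo} at {100 * pooled[lo]:.1f}%")
print(f"highest G/C: {hi} at {100 * pooled[hi]:.1f}%")
# the span mirrors the AT-rich vs GC-rich clades of the real amplicons.

# -- concatenation and column filtering -------------------------------------
f1 = Alignment({"t1": "ATG-GA", "t2": "ATGCGA", "t3": "AT--GA"}, name="f1")
f2 = Alignment({"t1": "CCTT", "t3": "CCTA"}, name="f2")
cat = concatenate([f1, f2])
print(f"\nconcatenated length: {cat.length}, fragments: {cat.fragments}")
print("t2 row (gap-padded where the fragment is missing):", cat.records["t2"])
filtered = filter_columns(cat, max_gap_fraction=0.34)
print(f"after dropping columns with >34% gaps: length {filtered.length}, "
      f"fragments {filtered.fragments}")
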