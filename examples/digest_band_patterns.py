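"""In silico DraI digestion and the two-site loss separating A2w from A6a.

A6a carries four TTTAAA sites (band pattern 47/108/63/191/420); two A->T
substitutions at amplicon positions 219 and 410 each turn a TTTAAA into
TTTTAA, removing two sites and yielding the A2w pattern 47/108/674.  Fragment
mass is conserved: both patterns sum to the 829-bp amplicon.
"""

from beemito import default_catalog
from beemito.digest import apply_variant_then_digest, digest, pattern_key

catalog = default_catalog()

for name in ("A6a", "A2w", "C1"):
    profile = digest(catalog.get(name).sequence)
    print(f"{name:4s}  {profile.n_sites} sites  pattern {pattern_key(profile)}"
          f"  (sum {sum(profile.fragments)} bp)")

a6a = catalog.get("A6a").sequence
converted = apply_variant_then_digest(a6a, [(219, "A", "T"), (410, "A", "T")])
print(f"\nA6a + TTTAAA->TTTTAA edits at 219 and 410 -> {converted.n_sites} sites,"
      f" pattern {pattern_key(converted)}")
print("matches A2w:", converted.fragments == digest(catalog.get("A2w").sequence).fragments)
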