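"""Architecture decomposition and naming of a never-seen haplotype.

A C1-derived sequence with one substitution is not identical to any reference,
so it becomes a novel mitotype: lineage from the best-matching reference,
name from the DraI band-pattern family plus the next free suffix letter.
"""

from beemito import default_catalog, locate_units
from beemito.architecture import Amplicon
from beemito.haplotyping import NovelNameRegistry, call_haplotype

catalog = default_catalog()

c1 = catalog.get("C1").sequence
mutant = c1[:199] + ("G" if c1[199] != "G" else "C") + c1[200:]

amplicon = Amplicon(sample_id="demo", sequence=mutant)
annotation = locate_units(amplicon, catalog.units)
print(f"architecture: P={annotation.p_variant}, Q copies={annotation.q_count}, "
      f"hint={annotation.lineage_hint}")

registry = NovelNameRegistry.from_catalog(catalog)
call = call_haplotype(amplicon, catalog, registry)
print(f"call: {call.haplotype} ({call.mode}), lineage {call.lineage}, "
      f"closest reference {call.matched_reference} at identity {call.identity:.4f}")
print(f"DraI pattern: {call.pattern}")
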