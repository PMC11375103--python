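"""Generate the packaged unit library and 14-haplotype reference catalog.

The published record never prints the unit consensus sequences, so the
packaged catalog is synthetic but structurally faithful (filenames/docstrings
label it as such): P0 is exactly 68 bp, Q is 196 bp, a C-type amplicon is
565 bp and a P0+2Q amplicon is 829 bp, so the A2w / A6a DraI band patterns
come out as the published 47/108/674 and 47/108/63/191/420 with A2w equal to
A6a after two A->T edits (TTTAAA -> TTTTAA) at amplicon positions 219 and 410.

Run from the repository root:  python scripts/build_default_catalog.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

from beemito.architecture import Amplicon, locate_units
from beemito.catalog import (
    Catalog,
    E2_PRIMER,
    H2_PRIMER_RC,
    ReferenceHaplotype,
    UnitLibrary,
    save_catalog,
    save_units,
)
from beemito.digest import digest
from beemito.simulate import apply_edits, build_amplicon

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "beemito" / "data"
MOTIF = "TTTAAA"
FORBIDDEN = (MOTIF, E2_PRIMER, H2_PRIMER_RC)

rng = np.random.default_rng(987_654_321)


def _rand(n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _clean(seq: str, allow_motif_at=()) -> bool:
    """No primers anywhere; TTTAAA only at the allowed 0-based positions."""
    for bad in (E2_PRIMER, H2_PRIMER_RC):
        if bad in seq:
            return False
    hits, i = [], seq.find(MOTIF)
    while i != -1:
        hits.append(i)
        i = seq.find(MOTIF, i + 1)
    return hits == sorted(allow_motif_at)


def make_unit(n: int, placements: dict, allow_motif_at=()) -> str:
    """Random unit with fixed GC caps at both ends (junction guard) and
    hard-coded placements; rejection-sampled until motif/primer-clean."""
    for _ in range(10_000):
        chars = list(_rand(n))
        chars[:3] = "CGC"
        chars[-3:] = "GCG"
        for pos, sub in placements.items():
            chars[pos : pos + len(sub)] = sub
        seq = "".join(chars)
        if _clean(seq, allow_motif_at):
            return seq
    raise RuntimeError("could not satisfy unit constraints")


def safe_sub(skeleton: str, pos: int) -> str:
    """A G/C substitution token at POS (G/C can never create TTTAAA)."""
    ref = skeleton[pos - 1]
    alt = "G" if ref != "G" else "C"
    return f"sub:{pos}:{ref}>{alt}"


def main() -> None:
    anchor5 = make_unit(80, {44: MOTIF}, allow_motif_at=[44])
    # Q carries near-site windows (one substitution each turns offsets 5-10,
    # 63-68 or 68-73, 1-based, into a DraI site), flanked by G/C guards so a
    # single TTTAAA -> TTTTAA edit removes a site instead of shifting it
    q = make_unit(196, {3: "GTTTAACG", 61: "GTTTAACTTAAAC"})
    p0 = make_unit(68, {})
    p = p0[:29] + p0[43:]  # 54 bp
    p1 = p0[:24] + p0[45:]  # 47 bp
    p2 = p0[:32] + p0[39:]  # 61 bp
    anchor3 = make_unit(289, {})
    for variant in (p, p1, p2):
        assert _clean(variant), "P-variant deletion created a forbidden motif"

    units = UnitLibrary(
        p_variants={"P0": p0, "P": p, "P1": p1, "P2": p2},
        q_consensus=q,
        anchor5=anchor5,
        anchor3=anchor3,
    )

    def skel(p_variant, q_count):
        parts = [anchor5]
        if p_variant:
            parts.append(units.p_variants[p_variant])
        parts.extend([q] * q_count)
        parts.append(anchor3)
        return "".join(parts)

    c_skel = skel(None, 1)
    a2_skel = skel("P0", 2)
    a1_skel = skel("P0", 1)
    p2q_skel = skel("P", 2)
    p1q_skel = skel("P", 1)

    c2_edits = [safe_sub(c_skel, 100), safe_sub(c_skel, 460)]
    # C2c: the single-cytosine deletion that separates it from C2
    del_pos = next(i + 1 for i in range(494, len(c_skel)) if c_skel[i] == "C")
    c2c_edits = c2_edits + [f"del:{del_pos}:C"]

    a6a_edits = ["sub:158:C>A", "sub:216:C>T", "sub:412:C>A"]
    a2w_edits = a6a_edits + ["sub:219:A>T", "sub:410:A>T"]

    spec = [
        # name, lineage, p_variant, q_count, accession, edits
        ("C1", "C", None, 1, "NC_001566", []),
        ("C2", "C", None, 1, "NC_061380.1", c2_edits),
        ("C2c", "C", None, 1, "MN_250878.1", c2c_edits),
        ("A1a", "A", "P0", 1, "KX463739", []),
        ("A1e", "A", "P0", 1, "MW677198", [safe_sub(a1_skel, 300)]),
        ("A4", "A", "P0", 2, "EF033650", [safe_sub(a2_skel, 350)]),
        ("A26", "A", "P", 0, "EF033651", [f"ins:134:{q[:130]}"]),
        ("A65", "A", "P0", 2, "MW677213", [safe_sub(a2_skel, 360), safe_sub(a2_skel, 600)]),
        ("A2w", "A", "P0", 2, "OY748522", a2w_edits),
        ("A6a", "A", "P0", 2, "OY748523", a6a_edits),
        ("M3", "M", "P", 2, "FJ743636.1", [safe_sub(p2q_skel, 200)]),
        ("M3a", "M", "P", 2, "KX463884", [safe_sub(p2q_skel, 200), safe_sub(p2q_skel, 210)]),
        ("M4", "M", "P", 1, "EF033656", [safe_sub(p1q_skel, 250)]),
        ("M79", "M", "P0", 2, "KX463882", [safe_sub(a2_skel, 250), safe_sub(a2_skel, 620)]),
    ]

    haplotypes = []
    for name, lineage, p_variant, q_count, accession, edits in spec:
        hap = ReferenceHaplotype(
            name=name,
            lineage=lineage,
            sequence="A",  # placeholder, replaced below
            p_variant=p_variant,
            q_count=q_count,
            source_accession=accession,
            edits=tuple(edits),
        )
        seq = build_amplicon(hap, units)
        haplotypes.append(
            ReferenceHaplotype(
                name=name,
                lineage=lineage,
                sequence=seq,
                p_variant=p_variant,
                q_count=q_count,
                source_accession=accession,
                edits=tuple(edits),
            )
        )

    catalog = Catalog(units=units, haplotypes=haplotypes)

    # --- consistency checks --------------------------------------------------
    seqs = [h.sequence for h in catalog]
    assert len(set(seqs)) == len(seqs), "haplotype sequences must be unique"
    for h in catalog:
        assert 550 <= len(h.sequence) <= 900, (h.name, len(h.sequence))
        assert E2_PRIMER not in h.sequence and H2_PRIMER_RC not in h.sequence
        ann = locate_units(Amplicon(h.name, h.sequence), units)
        assert (ann.p_variant, ann.q_count) == h.architecture, (
            h.name,
            ann.p_variant,
            ann.q_count,
        )
    assert digest(catalog.get("A2w").sequence).fragments == (47, 108, 674)
    assert digest(catalog.get("A6a").sequence).fragments == (47, 108, 63, 191, 420)
    assert len(catalog.get("C1").sequence) == 565
    assert len(catalog.get("A2w").sequence) == 829

    DATA_DIR.mkdir(parents=True, exist_ok=True)
    save_units(units, DATA_DIR / "units.fasta")
    save_catalog(catalog, DATA_DIR / "catalog.fasta", DATA_DIR / "catalog.tsv")
    print(f"wrote catalog with {len(catalog)} haplotypes to {DATA_DIR}")


if __name__ == "__main__":
    sys.exit(main())
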