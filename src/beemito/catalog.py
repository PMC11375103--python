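"""Reference catalog of named tRNAleu-COII haplotypes and the unit consensus library.

The intergenic region between the honey bee mitochondrial tRNA-Leu and COII
genes is a mosaic of two repeat units: a short P unit (~50-70 bp, in the
variants P0, P, P1 and P2 that differ by internal deletions) and a long Q unit
(~190-200 bp, present in one to several tandem copies).  C-lineage bees lack
the P unit and carry a single Q copy; A- and M-lineage bees carry a P variant
followed by a variable number of Q copies.  A named haplotype (mitotype) is a
specific full amplicon sequence; this module houses the library of unit
consensus sequences plus a catalog of named reference haplotypes, each stored
as its architecture (P variant, Q copy number) together with the list of
haplotype-defining edits against the architecture skeleton.

Catalog sequences are kept byte-exact: the packaged FASTA is reproducible from
``architecture skeleton + edits`` (see :func:`beemito.simulate.build_amplicon`),
which keeps the catalog and the synthetic generator mutually consistent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "E2_PRIMER",
    "H2_PRIMER",
    "H2_PRIMER_RC",
    "P_VARIANT_NAMES",
    "LINEAGES",
    "CatalogError",
    "AmbiguousPrimerError",
    "UnitLibrary",
    "ReferenceHaplotype",
    "Catalog",
    "load_units",
    "save_units",
    "load_catalog",
    "save_catalog",
    "default_catalog",
    "trim_to_amplicon",
]

#: Forward / reverse PCR primers delimiting the analysed amplicon (Garnery-style
#: E2/H2 pair).  H2 anneals on the reverse strand, so on the forward strand the
#: amplicon is followed by the reverse complement of H2.
E2_PRIMER = "GGCAGAATAAGTGCATTG"
H2_PRIMER = "CAATATCATTGATGACC"
H2_PRIMER_RC = str(Seq(H2_PRIMER).reverse_complement())

P_VARIANT_NAMES = ("P0", "P", "P1", "P2")
LINEAGES = ("A", "C", "M", "O", "Y")

_DNA = re.compile(r"^[ACGT]+$")
_DNA_N = re.compile(r"^[ACGTN]+$")

META_COLUMNS = ["name", "lineage", "p_variant", "q_count", "source_accession", "edits"]


class CatalogError(ValueError):
    """Raised when a catalog file pair is inconsistent or violates an invariant."""


class AmbiguousPrimerError(ValueError):
    """Raised when a primer sequence occurs more than once in a raw read."""


@dataclass(frozen=True)
class UnitLibrary:
    """Consensus sequences of the repeat units and the constant amplicon anchors.

    ``anchor5`` is the constant amplicon prefix (COI 3' end + tRNA-Leu) and
    ``anchor3`` the constant suffix (COII 5' start); between them sit the P and
    Q units.  A C-type amplicon is ``anchor5 + Q + anchor3``.
    """

    p_variants: dict  # variant name -> sequence
    q_consensus: str
    anchor5: str
    anchor3: str

    def __post_init__(self) -> None:
        for name in self.p_variants:
            if name not in P_VARIANT_NAMES:
                raise CatalogError(f"unknown P variant name {name!r}")
        for label, seq in self._all_sequences():
            if not _DNA.match(seq):
                raise CatalogError(f"unit {label} contains non-ACGT characters")
        p0 = self.p_variants.get("P0")
        if p0 is not None and len(p0) != 68:
            raise CatalogError(f"P0 must be 68 bp, got {len(p0)}")
        if not 190 <= len(self.q_consensus) <= 200:
            raise CatalogError(
                f"Q consensus must be 190-200 bp, got {len(self.q_consensus)}"
            )
        c_len = len(self.anchor5) + len(self.q_consensus) + len(self.anchor3)
        if not 550 <= c_len <= 650:
            raise CatalogError(
                f"C-type amplicon length {c_len} outside the expected 550-650 bp"
            )

    def _all_sequences(self):
        yield from self.p_variants.items()
        yield "Q", self.q_consensus
        yield "ANCHOR5", self.anchor5
        yield "ANCHOR3", self.anchor3


@dataclass(frozen=True)
class ReferenceHaplotype:
    """One named reference mitotype.

    ``p_variant``/``q_count`` declare the unit architecture; ``edits`` is the
    semicolon-split list of haplotype-defining edits (``sub:POS:R>A``,
    ``del:POS:R``, ``ins:POS:SEQ``, 1-based positions on the unedited
    architecture skeleton).
    """

    name: str
    lineage: str
    sequence: str
    p_variant: str | None
    q_count: int
    source_accession: str = ""
    edits: tuple = ()

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise CatalogError(f"{self.name}: unknown lineage {self.lineage!r}")
        if not _DNA.match(self.sequence):
            raise CatalogError(f"{self.name}: ambiguity codes not allowed in catalog")
        if self.p_variant is not None and self.p_variant not in P_VARIANT_NAMES:
            raise CatalogError(f"{self.name}: unknown P variant {self.p_variant!r}")
        if self.q_count < 0:
            raise CatalogError(f"{self.name}: negative q_count")
        if self.lineage == "C" and not (self.p_variant is None and self.q_count == 1):
            raise CatalogError(
                f"{self.name}: C-lineage haplotypes carry no P unit and exactly one Q"
            )

    @property
    def architecture(self) -> tuple:
        return (self.p_variant, self.q_count)


@dataclass
class Catalog:
    units: UnitLibrary
    haplotypes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [h.name for h in self.haplotypes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise CatalogError(f"duplicate haplotype names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self) -> Iterator[ReferenceHaplotype]:
        return iter(self.haplotypes)

    @property
    def names(self) -> list:
        return [h.name for h in self.haplotypes]

    def get(self, name: str) -> ReferenceHaplotype:
        for h in self.haplotypes:
            if h.name == name:
                return h
        raise KeyError(name)


# ---------------------------------------------------------------------------
# I/O


def load_units(path) -> UnitLibrary:
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    missing = {"Q", "ANCHOR5", "ANCHOR3"} - records.keys()
    if missing:
        raise CatalogError(f"unit FASTA {path} missing records: {sorted(missing)}")
    p_variants = {k: v for k, v in records.items() if k in P_VARIANT_NAMES}
    return UnitLibrary(
        p_variants=p_variants,
        q_consensus=records["Q"],
        anchor5=records["ANCHOR5"],
        anchor3=records["ANCHOR3"],
    )


def save_units(units: UnitLibrary, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=label, description="")
        for label, seq in units._all_sequences()
    ]
    SeqIO.write(recs, str(path), "fasta")


def _parse_meta(meta_path) -> dict:
    import csv

    rows = {}
    with open(meta_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(META_COLUMNS[:4]) <= set(
            reader.fieldnames
        ):
            raise CatalogError(
                f"catalog metadata {meta_path} must have columns {META_COLUMNS[:4]}"
            )
        for row in reader:
            name = row["name"]
            if name in rows:
                raise CatalogError(f"duplicate metadata row for {name!r}")
            rows[name] = row
    return rows


def load_catalog(fasta_path, meta_path, units_path=None) -> Catalog:
    """Load a haplotype catalog from a FASTA/TSV pair.

    Every FASTA record must have a metadata row carrying its lineage and
    declared architecture; haplotype order follows the FASTA.
    """
    if units_path is None:
        units_path = resources.files("beemito.data") / "units.fasta"
    units = load_units(units_path)
    meta = _parse_meta(meta_path)
    haplotypes = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = meta.get(rec.id)
        if row is None:
            raise CatalogError(f"FASTA record {rec.id!r} has no metadata row")
        p_variant = row["p_variant"] or None
        if p_variant in ("", ".", "none", "None"):
            p_variant = None
        edits = tuple(t for t in (row.get("edits") or "").split(";") if t and t != ".")
        haplotypes.append(
            ReferenceHaplotype(
                name=rec.id,
                lineage=row["lineage"],
                sequence=str(rec.seq).upper(),
                p_variant=p_variant,
                q_count=int(row["q_count"]),
                source_accession=(row.get("source_accession") or "").strip("."),
                edits=edits,
            )
        )
    return Catalog(units=units, haplotypes=haplotypes)


def save_catalog(catalog: Catalog, fasta_path, meta_path) -> None:
    """Write a catalog back to a FASTA/TSV pair (FASTA wrapped at 60 columns)."""
    recs = [
        SeqRecord(Seq(h.sequence), id=h.name, description="") for h in catalog
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
    lines = ["\t".join(META_COLUMNS)]
    for h in catalog:
        lines.append(
            "\t".join(
                [
                    h.name,
                    h.lineage,
                    h.p_variant or ".",
                    str(h.q_count),
                    h.source_accession or ".",
                    ";".join(h.edits) or ".",
                ]
            )
        )
    Path(meta_path).write_text("\n".join(lines) + "\n")


def default_catalog() -> Catalog:
    """The packaged catalog: the 14 haplotypes observed in the study population."""
    data = resources.files("beemito.data")
    return load_catalog(
        data / "catalog.fasta", data / "catalog.tsv", data / "units.fasta"
    )


# ---------------------------------------------------------------------------
# Primer trimming


def _find_once(seq: str, motif: str, label: str) -> int | None:
    first = seq.find(motif)
    if first == -1:
        return None
    if seq.find(motif, first + 1) != -1:
        raise AmbiguousPrimerError(f"primer {label} occurs more than once")
    return first


def trim_to_amplicon(raw: str) -> tuple:
    """Trim a raw read to the primer-delimited amplicon region.

    Returns ``(sequence, trimmed)``.  The region runs from the first base after
    the E2 forward primer through the last base before the reverse complement
    of the H2 reverse primer.  If neither primer is found the input is returned
    unchanged with ``trimmed=False``; a primer occurring more than once raises
    :class:`AmbiguousPrimerError`.
    """
    raw = raw.upper()
    start = _find_once(raw, E2_PRIMER, "E2")
    end = _find_once(raw, H2_PRIMER_RC, "H2(revcomp)")
    if start is None and end is None:
        return raw, False
    lo = 0 if start is None else start + len(E2_PRIMER)
    hi = len(raw) if end is None else end
    if hi <= lo:
        raise AmbiguousPrimerError("primers overlap or are out of order")
    return raw[lo:hi], True
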