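"""Assign amplicons to named mitotypes.

An amplicon that is identical (zero differences, indels included — the single
cytosine deletion separating C2c from C2 counts) to a catalog reference takes
that reference's name and lineage.  Anything else is a novel haplotype: its
lineage follows the best-matching reference (architecture is only logged as a
hint), its name is built from the lineage, the DraI band-pattern family of the
nearest catalog pattern, and the next unused lowercase suffix letter —
mirroring the pattern-based nomenclature used for names like A2w and A6a.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .architecture import Amplicon, ArchitectureAnnotation, locate_units
from .catalog import Catalog
from .digest import DigestProfile, digest, pattern_key

__all__ = [
    "HaplotypeCall",
    "NovelNameRegistry",
    "match_reference",
    "name_novel",
    "pattern_family",
    "call_haplotype",
]

#: per-fragment tolerance (bases) when matching a band pattern to a family
PATTERN_TOLERANCE = 5

_NAME_RE = re.compile(r"^([A-Z]+[0-9]+)([a-z]*)$")


@dataclass(frozen=True)
class HaplotypeCall:
    sample_id: str
    haplotype: str
    lineage: str
    mode: str  # "exact" | "novel"
    matched_reference: str | None
    identity: float
    pattern: str
    p_variant: str | None
    q_count: int
    lineage_hint: str

    def __post_init__(self) -> None:
        if self.mode == "exact" and self.identity != 1.0:
            raise ValueError("exact calls require identity 1.0")


class NovelNameRegistry:
    """Tracks issued haplotype names so novel names never collide.

    Also memoizes novel *sequences*: two bees carrying the same unnamed
    sequence are the same mitotype and must receive the same new name.
    """

    def __init__(self, used_names=()):
        self.used_names = set(used_names)
        self._by_sequence: dict = {}

    @classmethod
    def from_catalog(cls, catalog: Catalog) -> "NovelNameRegistry":
        return cls(catalog.names)

    def lookup_sequence(self, sequence: str):
        return self._by_sequence.get(sequence)

    def register(self, name: str, sequence: str | None = None) -> None:
        if name in self.used_names:
            raise ValueError(f"name {name!r} already issued")
        self.used_names.add(name)
        if sequence is not None:
            self._by_sequence[sequence] = name

    def max_index(self, lineage: str) -> int:
        best = 0
        for name in self.used_names:
            m = _NAME_RE.match(name)
            if m and m.group(1).rstrip("0123456789") == lineage:
                best = max(best, int(m.group(1)[len(lineage) :]))
        return best


def _suffixes():
    letters = "abcdefghijklmnopqrstuvwxyz"
    for a in letters:
        yield a
    for a in letters:
        for b in letters:
            yield a + b


def match_reference(amplicon: Amplicon, catalog: Catalog) -> tuple:
    """Best global-alignment match: ``(name, identity, is_exact)``.

    Identity is 1 - edit_distance / max(sequence lengths); ties on identity
    keep the first haplotype in catalog order.  N in the query never matches.
    """
    if len(catalog) == 0:
        raise ValueError("cannot match against an empty catalog")
    seq = amplicon.sequence
    best_name, best_identity = None, -1.0
    for ref in catalog:
        dist = edlib.align(seq, ref.sequence, mode="NW", task="distance")[
            "editDistance"
        ]
        identity = 1.0 - dist / max(len(seq), len(ref.sequence))
        if identity > best_identity:
            best_name, best_identity = ref.name, identity
    return best_name, best_identity, best_identity == 1.0


def family_base(name: str) -> str:
    """Strip the lowercase suffix: A1a -> A1, C2c -> C2, M79 -> M79."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"cannot parse haplotype name {name!r}")
    return m.group(1)


def pattern_family(
    profile: DigestProfile,
    catalog: Catalog,
    lineage: str,
    registry: NovelNameRegistry,
    tolerance: int = PATTERN_TOLERANCE,
) -> str:
    """Band-pattern family base for a novel haplotype.

    The profile is compared with the digest pattern of every catalog haplotype
    of the same lineage; a family matches when the fragment counts agree and
    every fragment is within ``tolerance`` bases.  With no match, a fresh
    numeric base (lineage + next free index) is opened.
    """
    frags = profile.fragments
    for ref in catalog:
        if ref.lineage != lineage:
            continue
        ref_frags = digest(ref.sequence).fragments
        if len(ref_frags) != len(frags):
            continue
        if all(abs(a - b) <= tolerance for a, b in zip(frags, ref_frags)):
            return family_base(ref.name)
    return f"{lineage}{registry.max_index(lineage) + 1}"


def name_novel(lineage: str, base: str, registry: NovelNameRegistry) -> str:
    """First unused name ``base + suffix`` with suffixes a..z, aa, ab, ...

    The name is registered before being returned.
    """
    for suffix in _suffixes():
        candidate = base + suffix
        if candidate not in registry.used_names:
            registry.register(candidate)
            return candidate
    raise RuntimeError(f"suffix space exhausted for family {base}")  # pragma: no cover


def call_haplotype(
    amplicon: Amplicon,
    catalog: Catalog,
    registry: NovelNameRegistry,
    min_identity: float = 0.80,
) -> HaplotypeCall:
    """Classify one amplicon: exact catalog match or a newly named mitotype."""
    annotation = locate_units(amplicon, catalog.units, min_identity=min_identity)
    profile = digest(amplicon)
    name, identity, is_exact = match_reference(amplicon, catalog)
    if is_exact:
        ref = catalog.get(name)
        return HaplotypeCall(
            sample_id=amplicon.sample_id,
            haplotype=name,
            lineage=ref.lineage,
            mode="exact",
            matched_reference=name,
            identity=1.0,
            pattern=pattern_key(profile),
            p_variant=annotation.p_variant,
            q_count=annotation.q_count,
            lineage_hint=annotation.lineage_hint,
        )
    lineage = catalog.get(name).lineage
    issued = registry.lookup_sequence(amplicon.sequence)
    if issued is None:
        base = pattern_family(profile, catalog, lineage, registry)
        issued = name_novel(lineage, base, registry)
        registry._by_sequence[amplicon.sequence] = issued
    return HaplotypeCall(
        sample_id=amplicon.sample_id,
        haplotype=issued,
        lineage=lineage,
        mode="novel",
        matched_reference=name,
        identity=identity,
        pattern=pattern_key(profile),
        p_variant=annotation.p_variant,
        q_count=annotation.q_count,
        lineage_hint=annotation.lineage_hint,
    )
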