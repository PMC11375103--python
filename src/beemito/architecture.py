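"""Decompose an amplicon into its P-unit variant and tandem Q-unit copies.

The scan is anchored: the constant 5' and 3' amplicon anchors are located
first, then the inter-anchor core is decomposed greedily 5'->3' — the best
P-variant match (if any) at the core start, followed by repeated matching of
the Q consensus left to right.  Matches are accepted when alignment identity
reaches ``min_identity`` (default 0.80) and the matched span length is within
+-15% of the consensus length; an incomplete Q remnant (as carried by the A26
mitotype) therefore does not count towards the Q copy number.

The architecture only *hints* at the lineage (no P and one Q is the C-lineage
signature); final lineage assignment belongs to reference matching, because
mitotypes such as M79 combine an A-typical P0 element with M-typical
restriction sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .catalog import UnitLibrary

__all__ = [
    "Amplicon",
    "ArchitectureAnnotation",
    "MalformedAmpliconError",
    "locate_units",
    "expected_length",
]

_DNA_N = re.compile(r"^[ACGTN]+$")

#: accepted relative deviation of a matched unit span from its consensus length
LENGTH_TOLERANCE = 0.15


class MalformedAmpliconError(ValueError):
    """Amplicon too short or otherwise unusable for unit decomposition."""


@dataclass(frozen=True)
class Amplicon:
    """A primer-delimited tRNAleu-COII sequence for one sampled bee."""

    sample_id: str
    sequence: str
    trimmed: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise MalformedAmpliconError(f"{self.sample_id}: empty sequence")
        if not _DNA_N.match(self.sequence):
            raise MalformedAmpliconError(
                f"{self.sample_id}: sequence contains characters outside ACGTN"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ArchitectureAnnotation:
    """Located P variant and ordered Q copies (1-based inclusive spans)."""

    p_variant: str | None
    p_span: tuple | None
    q_spans: tuple
    lineage_hint: str  # "C", "non-C" or "unknown"

    @property
    def q_count(self) -> int:
        return len(self.q_spans)

    def summary(self) -> str:
        p = self.p_variant or "none"
        return f"{p}+{self.q_count}Q"


def _identity(query: str, dist: int) -> float:
    return 1.0 - dist / len(query)


def _best_location(query: str, target: str):
    """Best infix alignment of query in target: (identity, start, end) 0-based incl."""
    if not target:
        return 0.0, None, None
    res = edlib.align(query, target, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return 0.0, None, None
    start, end = res["locations"][0]
    return _identity(query, res["editDistance"]), start, end


def locate_units(
    amplicon: Amplicon,
    units: UnitLibrary,
    min_identity: float = 0.80,
) -> ArchitectureAnnotation:
    if not 0.5 <= min_identity <= 1.0:
        raise ValueError("min_identity must lie in [0.5, 1.0]")
    seq = amplicon.sequence
    a5, a3 = units.anchor5, units.anchor3
    if len(seq) < len(a5) + len(a3):
        raise MalformedAmpliconError(
            f"{amplicon.sample_id}: amplicon shorter than the constant anchors"
        )

    # locate the constant anchors; fall back to nominal positions if degraded
    id5, _, end5 = _best_location(a5, seq[: len(a5) + 30])
    core_start = end5 + 1 if (end5 is not None and id5 >= 0.5) else len(a5)
    tail = seq[-(len(a3) + 30) :]
    id3, start3, _ = _best_location(a3, tail)
    if start3 is not None and id3 >= 0.5:
        core_end = len(seq) - len(tail) + start3
    else:
        core_end = len(seq) - len(a3)
    core = seq[core_start:core_end]

    # P variant: best identity within a window at the core start; ties to the
    # longer (more informative) variant
    p_variant = None
    p_span = None
    pos = 0
    if units.p_variants:
        max_p = max(len(v) for v in units.p_variants.values())
        window = core[: int(max_p * (1 + LENGTH_TOLERANCE)) + 20]
        best = None
        for name, consensus in units.p_variants.items():
            ident, start, end = _best_location(consensus, window)
            if start is None or ident < min_identity:
                continue
            span_len = end - start + 1
            if abs(span_len - len(consensus)) > LENGTH_TOLERANCE * len(consensus):
                continue
            key = (ident, len(consensus))
            if best is None or key > best[0]:
                best = (key, name, start, end)
        if best is not None:
            _, p_variant, start, end = best
            p_span = (core_start + start + 1, core_start + end + 1)
            pos = end + 1

    # greedy left-to-right tandem Q scan
    q = units.q_consensus
    qlen = len(q)
    q_spans = []
    while len(core) - pos >= qlen * (1 - LENGTH_TOLERANCE):
        window = core[pos : pos + int(qlen * (1 + LENGTH_TOLERANCE)) + 10]
        ident, start, end = _best_location(q, window)
        if start is None or ident < min_identity:
            break
        span_len = end - start + 1
        if abs(span_len - qlen) > LENGTH_TOLERANCE * qlen:
            break
        q_spans.append((core_start + pos + start + 1, core_start + pos + end + 1))
        pos += end + 1

    if p_variant is None and len(q_spans) == 1:
        hint = "C"
    elif p_variant is not None:
        hint = "non-C"
    else:
        hint = "unknown"
    return ArchitectureAnnotation(
        p_variant=p_variant,
        p_span=p_span,
        q_spans=tuple(q_spans),
        lineage_hint=hint,
    )


def expected_length(annotation: ArchitectureAnnotation, units: UnitLibrary) -> int:
    """Nominal amplicon length implied by an architecture (anchors + units)."""
    n = len(units.anchor5) + len(units.anchor3)
    if annotation.p_variant is not None:
        n += len(units.p_variants[annotation.p_variant])
    n += annotation.q_count * len(units.q_consensus)
    return n
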