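"""In silico DraI digestion of tRNAleu-COII amplicons.

DraI recognises the palindromic hexamer ``TTTAAA`` and cleaves bluntly between
the TTT and AAA half-sites.  Because the site is its own reverse complement a
single-strand scan of the forward strand finds every cut; the digest of the
reverse complement is simply the reversed fragment list.  All motif
occurrences are counted, including overlapping ones (possible inside longer
T/A runs), and a zero-site sequence digests to one full-length fragment.

Fragment-length patterns ("band patterns") are the basis of the classical
DraI PCR-RFLP mitotype nomenclature, so profiles are exported as a canonical
``/``-joined key in positional 5'->3' order, e.g. ``47/108/674``.

No partial-digest or star-activity behaviour is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DRAI_MOTIF",
    "DigestProfile",
    "EditError",
    "digest",
    "apply_variant_then_digest",
    "pattern_key",
]

DRAI_MOTIF = "TTTAAA"
_CUT_OFFSET = 3  # blunt cut between TTT and AAA


class EditError(ValueError):
    """An edit's reference base does not match the sequence."""


@dataclass(frozen=True)
class DigestProfile:
    """DraI cut positions and ordered fragment lengths for one amplicon.

    ``site_positions`` are the 1-based positions of the first T of each
    TTTAAA motif; ``cut_points`` are the 1-based positions after which the
    backbone is cleaved.  ``fragments`` always sums to the amplicon length and
    has one more entry than there are sites.
    """

    site_positions: tuple
    cut_points: tuple
    fragments: tuple

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)


def _sequence_of(amplicon) -> str:
    return getattr(amplicon, "sequence", amplicon).upper()


def digest(amplicon) -> DigestProfile:
    """Digest an :class:`~beemito.architecture.Amplicon` (or plain sequence)."""
    seq = _sequence_of(amplicon)
    if not seq:
        raise ValueError("cannot digest an empty sequence")
    sites = []
    i = seq.find(DRAI_MOTIF)
    while i != -1:
        sites.append(i)
        i = seq.find(DRAI_MOTIF, i + 1)  # overlapping occurrences all count
    cut_points = tuple(s + _CUT_OFFSET for s in sites)
    bounds = (0,) + cut_points + (len(seq),)
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestProfile(
        site_positions=tuple(s + 1 for s in sites),
        cut_points=cut_points,
        fragments=fragments,
    )


def apply_variant_then_digest(amplicon, edits) -> DigestProfile:
    """Apply single-base substitutions then digest.

    ``edits`` is an iterable of ``(position, ref, alt)`` with 1-based
    positions; each ref base is checked against the sequence first.  This is
    how a site loss such as TTTAAA -> TTTTAA is demonstrated.
    """
    seq = list(_sequence_of(amplicon))
    for pos, ref, alt in edits:
        if not 1 <= pos <= len(seq):
            raise EditError(f"edit position {pos} outside sequence")
        if seq[pos - 1] != ref.upper():
            raise EditError(
                f"ref mismatch at position {pos}: expected {ref}, found {seq[pos - 1]}"
            )
        seq[pos - 1] = alt.upper()
    return digest("".join(seq))


def pattern_key(profile: DigestProfile) -> str:
    """Canonical band-pattern key: fragment lengths joined 5'->3' by ``/``."""
    return "/".join(str(f) for f in profile.fragments)
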