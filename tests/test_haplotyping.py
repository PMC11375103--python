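"""Reference matching, novel naming and full haplotype calls."""

import numpy as np
import pytest

from beemito.architecture import Amplicon
from beemito.catalog import Catalog
from beemito.haplotyping import (
    NovelNameRegistry,
    call_haplotype,
    family_base,
    match_reference,
    name_novel,
)


def _amp(seq, sid="t"):
    return Amplicon(sample_id=sid, sequence=seq)


def _substitute(seq, positions, rng=None):
    chars = list(seq)
    for pos in positions:
        chars[pos] = {"A": "G", "C": "G", "G": "C", "T": "G"}[chars[pos]]
    return "".join(chars)


class TestMatchReference:
    def test_every_reference_matches_itself_exactly(self, catalog):
        for h in catalog:
            name, identity, exact = match_reference(_amp(h.sequence), catalog)
            assert (name, identity, exact) == (h.name, 1.0, True), h.name

    def test_single_base_deletion_separates_c2c_from_c2(self, catalog):
        """Indels count as differences: the C2c one-cytosine deletion."""
        c2c = catalog.get("C2c").sequence
        name, identity, exact = match_reference(_amp(c2c), catalog)
        assert (name, exact) == ("C2c", True)
        # against C2 itself the deletion costs exactly one edit
        c2 = catalog.get("C2").sequence
        assert len(c2) - len(c2c) == 1

    def test_substituted_sequence_is_near_but_not_exact(self, catalog):
        c1 = catalog.get("C1").sequence
        mutated = _substitute(c1, [50, 150, 250, 350, 450])
        name, identity, exact = match_reference(_amp(mutated), catalog)
        assert name == "C1"
        assert not exact
        assert identity == pytest.approx(1.0 - 5 / len(c1))

    def test_empty_catalog_is_a_configuration_error(self, catalog):
        empty = Catalog(units=catalog.units, haplotypes=[])
        with pytest.raises(ValueError):
            match_reference(_amp("ACGT" * 100), empty)


class TestNovelNaming:
    def test_family_base_strips_suffix(self):
        assert family_base("A1a") == "A1"
        assert family_base("C2c") == "C2"
        assert family_base("M79") == "M79"

    def test_next_letter_after_v_is_w(self):
        registry = NovelNameRegistry({"A2" + s for s in "abcdefghijklmnopqrstuv"})
        assert name_novel("A", "A2", registry) == "A2w"

    def test_first_suffix_is_a(self):
        assert name_novel("A", "A6", NovelNameRegistry()) == "A6a"
        assert name_novel("C", "C9", NovelNameRegistry()) == "C9a"

    def test_suffixes_continue_aa_after_z(self):
        used = {"M1" + s for s in "abcdefghijklmnopqrstuvwxyz"}
        registry = NovelNameRegistry(used)
        assert name_novel("M", "M1", registry) == "M1aa"

    def test_issued_names_are_registered(self):
        registry = NovelNameRegistry()
        first = name_novel("A", "A2", registry)
        second = name_novel("A", "A2", registry)
        assert first == "A2a" and second == "A2b"


class TestCallHaplotype:
    def test_exact_call_carries_catalog_lineage(self, catalog):
        registry = NovelNameRegistry.from_catalog(catalog)
        call = call_haplotype(_amp(catalog.get("C1").sequence), catalog, registry)
        assert call.haplotype == "C1"
        assert call.lineage == "C"
        assert call.mode == "exact"
        assert call.identity == 1.0

    def test_all_catalog_sequences_self_classify(self, catalog):
        registry = NovelNameRegistry.from_catalog(catalog)
        for h in catalog:
            call = call_haplotype(_amp(h.sequence, h.name), catalog, registry)
            assert (call.haplotype, call.mode) == (h.name, "exact")

    def test_one_substitution_off_c1_is_a_novel_c_haplotype(self, catalog):
        c1 = catalog.get("C1").sequence
        mutated = _substitute(c1, [200])  # no DraI site touched (G/C substitution)
        registry = NovelNameRegistry.from_catalog(catalog)
        call = call_haplotype(_amp(mutated), catalog, registry)
        assert call.mode == "novel"
        assert call.lineage == "C"
        assert call.haplotype == "C1a"  # same band family as C1, first free letter
        assert call.haplotype not in catalog.names
        assert call.matched_reference == "C1"

    def test_same_novel_sequence_gets_the_same_name(self, catalog):
        mutated = _substitute(catalog.get("C1").sequence, [200])
        registry = NovelNameRegistry.from_catalog(catalog)
        first = call_haplotype(_amp(mutated, "b1"), catalog, registry)
        second = call_haplotype(_amp(mutated, "b2"), catalog, registry)
        assert first.haplotype == second.haplotype

    def test_distinct_novel_sequences_get_distinct_names(self, catalog):
        registry = NovelNameRegistry.from_catalog(catalog)
        seqs = [
            _substitute(catalog.get("C1").sequence, [pos]) for pos in (200, 210, 220)
        ]
        names = {call_haplotype(_amp(s), catalog, registry).haplotype for s in seqs}
        assert len(names) == 3
        assert names.isdisjoint(set(catalog.names))

    def test_calls_are_deterministic(self, catalog):
        mutated = _substitute(catalog.get("M3").sequence, [300])
        calls = []
        for _ in range(2):
            registry = NovelNameRegistry.from_catalog(catalog)
            calls.append(call_haplotype(_amp(mutated), catalog, registry))
        assert calls[0] == calls[1]
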