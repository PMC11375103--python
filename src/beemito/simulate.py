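"""Synthetic amplicon populations with truth labels.

The generator rebuilds each reference haplotype from its architecture skeleton
(anchor5 + P variant + q_count Q copies + anchor3) plus its catalog-declared
edits, attaches the E2/H2 primers, and emits populations with year/province
metadata and coordinates.  The default composition replicates the study
population: 1143 bees, 14 mitotypes (C1 989, C2 124, C2c 2; A-lineage A1a 5,
A1e 3, A4 2, A26 1, A65 1, A2w 2, A6a 1; M-lineage M3 1, M3a 8, M4 3, M79 1)
sampled over 2020/2021/2022 (94/588/461) across nine provinces.

Optional per-sequence random substitutions (Poisson with mean
``mutation_rate``) are applied only between the primers, never inside them,
so trimming always succeeds and tests exercise classification rather than
primer robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .architecture import Amplicon
from .catalog import (
    Catalog,
    E2_PRIMER,
    H2_PRIMER_RC,
    ReferenceHaplotype,
    UnitLibrary,
)

__all__ = [
    "STUDY_COMPOSITION",
    "STUDY_YEAR_ALLOCATION",
    "PROVINCE_YEAR_COUNTS",
    "PROVINCE_BBOXES",
    "CompositionSpec",
    "SyntheticPopulation",
    "BuildError",
    "apply_edits",
    "build_amplicon",
    "generate_population",
    "study_spec",
    "write_population",
]


class BuildError(ValueError):
    """Architecture / edit list inconsistent with the unit library."""


#: per-haplotype counts of the study population (total 1143)
STUDY_COMPOSITION = {
    "C1": 989,
    "C2": 124,
    "C2c": 2,
    "A1a": 5,
    "A1e": 3,
    "A4": 2,
    "A26": 1,
    "A65": 1,
    "A2w": 2,
    "A6a": 1,
    "M3": 1,
    "M3a": 8,
    "M4": 3,
    "M79": 1,
}

#: how each haplotype's count distributes over sampling years; column sums per
#: reporting group match the published year-by-mitotype table (C1 80/511/398,
#: C2 9/65/52, M 3/6/4, A 2/6/7).  A6a was sampled in 2020 and both A2w bees
#: in 2021; the remaining splits are this package's deterministic choice.
STUDY_YEAR_ALLOCATION = {
    "C1": {2020: 80, 2021: 511, 2022: 398},
    "C2": {2020: 9, 2021: 63, 2022: 52},
    "C2c": {2020: 0, 2021: 2, 2022: 0},
    "A1a": {2020: 1, 2021: 2, 2022: 2},
    "A1e": {2020: 0, 2021: 1, 2022: 2},
    "A4": {2020: 0, 2021: 1, 2022: 1},
    "A26": {2020: 0, 2021: 0, 2022: 1},
    "A65": {2020: 0, 2021: 0, 2022: 1},
    "A2w": {2020: 0, 2021: 2, 2022: 0},
    "A6a": {2020: 1, 2021: 0, 2022: 0},
    "M3": {2020: 0, 2021: 0, 2022: 1},
    "M3a": {2020: 2, 2021: 4, 2022: 2},
    "M4": {2020: 0, 2021: 2, 2022: 1},
    "M79": {2020: 1, 2021: 0, 2022: 0},
}

#: bees analysed per province and year
PROVINCE_YEAR_COUNTS = {
    "PC": {2020: 13, 2021: 48, 2022: 115},
    "PR": {2020: 19, 2021: 107, 2022: 87},
    "RE": {2020: 5, 2021: 36, 2022: 25},
    "MO": {2020: 3, 2021: 30, 2022: 0},
    "BO": {2020: 29, 2021: 65, 2022: 56},
    "FE": {2020: 11, 2021: 0, 2022: 5},
    "RA": {2020: 4, 2021: 67, 2022: 6},
    "FC": {2020: 3, 2021: 166, 2022: 145},
    "RN": {2020: 7, 2021: 69, 2022: 22},
}

#: rare mitotypes reported from Piacenza apiaries
_FORCED_PROVINCE = {"A2w": "PC", "A6a": "PC", "A26": "PC", "M79": "PC"}

#: approximate administrative bounding boxes (lon_min, lon_max, lat_min,
#: lat_max, decimal degrees) used only to draw synthetic coordinates
PROVINCE_BBOXES = {
    "PC": (9.20, 10.10, 44.55, 45.10),
    "PR": (9.85, 10.50, 44.35, 45.05),
    "RE": (10.30, 10.90, 44.25, 44.95),
    "MO": (10.55, 11.25, 44.15, 44.95),
    "BO": (10.95, 11.85, 44.05, 44.80),
    "FE": (11.25, 12.30, 44.55, 44.98),
    "RA": (11.50, 12.40, 44.10, 44.62),
    "FC": (11.75, 12.50, 43.75, 44.35),
    "RN": (12.20, 12.80, 43.72, 44.15),
}


@dataclass(frozen=True)
class CompositionSpec:
    """Which haplotypes to emit, how many of each, and with what metadata."""

    entries: dict
    seed: int = 0
    mutation_rate: float = 0.0
    year_allocation: dict | None = None  # haplotype -> {year: count}
    province_year_counts: dict | None = None

    def total(self) -> int:
        return sum(self.entries.values())


@dataclass
class SyntheticPopulation:
    amplicons: list
    truth: pd.DataFrame

    def __len__(self) -> int:
        return len(self.amplicons)


def study_spec(seed: int = 42, mutation_rate: float = 0.0) -> CompositionSpec:
    """The study-replica composition (1143 bees, 14 mitotypes, 3 years)."""
    return CompositionSpec(
        entries=dict(STUDY_COMPOSITION),
        seed=seed,
        mutation_rate=mutation_rate,
        year_allocation={k: dict(v) for k, v in STUDY_YEAR_ALLOCATION.items()},
        province_year_counts={k: dict(v) for k, v in PROVINCE_YEAR_COUNTS.items()},
    )


# ---------------------------------------------------------------------------
# Sequence construction


def parse_edit(token: str) -> tuple:
    parts = token.split(":")
    try:
        op = parts[0]
        pos = int(parts[1])
        if op == "sub":
            ref, alt = parts[2].split(">")
            return ("sub", pos, ref, alt)
        if op == "del":
            return ("del", pos, parts[2], None)
        if op == "ins":
            return ("ins", pos, None, parts[2])
    except (IndexError, ValueError) as exc:
        raise BuildError(f"malformed edit token {token!r}") from exc
    raise BuildError(f"unknown edit op in {token!r}")


def apply_edits(sequence: str, edits) -> str:
    """Apply edit tokens (1-based positions on the *unedited* sequence).

    Edits are applied right-to-left so earlier positions stay valid;
    ``ins:POS:SEQ`` inserts after POS, ``del:POS:R`` removes the (checked)
    base at POS.
    """
    parsed = sorted((parse_edit(t) for t in edits), key=lambda e: e[1], reverse=True)
    seq = sequence
    for op, pos, ref, alt in parsed:
        if not 0 <= pos <= len(seq):
            raise BuildError(f"edit position {pos} outside sequence")
        if op in ("sub", "del"):
            if seq[pos - 1] != ref:
                raise BuildError(
                    f"edit ref mismatch at {pos}: expected {ref}, found {seq[pos - 1]}"
                )
        if op == "sub":
            seq = seq[: pos - 1] + alt + seq[pos:]
        elif op == "del":
            seq = seq[: pos - 1] + seq[pos:]
        else:  # ins
            seq = seq[:pos] + alt + seq[pos:]
    return seq


def build_amplicon(haplotype: ReferenceHaplotype, units: UnitLibrary) -> str:
    """Rebuild a reference amplicon from its skeleton and defining edits."""
    if haplotype.p_variant is not None and haplotype.p_variant not in units.p_variants:
        raise BuildError(
            f"{haplotype.name}: P variant {haplotype.p_variant} not in the library"
        )
    parts = [units.anchor5]
    if haplotype.p_variant is not None:
        parts.append(units.p_variants[haplotype.p_variant])
    parts.extend([units.q_consensus] * haplotype.q_count)
    parts.append(units.anchor3)
    return apply_edits("".join(parts), haplotype.edits)


# ---------------------------------------------------------------------------
# Population generation


def _assign_metadata(spec: CompositionSpec, order: list, rng) -> pd.DataFrame:
    """Deterministic year/province assignment honouring the per-year plans."""
    n = len(order)
    if spec.year_allocation:
        years = []
        for hap, _ in order:
            alloc = spec.year_allocation[hap]
            year = next(y for y in sorted(alloc) if alloc[y] > 0)
            alloc[year] -= 1
            years.append(year)
    else:
        years = [2021] * n

    provinces = [None] * n
    if spec.province_year_counts:
        for year in sorted(set(years)):
            idx = [i for i in range(n) if years[i] == year]
            pool = []
            for prov in PROVINCE_BBOXES:
                pool.extend([prov] * spec.province_year_counts[prov].get(year, 0))
            if len(pool) != len(idx):
                raise BuildError(
                    f"province plan for {year} covers {len(pool)} bees, need {len(idx)}"
                )
            # records of Piacenza-reported rare mitotypes take PC slots first
            forced = [i for i in idx if _FORCED_PROVINCE.get(order[i][0]) == "PC"]
            for i in forced:
                if "PC" in pool:
                    pool.remove("PC")
                    provinces[i] = "PC"
            rest = [i for i in idx if provinces[i] is None]
            # random assignment keeps mitotypes geographically unstructured
            # while preserving the per-province margins exactly
            pool = [pool[j] for j in rng.permutation(len(pool))]
            for i, prov in zip(rest, pool):
                provinces[i] = prov
    else:
        provinces = [list(PROVINCE_BBOXES)[0]] * n

    lons, lats = [], []
    for prov in provinces:
        lo_x, hi_x, lo_y, hi_y = PROVINCE_BBOXES[prov]
        lons.append(float(rng.uniform(lo_x, hi_x)))
        lats.append(float(rng.uniform(lo_y, hi_y)))
    return pd.DataFrame(
        {
            "year": years,
            "province": provinces,
            "longitude": np.round(lons, 5),
            "latitude": np.round(lats, 5),
        }
    )


def _mutate(seq: str, lo: int, hi: int, n_subs: int, rng) -> str:
    """Apply n random substitutions within seq[lo:hi] (0-based half-open)."""
    if n_subs == 0 or hi <= lo:
        return seq
    chars = list(seq)
    positions = rng.choice(np.arange(lo, hi), size=min(n_subs, hi - lo), replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def generate_population(
    spec: CompositionSpec, catalog: Catalog, with_primers: bool = True
) -> SyntheticPopulation:
    """Emit exactly the requested per-haplotype counts, deterministically.

    Output reads carry the E2/H2 primers when ``with_primers`` (the
    classification pipeline then exercises trimming); random substitutions
    (Poisson, mean ``mutation_rate`` per sequence) never touch the primers.
    """
    unknown = set(spec.entries) - set(catalog.names)
    if unknown:
        raise BuildError(f"spec names absent from the catalog: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    order = []
    for hap in catalog.names:
        count = spec.entries.get(hap, 0)
        if count < 0:
            raise BuildError(f"negative count for {hap}")
        order.extend([(hap, k) for k in range(count)])

    if not order:
        return SyntheticPopulation(
            amplicons=[],
            truth=pd.DataFrame(
                columns=[
                    "sample_id",
                    "haplotype",
                    "lineage",
                    "year",
                    "province",
                    "longitude",
                    "latitude",
                ]
            ),
        )

    meta = _assign_metadata(spec, order, rng)
    base_seqs = {h.name: build_amplicon(h, catalog.units) for h in catalog}
    amplicons, rows = [], []
    for i, (hap, _) in enumerate(order):
        sample_id = f"HB{i + 1:04d}"
        core = base_seqs[hap]
        if spec.mutation_rate > 0:
            core = _mutate(core, 0, len(core), int(rng.poisson(spec.mutation_rate)), rng)
        seq = E2_PRIMER + core + H2_PRIMER_RC if with_primers else core
        amplicons.append(Amplicon(sample_id=sample_id, sequence=seq, trimmed=not with_primers))
        rows.append(
            {
                "sample_id": sample_id,
                "haplotype": hap,
                "lineage": catalog.get(hap).lineage,
                "year": int(meta.loc[i, "year"]),
                "province": meta.loc[i, "province"],
                "longitude": float(meta.loc[i, "longitude"]),
                "latitude": float(meta.loc[i, "latitude"]),
            }
        )
    return SyntheticPopulation(amplicons=amplicons, truth=pd.DataFrame(rows))


def write_population(pop: SyntheticPopulation, fasta_path, truth_path) -> None:
    with open(fasta_path, "w") as fh:
        for amp in pop.amplicons:
            fh.write(f">{amp.sample_id}\n")
            for i in range(0, len(amp.sequence), 60):
                fh.write(amp.sequence[i : i + 60] + "\n")
    pop.truth.to_csv(truth_path, sep="\t", index=False, na_rep=".")
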