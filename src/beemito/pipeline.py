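"""End-to-end helpers: FASTA/amplicons -> calls table -> summaries."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .architecture import Amplicon, MalformedAmpliconError
from .catalog import Catalog, default_catalog, trim_to_amplicon
from .haplotyping import NovelNameRegistry, call_haplotype
from .popstats import (
    FrequencyTable,
    fisher_exact_mc,
    frequency_table,
    haplotype_diversity,
)

__all__ = ["read_amplicons", "classify_amplicons", "classify_fasta", "summarize_calls"]

CALL_COLUMNS = [
    "sample_id",
    "haplotype",
    "lineage",
    "mode",
    "matched_reference",
    "identity",
    "pattern",
    "p_variant",
    "q_count",
    "lineage_hint",
]


def read_amplicons(fasta_path, skip_bad: bool = False):
    """Parse a FASTA of raw reads, trimming primers; yields Amplicon objects."""
    skipped = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        try:
            seq, trimmed = trim_to_amplicon(str(rec.seq))
            yield Amplicon(sample_id=rec.id, sequence=seq, trimmed=trimmed)
        except (MalformedAmpliconError, ValueError):
            if not skip_bad:
                raise
            skipped.append(rec.id)
    if skipped:
        import sys

        print(f"warning: skipped {len(skipped)} malformed records", file=sys.stderr)


def classify_amplicons(amplicons, catalog: Catalog | None = None) -> pd.DataFrame:
    """Call every amplicon; returns one row per record (shared novel registry)."""
    if catalog is None:
        catalog = default_catalog()
    registry = NovelNameRegistry.from_catalog(catalog)
    rows = []
    for amp in amplicons:
        if not amp.trimmed:
            seq, trimmed = trim_to_amplicon(amp.sequence)
            amp = Amplicon(sample_id=amp.sample_id, sequence=seq, trimmed=trimmed)
        call = call_haplotype(amp, catalog, registry)
        rows.append({k: getattr(call, k) for k in CALL_COLUMNS})
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def classify_fasta(
    fasta_path, catalog: Catalog | None = None, skip_bad: bool = False
) -> pd.DataFrame:
    return classify_amplicons(read_amplicons(fasta_path, skip_bad=skip_bad), catalog)


def summarize_calls(
    calls: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    by: str = "year",
    level: str = "lineage-grouped",
    n_resamples: int = 100_000,
    seed: int = 1,
) -> tuple:
    """Frequency table plus headline statistics.

    Returns ``(FrequencyTable, stats dict)`` where stats carries both H
    variants (from full-resolution haplotype counts), and — when the table has
    at least two strata — the Monte-Carlo Fisher p for differentiation across
    strata.  The headline H is the uncorrected value; the corrected one is the
    footnote.
    """
    if meta is not None:
        # the calls table owns haplotype/lineage; take only new columns from meta
        extra = ["sample_id"] + [c for c in meta.columns if c not in calls.columns]
        merged = calls.merge(
            meta[extra], on="sample_id", how="left", validate="one_to_one"
        )
        orphans = merged[merged[by].isna()]["sample_id"].tolist() if by in merged else []
        if by not in merged.columns or orphans:
            raise ValueError(f"metadata join failed for: {orphans[:5]}")
    else:
        merged = calls
    table = frequency_table(merged, by=by, level=level)
    hap_counts = merged["haplotype"].value_counts().to_numpy()
    stats = {
        "N": int(len(merged)),
        "n_haplotypes": int(merged["haplotype"].nunique()),
        "H_uncorrected": haplotype_diversity(hap_counts, corrected=False).H,
        "H_corrected": haplotype_diversity(hap_counts, corrected=True).H
        if len(merged) > 1
        else 0.0,
    }
    if len(table.strata) >= 2 and len(table.categories) >= 2:
        test = fisher_exact_mc(table, n_resamples=n_resamples, seed=seed)
        stats.update(
            fisher_p=test.p_value,
            fisher_method=test.method,
            n_resamples=test.n_resamples,
            seed=test.seed,
        )
    return table, stats
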