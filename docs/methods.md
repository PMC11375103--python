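# Methods

## The marker and the model

The COI–COII (tRNAleu–COII) intergenic region of the honey bee mitochondrial
genome is modelled as a linear mosaic:

    anchor5 · [P variant] · Q × q_count · anchor3

where `anchor5` is the constant amplicon prefix (COI 3' end + tRNA-Leu),
`anchor3` the constant suffix (COII 5' start), the P unit is one of four
variants (P0, 68 bp; P, 54 bp; P1, 47 bp; P2, 61 bp — P/P1/P2 are P0 with
internal deletions of 14/21/7 bp) and the Q unit is a 196-bp element present
in 0–n tandem copies. C-lineage mitotypes have no P unit and exactly one Q;
all other lineages carry a P variant and a variable Q copy number. A named
mitotype is one concrete amplicon sequence; mitotypes differ by unit
architecture plus point edits (substitutions, single-base deletions,
truncated-unit insertions).

Amplicons are delimited by the E2 (forward) and H2 (reverse) primers; on the
forward strand the amplicon ends where the reverse complement of H2 begins.
Trimming demands each primer occur at most once; reads without primer hits
pass through unchanged but flagged.

## The packaged reference catalog is synthetic

The unit consensus sequences are not public, so the packaged library
(`src/beemito/data/`, generated by `scripts/build_default_catalog.py` with a
fixed RNG seed) is a **synthetic stand-in** with the published structure:

- P0 is exactly 68 bp; Q is 196 bp; a C-type amplicon is 565 bp and a P0+2Q
  amplicon 829 bp, inside the observed 550–900 bp envelope.
- Each unit starts/ends with fixed G/C bases so unit junctions can never form
  a DraI site, and units are rejection-sampled to contain no primer hits and
  no unintended `TTTAAA`.
- `anchor5` carries one constant DraI site (cut after amplicon position 47);
  the Q consensus carries G/C-guarded near-sites that single substitutions
  convert into true sites. The A6a reference uses three such edits to carry
  four sites with band pattern `47/108/63/191/420`; A2w is A6a plus two A→T
  edits at amplicon positions 219 and 410 that each turn `TTTAAA` into
  `TTTTAA`, leaving two sites and the pattern `47/108/674`. Fragment sums are
  conserved (829 bp), as in the published patterns.
- The 14 catalog haplotypes (C1, C2, C2c; A1a, A1e, A4, A26, A65, A2w, A6a;
  M3, M3a, M4, M79) are all rebuilt byte-for-byte from
  `architecture skeleton + declared edits`, which keeps the catalog and the
  synthetic generator mutually consistent by construction. C2c is C2 with a
  single cytosine deletion. A26 carries the P unit and *no complete* Q: it is
  modelled as P plus a 130-bp truncated Q insertion, which the unit scanner
  rejects by length, so its q_count is 0 while its amplicon (553 bp) stays in
  the printed envelope. M79 combines the A-typical P0 element with the
  M-typical restriction pattern — which is why lineage is never inferred from
  architecture alone.

Consequence for interpretation: tests passing on this catalog demonstrate the
*algorithms* (decomposition, digestion, identity matching, naming, statistics)
under realistic structure; they do not validate against the real deposited
sequences (ENA OY748522/OY748523), which users can substitute via
`load_catalog` with their own FASTA/TSV pair.

## Unit decomposition

`locate_units` aligns the anchors (edlib, infix mode), then scans the
inter-anchor core greedily 5'→3':

- **P variant**: each variant consensus is aligned within a window at the core
  start; accepted at identity ≥ `min_identity` (default **0.80**) and span
  within **±15 %** of the consensus length; the highest-identity variant wins,
  ties going to the longer (more informative) variant. Because variants are
  nested deletions, the true variant always scores identity 1.0 and wins.
- **Q copies**: the Q consensus is matched repeatedly left-to-right in a
  sliding window of 1.3×|Q|; the same identity/length acceptance applies;
  scanning stops at the first rejection. A 130-bp partial Q fails the length
  rule — this is the operational definition of "not a complete Q element".

The thresholds are this package's choice (none are published): loose enough
to absorb haplotype-defining SNPs, tight enough to reject anchor sequence and
partial units. Identity is `1 − edit_distance/|consensus|`.

`lineage_hint` is C iff no P was accepted and exactly one Q was; it is never
used for the final lineage call (M79 precedent).

## DraI digestion

Every occurrence of the palindromic `TTTAAA` on the forward strand is a site
(overlaps counted); cleavage is blunt between TTT and AAA — the published
fragment sums (47+108+674 = 47+108+63+191+420 = 829) force the within-motif
cut, which is also the canonical enzyme chemistry. Band-pattern keys preserve
positional 5'→3' order rather than gel-sorted order; the published A2w
pattern (47/108/674, neither ascending nor descending) is consistent with
positional order. Reverse-complement symmetry (digest of the reverse
complement = reversed fragments) is a tested property. No partial digestion
or star activity is modelled.

## Haplotype assignment and novel naming

Identity to a reference is global (Needleman–Wunsch) edit distance over the
trimmed amplicon; **exact** means zero differences, indels included, which is
what separates C2c from C2. Terminal sequencing overhangs are not specially
excluded: the catalog and generator always produce full-length amplicons, so
end-trimming heuristics would be untestable here; real ragged-end Sanger
reads should be quality-trimmed upstream (known limitation).

Non-exact sequences become novel mitotypes:

- **Lineage** follows the best-matching reference (ties to catalog order),
  never the architecture hint.
- **Family base**: the band pattern is compared with every same-lineage
  catalog pattern; a family matches when fragment counts agree and each
  fragment is within ±5 bp. With no match, a new numeric base
  (lineage + next free index) is opened. The full naming criteria are
  defined across the mitotype-nomenclature literature; this rule set is this
  package's explicit operationalization.
- **Suffix**: first unused letter a–z, continuing aa, ab, … The registry
  memoizes novel sequences, so identical novel sequences in one run share one
  name (the published A2w was observed in two bees).

## Population statistics

- **Haplotype diversity**: `H = 1 − Σ xᵢ²`, optionally × N/(N−1). Both
  variants are exposed because the published formula carries the correction
  while the published value (0.239) equals the *uncorrected* statistic at
  full 14-haplotype resolution (the corrected value is 0.2397, printing as
  0.240); the headline summary reports the uncorrected value and footnotes
  the corrected one.
- **Fisher exact test**: 2×2 tables are enumerated exactly (two-sided,
  table-probability criterion; cross-checked against an independent
  enumeration oracle and scipy). r×c tables use conditional Monte Carlo:
  resampled tables with both margins fixed (sequential multivariate
  hypergeometric rows), a resample counting as extreme when its null
  probability ≤ the observed table's, with the add-one correction
  p = (1+k)/(B+1) so p is never 0. The seed is a required, logged parameter;
  default B = 100,000. With N = 1143 full network enumeration is unnecessary.
- **Logistic regression** (presence/absence vs longitude): statsmodels GLM
  (binomial), i.e. IRLS, with the 1-df likelihood-ratio χ² against the
  intercept-only model. Complete separation (no longitude overlap between
  classes) is detected beforehand and returned as a flagged result rather
  than a divergent fit. Records are per-bee rows. The study's real-coordinate
  χ² (1.724) cannot be recomputed — apiary coordinates are unpublished — so
  this operation is validated by symmetry (null design ⇒ χ²≈0), parameter
  recovery (β = 1.5 recovered within ±0.2 at n = 2000) and affine invariance
  on synthetic data only.

## Synthetic populations

`generate_population` emits exactly the requested per-haplotype counts
(deterministic given the seed). The default `study_spec()` is the survey
composition: 1143 bees, 14 mitotypes, years 94/588/461 (2020/2021/2022),
province margins from the published sampling table. Per-haplotype year splits
honour what is published (A6a in 2020, both A2w bees in 2021; group-level
year totals match the published table) with the remainder fixed
deterministically; the rare Piacenza mitotypes (A2w, A6a, A26, M79) are
placed in PC. Provinces are otherwise assigned by random permutation within
year — margins preserved exactly, mitotypes geographically unstructured,
matching the published finding of random spatial distribution. Coordinates
are drawn uniformly within approximate per-province bounding boxes and exist
only to exercise the logistic regression.

Optional noise is substitution-only (Poisson per-sequence mean
`mutation_rate`, default 0), never inside the primers, so trimming always
succeeds. Not modelled: chromatogram/sequencing error profiles, indel errors,
within-colony relatedness, heteroplasmy. Passing round-trip tests therefore
show correctness of the pipeline logic, not robustness to raw Sanger noise.

## Problem sizes and determinism

The full study-replica run (simulate 1143 → trim → decompose → digest →
classify → summarize, plus a 100,000-resample Fisher test) completes in a few
seconds on one CPU; tests use the full 1143-bee population where the claim is
population-scale and down-sized compositions (2–3 per haplotype) for
round-trip properties. Every stochastic component takes an explicit seed;
identical seeds give byte-identical FASTA/TSV output.
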