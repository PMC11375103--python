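# beemito

Mitotyping of honey bees (*Apis mellifera*) from the tRNAleu–COII (COI–COII)
intergenic region of the mitochondrial DNA — the standard marker for assessing
the maternal-lineage composition of managed honey bee populations, e.g. when
monitoring the genetic integrity of a native subspecies such as
*A. m. ligustica*.

The package is aimed at population geneticists and apiculture researchers who
have Sanger amplicon sequences (E2/H2 primer pair, ~550–900 bp) and want to go
from FASTA to per-bee haplotype calls and regional summary statistics without
wet-lab RFLP work.

## What it computes

The COI–COII intergenic region is a mosaic of two repeat units: a short **P
unit** (~50–70 bp; variants P0, P, P1, P2 differing by internal deletions) and
a long **Q unit** (~190–200 bp, in 1–5 tandem copies). C-lineage bees lack the
P unit and carry a single Q; A- and M-lineage bees carry a P variant plus a
variable number of Q copies. `beemito` implements:

- **Primer trimming** (E2 forward / H2 reverse) and **unit decomposition**:
  locate the P variant and the tandem Q copies by alignment against a unit
  consensus library (identity ≥ 0.80, span within ±15 % of the consensus
  length).
- **In silico DraI test**: every `TTTAAA` site, blunt cut `TTT^AAA`, fragment
  band patterns as canonical keys such as `47/108/674`.
- **Haplotype assignment**: exact identity (indels count — a single cytosine
  deletion separates C2c from C2) against a packaged 14-haplotype reference
  catalog; non-matching sequences are named as novel mitotypes from the
  lineage, the DraI band-pattern family and the next free suffix letter
  (the rule that produces names like A2w and A6a).
- **Population summaries**: stratified frequency tables (full haplotype
  resolution or the C1 / C2(+C2c) / M / A reporting groups), haplotype
  diversity

      H = 1 − Σᵢ xᵢ²        (optionally × N/(N−1)),

  a Fisher exact test of differentiation across strata (exact enumeration for
  2×2; conditional Monte Carlo with the table-probability criterion for r×c),
  and a logistic regression of mitotype presence/absence on longitude
  (likelihood-ratio χ², 1 df).
- **Synthetic populations**: a generator that rebuilds any catalog haplotype
  from its architecture skeleton plus defining edits and emits labelled
  populations; its default composition is the 1143-bee regional survey it
  replicates (14 mitotypes over three years and nine provinces), so the whole
  pipeline runs offline.

The packaged unit/reference sequences are *synthetic but structurally
faithful* stand-ins (the real unit consensus sequences are not public); all
lengths, architectures, band patterns and variant relationships match the
published descriptions. See `docs/methods.md`.

## Worked example

```bash
python examples/classify_population.py
```

```text
classified 1143 bees into 14 haplotypes
C1             989  (86.5%)
C2 (+C2c)      126  (11.0%)
A lineage       15  (1.3%)
M lineage       13  (1.1%)
```

The generator emits the survey composition (seed-deterministic); with
`mutation_rate = 0` every read is an exact catalog match, so classification
recovers the composition exactly: C1 — the *A. m. ligustica* mitotype —
dominates at 86.5 %, C2 (typical of *A. m. carnica*) is at 11.0 %, and the
foreign A and M lineages are rare (1.3 % / 1.1 %). `haplotype_diversity` on
the 14 recovered counts prints H = 0.239 (corrected 0.240), and the
year×group Fisher test gives p ≈ 0.49: no differentiation across sampling
years. The other example scripts demonstrate the DraI band patterns (A6a
`47/108/63/191/420` → A2w `47/108/674` by two site-removing T/A edits), the
diversity/test statistics, and novel-name assignment.

The same workflow is available from the shell:

```bash
beemito simulate --out-fasta pop.fasta --out-truth truth.tsv --seed 42
beemito classify --fasta pop.fasta --out calls.tsv
beemito summarize --calls calls.tsv --meta truth.tsv --by year
beemito digest --fasta pop.fasta
```

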