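# Methods

## The problem and the model

The Kidd (JK, ISBT 009) blood group antigens JK1/Jk(a) and JK2/Jk(b) sit on
the urea transporter encoded by *SLC14A1* and differ by a single coding
change, c.838G>A (p.Asp280Asn).  Dozens of further alleles attenuate (weak)
or abolish (null) antigen expression, which matters clinically because a
weak-antigen donor unit mistyped as negative can boost antibodies in a
sensitized recipient.  `jktyper` re-implements a targeted amplicon-NGS
genotyping workflow for this system: per-amplicon base-count pileups over
the coding exons 3–10 of the JK*01 reference transcript (NM_015865.7) are
genotyped position by position, matched against an allele database, phased,
phenotyped, and counted into panel-stratified allele frequencies.

All coordinates are 1-based cDNA (HGVS `c.`); intronic positions are an
exon-boundary anchor plus a signed offset (`c.342-1`).  Genomic coordinates
are never used.

### Exon map

Five exon boundaries are fixed by the intron-anchored variants that appear
in the allele tables (exon 4 ends at c.341; exon 5 is c.342–470; exon 7 ends
at c.811; exon 8 at c.946; exon 9 is c.947–996).  The exon 3/4 and exon 6/7
junctions cannot be derived from those anchors; the shipped map places them
at c.144|145 and c.654|655 — placeholders tagged `source_tag="synthetic"`,
chosen inside the windows that the tables' printed exon assignments leave
open (c.130 is exon 3, c.159 exon 4; c.632 exon 6, c.667 exon 7).  Every
shipped variant's exon assignment is therefore anchor-determined or
table-given, never an artifact of the placeholder.  Two printed labels
contradict the anchors themselves (c.442C>T "exon 4", c.812-7T>C
"intron 8/E9-7"); the anchor rule wins and the printed labels are kept as
metadata.

### Allele database

Alleles are stored as absolute variant sets relative to JK*01 (an empty
set).  A row names a background allele plus additional changes; expansion is
the union, with a contradiction check at shared positions.  The shipped
fixtures transcribe the published validation table (16 alleles, with
serotypes and agglutination intensities), the prospective table (95
alleles, 96 distinct across both), and the ISBT definitions the names refer
to.  Obvious typographical defects are corrected with a provenance note in
the row (`56irsA` → `56insA`, which the running text prints correctly; the
`JK*01N.09.V175I` change printed as c.499G>A but cross-referenced by its
dbSNP id to c.523G>A).  Two printed names contradict their own printed
variants and are kept verbatim as database keys with the engine-derived
form documented (`279C_T` vs c.279T>C; `E9-7T_G` vs c.812-7T>C).

### Provisional nomenclature

Novel (non-ISBT-referenced) alleles are named `JK*<base>.<tokens>`:
amino-acid tokens first (one-letter code, nonsense written `X`), then exonic
nucleotide tokens (`588A_G`, `56insA`, `163del`), then intron tokens
(`E5-23G_A`, anchor exon plus signed distance), each class ordered by cDNA
position — the ordering observed across all printed names.  The engine
regenerates the printed name of all 85 nonreferenced alleles from
(background, extras), the two exceptions above audited against their
documented engine forms.

## Calling

**Run QC** — a run is accepted when cluster density is within
800–1,300 k/mm², more than 70% of clusters pass filter and Q30 exceeds 70%.

**Position genotyping** — bases below a noise floor (default 5% of reads)
are removed as sequencing error; one surviving base at ≥80% of reads is
homozygous, two bases each at ≥20% heterozygous, anything else
uninterpretable.  The error-correction step of the original analysis is
unspecified; a positional noise floor reproduces the reported near-1:1
heterozygous allele balance without modeling quality scores.  Coverage
acceptance: ≥80 reads for a homozygous call, ≥30 reads per allele for a
heterozygous call.  A sample is a no-call unless the entire set of eight
exon fragments passes.

**Intersection caller** — for each exon, the set of unordered allele pairs
whose combined variant pattern matches the observed genotypes at that
exon's positions; the candidate set is the intersection across all eight
exons (pair enumeration was chosen over per-haplotype group enumeration
because it is well-defined and directly checkable against a brute-force
pair scorer).  One survivor → unique; several → ambiguous; none → novel.

**Double-ARMS interpretation** — reaction A amplifies c.588..c.810 with
allele-specific primers at both ends, reaction B c.810..c.838; a combo band
appears only when one chromosome carries both primer-matched bases.  The
interpreter splits each reaction's one or two bands into per-chromosome
assignments and joins the reactions on the shared c.810 base; it returns
every haplotype pair whose predicted pattern equals the observation, and
raises an error when a control band is missing or no pair fits (three or
four bands in one reaction cannot come from two chromosomes).  A
consequence of this reaction design: when c.810 is homozygous, the
588/838 phase is not ARMS-resolvable (both pairings predict identical
bands), and the interpreter reports the ambiguity rather than guessing.

**Phase constraints** — ambiguous calls are narrowed by, in order of
confidence: ARMS evidence; the cohort's linkage rules (JK2 alleles carry
c.588G; c.810A occurs only in phase with c.588G and c.838A); and a
haplotype-frequency tie-break that ranks candidate pairs by the product of
their alleles' observed cohort counts under a Hardy-Weinberg prior
(unobserved alleles get a 0.5 pseudo-count).  Constraint- or
frequency-based resolutions are labeled `population_constraint` and are
never silent: the evidence level is part of the output.

**Novel alleles** — when no database pair fits, the caller finds the pair
explaining the genotype up to a minimal set of residual variants
(positions where a background sits on the reference base).  Homozygous
residuals go to both haplotypes; heterozygous residuals are phased by
read-backed within-amplicon co-occurrence records when present, then by the
phase rules; failing both, both arrangements are returned
(`ambiguous_novel`).  A residual matching a database-known variant reuses
its amino-acid annotation; otherwise the allele is named with the
nucleotide token and flagged for curation.  When the partner shares the
background, the arrangement is immaterial and the call carries a note that
serotype comparison is not possible.

## Phenotype inference

Each allele contributes to exactly one antigen (JK1 without c.838A, JK2
with) at a level normal/weak/null/unknown, read from one of two stored
category columns: `published` (the ISBT assignments) and `revised` (the
serology-corrected assignments, under which c.588A>G and c.810G>A are
neutral, the JK*01N.20 constellation — and hence its constituent changes
c.28G>A, c.226G>A, c.303G>A — expresses normal JK:1, truncations upstream
of codon 280 and the known null missense changes remain null, serotyped
novel missense changes such as M167V are normal, and unserotyped novel
changes stay unknown).  Per antigen: any normal contribution → positive;
otherwise an unknown contribution → unknown; otherwise weak → weak; all
null or no contributing allele → negative.  Normal dominates weak on the
same antigen, since such combinations are not serotyped distinctly.
Concordance against serotype records is qualitative (weak counts positive;
the 0–4 agglutination intensity is reported, not thresholded, being
reagent-dependent); non-predictable samples leave the denominator, and the
discrepancy rate is 100 × discordant / evaluated at two decimals.

## Frequencies

Direct counting: each resolved sample contributes two alleles (homozygotes
twice), no-calls leave numerator and denominator, percent = 100 × count /
(2 × genotyped), rounded half-up to two decimals (the rounding that matches
the printed tables; the few internally inconsistent printed cells are
flagged by `jktyper validate-db`, not special-cased).  Lineage rollups
(JK1/JK2 totals) classify by presence of c.838A.  Hardy-Weinberg ratios are
used only by the simulator; the frequency module is pure counting.

## The synthetic-data generator

The generator defines the study conditions the tests exercise:

| parameter | default | rationale |
|---|---|---|
| panel frequencies | panel-count table, normalized | the observed per-panel allele counts (alleles seen ≥5 times plus referenced; the rare remainder folds in proportionally) |
| samples per panel | the genotyped panel sizes | study cohort shape |
| mean coverage | 300× | within the reported per-amplicon range |
| coverage dispersion | negative binomial, k = 20 (CV ≈ 23%) | wide enough for the reported spread of amplicon means while keeping coverage failure a degraded-sample property (the validation set genotyped completely; no-calls traced to poor-quality DNA) |
| per-base error rate | 0.5% | typical amplicon short-read error, well under the 5% noise floor |
| degraded fraction | 30/7,512, at 0.1× coverage | the observed no-call rate |
| serotype mix-up rate | 5/551 | the observed discrepancy rate, attributed to sample mix-ups |

Each sample derives its own random generator from (seed, sample index), so
cohorts are reproducible and order-independent.  Reads split 50:50 between
haplotypes; errors flip to a uniformly chosen other base.  Deletions and
insertions are represented as single pileup symbols (`D`, `I`) at the
variant's anchor position, with `N` as the reference placeholder where the
tables print no reference base — a pileup-level simplification shared by
the simulator and the caller.

What the generator does **not** emulate: read-level artifacts (strand bias,
quality-correlated errors, indel realignment noise), amplicon dropout by
primer-site variants, contamination, and CNV/hybrid alleles.  Passing
round-trip tests therefore demonstrates the logic of calling, phasing,
naming and counting under the study's coverage/error regime — not
robustness to every failure mode of real libraries.

## Numerical and statistical choices

* Percentages use decimal half-up rounding, not banker's rounding.
* The het/hom windows (0.20/0.80) and the 5% noise floor are configurable;
  only the 80×/30× coverage minima are fixed by the workflow definition.
* Acceptance of the frequency round trip: with ~150 (panel, allele)
  binomial cells, demanding every cell within 3 SE would fail almost half
  of all runs by chance, so the check allows the expected number of
  exceedances (≤3 cells beyond 3 SE, none a genuine outlier at an exact
  binomial tail of 10⁻⁴).  Decided from sampling theory, not tuned.
* End-to-end recovery is measured on non-degraded samples (n = 500,
  ~10 s); the simulation sizes throughout (1,000 samples for the
  intersection oracle, 5,000 per panel for frequency recovery) keep the
  default suite around ten seconds on one core.

## Known limitations

* The allele database is JK-only; other blood group systems, JK3, CNVs and
  hybrid alleles are out of scope.
* Haplotype-frequency tie-breaking resolves to the most common pair; a
  genuinely rare pair with a common look-alike (e.g. JK*01W.06 + JK*02) is
  misresolved by design, exactly as frequency-based phasing without ARMS
  confirmation would be in practice — the `population_constraint` label
  exists so downstream users can treat such calls with lower confidence.
* dbSNP ids, GenBank accessions and population-database frequencies are
  carried as opaque metadata and never used in computation.
* The VCF export is a nonstandard cDNA-coordinate dialect (synthetic
  contig, `INTRON_OFFSET` INFO tag) intended for inspection, not for
  genome-coordinate interoperability.
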