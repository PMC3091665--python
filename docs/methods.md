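# Methods

## Digestion model

An enzyme is a blunt-cutting IUPAC pattern with a cut offset (e.g. TG^CA).
Every forward-strand occurrence produces one cut; overlapping occurrences
each cut. All seven supported enzymes (AccII CGCG, HaeIII GGCC, RsaI GTAC,
DpnI GATC, AluI AGCT, CviRI TGCA, CviJI RGCY) have IUPAC-palindromic sites,
so a forward scan is complete; the loader *validates* palindromicity and
rejects anything else rather than silently undercounting. Methylation
sensitivity is ignored — counts are sequence-only. An `N` base never
matches any code, so sites never span undetermined sequence. Digestion is a
partition: per chromosome, fragments are the intervals between consecutive
cuts plus the terminal pieces, and concatenating them reconstructs the
chromosome exactly. Cuts that would create an empty terminal fragment are
dropped.

Size selection keeps fragments with `min ≤ length ≤ max`, inclusive on both
ends ("between 70 and 200 bp" is ambiguous; inclusive was chosen and both
bounds are arguments). Tags are the first and last `tag_len` (33) bases of
a selected fragment in reference orientation; a fragment of ≤ 33 bp yields
a single collapsed tag; tags of fragments shorter than 66 bp overlap.

### Metric panel

With `n` selected fragments of total length `L` from a genome of `G` bp:

| metric | formula | default constants |
|---|---|---|
| complexity reduction % | `100·L/G` | `G = 1.1e9` |
| % selected portion | `100·n/n_total` | — |
| tag density / Mbp | `2n/(G/1e6)` | — |
| predicted SNPs | `2·tag_len·n/r` | `r = 5000` bp/SNP |
| coverage per run | `R/L` | `R = 1.9242e9` bp/run |

`G`, `r` and `R` are configuration parameters, never hard-coded; the
defaults are the constants under which the panel's published rows are
mutually consistent. A selected fragment counts as *repetitive* when either
terminal tag overlaps repeat annotation over ≥ 50% of its bases (threshold
configurable); the percentage reported is that count over selected
fragments — an explicitly declared definition, since no simple ratio
reproduces the historical column it stands in for.

## Synthetic data

The generator's defaults are the study conditions everything downstream is
tested under; they are set once and not tuned per test.

- Genome: 1 Mb over 2 chromosomes of i.i.d. uniform bases. Real genomes
  have compositional structure the background lacks; repeat content is what
  matters here and is modelled explicitly.
- Repeats: 3 families, 400 bp monomers, copies mutated at 5% divergence
  from the family seed and placed without overlap until ~59% of the genome
  is covered (the repeat content of the soybean genome this design was
  built for). Near-identical copies produce genuine multi-mapping ambiguity
  at a 2-mismatch budget.
- Paralog traps: 5 segmental duplications of 2 kb copied *exactly* to a
  second locus, kept out of the repeat mask. Tags from them place
  ambiguously (mapping quality 0), the error mode behind paralogous SNPs.
- Variants: parent-vs-parent SNPs at 1/5,000 bp; indels at 1/50,000 bp,
  1–3 bp, applied right-to-left with collisions skipped and logged. The
  truth table stores reference coordinates; indel offsets translate to
  alternate-haplotype coordinates. A truth variant's `in_footprint` flag is
  true only when both parents' digests put it inside a selected-tag
  footprint — a SNP that destroys its own cut site drops out of the
  alternate library (allele dropout) and is flagged not discoverable.
- Coverage: per tag per parent, `c ~ Poisson(μ·g)`, `g ~ Gamma(k, mean 1)`,
  μ = 20, k = 1; repetitive tags get a 10× mean multiplier. `Var/mean =
  1 + μ/k`. `k = None` disables the mixture (Poisson limit).
- Errors: each emitted base substitutes with 0.1% and becomes `N` with
  0.09% (≈ 2.9% of 33-mers carry an N). Qualities use a declared 3-level
  model: Q30 ordinary, Q10 error-injected, Q2 for N — enough structure to
  exercise quality-aware consumers without pretending to model a real
  instrument.
- Determinism: one root seed; each stage (background, duplications,
  repeats, snps, indels, coverage, errors) draws from a named substream
  derived via a CRC of the stage name, so adding a stage never shifts
  another's draws. Identical configs give byte-identical outputs.

What passing tests on this generator do **not** show: performance on real
base-composition, on diverged (rather than exact) paralogs, on indel-rich
material, or with real instrument error profiles.

## Alignment

Reads collapse to unique sequences with read counts and per-base mean
qualities. Unique sequences partition into with-N / single-read /
multi-read classes; N-carrying sequences are excluded from alignment.
Alignment is ungapped seed-and-verify: the tag is split into
`max_mismatches+1` disjoint seeds of the index k-mer length (k = 11 for 33
bp and 2 mismatches); by pigeonhole any placement within budget has an
exact seed, so enumeration is complete (property-tested against an
exhaustive Hamming scan). Reverse-strand hits are reported in forward
coordinates. Ties at the minimum mismatch count report the lowest locus
(chromosome order, then coordinate) for determinism.

Mapping quality is a proxy, not a reimplementation of a probabilistic
mapper: 40 = unique best hit and no alternative within budget; 25 = unique
best with a strictly worse alternative; 0 = tied best hits. Only the
threshold semantics ("trusted" ≥ 40, "ambiguous" = 0) are used downstream.
The stringent rule "mapping quality higher than 40" is interpreted as
≥ 40, since 40 is also the scale maximum; the threshold is configurable.

## Calling and filtering

Pileup columns accumulate per-allele read counts (each unique tag
contributes its read count at 33 columns), per-allele summed mean base
qualities, and the maximum mapping quality of covering tags; multi-hit
alignments contribute depth but flag the column. A column yields a
candidate when its best-supported non-reference allele has ≥ 1 read; only
that single alt allele is considered (two pooled inbreds imply biallelic
sites; count ties break alphabetically).

Consensus quality: `Q = min(40, round(−10·log₁₀ P[X ≥ alt_count]))` with
`X ~ Binomial(depth, e)`, `e = 10^(−Q̄/10)`, `Q̄` the column's mean base
quality. This is a declared score — only the ≥ 10 threshold matters
contractually.

Lenient tier: alt-supporting reads ≥ 3; position not inside a repeat
interval (point-in-interval, since the rule targets SNP positions, not tag
overlap); and no 10-bp window rule violation. Windows are every interval
`[p, p+10)`; a window holding ≥ 3 candidates discards them all (positions
100 and 109 co-occupy a window; 100 and 110 do not). The window census
runs over candidates that meet the support rule: a lone error read at a
deep column is not a credible variant and must not purge a genuine
neighbour.

Stringent tier is applied on top of the lenient set, so the tiers nest by
construction: no indel within 3 bp (inclusive; |SNP − indel| = 4
survives), total covering reads ≥ 10, maximum mapping quality ≥ 40,
consensus quality ≥ 10, and the window rule again. The support thresholds
deliberately differ in kind: the lenient rule counts *alt-supporting*
reads (its purpose is evidence for the allele), the stringent rule counts
*covering* reads (its purpose is a trustworthy column); the audit table
records both numbers per candidate. The indel track is declared input —
truth indels in simulation, a BED otherwise; no gapped discovery.

Cross-assembly exclusion: each surviving candidate's best-supported
alt-carrying tag is realigned to a second assembly (which may be the
first); candidates whose tag places non-uniquely, or not at all on the
repeat-masked second assembly, are dropped.

## Evaluation

Recovery is scored inside *unique selected-tag footprints*: footprints
whose reference tag places uniquely at mapping quality 40 and overlaps
neither repeat mask nor duplication. Truth SNPs there (with
`in_footprint` set) are the discoverable set; recall and precision are
computed against it, and lenient-tier false calls at repeat/duplication
loci are counted separately as the paralog error mode.

A structural note on expected recall: the alt allele at a pooled site is
covered by exactly one tag of the alt parent, whose read count is
Gamma-Poisson; with μ = 20, k = 1 the probability of the ≥ 3 alt reads
the lenient rule needs is `(20/21)³ ≈ 0.86`, which bounds expected
stringent recall from above under these defaults regardless of
implementation. Deeper coverage or larger k moves the bound toward 1; the
defaults are kept at the study conditions rather than adjusted.

## Numerical and design choices

- Coordinates 0-based half-open internally; 1-based in reports and VCF.
- Rounding of reported percentages: half-up at the stated precision
  (`rate(52, 61) → 85`, `rate(113, 171, 1) → 66.1`).
- Interval sets are merged on construction; overlap queries are two binary
  searches. Empty chromosomes and empty interval sets are valid.
- Zero selected fragments: panel ratios report 0 with a warning, not a
  division error. Zero-variance input to the correlation returns NaN;
  constant per-tag counts return an infinite dispersion-shape sentinel
  (method-of-moments `k̂ = m²/(v−m)` is undefined at v ≤ m). Include
  zero-count tags in the fit when they are known — truncation biases the
  moments.
- The histogram of read coverage uses bin width 1 over counts ≥ 3,
  reported as probabilities.
- "Sliding" windows for the repeat/GC survey are non-overlapping 10-kbp
  tiles (step = width, configurable); reads are assigned to windows by
  leftmost mapped coordinate.
- The high-coverage repeat enrichment classifies mapped tags by footprint
  overlap (≥ 1 bp) with the repeat mask; counts strictly above vs strictly
  below the 200-read threshold.

## Limitations

- Ungapped alignment only; indels enter via the declared track, never from
  gapped mapping, and are not emitted as variants.
- No allele-frequency estimation from pool depth; tags are treated as
  presence/absence evidence at a site.
- The mapping- and consensus-quality scores are declared proxies; absolute
  values are not comparable to probabilistic mappers beyond their
  thresholds.
- Recovery metrics at the 1 Mb default are computed over few discoverable
  SNPs (repeat-rich genome, ~8% tag footprint), so they carry visible
  sampling noise; scale `genome_length` up for tighter estimates.
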