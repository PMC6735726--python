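# Methods

## Molecular identification

Each read pair carries a 4 bp barcode: a 2 bp UMI from each fragment end,
read off the first bases of read 1 and read 2, followed by an invariant
`T` spacer required by the ligation chemistry. Extraction removes the
first three bases of each mate and rejects pairs whose spacer base is not
`T` on *either* mate (the design-compliance check is per read). UMIs
containing `N` are kept — grouping treats `N` as a literal fifth symbol —
because discarding them would lose molecules, and UMI base quality is not
checked: quality filtering belongs to the consensus stage. The barcode is
appended to the query name behind a `|` delimiter, a character that does
not occur in upstream read names and survives aligners that preserve
QNAME.

After alignment, one strand of one molecule is identified by the
**family key**: barcode, the 1-based leftmost mapping position and CIGAR
of each mate, and the orientation of read 1 (from which strand of origin
follows: R1-forward pairs derive from the plus strand). Positions are
taken as recorded — soft clips are not unwound, since CIGAR is itself part
of the key and already separates clip variants. Read number is encoded
positionally by the two coordinate/CIGAR slots. Grouping is exact-match;
UMI edit-distance clustering is deliberately out of scope.

The two strands of one molecule map to each other under the **duplex
transform**: barcode halves interchange (`AC/GT` ↔ `GT/AC`), the
read-number slots swap, and the orientation flips — read 1 of the plus
strand covers the same fragment end as read 2 of the minus strand. The
transform is an involution; the **duplex key**, the lexicographic minimum
of a key's serialization and its transform's, is therefore strand-agnostic
and hashes complementary strands together. Grouping guarantees at most
two strand families per duplex key, which downstream stages assert rather
than re-derive.

Reads that are unmapped, have an unmapped mate, or are
secondary/supplementary alignments are excluded before grouping; orphaned
records (mate absent after filtering) are dropped and counted. Improper
pairs that survive these filters are kept — key mismatch separates them
naturally.

## Consensus rules

**SSCS.** Families of ≥ 2 members collapse position-by-position (members
share CIGAR by key construction, so columns pair by read offset with no
realignment). Bases below Q30 are removed first; the most frequent
surviving base is called iff its proportion *of survivors* is ≥ 0.7,
otherwise `N`. Both thresholds are configurable (`ConsensusConfig`); the
cutoff must exceed 0.5 so the winner is unique and no tie-break is ever
exercised. The comparator is ≥ on both the quality and the proportion
boundary. The consensus quality is the maximum quality among agreeing
bases — a deliberate choice to preserve the Phred scale without inventing
a recalibration; `N` positions get quality 0.

**Singleton Correction.** Singletons are compared against the
complementary strand in reference coordinates (both records are aligned to
the same locus, so no explicit reverse complement is needed): first
against a complementary SSCS, else against the complementary singleton,
step-wise. A base survives only if both observations are ≥ Q30 and agree;
otherwise `N` with quality 0. Kept bases take the minimum of the two
qualities — the corrected read is only as trustworthy as its weaker
witness. SC by SSCS does not modify the SSCS; SC by singletons emits both
corrected reads so duplex pairing sees both strands. Correction is
symmetric under argument swap.

**DCS.** Complementary strand consensuses merge by preserving matched
bases; mismatches become `N`, quality is the maximum of the two strands at
concordant positions. The DCS is emitted under the canonical (duplex-key)
orientation so reruns are byte-stable. Family size is the sum of the two
contributing sizes.

**All unique molecules.** DCS + unpaired SSCS + uncorrected singletons,
with a hard error if any molecule appears twice. Without Singleton
Correction a molecule can be represented both by an unpaired SSCS and by
the opposite strand's singleton (or by two complementary singletons); the
merge then keeps one representative, preferring the consensus.

## Metrics

Coverage is **fragment** coverage: per panel position, distinct templates
with at least one aligned base, mates counted once; the mean includes
zero-depth panel positions. Efficiency = consensus coverage /
uncollapsed coverage; DCS recovery = DCS coverage / (SSCS coverage / 2),
the denominator being the theoretical maximum since each DCS consumes two
strand consensuses.

The error report tallies A/C/G/T observations per panel position (`N`
excluded from numerator and denominator, indels out of scope). A
non-reference allele below the 5% allele-frequency ceiling (strict `<`)
counts as error and is classified into one of the 12 reference>observed
substitution classes; at or above the ceiling it is treated as a putative
variant and excluded from the numerator for that allele only. Any
non-reference observation counts (no minimum support beyond one read).
`error_free_positions` is the fraction of covered panel positions with
zero non-reference bases. The oxidative-damage statistic is the smoothed
ratio (G>T + ½)/(C>A + ½), defined even when a profile is empty (a clean
profile gives ≈ 1).

Downsampling samples templates, never single records, with an independent
Bernoulli draw per query name at fraction `target / current` — unbiased,
mate-safe, and byte-deterministic given a seed.

## The simulator

`simulator` emulates the library design: fragments of N(200, 30) bp
(min 50) drawn uniformly from a ~50 kb two-contig toy genome restricted to
a target panel, 100 bp paired-end reads (read-through truncation when the
fragment is shorter), uniform 2+2 bp UMIs, independent per-base
substitution errors (uniform across the three alternatives), and
per-molecule oxidative lesions: with probability `oxidation_rate` one G
site of the fragment reads as T on plus-strand reads only, producing the
strand-asymmetric G>T excess characteristic of 8-oxoguanine. Base
qualities are a two-point Q37/Q25 mixture controlled by `frac_below_q30`,
a deliberately simple knob that exercises the Q30 filter. Optionally a
configurable number of spacer-mutated pairs is appended to the FASTQ to
exercise the design-compliance rejection path.

Per-strand read counts come from compact distribution specs: `fixed:k`,
`poisson:λ`, `ztpoisson:λ`, and `mixpoisson:λ_hi,λ_lo,w` — a
molecule-level mixture in which a fraction `w` of molecules amplify poorly
(both strands Poisson(λ_lo)). The shared factor couples the two strands;
this matters because with strand-independent counts the fraction of
singletons that can be rescued is provably monotone in depth, whereas real
libraries (and the mixture) show a peak at intermediate depth: at
saturation the surviving singletons are mostly dead molecules whose
complement was never sequenced, and at very low depth the complement is
lost to thinning. The default regime, `ztpoisson:1.2`, gives ≈ 52%
singleton strands — the singleton-rich hybrid-capture setting in which
correction pays off.

The simulator emits the truth-aligned BAM directly (coordinates are known,
so tests are free of aligner nondeterminism); a FASTQ path with the raw
UMI+spacer layout exists for end-to-end runs through an external aligner.
Everything is deterministic given the config seed.

`expected_stream_sizes` gives the closed-form mean and standard deviation
of every stream from the strand-pattern probabilities: (≥2, ≥2) → DCS in
both modes; (≥2, 1) and (1, 1) → DCS only with correction; (≥2, 0) →
unpaired SSCS; (1, 0) → uncorrected singleton. Per molecule every stream
contribution is a deterministic function of the pattern, so variances
follow directly and observed counts can be checked at 3σ.

What the simulator does **not** model: indel errors, GC and capture bias,
barcode synthesis errors, chimeric fragments, mapping ambiguity, and
quality-score correlation along reads. Passing tests therefore show the
*logic* of grouping, correction and accounting is right under the stated
error model, not that real libraries will match the simulated efficiency
numbers.

## Problem sizes and numerical choices

Bundled analyses run at 10⁴ molecules over the 50 kb toy panel (~10⁵ read
pairs at the default duplication), which puts raw base depth near 140× —
deep enough that a single sequencing error sits well below the 5% AF
ceiling and error rates are measured, not censored. The depth-sweep
demonstration uses 3 000 molecules under `mixpoisson:6,0.06,0.5` over four
4-fold depth steps. Coverage ratios that are exact by construction (e.g.
DCS/SSCS = ½ when every strand pairs) are asserted to machine precision;
stochastic stream counts at 3σ; error-rate orderings as >10× separations.

## Known limitations

- Consensus requires identical CIGAR within a family (guaranteed by the
  key); families differing only by clipping are treated as distinct
  molecules, slightly undercounting duplication.
- Barcode collisions (same 4 bp UMI pair, same coordinates, same CIGARs)
  merge distinct molecules; with 256 barcodes the combined coordinate+UMI
  space makes this negligible at bundled scales but it is not detected.
- The error report ignores indels entirely.
- Variant calling on the merged output is out of scope.
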