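# Methods

## The procedure

promhex implements promoter hexamer enrichment against a
resampling-standardized background null.

**Promoter windows.** A promoter is the `window_len` (default 1000) bases
immediately upstream of a gene's TSS, reported 5'→3' relative to the gene.
The TSS is the gene-level feature's 5' end (gene start on '+', gene end on
'-'); isoform-resolved TSS selection is out of scope. Internally all
coordinates are 0-based half-open on the forward strand (BED convention);
the familiar −1000…−1 convention is translated at the boundary: a '+'
gene with 1-based start S gets 0-based [S−1−window_len, S−1), a '−' gene
with 1-based end E gets [E, E+window_len) reverse-complemented. Windows
clipped at a chromosome edge are kept at their shorter length and flagged
`truncated` rather than dropped — dropping them would bias the background's
composition; their smaller valid-window count propagates automatically.
Sequences are normalized to A/C/G/T/N (uppercase, U→T, anything else → N).
Whether genes whose upstream kilobase runs into a neighboring gene belong
in the universe is a study-design choice, not a property of the method, so
overlap filtering is exposed as an off-by-default option
(`extract_promoters(..., exclude_overlapping=True)` skips and logs them).

**Counting.** All 4^6 = 4096 hexamers are enumerated lexicographically
(AAAAAA…TTTTTT). Occurrences are counted in overlapping windows (step 1)
on the promoter's own strand. Overlap counting is the conventional choice
for exhaustive k-mer frequency analysis; non-overlap would undercount
periodic motifs. A `both_strands` option in the element scanner adds
reverse-complement occurrences (a palindromic pattern is then counted
twice per site — documented, not special-cased). Windows containing N are
excluded from the numerator *and* from the valid-window denominator, so
masked sequence cancels instead of deflating frequencies. A clean 1-kb
promoter contributes exactly 995 windows; conservation
`sum(counts) == n_valid_windows` holds identically.

**The null.** Each of `n_replicates` (default 1000) replicates draws
`sample_size` (default 100) promoters uniformly *without replacement*
from the background universe — a "sample of 100 distinct promoters" —
while replicates themselves are independent, so a promoter may recur
across replicates. Per hexamer, the null is the mean and the n−1-denominator
standard deviation of the replicate totals. The background universe is an
explicit required input (never a hidden default): whether it should be all
promoters or expressed-gene promoters is a study choice.

**Scoring.** Observed counts are standardized to the per-`sample_size`
scale by `counts × sample_size / n_promoters`, so focal sets need not
contain exactly 100 genes. `z = (observed − mean)/sd`; hexamers with
`sd == 0` get an undefined z (NaN, never ±inf), are excluded from ranking
and flagged. Ranks are descending by z with lexicographic tie-break (a
stable sort over the lexicographic motif index). No multiple-testing
correction is applied — the output is a ranking, as in the original
analysis style; the `approx_p` column (two-sided normal tail) is a
labeled convenience only.

**Contrasts.** "Significantly enriched" for cross-condition comparison is
operationalized as rank ≤ 10 (optionally with a z floor). `compare`
aligns two tables, computes `delta = z_y − z_x` where both are defined,
and partitions top-10 membership into shared and condition-specific sets.
Because the axis quantities of the published scatter style are ambiguous,
`scatter_data` emits both readings: per-contrast frequency-vs-Z blocks
(default) or a single Z-vs-Z block across the two contrasts (`x_axis="z"`).

**Element dictionary.** Bundled as an editable TSV (name, IUPAC motif,
source). Elements shorter than 6 bp (e.g. BOXIII's CATTT) match as
substrings at any offset; equal-length patterns must match the full
hexamer; longer patterns never annotate a hexamer. Degenerate codes expand
to concrete-base classes only, so an N in a promoter never matches — an
all-N pattern of length 6 therefore counts exactly the valid windows.
ARR1AT is stored once as GTKATT, covering both its GTTATT and GTGATT
variants. Entries whose sequence we could not source (obo-Box, New1, New2)
carry the sentinel motif `-`: they keep their name for bookkeeping but are
excluded from matching; users can drop real sequences in without code
changes.

## Randomness contract

One explicit integer seed governs each stochastic component; there is no
hidden global state. Replicate r of the null is a pure function of
(seed, r) via `numpy`'s SeedSequence `[seed, r]`; the synthetic generator
derives its background stream from `[seed, 0]` and each gene set's stream
from `[seed, 1, crc32(name)]`, so gene sets are reproducible in isolation.
Identical seeds and inputs reproduce NullModel and EnrichmentTable
bit-identically.

## The synthetic generator

`synthetic_data` emulates the statistical structure the analysis assumes:
a background universe of `n_background = 5000` promoters of
`promoter_len = 1000` bp drawn iid from `base_probs` (uniform by default),
and focal sets of `n_genes = 100` background-like promoters with a motif
planted at `per_promoter_copies` non-overlapping, uniformly placed sites
(positions recorded as ground truth). Planting *overwrites* rather than
inserts, keeping promoter length — and the window denominator — unchanged.
The background is also written as a one-gene-per-contig genome with
alternating strands plus a BED annotation, with optional edge-truncated
promoters, so extraction can be round-tripped byte-for-byte against the
generator's own records.

Defaults mirror the study design: background samples of 100, 1000
replicates, top-100 focal sets. The iid background is deliberate — the
real analysis resamples actual promoters rather than fitting a
composition model — and a first-order Markov option exists for robustness
checks. What the generator does *not* emulate: real promoter base
composition (AT-rich in plants), dinucleotide and repeat structure,
TATA/TSS positional signals, shared cis-regulatory grammar between
co-regulated genes, and overlap between focal sets and background (focal
promoters are fresh draws, not members of the universe). Passing tests
therefore demonstrate correctness and calibration of the machinery under
its own null, not biological conclusions about any particular genome.

## Numerical and degenerate-input choices

- Sequences shorter than k yield an all-zero vector with zero valid
  windows (not an error); empty promoter collections are errors.
- A background exactly the size of one sample makes every replicate the
  whole set: sd = 0 everywhere, the model's `degenerate` flag is set, and
  every z is undefined rather than infinite.
- Counting is per-promoter first, then aggregated, so no window ever
  spans two promoters and per-gene presence/absence reuses the same scan.
- Both overlap counts (enrichment path) and per-gene presence/absence
  (scanner path) are computed, since either convention may be wanted when
  reporting; the two paths agree exactly on concrete hexamers and this is
  asserted in tests.
- The calibration bands used in tests (mean z within ±0.1; |z| ≥ 1.96
  fraction within [0.03, 0.07] across a 10-seed panel) reflect the normal
  approximation over 4096 correlated-but-weakly-so hexamer scores.
- Problem sizes in tests and the acceptance script (e.g. a 10-seed panel
  at 5000 background promoters × 1000 replicates; 300–1000 sequences for
  the counting oracle) were chosen to exercise full study scale while
  keeping a complete run in the tens of seconds.

## Known limitations

- Gene-level TSS only; no transcript-isoform awareness.
- Single-strand counting default assumes correctly oriented promoters.
- No GC- or composition-matched background stratification (the null
  inherits whatever composition the supplied universe has).
- No PWM scanning; the element model is exact-IUPAC words.
- The approximate p-values assume normality of replicate totals and are
  not corrected for 4096 tests; use the ranking, not the p-values, for
  inference.
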