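# Methods

## Model and procedure

`cisenrich` tests whether cis-regulatory elements are over- or
under-represented in an experimental promoter set relative to what
equally sized random sets drawn from the genomic promoter pool would
show. The procedure is deliberately assumption-light: no sequence
model is fitted to the background — the background *is* the genome's own
promoter complement, resampled.

1. **Scanning.** A motif is a fixed-length IUPAC word; matching is
   sliding-window set membership per position. Under the default
   `auto_antisense` policy a motif is searched as its Watson and its
   Crick word on the stored strand; the two matching on the same span
   (dyad-symmetric words like BACGTV) count once. Sequence characters
   outside {A,C,G,T} (masked/ambiguous bases) satisfy no pattern
   position, so N-runs cannot inflate counts. Overlapping self-matches
   of one motif are enumerated individually; no merging.
2. **Modules.** An ordered tuple of 2–3 member motifs. An instance is
   one hit per member such that hits appear in ascending start order,
   consecutive hits do not overlap, and the gap
   `start(next) − end(previous)` is between 0 and `max_gap` (default
   100 bp, the window covering most published functional plant module
   descriptions). All qualifying tuples are counted — no greedy pairing
   and no hit-reuse restriction, since any disambiguation rule would be
   arbitrary; presence (parameter I) is unaffected by this choice, and
   the tuple convention for parameters II/III is documented here rather
   than asserted as the only defensible one. Member hits may lie on
   either strand; order is defined by Watson start coordinates.
3. **Parameters.** Per target and promoter set: (I) promoters with ≥1
   occurrence, (II) mean occurrences per promoter, (III) total
   occurrences, (IV) sample variance (n−1 divisor; 0 for a singleton
   set) of per-promoter counts.
4. **Randomization.** ≥1000 random sets of the experimental size drawn
   uniformly without replacement (within a repetition; repetitions are
   independent) from the full pool. One seeded RNG stream is consumed
   in repetition order, so runs are bit-reproducible. All targets are
   evaluated on the same draws, making their backgrounds comparable.
   The experimental promoters stay in the sampling frame by default
   (they are part of the genome); `exclude_experimental` removes them.
5. **Significance.** z = (observed − background mean)/background SD;
   one-sided normal tail p in the observed direction, so enrichment and
   depletion are separate signed findings. Bonferroni correction over
   (number of targets) × 4 parameters by default (the exact family is
   configurable); retain corrected p ≤ 0.05, or raw p ≤ 0.01 when
   running uncorrected.

## Implementation notes

The whole pipeline reduces to one scanning product: the per-promoter
count matrix (genes × targets). Promoters are joined with an `X`
separator (matching no IUPAC class) and each motif located in a single
compiled-regex pass; module instances are counted per promoter by
suffix dynamic programming over member hit lists, equivalent to full
tuple enumeration. Background sampling uses Floyd's without-replacement
algorithm vectorised across repetitions. Observed statistics, background
samples and false-positive-rate trials all aggregate the same count
matrix, so the FPR procedure exercises exactly the arithmetic of a user
run.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `max_gap` | 100 bp | maximal flexible spacing between consecutive module members |
| `strand_policy` | `auto_antisense` | search Crick words too (`watson_only` disables) |
| `n_reps` | 1000 | random reference sets; raise to 3000–5000 when the pool is < 10× the set size (a warning says so) |
| `alpha` | 0.05 corrected / 0.01 uncorrected | retention threshold |
| `family_size` | targets × 4 | Bonferroni family |
| `min_frac` | 0.05 | presence floor for the *reported* occurrence list only — never applied to the statistics |

## Normality screen and the overabundant-motif caveat

The Z-test is only calibrated when the background is approximately
Gaussian. Each record carries `gaussian_ok` from a cheap, deterministic
moment screen: fail when |skewness| > 0.5, |excess kurtosis| > 1, or
>10% of background samples tie at one value. A formal normality test was
deliberately not used — at 1000+ samples such tests reject trivially
small departures.

For a motif present in nearly every promoter, parameter I is pinned just
below the set size: its background is discrete, left-skewed and capped,
and Gaussian tail areas are wrong in both directions — the enriched tail
is essentially unreachable (deflated calls) while modest deficits yield
grossly inflated depletion calls. The false-positive-rate procedure
reproduces this: on a 30,000 × 1000-bp i.i.d. null pool, GGWTW (MRE2,
presence ≈ 0.9996) shows an either-direction parameter-I call rate of
~6% at α = 0.01 (nominal 2%) for 200-gene sets, while its parameter II —
a mean of ~Poisson per-promoter counts, comfortably Gaussian — stays at
nominal. Hence the reporting rule: when parameter I fails the screen,
parameter II is elevated in the significance matrix, and occurrence-list
entries significant only through parameter II are asterisked. Truly
rare or saturated motifs would need Poisson/hypergeometric tail models;
these are out of scope and the normality flag is the guard rail.

## False-positive-rate estimation

Each trial draws a random "experimental" set, runs the full pipeline
against a fresh background of `n_reps` sets, and records calls at raw
p ≤ α. The default counts *enriched-direction* calls (nominal rate α,
matching the convention of asking how often a motif is termed enriched
by mistake); `direction="any"` counts both tails (nominal 2α). Exact
binomial 99% confidence intervals accompany each rate. With the count-
matrix design a 1000-trial × 1000-repetition calibration at set size 200
takes tens of seconds on one core.

## Synthetic data

The generator emulates a genomic promoter pool: i.i.d. bases with
P(G)=P(C)=GC/2 and P(A)=P(T), fixed length (default 30,000 promoters of
1000 bp — an Arabidopsis-scale upstream dump). Targets are planted by
overwriting bases in place (lengths stay constant): each planted
promoter receives one concrete instantiation — degenerate positions
resolved uniformly, module gaps uniform in [0, max_gap] — at a uniform
position avoiding previously planted spans. A scenario plants a
background fraction `q_bg` pool-wide, then tops up a designated
experimental subset to presence `q_exp` (top-up only; an effective
`q_exp < q_bg` is not enforceable). Truth records planted spans only;
because i.i.d. background can produce incidental extra matches, checks
assert "at least the planted occurrences".

What this does *not* emulate: dinucleotide composition, CpG/TATA
structure, positional bias of real sites toward the TSS, shared
promoters of tandem duplicates, or masked repeats. Passing tests
therefore demonstrate the statistics and the scanner, not that any
particular biological pool has Gaussian backgrounds — that must be
checked per pool via the diagnostics (and with real genomes the
normality flag does the same job).

## Numerical and design choices

- Gap convention: `0 ≤ start(next) − end(prev) ≤ max_gap`; "not
  overlapping" forbids negative gaps.
- Degenerate backgrounds (SD = 0): p = 1 when the observation equals the
  constant background, p = 0 otherwise; both flagged `degenerate`.
- z = 0 gives p = 0.5 and direction `none`.
- Occurrence lists: ranked by parameter I within single / bipartite /
  tripartite classes, ties share a rank span ("2-4"), alphabetical
  secondary order for byte-stable output; only corrected-significant
  targets present in ≥5% of the analysed promoters are listed.
- Significance-matrix p bins (\*, \*\*, \*\*\* at 0.05/0.01/0.001) are a
  display choice, not part of the statistics.
- Uniform whole-pool sampling means a promoter is expected to appear in
  `n_reps × n / pool` background sets (e.g. ~6.7 times for n = 200,
  1000 reps, 30,000 promoters); tools that report markedly lower reuse
  are sampling from a different frame. The draw tally is exported so
  users can inspect this directly.

## Problem sizes

Default test and calibration runs use a 30,000-promoter × 1000-bp pool,
set sizes 50–200, 1000 randomizations and 1000 false-positive-rate
trials; the unit suite uses smaller pools (hundreds to thousands of
promoters) chosen so each check's Monte-Carlo error is well inside its
assertion margin.

## Known limitations

- Bonferroni is the only correction offered (no FDR), matching the
  conservative retain-rule the method was designed around.
- No GC- or length-matched background sampling and no Markov shuffling:
  the background is the pool as given.
- Parameter IV (count variance) has a skewed background for sparse
  targets; its calls should be read alongside its `gaussian_ok` flag.
- Module multiplicity counts tuples, which overweights promoters with
  many member hits in parameters II/III; parameter I is immune.
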