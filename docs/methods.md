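# Methods

`microdepth` studies how uneven sequencing (coverage) depth biases
metagenome-based estimates of intraspecies diversity. It has two halves: a
ground-truth simulator of strain-mixture metagenomes, and a profiling /
rarefaction stack that measures nucleotide diversity (π), ANIr, depth and
breadth from read recruitments and quantifies their depth dependence.

## Metrics

**Nucleotide diversity (π).** At each reference site with A/C/G/T counts
`(n_A, n_C, n_G, n_T)` and depth `n = Σ n_b`, the per-site diversity is the
plugin heterozygosity

    π_site = 1 − Σ_b (n_b / n)²,

bounded in [0, 0.75] with the maximum at an equal quartet. The genome-wide π
is the unweighted mean of π_site over all sites with depth ≥ `min_cov`
(default 5). Deliberately, **no** `n/(n−1)` finite-sample correction is
applied: for true allele frequencies `p`, the plugin estimator at depth `n`
has expectation `(n−1)/n · π_true`, and this downward bias — together with
the stochastic loss of rare alleles — is precisely the depth dependence the
package measures. A property test verifies the `(n−1)/n` law by Monte Carlo
at n ∈ {5, 10, 50, 200}. An alternative denominator (`pi_denominator=
"covered"`: the π sum divided by all covered sites) is available behind a
flag.

**ANIr.** The mean alignment identity of recruited reads, in percent.
Identity is gap-columns identity `n_match / (n_match + n_mismatch + n_ins +
n_del)`: every inserted or deleted base counts as one non-matching column
and soft-clipped columns are excluded from both numerator and denominator.
This convention reproduces the expected error-model identities (ANIr ≈
100 − 100·Σ event probabilities per base). The default is one vote per read;
a base-weighted mean is available (`anir_weight="bases"`).

**Depth and breadth.** Mean depth counts match/mismatch pileup columns
divided by the full reference length (zeros included); breadth is the
percentage of positions with depth ≥ 1. Under uniform read placement breadth
follows the Lander–Waterman expectation `100·(1 − e^(−depth))`, so ~5X
already exceeds 99% breadth — tested directly.

## Recruitment contract

Alignments (SAM/BAM via pysam) are reduced to per-read edit counts using the
CIGAR plus the NM tag when present (mismatches = NM − ins − del); without a
usable NM, mismatches are re-derived by comparing aligned columns to the
reference. Filters, applied in order and idempotently:

1. identity ≥ `min_identity` (default 0.95, boundary inclusive);
2. non-discordant pairing: a read is dropped only when its mapped mate
   points at a different reference (vacuous for unpaired data);
3. best match: one alignment per read/mate, highest identity, ties broken by
   leftmost start then lexicographic reference id. Secondary and
   supplementary records are dropped before selection.

Deletions leave pileup gaps (no consensus filling), since π is defined over
observed nucleotide frequencies only.

## Simulator

**Strain sets.** An i.i.d. ancestor genome (configurable GC) plus `k`
strains; strain 1 is the ancestor, strain `j` carries `round(d_j · L)` point
substitutions at distinct uniform positions with `d_j ~ U(divergence range)`,
default range 0–2.49% so that all pairwise ANI stays ≥ 95.02% — inside the
species boundary and the recruitment regime. Pairwise ANI is computed
exactly from the edit lists. Substitutions only: no indels, rearrangements,
or gene-content differences between strains in v1.

**Abundances.** Weights ∝ exp(Normal(0, σ²)), normalised; σ = 1 by default,
a spread that makes the most abundant of 100 strains roughly two orders of
magnitude more abundant than the rarest — a realistic skew for a natural
community dominated by a few genomovars.

**Error model.** A five-parameter profile `(p_ins, p_del, p_mm, p_mm_start,
p_mm_end)` interpreted **per base**: each read base independently suffers at
most one event drawn categorically. The start/end mismatch surcharges apply
only within the first/last 10 bases of the read (window size configurable;
the read-orientation windows emulate the elevated error rate at read ends).
Mismatches replace the base uniformly over the three alternatives; an
insertion adds one uniform base after the position; a deletion drops the
base. Presets: error-free `(0,0,0,0,0)`, Q20 `(0.001, 0.001, 0.006, 0.001,
0.001)` (~1 error/1,000 bp) and Q30 `(0.0001, 0.0001, 0.0006, 0.0001,
0.0001)` (~1 error/10,000 bp). The per-base interpretation is what makes
the Q20/Q30 ANIr levels come out at ~99.2%/99.9% (≈ 100·(1 − Σ p)); a
per-read interpretation (one event per read per probability) is available
via `per_read=True` for comparison. Under this model the clonal-Q20 genome
π has the closed form `2e − (4/3)e²` (with `e` the effective per-base
mismatch rate) times the `(n−1)/n` depth factor; the simulator reproduces it.

**Outputs and ground truth.** Each read records its source strain, start,
strand, edit list, and identity. The truth SAM expresses every read against
the **ancestor** coordinates — strain substitutions and sequencing errors
composed into CIGAR + NM — so the recruitment module can be validated
exactly against the truth table (`true_identity` is likewise
ancestor-relative). FASTQ qualities are a constant placeholder ('I'); they
are not used downstream. Reads are 150 bp by default (200 bp fragments for
long-read shreds via `shred_reads`). Outputs are byte-identical under a
fixed seed.

**What the simulator does not emulate.** Real gene-content variation
(~79% shared genes among the real isolates), GC/positional coverage biases,
quality-score structure, true paired-end inserts, and reference N's. Passing
tests therefore demonstrate the depth-bias mechanism (allele sampling +
plugin estimator + error floor), not every property of real recruitments.

## Rarefaction and bias statistics

Subsampling is exact without replacement by default (`floor(fraction · N)`
units, mates kept together), with Bernoulli thinning as an option.
`rarefy_to_depth` converts a target depth into a fraction and refuses
infeasible targets. The diversity ratio is subsample metric / full-data
metric, with the full-data value computed once and reused as the fixed
denominator across replicates; a zero full-data value (clonal error-free π)
leaves the ratio undefined (NaN) and excluded from summaries. The average
absolute error is relative, `100·|sub − full| / full`, summarised per depth
bin {<10X, 10–50X, 50–200X, >200X} (bins chosen for tabular summaries; the
original analyses plot continuous depth). Both definitions applied to π and
ANIr alike.

## Experiment driver and problem sizes

`run_insilico_design` crosses strain counts × error profiles, one strain
set per strain count shared across profiles so error effects are compared on
identical communities. All seeds derive from one master seed through
`numpy.random.SeedSequence` (strings hashed via crc32), so reruns are
byte-identical and the paper-scale design is a config change, not a code
change.

Problem sizes are the package's own scaled-down defaults, chosen to keep any
single run in the minutes range on one core while staying deep enough for
the asymptotic regimes to show: default config 200 kb genome, strain counts
{1, 5, 20, 100}, ~300X full depth, 1–90% fraction grid, 3 replicates. The
analysis scripts use: 200 kb/100X (clonal baseline), 100 kb/600X/100 strains
(rarefaction bias), 50 kb/300X/12-metagenome grid (full design). The
acceptance script uses a 100 kb, 100-strain Q30 metagenome at ~1000X
(666,667 reads) for the rarefaction targets and 100k-read clonal runs for
the error-model targets.

## Numerical and design choices

- 0-based half-open coordinates internally; SAM output is 1-based as the
  format requires.
- Best-match ties: leftmost reference start, then lexicographic reference
  id — an arbitrary but deterministic rule.
- `genome_pi` returns NaN (not 0) when no site reaches `min_cov`; empty
  recruitments raise for ANIr and propagate NaN in tables.
- Error summaries report the population standard deviation (0 for
  single-point bins) and count excluded zero-denominator points.
- Reference FASTA loading is strict A/C/G/T; ambiguity codes are rejected
  rather than silently miscounted (real MAGs with N's are out of scope).
- The π variance-attribution step of observational comparisons (PERMANOVA)
  is not reimplemented; `compare_environments` emits a table formatted for
  external PERMANOVA software (e.g. vegan's adonis2).

## Known limitations

- Identity is computed against a single reference; with many divergent
  strains ANIr conflates error and divergence exactly as it does in real
  recruitments (intended), but there is no mm-level stratification.
- Unpaired simulation only; pairing logic is exercised through constructed
  alignments in tests.
- Subsampling treats the recruited read set as the population; no
  re-mapping after subsampling (equivalent for identity-filtered single
  references, cheaper to compute).
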