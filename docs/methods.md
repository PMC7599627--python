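# Methods

## Model and assumptions

The package treats ZW differentiation as a piecewise process on the Z
coordinate frame. Each stratum is an interval whose W copy stopped
recombining at one time; within it, Z/W divergence is modeled as an
independent per-site substitution probability, constant across the
interval. The PAR recombines, so Z and W are identical there. W decay is
modeled as deletion of intervals (absent sequence), not as N-runs. These
assumptions make windowed Z/W identity a step function plus binomial noise,
which is what the segmentation stage exploits.

Sex-linkage classification assumes a female sequenced individual: one W and
one Z against two copies of each autosome, hence half-coverage for all
differentiated sex-linked sequence. Identification is two-dimensional —
depth separates sex-linked from autosomal, and alignment to a reference Z
separates Z from W — because in a female depth alone cannot distinguish Z
from W.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| depth window size | 50 000 | bp | averages Poisson noise to ~1% at 30×; matches the scale at which scaffold coverage is usually assessed |
| min covered bases per window | 30 000 | bp | drops windows dominated by unmappable sequence |
| half-coverage band | (0.35, 0.65) × baseline | — | wide enough for Poisson noise at ≥20×, narrow enough to exclude autosomes |
| Z-aligned fraction threshold | 0.60 | — | above it a scaffold is Z-linked regardless of depth |
| alignment filters | ≥60% aligned fraction, ≥65 bp, ≤96% identity | — | short/low-fraction hits are spurious; near-perfect hits are repeats, not gametologous sequence. Boundary-inclusive because the removal rules are strict inequalities |
| similarity window | 100 000 | bp | one window ≈ 1e5 compared sites ⇒ binomial SE of identity ≈ 0.15 percentage points |
| segmentation: max segments 4, min 5 windows/segment, PAR threshold 0.985 | | | a PAR plus up to three strata; 5 windows (0.5 Mb) is the smallest block worth calling a stratum; 0.985 separates PAR (identity ≈ 1) from even the youngest strata (≈ 0.94) |
| expression thresholds | TPM < 1 removed; F/M fold > 2; R_ovary > 0.20; TPM > 50 high | — | strict inequalities at every boundary |
| HI threshold | 0.4 | probability | haploinsufficiency scores above it mark dosage-sensitive genes |
| k-mer k | 27 | nt | odd (no palindromic canonical collision), fits 2-bit encoding in 64 bits |
| k-mer error floor | 4 | count | excludes the sequencing-error spike from peak search |

## Numerical choices

- **Windowed depth.** A position counts as covered when its depth is
  positive (samtools-depth output omits zero positions anyway); window mean
  depth averages covered positions only. Per-scaffold depth is the
  covered-bases-weighted mean of retained windows; the autosomal baseline
  is the median retained-window depth, robust to the sex-linked minority.
- **Windowed identity.** Blocks spanning window edges contribute matches
  and aligned length pro-rata by bp overlap of their Z span. Window
  identity is length-weighted (Σ matches / Σ aligned), not a plain mean of
  block identities, so short noisy blocks do not dominate. Windows with no
  aligned bp have undefined identity and are excluded from means and from
  the segmentation fit.
- **Segmentation.** Piecewise-constant least squares solved *exactly* by
  dynamic programming for each candidate changepoint count (0 to 3), with
  BIC (`n·log(RSS/n) + 2k·log n`, two parameters — level and location —
  per changepoint) choosing the count. Exact search was preferred over
  greedy binary splitting because at these problem sizes (≤ a few hundred
  windows) it is equally cheap and provably optimal, so it always agrees
  with a brute-force changepoint scan. Ties in the DP break toward the
  earliest split; an `--boundaries` override accepts user-specified
  breakpoints. With fewer than 10 defined windows a single segment is
  returned with a warning. Labels: segments at ≥ the PAR threshold are PAR;
  the rest are S0, S1, … by increasing mean identity (oldest = most
  diverged = S0).
- **Distances and trees.** p-distances exclude gap columns pairwise and
  error on empty overlap. Neighbor joining is implemented directly with a
  deterministic tie-break (lowest-index Q-minimal pair) so trees are
  reproducible; branch lengths are clamped at zero. The origin test needs
  only the topology: it checks tree bipartitions, so no rooting step is
  required — 'shared' iff the W leaves form one side of an edge,
  'independent' iff every species' Z+W pair does. An outgroup, if present,
  simply participates in the tree.
- **Fisher's exact test.** Two-sided by the probability-mass rule, computed
  by full hypergeometric enumeration in exact integer arithmetic (floats
  enter only in the final division). This matches the convention of
  mainstream statistics packages; the suite cross-checks against scipy on
  random tables and against an independent float enumeration on all tables
  with total ≤ 40.
- **R_ovary.** The denominator excludes the ovary itself (the
  "other-tissue" reading); `denominator="all"` switches to including it.
  Zero denominators yield nan, reported not-dominant.
- **Profile comparison.** Spearman's rho on log1p(TPM) of the five female
  tissues; computed from the untied rank-difference formula when ranks are
  unique (so identical profiles give exactly 1.0), falling back to Pearson
  on ranks under ties.
- **k-mer counting.** Canonical k-mer = min(forward, reverse-complement)
  of the 2-bit rolling encoding; windows containing non-ACGT bases are
  skipped. Counts accumulate per ~20 Mb chunk and merge by sorted-array
  aggregation; a naive dictionary oracle verifies equality in the tests.
  The spectrum peak is the smoothed (width-3 moving average) mode among
  multiplicities ≥ error floor; `peak="mean"` instead uses the
  count-weighted mean multiplicity above the floor, since a one-line
  "mean coverage at the peak" rule admits both readings. Zero counts stay
  in the gene median so a deleted gene estimates copy number 0; rounding
  is half-up.

## What the generator emulates — and what it does not

`simdata` reproduces the *signal structure* of a female ZW re-sequencing
study: strata as independent per-site divergence blocks, W deletions as
omitted 1-kb tiles, Poisson(λ) per-base depth with λ halved on sex-linked
scaffolds, uniformly placed error-bearing reads with the copy-number gene
hemizygous (W-like) on one haplotype, log-normal TPM with planted
female-biased (female columns × fold), ovary-dominant (ovary set equal to
the sum of the other nine tissue-sex cells, ratio 0.5) and W-gametolog rows
(zero in males, a fixed down-regulation factor × the Z female values).
Gametolog sets are generated by mutating a root CDS along a two-epoch
history (recombination stop vs speciation first), giving near-additive
p-distance matrices.

It does **not** emulate: indels or rearrangements (apart from W deletions),
repeats and mappability structure, GC or coverage bias, substitution-model
heterogeneity or multiple hits (relevant only at divergences well above
0.3), read mapping artifacts (depth tables are consumed as if pre-filtered
at high mapping quality), or biological replicate noise beyond an optional
log-normal factor. Passing tests therefore demonstrate correctness of the
inference rules under their own model assumptions, not robustness to every
artifact of real libraries; on real data the upstream mapping, repeat
masking and alignment filtering carry that burden.

Default study conditions used by the test suite: 2 Mb chromosomes with
strata at divergences 0.30 / 0.20 / 0.06; 100-scaffold genomes at 30×
female depth; copy-number runs on a 1 Mb background at 60× diploid with
0.2% read error; origin tests on 3 kb CDS with branch divergences 0.10
(older epoch) and 0.02 (younger epoch), 100 seeded replicates.

## Known limitations

- The classifier cannot separate W from differentiated Z without the
  reference-Z alignment input; both sit at half coverage in a female.
- Stratum labels are identity ranks; two strata of similar age can swap
  labels when their identities are within noise of each other.
- The origin test is topology-only; it does not attempt to date events or
  to handle gene conversion between gametologs, which can make an old
  stratum look young locally.
- k-mer counting holds the count table in memory; it targets desk-scale
  datasets (≲ a few hundred Mb of reads), not full vertebrate-genome
  shotgun archives.
- Haploid-coverage estimation assumes a unimodal homozygous peak; very low
  coverage (peak below the error floor) raises an error rather than
  guessing.
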