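# Methods

## The statistic

All analyses reduce to the Shannon entropy of a discrete distribution
over group labels, H(X) = −Σ pᵢ log₂ pᵢ, in bits, with 0·log₂ 0 ≡ 0 so
empty groups contribute nothing. What varies between analyses is what
counts as an *item* and what counts as a *group*:

| analysis   | item                     | group                               |
|------------|--------------------------|-------------------------------------|
| network    | transcript               | co-expression module                |
| eQTL       | eQTL record              | genome bin (chromosome, cM window)  |
| circadian  | transcript (per CT hour) | CT phase group or module            |

The quantity of interest is the entropy of the top-*N* expressed items'
group distribution, divided by the entropy of the complete set under the
same grouping ("fraction of maximal information"). The denominator is
the experiment's own full-set entropy, not log₂ k: the question is how
much of *this* experiment's information survives subsetting, not how
close the subset comes to a uniform ideal. At N = total the fraction is
exactly 1 by construction.

Ranking is by descending expression with ties broken by ascending gene
identifier, so orderings are bit-reproducible across platforms and
input orders. Genes without a group assignment are excluded from both
numerator and denominator by default (logged count in the error path);
`include_unassigned=True` instead pools them into a reserved
`_unassigned` group. Duplicate memberships in input tables are rejected
unless the caller explicitly keeps the first listed one.

## eQTL binning

Genome coordinates are genetic (cM), 0-based per chromosome, with
half-open bins [w·j, w·(j+1)): a position exactly on a boundary falls
into the higher bin. Coarser resolutions (5, 10 cM — emulating smaller
mapping populations) can be computed either by direct binning or by
merging 1 cM counts (`rebin`); the two routes are identical because the
coarse widths are integer multiples of 1 cM, and merging can only lower
entropy (merge inequality), which is what makes the resolution ordering
H(1) ≥ H(5) ≥ H(10) a theorem rather than an empirical finding.
Normalisation is over eQTL records, not transcripts: a transcript with
three eQTL contributes three counts; a transcript with none occupies a
subset slot but contributes nothing. Fractions default to each
resolution's own full-set entropy (per-series normalisation), with a
flag for a common 1 cM denominator.

Hotspot profiles are unsmoothed per-1 cM count vectors, concatenated
chromosome by chromosome; subset agreement is the Jaccard index of the
top-k bins (ties broken by bin order), with k defaulting to the number
of planted hotspots in synthetic runs.

## Circadian analysis

CT phase groups bin each gene's peak phase at a width dividing 24 h
(1 h → 24 groups, 0.25 h → 96); the 0.25 h grouping refines the 1 h
one, so its entropy is cell-wise ≥ — again a theorem, checked as such.
Ranking is recomputed independently at every time point (replicate
columns averaged first), because rank turnover over the cycle is exactly
the threat the per-time-point analysis probes. The time effect on
entropy is tested with a one-way fixed-effects ANOVA implemented from
its sums-of-squares definition (F = MSB/MSW, upper-tail p from the F
distribution); replicate entropies come from replicate columns. The
all-identical degenerate case returns F = 0, p = 1; zero within-group
variance with a real between-group effect returns F = ∞, p = 0.

Oscillation reconstruction: per CT group, the mean expression of the
group's members inside each time point's top-N subset, compared with
the full-set trajectory by Pearson correlation over shared time points
(constant series are reported as undefined rather than r = 0; fewer
than 3 shared points is an error).

## Read depth

Reads are i.i.d. multinomial over transcripts — no length, GC or
positional bias, because the question is purely how many reads it takes
to see a gene k times. The per-gene count at depth R is Binomial(R, p),
so E[genes ≥ k] = Σ sf(k−1; R, p) via `scipy.stats.binom.sf`, which is
stable across the small-p/large-R regimes involved (no separate Poisson
fallback proved necessary). `reads_needed` bisects this monotone
expectation with an expanding upper bracket, so it is exact to one
read. The simulation/analytic agreement check uses the analytic
variance bound Σ sf(1−sf) (the multinomial's negative covariances make
it conservative), which keeps the 3-SE band meaningful at small
replicate counts. Multiplexing capacity is floor(lane reads / reads per
sample).

## Synthetic world

One master seed spawns an independent, fixed child stream per generator
(`numpy.random.SeedSequence([seed, stream])`), so any stage regenerates
identically in isolation. Defaults, chosen once for realism at the
scale of the emulated study system (Arabidopsis ATH1 transcriptome):

- **Modules**: 22,746 genes in 1,000 modules (the order of the
  published Arabidopsis regulon catalogues), sizes ∝ rank^−γ with
  γ = 1.0 (scale-free; exponent unknown for the real table, exposed in
  config), largest-remainder rounding so sizes sum exactly.
- **Expression**: log-normal, exp(module offset + gene offset + noise)
  with module sd 1.0, within-module sd 1.5, noise sd 0.25 (natural
  log). The within-module spread makes each large module span >2
  orders of magnitude — the property that lets small top-N subsets
  touch most modules. Under these defaults the full-set entropy is
  ≈7.5 bits, the same co-expression regime as the published regulon
  table's 7.1 bits (see *External check* below).
- **eQTL**: five chromosomes of 120/80/90/100/110 cM; per transcript a
  Poisson(1.5) number of eQTL; cis with probability 0.3 (at the
  transcript's own uniform position), otherwise trans from a bin
  mixture with two planted hotspots (chr 2 @ 30 cM, chr 4 @ 65 cM) at
  20× background weight.
- **Clock**: log-expression = mesor + A·cos(2π(t − φ)/24) + noise with
  mesor sd 1.5, amplitude A = 1.0 (≈7-fold peak-to-trough), noise sd
  0.2, phases uniform on [0, 24), CT 0–44 h every 4 h, 2 replicate
  columns per point.
- **Abundances**: normalised exp(N(0, 2.0²)); the top 5,000 genes
  carry well over half the reads, putting the 10×-on-5,000-genes depth
  at the few-hundred-thousand-read order.

## What a green test does and does not establish

The generators reproduce the *statistical shape* the analyses assume,
not the real datasets: no probe-level artefacts, no normalisation
effects, no real gene identifiers, no linkage structure in the eQTL
map, and module membership independent of expression level. Green
property tests therefore establish that the machinery is correct and
that the qualitative findings (most information in a small top slice;
resolution and refinement orderings; hotspot recovery; saturation
arithmetic) hold in a world with the stated structure — not that the
real data's printed fractions are reproduced. Quantities that depend on
the unavailable real data (the 7.1-bit regulon entropy, the 250,000-read
landmark from unpublished reads) are treated as calibration anchors:
the defaults land in the same regime but are not fitted to them.

**External check.** Computing the real full-transcriptome entropy under
the published regulon table only requires its two-column
(gene, module) form and `subset_entropy(profile, modules, n_total)`;
the table is external supplementary data and the check is therefore
optional and offline, not part of CI.

## Known limitations

- **Subset selection bias in CT-group reconstruction.** With uniform
  phases and log-normal baselines, a phase group in antiphase to the
  sampled hour keeps only its highest-baseline members inside the
  top-N subset; conditioning on crossing the subset threshold inflates
  the group mean exactly at trough, so small-subset trajectories
  flatten or even invert for some groups (at n = 1000: median r ≈ 0.92
  but minimum ≈ −0.35 at seed 1; by n = 5000 the minimum is ≈ 0.98).
  Real microarray data evidently reconstructs from smaller subsets;
  the synthetic world's baseline-vs-amplitude geometry makes boundary
  turnover harsher. The tests assert the computed behaviour (fidelity
  monotone in subset size, exact at full size) rather than a smaller-n
  claim this world does not support.
- The ANOVA assumes independent replicate entropies per time point;
  replicate columns generated by the clock simulator satisfy this by
  construction, real designs may not.
- `reads_needed` targets the *expected* gene count; a single library
  fluctuates around it with the variance bound given above.
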