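# Methods

This note documents the models, rules, and numerical choices behind
`chromloop`, and what the synthetic fixture does and does not show
about real data.

## Interaction calling

### Simple (loose) caller

Read pairs are filtered by restriction-site separation: an
intra-chromosomal pair is kept only if strictly more than `min_sites`
(default 3) cut sites lie strictly between its two 5′ positions. The
filter compensates for non-uniform cleavage spacing and removes
self-ligation/undigested products as a side effect (0 sites between ⇒
removed). Inter-chromosomal pairs are exempt: the criterion is a
genomic-distance rule with no meaning across chromosomes.

Retained pairs are assigned to 250 bp bins by floor division of the 5′
coordinate, and bin pairs are counted. The count threshold is derived
at the shortest considered distance, 4 bins: the smallest integer *t*
such that the fraction of distance-4 bin pairs with count ≥ *t* is at
most the top fraction (default 0.05). Ties at the boundary therefore
never exceed the nominal fraction. The threshold is floored at 2 reads
(two independent ligation events) and applied as a minimum count to all
larger distances and to inter-chromosomal bin pairs. We read "that
maximum number was applied to all subsequent bins" as exactly this:
the distance-4 cutoff reused as a count minimum at every greater
distance. Whether the distance-4 bin pairs themselves are kept as calls
is a flag (`keep_derivation_distance`, default on).

Scores: `score = count × (total retained read pairs / total calls in
the sample)`. "Total reads" means pairs surviving the site filter —
the raw sequenced total is unavailable after simulation and would only
rescale all scores by a constant. Scores are monotone in count within a
sample, so rising cutoffs give nested call sets.

### Stringent caller

Pairs are binned at 1 kb; intra-chromosomal bin pairs more than 3 kb
apart are tested. Per chromosome the contact matrix is balanced by
iterative correction; the update is square-root damped
(`bias ← bias·√(rowsum/mean)`), which converges in tens of iterations
even when one planted contact dominates a row (the undamped update can
stall). Rows with zero mass are masked.

The expected corrected count at bin distance *d* is the genome-wide
mean over *all* unmasked bin pairs at that distance (zeros included).
Distances with fewer than 50 bin-pair instances are merged greedily
with neighbours, and the profile is smoothed with a 3-point running
mean and linearly interpolated. A bin pair's expected raw count
restores its two ICE biases, globally rescaled so expected mass equals
observed mass; the p-value is the Poisson upper tail. This replaces a
spline-based distance model with a stratified one — validated by
calibration (uniform nulls are flagged at the nominal rate) rather
than by output identity with any external tool. Bin pairs with fewer
than 2 reads can never be calls and are excluded from the tested
universe (the expected model still uses them).

The FDR cutoff is permutation-calibrated: the largest candidate p such
that, averaged over ≥ 100 random interaction sets of equal size drawn
from the tested universe, the fraction of random p-values at or below
it stays ≤ α (default 0.05). Degenerate (all-equal) p-value sets get a
cutoff just below the minimum and a warning.

## Architecture

The compartment profile is the leading eigenvector of the Pearson
correlation matrix of bin contact profiles (zero-mass bins masked),
computed directly rather than through any external browser tool. Sign
convention: the larger cluster is positive; ties break on the loading
sum, which is permutation-invariant. Telomere metaplots average
anchored call counts in 20 kb offset bins over all chromosome ends;
centromere fractions report the percentage of inter-chromosomal calls
with both ends in the (optionally flanked) centromere mask, pooled and
per replicate.

## Classification and enrichment

Chromatin state splits the log2(H3K4me2/H3K9me2) ratio (pseudocount
0.1) at the kernel-density minimum between the two largest modes; a
unimodal distribution falls back to 0 with a warning. Methylation
classes use per-context thresholds 0.8 / 0.4 / 0.1 (CG/CHG/CHH) —
implementation defaults placed in the valley of typical bimodal level
distributions; the boundary value itself classifies as high (≥ rule).
DMBs are high-CHH wild-type bins with mutant/wild-type ratio < 0.25;
ratios > 0.75 are "other meCHH"; boundary values are "neither"; zero
wild-type levels are excluded and counted.

Enrichment at a feature bin set is observed anchored calls (a call
with both ends in features counts once) over the mean across
permutations (default 1000, seeded) of equal-size bin draws from the
mappable, non-centromeric universe. Ratios are reported pooled and per
replicate, with a two-sided paired t-test across replicates. Paired
differences that are identically zero give p = 1; nonzero but
zero-variance differences are degenerate and reported as p = 0 with a
warning.

Rank-sum comparisons (expression stratifications, ChIP enrichment,
fold-change splits) use the exact Mann–Whitney distribution when both
groups are below 20 without ties, otherwise the tie-corrected normal
approximation.

## The TSS × DMR surface

Calls at ≥ 10 kb separation contribute their score to every (TSS
offset, DMR-center offset) cell within ±5 kb (250 bp steps) of their
two ends; TSS offsets are strand-flipped. Cells accumulate *summed*
score: per-cell means are dominated by rarely-hit cells carrying a
single large-score call. The same accumulation over n (≥ 10)
size-matched uniform random region sets gives a background surface
whose mean is subtracted; a min–max scaled copy maps the result onto
[0, 1].

## Synthetic fixture

The generator is a pure function of (config, seed) and emulates the
study conditions downstream statistics are validated against:

* genome: 5 chromosomes × 2 Mb, cut sites from a Poisson process at
  4 sites/kb (a 4-cutter's genome-wide average), central centromere
  mask (10 %), 40 kb telomeres;
* intra-chromosomal background distances from a truncated power law
  ∝ (d + d₀)^(−α), d₀ = 1 kb (avoiding the singularity at d = 0),
  α = 1 by default — the availability-corrected log-log fit recovers α
  within a few percent at 10⁶ pairs;
* inter-chromosomal background (5 %) with telomere–telomere (10 %) and
  centromere–centromere (40 %) shares routed through per-interval
  hotspot positions seeded from the interval coordinates — stable
  across replicates and genotypes, mimicking repeat-element contact
  hotspots; without hotspots no inter-chromosomal bin pair recurs at
  desk-scale depth and none would survive the count threshold;
* planted loops with per-genotype intensity multipliers; a loop yields
  Poisson-distributed pairs with mean proportional to its multiplier,
  so excess counts are linear in intensity. Three classes: RdDM-
  repressed loops (true-DMR anchor ↔ gene promoter, 20–500 kb, off in
  wild-type except a 40 % borderline-detectable subset at a tiny
  absolute multiplier), constitutive loops (TF peak ↔ promoter, all
  genotypes), and genotype-neutral loops at stable-methylation DMR
  calls (see below) at 3–9 kb;
* background suppression modelling contact inhibition at methylated
  chromatin: true DMRs retain only 30 % of background pairs in
  wild-type and all of them in mutants; stable meCHH regions retain
  30 % in every genotype; inactive blocks retain 40 % everywhere;
* tracks with the classification structure the analyses need: bimodal
  log-ratio chromatin (modes ±gap/2, sd 0.5), high-CHH features whose
  mutant/wild-type ratio is ~0.1 at true DMRs and > 0.8 elsewhere,
  uniform control coverage with 2 % dropouts, MNase ratio 3 at a
  random half of the true DMRs;
* expression: lognormal base RPKM; genes wired to active loops are
  boosted 4-fold, so RdDM-loop genes are up-regulated only in mutants
  (DE label "up") and constitutively looped genes are highly expressed
  everywhere.

**False-positive DMR calls.** The published-style DMR BED mixes true
DMRs with intervals whose methylation does not change — as real DMR
call sets do. The neutral promoter loops anchor there. This makes
random-gene DMR-connection counts nonzero and genotype-balanced
(control ratio near 1) without touching the DMB class (stable
intervals never classify as DMBs) or the interaction surface (3–9 kb
is below its 10 kb floor). At this fixture size random gene sets still
catch some regulated genes (~3 % of genes are DE), so the control
ratio sits slightly above 1 (typically 1.1–1.7) while the DE-gene
ratio is several-fold.

**What passing does not show.** The fixture has no ligation chimeras,
PCR duplicates (an optional rate exists but defaults to 0), mappability
structure beyond random dropouts, copy-number or GC bias, or realistic
methylation landscapes beyond the classification structure; scores are
far larger than in deep real data because call counts are small, so
the published score cutoffs 5/10/15 are nested but not selective here.
Recovering the planted directions demonstrates the statistics measure
what the generator encodes — not that real data would show the same
effect sizes.

## Problem sizes

Defaults used by the tests and the acceptance script: 5 × 2 Mb genome,
150 k pairs per replicate × 3 replicates per genotype, 500 genes, 45
true + 30 false DMRs, 60 other-meCHH regions, 15 RdDM loops;
permutations 300–1000; decay fits at 10⁶ pairs. These sizes keep the
full suite within a few minutes on one CPU while leaving every
direction statistically unambiguous (the planted-direction checks hold
across seeds with wide margins).

## Known limitations

* The stringent caller's stratified expectation is coarser than a
  spline fit at very short distances; with `min_distance` = 3 kb this
  region is excluded anyway.
* `combine_replicates` concatenates pair tables; it does not verify
  genome identity beyond downstream chromosome checks.
* The CLI's stage subcommands replay the (deterministic) upstream
  chain rather than deserializing intermediate state; stage isolation
  is at the file level for outputs, not inputs.
* Inter-chromosomal significance testing is out of scope: the
  distance-stratified model is intra-chromosomal by construction.
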