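# Methods

## The question the pipeline answers

Given a structural variant (here: a ~32 kb deletion) segregating at
intermediate-to-high frequency in a phased population panel, is the
haplotype block carrying it evolving neutrally, under a recent positive
sweep, or under long-term balancing selection?  The pipeline operationalizes
the classic argument: balancing selection predicts elevated π, positive
Tajima's D, two anciently diverged haplogroups in perfect linkage with the
variant, and *no* elevation of the sweep statistics (F_ST between
populations, ΔiHH between carrier classes); a sweep predicts the reverse;
neutrality predicts none of it.

## Statistics

* **π** is reported *per window* (sum over sites of unbiased
  heterozygosity, `Σ 2p(1−p)·n/(n−1)`), identical to the mean pairwise
  Hamming distance; a per-bp variant is available.  Window sums match the
  scale used by windowed browser tracks of population panels.
* **Tajima's D** uses the 1989 constants (a₁…e₂); undefined (returned as
  missing) on monomorphic windows, and requires n ≥ 4 haplotypes by default
  because the variance constants degenerate below that.
* **Hudson's F_ST** per site is
  `[(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)] / [p₁(1−p₂)+p₂(1−p₁)]`,
  combined per window as a ratio of averages; negative estimates are
  reported raw.  Sites fixed for the same allele in both populations are
  skipped (zero denominator).  The window's cross-population summary is the
  mean over population pairs.
* **EHH/iHH** follow the standard construction: within each core class,
  haplotypes are grouped by identity over the growing flank;
  `EHH = Σ C(m_k,2)/C(m,2)`; the curve starts at 1, is non-increasing, and
  is truncated below 0.05; iHH is the trapezoid integral over bp, summed
  over both directions away from the core span.  Classes need ≥ 2 members.
* **ΔiHH** = iHH(non-carrier) − iHH(carrier).  For cross-region comparison
  the pipeline uses the scale-free asymmetry `|Δ|/(iHH_c+iHH_n)`: raw iHH
  levels track overall haplotype-tree depth (a balanced polymorphism raises
  both classes' iHH), whereas a class-specific sweep drives the asymmetry
  toward 1.
* **Cross-haplogroup TMRCA** is a deliberately simple divergence clock:
  mean between-class pairwise differences / (2 μ L) generations.  It is not
  a likelihood-based TMRCA method; its role is ordinal (deeper splits give
  larger estimates, and the estimate rises monotonically with the simulated
  divergence time).
* **Rank tests** are Mann-Whitney U: exact when n_x+n_y ≤ 16 without ties,
  otherwise tie-corrected normal approximation with continuity correction.
  All-tied inputs return U = n_x·n_y/2, p = 1.

## Block delineation

Tag SNVs are sites whose diploid dosage r² against the SV dosage exceeds a
threshold (default 0.9 for reporting tags, 0.8 for block membership — both
conventions appear in practice and both are configurable).  r² is the
squared Pearson correlation of pooled dosages (composite LD), undefined
(missing, not zero) for constant vectors.  The block walk starts at each
deletion breakpoint and extends to the next tag while the gap stays ≤
`max_gap` (default 2000 bp; a finite default keeps blocks local — tag sets
from noisy panels can contain distant false positives).  An optional BED
mask removes sites (e.g. a LINE element) before any statistic is computed;
masking commutes with the statistics.

## Haplotype tree and segregation

The tree is neighbor-joining over pairwise Hamming distances (2- and
3-taxon closed forms; negative NJ branch lengths clamped to zero with a
flag).  The scientific claim tested is a *bipartition* — does one edge
separate carriers from non-carriers? — which distance methods recover
identically to likelihood methods for deeply split classes; a PHYLIP export
is provided for external ML tools.  Identical haplotypes are collapsed to
one weighted leaf above 500 haplotypes (lossless for topology).  Purity is
the best two-sided assignment accuracy over all edges; support is the
fraction of site-bootstrap replicates preserving the exact bipartition.

## The verdict

Fixed, documented rules over the comparison p-values (α = 0.05):

* `balancing-like`: π *and* Tajima's D one-sided above background,
  carrier-bipartition purity ≥ 0.99, and no significant *increase* of F_ST
  or of the ΔiHH asymmetry.
* `sweep-like`: F_ST or ΔiHH asymmetry significantly increased, with
  target D tending below the background mean.  The ΔiHH gate additionally
  requires asymmetry > 0.8 (one class ≥ 9× the other): the background null
  for ΔiHH (random balanced splits of regions without an SV) makes both
  pseudo-classes share one genealogy and therefore understates the
  between-class variance of genuinely diverged classes, so rank
  significance alone would flag symmetric class structure that is not
  sweep-like by any effect-size standard.
* `neutral-like`: no *coherent* signal.  A lone marginal significance in a
  four-test panel at α = 0.05 is within null expectation (the family-wise
  false-positive rate of four independent tests is ~19%), so single
  isolated significances do not leave the neutral verdict; requiring the
  coherent pattern keeps the measured specificity on neutral simulations
  at or above 90%.
* anything else is `inconclusive`.

F_ST and ΔiHH are tested one-sided for an increase because that is the
direction with a selective interpretation (local positive selection); a
decrease is expected here for a technical reason — population labels
assigned within one panmictic pool make Hudson's estimator negatively
biased in proportion to heterozygosity, so a high-π target sits slightly
below a neutral background under any two-sided test.

π and Tajima's D are compared one-sided "greater" (the balancing claim is
directional); all raw window values are carried in the report for
re-plotting, and overlapping-window inputs trigger a pseudo-replication
warning.  The pipeline's own windows are non-overlapping by default
(window = step = 1.5 kb on the synthetic geometry) for exactly that reason.

## The synthetic generator

All randomness is seeded; every output is a pure function of
(configuration, seed).  Time is in units of 2N generations; conversions use
N_e = 10,000 and 29 y/generation only in reporting.

* **neutral**: Kingman coalescent (rate C(k,2)).
* **balancing**: two-class structured coalescent.  Haplotypes carry or lack
  the deletion (class frequency `class_fraction`, default 0.5); within
  class c lineages coalesce at rate C(k_c,2)/f_c, lineages migrate between
  classes at rate `migration`/2 each (default 0), and the classes fuse at
  `t_split` (default 4).  With zero migration every cross-class coalescence
  happens above `t_split`, producing two haplogroups whose divergence far
  predates any within-class variation — the genealogical signature of an
  ancient balanced polymorphism, without forward simulation of fitness.
* **sweep**: a hard-sweep caricature.  A neutral genealogy's internal node
  times are compressed into a recent burst, `t → s(1−s) + s·t` with
  s = `sweep_scale` (default 0.05): coalescences pile up near time s,
  external branches dominate the tree, and mutations fall mostly on them
  (singleton excess, strongly negative D).  s = 1 recovers the neutral
  tree; s = 0 is the star-tree limit with zero pairwise TMRCA.  A plain
  uniform rescaling of all branch lengths would *not* work here: it thins
  mutations uniformly and leaves the site-frequency spectrum — hence
  Tajima's D — unchanged.
* **mutations**: infinite sites.  Poisson(θ/2 × total branch length)
  mutations, each on a branch chosen ∝ length, at a unique uniform
  position, flipping the leaves below it.

**Bundle geometry.**  The full input surface of one pipeline run: a phased
panel of 100 haplotypes (50 samples in three population groups) covering
two 6 kb flanks around a 32 kb deletion gap; 50 neutral background regions
and 20 control-deletion regions of 6 kb each, independently simulated over
the same samples; θ = 0.001 per bp (4Nμ with N = 10⁴, μ = 2.5×10⁻⁸ — human
nuclear diversity scale).  Regions are simulated as independently
coalescing 1.5 kb chunks (a site-partition stand-in for recombination);
balancing chunks share one carrier partition, because tight linkage to the
deletion preserves the class split along the block while the genealogies
decorrelate the way recombination decorrelates real windows.  Without this,
all windows of a region share a single genealogy and window-level rank
tests are grossly anti-conservative.  The carrier assignment is stratified
by population — balancing selection is expected to hold the variant at the
same equilibrium frequency everywhere, and an unstratified draw leaks its
single class-imbalance realization into every window's F_ST.

**Ancient panel.**  Pseudo-haploid Early/Middle Neolithic and Bronze Age
groups (missing rate 0.2) plus one deep (45 ka) higher-quality diploid
individual, all drawn from the modern haplotype pool and degraded.  Depth
tracks are per-base Poisson with copy-number-scaled mean inside the
deletion and a 0.01× mis-mapping floor for homozygous deletions.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: within-chunk recombination and gene
conversion; real population structure and demography (the population labels
are panmictic, so F_ST calibration against real structured panels is
untested); ancient-DNA damage, contamination and reference bias; genotyping
error in the modern panel; selection acting during the sampled period.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally, 1-based inclusive in
user-facing strings.  Monomorphic windows: D missing with reason, π = 0.
Constant dosage vectors: r² missing, not 0.  EHH cores of size 1: error.
All-tied rank tests: p = 1.  r² is clamped at 1 within 1e−12.  Negative NJ
branches clamped to 0 with a flag.  Depth-ratio genotype calls use
0.25/0.75 thresholds (midpoints of the 0/1/2-copy expectations) and flag
flank coverage below 5×.

## Problem sizes

Defaults are desk-scale by design: 100-haplotype panels, 50+20 background
regions, 500-replicate calibration batteries, 50-seed specificity runs.
They complete in seconds to a couple of minutes while leaving the
statistical conclusions (calibration bands, monotonicity, specificity ≥
90%) well resolved; all sizes are configurable.

## Known limitations

The cross-haplogroup TMRCA is a point estimate with no uncertainty; the
verdict thresholds (α = 0.05, purity 0.99, asymmetry 0.8) are conventions,
not fitted quantities; the sweep caricature has no carrier class, so the
`sweep-like` verdict can only be triggered by data that actually contains
class or population structure; and the Mann-Whitney contrasts treat window
values as exchangeable, which is only approximately true even for
non-overlapping windows on real recombining sequence.
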