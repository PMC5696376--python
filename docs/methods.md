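# Methods

`ms4c` implements the computational pipeline of a multiplexed,
sonication-fragmented 4C-seq assay (ms4C-seq): many bait loci are profiled
in a single sequencing library, and the analysis turns paired ligation
reads into per-restriction-site interaction tracks and downstream
statistics about chromatin colocalization. This note records the models,
the parameter choices, and the places where the design was genuinely open.

## Read model and processing

A valid read pair spans a HindIII (AAGCTT) ligation junction: R1 runs from
a bait-specific primer through the reconstituted motif into the ligated
partner fragment; R2 reads back from the sonication breakpoint. Processing
splits R1 at the **first** AAGCTT, keeping the motif on both halves — the
bait part is a primer-proximal suffix ending in the motif, and the target
part begins with the motif because the partner fragment genomically starts
at a reconstituted HindIII site. Bait assignment compares the bait part
against each bait's expected prefix (suffix-aligned; `N` acts as a
wildcard) and, when several baits still match (paralogous loci such as a
gene and its pseudogenes), consults per-bait discriminating SNP bases.
Unresolvable ties are dropped as ambiguous and tallied.

Mapping on synthetic genomes is exact substring match; since the motif
occurs only at restriction sites, candidate alignments are exactly the
sites, and multi-hit reads are dropped. Real data enter through a
pre-mapped pairs table instead (an aligner is out of scope); a mapped
position is assigned to the restriction site whose fragment contains it.
Self-ligation (target fragment = bait fragment) and undigested pairs
(either adjacent fragment; the symmetric reading of "no digestion") are
flagged and excluded. PCR duplicates share
(bait, chromosome, site, strand, breakpoint) — the breakpoint is the
sonication end read from R2, and strand is part of the key because
opposite-strand breakpoints are distinct molecules. The first pair of each
key survives, in stable input order; artifact-flagged pairs bypass
deduplication so the accounting categories stay disjoint and sum exactly
to the input (checked by `DropTally.check`).

## Count tracks: wiggle vs raw

Each kept pair increments **every** restriction site within 1000 bp
(inclusive) of its target position; this window-smeared track is the
wiggle (WIG) output and the input to cis-hit coverage. Sites closer than
2 kb share reads, which makes sums of wiggle values over a window
overdispersed relative to the underlying read count — enough to inflate
the null rejection rate of window statistics severalfold. `SiteCounts`
therefore also carries a *raw* track in which each read is counted once,
at the junction-proximal site of its target fragment. All window
statistics (contact tests, gene RPM) consume the raw track — "reads in a
window" means reads, counted once — while the wiggle remains the display
and interchange convention. Both tracks round-trip through the WIG writer.

## Contact statistics

Contact probability at a position is the enrichment of reads in a small
distance window (up to ±100 kb) relative to a large local window (±3 Mb),
which cancels the overall distance-decay background. Two regimes:

* **Proximal** (≤8 Mb from the bait): one-sided Mann–Whitney U
  (alternative "greater") comparing per-site raw counts inside the small
  window against the large window *excluding* the small window (exclusion
  avoids biasing the statistic toward 0.5). Normal approximation with tie
  correction; fully tied or empty windows report p = 1 with an
  "uninformative" flag.
* **Distal** (>8 Mb): exact one-sided binomial, k = reads in the small
  window, n = reads in the large window, p₀ = (sites in small)/(sites in
  large). Windows truncate at chromosome ends and p₀ uses the realized
  truncated site counts.

The domainogram evaluates all sites × a ladder of 20 log-spaced half-widths
from 2 kb to 100 kb and stores −log₁₀ p capped at 10 (the black→yellow
colour scale runs p = 1 → 10⁻¹⁰). Raw p is displayed; FDR enters only at
calling. Gene-level calls use the binomial form on TSS ± 25 kb vs ± 3 Mb,
with Benjamini–Hochberg adjustment across all genes tested per bait (the
FDR family) and a default q ≤ 0.05. Genes whose small window intersects
the bait ± 100 kb are masked: that zone is dominated by religation
geometry, the same reason self-ligation pairs are removed. Under a
power-law decay no single-site enrichment inside the bait's ±3 Mb
neighbourhood is statistically visible — the background window contains
the bait peak — so the simulated studies plant interactions several Mb
away, where the method is designed to operate.

## Reproducibility

Counts are binarized (any read → 1) and averaged over all sites within
±100 kb of each site (inclusive, consistent with the counting convention);
a site is always inside its own window, so coverage is always defined.
Two coverage tracks on the same site grid are compared by Spearman rho
with average ranks; a constant track has no rank ordering and the
coefficient is reported as undefined (NaN), never coerced to 0.

## Gene states

A gene's transcriptional state is read off a ChromHMM-style segmentation
as the occupancy of the 500 bp window [TSS−250, TSS+250) (half-open;
TSS is strand-resolved upstream). States pool into superstates:
Poised_Promoter → bivalent; Active_Promoter + Weak_Promoter → active;
Repressed + Heterochrom → repressive. "Mainly occupied" is formalized as
a strict plurality of occupied bp among the three pools; no occupied pool,
or a tie, gives "other". Uncovered bp count toward a null state so
fractions sum to 1. The pool membership is configurable — in particular
whether a 15-state vocabulary's "Heterochrom/lo"-style label belongs in
the repressive pool is a vocabulary decision the caller can change.

## LADs

DamID log₂(Dam-LMNB1/Dam) probe values are binarized (positive → +1,
non-positive → −1; exact zeros are treated as non-lamina). Each interior
probe is scored D(i) = mean(binary of right 99 probes) − mean(left 99
probes), excluding probe i. Candidate edges are local maxima of |D| above
a threshold (default 1.0: a strong majority sign flip, since fully
opposite windows give |D| = 2); ties between adjacent probes go to the
leftmost probe for determinism. The |D|-local-maximum rule is this
package's formalization of the classic sliding-filter edge call. Left
edges (D > 0) pair with the next right edge (D < 0); a leading right edge
extends to the chromosome start, a trailing left edge to the end, and an
edge-free positive track is one spanning LAD. Candidates survive only if
their mean raw signal is positive. Per-gene lamina association is the mean
probe value over the gene body; gene groups are compared by ECDFs and
two-sided Mann–Whitney tests against a reference group.

## Colocalization and knockdown statistics

Bivalent enrichment among a bait's called targets compares the observed
bivalent count with (targets tested) × (bivalent fraction of genes on the
bait chromosome, the bait gene excluded). The statistic is log₂(O/E); when
O = 0 a 0.5 pseudocount is added to both counts to keep it finite. Note
E[log₂(O/E)] carries a small negative Jensen bias of order
−Var(O)/(2 ln2 · E²); averaging over the baits of a multi-bait study makes
it negligible. 2×2 association tests are Fisher's exact, computed by
summing hypergeometric probabilities not exceeding the observed table's
(with a 1e−7 relative tie tolerance); a zero margin gives p = 1 with an
undefined odds ratio. Knockdown reduction rates are RPM(sh)/RPM(shNeg) in
TSS ± 25 kb; "reduced to at least 30%" is read inclusively as
rate ≤ 0.7, and a target is disrupted when both independent shRNAs meet
it. Rates are invariant to library depth because RPM normalization
cancels. Mann–Whitney comparisons in this module are two-sided.

## Library QC and complexity

QC reports totals, the cis:trans ratio, and the observed fraction of the
estimated distinct cis-interaction pool. Distinct interactions are unique
(site, strand, breakpoint) tuples among filtered cis pairs; their
multiplicity histogram is modelled as a zero-truncated gamma-mixed
Poisson (negative binomial), whose ML fit gives the unseen fraction and
hence the expected distinct count at 10× depth. The fit falls back to the
Chao sample-coverage formula when degenerate, and a library with no
singletons is reported as saturated. Under strongly heavy-tailed contact
rates (power-law decay) 10× extrapolation is only partially identifiable
from the histogram and the estimate behaves as a lower bound; it is exact
in the uniform-rate regime where the mixture model holds. Pass thresholds
(total ≥ 1000 kept reads, cis:trans ≥ 1, ≥ 20% of the estimated pool
observed) are package defaults — the original assay's thresholds were
never published — and are configurable.

## Synthetic data

The generators emulate the statistical structure the analyses assume, not
the chemistry. A genome is an in-silico HindIII digest: inter-site gaps
are 30 bp plus an exponential, averaging the requested fragment size
(default 3 kb, close to a genomic HindIII digest); emitted sequence
carries AAGCTT exactly at the mapped sites. Ligation partners of a bait
fragment are drawn with probability ∝ distance^(−decay_exponent)
(site-to-site, from the bait junction; default exponent 1.0, the
field-standard contact-decay slope — the assay's own slope was never
published, so this is a simulation parameter, not a measured one), a
uniform trans background, planted (site, fold) enrichments, and a
per-molecule duplication probability that re-emits a pair with the same
breakpoint. R2 is synthesized from a sonication breakpoint 150–600 bp
from the junction. Truth sidecars (pair table, LAD intervals, gene
classes) are written alongside so tests compare against what was planted.

The standard simulated study used by the acceptance checks is a single
12 Mb chromosome (~4000 sites), a bait ~1 Mb in, 10⁴ pairs per bait,
decay exponent 1.0, and planted fold-50 interactions ≥3.5 Mb from the bait;
calibration runs use decay exponent 0 (uniform ligation), where the null
distribution of both contact tests is exact. `simulate_site_counts` is a
read-free shortcut that samples the same contact model directly into a
count track (the post-filter, post-dedup library) for many-seed studies.

What the generators deliberately do not model: splinkerette adapter
chemistry, primer efficiency differences, mappability and GC biases,
domain-level (multi-site) interaction structure, trans-contact biology
beyond a uniform background, and depth-coupled PCR resampling (duplication
is per-molecule). Passing tests therefore demonstrate correctness of the
statistics and bookkeeping under the stated generative model, not
robustness to artifacts real libraries may carry.

## Numerical conventions

Coordinates are 0-based half-open internally; the 1-based WIG convention
is converted only at the I/O boundary. "Within 1000 bp" and "within
100 kb" are inclusive distances from the motif's left coordinate. Window
statistics guard degenerate inputs (empty or fully tied windows → p = 1,
flagged). Binomial tails are exact; floats are written with `repr` so
tracks re-parse bit-identically. All generators are pure functions of
their seed.
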