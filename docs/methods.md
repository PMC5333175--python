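# Methods

## Coordinate model and inputs

All coordinates are 0-based half-open (UCSC database convention). BED is
consumed natively; the UCSC table dialects (cpgIslandExt, rmsk,
refGene/ensGene) are parsed with their fixed column layouts, with a leading
`bin` column autodetected by field count. Gene identity is a distinct
transcription start site: key = (chromosome, strand, TSS) with TSS = txStart on
`+` and txEnd on `−`. This is the minimal reading of TSS-based deduplication;
the same rule is applied to refGene and ensGene alike. Alu elements are rmsk
records whose repName starts with AluJ/AluS/AluY; FLAM/FRAM and other SINE
names are excluded. Strand is retained on tracks but ignored by every density
computation — nothing in the analysis conditions on strand.

## Binning

Chromosomes are tiled left to right with fixed-width bins (default 100 kb, the
resolution at which domain-scale chromatin claims live) plus one terminal
partial bin. Partial bins are excluded from statistics by default so every
usable bin shares one denominator; a gap mask further drops bins whose
assembly-gap coverage exceeds 0.5. The usable bins are the analysis'
"euchromatic" bin set — with external annotations its size depends entirely on
the gap track supplied, so no particular census number is built in.

Elements are assigned to the bin containing floor((start+end)/2). The elements
analyzed (CGIs ~1 kb, Alus ~300 bp, DHS 100–200 bp) are far smaller than the
bin, so midpoint assignment is exact up to boundary-straddling elements and
avoids the double counting an overlap rule introduces; the overlap rule remains
available. "Long L1" defaults to the top decile by length (near-full-length
copies are ~10% of the pool); an absolute ≥5 kb cut is available as an
alternative via the absolute-bounds filter.

## Statistical toolbox

**Contingency.** Presence means count ≥ 1 in a bin. The 2×2 χ² uses the
closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), df = 1; Yates correction
(subtract N/2 from |ad−bc|) is a flag, default off. Degenerate margins raise,
naming the margin.

**Correlation.** t = r√(n−2)/√(1−r²) with a two-sided p from the t
distribution at df = n−2. A `df_convention="n-1"` flag exists for replicating
reports that print that df convention; the statistic itself always uses n−2,
which is the convention the formula implies. |r| = 1 is reported as t = ±inf,
p = 0.

**Dispersion contrast.** "Clustered/exponential-like" versus
"binomial-like" count distributions are operationalized as maximum-likelihood
geometric versus Poisson fits — the discrete families with those tail
behaviors, since no continuous parameters are available for integer counts.
Verdict is heavy-tailed only when the geometric log-likelihood wins *and*
variance/mean > 1.1; the 10% overdispersion guard keeps borderline Poisson
samples (VMR fluctuates by ±√(2/n)) from flipping. Note that a mixture of
Poissons with class-dependent means is genuinely overdispersed, so
class-structured tracks (e.g. DHS) can earn a heavy-tailed verdict genome-wide
even though each class is Poisson within itself.

**ESD.** Rosner's generalized extreme studentized deviate procedure in its
two-sided form: step i removes the most mean-deviant value and compares
R_i = max|x−x̄|/s with λ_i = (n−i)·t_{p,n−i−1}/√((n−i−1+t²)(n−i+1)),
p = 1−α/(2(n−i+1)); the outlier count is the largest i with R_i > λ_i. With
max_outliers = 1 this is exactly the Grubbs test.

No multiple-testing correction is applied anywhere; all p-values are raw.

## Accessibility grouping

Bins are grouped by exact distinct grouping-track count, not quantiles: an
observed range 0..max yields at most max+1 non-empty groups, matching the way
a few hundred DHS-count clusters arise from ~30k bins. Profile regression
treats each group as one equally weighted point (a size-weighted option
exists); the zero-count group is kept by default, excludable by flag. The same
machinery serves gene-density-binned profiles by swapping the grouping track.

## Subcompartment overlay

Domains (median length about twice the bin size) are overlaid by majority
rule: a bin takes the class covering most of its length, ties broken
deterministically toward the earlier class in (A1, A2, B1, B2, B3, B4, NA).
Midpoint-of-bin labeling was rejected as more distortive at this size ratio.
B4 (25 domains, chromosome-19-specific) and NA are excluded from the overlay
statistics by default, configurable. The ANOVA observational unit is the
domain; densities are counts per 100 kb of domain length so bins and domains
share a scale. Domain lengths are not corrected for internal assembly gaps.
The F test comes from scipy, Tukey HSD adjusted p-values from statsmodels
(cross-checked in tests against scipy's independent Tukey implementation), and
the compact letter display is a greedy insert-and-absorb over the pairwise
significance matrix in descending-mean order.

## Methylation

Site score = 1000·I_meth/(I_meth+I_unmeth+100), the standard per-site scaled
beta with the 100-unit stabilizing offset — the only dialect on which the
0–1000 scale and the 400 threshold are coherent. A literal pooled-denominator
variant (one shared intensity total for all sites) is kept behind
`beta_score_pooled` for fidelity experiments; its scale depends on pool size
and is not used anywhere. CGI score is the unweighted mean of inner sites
(positions in [start, end)); with several cell lines, scores are averaged
across cell lines first, then sites — provably identical to the opposite order
on complete matrices. Classification is strict: score > 400 is
hypermethylated, exactly 400 is not. The 400 threshold is an empirical
convention, shipped as a configurable default, not a claim. Differentially
methylated CGIs are not modeled as a separate class.

## Superclusters

The scan runs on the 100 kb grid, not raw intervals, keeping the hotspot
definition at the study's resolution. A supercluster is a maximal run of bins
with ≥ min_density CGIs (default 10), tolerating ≤ max_gap_bins (default 1)
consecutive sub-threshold bins strictly inside the run, with span ≥ min_span
(default 300 kb); runs never cross chromosome boundaries. Defaults sit far
above background CGI density (genome mean ~2 per 100 kb) while a typical
500 kb hotspot of 50+ CGIs passes easily. Position classes use 2 Mb margins —
no published figure exists for "subtelomeric"/"pericentromeric", so the margin
is a documented, configurable choice; subtelomeric takes precedence when both
apply. The CGI share uses midpoints, consistent with bin counting.

## Synthetic data

The generator's defaults are the study conditions. Class geometry defaults to
the published hg19 subcompartment table (A1: 490 domains / 818 kb mean /
1217 kb sd, … , 4064 domains total); counts are scaled to the toy assembly
length. Domain lengths are drawn from a gamma matched to each class's mean/sd,
then rescaled per class so class total lengths hit their configured genome
shares exactly — the length distribution keeps its shape while the shares stop
depending on heavy-tailed draws. Domains are placed sequentially in globally
shuffled order, truncated at chromosome boundaries; uncovered tails are NA.

Per-bin counts come from a negative binomial for the clustered tracks (CGI,
gene: size 1.0; Alu: size 1.5 — chosen to reproduce published
variance-to-mean ratios of roughly 1.3–30 at the published means) and Poisson
for L1 and DHS. Per-class Alu intensities are the published values (A1 66,
A2 42, B1 44, B2 34, B3 30, B4 110 per 100 kb); CGI/gene/DHS class intensities
were chosen once so the share-weighted genome means land near the published
bin summaries (CGI 1.8, gene 2.3, DHS 101.8 per 100 kb) with density rising
from B3 to A1; L1 is uniform at 32.6. Elements are placed uniformly within
their bin — the analysis' claims live at bin resolution, so sub-bin structure
is deliberately not modeled. Methylation site scores come from a two-mode
mixture (modes 100/800, high weight 0.2, sd 50, clipped to [0, 950]) with the
mode drawn per CGI, reproducing both the U-shape and the ~20% hypermethylated
share; intensities are back-solved (total 4000) so the beta score reproduces
the drawn score exactly. A single seeded generator is threaded through all
draws; equal seeds give byte-identical fixture directories.

What the generator does *not* emulate: sequence composition, sub-bin spatial
correlation, strand structure, cell-line-specific methylation variation,
domain-state changes across cell types, and assembly gaps (the gap mask is
exercised with explicit toy gap tracks instead). Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
structure, not agreement with any particular genome's annotation.

## Problem sizes and numerics

The default synthetic study uses eight chromosomes totaling 500 Mb (5,000 bins
of 100 kb, ~700 domains, ~8,500 CGIs, ~500k DHS) — large enough for stable
class-density, slope, dispersion-family and mixture-share recovery, and the
whole suite plus the reproduction script run in well under a minute. Smaller
fixtures (120–130 Mb) back the unit tests. Ties in bin assignment, class
majority and letter grouping are all broken deterministically as documented
above; empty tracks, empty classes, constant vectors, zero margins and
zero-variance inputs either raise a named error or warn and degrade, as each
function documents.

## Known limitations

- Majority bin labeling blurs domains much smaller than a bin; domains under
  ~50 kb can be invisible in the overlay.
- The geometric/Poisson contrast is a two-family diagnostic, not a model
  selection over count distributions.
- The supercluster scan's bin quantization means cluster boundaries are only
  resolved to 100 kb, and a hotspot split across a bin edge needs the gap
  allowance to be detected as one run.
- External-genome figures that depend on specific assemblies and annotation
  compilations (exact bin censuses, genome-wide regression r values,
  chromosome-level outlier tests) are outside what synthetic data can
  reproduce; the package computes them given those inputs.
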