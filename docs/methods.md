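# Methods

This note documents the models behind each module, the tunable parameters
and their defaults, the numerical choices made where the design was open,
what the synthetic-data generators do and do not emulate, and the known
limitations.

## Synonymous divergence (teparyscan.ks)

**Alignment.** Ortholog CDS pairs are aligned globally in protein space
(BLOSUM62, gap open 10, extend 0.5, end gaps penalized) with Biopython's
`PairwiseAligner`, and each aligned residue column is projected back onto
its source codons. Columns containing a gap or an ambiguous base (N) in
either codon are dropped; a terminal stop codon is stripped before
alignment and an internal stop codon is a hard error.

**Estimator.** Ks/Ka uses Nei–Gojobori (1986) counting with Jukes–Cantor
correction rather than an ML codon model: it is fully specifiable,
verifiable against a brute-force oracle at desk scale, and at the
divergences that matter here (Ks ≤ 0.35) the peak locations — the only
quantity consumed downstream — agree closely with ML estimates. Details
that pin the arithmetic down:

- synonymous site fractions per codon position exclude changes to stop
  codons from the denominator, so s + n = 3 per codon always holds;
- multi-nucleotide codon differences are averaged over all minimal
  mutational pathways; pathways passing through a stop codon are discarded
  unless every pathway does, in which case all are used (steps into or out
  of a stop count as non-synonymous);
- the correction d = −3/4·ln(1 − 4p/3) is undefined at p ≥ 3/4; such pairs
  are flagged `saturated` and excluded from mixture fitting;
- zero observed differences give Ks = 0 even when a site class is empty.

**Mixture peaks.** Gaussian mixtures are fitted to log(Ks) — a component
mean exponentiates to a geometric-mean Ks, which reconciles mixture
modelling with reporting "the geometric mean of the peak". Values
≤ 0.001 are dropped first (rounding artefacts at tiny divergence produce
spurious peaks); at least 20 values must remain. EM runs for k = 1..4 with
evenly spaced quantile means as the first initialization plus 4 seeded
random restarts, σ floored at 10⁻⁶, and convergence declared when the
relative change in total log-likelihood falls below 10⁻⁵ (the criterion
mclust uses; an absolute tolerance makes over-specified k crawl to the
iteration cap, because the likelihood gain of a redundant component decays
but never vanishes). Fits that fail to converge within 500 iterations stop
the k-escalation — a k that cannot converge is over-specified, and larger k
only more so. The minimum-BIC model is selected with 3k−1 free parameters.

**Component merging.** Adjacent components with |μ₁−μ₂| < σ₁+σ₂ are
combined into their moment-matched weighted mixture (merged mean and
standard deviation of the Gaussian mixture). The sum-of-sds criterion is
the regime in which two Gaussians form a single skewed peak rather than two
resolvable modes; a max-sd criterion misses exactly the case it exists
for, because after BIC splits a skewed peak each component's σ shrinks
below the separation. Well-separated Ks peaks (log-separation ≈ 3.2 for
0.013 vs 0.32, σ ≈ 0.25) are never merged. The reported `peak_ks` is the
highest-weight component's geometric mean; all components are reported
alongside.

**Clock.** λ = Ks/(2T) and T = Ks/(2λ) exactly; calibration defaults in the
analysis scripts are the common bean/soybean peak (Ks 0.32, T 19.2 My).
The two operations are exact algebraic inverses, property-tested as such.

**Reciprocal best hits.** Best = maximum bitscore, ties broken by minimum
E-value then lexicographically smallest subject id (deterministic); edges
are pre-filtered at E ≤ 10⁻¹⁰. A pair is emitted iff each member is the
other's best hit.

## NLR repertoire (teparyscan.nlr)

**Two-pass universe.** The generic Pfam pass seeds the protein universe at
E < 10⁻⁶⁰ on the NB-ARC domain (per-domain independent E-value; the
full-sequence column is a defensible alternative but the independent
E-value is the stricter, per-domain quantity). A lineage-specific NB-ARC
profile pass rescues divergent domains: every protein with a profile hit
enters the universe, and its profile NB-ARC hits replace the generic ones
regardless of E — the profile re-scan exists precisely to rescue hits the
generic threshold loses.

**Classification.** Presence flags from the merged hits: T (TIR or TIR_2,
treated as equivalent), R (RPW8), C (COILS segment with probability
≥ 0.90), L (any of LRR_3/4/5/8), all at E < 1.0 except COILS. The core
class is the N-terminal letter by precedence T > R > C, then N, then L —
the eight classes are mutually exclusive, and the uncollapsed left-to-right
`domain_string` (e.g. C-N-N-L) preserves composite architectures so no
information is lost. COILS evidence is carried as a DomainHit with
probability stored as 1 − evalue, so one threshold mechanism serves both
evidence types. Motifs (P-loop GTTK, kinase-2 VLDD, ARC1 GLPL, ARC2 MHD)
are exact substring matches within an NB-ARC hit span; no mismatches.
An integrated domain is a non-canonical hit (E < 1.0) sharing no amino-acid
position with any other hit, canonical or not, COILS included.

**Clusters.** Per chromosome, NB-ARC genes in gene-rank order chain when
consecutive genes are < 200 kb apart (downstream start − upstream end,
floored at 0) and separated by ≤ 9 other gene models; maximal chains of
≥ 3 become clusters named by chromosome number plus letters in positional
order. "Between any two members" is read as between consecutive members —
the all-pairs reading would forbid clusters of more than ~11 genes.
Clusters across species are related when ≥ 1 reciprocal-best-hit pair has
a member in each. Strand is ignored throughout; the rules are positional.

## Selection scan (teparyscan.popgen)

**Per site.** With m called haplotypes (2 per diploid; a heterozygote
contributes one of each allele) and j alternate copies, the unbiased
π = 2j(m−j)/(m(m−1)); sites with m < 2 in a population are skipped for it.
Missing genotypes are first-class — all statistics are pairwise-complete
within a site and nothing is imputed.

**Windows.** 100 kb windows sliding by 10 kb, tiled from position 1 per
chromosome, last window truncated at the chromosome end (length taken from
a provided table, else the maximum site position, logged). π is the summed
site π over the window length in bp (diversity per bp); θ_W = S/(a·L) with
S the population's segregating sites in the window and a the harmonic
number of (median called haplotype count − 1) across the window's sites
(the median absorbs site-to-site missingness; the mean is one config flag
away). Windows with fewer than 5 SNPs are flagged low-confidence but not
excluded.

**Ratio tails and blocks.** The ratio π_wild/π_landrace is undefined when
both are 0 (window excluded) and +∞ when only the landrace is monomorphic —
these are precisely the complete-diversity-loss windows, and they are
always in the strict tail. Thresholds: the window ratios are resampled with
replacement 1000 times (seeded), the resamples pooled, and the 99.9%/99%
empirical quantiles taken (bootstrapping windows, not sites or individuals:
the simplest defensible reading, config-exposed). A window is a tail window
when its ratio is ≥ the threshold; a threshold equal to the distribution
minimum means the distribution is degenerate and the tail is empty. Maximal
runs of consecutive strict-tail windows (same chromosome, starts one step
apart) merge into domestication blocks spanning their union.

**Fixed differences.** A site qualifies iff it has no heterozygous call at
all, at least one call per population, and the two populations are
homozygous for opposite alleles across all called genotypes. Every fixed
difference is also labeled `fixed_difference` by the five-class SNP
classifier (poly_both / poly_wild_only / poly_landrace_only / mono_both /
fixed_difference), a cross-operation consistency that is tested.

**Gene report.** A gene overlaps a block at ≥ 1 shared bp; it is
monomorphic when none of its SNPs is polymorphic among landrace samples.
Genes with zero SNPs are a separate `no_data` class rather than
"monomorphic" — counting them would silently inflate the monomorphic tally.

## Synthetic data (teparyscan.simulate)

**Ortholog pairs.** The ancestor is codon-uniform over the 61 sense codons;
gene lengths are log-normal around the median `n_codons` (spread 0.35 by
default, floor 50) as in a real proteome — length dispersion matters
because at low divergence the per-pair substitution counts are small and
integer, and varied lengths are what smooth the Ks distribution into a
continuous peak. Each branch applies Poisson substitution events per codon
position at rate p_s·f (synonymous) and p_n·(1−f) (non-synonymous), each
event jumping to a uniformly chosen alternative of its class for the
codon's current state; p_s is therefore the per-branch synonymous
divergence per synonymous site and the planted pairwise Ks is 2·p_s. The
truth table records realized event counts over the ancestor's synonymous
sites, so the planted Ks is exact event arithmetic, independent of the
estimator. An optional indel mode deletes 1–3 codons from one descendant to
exercise alignment back-projection; deleted codons drop out of the truth.
The generator does not model transition/transversion bias, codon usage
bias, or rate variation among sites — NG86's small systematic biases under
such realism are not what the tests probe; the tests establish that the
estimator recovers what was planted, to oracle precision.

**NLR genomes.** Proteins are concatenations of random filler and domain
blocks laid out left-to-right per a per-protein architecture plan drawn
from the eight core classes (10% with double NB-ARC, 20% with an integrated
domain, 15% rescued only by the profile pass); motifs are embedded verbatim
at fixed offsets inside the first NB-ARC span, and filler is rejected until
it contains no accidental motif. Domain tables are emitted in the
domtblout dialect with planted E-values. The gene layout plants clusters
that satisfy the chaining rule by construction plus one negative control
per sub-rule (a 250 kb gap, a 10-gene insert, a two-gene group), and two
decoy proteins that must stay outside the universe. The two-species mode
reuses the plan so protein i of each species is the other's reciprocal best
hit, giving exact pairing truth. Planted E-values and coordinates are what
the rules consume; no claim is made about real HMMER score distributions.

**Two-population panels.** Defaults mirror the target panel: 16 wild + 39
landrace diploids, wild background diversity θ_bg = 0.0018/bp, a 10 Mb
two-chromosome genome, 2% missing calls. Sites are placed by a Poisson
process at density θ_bg·a(2n_wild−1) per bp; allele counts are drawn from
the neutral spectrum P(j) ∝ 1/j independently per population, which makes
E[π] = E[θ_W] hold exactly within each population (the basis of the
neutral-equilibrium check). Sites are unlinked — no coalescent, no
recombination, no linkage disequilibrium; sweep blocks are imposed, not
evolved: inside a block each site's landrace genotypes collapse, with
probability 1 − multiplier, to fixation for the wild-major allele (a
bottleneck fixes an allele segregating in the wild, and collapsing to the
minor allele would manufacture spurious fixed differences through
missingness). Planted fixed-difference sites are emitted with wild fixed
reference and landrace fixed alternate. Consequently, passing tests show
the window/bootstrap/block machinery recovers imposed diversity loss; they
say nothing about detecting sweeps against linked neutral variation.

## Problem sizes and determinism

The shipped analyses and the acceptance script use: 500 ortholog pairs of
median 300 codons for the calibration panel and 1500 pairs of median 450
codons for the low-divergence panel (dN/dS 0.2 on both); 100 seeded
replicates of 5000-value mixture panels; a 200-protein two-species NLR
genome; 10 Mb panels with three 300 kb sweeps and ten fixed sites. At these
sizes the full test suite runs in a few minutes. All randomness flows
through `numpy.random.default_rng` seeds; identical seeds give
byte-identical outputs, which the tests assert file-by-file.

## Known limitations

- NG86 with a single Jukes–Cantor correction slightly underestimates Ks at
  high divergence and saturates near p = 3/4; pairs there are flagged, not
  estimated. At Ks ≈ 0.013 with realistic gene lengths the geometric-mean
  peak sits a few percent below the planted value because per-pair counts
  are small integers truncated at the Ks > 0.001 floor.
- BIC on large samples can split a single skewed peak; the component
  merging rule addresses the common case but very heavy-tailed Ks
  distributions may still report extra components.
- The bootstrap construction (resampling windows) treats windows as
  exchangeable; overlapping windows are correlated, so the tails are
  meaningful as empirical quantiles, not as calibrated p-values.
- The NB-ARC Pfam accession (default PF00931) and every threshold are
  config-exposed; published repertoire counts depend on the proteome and
  Pfam release and are not reproduced by synthetic data.
- The cluster rule letters restart per chromosome and assume numeric
  chromosome names (digits are extracted; the raw name is the fallback).
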