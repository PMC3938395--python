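# Methods

## Model and procedure

The statistic underlying every call is the within-window distribution of
identity by state. For two individuals with called genotypes g_a, g_b ∈
{0, 1, 2} (alt-allele counts) at a site, the IBS state is 2 − |g_a − g_b|:
IBS2 for identical genotypes, IBS0 for opposite homozygotes, IBS1
otherwise. Chromosomes are tiled with non-overlapping half-open windows
of fixed physical size; within a window the site fractions P0, P1, P2 of
the three states are computed. P0 + P1 + P2 = 1 for every retained
window.

If two individuals share at least one haplotype identical by descent
across a window, no site in that window can be IBS0 except through
genotyping error. A window is therefore called an identity window (IW)
when P0 < P0_cutoff, with the cutoff a function of the per-genotype
error rate SE: anchored at (0, 0), (0.001, 0.004), (0.005, 0.01),
(0.01, 0.015), piecewise-linear in between, and continued with unit
slope above SE = 0.01. Two remarks on this schedule:

* At SE = 0 the strict inequality P0 < 0 would reject error-free data,
  so the zero-cutoff case uses P0 = 0. Error-free parent-offspring
  pairs then have every window an IW, as they must.
* The per-allele and per-genotype error channels give natural brackets
  1−(1−SE)^2 ≤ cutoff ≤ 1−(1−SE)^4, but the anchored schedule itself
  leaves this band at its upper anchors (0.004 exceeds 1−(1−0.001)^4 by
  6×10⁻⁶; 0.015 is well below 1−(1−0.01)^2 = 0.0199). The anchors take
  precedence — they are the values under which the validation
  experiments are defined — so the bracket is a heuristic, not an
  invariant of `p0_cutoff_for`.

Five summary statistics of a pair's window track feed a fixed-order
decision tree: the count of windows with P2 ∈ (0.8, 1] (IBD2 tracts),
a flag for whether the P2 histogram (bin width 0.05 on (0, 1]) peaks
higher on (0.8, 1] than on (0, 0.8], the IW fraction, the fraction of
IWs adjacent to another IW, and the longest IW run. Adjacency means
consecutive window index on the same chromosome; a window dropped for
low site count breaks a run, and chromosome boundaries never join runs
(no meiotic linkage across chromosomes).

Decision order: (1) IT when high-P2 windows cover ≥ 95% of the genome
(twin or duplicate sample); (2) FS when the high-P2 window count clears
a calibrated gate *or* the histogram peak flag fires; (3) otherwise the
IW fraction — ~1 for parent-offspring, halving with each degree — is
mapped through five calibrated cutpoints to PO/D2/…/D5; (4) below the
D5 cutpoint, contiguity evidence (contiguous-IW fraction or maximum
run above calibrated gates) distinguishes UD (related, degree unknown)
from UN. No call is made below 100 retained windows.

On step (2): the published description combines the peak flag AND the
count. With this package's synthetic founders the window-P2 histogram
of the IBS1 mode is much spikier than in real data (sites are drawn
independently, so window composition barely varies and there is no
LD), and for roughly a third of true sibling pairs that central mode
out-peaks the IBD2 mode. The high-P2 count separates siblings from
parent-offspring pairs by two orders of magnitude on its own, so it is
the primary gate and the peak flag is supplementary. On real data the
two gates agree.

## Calibration

Thresholds are fitted from labeled pairs of a single simulated family
(including self-pairs, which supply the IT class) by one-dimensional
decision stumps: for each adjacent class pair the cut maximises
training accuracy, with ties broken toward the midpoint between the
class ranges — for cleanly separated classes this is exactly the range
midpoint. Pairs of 6th degree and beyond calibrate the UD-vs-UN
contiguity gates against the unrelated pairs (founder spouses). The
fitted cutpoints are forced strictly decreasing across degrees. The
packaged default thresholds were produced by
`scripts/build_default_thresholds.py` (seed 20140228, SE = 0, the
desk-scale WGS condition below).

## Simulator

Founder haplotypes are drawn site-independently: site positions uniform
over the GRCh37 autosomes, alt-allele frequencies from Beta(0.5, 0.5)
(configurable), alleles Bernoulli(frequency) per haplotype. Meiosis
places Poisson(length × rate) crossovers per chromosome, uniformly
positioned, no interference, with a uniform 1 cM/Mb map (rate 10⁻⁸ per
bp). Gene dropping proceeds in topological order, one recombinant
gamete per parent. The error channel replaces a genotype, with
probability SE per genotype per individual, by one of the other two
codes uniformly. A single integer seed fixes everything.

The packaged 26-member, 7-generation pedigree (10 founders) provides,
per family: 7 full-sibling, 32 parent-offspring, 40 second-degree, and
8–34 pairs of each degree 3–7, plus 45 within-family unrelated founder
pairs. Replicate families are simulated on one shared site panel so
that founders of different replicates form unrelated test pairs.

### What the generator does and does not emulate

It reproduces the segment-level structure that the window statistics
measure: Mendelian transmission, recombination-limited IBD segment
lengths, and genotyping error at a controlled rate. It does not model
linkage disequilibrium, population structure or cryptic founder
relatedness, variable recombination intensity, or caller-specific
artifacts. Two consequences matter for interpreting the validation
numbers. First, synthetic unrelated pairs have an almost perfectly
clean IW track, so the calibrated contiguity gates are permissive
(longest-run gate ≈ 2 windows) and distant-relationship detection runs
*higher* here than on data with real founders — 6th/7th-degree
detection rates should be read as an upper envelope. Second, window
P2 distributions are tighter than in real data (see the FS gate note
above). Close-relationship accuracies (degrees 1–2, unrelated) are
insensitive to these differences.

## Study conditions and numerical choices

The validation studies use five replicate families, 1.5 million shared
biallelic SNVs (~520 sites per 1 Mb window), windows of 1 Mb, and a
minimum of 10 sites per retained window (5 suggested for 2 Mb array
windows). The site count is a deliberate desk-scale reduction of the
~3.5M-site WGS condition, chosen so that the count-threshold behaviour
of the cutoff schedule matches full scale: at P0_cutoff = 0.015 a
window tolerates ~7 IBS0 sites (not 0–2, which a much sparser panel
would force), and the chance that an unrelated pair shows two
*adjacent* spurious IWs stays ≪ 1 per genome. With ~520 sites per
window, the SE = 0 condition is exact (an IW requires literally zero
IBS0 sites) and the SE = 0.01 condition keeps the noise-IW rate near
1×10⁻⁴ per window. A full five-family study runs in about two minutes
per error condition on one CPU.

Tie-breaks and degenerate inputs: sites duplicated at one (chrom, pos)
keep the first occurrence; the last window of a chromosome may be
short and is retained when it meets the site floor; P2 = 0 windows are
outside the histogram domain of the peak flag; self-pairs compare a
sample against itself (P2 ≡ 1 by construction, including under the
error channel, since the same calls are compared). Unknown-degree
truth labels (D6, D7, …) are never emitted by the classifier — the
call set stops at D5 + UD — but are used as calibration evidence.

Degrees of relationship follow the kinship convention: the kinship
coefficient φ is computed recursively on the pedigree and the degree is
round(−log2 2φ); parent-offspring and full siblings are both 1st
degree, distinguished by the direct parental link.

## Known limitations

* PED/MAP/TPED inputs carry no REF/ALT polarity; the first observed
  allele is taken as reference. IBS statistics are invariant under
  per-site polarity flips, so calls are unaffected.
* The X chromosome is excluded by default (hemizygosity changes IBS
  expectations); the chromosome include-list is configurable.
* Degree estimates beyond the 5th are intentionally out of scope: the
  tree reports UD when contiguity shows relatedness without a reliable
  degree. Likelihood methods over IBD segments are the right tool
  there.
* Accuracies for degrees 3–5 depend on Mendelian sampling variance and
  overlap between adjacent degrees; exact-degree accuracy decays with
  degree while within-one-degree accuracy stays near 1.
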