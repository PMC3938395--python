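# grab

Genetic **R**elationship estimation by **A**veraged **B**locks: infer the
degree of relationship between pairs of individuals directly from
whole-genome variant calls, without phasing or population allele-frequency
panels, plus the gene-dropping pedigree simulator used to calibrate and
validate the classifier.

## Who this is for

Family-genomics and cohort QC workflows: validating reported pedigrees,
flagging sample swaps and duplicate inclusions, and finding unreported
relatives before association analyses. The method is designed for
WGS-scale callsets (~3.5M biallelic SNVs per individual), where per-site
noise is higher than on curated genotyping arrays, and also works on
high-density array data.

## The method

For a pair of individuals, every co-called biallelic SNV is assigned an
identity-by-state (IBS) status: IBS2 (identical genotypes), IBS1 (one
shared allele), or IBS0 (opposite homozygotes). The genome is tiled with
non-overlapping windows — 1 Mb for WGS, 2 Mb for arrays — and within each
window the IBS fractions P0, P1, P2 are computed. Averaging over a window
acts as a low-pass filter: isolated genotyping errors are absorbed while
the long-range signal of identity by descent (IBD) survives.

A window is an **identity window (IW)** when P0 < P0_cutoff: sharing at
least one haplotype across a window forbids opposite homozygotes, up to
genotyping error. The cutoff follows the per-genotype error rate SE on
the schedule (SE, P0_cutoff) = (0, 0), (0.001, 0.004), (0.005, 0.01),
(0.01, 0.015), interpolated in between.

Five statistics of the window track feed a decision tree:

| statistic | captures |
|---|---|
| `n_high_p2` — windows with P2 ∈ (0.8, 1] | IBD2 tracts (siblings, twins) |
| `peak_flag` — P2 histogram peaks high | sibling IBD2 component |
| `n_iw` / `n_windows` — IW fraction | ≈1 for parent-offspring, halves per degree |
| `frac_contig_iw` — IWs adjacent to an IW | genuine IBD segments vs noise |
| `max_run` — longest IW run | segment length, shrinks with distance |

The tree emits IT (twin/self), FS, PO, D2–D5, UD (related, degree
unknown) or UN (unrelated). Thresholds are calibrated on one simulated
family and reused; the packaged defaults were produced this way from a
seed-fixed simulation (`scripts/build_default_thresholds.py`).

The simulator draws founder haplotypes from a Beta(0.5, 0.5) allele
frequency spectrum, gene-drops them through an arbitrary pedigree with
Poisson-distributed crossovers (1 cM/Mb), and perturbs genotypes with a
symmetric per-genotype error channel. The packaged 26-member,
7-generation pedigree contains full-sibling, parent-offspring and 2nd-
through 7th-degree pairs.

## Worked example

Simulate a family on a small genome, then estimate every pairwise
relationship:

```sh
printf '1\t60000000\n2\t60000000\n3\t60000000\n4\t60000000\n' > lengths.tsv
grab simulate --pedigree default --n-sites 60000 --seed 11 \
     --chrom-lengths lengths.tsv --out-prefix fam
grab estimate --input fam.vcf --pairs "A1,B1;B1,B2;A1,A2" \
     --chrom-lengths lengths.tsv --out calls.tsv
cat calls.tsv
```

```
sample1	sample2	n_windows	n_high_p2	peak_flag	n_iw	frac_contig_iw	max_run	predicted_label
A1	B1	240	6	False	240	1.0	60	PO
B1	B2	240	74	True	183	1.0	60	FS
A1	A2	240	0	False	0	0.0	0	UN
```

A1–B1 is parent and child: every one of the 240 windows shares a
haplotype, so all are identity windows (the longest run, 60, is a full
chromosome — runs never cross chromosome boundaries) and the pair is
called PO. B1–B2 are siblings: 74 windows have P2 > 0.8 — IBD2 tracts
where both haplotypes are shared — and the P2 histogram peaks in the
high region, which the tree reads as FS. A1–A2 are the founding couple:
no identity windows at all, hence UN.

Calibrating your own thresholds from labeled data:

```sh
grab simulate --pedigree default --n-sites 1500000 --seed 1 --out-prefix train
grab calibrate --input train.vcf --truth train.truth.tsv \
     --out-thresholds thresholds.txt --report report.tsv
grab estimate --input cohort.vcf --thresholds thresholds.txt --out calls.tsv
```

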