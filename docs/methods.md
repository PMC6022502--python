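# Methods

`domestiscan` detects candidate domestication regions (CDRs) by contrasting
village dogs against gray wolves with three complementary window statistics
— Hudson-estimator F_ST, pooled heterozygosity (H_P) with an ancient-dog
ΔH_P haplotype check, and the XP-CLR composite likelihood ratio — plus a
read-depth copy-number V_ST scan and permutation-calibrated GO enrichment.
Significance thresholds are not arbitrary Z cutoffs: they are percentiles of
the same statistics computed on neutral coalescent simulations of the
cohort's demographic history. This note records the models, parameter
choices, numerical conventions, and what the synthetic data do and do not
establish.

## Cohort structure and site filters

The cohort is 43 village dogs and 10 gray wolves (53 diploids, 106
chromosomes), plus 2 ancient dogs used only by the ΔH_P filter. Input sites
are biallelic SNPs with complete genotypes; sites within 5 bp of an indel in
the same VCF, triallelic records, and X-nonPAR sites with a male
heterozygote are dropped. Males contribute one chromosome to every count on
the X-nonPAR (their calls are stored as homozygous dosages). The
minor-allele filter removes sites with fewer than 3 copies of the minor
allele over the 106 modern chromosomes — a frequency cutoff of 3/106 ≈
0.028. Ancient samples never enter the MAF filter or population
frequencies.

## Window statistics

**F_ST.** Per site, with dog/wolf ALT frequencies p1, p2:

    num = (p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1)

where n1, n2 are the *haploid* sample sizes (86 and 20 on autosomes; males
count one chromosome on X-nonPAR). With per-individual n the correction
terms would double-count sampling noise and bias the estimator to about
−1/n under no differentiation; with chromosome counts the single-population
expectation is ~0, which the tests verify. Sites where both populations are
fixed for the same allele (den = 0) are excluded rather than scored 0.
Window values are the ratio of averages — mean numerator over mean
denominator — in 200-kb windows sliding by 50 kb, requiring ≥ 10 SNPs.
Z-transformation (sample sd) is done separately for autosomes + X-PAR and
X-nonPAR; the empirical outlier mode keeps Z ≥ 5 (autosome/X-PAR) or Z ≥ 3
(X-nonPAR), the calibrated mode keeps values strictly above the neutral
99th percentile.

**H_P and ΔH_P.** Pooled dog heterozygosity per window is
2·Σn_MAJ·Σn_MIN/(Σn_MAJ+Σn_MIN)², where the major/minor axis per site is
assigned within modern dogs (ties → reference allele is major) and then
frozen. ΔH_P is the change in H_P when the ancient dogs' chromosomes join
the pool under that frozen axis: ancient dogs carrying the putatively swept
(major) haplotype give ΔH_P ≤ 0 deterministically, while ancients carrying
a different haplotype add minor alleles and push ΔH_P positive. A candidate
window must have (i) H_P below the 0.1th percentile of the neutral
simulations and (ii) ΔH_P at or below a threshold taken as the 95th
percentile of the background (non-candidate) windows' ΔH_P, capped at 0.
The cap encodes the filter's intent — ancient samples must not *add*
diversity to a putatively swept window — and mirrors the fact that the
original analysis's operative ΔH_P thresholds were negative; the background
restriction keeps the percentile meaningful when a benchmark genome carries
a large planted-sweep fraction. Missing ancient calls are skipped per site.

**XP-CLR.** An independent re-implementation of the Chen, Patterson & Reich
(2010) cross-population composite likelihood framework, scored on a 2-kb
grid using the SNPs within a 50-kb window around each grid point. The
neutral model treats the dog frequency as the wolf frequency plus Brownian
drift: p1 ~ N(p2, ω·p2(1−p2)), truncated to [0,1] with atoms at the
boundaries. ω is estimated genome-wide by method of moments from
(p1−p2)²/(p2(1−p2)) and is split into a sampling component ω_s ≈ 1/(2n1) +
1/(2n2) and a drift component ω_d = ω − ω_s (floored at 5% of ω). Under a
sweep of scale s (Morgans) centred at the grid point, a lineage at genetic
distance r escapes with probability e = 1 − exp(−r/s); the dog frequency
becomes a two-component mixture (hitchhiking component at 1−e+e·p2 with
weight p2, escaped component at e·p2 with weight 1−p2) whose drift variance
scales with e² while the sampling variance does not — without that floor an
observed fixation would never favour the sweep model, since the component
mean approaches the boundary at exactly the rate its sd shrinks. The score
is 2·[max over the s grid of the composite log likelihood − the neutral
value]; s = 0 (e = 1) collapses the mixture onto the neutral model exactly,
so scores are non-negative by construction. The default s grid spans 2×10⁻⁵
to 10⁻² Morgans — footprints from a few kb to the whole SNP window at the
1 cM/Mb default map. Wolf frequencies are clamped to
[1/(2n2+1), 1−1/(2n2+1)] to keep likelihoods finite. Grid scores are
averaged in 25-kb windows sliding by 10 kb; windows with fewer than 5
scored grid points are removed; passing windows within 50 kb merge into
candidate regions. Genetic distances come from a (chrom, pos, Morgans)
anchor table with linear interpolation and terminal-rate extrapolation, or
a uniform 1 cM/Mb fallback.

## Neutral calibration

The default demographic model is a two-population split: dog Ne 30,000,
wolf Ne 20,000, ancestral Ne 35,000, split 7,500 generations (~22 kya at 3
years/generation), mutation rate 4×10⁻⁹ per site per generation,
recombination 10⁻⁸ per bp. The sizes were chosen so village-dog nucleotide
diversity lands near the observed ~5×10⁻⁴–10⁻³ per site given the 4×10⁻⁹
rate, and genome-wide dog–wolf F_ST comes out around 0.15; both matter
because the ΔH_P filter's resolution scales directly with SNP density per
window. A 10-lineage configuration with admixture pulses and bottlenecks is
supported through YAML (`configs/demography_10lineage_synthetic.yaml`, a
synthetic stand-in with round-number parameters) but the two-population
model is the tested default. Thresholds pool window values over all
replicates and take a linear-interpolation ("type 7") percentile — the
definition is fixed so thresholds are reproducible from stored values.
Simulated SNP sets pass the same MAF rule as the real data and can be
thinned uniformly at random to the real per-chromosome SNP counts
(`match_real_snps`); the default studies skip thinning because cohort and
replicates come from the same generator and densities already match.

Problem sizes (the package's defaults for tests and the acceptance script):
25 calibration replicates of a 20-Mb genome (2 × 10-Mb chromosomes),
held-out false-positive rates measured on 3 further replicates using
*disjoint* windows (step = window size) so the binomial comparison is not
distorted by sliding-window overlap, compound-cascade false positives on 10
sweep-free 20-Mb cohorts, and a 50-Mb benchmark cohort (5 × 10-Mb
chromosomes) for sweep recovery. The X chromosome is excluded from
simulation-calibrated thresholds; X windows use only the empirical Z mode.

## Synthetic cohorts and planted truth

Genotypes are neutral coalescent draws (msprime, binary mutation model,
sites kept if polymorphic). Sweeps are imposed afterwards by haplotype
overwriting: within each interval the modern dog chromosomes collapse onto
the per-site major allele, except at a residual fraction of sites
(default benchmark: 10 sweeps of 400 kb, residual 0.04, two per
chromosome). Overwriting neutral genotypes gives exact truth labels without
forward simulation. The pre-sweep dog haplotypes are stored per sweep.
Ancient samples are two held-out dog diploids sampled at time 0: carriers
are set homozygous for the swept haplotype across the interval;
non-carriers get, per chromosome, a per-site recombinant mosaic of the
stored pre-sweep haplotypes — a single intact modern haplotype would be
locally identical to the swept consensus across many 25-kb windows
(coalescent LD), which no ΔH_P threshold can detect, whereas a
millennia-separated non-carrier lineage carries ancestral diversity broken
up by recombination. Sweep removal in the non-carrier benchmark is judged
on windows fully inside each sweep; windows straddling a boundary are
dominated by neutral flanking sites and say nothing about the swept
haplotype.

What passing these benchmarks shows: the statistics, thresholds and filter
cascade behave as designed under the assumed demography, with honest
false-positive control and truth-label recovery. What they do not show:
performance under ancient-DNA damage and temporal drift (ancients here are
modern-like), reference bias, mapping artefacts, or demographic
misspecification — the real data's ΔH_P distribution is wider and shifted
relative to this emulation, which is why the published (negative) ΔH_P
thresholds are not numerically reproducible here.

## Copy number and V_ST

Depth tracks are 3-kb windows with a per-window GC fraction. The synthetic
generator emulates depth = mean_depth × (CN/2) × gc_bias(GC) × (1 + ε),
ε ~ N(0, sd); the default bias curve is unimodal, peaking at GC 0.45 with
factors in [0.6, 1.1]. GC correction bins windows by 1% GC and multiplies
by (global control mean / control mean of the window's bin), per sample;
windows whose bin holds no control window are flagged uncorrectable (NaN).
Copy number is 2 × corrected depth / per-sample control mean, so control
regions average CN 2 by construction; per-sample SNR is the control-window
mean over its sample sd. V_ST = (V_T − V_S)/V_T uses population variances
(denominator N) so identical distributions give exactly 0 and fixed
differences exactly 1; male X-nonPAR values are doubled first. Outliers
need a CN range ≥ 1.5 across samples and Z-transformed V_ST strictly above
5 (autosome/X-PAR) or 3 (X-nonPAR), with V_T = 0 windows excluded from the
transform, and only runs of more than one window are reported. The
benchmark plants a dog-specific CN-4 duplication spanning 3 windows on a
3-Mb track at 5% noise.

## Enrichment

Genes within 50 kb of a candidate region form the test set. Each term is
scored with the parent–child over-representation test in the *union*
variant (conditioning on the union of the parents' propagated gene sets;
the union/intersection choice is not specified by the cited sources, and
union is the common default). Root terms get p = 1; terms whose parents
annotate no universe gene are skipped. Calibration: N length- and
chromosome-preserving uniform shuffles of the candidate intervals
(non-overlap enforced by rejection), recomputing the test per shuffle, and
p_perm = (X_perm + 1)/(N + 1) with ties counting toward X_perm
(conservative). Reported terms need p_perm < 0.05, more than one
supporting locus, and more than one supporting gene. No global
multiple-testing correction is applied, matching the upstream procedure;
the full test count is the caveat to carry.

## Numerical conventions and degenerate inputs

Only full-size windows are emitted (terminal fragments dropped, so window
statistics stay comparable). "Within 50 kb" merging means inter-window gap
≤ 50 kb. Calibrated thresholds use strict ">" ("exceed"). Z-transformation
raises on zero variance rather than emitting NaN. Likelihoods are floored
at 1e-300 before logs. Empty windows, V_T = 0 windows, and grid points
without SNPs carry NaN/flags and are excluded from downstream thresholds.
All generators and studies are deterministic given their seed; derived
seeds stay below 2³¹.

## Known limitations

* The ΔH_P filter's per-window resolution is set by SNP density; at the
  default diversity (~20–60 post-MAF SNPs per 25-kb window) a non-carrier
  window needs at least one ancient minor allele to be detected, which the
  mosaic construction makes overwhelmingly likely but not certain.
* XP-CLR here is validated by its invariants (null reduction,
  non-negativity, monotonicity in differentiation, planted-sweep recovery),
  not by numeric identity with the original executable; absolute score
  scales differ from other implementations.
* The published genome-scale thresholds (F_ST 0.308, XP-CLR 19.78, H_P
  0.0598) arise from a 10-lineage demography and 2.2-Gb genome not
  reproducible at desk scale; the package reports its own calibrated
  thresholds under the default model instead.
* fastCN/QuicK-mer internals (multi-mapping, k-mer counting) are out of
  scope: the copy-number module consumes windowed depth from any source and
  implements the normalisation/statistics layer only.
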