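# Methods

## The linked-locus phasing model

The five sequenced *Xpr1* fragments (exon 4, the ECL3 and ECL4 loop
fragments) span ~40 kb and are treated as a single non-recombining locus:
specific alleles are only observed together in homozygous animals, which is
what licenses parsimony phasing in the first place. The algorithm is a
deterministic Clark-style chain:

1. Every fully called individual heterozygous at ≤ 1 site resolves
   trivially; its two chromosomes seed the known-haplotype set.
2. Iterating to a fixpoint over the remaining individuals (ascending
   heterozygosity, ties broken by sample id): if exactly one resolution
   into two *known* haplotypes exists it is taken; if none exists but
   exactly one known anchor forces a fully determined novel complement,
   the complement is admitted. Known-known resolutions always outrank
   known-novel ones (novel haplotypes are only admitted when parsimony
   forces them).
3. Anything else — including genotypes explicable by two different
   known pairs — is AMBIGUOUS and excluded downstream.

Ambiguity is a real outcome, not an error: a genotype heterozygous at the
three exon-4 sites *and* the ECL3 site is explained equally by I+III and by
II+IV once all four are known, and no processing order can fix that; such
samples must be dropped, mirroring the original survey's removal of one
unphaseable animal. Missing calls constrain nothing at their site; an
individual is assigned only if all consistent resolutions agree at its
called sites, and novel complements are never admitted from partially
called genotypes.

Codon contexts are strand-normalised (reference codon on the coding strand
with the site's 1-based offset), making syn/nonsyn classification
strand-invariant by construction. Indels are carried as single biallelic
presence/absence sites; they distinguish haplotypes but are excluded from
nucleotide-diversity statistics by default (the survey's small printed S
values imply the same convention).

## Neutrality statistics

All statistics are functions of the folded (or outgroup-polarised) site
frequency spectrum. π uses the exact pairwise formula; per-site π divides
by the surveyed length L, a property of the sequencing design that must be
supplied by the caller (the packaged reconstruction uses L = 507 bp, the
unique value consistent with every printed per-site diversity). Singletons
for the starred Fu & Li statistics are alleles observed exactly once,
regardless of ancestral state.

Two sets of Fu & Li variance constants circulate: the constants as printed
in Fu & Li (1993) and the Simonsen-Churchill-Aquadro (1995) corrections.
Both are implemented behind `variant=`; the 1993 set is the default
because it reproduces the published survey values exactly (it is also what
DNAsp uses). The choice changes F* by ~0.5 at n≈24, so it matters.

Significance is assessed by simulating the standard Kingman coalescent
conditioned on the observed number of segregating sites: S mutations are
dropped on a simulated genealogy proportional to branch length, the
statistic recomputed, and the two-tailed p-value taken as
(r+1)/(reps+1). This is assumption-explicit and reproducible given a seed,
unlike closed-form beta approximations. Note that for very small S the
null distribution has atom-like support, so p-values are conservative and
only approximately uniform; the uniformity self-check therefore runs at
n=20, S=8.

## Introgression detection and the two clocks

An allele is *informative* when its donor frequency is ≥ `f_donor_min`
(default 0.5) and its frequency in every non-donor population is ≤
`f_other_max` (default 0.05). The recipient population must be excluded
from the non-donor pool, otherwise the introgressed allele disqualifies
itself.

**Mutation clock.** Among recipient chromosomes homozygous for the donor
haplotype, the fraction f of alleles that differ from the informative
allele are new stepwise mutations accumulated since the pulse. The default
calibration is the single published anchor (f = 0.05 ↦ 1,200 generations)
in `nearest_anchor` mode, reproducing the original arithmetic
(1/14 ≈ 7 % ↦ 1,200 generations ≈ 400 years at 3 generations/year);
`linear` mode interpolates G(f) piecewise-linearly through multiple
anchors (proportionally through the origin below the first), which the
simulation-generated calibrations need.

**Recombination clock.** The expected donor-tract length around the focal
locus shrinks as recombination breaks it down; `tract_length_age` inverts
E[ℓ] = 1/(g(1−α)) Morgans. Two caveats are deliberate and flagged
APPROXIMATE: the observed span is the *two-sided* tract whose expectation
is 2/(g(1−α)), biasing the estimate young by up to a factor ~2; and α is
the donor-haplotype frequency at the time recombination acted, which
drifts. The clock corroborates orders of magnitude, not years.

**Genome scan.** `windowed_scan` computes S, per-site π, and Tajima's D in
successive fixed-width windows (0-based half-open; default 1 kb) from
biallelic SNP records of a VCF (multi-allelic and non-SNP records are
skipped and counted); per-site allele counts use the called chromosomes at
that site, while the window's D uses the panel's full chromosome count.
`detect_outlier_region` grows the maximal run of windows overlapping the
focal interval with π at or above a track-wide quantile (default 0.95) and
D ≥ 0.5, bridging ≤ 3 low windows. The thresholds are exposed rather than
fixed because the original region extent was read off a browser view; the
quantile must exceed the expected elevated fraction of the track (e.g. use
a lower quantile when the elevated block is a sizeable share of the
scanned region).

## The forward simulator

Discrete-generation diploid Wright-Fisher with random mating (selfing
allowed): each offspring draws two parents, each gamete receives
Poisson(ℓ_Morgans) crossovers placed uniformly on the region, and
microsatellites mutate by ±1 repeat (±2 bp, equal probability) at rate μ
per locus per generation. At `pulse_time` generations before present a
fraction α of gene copies is replaced by donor chromosomes — either the
donor founder state or, when a donor population is co-simulated, draws
from its state at the pulse generation. Ancestry is tracked as explicit
(start, end, origin) segments from the pulse onwards, so the sampled
chromosomes carry exact donor-tract boundaries; the novel-mutation count
is the number of donor-background microsatellite alleles differing from
the donor founder among sampled chromosomes. An additive viability
selection coefficient on the donor focal haplotype exists as a hook but
defaults to 0, since no value can be calibrated from the survey.

Default parameters are the study design: 9 microsatellites within 200 kb
around the focal gene, samples of 12 diploids, r = 0.5 cM/Mb (a typical
mouse autosomal rate), μ = 5 × 10⁻⁴ (a standard dinucleotide
microsatellite rate), step 2 bp. Donor founder microsatellite alleles are
offset +84 bp so donor and native spectra never collide within simulated
timescales.

What the generator does *not* emulate: population structure and migration
beyond the single pulse, selection on the introgressed haplotype, mutation
at the SNP panel itself (haplotypes are fixed founder types), allele
dropout/genotyping error, and microsatellite length homoplasy between
donor and native pools. Passing tests therefore demonstrate the
estimators' correctness under the stated model, not robustness to those
real-data complications.

### Moment checks and their exact forms

Two analytic oracles validate the engine:

- **Stepwise variance.** A single line of descent accumulates allele-size
  variance μ per generation (one ±1-repeat step at rate μ), so two
  chromosomes *from independent replicates* satisfy E[(X−Y)²] = 2μg
  repeat². Within one population the same quantity is smaller because
  lineages coalesce; the test therefore samples one chromosome per
  replicate.
- **Tract edges.** The one-sided distance from the focal locus to the
  donor-tract edge is ~Exp(g(1−α)) per side. At desk scale (N = 500,
  g = 600, pulse α = 0.1) the donor fraction drifts substantially and
  sampled tracts are size-biased toward replicates where it rose, so the
  oracle conditions on the realized path: α is taken as the tract-weighted
  trapezoid average of the pulse fraction and the sampled final frequency.
  With that correction simulation and theory agree to ~5 %; with the
  nominal α they differ by ~35 %, which is a property of drift, not an
  engine error.

## Parameter recovery

`recover_age` co-simulates donor and recipient populations (recipient:
N = 1000, pulse at 600 generations, α = 0.5, 24 diploids sampled over a
4 Mb region with the microsatellites in the central 200 kb), runs the full
estimation chain per replicate, and combines the mutation and tract clocks
by geometric mean — the mutation clock is roughly unbiased while the tract
clock is biased young by ~2, so the combination stays within ~30 % in
expectation. α = 0.5 and 24 sampled diploids keep donor-haplotype
homozygotes present in most samples (replicates without them are flagged,
never dropped); the 4 Mb region keeps ~1/(g(1−α)·r)-sized tracts from
being censored at the edges. The G(f) calibration is regenerated from the
simulator itself rather than trusting the published anchor, isolating
estimator error from calibration error; because every line of descent
spans exactly g generations, the *mean* changed-allele fraction depends
only on μ and g, so calibration runs use a small population (N = 200) with
several replicates per grid age. Observed performance at these settings:
median relative error ≈ 0.37, median bias ≈ +0.16, typically ≤ 2 flagged
replicates of 20 (recomputed by the tests and `analysis/06`).

## Numerical and formatting conventions

Panel and VCF positions are 1-based; windows, BED output and tract
coordinates are 0-based half-open. TSV files use "." for missing values.
Statistics are reported to callers at full precision and displayed rounded
to 2 decimals (survey convention); monomorphic samples yield explicit
nulls ("n.a."), never 0. Significance stars are appended only when
p-values were actually computed. All randomness flows from a single named
seed per entry point; fixture regeneration and simulation are
byte-reproducible given the seed.

## Simulation sizes used by the shipped tests and drivers

Coalescent p-values: 10⁴ replicates (acceptance), 5 × 10³ (analysis
driver). Monte-Carlo oracle means: 1.5–2 × 10³ msprime draws. Moment
checks: 50 replicates each. Recovery: 20 replicates. These sizes give
Monte-Carlo error comfortably inside each asserted tolerance.

## Known limitations

- The parsimony phaser is exact for the survey's haplotype structure but
  has no statistical model; densely heterozygous panels with many unknown
  haplotypes will return many AMBIGUOUS samples (by design).
- The fixed-S null conditions on the observed S; it is not a full
  demographic null, and p-values for very small S are conservative.
- The recombination clock's factor-2 span bias and drift sensitivity are
  documented above; its output is flagged APPROXIMATE.
- The windowed scan's Tajima's D assumes near-complete genotyping within
  a window (it uses the panel-wide n for the constants).
- The reconstruction bundle reproduces the survey's *published summaries*;
  individual-level pairings and minor-haplotype placements within Fra_MC
  are choices consistent with, not dictated by, the survey (they are
  marked as such in the fixture docstring).
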