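# Methods

`kiwisat` implements the analysis chain behind noninvasive genetic
monitoring of kiwi (*Apteryx* spp.) from low-template samples such as
fecal swabs and molted feathers: replicated ("multi-tube") microsatellite
genotyping with consensus calling and quality scoring, genotyping-error
estimation, diversity and probability-of-identity statistics, ZW
fragment-size sexing, ordination of genotypes, and qPCR-based DNA
quantification and inhibition QC. This note records the models, the
defaults and why they were chosen, and what the synthetic-data generator
does and does not emulate.

## Consensus genotyping and the quality index

Each sample × locus is amplified in `R` replicates (default 4). A
heterozygote A/B is called when A and B each appear in at least
`het_min = 2` positive replicates; a homozygote A/A when A appears in at
least `hom_min = 3` positive replicates and no second allele reaches
`het_min`; three or more alleles reaching `het_min` is an irresolvable
conflict and yields a missing call with a flag (never an exception). The
thresholds follow common multi-tube practice at R = 4 — two independent
confirmations of each heterozygous allele, three of a homozygous one —
and are configurable because published protocols vary. When a
high-quality reference profile of the same individual exists (e.g. from a
plucked feather), it overrides the replicate-based call and replicates
are scored against it.

The quality index (QI) scores each replicate 1 if its full genotype
equals the consensus and 0 otherwise. Failed amplifications score 0
rather than being excluded: QI is a sample-quality measure and a
replicate that produced nothing is evidence of poor template. A locus
whose consensus is missing contributes 0 for every replicate (nothing can
match an undefined call); a sample with no consensus-defined locus at all
has undefined (NaN) QI. QI(sample, locus) is the mean over replicates,
QI(sample) the mean over loci, and the dataset value the mean ± SD over
samples. A genotype is classed successful when QI ≥ 0.75 (inclusive);
the threshold is a convention, exposed as a parameter.

## Error rates

Errors are discrepancies of each replicate to its consensus (or
reference) profile:

- **Allelic dropout (ADO)** — among positive replicates at sample-loci
  with a *heterozygous* consensus, the fraction showing exactly one
  consensus allele and no other.
- **False alleles (FA)** — among positive replicates at sample-loci with
  a defined consensus, the fraction containing at least one allele absent
  from the consensus. Tool conventions differ on the denominator, so
  `fa_denominator="het"` restricts it to heterozygous consensus; the
  default `"all"` uses every consensus-defined sample-locus.
- **Amplification failure** — failed replicates over all replicates.

"Across loci" and "across samples" summaries are unweighted means of the
defined per-locus / per-sample rates; a locus with no heterozygous
consensus has undefined (NaN) ADO, never zero. Samples whose consensus is
missing at more than 2 loci are removed before population-level analysis
(configurable `max_failed_loci`).

## Diversity and probability of identity

Allele frequencies are simple counts over 2 × typed individuals per
population × locus. He = 1 − Σp², with the 2N/(2N−1) small-sample
variant behind a flag (the uncorrected form is the default; the choice is
not identifiable from typical published tables). Ho is the observed
heterozygote fraction, and FIS = (He − Ho)/He per locus, undefined at
monomorphic loci and excluded from the mean. Because species-level tables
in the literature are ambiguous about whether FIS is averaged per locus
or formed from mean He and Ho — the two disagree whenever locus sets
differ — both estimators are reported (`fis_mean_loci`,
`fis_ratio_of_means`). Private alleles are counted on frequency support
(> 0) with no minimum-frequency filter.

Per-locus identity probabilities use the standard unbiased-population
forms (s2 = Σp², s4 = Σp⁴):

    PI      = 2·s2² − s4
    PIsibs  = 0.25 + 0.5·s2 + 0.5·s2² − 0.25·s4

both verified in the test suite against exhaustive enumeration of
genotype pairs (PI) and of parental genotype pairs with Mendelian
offspring distributions (PIsibs) to 1e-12. Multilocus values are products
over loci in panel order by default (an explicit order or
most-informative-first is available); named loci can be excluded, e.g.
the five lowest-QI markers of a panel or a locus that fails in one
species. The sex-linked locus may be included with frequencies computed
from all observed fragments — mirroring "all 23 loci" accounting
despite its non-HWE behavior — or excluded by leaving it out of the
genotype table passed in.

## Sexing

Birds are ZW: the sex locus yields a 92 bp W fragment in all five kiwi
species and species-specific Z fragments (96/98/100 for *A. mantelli*,
96/98 for *A. australis*, 96 for *A. rowi*, 94 for *A. owenii* and
*A. haastii*; the 98 and 100 bp alleles are restricted to particular
lineages and are annotated, not rejected, outside them). Any positive
replicate containing the W size calls a female. A male call requires at
least `min_pos_male = 2` W-free positive replicates showing a Z-pool
fragment: dropout in a ZW system can only fabricate males, never
females, so a single W-free replicate is reported `ambiguous` rather
than `male`. Fragments are matched exactly in integer bp after ladder
binning; no ±1 bp tolerance is applied by default. Fragments outside
the species pool are flagged.

## Genotype matching

All sample pairs are compared as unordered allele pairs at their shared
typed loci; pairs with ≤ `max_mismatch` mismatches over ≥
`min_shared_loci` shared loci are flagged as the same individual. The
expected number of matching unrelated pairs is Σ_pairs Π_l PI_l, which
the tests verify by simulation.

## Ordination

The pairwise metric is the Smouse–Peakall codominant squared distance,
computed as half the squared Euclidean distance between allele-count
vectors, which reproduces the canonical case table (0/0/1/1/2/3/4).
Loci untyped in either member of a pair are skipped; with
`scaling="mean"` the sum is rescaled by (total loci / shared loci) so
incomplete noninvasive genotypes (admitted if they pass the
≤ 2-failed-loci filter) remain comparable — spreadsheet-tool
interpolation of missing data is deliberately not replicated. PCoA
Gower-centers −½d², eigendecomposes symmetrically, scales eigenvectors
by √eigenvalue, reports negative eigenvalues and drops their axes, and
expresses per-axis variance as a share of the positive-eigenvalue sum.

## qPCR quantification and inhibition

The standard curve is a least-squares fit of Cq on log10(concentration)
over ≥ 3 distinct standards (default simulation: ten serial dilutions
from 5 to 0.002 ng/µl in triplicate); efficiency 10^(−1/slope) − 1
warns outside [0.9, 1.1]. Replicate Cqs are averaged on the Cq scale
before back-transform (matching how plate software reports "average
Cq"), with the replicate-wise back-transformed SD as spread. The
inhibition statistic is ΔCq = mean spiked-sample Cq − mean spike-only
control Cq; failed spiked wells are imputed Cq = 45 (the total cycle
count) so a fully inhibited sample reads maximally inhibited; ΔCq > 0
flags inhibition (threshold configurable; the spike contribution cancels
because spiked wells are compared to spike-only controls). The
target-to-total ratio divides qPCR target DNA (pg/µl) by fluorometric
total DNA (ng/µl) as a percentage; total DNA is an input column, not
modeled.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes:
populations (species or lineages) with Dirichlet-distributed allele
frequencies over per-locus size ladders, planted private alleles whose
support is disjoint across populations, HWE-with-inbreeding genotypes
(P(AA) = p² + fp(1−p), P(AB) = 2pq(1−f), applied per locus
independently — no identity disequilibrium), and a per-replicate error
process: failure empties the replicate with `fail_prob`; a heterozygous
replicate loses one uniformly chosen allele with `ado_prob` (per
replicate, not per allele, so the replicate-scored ADO estimator targets
`ado_prob` directly and recovery is exact in expectation); with
`fa_prob` a positive replicate gains a stutter-like artifact one repeat
unit from a true allele, never equal to a true allele and clipped to the
locus range. Sex-linked dropout uses the same `ado_prob` with W and Z
equally likely to drop. Default error rates in examples and fixtures
follow the ranges reported for noninvasive kiwi samples (failure
6–28%, ADO 12–25%, FA 0.3–1.9%); the parameter-recovery suite uses
the fecal-swab-like point (fail 0.06, ADO 0.20, FA 0.01) at 200 samples
× 23 loci × 4 replicates, sized so three Monte Carlo SEs resolve the
rates in seconds of runtime. qPCR plates place Cq on the log-linear
curve with Gaussian noise and optional per-sample inhibition shifts.

What the generator does **not** emulate: peak heights or
electropherograms (so no height-aware calling), degradation gradients
along fragment size, locus-specific error heterogeneity, null alleles,
linkage or identity disequilibrium, and relatedness structure within
populations. Passing tests therefore demonstrate the estimators are
correct for the stated observation model, not that real noninvasive
data meet that model.

## Numerical and design notes

- Frequency vectors must sum to 1 within 1e-9; PI formulas are
  enumeration-verified to 1e-12.
- PCoA treats eigenvalues within ±1e-8 of zero as null axes.
- Consensus conflicts, all-failed loci, undefined rates and undefined QI
  are represented as flagged missing values, never silent zeros.
- Tables are plain CSV with one header row, empty fields for missing
  values, and semicolon-joined allele sizes within a replicate field;
  writers are byte-deterministic and a GenAlEx-style two-column-per-locus
  export is provided for interoperability.
- All simulation entry points take integer seeds; identical seeds give
  byte-identical output tables.

## Known limitations

- No probabilistic (likelihood-based) genotype calling; the threshold
  rules are transparent but discard peak-level information.
- No exact HWE tests, F-statistics beyond FIS, rarefied allelic
  richness, AMOVA, assignment tests, or parentage inference.
- GenAlEx's version-dependent missing-data interpolation in distances is
  not reproduced; the rescaling documented above is used instead.
- Fluorometer calibration is out of scope; total DNA is taken as given.
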