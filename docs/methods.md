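# Methods

## Problem and model

`haploscreen` screens phased, imputed SNP-array cohorts for probable
carriers of a rare disease-causing variant (DCV) with a known founder
effect. The DCV itself is usually untyped and too rare to impute, but every
carrier descending from the founder shares an identical-by-descent (IBD)
haplotype around the DCV locus. Given one or more *disease haplotypes* —
pedigree-phased haplotypes from confirmed carriers — the method asks, for
each test individual, whether either of their two phased haplotypes shows
IBD with a disease haplotype around the locus.

The statistic is a log-likelihood ratio, the **IBD score**
`ln(L1/L0)`, computed by a first-order hidden Markov model. Because the
boundaries of the shared segment are unknown, two Markov chains start at
the marker nearest the DCV ("marker 0") and extend left and right; the
pair score is the sum of the two chain values, with marker 0 counted once
(by the right chain). With several disease haplotypes for one variant, the
individual's score is the maximum over the set.

### Hidden states and emissions

The alternative model H1 has three states:

- `IBD_A`, `IBD_B` — the disease haplotype is IBD with test haplotype A or
  B. The tracked haplotype's observed allele matches the disease allele
  with probability `1 − g` and mismatches with probability `g`, where `g`
  (default 1%) absorbs genotype *and* imputation error uniformly across
  markers; the two error sources are indistinguishable at scoring time.
- `nonIBD` — sharing has ended. The state is absorbing within a chain: the
  IBD segment containing the DCV is contiguous, so once it ends it does not
  resume; re-entry would model unrelated background sharing the statistic
  does not target. Its emission marginalizes over which haplotype is read:
  the mean of the two observed alleles' population frequencies (when one
  allele is missing, the frequency of the observed one).

The null model H0 is random sharing: the mean over the two test haplotypes
of the product of their observed-allele population frequencies. Using the
mean of per-haplotype products keeps H0 and H1 conditioned on the same
observations, so the ratio is a proper contrast. No linkage disequilibrium
is modelled in either likelihood: the target IBD segments (0.5 cM and
longer) exceed typical LD-block scale. LD still shapes the *distribution*
of scores, which is why significance is assessed empirically (below).

### Transitions

The usual waiting time of an HMM is replaced by genetic-map distance. Over
an inter-marker interval of `d` Morgans and `b` base pairs:

- IBD survives with probability `exp(−k·d)`, where `k` (`decay_meioses`,
  default 20) is the expected number of meioses separating the test and
  disease haplotypes from their common founder. The default corresponds to
  roughly ten generations on each lineage, consistent with founder events
  detectable at 0.5–5 cM of residual sharing; it is exposed as a parameter.
- Conditional on survival, the chain hops between `IBD_A` and `IBD_B` with
  probability `s = min(1, r·b)`, where `r` (default one switch per
  20.05 Mbp) mirrors the block phase-switch error rate of statistical
  phasing. This lets the score survive phasing errors in the test data.
- `1 − exp(−k·d)` flows to the absorbing `nonIBD` state.

Transitions are applied between consecutive *informative* markers only,
with distance accumulated over skipped ones (per individual). This makes
"skip a marker" exactly equivalent to "delete the marker from the panel",
which would not hold if a kernel were applied at skipped markers, because
`min(1, r·b)` does not compose across subintervals.

### Missing data

A marker is skipped for everyone when the disease haplotype is missing
there, and per-individual when both test alleles are missing. When exactly
one test haplotype is missing, the marker is still used: the missing
haplotype's emission is marginalized to 1 and its null factor likewise, the
narrowest defensible reading of excluding missing genotypes.

### Chain start, termination, and the score

At marker 0 the H1 chain starts with probability ½ in each IBD state and 0
in `nonIBD` (the model conditions on the segment containing the DCV). The
cumulative LLR is tracked marker by marker; a chain terminates at the first
marker where the LLR falls `drop_threshold` (default 10) ln-units below its
running maximum, or at the window edge. The chain's value is the running
maximum and its end index is where that maximum was attained — an
operational reading of "sharing has stopped" that is robust to isolated
errors at `g = 1%`, where any fixed run of consecutive mismatches would not
be. With the absorbing mixture the LLR plateaus rather than diverging after
sharing ends, so the drop rule mostly saves computation; the reported score
is unaffected.

The left/right decomposition also fixes a symmetry convention: the left
chain excludes marker 0 (`include_origin=False`) so the marker is counted
exactly once in the pair score.

## Empirical null and calls

Under H0 the LLR would be asymptotically chi-square, but local LD makes
control scores deviate, so significance is empirical. Controls from the
same ancestral population are scored against the identical disease
haplotype set and marker panel (enforced by a panel fingerprint); the
critical value is the `ceil(p/100·n)`-th order statistic of the `n` control
scores (type-1, no interpolation — conservative: the fraction of controls
strictly above it is at most `1 − p/100`, which interpolated quantiles do
not guarantee on heavy-tailed nulls). Calls use strict exceedance
(`score > threshold`), and p-values are add-one exceedance fractions
`(1 + #{controls ≥ score}) / (n + 1)`, which cannot be zero. For large
cohorts, where the number of threshold exceedances is impractical to follow
up, the top-N ranked individuals can be taken instead (ties broken by
individual id for determinism).

Fewer than ~100 controls make the 99th percentile unstable; the package
warns below that size. With `n` controls, the expected exceedance
probability of the threshold is `(n + 1 − k)/(n + 1)` with
`k = ceil(0.99·n)` — 1.19% at `n = 503` but 1.01% at `n = 10 000` — so
calibration experiments here use large control sets to centre the
false-positive rate on 1%.

## Synthetic cohorts: what they emulate and what they do not

`synth_cohort` builds phased haplotypes as mosaics of `n_founders = 16`
founder haplotypes with founder-switch points Poisson in genetic distance
(`founder_switch_cm = 0.5`). This induces LD between nearby markers and —
critically for this method — realistic background haplotype sharing:
"unrelated" individuals share ~0.5 cM founder blocks at appreciable rates,
which is exactly the confound the empirical null exists to absorb. Marker
frequencies are drawn from a U-shaped Beta(0.8, 0.8) spectrum truncated to
[0.01, 0.99]; recorded frequencies are the realized cohort frequencies, and
markers that come out monomorphic are dropped. The genetic map is linear at
1 cM/Mb with one marker per 0.01 cM (~100 markers/cM, imputed-array
density); the default cohort size of 503 matches the European reference
control design used for screening. The DCV sits at the central marker.

What the generator does *not* emulate: coalescent-accurate allele-frequency
and LD spectra, recombination-rate variation along the chromosome,
population structure, and locus-to-locus heterogeneity of real genomes.
Power numbers on synthetic cohorts therefore demonstrate the *trends*
(power rising with sharing length, single- vs multiple-founder ordering,
gains from more disease haplotypes, 1% calibration) rather than the
absolute sensitivities attainable on real reference haplotypes; the
scenario code accepts any `PhasedCohort`, so real phased reference panels
can be substituted for full-scale replication.

## Founder-effect scenarios

A scenario (`ScenarioSpec`) implants disease haplotypes into designated
cases: 10 disease haplotypes × 5 cases each (50 cases) by default, at
sharing lengths of 0.5, 1, 2 or 5 cM, symmetric in cM around the DCV (L/2
each side — the neutral reading, matching the two-chain scorer). In
*single*-founder mode all 10 disease haplotypes copy one ancestor haplotype
over windows of length uniform between the core length (5 cM by default,
always ≥ the simulated sharing) and the panel span, spliced onto distinct
background haplotypes — guaranteeing the shared ancestral core that defines
a single founder event. In *multiple*-founder mode the 10 haplotypes are
taken verbatim from 10 distinct individuals, with no shared core. Donors
(ancestor + backgrounds, or the 10 sources) are removed from the test
cohort, leaving 492 (single) or 493 (multiple) individuals at the default
503.

After implantation the whole test cohort — cases and controls alike —
receives 1% genotype-allele flips and phase-switch errors at one switch per
20.05 Mbp (Poisson along bp, labels exchanged after each switch point).
Disease haplotypes are never passed through error injection, matching their
pedigree-phased provenance. Error order is implant → genotype errors →
phase switches, so cases carry errors like everyone else.

## Evaluation

AUPRC is computed as average precision (step-wise interpolation, via
scikit-learn), never trapezoidal over precision, which is optimistic; a
brute-force threshold sweep cross-checks it in the tests. A random
classifier's AUPRC converges to the baseline rate (cases / cohort size;
50/492 ≈ 0.1 in the default design). Two sensitivity definitions are
reported when varying the number of disease haplotypes in use:
*ancestor-aware* (only cases sharing a founder with the haplotypes in use
count in the denominator) and *all-case*; with the full set they coincide.
Thresholds are recomputed per haplotype subset from the control scores of
the identical subset. Batch parallelism is a contract, not a framework:
every disease–test pair is scored independently, and results are invariant
to chunking and individual order (tested).

## Numerical choices and problem sizes

The forward pass runs in scaled linear space (per-step normalization, log
scale accumulated), vectorized across individuals; it matches exhaustive
hidden-state path enumeration to < 1e-9 ln-units on panels up to 12
markers. Degenerate inputs are rejected at the boundary: frequencies must
lie strictly in (0, 1), the disease haplotype must be non-missing at marker
0, unphased genotypes are a hard error. The DCV snaps to the nearest marker
by bp, ties toward the lower index.

Test-suite and reproduction runs use desk scales chosen to keep the full
statistical checks meaningful: the power-trend grid uses one 503 × ~2100
marker cohort and 16 scenarios (2 modes × 4 lengths × 2 seeds); the
calibration check uses 5 000 controls and 10 000 fresh non-carriers at 800
markers; the acceptance script uses 20 000 controls and 10 000 fresh
non-carriers at ~1750 markers with 10 single-founder disease haplotypes.

## Known limitations

- `g` is uniform across markers; a refinement would let error rates depend
  on MAF and imputation quality.
- No LD in the likelihood: short IBD segments (≤ 1 cM) from old founders
  are harder to separate from background sharing.
- Carriers descending from a founder not represented among the disease
  haplotypes are undetectable by construction; the method is a screen, not
  an exhaustive carrier test, and it cannot count disease-haplotype copies.
- Allele harmonization between frequency tables and VCF handles ref/alt
  swaps (complemented, flagged) but not strand flips (dropped, counted).
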